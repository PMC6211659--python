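"""Standard curves, detection calling, inhibition and volume adjustment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from alosaedna.qpcr import (
    COMPLETE,
    NO_AMP,
    adjust_copies,
    call_detection,
    cq_to_copies,
    fit_standard_curve,
    flag_inhibition,
    is_no_amp,
    plate_qc,
    quantify,
    reaction_volume_equivalent,
)


class TestStandardCurve:
    def test_exact_inversion_of_perfect_standards(self, perfect_plate):
        curve = fit_standard_curve(perfect_plate)
        assert curve.slope == pytest.approx(-3.3219, abs=1e-9)
        assert curve.intercept == pytest.approx(40.0, abs=1e-9)
        assert curve.r2 == pytest.approx(1.0, abs=1e-12)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-3)

    def test_shifted_duplicate_fails_qc(self, perfect_plate):
        plate = perfect_plate.copy()
        idx = plate.index[plate["known_copies"] == 30][0]
        plate.loc[idx, "cq"] += 5.0
        curve = fit_standard_curve(plate)
        # oracle: recompute r^2 by hand over the 10 nonzero points
        pts = plate[plate["known_copies"] > 0]
        x = np.log10(pts["known_copies"].to_numpy(float))
        y = pts["cq"].to_numpy(float)
        b, a = np.polyfit(x, y, 1)
        resid = y - (a + b * x)
        r2_hand = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert curve.r2 == pytest.approx(r2_hand, abs=1e-12)
        assert curve.r2 < 0.98
        assert not plate_qc(curve).passed

    def test_constant_cq_gives_invalid_curve(self, perfect_plate):
        plate = perfect_plate.copy()
        plate.loc[plate["known_copies"] > 0, "cq"] = 25.0
        curve = fit_standard_curve(plate)
        assert curve.slope == 0.0
        assert not curve.valid
        with pytest.raises(ValueError):
            cq_to_copies(curve, 25.0)

    def test_single_level_is_an_error(self):
        plate = pd.DataFrame({"known_copies": [300, 300], "cq": [30.0, 30.1]})
        with pytest.raises(ValueError, match="2 distinct"):
            fit_standard_curve(plate)

    def test_failed_standard_counts_toward_qc(self, perfect_plate):
        plate = perfect_plate.copy()
        idx = plate.index[plate["known_copies"] == 30][0]
        plate.loc[idx, "cq"] = NO_AMP
        curve = fit_standard_curve(plate)
        assert curve.failed_standards == 1
        qc = plate_qc(curve)
        assert not qc.passed
        assert any("failed to amplify" in r for r in qc.reasons)

    def test_roundtrip_recovers_copies(self, perfect_plate):
        curve = fit_standard_curve(perfect_plate)
        for c in np.geomspace(30, 3e5, 25):
            cq = 40.0 - 3.3219 * math.log10(c)
            assert cq_to_copies(curve, cq) == pytest.approx(c, rel=1e-6)

    def test_lower_cq_never_fewer_copies(self, perfect_plate):
        curve = fit_standard_curve(perfect_plate)
        cqs = np.linspace(15, 39, 50)
        copies = [cq_to_copies(curve, cq) for cq in cqs]
        assert all(a >= b for a, b in zip(copies, copies[1:]))

    def test_slope_recovered_within_3_se_on_noisy_plates(self):
        # Gaussian Cq noise sigma=0.2 on duplicate 5-level standards:
        # the fitted slope should sit within 3 standard errors of the
        # generating slope in at least 95% of simulations
        rng = np.random.default_rng(12345)
        true_slope = -3.3219
        levels = np.log10(np.array([3e5, 3e4, 3e3, 300, 30]))
        x = np.repeat(levels, 2)
        ok = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = 40.0 + true_slope * x + rng.normal(0, 0.2, size=x.size)
            fit = stats.linregress(x, y)
            if abs(fit.slope - true_slope) <= 3 * fit.stderr:
                ok += 1
        assert ok / n_sim >= 0.95


class TestPlateQC:
    def test_clean_plate_passes(self, perfect_plate):
        curve = fit_standard_curve(perfect_plate)
        assert plate_qc(curve, ntc_cqs=[NO_AMP, NO_AMP]).passed

    def test_low_r2_reason_enumerated(self):
        from alosaedna.qpcr import StandardCurve
        curve = StandardCurve(slope=-3.3, intercept=40, r2=0.97, n_points=10)
        qc = plate_qc(curve)
        assert not qc.passed
        assert any("r2 below 0.98" in r for r in qc.reasons)

    def test_amplifying_ntc_fails(self, perfect_plate):
        curve = fit_standard_curve(perfect_plate)
        qc = plate_qc(curve, ntc_cqs=[35.0])
        assert not qc.passed
        assert any("template-free" in r for r in qc.reasons)


class TestDetectionRule:
    @pytest.mark.parametrize("cqs,expected", [
        ([35.1, 36.0, NO_AMP], True),
        ([38.5, NO_AMP, NO_AMP], False),
        ([39.0, 38.0, 38.0], True),   # 39.0 itself is not below 39
        ([39.0, 39.0, 38.0], False),
        ([NO_AMP, NO_AMP, NO_AMP], False),
    ])
    def test_two_of_three_below_cutoff(self, cqs, expected):
        assert call_detection(cqs) is expected

    def test_exhaustive_truth_table_vs_enumeration_oracle(self):
        # all 64 patterns of {below, at, above, NO_AMP} x 3 replicates
        values = {"below": 38.0, "at": 39.0, "above": 40.0, "no_amp": NO_AMP}
        for pattern in itertools.product(values, repeat=3):
            cqs = [values[p] for p in pattern]
            oracle = sum(p == "below" for p in pattern) >= 2
            assert call_detection(cqs) is oracle, pattern

    def test_order_invariance(self):
        for perm in itertools.permutations([35.0, NO_AMP, 38.9]):
            assert call_detection(list(perm)) is True

    def test_two_replicates_warns_but_applies_rule(self):
        with pytest.warns(UserWarning):
            assert call_detection([35.0, 36.0]) is True

    def test_empty_replicates_error(self):
        with pytest.raises(ValueError):
            call_detection([])


class TestInhibition:
    def test_three_and_a_half_cycle_shift_is_inhibited(self):
        delta, inhibited = flag_inhibition(18.0, 21.5)
        assert delta == pytest.approx(3.5)
        assert inhibited

    def test_no_shift_not_inhibited(self):
        delta, inhibited = flag_inhibition(18.0, 18.0)
        assert delta == 0.0 and not inhibited

    def test_exactly_three_cycles_is_inhibited(self):
        _, inhibited = flag_inhibition(18.0, 21.0)
        assert inhibited

    def test_no_amplification_is_complete_inhibition(self):
        delta, inhibited = flag_inhibition(18.0, NO_AMP)
        assert delta == COMPLETE and inhibited

    def test_missing_baseline_is_plate_error(self):
        with pytest.raises(ValueError, match="baseline"):
            flag_inhibition(NO_AMP, 21.0)


class TestVolumeAdjustment:
    @pytest.mark.parametrize("vol,copies,expected", [
        (1000.0, 5000.0, 5000.0),
        (500.0, 100.0, 200.0),
        (800.0, 800.0, 1000.0),
    ])
    def test_standardized_to_one_liter(self, vol, copies, expected):
        assert adjust_copies(copies, vol) == pytest.approx(expected)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            adjust_copies(100.0, 0.0)

    @pytest.mark.parametrize("args,expected", [
        ((1000, 100, 4), 40.0),
        ((1000, 100, 100), 1000.0),
        ((500, 100, 4), 20.0),
    ])
    def test_reaction_volume_equivalent(self, args, expected):
        assert reaction_volume_equivalent(*args) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(copies=st.floats(0, 1e6), vol=st.floats(1, 5000),
           k=st.floats(0.01, 100))
    def test_homogeneity(self, copies, vol, k):
        base = adjust_copies(copies, vol)
        assert adjust_copies(k * copies, vol) == pytest.approx(k * base, rel=1e-9)
        assert adjust_copies(copies, k * vol) == pytest.approx(base / k, rel=1e-9)


class TestQuantifyOrchestration:
    def _plate_with_unknowns(self, perfect_plate):
        extra = []
        for sid, cqs in [("wet", [30.0, 30.2, 30.1]),
                         ("dry", [NO_AMP, NO_AMP, NO_AMP])]:
            for cq in cqs:
                extra.append({"plate_id": "p1", "well": "", "sample_id": sid,
                              "role": "unknown", "known_copies": np.nan,
                              "cq": cq})
        baseline = 40.0 - 3.3219 * math.log10(300_000)
        extra.append({"plate_id": "p1", "well": "", "sample_id": "wet",
                      "role": "spike_control", "known_copies": np.nan,
                      "cq": baseline + 4.0})
        extra.append({"plate_id": "p1", "well": "", "sample_id": "dry",
                      "role": "spike_control", "known_copies": np.nan,
                      "cq": baseline + 0.5})
        return pd.concat([perfect_plate, pd.DataFrame(extra)], ignore_index=True)

    def test_detected_sample_quantified_and_flagged(self, perfect_plate):
        plates = self._plate_with_unknowns(perfect_plate)
        samples = pd.DataFrame({"sample_id": ["wet", "dry"],
                                "volume_ml": [500.0, 800.0]})
        quant, qc = quantify(plates, samples)
        assert qc["passed"].all()
        wet = quant.set_index("sample_id").loc["wet"]
        assert wet["detected"]
        expected = np.mean([10 ** ((cq - 40.0) / -3.3219)
                            for cq in (30.0, 30.2, 30.1)])
        assert wet["reaction_copies"] == pytest.approx(expected, rel=1e-9)
        assert wet["adjusted_copies"] == pytest.approx(2 * expected, rel=1e-9)
        assert wet["inhibited"] and wet["inhibition_delta_cq"] == pytest.approx(4.0)
        dry = quant.set_index("sample_id").loc["dry"]
        assert not dry["detected"]
        assert math.isnan(dry["adjusted_copies"])
        assert not dry["inhibited"]

    def test_missing_sample_metadata_is_error(self, perfect_plate):
        plates = self._plate_with_unknowns(perfect_plate)
        samples = pd.DataFrame({"sample_id": ["wet"], "volume_ml": [500.0]})
        with pytest.raises(KeyError, match="dry"):
            quantify(plates, samples)


def test_no_amp_sentinel_semantics():
    assert is_no_amp(NO_AMP)
    assert is_no_amp(None)
    assert not is_no_amp(39.0)
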