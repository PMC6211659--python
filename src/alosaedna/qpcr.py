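"""Standard-curve calibration and absolute quantification of eDNA qPCR plates.

Each plate carries five standards (300,000 down to 30 copies of a
synthesized CO1 oligo) plus a water blank, all in duplicate (12 standard
wells), unknown samples in triplicate, no-template controls, and one
inhibition control per sample (a 300,000-copy standard spiked with 1 µl of
the unknown).  Quantification cycle (Cq) is regressed on log10 copies;
plates with r² < 0.98 or any template-free amplification fail QC.  A water
sample is called positive when at least two of its three replicates cross
threshold strictly below cycle 39; its copy number is standardized to the
volume of water filtered (1 L) and, because 4 µl of a 100 µl elution enter
each reaction, one reaction represents 40 mL of source water.

Cq values are floats; the sentinel :data:`NO_AMP` (NaN) marks a reaction
that never crossed threshold in the observation window.  Complete
inhibition (spiked control failing to amplify at all) is reported as
:data:`COMPLETE` (infinite Cq shift).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NO_AMP",
    "COMPLETE",
    "is_no_amp",
    "Well",
    "StandardCurve",
    "PlateQC",
    "SampleQuantification",
    "STANDARD_LEVELS",
    "fit_standard_curve",
    "plate_qc",
    "cq_to_copies",
    "call_detection",
    "flag_inhibition",
    "adjust_copies",
    "reaction_volume_equivalent",
    "quantify",
]

NO_AMP: float = math.nan
COMPLETE: float = math.inf

#: Copy levels of the per-plate dilution series, highest to lowest, plus
#: the zero-copy water blank.  Run in duplicate: 12 standard wells.
STANDARD_LEVELS: tuple[int, ...] = (300_000, 30_000, 3_000, 300, 30, 0)

ROLES = ("standard", "unknown", "ntc", "cooler_blank", "spike_control")


def is_no_amp(cq: float | None) -> bool:
    """True when a Cq value is the no-amplification sentinel."""
    return cq is None or (isinstance(cq, float) and math.isnan(cq))


@dataclass
class Well:
    plate_id: str
    sample_id: str
    role: str
    cq: float
    known_copies: float | None = None
    well: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        if self.role == "standard" and self.known_copies is None:
            raise ValueError("standard wells must carry known_copies")


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Cq on log10(copies): Cq = intercept + slope * log10(c).

    ``efficiency`` is the per-cycle amplification gain implied by the
    slope, 10^(-1/slope) - 1; perfect doubling gives slope -3.3219
    cycles per decade and efficiency 1.0.
    """

    slope: float
    intercept: float
    r2: float
    n_points: int
    failed_standards: int = 0

    @property
    def efficiency(self) -> float:
        if self.slope == 0:
            return math.nan
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def valid(self) -> bool:
        return self.slope < 0


def fit_standard_curve(wells: list[Well] | pd.DataFrame) -> StandardCurve:
    """Fit the per-plate standard curve by OLS of Cq on log10 known copies.

    Zero-copy blanks are excluded from the fit.  Nonzero standards that
    failed to amplify are excluded but counted in ``failed_standards`` —
    plate QC fails on any.  Requires >= 2 distinct nonzero copy levels
    with numeric Cq.
    """
    if isinstance(wells, pd.DataFrame):
        copies = wells["known_copies"].to_numpy(dtype=float)
        cqs = wells["cq"].to_numpy(dtype=float)
    else:
        copies = np.array([w.known_copies for w in wells], dtype=float)
        cqs = np.array([w.cq for w in wells], dtype=float)
    nonzero = copies > 0
    failed = int(np.sum(nonzero & np.isnan(cqs)))
    use = nonzero & ~np.isnan(cqs)
    x = np.log10(copies[use])
    y = cqs[use]
    if len(np.unique(x)) < 2:
        raise ValueError("standard curve needs >= 2 distinct nonzero copy levels")
    if np.ptp(y) == 0:
        # all standards at one Cq: slope 0, degenerate but representable
        return StandardCurve(slope=0.0, intercept=float(y[0]), r2=0.0,
                             n_points=len(y), failed_standards=failed)
    fit = stats.linregress(x, y)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        n_points=len(y),
        failed_standards=failed,
    )


@dataclass
class PlateQC:
    passed: bool
    reasons: list[str] = field(default_factory=list)


def plate_qc(
    curve: StandardCurve,
    ntc_cqs: list[float] = (),
    r2_min: float = 0.98,
    cutoff: float = 39.0,
) -> PlateQC:
    """Per-plate acceptance: curve r² and template-free amplification.

    ``ntc_cqs`` covers both no-template controls and cooler blanks —
    any of them crossing threshold below the cutoff fails the plate.
    """
    reasons = []
    if curve.r2 < r2_min:
        reasons.append(f"standard-curve r2 below {r2_min} (r2={curve.r2:.4f})")
    if not curve.valid:
        reasons.append(f"standard-curve slope not negative (slope={curve.slope:.4f})")
    if curve.failed_standards:
        reasons.append(f"{curve.failed_standards} nonzero standard(s) failed to amplify")
    for cq in ntc_cqs:
        if not is_no_amp(cq) and cq < cutoff:
            reasons.append(f"template-free amplification (Cq={cq:g})")
    return PlateQC(passed=not reasons, reasons=reasons)


def cq_to_copies(curve: StandardCurve, cq: float) -> float:
    """Invert the standard curve: copies = 10^((Cq - intercept)/slope).

    NO_AMP maps to 0.0 (no template detected).
    """
    if not curve.valid:
        raise ValueError("standard curve invalid (slope must be < 0)")
    if is_no_amp(cq):
        return 0.0
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def call_detection(replicate_cqs, cutoff: float = 39.0) -> bool:
    """Positive-detection rule: >= 2 replicates strictly below the cutoff.

    The comparison is strict — a replicate at exactly the cutoff cycle is
    not "below" it.  Three replicates are expected; fewer are accepted
    with a warning (the >=2 rule still applies), an empty list is an error.
    """
    cqs = list(replicate_cqs)
    if not cqs:
        raise ValueError("no replicate Cq values")
    if len(cqs) != 3:
        warnings.warn(f"expected 3 replicates, got {len(cqs)}", stacklevel=2)
    return sum(1 for cq in cqs if not is_no_amp(cq) and cq < cutoff) >= 2


def flag_inhibition(
    baseline_spike_cq: float,
    spiked_sample_cq: float,
    threshold: float = 3.0,
) -> tuple[float, bool]:
    """Cq shift of the spiked 300,000-copy control, and the inhibition flag.

    delta = spiked - baseline; inhibited when delta >= threshold (3 cycles).
    A spiked control that never amplifies is complete inhibition
    (delta = COMPLETE).  A non-amplifying baseline is a plate-level error.
    """
    if is_no_amp(baseline_spike_cq):
        raise ValueError("baseline 300,000-copy standard did not amplify")
    if is_no_amp(spiked_sample_cq):
        return COMPLETE, True
    delta = spiked_sample_cq - baseline_spike_cq
    return delta, delta >= threshold


def adjust_copies(reaction_copies: float, sample_vol_ml: float) -> float:
    """Standardize a copy estimate to 1 L of filtered water.

    adjusted = (1000 mL / volume filtered) * copies.
    """
    if sample_vol_ml <= 0:
        raise ValueError("sample volume must be positive")
    return (1000.0 / sample_vol_ml) * reaction_copies


def reaction_volume_equivalent(
    sample_vol_ml: float = 1000.0,
    elution_ul: float = 100.0,
    template_ul: float = 4.0,
) -> float:
    """Millilitres of source water represented by one qPCR reaction.

    With the whole sample filtered, eluted into ``elution_ul`` and
    ``template_ul`` loaded per reaction: sample_vol * template / elution.
    The study protocol (1 L, 100 µl, 4 µl) gives 40 mL per reaction.
    """
    if min(sample_vol_ml, elution_ul, template_ul) <= 0:
        raise ValueError("all volumes must be positive")
    return sample_vol_ml * template_ul / elution_ul


@dataclass
class SampleQuantification:
    sample_id: str
    replicate_cqs: list[float]
    detected: bool
    reaction_copies: float  # NaN when not detected
    sample_vol_ml: float
    adjusted_copies: float  # NaN when not detected
    inhibition_delta_cq: float  # NaN when no spike well present
    inhibited: bool


def _mean_copies(curve, cqs, cutoff, mode):
    """Mean per-reaction copy estimate across replicates.

    mode='detected': average only replicates below the cutoff (the default;
    figure legends report "mean mtDNA copies" of amplifying reactions).
    mode='all': non-detections count as zero copies.
    """
    per_rep = [cq_to_copies(curve, cq) for cq in cqs]
    if mode == "detected":
        vals = [c for c, cq in zip(per_rep, cqs) if not is_no_amp(cq) and cq < cutoff]
        return float(np.mean(vals)) if vals else math.nan
    if mode == "all":
        vals = [c if (not is_no_amp(cq) and cq < cutoff) else 0.0
                for c, cq in zip(per_rep, cqs)]
        return float(np.mean(vals))
    raise ValueError(f"unknown mean mode {mode!r}")


def quantify(
    plates: pd.DataFrame,
    samples: pd.DataFrame,
    cutoff: float = 39.0,
    inhibition_delta: float = 3.0,
    r2_min: float = 0.98,
    mean_mode: str = "detected",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full per-plate quantification over a plate table.

    ``plates`` columns: plate_id, well, sample_id, role, known_copies, cq
    (NaN = no amplification).  ``samples`` columns: sample_id, volume_ml
    (plus any metadata, carried through).  Returns (quantifications, qc)
    where ``qc`` has one row per plate with pass/fail and reasons.

    Standards are fitted per plate, never pooled.  The inhibition baseline
    is the mean Cq of the plate's own 300,000-copy standards.  Inhibited
    samples are flagged, not dropped.
    """
    qc_rows, out_rows = [], []
    samples = samples.set_index("sample_id")
    for plate_id, plate in plates.groupby("plate_id", sort=False):
        std = plate[plate["role"] == "standard"]
        curve = fit_standard_curve(std)
        ntc_cqs = plate.loc[plate["role"].isin(["ntc", "cooler_blank"]), "cq"].tolist()
        qc = plate_qc(curve, ntc_cqs, r2_min=r2_min, cutoff=cutoff)
        qc_rows.append({
            "plate_id": plate_id, "passed": qc.passed,
            "reasons": "; ".join(qc.reasons),
            "slope": curve.slope, "intercept": curve.intercept,
            "r2": curve.r2, "efficiency": curve.efficiency if curve.valid else math.nan,
        })
        top = std[(std["known_copies"] == 300_000) & ~std["cq"].isna()]
        baseline = float(top["cq"].mean()) if len(top) else math.nan

        spikes = plate[plate["role"] == "spike_control"].set_index("sample_id")["cq"]
        for sample_id, grp in plate[plate["role"] == "unknown"].groupby("sample_id"):
            cqs = grp["cq"].tolist()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                detected = call_detection(cqs, cutoff=cutoff)
            reaction = _mean_copies(curve, cqs, cutoff, mean_mode) if (
                detected and curve.valid) else math.nan
            try:
                vol = float(samples.at[sample_id, "volume_ml"])
            except KeyError:
                raise KeyError(f"sample {sample_id!r} missing from sample table")
            adjusted = adjust_copies(reaction, vol) if detected else math.nan
            if sample_id in spikes.index:
                delta, inhibited = flag_inhibition(
                    baseline, spikes.loc[sample_id], threshold=inhibition_delta)
            else:
                delta, inhibited = math.nan, False
            out_rows.append({
                "sample_id": sample_id, "plate_id": plate_id,
                "detected": detected, "reaction_copies": reaction,
                "sample_vol_ml": vol, "adjusted_copies": adjusted,
                "inhibition_delta_cq": delta, "inhibited": inhibited,
                "plate_qc_passed": qc.passed,
            })
    quant = pd.DataFrame(out_rows)
    if len(quant):
        meta_cols = [c for c in samples.columns if c != "volume_ml"]
        quant = quant.merge(samples[meta_cols], left_on="sample_id",
                            right_index=True, how="left")
    return quant, pd.DataFrame(qc_rows)
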