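"""Synthetic data with the statistical structure the analysis assumes.

Everything the pipeline consumes can be generated here: a species-labelled
CO1 reference panel carrying the assay's geometry, qPCR plates that invert
the standard-curve model, Sanger peak tables that invert the peak-height
estimator, and whole field seasons of co-located eDNA / ichthyoplankton /
adult observations with occupancy structured by shore, lognormal copy
abundance, species-specific spawning phenology and PCR-inhibition
heterogeneity by stream type.

All randomness flows from one explicitly passed numpy Generator; identical
config + seed gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .assay import ReferenceSet, RIVER_HERRING_OLIGOS
from .qpcr import NO_AMP, STANDARD_LEVELS, quantify
from .peaks import BASES

__all__ = [
    "synthetic_reference_set",
    "synthetic_alewife_amplicon",
    "ScenarioConfig",
    "simulate_plate",
    "simulate_chromatogram",
    "simulate_survey",
    "simulate_bundle",
    "RIVERS",
]


# ---------------------------------------------------------------------------
# Synthetic CO1 reference panel
# ---------------------------------------------------------------------------

#: 1-based amplicon positions fixed for different bases in the two river
#: herring species of the synthetic panel (bp 104 is T alewife / C blueback).
DIAGNOSTIC_POSITIONS = {40: ("A", "G"), 104: ("T", "C"), 120: ("C", "T")}

AMPLICON_LENGTH = 164
_PROBE_LOOP_START = 60  # 1-based amplicon position of the beacon loop
_FLANK_5, _FLANK_3 = 160, 180  # reference sequence beyond the amplicon

# per-species mismatch design: (n sequences, fwd, rev, probe-loop substitutions)
_PANEL = {
    "alewife": (12, 0, 0, 0),
    "blueback": (12, 0, 0, 0),
    "hickory_shad": (4, 1, 1, 3),
    "american_shad": (8, 2, 2, 4),
    "atlantic_menhaden": (6, 2, 2, 2),
    "gizzard_shad": (6, 2, 1, 3),
    "atlantic_herring": (5, 3, 3, 5),
    "threadfin_shad": (2, 4, 4, 4),
    "bay_anchovy": (4, 5, 5, 6),
    "white_perch": (2, 6, 6, 7),
    "striped_bass": (4, 6, 6, 8),
    "atlantic_sturgeon": (3, 7, 7, 9),
}

_OTHER_BASE = {"A": "G", "C": "T", "G": "A", "T": "C"}


def synthetic_alewife_amplicon(seed: int = 2015) -> str:
    """The 164-bp sense-strand amplicon of the panel's alewife sequences.

    Synthetic stand-in for the published amplicon: forward-primer
    footprint at bp 1-18, the beacon loop embedded at bp 60-84, the
    reverse-primer footprint at bp 147-164, T at the bp-104 diagnostic
    site, seeded random filler elsewhere.
    """
    rng = np.random.default_rng(seed)
    oligos = RIVER_HERRING_OLIGOS
    from Bio.Seq import Seq
    amp = list(rng.choice(list("ACGT"), size=AMPLICON_LENGTH))
    amp[:18] = list(oligos.forward)
    amp[-18:] = list(str(Seq(oligos.reverse).reverse_complement()))
    loop = oligos.probe_loop
    amp[_PROBE_LOOP_START - 1: _PROBE_LOOP_START - 1 + len(loop)] = list(loop)
    for pos, (base_a, _) in DIAGNOSTIC_POSITIONS.items():
        amp[pos - 1] = base_a
    return "".join(amp)


def _mutate(seq: list[str], positions: np.ndarray) -> None:
    for p in positions:
        seq[p] = _OTHER_BASE[seq[p]]


def synthetic_reference_set(seed: int = 2015) -> ReferenceSet:
    """A synthetic 68-sequence, 12-species CO1 panel mirroring the assay.

    Synthetic stand-in for the real multi-species CO1 alignment used to
    design the assay (which must be downloaded separately).  Construction
    guarantees, by design rather than by accident:

    * every sequence spans a 164-bp amplicon region flanked by extra
      CO1-like sequence;
    * alewife and blueback herring match both primers and the beacon
      loop exactly and differ at exactly three amplicon positions
      (fixed differences), including T/C at bp 104;
    * non-target species carry increasing primer/probe mismatches, with
      Atlantic menhaden one probe mismatch fewer than hickory shad (the
      ordering behind the faint late off-target amplification seen in
      lab trials);
    * distantly related species have too many primer mismatches to
      yield an amplicon at the default search stringency.

    Within-species variation is confined to the flanks outside the
    amplicon, so amplicon columns are fixed within species.
    """
    rng = np.random.default_rng(seed)
    amp_a = synthetic_alewife_amplicon(seed)
    flank5 = "".join(rng.choice(list("ACGT"), size=_FLANK_5))
    flank3 = "".join(rng.choice(list("ACGT"), size=_FLANK_3))
    base = list(flank5 + amp_a + flank3)
    a0 = _FLANK_5  # 0-based start of amplicon in the full reference

    # base-change positions per oligo window, shared within each species
    fwd_pool = np.arange(a0, a0 + 18)
    rev_pool = np.arange(a0 + AMPLICON_LENGTH - 18, a0 + AMPLICON_LENGTH)
    loop_len = len(RIVER_HERRING_OLIGOS.probe_loop)
    loop_pool = np.arange(a0 + _PROBE_LOOP_START - 1,
                          a0 + _PROBE_LOOP_START - 1 + loop_len)
    # amplicon interior positions free for neutral interspecific change
    reserved = set(fwd_pool) | set(rev_pool) | set(loop_pool) | {
        a0 + p - 1 for p in DIAGNOSTIC_POSITIONS}
    interior_pool = np.array([i for i in range(a0, a0 + AMPLICON_LENGTH)
                              if i not in reserved])
    flank_pool = np.array(list(range(a0)) +
                          list(range(a0 + AMPLICON_LENGTH, len(base))))

    records: list[tuple[str, str]] = []
    acc = 0
    for species, (n_seqs, n_fwd, n_rev, n_probe) in _PANEL.items():
        sp_seq = list(base)
        if species == "blueback":
            for pos, (_, base_b) in DIAGNOSTIC_POSITIONS.items():
                sp_seq[a0 + pos - 1] = base_b
        if species not in ("alewife", "blueback"):
            _mutate(sp_seq, rng.choice(fwd_pool, size=n_fwd, replace=False))
            _mutate(sp_seq, rng.choice(rev_pool, size=n_rev, replace=False))
            _mutate(sp_seq, rng.choice(loop_pool, size=n_probe, replace=False))
            # background divergence in the amplicon interior and flanks
            n_bg = int(rng.integers(4, 9))
            _mutate(sp_seq, rng.choice(interior_pool, size=n_bg, replace=False))
            _mutate(sp_seq, rng.choice(flank_pool, size=12, replace=False))
        for i in range(n_seqs):
            rec = list(sp_seq)
            # private haplotype variation, flanks only
            n_priv = int(rng.integers(0, 3))
            if n_priv:
                _mutate(rec, rng.choice(flank_pool, size=n_priv, replace=False))
            acc += 1
            records.append((f"{species}|SYN{acc:05d}", "".join(rec)))
    return ReferenceSet(records=records, aligned=True)


def write_reference_fasta(refs: ReferenceSet, path) -> None:
    with open(path, "w") as fh:
        for label, seq in refs.records:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")


# ---------------------------------------------------------------------------
# qPCR plate simulator
# ---------------------------------------------------------------------------

def simulate_plate(
    truth: dict[str, float],
    rng: np.random.Generator,
    slope: float = -3.3219,
    intercept: float = 38.0,
    noise_sigma: float = 0.2,
    plate_id: str = "plate1",
    inhibition: dict[str, float] | None = None,
    obs_limit: float = 39.0,
) -> pd.DataFrame:
    """One plate inverting the quantification model.

    ``truth`` maps sample_id to true per-reaction starting copies.  The
    layout follows the protocol: five standard levels plus blanks, all in
    duplicate (12 standard wells), two no-template controls, unknowns in
    triplicate and a spiked 300,000-copy inhibition control per sample.
    Cq = intercept + slope * log10(copies) + N(0, sigma), censored to
    NO_AMP beyond the ``obs_limit`` observation window; zero copies never
    amplify.  ``inhibition`` maps sample_id to a Cq shift applied to that
    sample's unknown and spiked wells (math.inf = complete inhibition).
    """
    if slope >= 0:
        raise ValueError("curve slope must be negative")
    inhibition = inhibition or {}

    def draw_cq(copies: float, shift: float = 0.0) -> float:
        if copies <= 0 or not math.isfinite(shift):
            return NO_AMP
        cq = intercept + slope * math.log10(copies) + shift
        if noise_sigma > 0:
            cq += rng.normal(0.0, noise_sigma)
        return cq if cq <= obs_limit else NO_AMP

    rows = []
    w = 0

    def add(sample_id, role, cq, known=None):
        nonlocal w
        w += 1
        rows.append({"plate_id": plate_id, "well": f"W{w:03d}",
                     "sample_id": sample_id, "role": role,
                     "known_copies": known, "cq": cq})

    for level in STANDARD_LEVELS:
        for _ in range(2):
            if level == 0:
                add("std_blank", "standard", NO_AMP, known=0)
            else:
                add(f"std_{level}", "standard", draw_cq(level), known=level)
    for _ in range(2):
        add("ntc", "ntc", NO_AMP)
    top_cq = intercept + slope * math.log10(300_000)
    for sample_id, copies in truth.items():
        shift = inhibition.get(sample_id, 0.0)
        for _ in range(3):
            add(sample_id, "unknown", draw_cq(copies, shift))
        # spiked control: the 300k standard plus the sample extract
        if math.isfinite(shift):
            spike = top_cq + shift + (rng.normal(0.0, noise_sigma)
                                      if noise_sigma > 0 else 0.0)
        else:
            spike = NO_AMP
        add(sample_id, "spike_control", spike)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Chromatogram simulator
# ---------------------------------------------------------------------------

def simulate_chromatogram(
    p_alewife: float,
    rng: np.random.Generator,
    length: int = AMPLICON_LENGTH,
    focal: int = 104,
    bias: dict[str, float] | None = None,
    noise_cv: float = 0.0,
    base_height: float = 1000.0,
    span: int | None = None,
    sample_id: str = "",
) -> pd.DataFrame:
    """Peak-height table for a two-species mixture at the diagnostic SNP.

    Flanking positions are monomorphic with the synthetic alewife
    amplicon as the called sequence; each called peak's height is
    base_height x the base's bias factor x multiplicative lognormal
    noise of the given CV.  At the focal position the T and C heights
    are proportional to p x f_T and (1-p) x f_C — the model the
    corrected-ratio estimator inverts exactly at zero noise.  ``span``
    limits output to focal +/- span positions (None = full length).
    """
    if not 0 <= p_alewife <= 1:
        raise ValueError("p_alewife must be in [0, 1]")
    bias = dict(bias or {})
    f = {b: float(bias.get(b, 1.0)) for b in BASES}
    seq = synthetic_alewife_amplicon()[:length]
    positions = range(1, length + 1) if span is None else \
        range(max(1, focal - span), min(length, focal + span) + 1)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1 + noise_cv ** 2))

        def noise() -> float:
            return float(np.exp(rng.normal(-sigma ** 2 / 2, sigma)))
    else:
        def noise() -> float:
            return 1.0

    rows = []
    for pos in positions:
        heights = {b: 0.0 for b in BASES}
        if pos == focal:
            heights["T"] = base_height * f["T"] * p_alewife * noise()
            heights["C"] = base_height * f["C"] * (1 - p_alewife) * noise()
            called = "T" if heights["T"] >= heights["C"] else "C"
        else:
            called = seq[pos - 1]
            heights[called] = base_height * f[called] * noise()
        row = {"sample_id": sample_id, "position": pos, "called_base": called}
        row.update({f"height_{b}": heights[b] for b in BASES})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Field-season simulator
# ---------------------------------------------------------------------------

#: Tributaries sampled, with shore and stream type (piedmont streams are
#: faster-moving with less dissolved organic matter; coastal-plain streams
#: carry more PCR inhibitors).
RIVERS: dict[str, tuple[str, str]] = {
    "Choptank": ("eastern", "coastal"),
    "Nanticoke": ("eastern", "coastal"),
    "Northeast": ("eastern", "piedmont"),
    "Deer Creek": ("western", "piedmont"),
    "Gunpowder": ("western", "piedmont"),
    "James": ("western", "coastal"),
    "Mattaponi": ("western", "coastal"),
    "Pamunkey": ("western", "mixed"),
    "Patapsco": ("western", "mixed"),
    "Patuxent": ("western", "piedmont"),
    "Piankatank": ("western", "mixed"),
    "Rappahannock": ("western", "coastal"),
}


@dataclass
class ScenarioConfig:
    """Defaults emulate the study's field conditions.

    Occupancy probabilities mirror the observed shore-level detection
    rates (33% eastern, 18% western); per-occupied-site copy abundance is
    lognormal with median ~1,771 per-reaction copies spanning roughly
    1-5x10^5; alewife peak about a month before blueback; inhibition is
    commoner in coastal-plain streams, averaging near the observed 38%.
    """

    seed: int = 0
    rivers: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(RIVERS))
    sites_per_river: int = 4
    season_start: str = "2015-03-01"
    season_end: str = "2015-05-31"
    visit_interval_days: int = 7
    occupancy: dict[str, float] = field(
        default_factory=lambda: {"eastern": 0.33, "western": 0.18})
    p_alewife: dict[str, float] = field(
        default_factory=lambda: {"eastern": 0.75, "western": 0.40})
    p_both: float = 0.18
    log_copies_mu: float = math.log(1771.0)
    log_copies_sigma: float = 1.5
    peak_date: dict[str, str] = field(
        default_factory=lambda: {"alewife": "03-25", "blueback": "05-01"})
    peak_width_days: float = 14.0
    inhibition_prob: dict[str, float] = field(
        default_factory=lambda: {"coastal": 0.55, "piedmont": 0.15, "mixed": 0.35})
    complete_inhibition_frac: float = 0.10
    curve_slope: float = -3.3219
    curve_intercept: float = 38.0
    cq_noise_sigma: float = 0.2
    volume_ml: float = 800.0
    ichthyo_alpha: float = 0.05
    ichthyo_beta: float = 0.8
    ichthyo_dispersion: float = 0.6
    contamination_rate: float = 0.02
    adult_given_occupied: float = 0.45
    adult_given_empty: float = 0.03
    chromatogram_bias: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "C": 0.8, "G": 1.1, "T": 1.2})
    chromatogram_noise_cv: float = 0.10
    samples_per_plate: int = 20

    def __post_init__(self) -> None:
        for d in (self.occupancy, self.p_alewife, self.inhibition_prob):
            for k, v in d.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"probability {k}={v} outside [0, 1]")
        if self.log_copies_sigma < 0 or self.cq_noise_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        if pd.Timestamp(self.season_start) >= pd.Timestamp(self.season_end):
            raise ValueError("season_start must precede season_end")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _temporal_factor(dates: pd.Series, peak: pd.Timestamp, width: float) -> np.ndarray:
    dt = (dates - peak).dt.days.to_numpy(dtype=float)
    return np.exp(-(dt ** 2) / (2 * width ** 2))


def _draw_truth(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Site x visit grid with latent occupancy, species and true copies."""
    year = pd.Timestamp(cfg.season_start).year
    dates = pd.date_range(cfg.season_start, cfg.season_end,
                          freq=f"{cfg.visit_interval_days}D")
    rows = []
    for river, (shore, stream_type) in cfg.rivers.items():
        for s in range(1, cfg.sites_per_river + 1):
            site = f"{river.replace(' ', '')}_{s:02d}"
            for d in dates:
                rows.append((site, river, shore, stream_type, d))
    df = pd.DataFrame(rows, columns=["site_id", "river", "shore",
                                     "stream_type", "date"])
    n = len(df)
    occ_p = df["shore"].map(cfg.occupancy).to_numpy(dtype=float)
    df["occupied"] = rng.random(n) < occ_p

    pa = df["shore"].map(cfg.p_alewife).to_numpy(dtype=float)
    u = rng.random(n)
    both = rng.random(n) < cfg.p_both
    species = np.where(both, "both", np.where(u < pa, "alewife", "blueback"))
    species = np.where(df["occupied"], species, "none")
    df["species"] = species
    df["mix_alewife"] = np.select(
        [species == "alewife", species == "blueback", species == "both"],
        [1.0, 0.0, rng.uniform(0.15, 0.85, size=n)], default=np.nan)

    base = rng.lognormal(cfg.log_copies_mu, cfg.log_copies_sigma, size=n)
    peaks = {sp: pd.Timestamp(f"{year}-{md}") for sp, md in cfg.peak_date.items()}
    factor = np.ones(n)
    for sp, pk in peaks.items():
        tf = _temporal_factor(df["date"], pk, cfg.peak_width_days)
        factor = np.where(species == sp, tf, factor)
    tf_a = _temporal_factor(df["date"], peaks["alewife"], cfg.peak_width_days)
    tf_b = _temporal_factor(df["date"], peaks["blueback"], cfg.peak_width_days)
    mix = df["mix_alewife"].to_numpy()
    factor = np.where(species == "both",
                      np.nan_to_num(mix) * tf_a + np.nan_to_num(1 - mix) * tf_b,
                      factor)
    df["true_copies"] = np.where(df["occupied"], base * factor, 0.0)

    inh_p = df["stream_type"].map(cfg.inhibition_prob).to_numpy(dtype=float)
    inhibited = rng.random(n) < inh_p
    delta = np.where(inhibited, 3.0 + rng.exponential(2.0, size=n),
                     rng.normal(0.0, 0.3, size=n))
    complete = inhibited & (rng.random(n) < cfg.complete_inhibition_frac)
    delta = np.where(complete, np.inf, delta)
    df["true_inhibition_delta"] = delta
    df["sample_id"] = [f"S{i:05d}" for i in range(1, n + 1)]
    return df


def simulate_survey(
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
    return_tables: bool = False,
):
    """Simulate a field season end to end.

    Latent occupancy, species and copy abundance are drawn per site x
    visit; eDNA detection runs through the full plate pathway
    (:func:`simulate_plate` then :func:`alosaedna.qpcr.quantify`), so Cq
    noise, the 39-cycle window, the 2-of-3 rule and inhibition all act
    exactly as in the analysis.  Ichthyoplankton counts are negative
    binomial with a power-law mean in true copies (plus a small
    contamination rate of look-alike eggs at unoccupied sites); adult
    sightings are Bernoulli given occupancy.

    Returns (survey, truth) DataFrames, or (survey, truth, plates,
    samples) when ``return_tables`` to feed the file-based pipeline.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    truth = _draw_truth(cfg, rng)
    n = len(truth)

    samples = truth[["sample_id", "site_id", "river", "shore",
                     "stream_type", "date"]].copy()
    samples["date"] = samples["date"].dt.strftime("%Y-%m-%d")
    samples["volume_ml"] = cfg.volume_ml

    plate_frames = []
    for start in range(0, n, cfg.samples_per_plate):
        chunk = truth.iloc[start: start + cfg.samples_per_plate]
        plate_frames.append(simulate_plate(
            dict(zip(chunk["sample_id"], chunk["true_copies"])),
            rng=rng, slope=cfg.curve_slope, intercept=cfg.curve_intercept,
            noise_sigma=cfg.cq_noise_sigma,
            plate_id=f"plate{start // cfg.samples_per_plate + 1:03d}",
            inhibition=dict(zip(chunk["sample_id"],
                                chunk["true_inhibition_delta"])),
        ))
    plates = pd.concat(plate_frames, ignore_index=True)
    quant, _qc = quantify(plates, samples)
    quant = quant.set_index("sample_id").loc[truth["sample_id"]]

    mu = cfg.ichthyo_alpha * np.power(np.maximum(truth["true_copies"], 1e-9),
                                      cfg.ichthyo_beta)
    k = cfg.ichthyo_dispersion
    counts = rng.negative_binomial(k, k / (k + mu))
    contam = (~truth["occupied"]) & (rng.random(n) < cfg.contamination_rate)
    counts = np.where(truth["occupied"], counts,
                      np.where(contam, rng.poisson(2.0, size=n) + 1, 0))

    adult_p = np.where(truth["occupied"], cfg.adult_given_occupied,
                       cfg.adult_given_empty)
    adult = rng.random(n) < adult_p

    detected = quant["detected"].to_numpy(dtype=bool)
    species_call = np.where(detected, truth["species"].replace("none", "other"),
                            "")
    survey = pd.DataFrame({
        "site_id": truth["site_id"].to_numpy(),
        "river": truth["river"].to_numpy(),
        "shore": truth["shore"].to_numpy(),
        "stream_type": truth["stream_type"].to_numpy(),
        "date": truth["date"].dt.strftime("%Y-%m-%d"),
        "edna_detected": detected,
        "edna_copies": np.where(detected, quant["adjusted_copies"], np.nan),
        "species_call": species_call,
        "ichthyo_count": counts,
        "adult_present": adult,
        "sample_id": truth["sample_id"].to_numpy(),
        "inhibited": quant["inhibited"].to_numpy(dtype=bool),
    })
    truth_out = truth.copy()
    truth_out["date"] = truth_out["date"].dt.strftime("%Y-%m-%d")
    if return_tables:
        return survey, truth_out, plates, samples
    return survey, truth_out


def simulate_bundle(cfg: ScenarioConfig, outdir,
                    rng: np.random.Generator | None = None) -> dict:
    """Write a complete input bundle: plates, samples, peaks, survey, truth.

    Peak tables are generated for every detected sample from its true
    species mixture, with the configured base bias and height noise, so
    the apportionment stage has something real to recover.
    """
    import pathlib
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    survey, truth, plates, samples = simulate_survey(cfg, rng, return_tables=True)

    peak_frames = []
    det = survey[survey["edna_detected"]]
    mix = truth.set_index("sample_id")["mix_alewife"]
    for sid in det["sample_id"]:
        p = mix.loc[sid]
        if not np.isfinite(p):
            continue
        peak_frames.append(simulate_chromatogram(
            float(p), rng=rng, bias=cfg.chromatogram_bias,
            noise_cv=cfg.chromatogram_noise_cv, span=10, sample_id=sid))
    peaks = (pd.concat(peak_frames, ignore_index=True) if peak_frames
             else pd.DataFrame(columns=["sample_id", "position", "called_base",
                                        "height_A", "height_C", "height_G",
                                        "height_T"]))

    paths = {}
    for name, df in [("plates", plates), ("samples", samples),
                     ("peaks", peaks), ("survey", survey), ("truth", truth)]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, na_rep="NA")
        paths[name] = str(p)
    return paths
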