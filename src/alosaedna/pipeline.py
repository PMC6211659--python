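"""End-to-end orchestration: quantify -> apportion -> field statistics.

A run consumes the four input tables (plates, samples, peaks, survey),
executes every stage, and writes a report directory: quantification and
apportionment CSVs, a stats JSON, two diagnostic figures (the permutation
null of Spearman's rho, and copies over the season by species) and a
manifest recording input checksums and every parameter, so any reported
number is traceable and a rerun with the same manifest reproduces it.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as io_
from .qpcr import quantify
from .peaks import apportion_table
from . import fieldstats as fs

__all__ = ["PipelineError", "RunManifest", "run_pipeline", "survey_stats"]


class PipelineError(RuntimeError):
    """A stage failed in a way that should stop the run (e.g. plate QC)."""


@dataclass
class RunManifest:
    inputs: dict[str, str]  # path -> sha256
    parameters: dict
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def survey_stats(survey: pd.DataFrame, n_perm: int = 1000, seed: int = 0,
                 split_date: tuple[int, int] = (4, 15),
                 inhibition_groups: dict | None = None) -> dict:
    """The statistical layer over one survey table, as a JSON-able dict.

    Presence/absence agreement (Phi) between eDNA and each companion
    data set, Fisher tests on the 2x2 groupings, permutation Spearman of
    copies against counts, the early/late Mann-Whitney split per
    species, the log-log regression, and the Marascuilo procedure over
    per-river proportions (inhibition proportions when
    ``inhibition_groups`` is given, detection proportions otherwise).
    """
    edna = survey["edna_detected"].astype(bool).to_numpy()
    ich = (survey["ichthyo_count"].fillna(0) > 0).to_numpy()
    adult = survey["adult_present"].astype(bool).to_numpy()

    def xtab(u, v):
        return [[int(np.sum(u & v)), int(np.sum(u & ~v))],
                [int(np.sum(~u & v)), int(np.sum(~u & ~v))]]

    out: dict = {"n_records": int(len(survey))}
    for name, other in [("ichthyo", ich), ("adult", adult)]:
        t = xtab(edna, other)
        try:
            phi = fs.phi_coefficient(t)
        except ValueError:
            phi = math.nan
        out[f"phi_edna_{name}"] = phi
        out[f"fisher_p_edna_{name}"] = fs.fisher_exact_2x2(t)
        out[f"table_edna_{name}"] = t

    detected = survey[survey["edna_detected"].astype(bool)]
    pairs = detected[["edna_copies", "ichthyo_count"]].dropna()
    # align on all co-sampled records: copies are 0 where not detected
    copies_all = survey["edna_copies"].fillna(0.0).to_numpy(dtype=float)
    counts_all = survey["ichthyo_count"].fillna(0.0).to_numpy(dtype=float)
    try:
        sp = fs.spearman_with_permutation(copies_all, counts_all,
                                          n_perm=n_perm, seed=seed)
        out["spearman"] = {"rho": sp.rho, "p_analytic": sp.p_analytic,
                           "p_permutation": sp.p_permutation,
                           "n": sp.n, "n_perm": sp.n_perm}
        out["_spearman_null"] = sp.null_distribution
    except ValueError as exc:
        out["spearman"] = {"error": str(exc)}

    try:
        ll = fs.loglog_regression(pairs["edna_copies"], pairs["ichthyo_count"])
        out["loglog"] = asdict(ll)
    except ValueError as exc:
        out["loglog"] = {"error": str(exc)}

    out["temporal_split"] = fs.temporal_split_test(survey, split_date=split_date)
    for grouping in ("year", "shore", "river"):
        res = fs.detection_rate_tables(survey, grouping)
        out[f"detection_by_{grouping}"] = {
            "rates": res["rates"].to_dict(orient="records"),
            "fisher_p": res["fisher_p"],
        }
    if "species_call" in survey.columns:
        res = fs.detection_rate_tables(survey, "species_by_shore")
        out["species_by_shore"] = {
            "table": res["rates"].to_dict(),
            "fisher_p": res["fisher_p"],
        }

    if inhibition_groups is None:
        rates = fs.detection_rate_tables(survey, "river")["rates"]
        groups = {r.river: (int(r.hits), int(r.n)) for r in rates.itertuples()}
        out["marascuilo_basis"] = "detection proportion by river"
    else:
        groups = inhibition_groups
        out["marascuilo_basis"] = "inhibition proportion by river"
    groups = {k: v for k, v in groups.items() if v[1] > 0}
    if len(groups) >= 2:
        out["marascuilo"] = fs.marascuilo(groups).to_dict(orient="records")
    return out


def _figures(stats: dict, survey: pd.DataFrame, outdir: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    null = stats.pop("_spearman_null", None)
    if null is not None and "rho" in stats.get("spearman", {}):
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(np.asarray(null), bins=40, color="0.7", edgecolor="0.4")
        ax.axvline(stats["spearman"]["rho"], color="crimson", ls="--",
                   label=f"observed rho = {stats['spearman']['rho']:.2f}")
        ax.set_xlabel("permuted Spearman's rho")
        ax.set_ylabel("frequency")
        ax.legend()
        p = outdir / "spearman_permutation.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(p))

    det = survey[survey["edna_detected"].astype(bool)
                 & survey["edna_copies"].notna()]
    if len(det):
        fig, ax = plt.subplots(figsize=(7, 4))
        colors = {"alewife": "crimson", "blueback": "royalblue",
                  "both": "purple"}
        dates = pd.to_datetime(det["date"])
        for sp, grp in det.groupby(det.get("species_call", "all")):
            ax.scatter(dates.loc[grp.index], grp["edna_copies"],
                       s=18, alpha=0.7, label=str(sp),
                       color=colors.get(str(sp), "0.4"))
        ax.set_yscale("log")
        ax.set_xlabel("date")
        ax.set_ylabel("eDNA copies (per 1 L)")
        ax.legend(fontsize=8)
        fig.autofmt_xdate()
        p = outdir / "copies_by_date.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(p))
    return written


def run_pipeline(
    plates_path,
    samples_path,
    survey_path,
    outdir,
    peaks_path=None,
    cutoff: float = 39.0,
    inhibition_delta: float = 3.0,
    focal: int = 104,
    window: int = 8,
    minor_floor: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    split_date: tuple[int, int] = (4, 15),
    allow_qc_fail: bool = False,
) -> dict:
    """Execute quantify -> apportion -> stats and write the report bundle.

    Raises :class:`PipelineError` when any plate fails QC, unless
    ``allow_qc_fail``; failing plates' samples are then retained but
    flagged in the quantification table.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    plates = io_.read_plates_csv(plates_path)
    samples = io_.read_samples_csv(samples_path)
    survey = io_.read_survey_csv(survey_path)

    quant, qc = quantify(plates, samples, cutoff=cutoff,
                         inhibition_delta=inhibition_delta)
    failed = qc[~qc["passed"]]
    if len(failed) and not allow_qc_fail:
        raise PipelineError(
            "plate QC failed: " + "; ".join(
                f"{r.plate_id}: {r.reasons}" for r in failed.itertuples()))
    quant.to_csv(out / "quantification.csv", index=False, na_rep="NA")
    qc.to_csv(out / "plate_qc.csv", index=False, na_rep="NA")

    if peaks_path is not None:
        peaks = io_.read_peaks_csv(peaks_path)
        appo = apportion_table(peaks, quant, focal_pos=focal, window=window,
                               minor_floor=minor_floor)
        appo.to_csv(out / "apportionment.csv", index=False, na_rep="NA")

    inhibition_groups = None
    if "river" in quant.columns:
        g = quant.groupby("river")["inhibited"].agg(["sum", "count"])
        inhibition_groups = {river: (int(s), int(n))
                             for river, (s, n) in g.iterrows()}
    stats = survey_stats(survey, n_perm=n_perm, seed=seed,
                         split_date=split_date,
                         inhibition_groups=inhibition_groups)
    figures = _figures(stats, survey, out)
    with open(out / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, default=float)

    manifest = RunManifest(
        inputs={str(p): _sha256(p) for p in
                [plates_path, samples_path, survey_path] +
                ([peaks_path] if peaks_path else [])},
        parameters={"cutoff": cutoff, "inhibition_delta": inhibition_delta,
                    "focal": focal, "window": window,
                    "minor_floor": minor_floor, "n_perm": n_perm,
                    "seed": seed, "split_date": list(split_date),
                    "allow_qc_fail": allow_qc_fail},
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return {"outdir": str(out), "stats": stats, "figures": figures,
            "n_plates_failed_qc": int(len(failed))}
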