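"""Statistics comparing eDNA detections with traditional survey data.

Co-located observations — eDNA detection/copy number, ichthyoplankton
counts (standardized per sample volume) and adult presence — are compared
with the toolkit ecologists reach for on zero-inflated presence/abundance
data: the Phi coefficient for agreement of paired presence/absence
records, Fisher's exact test for 2x2 detection tables, Spearman rank
correlation with a permutation null for the quantitative association,
Mann-Whitney for the early/late seasonal split, the Marascuilo procedure
for simultaneous pairwise comparison of proportions across rivers, and
ordinary least squares on the log-log copy/count relation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "phi_coefficient",
    "fisher_exact_2x2",
    "SpearmanPermutation",
    "spearman_with_permutation",
    "marascuilo",
    "temporal_split_test",
    "detection_rate_tables",
    "loglog_regression",
]


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    return t


def phi_coefficient(table) -> float:
    """Phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) for a 2x2 table.

    Equals the Pearson correlation of the underlying 0/1 codings.
    Undefined (error) when any margin is zero.
    """
    t = _as_2x2(table)
    a, b = t[0]
    c, d = t[1]
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("phi undefined: zero margin")
    return float((a * d - b * c) / math.sqrt(math.prod(margins)))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    all tables with the observed margins no more probable than the
    observed one."""
    t = _as_2x2(table).astype(int)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class SpearmanPermutation:
    rho: float
    p_analytic: float
    p_permutation: float
    null_distribution: np.ndarray
    n: int
    n_perm: int


def _exact_spearman_p(rho_obs: float, n: int) -> float:
    """Two-sided exact p by enumeration of all rank permutations (n <= 9,
    no ties)."""
    base = np.arange(1, n + 1, dtype=float)
    base_c = base - base.mean()
    denom = float(base_c @ base_c)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = base[list(perm)] - base.mean()
        rho = float(base_c @ r) / denom
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_with_permutation(
    x, y, n_perm: int = 1000, seed: int | np.random.Generator = 0
) -> SpearmanPermutation:
    """Spearman's rho with an analytic p and a permutation null.

    Rho is Pearson correlation on average ranks (ties allowed).  The
    analytic p is exact by enumeration for n <= 9 tie-free data, else
    the t-approximation.  The permutation p shuffles y against x
    ``n_perm`` times and applies the add-one rule
    (1 + #{|rho*| >= |rho|}) / (n_perm + 1); the null draw vector is
    returned for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    rho = float(rxc @ ryc) / denom

    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 9 and tie_free:
        p_analytic = _exact_spearman_p(rho, n)
    else:
        p_analytic = float(stats.spearmanr(x, y).pvalue)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permuted(np.tile(ryc, (n_perm, 1)), axis=1)
    null = (perm @ rxc) / denom
    p_perm = (1 + int(np.sum(np.abs(null) >= abs(rho) - 1e-15))) / (n_perm + 1)
    return SpearmanPermutation(rho=rho, p_analytic=p_analytic,
                               p_permutation=p_perm, null_distribution=null,
                               n=n, n_perm=n_perm)


def marascuilo(groups: dict[str, tuple[int, int]], alpha: float = 0.05) -> pd.DataFrame:
    """Simultaneous pairwise comparison of k proportions.

    ``groups`` maps a label to (hits, n).  For each pair the statistic is
    |p_i - p_j| and the critical range is
    sqrt(chi2_{1-alpha, k-1}) * sqrt(p_i(1-p_i)/n_i + p_j(1-p_j)/n_j);
    the pair differs significantly when the statistic exceeds its range.
    All k(k-1)/2 comparisons are returned, simultaneity built in.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for label, (h, n) in groups.items():
        if n <= 0:
            raise ValueError(f"group {label!r} has n <= 0")
        if not 0 <= h <= n:
            raise ValueError(f"group {label!r} has hits outside [0, n]")
    k = len(groups)
    crit = math.sqrt(stats.chi2.ppf(1 - alpha, df=k - 1))
    props = {lab: h / n for lab, (h, n) in groups.items()}
    rows = []
    for (la, lb) in combinations(groups, 2):
        pa, pb = props[la], props[lb]
        na, nb = groups[la][1], groups[lb][1]
        r = crit * math.sqrt(pa * (1 - pa) / na + pb * (1 - pb) / nb)
        diff = abs(pa - pb)
        rows.append({"group_a": la, "group_b": lb, "prop_a": pa, "prop_b": pb,
                     "statistic": diff, "critical_range": r,
                     "significant": diff > r})
    return pd.DataFrame(rows)


def temporal_split_test(
    records: pd.DataFrame,
    split_date: tuple[int, int] = (4, 15),
    copies_col: str = "edna_copies",
    species_col: str = "species_call",
    date_col: str = "date",
    min_per_period: int = 3,
) -> dict[str, dict]:
    """Per-species Mann-Whitney comparison of copy numbers early vs late.

    Alewife spawn weeks ahead of blueback herring; splitting the season
    at April 15 ("early" = on or before the split, any year) and
    comparing detected copy numbers across the two periods per species
    tests whether the eDNA signal recovers that phenology.  Species with
    fewer than ``min_per_period`` detections in either period are
    skipped with a warning.
    """
    df = records.loc[records[copies_col].notna(),
                     [date_col, species_col, copies_col]].copy()
    dates = pd.to_datetime(df[date_col])
    month, day = split_date
    early = (dates.dt.month < month) | ((dates.dt.month == month) & (dates.dt.day <= day))
    out: dict[str, dict] = {}
    for sp, grp in df.groupby(species_col):
        e = grp.loc[early.loc[grp.index], copies_col].to_numpy(dtype=float)
        l = grp.loc[~early.loc[grp.index], copies_col].to_numpy(dtype=float)
        if len(e) < min_per_period or len(l) < min_per_period:
            warnings.warn(f"species {sp!r}: too few detections per period "
                          f"({len(e)} early, {len(l)} late); skipped", stacklevel=2)
            continue
        u, p = stats.mannwhitneyu(e, l, alternative="two-sided")
        out[sp] = {"U": float(u), "p": float(p),
                   "n_early": len(e), "n_late": len(l),
                   "median_early": float(np.median(e)),
                   "median_late": float(np.median(l))}
    return out


def detection_rate_tables(
    records: pd.DataFrame,
    grouping: str,
    detected_col: str = "edna_detected",
) -> dict:
    """Detection counts and proportions by year, shore, river or
    species x shore.

    Returns {"rates": DataFrame, "fisher_p": float or None}; the Fisher
    test is attached when the grouping yields a 2x2 table (two years,
    two shores, or the species-by-shore cross of detected samples).
    """
    df = records.copy()
    if grouping == "year":
        df["_g"] = pd.to_datetime(df["date"]).dt.year
        key = ["_g"]
    elif grouping in ("shore", "river"):
        key = [grouping]
    elif grouping == "species_by_shore":
        sub = df[df[detected_col].astype(bool)
                 & df["species_call"].isin(["alewife", "blueback"])]
        table = pd.crosstab(sub["species_call"], sub["shore"])
        fisher = fisher_exact_2x2(table.to_numpy()) if table.shape == (2, 2) else None
        return {"rates": table, "fisher_p": fisher}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rates = (df.groupby(key)[detected_col]
             .agg(hits="sum", n="count"))
    rates["proportion"] = np.where(rates["n"] > 0,
                                   rates["hits"] / rates["n"], np.nan)
    rates = rates.reset_index().rename(columns={"_g": grouping})
    fisher = None
    if len(rates) == 2:
        t = [[int(r.hits), int(r.n - r.hits)] for r in rates.itertuples()]
        fisher = fisher_exact_2x2(t)
    return {"rates": rates, "fisher_p": fisher}


def loglog_regression(
    copies, counts, zero_mode: str = "drop"
) -> "RegressionResult":
    """OLS of log10 eDNA copies on log10 ichthyoplankton counts.

    Zeros carry no information on the log scale; by default pairs with a
    nonpositive value on either side are dropped (``zero_mode='offset'``
    instead adds 1 to both variables first).  Needs >= 3 usable pairs.
    """
    from .peaks import RegressionResult, _ols
    x = np.asarray(counts, dtype=float)
    y = np.asarray(copies, dtype=float)
    if zero_mode == "offset":
        x, y = x + 1, y + 1
    elif zero_mode != "drop":
        raise ValueError(f"unknown zero_mode {zero_mode!r}")
    keep = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable pairs for log-log regression")
    return _ols(np.log10(x[keep]), np.log10(y[keep]))
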