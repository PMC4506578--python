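"""Flow-cytometry subset statistics for paired BIL/PBMC cohorts.

Inputs are per-sample CD3+ subset tables: percent alpha-beta and gamma-delta
T cells (of gated CD3+), the CD4/CD8 split of the alpha-beta subset, and
CD69+ activated fractions of each subset.  The module computes subset-ratio
summaries (median and range), paired Wilcoxon signed-rank contrasts between
compartments, and the Pearson correlation (with Fisher-z confidence interval)
between alpha-beta and gamma-delta activation.

The Wilcoxon routine uses midranks for ties, exact sign-assignment
enumeration (dynamic program over the 2^n assignments) for n <= 25 without
ties, and a tie-corrected normal approximation otherwise; all tests are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InputFormatError

REQUIRED_COLUMNS = [
    "sample",
    "compartment",
    "pct_ab",
    "pct_gd",
    "pct_cd4_ab",
    "pct_cd8_ab",
    "pct_cd69_ab",
    "pct_cd69_gd",
]

PCT_TOLERANCE = 1.0  # flow spillover tolerance on pct_ab + pct_gd <= 100


def validate_flow_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, percentage ranges, and row uniqueness."""
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise InputFormatError(f"flow table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["sample", "compartment"])
    if dup.any():
        raise InputFormatError(
            f"duplicate (sample, compartment) rows at index {list(table.index[dup])}"
        )
    pct_cols = [c for c in REQUIRED_COLUMNS if c.startswith("pct_")]
    vals = table[pct_cols].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if ((vals < 0) & finite).any() or ((vals > 100) & finite).any():
        bad = table.index[(((vals < 0) | (vals > 100)) & finite).any(axis=1)]
        raise InputFormatError(f"percentages outside [0, 100] at rows {list(bad)}")
    over = table["pct_ab"] + table["pct_gd"] > 100.0 + PCT_TOLERANCE
    if over.any():
        raise InputFormatError(f"pct_ab + pct_gd exceeds 100 at rows {list(table.index[over])}")
    return table


@dataclass(frozen=True)
class RatioSummary:
    ratios: pd.Series  # index: sample ids
    median: float
    min: float
    max: float
    excluded: list[str]  # samples dropped for missing / zero denominator


def ratio_summary(
    table: pd.DataFrame, numerator: str, denominator: str, compartment: str
) -> RatioSummary:
    """Per-sample ratio of two subset percentages within one compartment."""
    sub = table[table["compartment"] == compartment].set_index("sample")
    num, den = sub[numerator], sub[denominator]
    bad = num.isna() | den.isna() | (den == 0)
    excluded = list(sub.index[bad])
    ratios = (num[~bad] / den[~bad]).astype(float)
    if ratios.empty:
        raise DegenerateDataError(f"no usable samples for {numerator}/{denominator}")
    return RatioSummary(
        ratios=ratios,
        median=float(ratios.median()),
        min=float(ratios.min()),
        max=float(ratios.max()),
        excluded=excluded,
    )


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-) over nonzero differences
    w_plus: float
    n: int  # pairs remaining after dropping zero differences
    p_value: float
    method: str  # "exact" | "normal-approx"


def _exact_wplus_sf_cdf(ranks: np.ndarray, w: float) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under the null, by dynamic programming over
    the 2^n equiprobable sign assignments.

    Midranks are multiples of 1/2, so doubling makes every rank an integer
    and the enumeration exact even in the presence of ties.
    """
    r2 = np.rint(2 * np.asarray(ranks)).astype(int)
    w2 = 2.0 * w
    max_sum = int(r2.sum())
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: max_sum + 1 - r]
        counts = counts + shifted
    total = counts.sum()
    lo = int(np.floor(w2 + 1e-9))
    hi = int(np.ceil(w2 - 1e-9))
    return counts[: lo + 1].sum() / total, counts[hi:].sum() / total


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; requires >= 5 informative pairs.  Exact
    enumeration (midranks for ties) when n <= 25, else normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputFormatError("paired samples must have equal length")
    d = x - y
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n < 5:
        raise DegenerateDataError(f"only {n} nonzero differences; need >= 5")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= 25:
        cdf, sf = _exact_wplus_sf_cdf(ranks, w_plus)
        p = min(1.0, 2.0 * min(cdf, sf))
        return WilcoxonResult(statistic, w_plus, n, p, "exact")
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(statistic, w_plus, n, p, "normal-approx")


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def pearson_ci(x: Sequence[float], y: Sequence[float], conf: float = 0.95) -> PearsonResult:
    """Pearson correlation with Fisher-z confidence interval and two-sided
    t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise DegenerateDataError(f"need >= 4 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in one of the variables")
    r = float(np.corrcoef(x, y)[0, 1])
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    ci_low, ci_high = float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return PearsonResult(r, ci_low, ci_high, p, n)


def fig1_report(table: pd.DataFrame) -> dict:
    """Cohort summary: subset medians/ranges per compartment, paired
    compartment contrasts, and the activation correlation in infiltrates.

    Requires >= 5 samples measured in both compartments.
    """
    table = validate_flow_table(table)
    comps = set(table["compartment"])
    if not {"BIL", "PBMC"} <= comps:
        raise InputFormatError("report requires both BIL and PBMC compartments")
    wide = table.set_index(["sample", "compartment"])
    paired_samples = sorted(
        set(table.loc[table["compartment"] == "BIL", "sample"])
        & set(table.loc[table["compartment"] == "PBMC", "sample"])
    )
    if len(paired_samples) < 5:
        raise InputFormatError(f"only {len(paired_samples)} paired samples; need >= 5")

    report: dict = {"n_paired": len(paired_samples)}
    for comp in ("BIL", "PBMC"):
        sub = table[table["compartment"] == comp]
        abgd = ratio_summary(table, "pct_ab", "pct_gd", comp)
        cd48 = ratio_summary(table, "pct_cd4_ab", "pct_cd8_ab", comp)
        report[comp] = {
            "pct_ab_median": float(sub["pct_ab"].median()),
            "pct_ab_range": (float(sub["pct_ab"].min()), float(sub["pct_ab"].max())),
            "pct_gd_median": float(sub["pct_gd"].median()),
            "pct_gd_range": (float(sub["pct_gd"].min()), float(sub["pct_gd"].max())),
            "ab_gd_ratio_median": abgd.median,
            "ab_gd_ratio_range": (abgd.min, abgd.max),
            "cd4_cd8_ratio_median": cd48.median,
            "cd4_cd8_ratio_range": (cd48.min, cd48.max),
            "pct_cd69_ab_median": float(sub["pct_cd69_ab"].median()),
            "pct_cd69_ab_range": (
                float(sub["pct_cd69_ab"].min()),
                float(sub["pct_cd69_ab"].max()),
            ),
            "pct_cd69_gd_median": float(sub["pct_cd69_gd"].median()),
            "pct_cd69_gd_range": (
                float(sub["pct_cd69_gd"].min()),
                float(sub["pct_cd69_gd"].max()),
            ),
        }
    # paired BIL-vs-PBMC contrasts
    contrasts = {}
    for label, col in (("pct_ab", "pct_ab"), ("pct_gd", "pct_gd")):
        bil = np.array([wide.loc[(s, "BIL"), col] for s in paired_samples], dtype=float)
        pb = np.array([wide.loc[(s, "PBMC"), col] for s in paired_samples], dtype=float)
        res = wilcoxon_paired(bil, pb)
        contrasts[label] = {"statistic": res.statistic, "p_value": res.p_value, "method": res.method}
    bil48 = ratio_summary(table, "pct_cd4_ab", "pct_cd8_ab", "BIL").ratios
    pb48 = ratio_summary(table, "pct_cd4_ab", "pct_cd8_ab", "PBMC").ratios
    common = [s for s in paired_samples if s in bil48.index and s in pb48.index]
    res = wilcoxon_paired(bil48[common].to_numpy(), pb48[common].to_numpy())
    contrasts["cd4_cd8_ratio"] = {
        "statistic": res.statistic,
        "p_value": res.p_value,
        "method": res.method,
    }
    report["wilcoxon"] = contrasts
    # activation correlation in the infiltrate
    bil = table[table["compartment"] == "BIL"]
    try:
        pres = pearson_ci(bil["pct_cd69_ab"].to_numpy(), bil["pct_cd69_gd"].to_numpy())
        rho, rho_p = stats.spearmanr(
            bil["pct_cd69_ab"], bil["pct_cd69_gd"], nan_policy="omit"
        )
        report["cd69_correlation"] = {
            "r": pres.r,
            "ci": (pres.ci_low, pres.ci_high),
            "p_value": pres.p_value,
            "n": pres.n,
            "spearman_rho": float(rho),
            "spearman_p": float(rho_p),
        }
    except DegenerateDataError:
        report["cd69_correlation"] = {"r": float("nan"), "ci": (float("nan"), float("nan")),
                                      "p_value": float("nan"), "n": 0,
                                      "spearman_rho": float("nan"), "spearman_p": float("nan")}
    return report
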