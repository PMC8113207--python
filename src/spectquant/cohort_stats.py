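"""Cohort statistics: Pearson correlations, Kruskal-Wallis, report assembly.

Pairwise analyses are complete-case per pair: each correlation uses exactly
the subjects with both members present, so denominators vary across rows.
No multiple-testing adjustment is applied anywhere in this module; p-values
are reported raw, and the conventional 0.05 threshold is never used to
filter rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import METRICS, STRAIN_REGIONS
from .quantify import apical_sparing_echo


@dataclass(frozen=True)
class CorrelationResult:
    """One correlation row: pair label, coefficient, p-value, subjects used."""

    pair: str
    r: float
    p: float
    n_used: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r out of range: {self.r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p out of range: {self.p}")
        if self.n_used < 3:
            raise ValueError("n_used must be >= 3")


def pearson(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    pair: str = "",
) -> CorrelationResult:
    """Product-moment correlation with a two-tailed t-test p-value.

    Pairs with a missing member are dropped first (complete-case).  The
    p-value comes from ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.sum(xd * xd))
    sy = np.sqrt(np.sum(yd * yd))
    if sx == 0 or sy == 0:
        raise ValueError("degenerate (zero-variance) input")
    r = float(np.sum(xd * yd) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(pair=pair, r=r, p=p, n_used=n)


def log10_transform(values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Elementwise base-10 log; rejects non-positive entries by position."""
    arr = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(arr)
    bad = np.flatnonzero(finite & (arr <= 0))
    if bad.size:
        raise ValueError(f"non-positive value(s) at row(s) {bad.tolist()}")
    out = np.full_like(arr, np.nan)
    out[finite] = np.log10(arr[finite])
    return out


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based H test across groups with mid-rank tie correction.

    Returns (H, p) with p from the chi-square approximation on k - 1
    degrees of freedom.  When every observation is identical the statistic
    is 0 by convention and p = 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    h = 12.0 / (n_total * (n_total + 1))
    start = 0
    accum = 0.0
    for g in groups:
        r_sum = ranks[start : start + g.size].sum()
        accum += r_sum**2 / g.size
        start += g.size
    h = h * accum - 3.0 * (n_total + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    if denom == 0.0:  # all observations identical
        return 0.0, 1.0
    h /= denom
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


#: biomarker column -> report label
_BIOMARKERS = ("troponin_t", "nt_probnp", "log10_nt_probnp")


def build_correlation_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-metric correlation table of a cohort.

    For each uptake metric, region-wise metric-vs-strain correlations
    (lateral wall, septum, apex, RV free wall, merged LV), followed by the
    whole-heart ("ventricles") metric against troponin T, NT-ProBNP and
    log10(NT-ProBNP).  Region labels on both sides of every pair match by
    construction.
    """
    ntp = cohort["nt_probnp"]
    log_ntp = pd.Series(
        log10_transform(ntp.to_numpy()), index=cohort.index, name="log10_nt_probnp"
    )
    rows = []
    for metric in METRICS:
        for region in STRAIN_REGIONS:
            res = pearson(
                cohort[f"{metric}_{region}"],
                cohort[f"strain_{region}"],
                pair=f"{metric}_{region} vs strain_{region}",
            )
            rows.append(
                {
                    "metric": metric,
                    "pair": res.pair,
                    "region": region,
                    "target": "strain",
                    "r": res.r,
                    "p": res.p,
                    "n_used": res.n_used,
                }
            )
        vent = cohort[f"{metric}_ventricles"]
        for label, series in (
            ("troponin_t", cohort["troponin_t"]),
            ("nt_probnp", ntp),
            ("log10_nt_probnp", log_ntp),
        ):
            res = pearson(vent, series, pair=f"{metric}_ventricles vs {label}")
            rows.append(
                {
                    "metric": metric,
                    "pair": res.pair,
                    "region": "ventricles",
                    "target": label,
                    "r": res.r,
                    "p": res.p,
                    "n_used": res.n_used,
                }
            )
    return pd.DataFrame(rows)


def echo_sparing_ratios(cohort: pd.DataFrame) -> pd.Series:
    """Per-subject strain apical-sparing ratio apical / (basal + mid)."""
    ratios = [
        apical_sparing_echo(a, b, m).ratio
        for a, b, m in zip(
            cohort["apical_avg_strain"],
            cohort["basal_avg_strain"],
            cohort["mid_avg_strain"],
        )
    ]
    return pd.Series(ratios, index=cohort.index, name="echo_sparing_ratio")


def sparing_prevalence(cohort: pd.DataFrame) -> float:
    """Fraction of subjects whose strain sparing ratio exceeds 1."""
    ratios = echo_sparing_ratios(cohort)
    return float((ratios > 1.0).mean())
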