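"""Cohort statistics: Spearman correlation with axial length, Holm
correction, and repeat-session comparisons.

Correlations between per-eye summary features and axial length use
Spearman's rank rho with midranks for ties.  The 95% confidence interval
comes from Fisher's z-transformation,

    tanh( atanh(rho) +- z_{0.975} * c / sqrt(n - 3) ),

with c = 1.06, the variance inflation appropriate for Spearman's statistic
(c = 1 recovers the Pearson interval).  The two-sided p-value is computed
on the same z scale.  Multiplicity over the declared family of tabulated
correlations is handled by the Holm step-down procedure at alpha = 0.05.

Repeat-scan reliability compares per-eye aggregates (max, min, median, IQR
over regions) of each regional descriptor between two sessions with the
two-sided Wilcoxon signed-rank test (exact for small samples; zero
differences dropped).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .reference import SUMMARY_STATS, _iqr

logger = logging.getLogger(__name__)

DEFAULT_SE_CONST = 1.06
ALL_SCOPE_LABEL = "all of eye"

#: the 8 tabulated feature columns: median and IQR of each descriptor
TABLE_FEATURES = tuple(f"{kind}_{stat}" for kind in ("median", "iqr")
                       for stat in SUMMARY_STATS)


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    """One Spearman correlation against axial length."""

    feature: str
    scope: str
    rho: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    holm_significant: bool = False
    alpha: float = 0.05
    estimable: bool = True


def spearman_ci(x, y, *, se_const: float = DEFAULT_SE_CONST,
                alpha: float = 0.05, feature: str = "", scope: str = "") -> CorrelationResult:
    """Spearman rho with a Fisher-z confidence interval and p-value.

    Requires n >= 5 paired observations; ties get midranks.  |rho| = 1
    yields a degenerate interval at rho (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 5:
        raise StatsError(f"need at least 5 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined: zero variance input")
    rho = float(sstats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0 - 1e-12:   # perfect monotone up to round-off
        rho = float(np.sign(rho))
    zcrit = float(sstats.norm.ppf(1 - alpha / 2))
    if abs(rho) >= 1.0:
        logger.warning("degenerate |rho| = 1 for %s / %s; CI collapses", feature, scope)
        return CorrelationResult(feature=feature, scope=scope, rho=rho,
                                 ci_low=rho, ci_high=rho, p=0.0, n=n, alpha=alpha)
    z = np.arctanh(rho)
    se = se_const / np.sqrt(n - 3)
    ci_low, ci_high = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    p = 2 * float(sstats.norm.sf(abs(z) / se))
    return CorrelationResult(feature=feature, scope=scope, rho=rho,
                             ci_low=float(ci_low), ci_high=float(ci_high),
                             p=p, n=n, alpha=alpha)


def holm_flags(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejection flags for a family of p-values.

    Sort p ascending; compare p_(i) with alpha / (m - i + 1); reject until
    the first failure, after which nothing is rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise StatsError("empty p-value family")
    order = np.argsort(p, kind="mergesort")
    m = p.size
    flags = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            flags[idx] = True
        else:
            break
    return flags


def holm_adjust(results: list[CorrelationResult],
                alpha: float = 0.05) -> list[CorrelationResult]:
    """Set ``holm_significant`` jointly across a family of results.

    Non-estimable results are passed through unflagged and excluded from
    the family.  The smallest implied threshold alpha/m is logged.
    """
    family = [r for r in results if r.estimable]
    if not family:
        raise StatsError("empty correlation family")
    flags = holm_flags([r.p for r in family], alpha=alpha)
    logger.info("Holm family of %d tests; smallest threshold alpha/m = %.3g",
                len(family), alpha / len(family))
    flagged = iter(flags)
    return [
        replace(r, holm_significant=bool(next(flagged)), alpha=alpha)
        if r.estimable else replace(r, holm_significant=False, alpha=alpha)
        for r in results
    ]


def correlation_table(all_summary: pd.DataFrame,
                      regional_summary: pd.DataFrame | None = None,
                      *, alpha: float = 0.05,
                      se_const: float = DEFAULT_SE_CONST,
                      exclude_eyes: tuple[str, ...] = (),
                      min_n: int = 5) -> pd.DataFrame:
    """Correlate per-eye summary features with axial length, Holm-adjusted.

    ``all_summary`` holds one row per eye (all-of-eye features, columns
    ``eye_id, axial_length_mm, median_*/iqr_*``); ``regional_summary``
    holds one row per eye x region.  Returns one row per (scope, feature)
    with rho, CI, p, n and the joint Holm flag.  ``exclude_eyes`` supports
    sensitivity reruns (e.g. dropping the longest eye); scopes with fewer
    than ``min_n`` eyes or zero feature variance are marked non-estimable
    and left out of the Holm family.
    """
    blocks: list[tuple[str, pd.DataFrame]] = [(ALL_SCOPE_LABEL, all_summary)]
    if regional_summary is not None:
        for region, grp in regional_summary.groupby("region", sort=True):
            blocks.append((str(region), grp))

    results: list[CorrelationResult] = []
    for scope, frame in blocks:
        frame = frame[~frame["eye_id"].astype(str).isin([str(e) for e in exclude_eyes])]
        for feature in TABLE_FEATURES:
            if feature not in frame.columns:
                continue
            sub = frame[["axial_length_mm", feature]].dropna()
            n = len(sub)
            estimable = n >= min_n and np.ptp(sub[feature].to_numpy()) > 0 \
                and np.ptp(sub["axial_length_mm"].to_numpy()) > 0
            if not estimable:
                logger.warning("scope %r feature %s not estimable (n = %d)",
                               scope, feature, n)
                results.append(CorrelationResult(
                    feature=feature, scope=scope, rho=np.nan, ci_low=np.nan,
                    ci_high=np.nan, p=np.nan, n=n, alpha=alpha, estimable=False))
                continue
            results.append(spearman_ci(
                sub[feature], sub["axial_length_mm"], se_const=se_const,
                alpha=alpha, feature=feature, scope=scope))
    results = holm_adjust(results, alpha=alpha)
    return pd.DataFrame([vars(r) for r in results])


@dataclass(frozen=True)
class RepeatTestResult:
    """Wilcoxon signed-rank comparison of one repeat-scan statistic."""

    feature: str
    p: float
    n_pairs: int


AGGREGATES = ("max", "min", "median", "iqr")


def _aggregate_regions(regional_summary: pd.DataFrame) -> pd.DataFrame:
    """Per-eye max/min/median/IQR over regions of each regional descriptor."""
    rows = []
    for eye_id, grp in regional_summary.groupby("eye_id", sort=True):
        row = {"eye_id": eye_id}
        for stat in SUMMARY_STATS:
            v = grp[f"median_{stat}"].to_numpy(dtype=float)
            row[f"max_{stat}"] = float(v.max())
            row[f"min_{stat}"] = float(v.min())
            row[f"median_{stat}"] = float(np.median(v))
            row[f"iqr_{stat}"] = _iqr(v)
        rows.append(row)
    return pd.DataFrame(rows).set_index("eye_id")


def repeat_scan_test(session_a: pd.DataFrame, session_b: pd.DataFrame,
                     *, min_pairs: int = 5) -> list[RepeatTestResult]:
    """Compare two sessions' regional summaries by Wilcoxon signed rank.

    Inputs are regional summary tables (one row per eye x region with
    ``median_<stat>`` columns).  For each descriptor the per-eye maximum,
    minimum, median and IQR over regions are compared between sessions,
    paired by eye.  Zero differences are dropped (Wilcoxon convention); if
    every difference is zero the comparison is degenerate and reported as
    p = 1 with a warning.  Exact p-values for up to 25 pairs.
    """
    agg_a = _aggregate_regions(session_a)
    agg_b = _aggregate_regions(session_b)
    common = agg_a.index.intersection(agg_b.index)
    if len(common) == 0:
        raise StatsError("no matched eyes between sessions")

    results = []
    for stat in SUMMARY_STATS:
        for agg in AGGREGATES:
            col = f"{agg}_{stat}"
            a = agg_a.loc[common, col].to_numpy(dtype=float)
            b = agg_b.loc[common, col].to_numpy(dtype=float)
            diffs = a - b
            nz = diffs[diffs != 0]
            if nz.size < min_pairs:
                if np.all(diffs == 0):
                    warnings.warn(
                        f"all paired differences zero for {col}; "
                        "test degenerate, reporting p = 1", stacklevel=2)
                    results.append(RepeatTestResult(feature=col, p=1.0,
                                                    n_pairs=len(common)))
                    continue
                raise StatsError(
                    f"fewer than {min_pairs} non-zero pairs for {col}")
            method = "exact" if nz.size <= 25 else "approx"
            res = sstats.wilcoxon(a, b, zero_method="wilcox",
                                  alternative="two-sided", method=method)
            results.append(RepeatTestResult(feature=col, p=float(res.pvalue),
                                            n_pairs=len(common)))
    return results
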