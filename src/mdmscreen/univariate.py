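"""Per-metabolite group statistics.

For each metabolite the report gives group means of the creatinine-
normalized values, the percent difference between groups, Welch's unequal-
variance t-test on raw and square-root-transformed values, Benjamini–
Hochberg q-values, the single-marker AUROC (the Mann–Whitney probability
that a random affected value exceeds a random reference value), the
fraction of affected participants outside the TD reference range, and the
pooled fraction of censored (below-LOD) measurements. Urinary metabolite
concentrations are strongly right-skewed, hence the square-root transform
companion test; AUROC is reported because it is rank-based and so immune
to that skew.

Standard tests go through scipy/statsmodels; this module defines the
report layout, orientation conventions (AUROC > 0.5 means affected values
stochastically larger), and missing/censored handling.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import NormalizedMatrix
from .panel import MetabolitePanel
from .scoring import ReferenceRangeSet, build_reference_ranges

logger = logging.getLogger(__name__)


class TTestResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def welch_t(x, y) -> TTestResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Uses the Welch–Satterthwaite degrees of freedom. If both samples have
    zero variance and equal means the test is degenerate; by convention
    t = 0, p = 1 (logged).
    """
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 non-missing values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            logger.info("welch_t: both samples constant and equal; p = 1")
            return TTestResult(0.0, float(len(x) + len(y) - 2), 1.0)
        raise ValueError("both variances zero with unequal means: t undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def sqrt_transform_then_test(x, y) -> TTestResult:
    """Square-root transform both samples, then Welch's t-test."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.nanmin(x) < 0 or np.nanmin(y) < 0:
        raise ValueError("square-root transform requires non-negative values")
    return welch_t(np.sqrt(x), np.sqrt(y))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{k >= i} (m * p_(k) / k), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def auroc(x, y) -> float:
    """P(X > Y) + 0.5 P(X = Y) via the Mann–Whitney rank formula.

    ``x`` is the affected (ASD) sample, ``y`` the reference (TD) sample, so
    values above 0.5 mean the affected group is stochastically larger.
    """
    x, y = _clean(x), _clean(y)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0
    return float(u / (len(x) * len(y)))


def percent_difference(mean_asd: float, mean_td: float) -> float:
    """100 × (mean_ASD − mean_TD)/mean_TD; requires a positive TD mean."""
    if not mean_td > 0:
        raise ValueError("percent difference undefined: TD mean must be > 0")
    return 100.0 * (mean_asd - mean_td) / mean_td


def pct_above_reference(values, lower: float, upper: float,
                        direction: str = "high") -> float:
    """Percent of values strictly outside the reference bound.

    High-direction: strictly above ``upper``; low-direction: strictly below
    ``lower``. Missing values count in the denominator but can never
    exceed, matching the indicator convention of the scoring module.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if direction == "low":
        hits = np.nansum(v < lower)
    else:
        hits = np.nansum(v > upper)
    return 100.0 * float(hits) / v.size


def pct_below_lod(lod_flags) -> float:
    """Percent of censored cells over all participants pooled."""
    f = np.asarray(lod_flags, dtype=bool)
    if f.size == 0:
        raise ValueError("empty flag vector")
    return 100.0 * float(f.sum()) / f.size


def correlation_matrix(norm: NormalizedMatrix, method: str = "pearson") -> pd.DataFrame:
    """Pairwise-complete metabolite correlation matrix (diagonal 1).

    Pearson by default; ``method="spearman"`` for the rank version.
    Constant columns yield undefined (NaN) correlations and are logged.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr = norm.values.corr(method=method, min_periods=3)
    constant = [
        m for m in norm.values.columns
        if norm.values[m].dropna().nunique() <= 1
    ]
    if constant:
        logger.warning("constant column(s), correlation undefined: %s", constant)
    return corr


def univariate_table(
    norm: NormalizedMatrix,
    groups: pd.Series,
    panel: MetabolitePanel,
    ranges: ReferenceRangeSet | None = None,
    include_q: bool = True,
) -> pd.DataFrame:
    """Full per-metabolite report.

    Columns: mean_asd, mean_td, pct_difference, p_raw, p_sqrt, q_value,
    auroc, pct_asd_above_td, pct_below_lod. If ``ranges`` is None they are
    built in-sample from the TD rows. ``include_q=False`` omits the BH
    column (the convention for reports where no multiplicity correction is
    applied).
    """
    if ranges is None:
        ranges = build_reference_ranges(norm, groups, panel)
    asd_rows = groups == "ASD"
    td_rows = groups == "TD"
    records = {}
    for m in norm.values.columns:
        x = norm.values.loc[asd_rows, m].to_numpy()
        y = norm.values.loc[td_rows, m].to_numpy()
        mean_asd = float(np.nanmean(x))
        mean_td = float(np.nanmean(y))
        try:
            pct_diff = percent_difference(mean_asd, mean_td)
        except ValueError:
            logger.warning("%s: TD mean not positive, percent difference undefined", m)
            pct_diff = np.nan
        t_raw = welch_t(x, y)
        t_sqrt = sqrt_transform_then_test(x, y)
        entry = panel[m]
        records[m] = {
            "family": entry.family,
            "direction": entry.direction,
            "mean_asd": mean_asd,
            "mean_td": mean_td,
            "pct_difference": pct_diff,
            "p_raw": t_raw.pvalue,
            "p_sqrt": t_sqrt.pvalue,
            "auroc": auroc(x, y),
            "pct_asd_above_td": pct_above_reference(
                x, ranges.table.at[m, "lower"], ranges.table.at[m, "upper"],
                entry.direction,
            ),
            "pct_below_lod": pct_below_lod(norm.lod_mask[m].to_numpy()),
        }
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "metabolite_id"
    if include_q:
        q = bh_fdr(table["p_raw"].to_numpy())
        table.insert(table.columns.get_loc("p_sqrt") + 1, "q_value", q)
        table["significant_q"] = table["q_value"] < 0.05
    return table


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def format_univariate_report(table: pd.DataFrame) -> pd.DataFrame:
    """Render the numeric table with conventional report rounding.

    Percent columns to the nearest integer, AUROC to two decimals,
    p/q-values to two significant figures.
    """
    out = pd.DataFrame(index=table.index)
    if "family" in table.columns:
        out["family"] = table["family"]
    for col in ("mean_asd", "mean_td"):
        out[col] = table[col].map(lambda v: f"{v:.4g}")
    for col in ("pct_difference", "pct_asd_above_td", "pct_below_lod"):
        out[col] = table[col].map(
            lambda v: "" if pd.isna(v) else f"{_round_half_up(v)}%"
        )
    for col in ("p_raw", "p_sqrt", "q_value"):
        if col in table.columns:
            out[col] = table[col].map(lambda v: f"{v:.2g}")
    out["auroc"] = table["auroc"].map(lambda v: f"{v:.2f}")
    return out
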