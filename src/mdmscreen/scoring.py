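"""Reference-range exceedance scoring (the MDM Total Score).

The screen works by reference-interval exceedance rather than by a fitted
model. For each metabolite, the typically-developing (TD) group defines a
reference range as the full span [min, max] of its creatinine-normalized
values. A participant earns one point per metabolite whose value lies
strictly outside that range on the abnormal side (above the TD maximum for
elevation markers; below the TD minimum for depletion markers). The MDM
Total Score is the number of such points, and a participant is classified
screen-positive when the score reaches a cut-off (default: one or more
exceedances).

Two consequences of this construction are worth keeping in mind:

* evaluated in-sample, every TD participant scores zero by definition
  (nothing exceeds its own group's extremes), so in-sample specificity is
  tautologically 100%;
* a *fresh* unaffected sample exceeds the maximum of an n-sample reference
  with probability 1/(n+1) per metabolite (order statistics of exchangeable
  continuous draws), which sets the false-positive floor of a deployed
  screen.

Ranges are therefore intended to be frozen artifacts: built once from a
reference cohort, serialized, and applied to new samples; in-sample
evaluation is a separate, clearly labelled mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import NormalizedMatrix
from .errors import ReferenceRangeError
from .panel import MetabolitePanel

logger = logging.getLogger(__name__)


@dataclass
class ReferenceRangeSet:
    """Per-metabolite [lower, upper] bounds from a TD reference group."""

    table: pd.DataFrame  # index metabolite_id; columns lower, upper, n_reference
    panel_hash: str = ""

    def __post_init__(self):
        t = self.table
        if (t["lower"] > t["upper"]).any():
            raise ReferenceRangeError("lower > upper for some metabolite")
        if (t["n_reference"] < 2).any():
            bad = list(t.index[t["n_reference"] < 2])
            raise ReferenceRangeError(f"n_reference < 2 for {bad}")

    def metabolites(self) -> list[str]:
        return list(self.table.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "panel_hash": self.panel_hash,
            "ranges": {
                m: {
                    "lower": float(r["lower"]),
                    "upper": float(r["upper"]),
                    "n_reference": int(r["n_reference"]),
                }
                for m, r in self.table.iterrows()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceRangeSet":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        table = pd.DataFrame.from_dict(payload["ranges"], orient="index")
        table.index.name = "metabolite_id"
        return cls(table=table, panel_hash=payload.get("panel_hash", ""))


def build_reference_ranges(
    norm: NormalizedMatrix, groups: pd.Series, panel: MetabolitePanel
) -> ReferenceRangeSet:
    """Per-metabolite [min, max] over the TD rows of a normalized matrix.

    Censored cells participate with their imputed values (an imputed low
    value cannot raise the maximum, so elevation scoring is unaffected by
    the imputation choice). A metabolite with fewer than two non-missing TD
    values is an error naming it.
    """
    td = norm.values.loc[groups == "TD"]
    if td.shape[0] < 2:
        raise ReferenceRangeError(
            f"need at least 2 TD participants, got {td.shape[0]}"
        )
    rows = {}
    for m in norm.values.columns:
        col = td[m].dropna()
        if len(col) < 2:
            raise ReferenceRangeError(
                f"metabolite {m!r}: fewer than 2 non-missing TD values "
                f"({len(col)}); cannot build a reference range"
            )
        rows[m] = {"lower": float(col.min()), "upper": float(col.max()),
                   "n_reference": int(len(col))}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "metabolite_id"
    return ReferenceRangeSet(table=table, panel_hash=norm.panel_hash)


def exceedance_indicators(
    norm: NormalizedMatrix, ranges: ReferenceRangeSet, panel: MetabolitePanel
) -> pd.DataFrame:
    """0/1 indicator per participant × metabolite of strict range exceedance.

    Elevation markers score 1 when the value is strictly above the reference
    upper bound; depletion markers when strictly below the lower bound. A
    value exactly at the bound scores 0 (the range is the full observed TD
    span, so equality means "seen in TD"). Missing values score 0 and are
    counted in a log notice.
    """
    missing_ranges = [m for m in norm.values.columns if m not in ranges.table.index]
    if missing_ranges:
        raise ReferenceRangeError(
            f"no reference range for metabolite(s): {missing_ranges}"
        )
    out = pd.DataFrame(
        0, index=norm.values.index, columns=norm.values.columns, dtype=int
    )
    n_missing = 0
    for m in norm.values.columns:
        col = norm.values[m]
        lo = ranges.table.at[m, "lower"]
        hi = ranges.table.at[m, "upper"]
        if panel[m].direction == "low":
            ind = col < lo
        else:
            ind = col > hi
        n_missing += int(col.isna().sum())
        out[m] = ind.fillna(False).astype(int)
    if n_missing:
        logger.info(
            "exceedance_indicators: %d missing cell(s) scored as 0", n_missing
        )
    return out


def mdm_total_score(indicators: pd.DataFrame, cutoff: int = 1) -> pd.DataFrame:
    """Row-sum the indicator matrix into MDM Total Scores.

    Returns a DataFrame indexed like ``indicators`` with columns ``total``
    (the score) and ``classified_positive`` (total >= cutoff).
    """
    total = indicators.sum(axis=1).astype(int)
    return pd.DataFrame(
        {"total": total, "classified_positive": total >= cutoff},
        index=indicators.index,
    )


@dataclass
class ClassificationReport:
    """Confusion counts and derived screening metrics (fractions in [0,1]).

    A ratio whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "ClassificationReport":
        def ratio(num, den):
            return num / den if den > 0 else None

        return cls(
            tp=tp, fp=fp, tn=tn, fn=fn,
            sensitivity=ratio(tp, tp + fn),
            specificity=ratio(tn, tn + fp),
            ppv=ratio(tp, tp + fp),
            npv=ratio(tn, tn + fn),
            accuracy=ratio(tp + tn, tp + tn + fp + fn),
        )

    def to_dict(self, percent: bool = False) -> dict:
        d = {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}
        for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, k)
            d[k] = None if v is None else (100.0 * v if percent else v)
        return d


def classify_cohort(
    scores: pd.DataFrame, groups: pd.Series, positive_group: str = "ASD"
) -> ClassificationReport:
    """Confusion matrix of screen positivity against the clinical label."""
    if not scores.index.equals(groups.index):
        groups = groups.reindex(scores.index)
        if groups.isna().any():
            raise ValueError("groups and scores are not aligned")
    truth = (groups == positive_group).to_numpy()
    pred = scores["classified_positive"].to_numpy()
    tp = int(np.sum(truth & pred))
    fp = int(np.sum(~truth & pred))
    tn = int(np.sum(~truth & ~pred))
    fn = int(np.sum(truth & ~pred))
    return ClassificationReport.from_counts(tp, fp, tn, fn)
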