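"""End-to-end orchestration: load → normalize → range → score → report.

Two evaluation modes are exposed and labelled on every report:

* ``insample`` — reference ranges are built from the TD rows of the cohort
  being evaluated. This is the study-style evaluation; note that TD
  specificity is then 100% by construction and carries no information.
* ``deploy`` — ranges are loaded from a frozen JSON artifact built on a
  previous reference cohort; this is the intended screening use.

Each run writes the univariate table, per-participant scores, the
classification report, a score-vs-age scatter, and a run log with the
configuration, panel hash and library versions, into one output
directory. A failed stage aborts the run, names the stage, and removes
partial outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, load_cohort, normalize_by_creatinine
from .errors import PipelineError
from .multivariate import combination_results_frame, combination_search
from .panel import MetabolitePanel
from .scoring import (
    ReferenceRangeSet,
    build_reference_ranges,
    classify_cohort,
    exceedance_indicators,
    mdm_total_score,
)
from .univariate import format_univariate_report, univariate_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    cohort_path: str
    panel_path: str
    out_dir: str
    ranges_path: str | None = None  # required for mode="deploy"
    mode: str = "insample"
    lod_policy: str = "half_lod"
    cutoff: int = 1
    transform: str = "sqrt"  # feature transform for the FDA search
    fda_k: int | None = None  # None disables the combination search
    fda_floor: float = 0.0
    fda_loocv: bool = False
    include_q: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("insample", "deploy"):
            raise PipelineError("config", f"unknown mode {self.mode!r}")
        if self.mode == "deploy" and not self.ranges_path:
            raise PipelineError("config", "mode=deploy requires ranges_path")
        if self.transform not in ("sqrt", "log1p", "none"):
            raise PipelineError("config", f"unknown transform {self.transform!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _transform(values: pd.DataFrame, kind: str) -> pd.DataFrame:
    if kind == "sqrt":
        return np.sqrt(values)
    if kind == "log1p":
        return np.log1p(values)
    return values


def plot_scores_vs_age(
    scores: pd.DataFrame,
    ages: pd.Series,
    groups: pd.Series,
    path: str | Path,
) -> None:
    """Scatter of MDM Total Score against age, one series per group.

    Participants with missing age are dropped with a log notice.
    """
    keep = ~ages.isna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("plot_scores_vs_age: dropping %d participant(s) without age", n_drop)
    fig, ax = plt.subplots(figsize=(6, 4))
    style = {"ASD": dict(marker="o", color="tab:red"),
             "TD": dict(marker="s", color="tab:blue")}
    for grp in ("TD", "ASD"):
        sel = keep & (groups == grp)
        if sel.any():
            ax.scatter(ages[sel], scores.loc[sel, "total"], label=grp,
                       alpha=0.7, **style[grp])
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("MDM Total Score (metabolites outside TD range)")
    if ax.get_legend_handles_labels()[0]:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the full analysis; returns a name → path map of artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, path: Path):
        written.append(path)
        artifacts[name] = str(path)

    artifacts: dict[str, str] = {}
    stage = "load"
    try:
        panel = MetabolitePanel.load(config.panel_path)
        cohort = load_cohort(config.cohort_path, panel)

        stage = "normalize"
        norm = normalize_by_creatinine(cohort, config.lod_policy)

        stage = "ranges"
        if config.mode == "deploy":
            ranges = ReferenceRangeSet.from_json(config.ranges_path)
        else:
            ranges = build_reference_ranges(norm, cohort.groups, panel)
            p = out_dir / "reference_ranges.json"
            ranges.to_json(p)
            _emit("ranges", p)

        stage = "score"
        indicators = exceedance_indicators(norm, ranges, panel)
        scores = mdm_total_score(indicators, cutoff=config.cutoff)
        p = out_dir / "scores.csv"
        scores.to_csv(p)
        _emit("scores", p)

        stage = "classify"
        report = classify_cohort(scores, cohort.groups)
        p = out_dir / "classification.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(
                {"mode": config.mode, "cutoff": config.cutoff,
                 **report.to_dict(percent=True)},
                fh, indent=2,
            )
        _emit("classification", p)

        stage = "univariate"
        table = univariate_table(norm, cohort.groups, panel, ranges,
                                 include_q=config.include_q)
        p = out_dir / "univariate.csv"
        table.to_csv(p)
        _emit("univariate", p)
        p = out_dir / "univariate_report.csv"
        format_univariate_report(table).to_csv(p)
        _emit("univariate_report", p)

        if config.fda_k:
            stage = "fda_search"
            feats = _transform(
                norm.values.fillna(0.0), config.transform
            )
            results = combination_search(
                feats, cohort.groups.to_numpy(), k=config.fda_k,
                auroc_floor=config.fda_floor, loocv=config.fda_loocv,
            )
            p = out_dir / "fda_search.csv"
            combination_results_frame(results).to_csv(p, index=False)
            _emit("fda_search", p)

        stage = "plot"
        p = out_dir / "scores_vs_age.png"
        plot_scores_vs_age(scores, cohort.meta["age_years"], cohort.groups, p)
        _emit("plot", p)

        stage = "runlog"
        p = out_dir / "run_log.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "config": config.to_dict(),
                    "panel_hash": panel.content_hash(),
                    "n_participants": cohort.n_participants,
                    "versions": {
                        "mdmscreen": __version__,
                        "numpy": np.__version__,
                        "pandas": pd.__version__,
                    },
                },
                fh, indent=2,
            )
        _emit("runlog", p)
    except PipelineError:
        for f in written:
            f.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for f in written:
            f.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc
    return artifacts
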