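"""Synthetic two-group urine-metabolomics cohorts with known ground truth.

The generator emulates the statistical structure the screening analysis
assumes, so that every downstream stage is testable without access to the
(undeposited) study data:

* **Baseline**: each metabolite's raw concentration is log-normal and
  i.i.d. across participants (urinary metabolite levels are strongly
  right-skewed). Unaffected (TD) participants and non-elevated affected
  (ASD) participants are exchangeable.
* **Elevations**: for each ASD participant and metabolite, an elevation
  event fires with a per-metabolite probability; when it fires the
  baseline value is multiplied by a fold sampled log-uniformly from
  ``fold_range`` (default 100–1000×, the magnitude reported for extreme
  microbial-metabolite elevations). Depletion markers (direction ``low``)
  are divided by the fold instead.
* **Family coupling**: elevation events within a metabolite family share a
  per-participant latent uniform with probability ``family_coupling``
  (a comonotone mixture). Coupling 0 gives independent events; coupling 1
  makes events within a family all-or-none at equal probabilities, while
  leaving every marginal probability untouched.
* **Creatinine** is log-normal per participant; all of a participant's
  normalized values share it, as in real urine.
* **Censoring**: a per-metabolite limit of detection can be set at a
  quantile of the pooled marginal; cells below it are blanked and flagged,
  and the realized LOD is written into the returned panel.

Every random draw comes from a per-purpose substream keyed by a hash of
its label (NumPy ``SeedSequence``/``default_rng``, i.e. PCG64), so adding
a metabolite to the panel does not reshuffle the draws of existing ones
and identical seeds reproduce cohorts bit-for-bit.

The ground truth (which participant truly carries which elevation, and
with what fold) is returned alongside the cohort for use as a test oracle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, normalize_by_creatinine
from .errors import InfeasibleTargetError, MdmError
from .panel import FAMILIES, MetabolitePanel, PanelEntry
from .panels import SEMIQUANT_EXCEEDANCE_TARGETS, builtin_semiquant_panel

logger = logging.getLogger(__name__)

#: Within-family coupling of elevation events. Chosen once by simulation so
#: that, under the default calibrated probabilities, the fraction of
#: affected participants with at least one elevated tryptophan (resp.
#: phenylalanine) metabolite lands near the reported ~64% / ~60%.
DEFAULT_FAMILY_COUPLING = 0.75

DEFAULT_LOG_MEAN = math.log(10.0)
DEFAULT_LOG_SD = 0.8
DEFAULT_CREATININE_LOG_MEAN = math.log(8.0)  # mmol/L, young children
DEFAULT_CREATININE_LOG_SD = 0.45


def _per_metabolite(value, ids: list[str], name: str) -> dict[str, float]:
    if isinstance(value, dict):
        missing = [m for m in ids if m not in value]
        if missing:
            raise MdmError(f"{name}: missing entries for {missing}")
        return {m: float(value[m]) for m in ids}
    return {m: float(value) for m in ids}


@dataclass
class SimulationConfig:
    """Generator parameters; scalars broadcast over the panel."""

    panel: MetabolitePanel
    n_asd: int = 50
    n_td: int = 47
    log_mean: float | dict = DEFAULT_LOG_MEAN
    log_sd: float | dict = DEFAULT_LOG_SD
    elevation_prob: float | dict = 0.0
    fold_range: tuple[float, float] = (100.0, 1000.0)
    family_coupling: float = DEFAULT_FAMILY_COUPLING
    creatinine_log_mean: float = DEFAULT_CREATININE_LOG_MEAN
    creatinine_log_sd: float = DEFAULT_CREATININE_LOG_SD
    lod_quantile: float | dict = 0.0
    age_range: tuple[float, float] = (2.0, 11.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_asd < 1 or self.n_td < 2:
            raise MdmError("need n_asd >= 1 and n_td >= 2")
        lo, hi = self.fold_range
        if not (lo > 1.0 and hi >= lo):
            raise MdmError("fold_range must satisfy 1 < low <= high")
        if not (0.0 <= self.family_coupling <= 1.0):
            raise MdmError("family_coupling must lie in [0, 1]")
        ids = self.panel.ids()
        for p in _per_metabolite(self.elevation_prob, ids, "elevation_prob").values():
            if not (0.0 <= p <= 1.0):
                raise MdmError("elevation probabilities must lie in [0, 1]")
        for q in _per_metabolite(self.lod_quantile, ids, "lod_quantile").values():
            if not (0.0 <= q < 1.0):
                raise MdmError("lod_quantile must lie in [0, 1)")
        if self.creatinine_log_sd < 0:
            raise MdmError("creatinine_log_sd must be non-negative")

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        payload = {
            "n_asd": self.n_asd,
            "n_td": self.n_td,
            "log_mean": self.log_mean,
            "log_sd": self.log_sd,
            "elevation_prob": self.elevation_prob,
            "fold_range": list(self.fold_range),
            "family_coupling": self.family_coupling,
            "creatinine_log_mean": self.creatinine_log_mean,
            "creatinine_log_sd": self.creatinine_log_sd,
            "lod_quantile": self.lod_quantile,
            "age_range": list(self.age_range),
            "seed": self.seed,
            "panel": self.panel.to_dicts(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        panel = MetabolitePanel([PanelEntry(**e) for e in d.pop("panel")])
        d["fold_range"] = tuple(d.get("fold_range", (100.0, 1000.0)))
        d["age_range"] = tuple(d.get("age_range", (2.0, 11.0)))
        return cls(panel=panel, **d)


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground-truth elevation record."""

    cohort: Cohort
    #: participant_id -> {metabolite_id: applied fold (> 1)}
    truth: dict[str, dict[str, float]]
    #: ASD participants × families: the shared latent uniform and a binary
    #: dysbiosis indicator (uniform below the family's largest event prob.)
    latent_factors: pd.DataFrame

    def truth_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _substream(seed: int, label: str) -> np.random.Generator:
    tag = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, tag]))


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic cohort; fully reproducible from ``config.seed``."""
    panel = config.panel
    ids = panel.ids()
    n_td, n_asd = config.n_td, config.n_asd
    n = n_td + n_asd
    seed = config.seed

    log_mean = _per_metabolite(config.log_mean, ids, "log_mean")
    log_sd = _per_metabolite(config.log_sd, ids, "log_sd")
    probs = _per_metabolite(config.elevation_prob, ids, "elevation_prob")
    lod_q = _per_metabolite(config.lod_quantile, ids, "lod_quantile")

    pids = [f"TD{i + 1:03d}" for i in range(n_td)] + [
        f"ASD{i + 1:03d}" for i in range(n_asd)
    ]
    groups = ["TD"] * n_td + ["ASD"] * n_asd

    ages = _substream(seed, "ages").uniform(*config.age_range, size=n)
    sexes = _substream(seed, "sex").choice(["M", "F"], size=n)
    creatinine = _substream(seed, "creatinine").lognormal(
        config.creatinine_log_mean, config.creatinine_log_sd, size=n
    )

    # per-family shared latent uniform, one per ASD participant
    fam_u = {
        fam: _substream(seed, f"latent|{fam}").uniform(size=n_asd)
        for fam in FAMILIES
    }

    values = np.empty((n, len(ids)))
    event_matrix = np.zeros((n_asd, len(ids)), dtype=bool)
    folds_matrix = np.ones((n_asd, len(ids)))
    realized_lod: dict[str, float] = {}
    lod_mask = np.zeros((n, len(ids)), dtype=bool)

    for j, entry in enumerate(panel):
        m = entry.metabolite_id
        base = _substream(seed, f"baseline|{m}").lognormal(
            log_mean[m], log_sd[m], size=n
        )
        rng_e = _substream(seed, f"event|{m}")
        choice = rng_e.uniform(size=n_asd)
        own_u = rng_e.uniform(size=n_asd)
        eff_u = np.where(choice < config.family_coupling, fam_u[entry.family], own_u)
        event = eff_u < probs[m]
        folds = np.exp(
            _substream(seed, f"fold|{m}").uniform(
                math.log(config.fold_range[0]),
                math.log(config.fold_range[1]),
                size=n_asd,
            )
        )
        col = base.copy()
        asd_slice = slice(n_td, n)
        if entry.direction == "low":
            col[asd_slice] = np.where(event, base[asd_slice] / folds, base[asd_slice])
        else:
            col[asd_slice] = np.where(event, base[asd_slice] * folds, base[asd_slice])
        event_matrix[:, j] = event
        folds_matrix[:, j] = folds
        if lod_q[m] > 0.0:
            lod = float(np.quantile(col, lod_q[m]))
            realized_lod[m] = lod
            censored = col < lod
            lod_mask[:, j] = censored
            col = np.where(censored, np.nan, col)
        values[:, j] = col

    out_panel = panel.with_lods(realized_lod) if realized_lod else panel
    index = pd.Index(pids, name="participant_id")
    meta = pd.DataFrame(
        {"group": groups, "age_years": ages, "sex": sexes, "creatinine": creatinine},
        index=index,
    )
    cohort = Cohort(
        meta=meta,
        values=pd.DataFrame(values, index=index, columns=ids),
        lod_mask=pd.DataFrame(lod_mask, index=index, columns=ids),
        panel=out_panel,
    )

    truth: dict[str, dict[str, float]] = {}
    for i in range(n_asd):
        pid = pids[n_td + i]
        fired = {
            ids[j]: float(folds_matrix[i, j])
            for j in range(len(ids))
            if event_matrix[i, j]
        }
        if fired:
            truth[pid] = fired

    fam_max_p = {
        fam: max(
            (probs[e.metabolite_id] for e in panel if e.family == fam), default=0.0
        )
        for fam in FAMILIES
    }
    latent = pd.DataFrame(
        {
            f"{fam}_u": fam_u[fam] for fam in FAMILIES
        }
        | {
            f"{fam}_dysbiosis": fam_u[fam] < fam_max_p[fam] for fam in FAMILIES
        },
        index=pd.Index(pids[n_td:], name="participant_id"),
    )
    return SyntheticCohort(cohort=cohort, truth=truth, latent_factors=latent)


# ---------------------------------------------------------------------------
# calibration to published exceedance fractions
# ---------------------------------------------------------------------------


def measure_exceedance(
    config: SimulationConfig, n_rep: int = 40, seed: int = 1234567
) -> pd.Series:
    """Monte-Carlo per-metabolite ASD exceedance fraction under ``config``.

    For each replicate, ranges are built from the TD rows and the ASD rows
    are scored; the mean indicator per metabolite over replicates is the
    achieved exceedance fraction (it includes order-statistic leakage from
    the finite TD reference maximum, not just true elevations).
    """
    from .scoring import build_reference_ranges, exceedance_indicators

    acc = None
    for r in range(n_rep):
        cfg = replace(config, seed=(seed + r) & 0x7FFFFFFF)
        sc = generate_cohort(cfg)
        norm = normalize_by_creatinine(
            sc.cohort,
            "half_lod" if any(
                e.lod is not None for e in sc.cohort.panel
            ) else "zero",
        )
        ranges = build_reference_ranges(norm, sc.cohort.groups, sc.cohort.panel)
        ind = exceedance_indicators(norm, ranges, sc.cohort.panel)
        frac = ind.loc[sc.cohort.groups == "ASD"].mean(axis=0)
        acc = frac if acc is None else acc + frac
    return acc / n_rep


def calibrate_to_table(
    targets: dict[str, float],
    n_td: int,
    panel: MetabolitePanel | None = None,
    n_asd: int = 50,
    base_config: SimulationConfig | None = None,
    n_rep: int = 40,
    rounds: int = 3,
    mc_seed: int = 1234567,
) -> SimulationConfig:
    """Find elevation probabilities reproducing target exceedance fractions.

    The observed fraction of affected participants outside a finite TD
    reference range mixes true elevations with order-statistic leakage
    (a non-elevated draw beats the max of n references with probability
    1/(n+1)). The analytic first guess

        p0 = (target − leak) / (1 − leak),  leak = 1/(n_td + 1)

    is then refined by Monte-Carlo fixed-point iteration against the
    achieved fractions. Achieved-vs-target values are logged. A target of
    1.0 (or one the fold range cannot reach) raises
    :class:`InfeasibleTargetError`.
    """
    for m, t in targets.items():
        if not (0.0 <= t <= 1.0):
            raise InfeasibleTargetError(f"{m}: target {t} outside [0, 1]")
        if t >= 0.995:
            raise InfeasibleTargetError(
                f"{m}: target {t} is unreachable — leakage aside, a finite "
                f"fold range cannot push every baseline above the TD maximum"
            )
    if panel is None:
        semiquant = builtin_semiquant_panel()
        if set(targets) <= set(semiquant.ids()):
            panel = semiquant.subset(list(targets))
        else:
            panel = MetabolitePanel(
                [PanelEntry(m, m, "yeast_other", "high") for m in targets]
            )
    ids = panel.ids()
    tvec = pd.Series({m: targets[m] for m in ids})

    leak = 1.0 / (n_td + 1)
    p = ((tvec - leak) / (1.0 - leak)).clip(0.0, 1.0)

    if base_config is None:
        config = SimulationConfig(
            panel=panel, n_asd=n_asd, n_td=n_td, elevation_prob=p.to_dict()
        )
    else:
        config = replace(
            base_config, panel=panel, n_asd=n_asd, n_td=n_td,
            elevation_prob=p.to_dict(),
        )

    achieved = None
    for _ in range(rounds):
        achieved = measure_exceedance(config, n_rep=n_rep, seed=mc_seed)
        p = (p + (tvec - achieved)).clip(0.0, 1.0)
        config = replace(config, elevation_prob=p.to_dict())
    achieved = measure_exceedance(config, n_rep=n_rep, seed=mc_seed)

    stuck = (p >= 1.0) & (achieved < tvec - 0.03)
    if stuck.any():
        raise InfeasibleTargetError(
            f"targets unreachable even at elevation probability 1: "
            f"{list(tvec.index[stuck])}"
        )
    for m in ids:
        logger.info(
            "calibrate_to_table: %s target=%.3f achieved=%.3f p=%.3f",
            m, tvec[m], achieved[m], p[m],
        )
    return config


def default_semiquant_config(seed: int = 0, calibrated: bool = True) -> SimulationConfig:
    """The package's reference study condition: a 19-metabolite panel with
    elevation probabilities calibrated to the published per-metabolite
    exceedance fractions, 50 affected vs 47 reference participants."""
    if not calibrated:
        return SimulationConfig(panel=builtin_semiquant_panel(), seed=seed)
    config = calibrate_to_table(
        SEMIQUANT_EXCEEDANCE_TARGETS, n_td=47, n_asd=50,
        panel=builtin_semiquant_panel(),
    )
    return replace(config, seed=seed)
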