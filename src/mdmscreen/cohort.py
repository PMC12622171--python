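"""Cohort tables and creatinine normalization.

A cohort is a wide table of per-participant raw urinary metabolite
concentrations together with a group label (ASD or TD), urinary creatinine,
and optional age and sex. Concentration cells may be censored below the
assay limit of detection (LOD) — recorded in the CSV dialect as the literal
token ``<LOD`` — or missing (empty cell). Censored and missing cells are
tracked separately: a censored value is known to be small, a missing value
is not known at all.

Creatinine normalization divides each raw concentration by the
participant's urinary creatinine to correct for hydration/dilution,
yielding values in µmol analyte per mmol creatinine. Ratio
pseudo-metabolites (marked ``is_ratio`` in the panel) are unitless and pass
through unchanged. Censored cells are imputed according to an explicit
policy (``half_lod``, ``zero``, or ``exclude``) and stay flagged so that
downstream statistics can account for them.

CSV dialect: comma-separated, UTF-8, ``.`` decimal, one header row;
``<LOD`` and the empty string are the only censored/missing tokens.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortValidationError, NormalizationError
from .panel import MetabolitePanel

logger = logging.getLogger(__name__)

GROUPS = ("ASD", "TD")
LOD_TOKEN = "<LOD"
META_COLUMNS = ("participant_id", "group", "age_years", "sex", "creatinine")

#: accepted creatinine units and their factor to mmol/L
_CREATININE_UNIT_FACTORS = {"mmol/L": 1.0, "mol/L": 1000.0}


@dataclass
class Cohort:
    """Validated participants × metabolites raw-concentration table.

    Attributes
    ----------
    meta : DataFrame indexed by participant_id with columns
        ``group``, ``age_years``, ``sex``, ``creatinine``.
    values : DataFrame of raw concentrations (NaN where censored or missing).
    lod_mask : boolean DataFrame, True where the cell is censored below LOD.
    panel : the metabolite panel the columns belong to.
    creatinine_units : units of the creatinine column (default mmol/L).
    """

    meta: pd.DataFrame
    values: pd.DataFrame
    lod_mask: pd.DataFrame
    panel: MetabolitePanel
    creatinine_units: str = "mmol/L"

    def __post_init__(self):
        self.validate()

    # -- convenience --------------------------------------------------------

    @property
    def participant_ids(self) -> pd.Index:
        return self.meta.index

    @property
    def groups(self) -> pd.Series:
        return self.meta["group"]

    @property
    def n_participants(self) -> int:
        return len(self.meta)

    def validate(self) -> None:
        idx = self.meta.index
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise CohortValidationError(f"duplicate participant ids: {dupes}")
        bad_groups = set(self.meta["group"].unique()) - set(GROUPS)
        if bad_groups:
            raise CohortValidationError(
                f"group column contains labels other than {GROUPS}: {sorted(bad_groups)}"
            )
        if self.creatinine_units not in _CREATININE_UNIT_FACTORS:
            raise CohortValidationError(
                f"creatinine units {self.creatinine_units!r} not recognised "
                f"(expected one of {sorted(_CREATININE_UNIT_FACTORS)})"
            )
        cre = self.meta["creatinine"]
        bad = cre.index[~(cre > 0)]
        if len(bad):
            raise CohortValidationError(
                f"creatinine must be strictly positive; offending participants: "
                f"{list(bad)}"
            )
        unknown = [c for c in self.values.columns if c not in self.panel]
        if unknown:
            raise CohortValidationError(
                f"metabolite columns absent from panel: {unknown}"
            )
        if not self.values.index.equals(idx) or not self.lod_mask.index.equals(idx):
            raise CohortValidationError("values/lod_mask index must match meta index")
        if not self.values.columns.equals(self.lod_mask.columns):
            raise CohortValidationError("values and lod_mask columns differ")
        # a below-LOD flag implies the stored raw value is absent or <= LOD
        for m in self.values.columns:
            flagged = self.lod_mask[m]
            if not flagged.any():
                continue
            stored = self.values.loc[flagged, m]
            lod = self.panel[m].lod
            limit = np.inf if lod is None else lod
            if ((~stored.isna()) & (stored > limit)).any():
                raise CohortValidationError(
                    f"{m}: a below-LOD flagged cell stores a value above the LOD"
                )
        neg = (self.values < 0).any()
        if neg.any():
            raise CohortValidationError(
                f"negative concentrations in columns: {list(neg.index[neg])}"
            )


def load_cohort(
    cohort_path: str | Path,
    panel: MetabolitePanel | str | Path,
    creatinine_units: str = "mmol/L",
) -> Cohort:
    """Read and validate a wide cohort CSV.

    Rows with missing creatinine are rejected and itemized in a warning;
    creatinine equal to zero (or negative) is a hard error naming the
    participant. ``<LOD`` tokens set the censoring flag; empty cells are
    missing. Any other non-numeric cell is a hard error with its row and
    column coordinates.
    """
    if not isinstance(panel, MetabolitePanel):
        panel = MetabolitePanel.load(panel)

    raw = pd.read_csv(cohort_path, dtype=str, keep_default_na=False)
    required = {"participant_id", "group", "creatinine"}
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise CohortValidationError(
            f"{cohort_path}: missing required columns {sorted(missing_cols)}"
        )

    met_cols = [c for c in raw.columns if c not in META_COLUMNS]
    unknown = [c for c in met_cols if c not in panel]
    if unknown:
        raise CohortValidationError(
            f"{cohort_path}: metabolite column(s) absent from panel: {unknown}"
        )

    pids = raw["participant_id"]
    if pids.duplicated().any():
        dupes = sorted(pids[pids.duplicated()].unique())
        raise CohortValidationError(f"duplicate participant ids: {dupes}")

    # reject rows with missing creatinine, itemized
    blank_cre = raw["creatinine"].str.strip() == ""
    if blank_cre.any():
        rejected = list(raw.loc[blank_cre, "participant_id"])
        logger.warning(
            "rejected %d row(s) with missing creatinine: %s", len(rejected), rejected
        )
        raw = raw[~blank_cre].reset_index(drop=True)

    def _num(cell: str, row: int, col: str) -> float:
        try:
            return float(cell)
        except ValueError:
            raise CohortValidationError(
                f"non-numeric value {cell!r} at row {row}, column {col!r}"
            ) from None

    n = len(raw)
    creatinine = np.empty(n)
    ages = np.full(n, np.nan)
    for i, row in raw.iterrows():
        creatinine[i] = _num(row["creatinine"], i, "creatinine")
        if creatinine[i] <= 0:
            raise CohortValidationError(
                f"participant {row['participant_id']!r}: creatinine must be "
                f"strictly positive (got {creatinine[i]})"
            )
        if "age_years" in raw.columns and row["age_years"].strip() != "":
            ages[i] = _num(row["age_years"], i, "age_years")

    values = pd.DataFrame(np.nan, index=range(n), columns=met_cols, dtype=float)
    lod_mask = pd.DataFrame(False, index=range(n), columns=met_cols)
    for col in met_cols:
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == "":
                continue
            if cell == LOD_TOKEN:
                lod_mask.iloc[i, lod_mask.columns.get_loc(col)] = True
                continue
            values.iloc[i, values.columns.get_loc(col)] = _num(cell, i, col)

    meta = pd.DataFrame(
        {
            "group": raw["group"].values,
            "age_years": ages,
            "sex": raw["sex"].values if "sex" in raw.columns else [""] * n,
            "creatinine": creatinine,
        },
        index=pd.Index(raw["participant_id"], name="participant_id"),
    )
    values.index = meta.index
    lod_mask.index = meta.index
    return Cohort(meta, values, lod_mask, panel, creatinine_units)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort in the canonical CSV dialect (round-trips losslessly)."""
    met_cols = [m for m in cohort.panel.ids() if m in cohort.values.columns]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(list(META_COLUMNS) + met_cols) + "\n")
        for pid in cohort.participant_ids:
            row = [str(pid), cohort.meta.at[pid, "group"]]
            age = cohort.meta.at[pid, "age_years"]
            row.append("" if pd.isna(age) else repr(float(age)))
            row.append(str(cohort.meta.at[pid, "sex"]))
            row.append(repr(float(cohort.meta.at[pid, "creatinine"])))
            for m in met_cols:
                if cohort.lod_mask.at[pid, m]:
                    row.append(LOD_TOKEN)
                else:
                    v = cohort.values.at[pid, m]
                    row.append("" if pd.isna(v) else repr(float(v)))
            fh.write(",".join(row) + "\n")


LOD_POLICIES = ("half_lod", "zero", "exclude")


@dataclass
class NormalizedMatrix:
    """Creatinine-normalized concentrations with censoring provenance.

    ``values`` are in µmol analyte per mmol creatinine (ratio columns
    unitless); ``lod_mask`` marks cells that were imputed from a censored
    measurement; ``policy`` names the imputation used.
    """

    values: pd.DataFrame
    lod_mask: pd.DataFrame
    policy: str
    panel_hash: str

    def write(self, path: str | Path) -> None:
        """CSV plus a sidecar ``<path>.provenance.json``."""
        path = Path(path)
        self.values.to_csv(path)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump(
                {"lod_policy": self.policy, "panel_hash": self.panel_hash,
                 "units": "umol per mmol creatinine"},
                fh, indent=2,
            )


def normalize_by_creatinine(
    cohort: Cohort, lod_policy: str = "half_lod"
) -> NormalizedMatrix:
    """Divide raw concentrations by urinary creatinine.

    Censored cells are imputed per ``lod_policy``:

    * ``half_lod`` — (LOD/2)/creatinine (requires a panel LOD for every
      censored metabolite, else :class:`NormalizationError`);
    * ``zero`` — 0;
    * ``exclude`` — left missing.

    Cells stay flagged in the returned mask regardless of policy, so the
    count of censored cells is conserved. Row and column order match the
    input. Ratio pseudo-metabolites are not divided by creatinine.
    """
    if lod_policy not in LOD_POLICIES:
        raise NormalizationError(
            f"unknown lod_policy {lod_policy!r}; expected one of {LOD_POLICIES}"
        )
    factor = _CREATININE_UNIT_FACTORS[cohort.creatinine_units]
    cre_mmol = cohort.meta["creatinine"].astype(float) * factor

    out = pd.DataFrame(
        np.nan, index=cohort.values.index, columns=cohort.values.columns, dtype=float
    )
    for m in cohort.values.columns:
        entry = cohort.panel[m]
        col = cohort.values[m].astype(float)
        norm = col.copy() if entry.is_ratio else col / cre_mmol
        censored = cohort.lod_mask[m]
        if censored.any():
            if lod_policy == "half_lod":
                if entry.lod is None:
                    raise NormalizationError(
                        f"policy half_lod needs an LOD for censored metabolite "
                        f"{m!r} but the panel has none"
                    )
                fill = entry.lod / 2.0
                norm[censored] = fill if entry.is_ratio else fill / cre_mmol[censored]
            elif lod_policy == "zero":
                norm[censored] = 0.0
            else:  # exclude
                norm[censored] = np.nan
        out[m] = norm

    bad = out.to_numpy()
    finite_ok = np.isfinite(bad) | np.isnan(bad)
    if not finite_ok.all():
        raise NormalizationError("normalization produced non-finite values")
    return NormalizedMatrix(
        values=out,
        lod_mask=cohort.lod_mask.copy(),
        policy=lod_policy,
        panel_hash=cohort.panel.content_hash(),
    )
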