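"""Metabolite panel definitions.

A panel lists the urinary metabolites evaluated by the screen. Each entry
records the metabolic family the compound belongs to (phenylalanine-derived,
tryptophan-derived, or yeast/other microbial), the direction in which an
abnormal value departs from the typically-developing (TD) reference range
(``high`` for elevations — the usual case for microbially-derived
metabolites — or ``low`` for depletions such as N-formyl methionine), the
assay limit of detection (LOD) in raw concentration units, and the
measurement units. Ratio pseudo-metabolites (e.g. the phenylalanine/tyrosine
ratio) are marked so that creatinine normalization leaves them untouched.

Panels are serializable to YAML and CSV and carry a stable content hash used
to tie reference-range artifacts to the panel they were built with.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import yaml

from .errors import PanelError

FAMILIES = ("phenylalanine", "tryptophan", "yeast_other")
DIRECTIONS = ("high", "low")


@dataclass(frozen=True)
class PanelEntry:
    """One metabolite in the panel."""

    metabolite_id: str
    display_name: str = ""
    family: str = "yeast_other"
    direction: str = "high"
    lod: float | None = None
    units: str = "umol/L"
    is_ratio: bool = False

    def __post_init__(self):
        if not self.metabolite_id:
            raise PanelError("metabolite_id must be non-empty")
        if self.family not in FAMILIES:
            raise PanelError(
                f"{self.metabolite_id}: family {self.family!r} not one of {FAMILIES}"
            )
        if self.direction not in DIRECTIONS:
            raise PanelError(
                f"{self.metabolite_id}: direction {self.direction!r} not one of {DIRECTIONS}"
            )
        if self.lod is not None and not (self.lod >= 0):
            raise PanelError(f"{self.metabolite_id}: lod must be non-negative")


@dataclass
class MetabolitePanel:
    """Ordered collection of :class:`PanelEntry` with unique ids."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.metabolite_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate metabolite ids: {dupes}")

    def ids(self) -> list[str]:
        return [e.metabolite_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self.entries)

    def __contains__(self, metabolite_id: str) -> bool:
        return any(e.metabolite_id == metabolite_id for e in self.entries)

    def __getitem__(self, metabolite_id: str) -> PanelEntry:
        for e in self.entries:
            if e.metabolite_id == metabolite_id:
                return e
        raise KeyError(metabolite_id)

    def subset(self, metabolite_ids: list[str]) -> "MetabolitePanel":
        return MetabolitePanel([self[m] for m in metabolite_ids])

    def with_lods(self, lods: dict[str, float | None]) -> "MetabolitePanel":
        """Return a copy with LODs replaced where given."""
        new = []
        for e in self.entries:
            if e.metabolite_id in lods:
                new.append(
                    PanelEntry(
                        e.metabolite_id, e.display_name, e.family, e.direction,
                        lods[e.metabolite_id], e.units, e.is_ratio,
                    )
                )
            else:
                new.append(e)
        return MetabolitePanel(new)

    # -- serialization ------------------------------------------------------

    def to_dicts(self) -> list[dict]:
        return [asdict(e) for e in self.entries]

    def content_hash(self) -> str:
        """SHA-256 of the canonical JSON serialization (first 16 hex chars)."""
        blob = json.dumps(self.to_dicts(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"metabolites": self.to_dicts()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MetabolitePanel":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "metabolites" not in data:
            raise PanelError(f"{path}: expected a mapping with a 'metabolites' key")
        return cls([PanelEntry(**d) for d in data["metabolites"]])

    def to_csv(self, path: str | Path) -> None:
        cols = ["metabolite_id", "display_name", "family", "direction",
                "lod", "units", "is_ratio"]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for d in self.to_dicts():
                d = dict(d)
                d["lod"] = "" if d["lod"] is None else d["lod"]
                d["is_ratio"] = "true" if d["is_ratio"] else "false"
                w.writerow(d)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MetabolitePanel":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                lod = row.get("lod", "")
                entries.append(
                    PanelEntry(
                        metabolite_id=row["metabolite_id"],
                        display_name=row.get("display_name", ""),
                        family=row.get("family", "yeast_other"),
                        direction=row.get("direction", "high"),
                        lod=None if lod in ("", None) else float(lod),
                        units=row.get("units", "umol/L"),
                        is_ratio=str(row.get("is_ratio", "false")).lower()
                        in ("true", "1", "yes"),
                    )
                )
        return cls(entries)

    @classmethod
    def load(cls, path: str | Path) -> "MetabolitePanel":
        """Load from YAML (.yaml/.yml) or CSV (anything else)."""
        p = Path(path)
        if p.suffix.lower() in (".yaml", ".yml"):
            return cls.from_yaml(p)
        return cls.from_csv(p)
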