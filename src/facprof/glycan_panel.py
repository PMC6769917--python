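"""Glycan panel data model and TSV I/O.

A panel is the ordered list of pyridylaminated (PA) glycans profiled on a
lectin column.  Each glycan carries a zero-padded string id (leading zeros
are significant: "003" != "3"), a free-text composition name, exactly one
structural class, and a set of independent boolean motif flags.  Motifs are
input data, not derived from structure parsing: the biology downstream
reasons at the motif level (e.g. presence of a Man-alpha1-6-Man arm, a
bisecting GlcNAc, or the plant fucose/xylose core).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

GLYCAN_CLASSES = (
    "high_mannose",
    "hybrid",
    "agalacto",
    "galactosylated",
    "sialylated",
    "glycolipid",
    "other",
)

#: The five asparagine-linked structural classes (the "61 N-linked" axis).
N_LINKED_CLASSES = GLYCAN_CLASSES[:5]

#: Complex-type N-glycan classes used for subgroup classification.
COMPLEX_CLASSES = ("agalacto", "galactosylated", "sialylated")

MOTIF_FLAGS = (
    "man_a1_6_man",
    "man_a1_3_man",
    "bisecting_glcnac",
    "core_pentasaccharide",
    "plant_fuc_xyl_core",
    "four_branch",
    "chitin_type",
)


@dataclass(frozen=True)
class GlycanRecord:
    """One glycan: id, composition name, structural class, motif flags."""

    id: str
    name: str
    glycan_class: str
    motifs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("glycan id must be non-empty")
        if self.glycan_class not in GLYCAN_CLASSES:
            raise ValidationError(
                f"unknown glycan class {self.glycan_class!r} for id {self.id!r}; "
                f"expected one of {GLYCAN_CLASSES}"
            )
        unknown = set(self.motifs) - set(MOTIF_FLAGS)
        if unknown:
            raise ValidationError(
                f"unknown motif flags {sorted(unknown)} for id {self.id!r}"
            )

    def has_motif(self, flag: str) -> bool:
        return flag in self.motifs


@dataclass(frozen=True)
class GlycanPanel:
    """Ordered, id-unique collection of glycan records."""

    records: tuple[GlycanRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("panel must contain at least one glycan")
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate glycan id {rec.id!r} in panel")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rec.id for rec in self.records)

    def get(self, glycan_id: str) -> GlycanRecord:
        for rec in self.records:
            if rec.id == glycan_id:
                return rec
        raise KeyError(glycan_id)

    def __contains__(self, glycan_id: str) -> bool:
        return any(rec.id == glycan_id for rec in self.records)

    def ids_in_classes(self, classes) -> tuple[str, ...]:
        wanted = set(classes)
        return tuple(r.id for r in self.records if r.glycan_class in wanted)

    def ids_with_motif(self, flag: str) -> tuple[str, ...]:
        return tuple(r.id for r in self.records if flag in r.motifs)


def class_counts(panel: GlycanPanel) -> dict[str, int]:
    """Number of glycans per structural class; values sum to len(panel)."""
    counts = Counter(rec.glycan_class for rec in panel)
    return {cls: counts.get(cls, 0) for cls in GLYCAN_CLASSES if counts.get(cls, 0)}


def n_linked_count(panel: GlycanPanel) -> int:
    """Total glycans across the five N-linked structural classes."""
    counts = class_counts(panel)
    return sum(counts.get(cls, 0) for cls in N_LINKED_CLASSES)


def load_panel(path) -> GlycanPanel:
    """Read a panel TSV (columns: id, name, class, one 0/1 column per motif).

    Ids are read as strings so zero-padded codes survive the round trip.
    Raises :class:`ValidationError` on duplicate ids, unknown class labels,
    missing required columns, or an empty file.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"id": str}, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"panel file {path} is empty") from None
    required = {"id", "name", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"panel file {path} missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"panel file {path} has no records")
    motif_cols = [c for c in df.columns if c in MOTIF_FLAGS]
    records = []
    for d in df.to_dict("records"):
        motifs = frozenset(m for m in motif_cols if int(d[m]) == 1)
        records.append(
            GlycanRecord(
                id=str(d["id"]),
                name=str(d["name"]),
                glycan_class=str(d["class"]),
                motifs=motifs,
            )
        )
    return GlycanPanel(records=tuple(records), provenance=str(path))


def write_panel(panel: GlycanPanel, path) -> None:
    """Write a panel to TSV in the format accepted by :func:`load_panel`."""
    rows = []
    for rec in panel:
        row = {"id": rec.id, "name": rec.name, "class": rec.glycan_class}
        for flag in MOTIF_FLAGS:
            row[flag] = int(flag in rec.motifs)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
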