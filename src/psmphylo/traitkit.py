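"""Family x metabolite-class presence matrices and their summaries.

A :class:`TraitMatrix` is a families x classes grid of ternary cells
(present / absent / unknown).  The analysis view is binary: present -> 1,
absent and unknown -> 0, mirroring the coding convention under which a class
is scored 1 for a family if at least one surveyed taxon in it has the class
and 0 if it is absent from, or unclear in, all known taxa.  The ternary
states are kept distinct in storage so that "absent" and "never surveyed"
remain distinguishable for later re-analysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .treekit import Phylogeny

__all__ = [
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "PSMRecord",
    "TraitMatrix",
    "AlignmentReport",
    "code_matrix",
    "class_prevalence",
    "richness_histogram",
    "usable_family_count",
    "align_to_tree",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_records_tsv",
]

PRESENT: int = 1
ABSENT: int = 0
UNKNOWN: int = -1

_STATE_SYNONYMS = {
    "1": PRESENT,
    "present": PRESENT,
    "0": ABSENT,
    "absent": ABSENT,
    "na": UNKNOWN,
    "nan": UNKNOWN,
    "": UNKNOWN,
    "unknown": UNKNOWN,
    "?": UNKNOWN,
}
_STATE_TO_TEXT = {PRESENT: "1", ABSENT: "0", UNKNOWN: "NA"}


@dataclass(frozen=True)
class PSMRecord:
    """One literature record: a taxon in a family reported to have a class."""

    taxon: str
    family: str
    class_name: str
    evidence: str = ""

    def __post_init__(self):
        if not self.family:
            raise ValueError("record family must be non-empty")
        if not self.class_name:
            raise ValueError("record class_name must be non-empty")


class TraitMatrix:
    """Ternary presence matrix over ordered families and classes.

    Backed by an int8 DataFrame with cells in {1 present, 0 absent,
    -1 unknown}; family order and class order are part of the object's
    identity (writers emit them verbatim).
    """

    def __init__(self, cells: pd.DataFrame):
        if cells.shape[1] == 0:
            raise ValueError("no classes")
        if cells.shape[0] == 0:
            raise ValueError("no families")
        if cells.index.has_duplicates:
            raise ValueError("duplicate family names")
        if cells.columns.has_duplicates:
            raise ValueError("duplicate class names")
        values = cells.to_numpy()
        bad = ~np.isin(values, (PRESENT, ABSENT, UNKNOWN))
        if bad.any():
            raise ValueError("cells must be in {present=1, absent=0, unknown=-1}")
        self._cells = cells.astype(np.int8)

    # -- basic views -------------------------------------------------------

    @property
    def families(self) -> list[str]:
        return list(self._cells.index)

    @property
    def classes(self) -> list[str]:
        return list(self._cells.columns)

    @property
    def cells(self) -> pd.DataFrame:
        """Ternary cells (int8 copy)."""
        return self._cells.copy()

    def binary(self) -> pd.DataFrame:
        """Analysis view: present -> 1, absent/unknown -> 0."""
        return (self._cells == PRESENT).astype(np.int8)

    def state(self, family: str, class_name: str) -> int:
        return int(self._cells.at[family, class_name])

    def column_values(self, class_name: str, families: Sequence[str]) -> dict[str, int]:
        """Binary values of one class for the given families, as a dict."""
        col = self.binary()[class_name]
        return {f: int(col[f]) for f in families}

    def n_present(self) -> int:
        return int((self._cells.to_numpy() == PRESENT).sum())

    def restrict(self, families: Sequence[str]) -> "TraitMatrix":
        return TraitMatrix(self._cells.loc[list(families)])

    def with_cells(self, cells: pd.DataFrame) -> "TraitMatrix":
        return TraitMatrix(cells)

    def rename_families(self, synonyms: Mapping[str, str]) -> "TraitMatrix":
        """Normalization hook: rename families via a synonym table."""
        renamed = self._cells.rename(index=dict(synonyms))
        return TraitMatrix(renamed)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraitMatrix):
            return NotImplemented
        return self._cells.equals(other._cells)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TraitMatrix {len(self.families)} families x {len(self.classes)} classes>"


@dataclass
class AlignmentReport:
    """Names dropped on each side when aligning a matrix to a tree."""

    tree_only: list[str] = field(default_factory=list)
    matrix_only: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Coding and summaries
# ---------------------------------------------------------------------------


def code_matrix(
    records: Iterable[PSMRecord],
    families: Sequence[str],
    classes: Sequence[str],
) -> tuple[TraitMatrix, list[PSMRecord]]:
    """Code literature records into a ternary matrix.

    A cell is marked present iff at least one record names that (family,
    class) pair; duplicate records are idempotent.  Families with no records
    stay all-unknown.  Records whose family is not in ``families`` are
    returned as rejects rather than silently dropped; a record naming an
    unlisted class is an error (the class list is the analysis contract).
    """
    families = list(families)
    classes = list(classes)
    cells = pd.DataFrame(
        np.full((len(families), len(classes)), UNKNOWN, dtype=np.int8),
        index=families,
        columns=classes,
    )
    fam_set = set(families)
    rejects: list[PSMRecord] = []
    for rec in records:
        if rec.class_name not in classes:
            raise ValueError(f"record class {rec.class_name!r} not in class list")
        if rec.family not in fam_set:
            rejects.append(rec)
            continue
        cells.at[rec.family, rec.class_name] = PRESENT
    return TraitMatrix(cells), rejects


def class_prevalence(matrix: TraitMatrix, class_name: str) -> int:
    """Number of families scored present for one class (binary column sum)."""
    if class_name not in matrix.classes:
        raise KeyError(f"unknown class {class_name!r}")
    return int(matrix.binary()[class_name].sum())


def richness_histogram(matrix: TraitMatrix) -> dict[int, int]:
    """How many families have exactly k classes present, for observed k.

    Returns a sparse mapping (zero-count richness levels omitted); values
    sum to the number of families.
    """
    richness = matrix.binary().sum(axis=1)
    counts = richness.value_counts().sort_index()
    return {int(k): int(v) for k, v in counts.items()}


def usable_family_count(matrix: TraitMatrix) -> int:
    """Families with at least one class present (>=1 recorded class)."""
    return int((matrix.binary().sum(axis=1) > 0).sum())


def align_to_tree(
    matrix: TraitMatrix, tree: Phylogeny
) -> tuple[TraitMatrix, AlignmentReport]:
    """Restrict the matrix to families on the tree, in tree tip order."""
    tip_order = tree.tip_labels
    fam_set = set(matrix.families)
    shared = [f for f in tip_order if f in fam_set]
    if not shared:
        raise ValueError("no families shared between matrix and tree")
    report = AlignmentReport(
        tree_only=[f for f in tip_order if f not in fam_set],
        matrix_only=[f for f in matrix.families if f not in set(tip_order)],
    )
    return matrix.restrict(shared), report


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_matrix_tsv(path: str | os.PathLike) -> TraitMatrix:
    """Read a matrix TSV: first column ``family``, one column per class.

    Cells may use {1,0,NA} or the synonyms {present,absent,unknown,?}.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "family":
        raise ValueError("matrix TSV must start with a 'family' column")
    df = df.set_index("family")

    def decode(cell: str) -> int:
        key = cell.strip().lower()
        if key not in _STATE_SYNONYMS:
            raise ValueError(f"unrecognized cell value {cell!r}")
        return _STATE_SYNONYMS[key]

    coded = df.map(decode).astype(np.int8)
    return TraitMatrix(coded)


def write_matrix_tsv(matrix: TraitMatrix, path: str | os.PathLike) -> None:
    """Write the matrix with cells in {1,0,NA}, preserving stored order."""
    out = matrix.cells.map(lambda v: _STATE_TO_TEXT[int(v)])
    out.index.name = "family"
    out.to_csv(path, sep="\t")


def read_records_tsv(path: str | os.PathLike) -> list[PSMRecord]:
    """Read records TSV with columns taxon, family, class, evidence."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"taxon", "family", "class"}
    if not needed.issubset(df.columns):
        raise ValueError(f"records TSV must have columns {sorted(needed)}")
    return [
        PSMRecord(
            taxon=row["taxon"],
            family=row["family"],
            class_name=row["class"],
            evidence=row.get("evidence", ""),
        )
        for _, row in df.iterrows()
    ]
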