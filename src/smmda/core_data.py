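"""Tabular inputs, name/index bookkeeping, and the association matrix.

The pipeline's ground truth is a list of known (miRNA, disease) pairs —
the positive class of a bipartite link-prediction problem.  This module
reads those lists, canonicalizes names, builds the 0/1 disease×miRNA
incidence matrix, and parses MeSH-style descriptor tables (heading plus
one or more dot-delimited tree numbers) from which the disease hierarchy
is later derived.

Conventions
-----------
* Names are canonicalized by whitespace-trimming and case-folding; no
  alias resolution is attempted.
* All indices are sorted lexicographically so every downstream matrix is
  reproducible without a stored ordering.
* The association matrix is oriented diseases×rows, miRNAs×columns; code
  always refers to axes by role.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataValidationError, EmptyInputError

__all__ = [
    "AssociationList",
    "AssociationMatrix",
    "MeshDescriptorTable",
    "canonical_name",
    "read_association_list",
    "write_association_list",
    "build_adjacency",
    "parse_mesh_descriptors",
    "TREE_NUMBER_RE",
]

TREE_NUMBER_RE = re.compile(r"^[A-Z][0-9]+(\.[0-9]+)*$")


def canonical_name(name: str) -> str:
    """Trim surrounding whitespace and case-fold a miRNA/disease name."""
    return name.strip().casefold()


@dataclass(frozen=True)
class AssociationList:
    """Deduplicated, canonicalized (miRNA, disease) pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for m, d in self.pairs:
            if not m or not d:
                raise DataValidationError(f"empty name in pair {(m, d)!r}")
            if (m, d) in seen:
                raise DataValidationError(f"duplicate pair {(m, d)!r}")
            seen.add((m, d))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationList":
        """Canonicalize and deduplicate, preserving first-seen order."""
        out: dict[tuple[str, str], None] = {}
        for m, d in pairs:
            out[(canonical_name(m), canonical_name(d))] = None
        return cls(tuple(out))

    @property
    def mirnas(self) -> tuple[str, ...]:
        return tuple(sorted({m for m, _ in self.pairs}))

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted({d for _, d in self.pairs}))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class AssociationMatrix:
    """0/1 incidence matrix, rows = diseases, columns = miRNAs."""

    values: np.ndarray
    disease_index: tuple[str, ...]
    mirna_index: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.disease_index), len(self.mirna_index)):
            raise DataValidationError(
                f"matrix shape {v.shape} does not match index sizes "
                f"({len(self.disease_index)}, {len(self.mirna_index)})"
            )
        if not np.isin(v, (0, 1)).all():
            raise DataValidationError("association matrix entries must be 0/1")

    def disease_pos(self, name: str) -> int:
        return self.disease_index.index(name)

    def mirna_pos(self, name: str) -> int:
        return self.mirna_index.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.disease_index), columns=list(self.mirna_index)
        )

    def positive_pairs(self) -> list[tuple[str, str]]:
        """All (miRNA, disease) pairs with a 1 entry."""
        di, mi = np.nonzero(self.values)
        return [(self.mirna_index[j], self.disease_index[i]) for i, j in zip(di, mi)]


@dataclass(frozen=True)
class MeshDescriptorTable:
    """MeSH-style records: heading name plus its tree numbers."""

    records: tuple[tuple[str, tuple[str, ...]], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for heading, numbers in self.records:
            for tn in numbers:
                if not TREE_NUMBER_RE.match(tn):
                    raise DataValidationError(
                        f"invalid tree number {tn!r} for heading {heading!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def headings(self) -> tuple[str, ...]:
        return tuple(h for h, _ in self.records)

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return dict(self.records)


def _resolve_columns(
    df: pd.DataFrame, mirna_col: str | int | None, disease_col: str | int | None
) -> tuple[str, str]:
    def pick(col, default_pos, role):
        if col is None:
            if df.shape[1] <= default_pos:
                raise ConfigurationError(
                    f"no column available for the {role} names (file has "
                    f"{df.shape[1]} columns)"
                )
            return df.columns[default_pos]
        if isinstance(col, int):
            if col >= df.shape[1]:
                raise ConfigurationError(f"{role} column index {col} out of range")
            return df.columns[col]
        if col not in df.columns:
            raise ConfigurationError(
                f"{role} column {col!r} not found; available: {list(df.columns)}"
            )
        return col

    return pick(mirna_col, 0, "miRNA"), pick(disease_col, 1, "disease")


def read_association_list(
    path: str | Path,
    *,
    sep: str | None = None,
    mirna_col: str | int | None = None,
    disease_col: str | int | None = None,
    header: bool = True,
) -> AssociationList:
    """Read a 2+-column TSV/CSV of (miRNA, disease) pairs.

    By default the first column holds miRNA names and the second disease
    names; pass ``mirna_col``/``disease_col`` (name or position) when the
    file uses another layout.  ``sep=None`` picks comma for ``.csv``
    files and tab otherwise.

    Raises
    ------
    EmptyInputError
        If the file holds no data rows.
    ConfigurationError
        If a requested column cannot be resolved.
    DataValidationError
        If any row has an empty miRNA or disease name (the offending row
        is named in the message).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            engine="python",
            header=0 if header else None,
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"association file {path} is empty") from None
    if df.empty:
        raise EmptyInputError(f"association file {path} has no data rows")
    mcol, dcol = _resolve_columns(df, mirna_col, disease_col)
    pairs = []
    for row_number, (m, d) in enumerate(zip(df[mcol], df[dcol]), start=1):
        m = "" if pd.isna(m) else canonical_name(str(m))
        d = "" if pd.isna(d) else canonical_name(str(d))
        if not m or not d:
            raise DataValidationError(
                f"{path}: data row {row_number} has an empty "
                f"{'miRNA' if not m else 'disease'} name"
            )
        pairs.append((m, d))
    return AssociationList.from_pairs(pairs)


def write_association_list(assocs: AssociationList, path: str | Path) -> None:
    """Write pairs as a two-column TSV (miRNA, disease) with a header."""
    df = pd.DataFrame(list(assocs.pairs), columns=["mirna", "disease"])
    df.to_csv(path, sep="\t", index=False)


def build_adjacency(assocs: AssociationList) -> AssociationMatrix:
    """Build the 0/1 disease×miRNA incidence matrix.

    Row and column indices are the lexicographically sorted unique names,
    so the result is invariant under permutation of the input pair list.
    """
    if len(assocs) == 0:
        raise EmptyInputError("cannot build an adjacency matrix from zero pairs")
    mirnas = assocs.mirnas
    diseases = assocs.diseases
    mpos = {m: j for j, m in enumerate(mirnas)}
    dpos = {d: i for i, d in enumerate(diseases)}
    values = np.zeros((len(diseases), len(mirnas)), dtype=np.int8)
    for m, d in assocs.pairs:
        values[dpos[d], mpos[m]] = 1
    return AssociationMatrix(values=values, disease_index=diseases, mirna_index=mirnas)


def _parse_mesh_tsv(path: Path) -> list[tuple[str, tuple[str, ...]]]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataValidationError(
                    f"{path}:{lineno}: expected 'heading<TAB>tree;numbers'"
                )
            heading = canonical_name(parts[0])
            numbers = tuple(t.strip() for t in parts[1].split(";") if t.strip())
            records.append((heading, numbers))
    return records


def _parse_mesh_ascii(path: Path) -> list[tuple[str, tuple[str, ...]]]:
    # MeSH ASCII descriptor export: *NEWRECORD blocks with MH = / MN = lines.
    records: list[tuple[str, tuple[str, ...]]] = []
    heading: str | None = None
    numbers: list[str] = []

    def flush():
        nonlocal heading, numbers
        if heading is not None:
            records.append((heading, tuple(numbers)))
        heading, numbers = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("*NEWRECORD"):
                flush()
            elif line.startswith("MH = "):
                heading = canonical_name(line[5:])
            elif line.startswith("MN = "):
                numbers.append(line[5:].strip())
    flush()
    return records


def _parse_mesh_xml(path: Path) -> list[tuple[str, tuple[str, ...]]]:
    # MeSH XML descriptor export (DescriptorRecordSet); stdlib etree suffices.
    import xml.etree.ElementTree as ET

    tree = ET.parse(path)
    records = []
    for rec in tree.getroot().iter("DescriptorRecord"):
        name = rec.findtext("DescriptorName/String")
        if name is None:
            continue
        numbers = tuple(
            tn.text.strip() for tn in rec.iter("TreeNumber") if tn.text is not None
        )
        records.append((canonical_name(name), numbers))
    return records


def parse_mesh_descriptors(
    path: str | Path, format: str = "tsv"
) -> MeshDescriptorTable:
    """Parse a MeSH-style descriptor table.

    ``format="tsv"`` is the package's minimal dialect: one line per
    heading, ``heading<TAB>number;number``.  ``"ascii"`` reads the NLM
    ``*NEWRECORD``/``MH =``/``MN =`` export, ``"xml"`` the descriptor XML.
    Tree numbers are validated against ``[A-Z][0-9]+(.[0-9]+)*``.
    """
    path = Path(path)
    parsers = {"tsv": _parse_mesh_tsv, "ascii": _parse_mesh_ascii, "xml": _parse_mesh_xml}
    if format not in parsers:
        raise ConfigurationError(f"unknown MeSH format {format!r}")
    return MeshDescriptorTable(records=tuple(parsers[format](path)))


def write_mesh_descriptors(table: MeshDescriptorTable, path: str | Path) -> None:
    """Write the minimal TSV dialect (heading TAB semicolon-joined numbers)."""
    with open(path, "w") as fh:
        for heading, numbers in table.records:
            fh.write(f"{heading}\t{';'.join(numbers)}\n")
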