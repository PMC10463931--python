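"""Multiple sequence alignments and generic-position (Ballesteros-Weinstein) mapping.

An :class:`MSA` holds aligned rows of equal length ``L`` and, per target, the
strictly increasing map from ungapped residue index to 1-based alignment
column.  Residue-specific descriptor features are laid out position-major over
the ``L`` columns, so this module is also where feature names of the form
``AA{column}_PC{component}`` are parsed and traced back to GPCR generic
positions (Ballesteros-Weinstein labels such as ``3.32``) or, failing that, to
a region label (N-term, TM1-7, ICL1-3, ECL1-3, H8, C-term).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import AlignIO

__all__ = [
    "MSA",
    "GenericPositionTable",
    "parse_msa",
    "column_to_residue",
    "trace_feature",
    "write_msa",
]

GAP_CHARS = ("-", ".")

#: regex for residue-specific descriptor feature names, e.g. "AA223_PC3"
_FEATURE_RE = re.compile(r"^AA(\d+)_PC(\d+)$")


@dataclass
class MSA:
    """An aligned set of sequences with per-target residue-to-column maps.

    Attributes
    ----------
    ids : list of str
        Target identifiers, in file order.
    rows : dict
        Target id -> aligned row (residues plus gap characters), length ``L``.
    maps : dict
        Target id -> list of 1-based alignment columns, one per ungapped
        residue, strictly increasing.
    """

    ids: list[str]
    rows: dict[str, str]
    maps: dict[str, list[int]] = field(init=False)

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("alignment has no records")
        lengths = {len(self.rows[i]) for i in self.ids}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")
        self.maps = {}
        for tid in self.ids:
            row = self.rows[tid]
            self.maps[tid] = [
                col for col, ch in enumerate(row, start=1) if ch not in GAP_CHARS
            ]

    @property
    def n_columns(self) -> int:
        """Alignment length L."""
        return len(self.rows[self.ids[0]])

    def ungapped_length(self, target_id: str) -> int:
        return len(self.map_for(target_id))

    def map_for(self, target_id: str) -> list[int]:
        if target_id not in self.rows:
            raise KeyError(f"target {target_id!r} not in alignment")
        return self.maps[target_id]

    def sequence(self, target_id: str) -> str:
        """Ungapped sequence of a target."""
        row = self.rows[target_id] if target_id in self.rows else None
        if row is None:
            raise KeyError(f"target {target_id!r} not in alignment")
        return "".join(ch for ch in row if ch not in GAP_CHARS)

    def gap_columns(self, target_id: str) -> set[int]:
        """1-based columns where the target has a gap."""
        return set(range(1, self.n_columns + 1)) - set(self.map_for(target_id))


def parse_msa(path: str | Path) -> MSA:
    """Read an aligned FASTA file into an :class:`MSA`.

    Both ``-`` and ``.`` are accepted as gap characters.  Raises on ragged
    rows (Biopython refuses them) and on duplicate record ids.
    """
    alignment = AlignIO.read(str(path), "fasta")
    ids = [rec.id for rec in alignment]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in alignment")
    rows = {rec.id: str(rec.seq) for rec in alignment}
    return MSA(ids=ids, rows=rows)


def write_msa(msa: MSA, path: str | Path) -> None:
    """Write an :class:`MSA` as aligned FASTA."""
    with open(path, "w") as fh:
        for tid in msa.ids:
            fh.write(f">{tid}\n{msa.rows[tid]}\n")


GAP = object()  #: sentinel returned by column_to_residue at gap columns


def column_to_residue(msa: MSA, target_id: str, column: int):
    """Invert the residue->column map at one 1-based column.

    Returns the 0-based residue index of ``target_id`` whose alignment column
    is ``column``, or the :data:`GAP` sentinel if the target has a gap there.
    """
    if not 1 <= column <= msa.n_columns:
        raise ValueError(f"column {column} out of range 1..{msa.n_columns}")
    cmap = msa.map_for(target_id)
    try:
        return cmap.index(column)
    except ValueError:
        return GAP


@dataclass
class GenericPositionTable:
    """MSA column -> Ballesteros-Weinstein label and/or region label.

    Loaded from a two/three-column CSV (``column``, ``bw``, ``region``); either
    annotation may be empty for a column.  BW labels are "t.nn" strings
    (helix.offset, x.50 at the most conserved residue of each helix).
    """

    bw: dict[int, str]
    region: dict[int, str]

    _BW_RE = re.compile(r"^\d+x?\.\d+$|^\d+x\d+$|^\d+\.\d+$")
    _REGIONS = {
        "N-term", "TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7",
        "ICL1", "ICL2", "ICL3", "ECL1", "ECL2", "ECL3", "H8", "C-term",
    }

    def __post_init__(self) -> None:
        for col, label in self.bw.items():
            if not self._BW_RE.match(label):
                raise ValueError(f"malformed BW label {label!r} at column {col}")
        for col, label in self.region.items():
            if label not in self._REGIONS:
                raise ValueError(f"unknown region label {label!r} at column {col}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenericPositionTable":
        df = pd.read_csv(path)
        bw: dict[int, str] = {}
        region: dict[int, str] = {}
        for _, row in df.iterrows():
            col = int(row["column"])
            if "bw" in df.columns and isinstance(row.get("bw"), str) and row["bw"]:
                bw[col] = row["bw"]
            if (
                "region" in df.columns
                and isinstance(row.get("region"), str)
                and row["region"]
            ):
                region[col] = row["region"]
        return cls(bw=bw, region=region)

    def label_for(self, column: int) -> str:
        """BW label when present, else region label, else "unannotated"."""
        if column in self.bw:
            return self.bw[column]
        return self.region.get(column, "unannotated")


@dataclass(frozen=True)
class FeatureTrace:
    """Where a residue-specific descriptor feature lives in the protein."""

    column: int
    component: int
    label: str
    residue: int | None  # 0-based residue index in the queried target, if any


def parse_feature_name(name: str) -> tuple[int, int]:
    """Split ``AA{col}_PC{c}`` into (column, component); raises on malformed names."""
    m = _FEATURE_RE.match(name)
    if m is None:
        raise ValueError(f"malformed feature name {name!r}")
    return int(m.group(1)), int(m.group(2))


def trace_feature(
    feature_name: str,
    bw: GenericPositionTable,
    msa: MSA,
    target_id: str | None = None,
) -> FeatureTrace:
    """Trace a descriptor feature back to its generic position.

    The feature name encodes the 1-based alignment column and the residue-PCA
    component.  The returned label is the column's BW generic number when
    annotated, otherwise its region; when ``target_id`` is given, the concrete
    residue of that target at the column is resolved as well (``None`` if the
    target has a gap there).
    """
    column, component = parse_feature_name(feature_name)
    if not 1 <= column <= msa.n_columns:
        raise ValueError(f"column {column} out of range 1..{msa.n_columns}")
    residue = None
    if target_id is not None:
        hit = column_to_residue(msa, target_id, column)
        residue = None if hit is GAP else hit
    return FeatureTrace(
        column=column,
        component=component,
        label=bw.label_for(column),
        residue=residue,
    )
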