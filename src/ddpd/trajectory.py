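"""Topology/trajectory containers, atom and residue selections, RMSD and RMSF.

Coordinates are held in nanometres throughout (the dominant trajectory-library
convention); PDB I/O converts from/to Angstrom via mdtraj.  Residue indices are
0-based internally; alignment columns are 1-based where they surface in
feature names and reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import mdtraj as md
import numpy as np
from mdtraj.core import element as _element

from .msa import MSA

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Trajectory",
    "AtomSelection",
    "ResidueSelection",
    "load_trajectory",
    "select_atoms",
    "select_residues",
    "compute_rmsd",
    "compute_rmsf",
    "map_rmsf_to_msa",
]


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    residue_index: int


@dataclass(frozen=True)
class Residue:
    index: int
    name: str
    number: int  # author numbering, retained for reporting


def _check_element(symbol: str) -> str:
    try:
        _element.get_by_symbol(symbol)
    except KeyError as exc:
        raise ValueError(f"unknown element symbol {symbol!r}") from exc
    return symbol


@dataclass
class Topology:
    """Atoms, residues and a bond graph.

    Hydrogens are kept in the topology (the partial-charge computation needs
    them) and removed only through :class:`AtomSelection`.
    """

    atoms: list[Atom]
    residues: list[Residue]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise ValueError("atom indices must be contiguous from 0")
            _check_element(atom.element)
            if not 0 <= atom.residue_index < len(self.residues):
                raise ValueError(
                    f"atom {i} references missing residue {atom.residue_index}"
                )
        n = len(self.atoms)
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a}, {b}) references a missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    def residue_indices(self) -> np.ndarray:
        """Per-atom residue membership."""
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def atoms_of_residue(self, residue_index: int) -> list[int]:
        return [a.index for a in self.atoms if a.residue_index == residue_index]

    def alpha_carbons(self) -> list[int]:
        """One CA atom index per residue; raises if a residue lacks one."""
        out = []
        for res in self.residues:
            cas = [
                a.index
                for a in self.atoms
                if a.residue_index == res.index and a.name == "CA"
            ]
            if len(cas) != 1:
                raise ValueError(
                    f"residue {res.index} has {len(cas)} CA atoms (need exactly 1)"
                )
            out.append(cas[0])
        return out

    def to_mdtraj(self) -> md.Topology:
        top = md.Topology()
        chain = top.add_chain()
        md_res = []
        for res in self.residues:
            md_res.append(top.add_residue(res.name, chain, resSeq=res.number))
        md_atoms = []
        for atom in self.atoms:
            md_atoms.append(
                top.add_atom(
                    atom.name,
                    _element.get_by_symbol(atom.element),
                    md_res[atom.residue_index],
                )
            )
        for a, b in self.bonds:
            top.add_bond(md_atoms[a], md_atoms[b])
        return top

    @classmethod
    def from_mdtraj(cls, top: md.Topology) -> "Topology":
        residues = [
            Residue(index=r.index, name=r.name, number=r.resSeq)
            for r in top.residues
        ]
        atoms = [
            Atom(
                index=a.index,
                name=a.name,
                element=a.element.symbol if a.element is not None else "VS",
                residue_index=a.residue.index,
            )
            for a in top.atoms
        ]
        bonds = [(b[0].index, b[1].index) for b in top.bonds]
        return cls(atoms=atoms, residues=residues, bonds=bonds)


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (nm) bound to a :class:`Topology`."""

    xyz: np.ndarray
    topology: Topology
    timestep: float | None = None  # ps between frames, if known

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.xyz.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.xyz.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.xyz.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if not np.isfinite(self.xyz).all():
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def to_mdtraj(self) -> md.Trajectory:
        return md.Trajectory(self.xyz.astype(np.float32), self.topology.to_mdtraj())

    def save_pdb(self, path: str | Path) -> None:
        """Write the topology plus the first frame as a PDB file."""
        self.to_mdtraj()[0].save_pdb(str(path))

    def save_dcd(self, path: str | Path) -> None:
        self.to_mdtraj().save_dcd(str(path))

    def save_xtc(self, path: str | Path) -> None:
        self.to_mdtraj().save_xtc(str(path))


def load_trajectory(topology_path: str | Path, coords_path: str | Path) -> Trajectory:
    """Load a PDB topology plus a DCD/XTC/TRR coordinate file.

    Coordinates come back in nanometres.  Bonds are whatever the PDB reader
    reconstructs (CONECT records plus standard residue templates).
    """
    topology_path, coords_path = Path(topology_path), Path(coords_path)
    for p in (topology_path, coords_path):
        if not p.exists():
            raise FileNotFoundError(p)
    ref = md.load(str(topology_path))
    try:
        traj = md.load(str(coords_path), top=ref.topology)
    except Exception as exc:  # mdtraj raises assorted types on mismatch
        raise ValueError(
            f"could not bind {coords_path.name} to {topology_path.name}: {exc}"
        ) from exc
    if traj.n_atoms != ref.n_atoms:
        raise ValueError(
            f"atom-count mismatch: topology {ref.n_atoms}, trajectory {traj.n_atoms}"
        )
    return Trajectory(
        xyz=traj.xyz.astype(np.float64),
        topology=Topology.from_mdtraj(traj.topology),
    )


@dataclass(frozen=True)
class AtomSelection:
    """Ordered atom indices under one of the two selection modes.

    ``all-heavy`` keeps every non-hydrogen atom; ``non-carbon`` additionally
    drops carbons.  Hydrogens never enter a selection.
    """

    indices: tuple[int, ...]
    mode: str

    def __post_init__(self) -> None:
        if list(self.indices) != sorted(set(self.indices)):
            raise ValueError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


ATOM_SELECTION_MODES = ("all-heavy", "non-carbon")


def select_atoms(topology: Topology, mode: str = "all-heavy") -> AtomSelection:
    """Select heavy atoms, optionally excluding carbons ("minus C")."""
    if mode not in ATOM_SELECTION_MODES:
        raise ValueError(f"mode must be one of {ATOM_SELECTION_MODES}, got {mode!r}")
    excluded = {"H"} if mode == "all-heavy" else {"H", "C"}
    indices = tuple(a.index for a in topology.atoms if a.element not in excluded)
    if not indices:
        raise ValueError(f"empty atom selection under mode {mode!r}")
    return AtomSelection(indices=indices, mode=mode)


@dataclass(frozen=True)
class ResidueSelection:
    """Ordered residue indices, tagged with the family level they encode."""

    indices: tuple[int, ...]
    level: str = "full"
    pocket_columns: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if not self.indices:
            raise ValueError("empty residue selection")


RESIDUE_SELECTION_LEVELS = ("full", "class", "family", "subfamily", "target")


def select_residues(
    topology: Topology,
    level: str = "full",
    pocket_columns: set[int] | None = None,
    msa: MSA | None = None,
    target_id: str | None = None,
) -> ResidueSelection:
    """Select all residues, or the residues at a set of pocket MSA columns.

    Non-``full`` levels encode binding-pocket definitions at some family level;
    all of them resolve the same way here: the selection keeps the residues of
    ``target_id`` whose alignment column is in ``pocket_columns``.
    """
    if level not in RESIDUE_SELECTION_LEVELS:
        raise ValueError(f"unknown selection level {level!r}")
    if level == "full":
        return ResidueSelection(
            indices=tuple(r.index for r in topology.residues), level=level
        )
    if pocket_columns is None or msa is None or target_id is None:
        raise ValueError(
            "pocket_columns, msa and target_id are required for non-full selections"
        )
    cmap = msa.map_for(target_id)
    hits = tuple(
        res_idx for res_idx, col in enumerate(cmap) if col in pocket_columns
    )
    hits = tuple(i for i in hits if i < topology.n_residues)
    if not hits:
        raise ValueError("pocket columns fall entirely in the target's gaps")
    return ResidueSelection(
        indices=hits, level=level, pocket_columns=frozenset(pocket_columns)
    )


def compute_rmsd(traj: Trajectory) -> np.ndarray:
    """Per-frame RMSD (nm) against frame 0, after optimal superposition.

    Every frame is rigid-body superposed onto the first frame over all protein
    atoms before the deviation is measured, so the series is invariant to
    rigid motions of whole frames and frame 0 maps to exactly 0.
    """
    m = traj.to_mdtraj()
    out = md.rmsd(m, m, 0).astype(np.float64)
    out[0] = 0.0  # exact, not float-fuzzy
    return out


def compute_rmsf(traj: Trajectory) -> np.ndarray:
    """Per-residue RMSF (nm) of the C-alpha atoms over all frames.

    Frames are superposed (on the C-alpha atoms) first onto frame 0 and then
    onto the resulting average structure; the fluctuation of each residue's
    C-alpha about its mean position is
    ``RMSF_r = sqrt(mean_t |x_r(t) - xbar_r|^2)``.
    """
    ca = traj.topology.alpha_carbons()
    m = traj.to_mdtraj()
    m.superpose(m, 0, atom_indices=ca)
    mean_xyz = m.xyz.mean(axis=0, keepdims=True)
    ref = md.Trajectory(mean_xyz, m.topology)
    m.superpose(ref, 0, atom_indices=ca)
    x = m.xyz[:, ca, :].astype(np.float64)
    mean = x.mean(axis=0)
    return np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0))


def map_rmsf_to_msa(rmsf: np.ndarray, msa: MSA, target_id: str) -> np.ndarray:
    """Place per-residue RMSF values at the target's alignment columns.

    Returns a length-L array with NaN (an explicit missing marker, not zero)
    at the target's gap columns.
    """
    rmsf = np.asarray(rmsf, dtype=np.float64)
    cmap = msa.map_for(target_id)
    if rmsf.shape[0] != len(cmap):
        raise ValueError(
            f"RMSF length {rmsf.shape[0]} != target ungapped length {len(cmap)}"
        )
    out = np.full(msa.n_columns, np.nan)
    for res_idx, col in enumerate(cmap):
        out[col - 1] = rmsf[res_idx]
    return out
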