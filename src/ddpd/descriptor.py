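"""The 3DDPD engine: sub-trajectory statistics, charges, two-stage PCA, assembly.

The descriptor pipeline condenses an MD trajectory into a fixed-length vector:

1. the trajectory is cut into sub-trajectories of ``f`` frames and, per
   selected atom and axis, the mean/median/SD ("coordinate" mode) or only the
   SD ("rigidity" mode) of the coordinates is collected per sub-trajectory;
2. one Gasteiger (PEOE) partial charge per atom, computed once on the static
   topology, is appended as a final column;
3. the atom-feature matrix is min-max standardized per column and reduced by
   PCA, keeping the smallest number of components whose cumulative explained
   variance reaches the configured fraction;
4. residue-specific (rs3DDPD): atom-PC scores are grouped per residue as mean
   and SD, standardized again, reduced by a second PCA to exactly ``n``
   components, and laid out position-major over the columns of a reference
   MSA (gap columns are zero blocks) -> length ``n * L``;
   protein-specific (ps3DDPD): the matrices of all targets are stacked and
   reduced together, and each retained PC's scores are aggregated per target
   as average/median/SD -> length ``m * 3``.

Everything here is deterministic: there is no randomness anywhere in
descriptor generation, and PCA axes carry a fixed sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .msa import MSA
from .trajectory import (
    AtomSelection,
    ResidueSelection,
    Topology,
    Trajectory,
    select_atoms,
    select_residues,
)

__all__ = [
    "DescriptorConfig",
    "AtomFeatureMatrix",
    "DescriptorVector",
    "split_subtrajectories",
    "subtrajectory_statistics",
    "gasteiger_charges",
    "assemble_feature_matrix",
    "minmax_standardize",
    "pca_project",
    "compute_rs3ddpd",
    "compute_ps3ddpd",
]

MODES = ("coordinate", "rigidity")
_STATS = {"coordinate": ("mean", "median", "sd"), "rigidity": ("sd",)}
_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class DescriptorConfig:
    """Tunable generation parameters for both descriptor flavors.

    Defaults are the optimized residue-specific settings: rigidity statistics
    on 100-frame splits, 95% atom-PCA variance, 5 residue PCs, all heavy
    atoms, full sequence.  The optimized protein-specific settings differ only
    in the statistics mode (``coordinate``); see :meth:`ps_default`.
    """

    mode: str = "rigidity"
    frame_split: int = 100
    atom_variance: float = 0.95
    residue_pcs: int = 5
    atom_selection: str = "all-heavy"
    residue_selection: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.frame_split < 2:
            raise ValueError("frame_split must be >= 2")
        if not 0 < self.atom_variance <= 1:
            raise ValueError("atom_variance must be in (0, 1]")
        if self.residue_pcs < 1:
            raise ValueError("residue_pcs must be >= 1")

    @classmethod
    def rs_default(cls) -> "DescriptorConfig":
        return cls()

    @classmethod
    def ps_default(cls) -> "DescriptorConfig":
        return cls(mode="coordinate")

    def fingerprint(self) -> str:
        """Compact provenance string recorded on descriptor vectors."""
        return (
            f"mode={self.mode};f={self.frame_split};v={self.atom_variance};"
            f"n={self.residue_pcs};atoms={self.atom_selection};"
            f"residues={self.residue_selection}"
        )


@dataclass
class AtomFeatureMatrix:
    """Per-atom sub-trajectory coordinate statistics (+ optional charge column).

    Rows follow the atom selection order; columns are sub-trajectory-major,
    axis next, statistic innermost, with the partial-charge column (if
    present) last: width ``9*S + 1`` in coordinate mode, ``3*S + 1`` in
    rigidity mode.
    """

    values: np.ndarray
    column_names: list[str]
    atom_indices: tuple[int, ...]
    residue_indices: np.ndarray  # per-row residue membership
    mode: str
    n_subtrajectories: int
    has_charge: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite entries in atom feature matrix")
        expected = len(_STATS[self.mode]) * 3 * self.n_subtrajectories + int(
            self.has_charge
        )
        if self.values.shape[1] != expected:
            raise ValueError(
                f"column count {self.values.shape[1]} != expected {expected}"
            )
        if self.values.shape[0] != len(self.atom_indices):
            raise ValueError("row count != selection size")


@dataclass
class DescriptorVector:
    """A named rs3DDPD or ps3DDPD vector with provenance."""

    kind: str  # "rs" | "ps"
    values: np.ndarray
    feature_names: list[str]
    target_id: str
    config_fingerprint: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.feature_names):
            raise ValueError("values and feature names disagree in length")

    def __len__(self) -> int:
        return self.values.shape[0]


def split_subtrajectories(n_frames: int, frames_per_split: int) -> list[range]:
    """Cut ``n_frames`` into ``floor(F/f)`` contiguous half-open frame ranges.

    Trailing remainder frames are dropped so every sub-trajectory has the same
    length and its statistics stay comparable.
    """
    if frames_per_split < 2:
        raise ValueError("frames_per_split must be >= 2")
    if n_frames < frames_per_split:
        raise ValueError(
            f"trajectory has {n_frames} frames, fewer than the split size "
            f"{frames_per_split}"
        )
    n_splits = n_frames // frames_per_split
    return [
        range(i * frames_per_split, (i + 1) * frames_per_split)
        for i in range(n_splits)
    ]


def subtrajectory_statistics(
    traj: Trajectory,
    ranges: list[range],
    mode: str,
    selection: AtomSelection,
) -> AtomFeatureMatrix:
    """Per-atom coordinate statistics over each sub-trajectory.

    SD is the population form (divide by the sub-trajectory length).  The
    returned matrix has no charge column yet.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if len(selection) == 0:
        raise ValueError("empty atom selection")
    idx = np.array(selection.indices)
    stats = _STATS[mode]
    cols: list[np.ndarray] = []
    names: list[str] = []
    for si, rng in enumerate(ranges, start=1):
        sub = traj.xyz[rng.start : rng.stop, idx, :]
        for ai, axis in enumerate(_AXES):
            data = sub[:, :, ai]
            for stat in stats:
                if stat == "mean":
                    cols.append(data.mean(axis=0))
                elif stat == "median":
                    cols.append(np.median(data, axis=0))
                else:
                    cols.append(data.std(axis=0))  # population SD
                names.append(f"s{si}_{axis}_{stat}")
    res_of_atom = traj.topology.residue_indices()[idx]
    return AtomFeatureMatrix(
        values=np.column_stack(cols),
        column_names=names,
        atom_indices=selection.indices,
        residue_indices=res_of_atom,
        mode=mode,
        n_subtrajectories=len(ranges),
    )


# Sanitization raises inside RDKit on valence problems etc.; we surface those
# as ValueError with the offending topology context.
def gasteiger_charges(topology: Topology) -> np.ndarray:
    """Gasteiger (PEOE) partial charges, one per topology atom.

    The molecule is rebuilt from the topology's elements and bond graph with
    single bonds; hydrogens not present explicitly are treated as implicit by
    RDKit.  Charges are computed once per topology — the charge channel of the
    descriptor is frame-independent.
    """
    if topology.n_atoms == 0:
        raise ValueError("empty topology")
    mol = Chem.RWMol()
    for atom in topology.atoms:
        try:
            mol.AddAtom(Chem.Atom(atom.element))
        except Exception as exc:
            raise ValueError(
                f"element {atom.element!r} not constructible by RDKit"
            ) from exc
    for a, b in topology.bonds:
        mol.AddBond(int(a), int(b), Chem.BondType.SINGLE)
    m = mol.GetMol()
    try:
        Chem.SanitizeMol(m)
    except Exception as exc:
        raise ValueError(f"cannot sanitize topology molecule: {exc}") from exc
    AllChem.ComputeGasteigerCharges(m)
    charges = np.array(
        [a.GetDoubleProp("_GasteigerCharge") for a in m.GetAtoms()], dtype=np.float64
    )
    if not np.isfinite(charges).all():
        raise ValueError(
            "Gasteiger charges did not converge to finite values "
            "(unparameterized element or isolated atom?)"
        )
    return charges


def assemble_feature_matrix(
    stats: AtomFeatureMatrix, charges: np.ndarray, selection: AtomSelection
) -> AtomFeatureMatrix:
    """Append each selected atom's partial charge as the final column."""
    charges = np.asarray(charges, dtype=np.float64)
    if stats.has_charge:
        raise ValueError("matrix already carries a charge column")
    if stats.atom_indices != selection.indices:
        raise ValueError("selection does not match the statistics rows")
    if charges.shape[0] <= max(selection.indices):
        raise ValueError(
            f"charge series covers {charges.shape[0]} atoms but selection "
            f"references index {max(selection.indices)}"
        )
    sel = charges[np.array(selection.indices)]
    return AtomFeatureMatrix(
        values=np.column_stack([stats.values, sel]),
        column_names=stats.column_names + ["charge"],
        atom_indices=stats.atom_indices,
        residue_indices=stats.residue_indices,
        mode=stats.mode,
        n_subtrajectories=stats.n_subtrajectories,
        has_charge=True,
    )


def minmax_standardize(matrix: np.ndarray) -> np.ndarray:
    """Scale every column to [0, 1]; constant columns map to all-zero."""
    X = np.asarray(matrix, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries")
    mn = X.min(axis=0)
    mx = X.max(axis=0)
    span = mx - mn
    out = np.zeros_like(X)
    nz = span > 0
    out[:, nz] = (X[:, nz] - mn[nz]) / span[nz]
    return out


def pca_project(
    matrix: np.ndarray,
    n_components: int | None = None,
    variance: float | None = None,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Mean-centered PCA with a deterministic sign convention.

    Exactly one of ``n_components`` (fixed count) or ``variance`` (retain the
    smallest k whose cumulative explained-variance fraction reaches the
    threshold) must be given.  Each principal axis is oriented so that its
    largest-magnitude loading is positive.  Returns
    ``(scores, k, explained_variance_fractions)`` where the fractions cover
    all components, not only the retained ones.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    if (n_components is None) == (variance is None):
        raise ValueError("give exactly one of n_components or variance")
    Xc = X - X.mean(axis=0)
    # SVD is deterministic (LAPACK) and numerically preferable to forming the
    # covariance matrix explicitly.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2
    total = ev.sum()
    if total <= 0:
        raise ValueError("matrix has zero variance (rank 0)")
    evr = ev / total
    tol = max(Xc.shape) * np.finfo(float).eps * s[0]
    rank = int((s > tol).sum())
    if variance is not None:
        if not 0 < variance <= 1:
            raise ValueError("variance must be in (0, 1]")
        k = int(np.searchsorted(np.cumsum(evr), variance - 1e-12) + 1)
        k = min(k, rank)
    else:
        k = int(n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if k > rank:
            raise ValueError(f"requested {k} components but matrix rank is {rank}")
    axes = Vt[:k]
    # sign convention: largest-|loading| entry of every axis is positive
    flip = axes[np.arange(k), np.abs(axes).argmax(axis=1)] < 0
    axes = np.where(flip[:, None], -axes, axes)
    scores = Xc @ axes.T
    return scores, k, evr


def _group_by_residue(
    scores: np.ndarray, residue_indices: np.ndarray, residues: tuple[int, ...]
) -> np.ndarray:
    """Mean and population SD of each atom-PC score over each residue's atoms.

    Output: residues x (2k) with columns ordered PC-major (PC1_mean, PC1_sd,
    PC2_mean, ...).  Single-atom residues get SD 0.
    """
    k = scores.shape[1]
    out = np.zeros((len(residues), 2 * k))
    for ri, res in enumerate(residues):
        rows = scores[residue_indices == res]
        if rows.shape[0] == 0:
            raise ValueError(f"residue {res} has no atoms in the selection")
        out[ri, 0::2] = rows.mean(axis=0)
        out[ri, 1::2] = rows.std(axis=0)
    return out


def _resolve_selections(
    traj: Trajectory,
    config: DescriptorConfig,
    msa: MSA | None = None,
    target_id: str | None = None,
    pocket_columns: set[int] | None = None,
) -> tuple[AtomSelection, ResidueSelection]:
    residues = select_residues(
        traj.topology,
        level=config.residue_selection,
        pocket_columns=pocket_columns,
        msa=msa,
        target_id=target_id,
    )
    atoms = select_atoms(traj.topology, config.atom_selection)
    if config.residue_selection != "full":
        keep = set(residues.indices)
        indices = tuple(
            i
            for i in atoms.indices
            if traj.topology.atoms[i].residue_index in keep
        )
        if not indices:
            raise ValueError("atom selection empty after residue restriction")
        atoms = AtomSelection(indices=indices, mode=atoms.mode)
    return atoms, residues


def _atom_feature_matrix(
    traj: Trajectory, config: DescriptorConfig, atoms: AtomSelection
) -> AtomFeatureMatrix:
    ranges = split_subtrajectories(traj.n_frames, config.frame_split)
    stats = subtrajectory_statistics(traj, ranges, config.mode, atoms)
    charges = gasteiger_charges(traj.topology)
    return assemble_feature_matrix(stats, charges, atoms)


def compute_rs3ddpd(
    traj: Trajectory,
    msa: MSA,
    target_id: str,
    config: DescriptorConfig | None = None,
    pocket_columns: set[int] | None = None,
) -> DescriptorVector:
    """Residue-specific 3DDPD for one target, length ``n * L``.

    The target's residues (in topology order) are identified with its
    ungapped MSA row, so the topology residue count must equal the target's
    ungapped length.  Features are position-major over alignment columns
    ("AA{col}_PC1..PCn"); the target's gap columns are exact zero blocks.
    """
    config = config or DescriptorConfig.rs_default()
    cmap = msa.map_for(target_id)
    if traj.topology.n_residues != len(cmap):
        raise ValueError(
            f"topology has {traj.topology.n_residues} residues but target "
            f"{target_id!r} has ungapped length {len(cmap)}"
        )
    atoms, residues = _resolve_selections(
        traj, config, msa=msa, target_id=target_id, pocket_columns=pocket_columns
    )
    matrix = _atom_feature_matrix(traj, config, atoms)
    X = minmax_standardize(matrix.values)
    scores, k, _ = pca_project(X, variance=config.atom_variance)
    res_features = _group_by_residue(scores, matrix.residue_indices, residues.indices)
    n = config.residue_pcs
    if min(res_features.shape) < n:
        raise ValueError(
            f"residue matrix {res_features.shape} cannot yield {n} principal "
            "components"
        )
    res_std = minmax_standardize(res_features)
    res_scores, _, _ = pca_project(res_std, n_components=n)
    L = msa.n_columns
    values = np.zeros(n * L)
    names = [f"AA{col}_PC{c}" for col in range(1, L + 1) for c in range(1, n + 1)]
    for row, res_idx in enumerate(residues.indices):
        col = cmap[res_idx]  # 1-based alignment column of this residue
        values[(col - 1) * n : col * n] = res_scores[row]
    return DescriptorVector(
        kind="rs",
        values=values,
        feature_names=names,
        target_id=target_id,
        config_fingerprint=config.fingerprint(),
    )


def compute_ps3ddpd(
    per_target: Mapping[str, Trajectory],
    config: DescriptorConfig | None = None,
) -> dict[str, DescriptorVector]:
    """Protein-specific 3DDPDs for a batch of targets, each of length ``m * 3``.

    The per-target atom-feature matrices are column-truncated to the minimum
    shared sub-trajectory count (trajectories of unequal length are thereby
    reconciled), stacked row-wise, min-max standardized globally, and reduced
    by one PCA at the configured variance threshold; each retained PC's scores
    are then aggregated per target as average, median and population SD.
    Feature order is PC-major: PC1_avg, PC1_median, PC1_sd, PC2_avg, ...
    """
    config = config or DescriptorConfig.ps_default()
    if len(per_target) < 2:
        raise ValueError("ps3DDPD needs at least 2 targets")
    # deterministic processing order; output is permutation-equivariant anyway
    order = sorted(per_target)
    matrices: dict[str, AtomFeatureMatrix] = {}
    for tid in order:
        traj = per_target[tid]
        atoms, _ = _resolve_selections(traj, config)
        matrices[tid] = _atom_feature_matrix(traj, config, atoms)
    stats_per_s = len(_STATS[config.mode]) * 3
    s_min = min(m.n_subtrajectories for m in matrices.values())
    width = stats_per_s * s_min
    blocks, slices, start = [], {}, 0
    for tid in order:
        m = matrices[tid]
        truncated = np.column_stack([m.values[:, :width], m.values[:, -1]])
        blocks.append(truncated)
        slices[tid] = slice(start, start + truncated.shape[0])
        start += truncated.shape[0]
    stacked = minmax_standardize(np.vstack(blocks))
    scores, m_pcs, _ = pca_project(stacked, variance=config.atom_variance)
    names = [
        f"PC{j}_{stat}" for j in range(1, m_pcs + 1) for stat in ("avg", "median", "sd")
    ]
    out: dict[str, DescriptorVector] = {}
    for tid in order:
        sc = scores[slices[tid]]
        vec = np.empty(3 * m_pcs)
        vec[0::3] = sc.mean(axis=0)
        vec[1::3] = np.median(sc, axis=0)
        vec[2::3] = sc.std(axis=0)
        out[tid] = DescriptorVector(
            kind="ps",
            values=vec,
            feature_names=list(names),
            target_id=tid,
            config_fingerprint=config.fingerprint(),
        )
    return out
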