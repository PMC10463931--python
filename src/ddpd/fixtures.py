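"""Synthetic inputs with known statistical structure.

Real 3DDPD inputs are long GPCR MD trajectories, a class-A alignment and a
curated bioactivity table.  The generators here emulate each of those with
fully controlled statistics so that every downstream stage can be tested
end-to-end and offline:

* harmonic-fluctuation trajectories — frames are the reference coordinates
  plus isotropic i.i.d. Gaussian displacements whose per-axis SD is a
  per-residue amplitude ``sigma_r``, so the expected RMSF has the closed form
  ``sigma_r * sqrt(3)``;
* structured trajectories — per-sub-trajectory mean offsets and per-axis
  amplitudes let tests plant an exact number of orthogonal variance
  directions into the descriptor pipeline's atom-statistics matrix;
* gapped alignments with prescribed residue-to-column maps;
* additive-effect bioactivity tables (global mean + target effect + compound
  effect + noise) over a fixed pool of valid drug-like SMILES.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hadamard

from .msa import MSA, GAP_CHARS
from .pcm import BioactivityDataset
from .trajectory import Atom, Residue, Topology, Trajectory

__all__ = [
    "ResidueTemplate",
    "PEPTIDE_TEMPLATE",
    "NC_TEMPLATE",
    "FluctuationProfile",
    "SyntheticBioactivitySpec",
    "SMILES_POOL",
    "homolog_smiles_pool",
    "synth_topology",
    "helical_reference",
    "synth_trajectory",
    "synth_structured_trajectory",
    "synth_msa",
    "synth_bioactivity",
    "anisotropic_trajectory",
    "variance_structured_targets",
]


@dataclass(frozen=True)
class ResidueTemplate:
    """Per-residue atom list with elements and within-residue bonds.

    ``link`` names the (tail, head) atom indices bonded between consecutive
    residues (the peptide C->N bond in the default template).
    """

    name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]
    link: tuple[int, int] | None = None


#: Glycine-like backbone: N, CA, C, O plus the amide hydrogen.
PEPTIDE_TEMPLATE = ResidueTemplate(
    name="GLY",
    atom_names=("N", "CA", "C", "O", "H"),
    elements=("N", "C", "C", "O", "H"),
    bonds=((0, 1), (1, 2), (2, 3), (0, 4)),
    link=(2, 0),
)

#: Minimal two-heavy-atom repeat whose Gasteiger charges alternate between
#: exactly two values on a cyclic chain — used by variance-controlled fixtures.
NC_TEMPLATE = ResidueTemplate(
    name="UNK",
    atom_names=("N", "C"),
    elements=("N", "C"),
    bonds=((0, 1),),
    link=(1, 0),
)


def synth_topology(
    n_residues: int,
    template: ResidueTemplate = PEPTIDE_TEMPLATE,
    cyclic: bool = False,
) -> Topology:
    """Replicate a residue template into a linear (or cyclic) topology.

    ``cyclic`` closes the chain with one extra link bond from the last residue
    back to the first, removing end effects from the charge pattern.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    per = len(template.atom_names)
    for a, b in template.bonds:
        if not (0 <= a < per and 0 <= b < per):
            raise ValueError(f"template bond ({a}, {b}) references a missing atom")
    atoms: list[Atom] = []
    residues: list[Residue] = []
    bonds: list[tuple[int, int]] = []
    for r in range(n_residues):
        residues.append(Residue(index=r, name=template.name, number=r + 1))
        base = r * per
        for j, (nm, el) in enumerate(zip(template.atom_names, template.elements)):
            atoms.append(
                Atom(index=base + j, name=nm, element=el, residue_index=r)
            )
        bonds.extend((base + a, base + b) for a, b in template.bonds)
        if template.link is not None and r < n_residues - 1:
            tail, head = template.link
            bonds.append((base + tail, base + per + head))
    if cyclic:
        if template.link is None or n_residues < 3:
            raise ValueError("cyclic topologies need a link and >= 3 residues")
        tail, head = template.link
        bonds.append(((n_residues - 1) * per + tail, head))
    return Topology(atoms=atoms, residues=residues, bonds=bonds)


def helical_reference(
    topology: Topology, radius: float = 0.23, rise: float = 0.15
) -> np.ndarray:
    """Coarse helical reference coordinates (nm), one point per atom.

    Residues advance 100 degrees per step around a helix of the given radius
    and rise; atoms within a residue fan out on small deterministic offsets so
    superposition code paths are non-degenerate.
    """
    coords = np.zeros((topology.n_atoms, 3))
    turn = np.deg2rad(100.0)
    for atom in topology.atoms:
        r = atom.residue_index
        theta = turn * r
        local = atom.index - min(topology.atoms_of_residue(r))
        coords[atom.index] = (
            radius * np.cos(theta) + 0.03 * local,
            radius * np.sin(theta) + 0.02 * (local % 2),
            rise * r + 0.025 * local,
        )
    return coords


@dataclass
class FluctuationProfile:
    """Per-residue isotropic fluctuation amplitudes for a synthetic trajectory.

    ``sigma`` is the per-axis displacement SD (nm) of every atom of each
    residue; displacements are i.i.d. across frames, atoms and axes, so the
    expected RMSF of residue r is ``sigma_r * sqrt(3)``.
    """

    sigma: np.ndarray
    n_frames: int
    seed: int = 0
    reference: np.ndarray | None = None  # per-atom coords; helical if None

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if (self.sigma < 0).any():
            raise ValueError("sigma must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


def synth_trajectory(topology: Topology, profile: FluctuationProfile) -> Trajectory:
    """Reference coordinates plus isotropic Gaussian fluctuation per residue."""
    if profile.sigma.shape[0] != topology.n_residues:
        raise ValueError(
            f"profile length {profile.sigma.shape[0]} != residue count "
            f"{topology.n_residues}"
        )
    ref = (
        profile.reference
        if profile.reference is not None
        else helical_reference(topology)
    )
    ref = np.asarray(ref, dtype=np.float64)
    if ref.shape != (topology.n_atoms, 3):
        raise ValueError("reference coordinates must be (n_atoms, 3)")
    sigma_atom = profile.sigma[topology.residue_indices()]
    rng = np.random.default_rng(profile.seed)
    noise = rng.normal(
        0.0, 1.0, size=(profile.n_frames, topology.n_atoms, 3)
    ) * sigma_atom[None, :, None]
    return Trajectory(xyz=ref[None, :, :] + noise, topology=topology)


def synth_structured_trajectory(
    topology: Topology,
    frame_split: int,
    offsets: np.ndarray,
    axis_sigma: np.ndarray,
    reference: np.ndarray | None = None,
    seed: int = 0,
) -> Trajectory:
    """Trajectory with planted sub-trajectory structure.

    ``offsets`` has shape (S, n_residues, 3): a deterministic displacement
    added to every frame of sub-trajectory s (it moves that block's mean and
    median without touching its within-block SD).  ``axis_sigma`` has shape
    (n_residues, 3): per-axis Gaussian fluctuation SD, constant over time.
    Together they let a test place an exact set of variance directions into
    the atom-statistics matrix of the descriptor pipeline.
    """
    offsets = np.asarray(offsets, dtype=np.float64)
    axis_sigma = np.asarray(axis_sigma, dtype=np.float64)
    S = offsets.shape[0]
    R = topology.n_residues
    if offsets.shape != (S, R, 3):
        raise ValueError("offsets must be (n_subtrajectories, n_residues, 3)")
    if axis_sigma.shape != (R, 3):
        raise ValueError("axis_sigma must be (n_residues, 3)")
    if (axis_sigma < 0).any():
        raise ValueError("axis_sigma must be non-negative")
    ref = np.zeros((topology.n_atoms, 3)) if reference is None else np.asarray(reference)
    res_of_atom = topology.residue_indices()
    rng = np.random.default_rng(seed)
    F = S * frame_split
    xyz = np.empty((F, topology.n_atoms, 3))
    for s in range(S):
        block = slice(s * frame_split, (s + 1) * frame_split)
        noise = rng.normal(0.0, 1.0, size=(frame_split, topology.n_atoms, 3))
        noise *= axis_sigma[res_of_atom][None]
        xyz[block] = ref[None] + offsets[s][res_of_atom][None] + noise
    return Trajectory(xyz=xyz, topology=topology)


def synth_msa(
    sequences: dict[str, str],
    gap_plan: dict[str, set[int]] | None = None,
    pad_to: int | None = None,
) -> MSA:
    """Build an aligned set of rows with prescribed gap columns.

    Each sequence fills the non-forbidden columns left to right; ``gap_plan``
    maps a target id to 1-based columns that must be gaps for it; remaining
    columns to the right are padded with gaps up to ``pad_to`` (default: the
    smallest width that fits every row).
    """
    if not sequences:
        raise ValueError("no sequences given")
    gap_plan = gap_plan or {}
    need = max(
        len(seq) + len(gap_plan.get(tid, set())) for tid, seq in sequences.items()
    )
    L = need if pad_to is None else pad_to
    if L < need:
        raise ValueError(f"pad_to={pad_to} too small; need at least {need} columns")
    rows: dict[str, str] = {}
    for tid, seq in sequences.items():
        if any(ch in GAP_CHARS for ch in seq):
            raise ValueError("sequences must be ungapped residue strings")
        forbidden = gap_plan.get(tid, set())
        row = []
        it = iter(seq)
        for col in range(1, L + 1):
            if col in forbidden:
                row.append("-")
            else:
                row.append(next(it, "-"))
        if len([c for c in row if c != "-"]) != len(seq):
            raise ValueError(f"pad_to={L} too small for target {tid!r}")
        rows[tid] = "".join(row)
    return MSA(ids=list(sequences), rows=rows)


#: Fixed pool of valid drug-like SMILES so compound fingerprints vary without
#: any external files.
SMILES_POOL: tuple[str, ...] = (
    "CCO",
    "CC(=O)O",
    "c1ccccc1",
    "Cc1ccccc1",
    "CCc1ccccc1",
    "c1ccncc1",
    "Cc1ccncc1",
    "c1ccc2ccccc2c1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "CC(=O)Oc1ccccc1C(=O)O",
    "CC(=O)Nc1ccc(O)cc1",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "NCCc1ccc(O)c(O)c1",
    "NC(Cc1ccccc1)C(=O)O",
    "OCC(O)CO",
    "CCN(CC)CC",
    "CCOC(C)=O",
    "CCCCCCO",
    "CC(C)O",
    "CC(C)=O",
    "CCOCC",
    "CCCC(=O)O",
    "OC(=O)c1ccccc1",
    "Nc1ccccc1",
    "Oc1ccccc1",
    "Clc1ccccc1",
    "Fc1ccccc1",
    "Brc1ccccc1",
    "COc1ccccc1",
    "CS(=O)(=O)O",
    "NS(=O)(=O)c1ccccc1",
    "NC(=O)c1ccccc1",
    "CC(N)C(=O)O",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOC1",
    "O=C1CCCCC1",
    "c1ccc(-c2ccccc2)cc1",
    "O=C(c1ccccc1)c1ccccc1",
    "CC(C)(C)c1ccccc1",
    "CCCCN",
    "NCCO",
    "OCCO",
    "N#Cc1ccccc1",
    "O=[N+]([O-])c1ccccc1",
    "CNC(=O)c1ccccc1",
    "Cn1ccnc1",
    "c1ccsc1",
    "c1ccoc1",
    "CCSCC",
)


def homolog_smiles_pool(n: int) -> tuple[str, ...]:
    """Enumerate ``n`` distinct valid ester homologs (alkyl-CO-O-alkyl).

    Extends the fixed drug-like pool when a scenario needs more compounds
    than :data:`SMILES_POOL` holds (e.g. large record counts with compounds
    not shared across targets).  All strings are valid by construction.
    """
    out: list[str] = []
    for a in range(1, 50):
        for b in range(1, 50):
            out.append("C" * a + "C(=O)O" + "C" * b)
            if len(out) == n:
                return tuple(out)
    raise ValueError(f"cannot enumerate {n} homologs")


@dataclass
class SyntheticBioactivitySpec:
    """Additive-effect bioactivity generator parameters.

    pChEMBL(target t, compound c) = ``global_mean + a_t + b_c + eps`` with
    ``a_t ~ N(0, target_effect_scale^2)`` per target, ``b_c ~ N(0,
    compound_effect_scale^2)`` per pool compound (shared across targets) and
    ``eps ~ N(0, noise_sd^2)`` per record.  Publication years are uniform over
    ``year_range`` (inclusive).

    With ``partition_compounds`` each target receives a disjoint slice of the
    pool, so no compound is shared between targets; permutation-null controls
    are then free of the cross-target compound grouping that a shared pool
    induces.
    """

    n_targets: int = 10
    compounds_per_target: int = 30
    target_effect_scale: float = 0.8
    compound_effect_scale: float = 0.8
    noise_sd: float = 0.3
    global_mean: float = 6.5
    year_range: tuple[int, int] = (2005, 2020)
    seed: int = 0
    smiles_pool: tuple[str, ...] = field(default=SMILES_POOL)
    partition_compounds: bool = False

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("need at least one target")
        if not self.smiles_pool:
            raise ValueError("empty SMILES pool")
        if min(self.target_effect_scale, self.compound_effect_scale, self.noise_sd) < 0:
            raise ValueError("scales must be non-negative")
        if self.compounds_per_target < 1:
            raise ValueError("need at least one compound per target")
        needed = (
            self.compounds_per_target * self.n_targets
            if self.partition_compounds
            else self.compounds_per_target
        )
        if needed > len(self.smiles_pool):
            raise ValueError(
                f"pool of {len(self.smiles_pool)} SMILES cannot supply "
                f"{needed} distinct compounds; (target, compound) pairs must "
                "be unique"
            )
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (low, high)")


def synth_bioactivity(spec: SyntheticBioactivitySpec) -> BioactivityDataset:
    """Generate an additive-effect bioactivity table (see the spec dataclass)."""
    rng = np.random.default_rng(spec.seed)
    pool = list(spec.smiles_pool)
    target_ids = [f"T{t:03d}" for t in range(spec.n_targets)]
    target_effect = rng.normal(0.0, spec.target_effect_scale, spec.n_targets)
    compound_effect = rng.normal(0.0, spec.compound_effect_scale, len(pool))
    if spec.partition_compounds:
        order = rng.permutation(len(pool))
    records = []
    lo, hi = spec.year_range
    for t, tid in enumerate(target_ids):
        if spec.partition_compounds:
            chosen = order[
                t * spec.compounds_per_target : (t + 1) * spec.compounds_per_target
            ]
        else:
            chosen = rng.choice(
                len(pool), size=spec.compounds_per_target, replace=False
            )
        for c in chosen:
            value = (
                spec.global_mean
                + target_effect[t]
                + compound_effect[c]
                + rng.normal(0.0, spec.noise_sd)
            )
            year = int(rng.integers(lo, hi + 1))
            records.append((tid, pool[c], float(value), year))
    return BioactivityDataset.from_records(records)


def anisotropic_trajectory(
    seed: int = 0,
    n_residues: int = 32,
    frame_split: int = 100,
    n_splits: int = 3,
    sigma_low: float = 0.05,
    sigma_high: float = 0.5,
) -> Trajectory:
    """Single-target fixture with three orthogonal per-axis amplitude patterns.

    Per-axis fluctuation amplitudes follow three mutually orthogonal Hadamard
    sign patterns over residues (values ``sigma_low``/``sigma_high``), so the
    rigidity-mode atom-statistics matrix has four well-separated variance
    directions (three amplitude axes plus the charge column) and the 95%
    variance rule retains enough atom PCs for downstream residue grouping.
    Built on a cyclic N-C topology (balanced binary charge column).
    """
    H = hadamard(n_residues)
    topo = synth_topology(n_residues, template=NC_TEMPLATE, cyclic=True)
    mid = 0.5 * (sigma_low + sigma_high)
    amp = 0.5 * (sigma_high - sigma_low)
    axis_sigma = np.stack([mid + amp * H[ax + 1] for ax in range(3)], axis=1)
    offsets = np.zeros((n_splits, n_residues, 3))
    return synth_structured_trajectory(
        topo,
        frame_split=frame_split,
        offsets=offsets,
        axis_sigma=axis_sigma,
        reference=helical_reference(topo),
        seed=seed,
    )


def variance_structured_targets(
    seed: int = 0,
    n_targets: int = 2,
    n_residues: int = 32,
    frame_split: int = 100,
    n_splits: int = 2,
) -> dict[str, Trajectory]:
    """Multi-target fixture whose stacked atom statistics have ten variance directions.

    Across the concatenated residues of all targets, Hadamard rows plant six
    orthogonal per-(axis, sub-trajectory) mean-offset patterns and three
    orthogonal per-axis amplitude patterns; a cyclic N-C topology contributes
    a balanced binary partial-charge column as the tenth direction.  On the
    min-max standardized stacked matrix the cumulative explained variance sits
    near 93% after nine components and above 99% after ten, so a 95% variance
    rule retains exactly ten PCs (the ps3DDPD then has 30 features).
    """
    if n_splits * 3 + 3 + 1 != 10:
        raise ValueError("construction plants 3*n_splits + 4 directions; need 10")
    total = n_targets * n_residues
    H = hadamard(total)
    out: dict[str, Trajectory] = {}
    for g in range(n_targets):
        gi = np.arange(g * n_residues, (g + 1) * n_residues)
        topo = synth_topology(n_residues, template=NC_TEMPLATE, cyclic=True)
        offsets = np.zeros((n_splits, n_residues, 3))
        row = 1
        for ax in range(3):
            for s in range(n_splits):
                offsets[s, :, ax] = H[row, gi]
                row += 1
        axis_sigma = np.zeros((n_residues, 3))
        for ax in range(3):
            axis_sigma[:, ax] = 0.275 + 0.225 * H[row, gi]
            row += 1
        out[f"T{g:02d}"] = synth_structured_trajectory(
            topo,
            frame_split=frame_split,
            offsets=offsets,
            axis_sigma=axis_sigma,
            reference=None,
            seed=seed + g,
        )
    return out
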