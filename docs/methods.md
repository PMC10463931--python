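# Methods

## The descriptor model

A 3DDPD treats an MD trajectory as a sample from the protein's conformational
ensemble and summarizes, per atom, the location and dispersion of its
coordinates over consecutive time windows. The assumptions are deliberately
weak: no force-field awareness, no contact or solvent analysis, no
periodic-boundary handling — the input trajectory is expected to be a wrapped,
protein-only production run. Chemistry enters through a single static channel,
one Gasteiger (PEOE) partial charge per atom computed from the bond graph;
because the charge is conformation-independent it is computed once per
topology, never per frame. Charges of implicit hydrogens are not folded into
their heavy atoms; when a topology carries explicit hydrogens they receive
their own charges but are excluded from the atom selection (selections never
contain hydrogens).

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `mode` | coordinate statistics per window: mean+median+SD, or SD only ("rigidity") | rigidity (rs), coordinate (ps) | the optimized settings per flavor |
| `frame_split` f | frames per sub-trajectory window | 100 | resolves slow drift without exploding the matrix; 2500-frame runs give S = 25 |
| `atom_variance` v | cumulative explained-variance threshold of the atom PCA | 0.95 | keeps the dominant fluctuation modes, discards window noise |
| `residue_pcs` n | residue-PCA components kept (rs only) | 5 | 5 features per alignment column; more inflates the vector with noise components |
| `atom_selection` | all-heavy or non-carbon | all-heavy | |
| `residue_selection` | full sequence or a pocket-column subset | full | pocket subsets require an MSA column set |

Coordinates are nanometres internally; PDB I/O converts from Angstrom.
Because every column is min-max standardized before PCA, descriptor values
are unit-free either way.

### Numerical conventions

- **Window split**: `S = ⌊F/f⌋` equal windows; remainder frames are dropped so
  window statistics stay comparable. SD is the population form throughout
  (windows have fixed length; the estimator choice is a convention, recorded
  here).
- **Min-max standardization**: `(x − min)/(max − min)` per column; a constant
  column maps to all-zero, which keeps degenerate channels inert rather than
  letting them blow up.
- **PCA**: mean-centered SVD. The retained count under the variance rule is
  the smallest k whose cumulative explained-variance fraction reaches the
  threshold, capped at the numerical rank. Every axis is oriented so that its
  largest-magnitude loading is positive — a fixed sign convention that makes
  repeated runs bit-identical. A fixed-count request beyond the rank is an
  error; a variance-rule result of k = 1 is allowed (only rank 0 errors).
- **rs residue stage**: atom-PC scores are grouped per residue as mean and
  population SD (single-atom residues get SD 0), min-max standardized again
  (mirroring the atom stage), and reduced to exactly n components. Residue
  scores land position-major at the target's 1-based alignment columns
  (`AA{col}_PC{c}`); the target's gap columns are exact zero blocks.
- **ps cross-target alignment**: per-target atom matrices are column-truncated
  to the minimum shared window count before stacking, so targets simulated
  for different lengths are reconciled by their common early windows. The
  stacked matrix is standardized globally; per-target aggregation is
  average/median/population SD per retained PC, PC-major.
- **Descriptor generation contains no randomness**: re-runs are bit-identical,
  and two targets with identical topology and trajectory get identical
  descriptors.

### Trajectory analysis

RMSD is computed against frame 0 after optimal rigid-body superposition of
every frame (all protein atoms). RMSF uses the Cα atoms: frames are superposed
first onto frame 0 and then onto the resulting average structure, and the
fluctuation about the mean position is reported per residue. The superposition
reference for RMSF (mean structure rather than frame 0) is this package's
choice of the standard practice. Mapped onto an alignment, RMSF carries NaN —
an explicit missing marker, never zero — at gap columns, while descriptor
vectors use zeros at gaps by construction; the clustering distance removes
positions that are zero (or missing) across all compared vectors before
computing Euclidean distances, so shared padding never dilutes the metric.

### Clustering

Agglomerative clustering with average linkage (UPGMA) by default; the linkage
behind published variant dendrograms is not fixed by the method, so it is
configurable and recorded on the tree. Flat clusters come from cutting at a
fraction of the final merge distance (0.7 in the standard analysis). The
"non-null bits" rule is implemented as all-zero-column removal across the
compared set; per-vector null handling would break metric symmetry.

### The PCM harness

Random forests at library defaults (no hyperparameter search, by design — the
benchmark compares descriptors, not tuning skill), replicated over ten fixed
seeds (1234 … 9999). The seed drives CV-fold shuffling, the random 80:20
split, and forest initialization. The temporal split trains on records first
published before 2013 and tests on the rest; pChEMBL ≥ 6.5 is active (the
boundary value counts as active). MCC maps any degenerate confusion factor to
0. The QSAR baseline is one compound-only model per target, averaged with
equal weights. Descriptor comparisons use a two-sided independent t-test with
the conventional star thresholds (0.05/0.01/0.001). AVE bias is computed on
compound fingerprints with a nearest-neighbour nearness equal to one minus
the mean NN Jaccard distance — the continuous limit of averaging threshold
indicators over a dense uniform grid on [0, 1]; the thresholds are a
configuration choice of this implementation, recorded here.

## Synthetic data: what it emulates, and what it does not

The generators stand in for real inputs (deposited GPCR trajectories, a
curated class A alignment, a curated bioactivity set) with objects whose
statistics are known exactly:

- **Harmonic-fluctuation trajectories**: frames are reference coordinates
  plus i.i.d. isotropic Gaussian displacements with per-residue amplitude
  σ_r, so RMSF has the closed form σ_r·√3 — the recovery tests check the full
  superposition+RMSF path against that value at F = 2500 within 5%. I.i.d.
  frames mean no autocorrelation, no collective modes, no anisotropy (unless
  planted), and no replicate-to-replicate variability: passing tests show the
  pipeline computes the right functionals of an ensemble, not that MD
  ensembles are well described by them.
- **Structured trajectories** plant exact variance directions: Hadamard sign
  patterns over residues drive per-window mean offsets and per-axis
  amplitudes, and a cyclic N–C backbone contributes a balanced two-valued
  charge column. The multi-target fixture plants 6 offset + 3 amplitude
  directions plus the charge column = ten dominant orthogonal directions, so
  the 95% rule retains exactly ten atom PCs (cumulative explained variance
  ≈ 0.93 at nine, ≈ 0.99 at ten, stable across seeds) and the ps3DDPD has 30
  features by construction.
- **Variant fixtures**: amplitude-perturbed copies of a target share the
  generator's noise stream. Real variants share a fold and most of their
  dynamics; with fully independent noise the trailing residue-PCA components
  are noise-dominated and within-target descriptor distances approach
  between-target ones, which no amount of data would fix under this
  generator. Shared-stream-plus-perturbation is the i.i.d. model's honest
  analogue of "same protein, perturbed dynamics".
- **Bioactivity tables**: pChEMBL = global mean + target effect + compound
  effect + Gaussian noise, years uniform. Compounds come from a fixed pool of
  50 valid drug-like SMILES; scenarios that need more distinct compounds (or
  compounds not shared between targets) use a programmatically enumerated
  ester-homolog pool. The large signal-recovery scenario partitions compounds
  across targets with target-effect scale 1.0: a shared pool at 2000 records
  would let a forest learn spurious per-compound means even of permuted
  labels (leakage share ≈ (targets + compounds)/records), contaminating the
  permutation-null control that the scenario is designed to exhibit.

## Classical scale tables

The five-component z-scale table carries the extended (1998) values and the
three-component table the original (1987) values, both transcribed from the
standard reprints; the PhysChem table is Kyte–Doolittle hydropathy, average
residue mass and a conventional side-chain charge. The MS-WHIM and ST-scale
tables are **synthetic stand-ins** with the published dimensionalities (3 and
8): deterministic orthogonal recombinations of the embedded property matrix,
shipped so the five-descriptor benchmark surface is complete. Conclusions
about those two specific scales' values cannot be drawn from this package.

## Problem sizes

Tests and the acceptance script run at desk scale: trajectories of 200–2500
frames over 15–150 atoms, alignments up to 757 columns, benchmark datasets of
up to 2000 records with 1024-bit fingerprints. These sizes were chosen so the
statistical checks (CLT tolerances, permutation nulls, variance-rule margins)
are comfortably resolved while the full suite stays fast.

## Known limitations

- Gasteiger charges require a sanitizable bond graph; exotic valences and
  elements outside the PEOE parameter set are rejected rather than guessed.
- The ps3DDPD's cross-target PCA makes each vector depend on the batch: adding
  a target changes everyone's descriptors. That is inherent to the global
  standardization+PCA design, not an implementation artifact.
- Replicate trajectories are not aggregated; descriptors describe the one
  trajectory they are given.
- Fingerprint bit-compatibility across cheminformatics backends is not
  promised, only within-package determinism.
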