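"""The descriptor engine: statistics, charges, standardization, two-stage PCA."""

import numpy as np
import pytest

from ddpd import fixtures
from ddpd.descriptor import (
    DescriptorConfig,
    assemble_feature_matrix,
    compute_ps3ddpd,
    compute_rs3ddpd,
    gasteiger_charges,
    minmax_standardize,
    pca_project,
    split_subtrajectories,
    subtrajectory_statistics,
)
from ddpd.trajectory import Atom, Residue, Topology, Trajectory, select_atoms


class TestSplitSubtrajectories:
    @pytest.mark.parametrize(
        "frames,split,expected",
        [(2500, 100, 25), (1250, 100, 12), (200, 100, 2), (250, 100, 2)],
    )
    def test_floor_rule(self, frames, split, expected):
        ranges = split_subtrajectories(frames, split)
        assert len(ranges) == expected
        assert ranges[0] == range(0, split)
        assert ranges[-1] == range((expected - 1) * split, expected * split)

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="fewer"):
            split_subtrajectories(99, 100)


def _one_atom_trajectory(x_values, const=5.0):
    topo = Topology(
        atoms=[Atom(0, "C1", "C", 0)], residues=[Residue(0, "UNK", 1)], bonds=[]
    )
    xyz = np.full((len(x_values), 1, 3), const)
    xyz[:, 0, 0] = x_values
    return topo, Trajectory(xyz=xyz, topology=topo)


class TestSubtrajectoryStatistics:
    def test_two_frame_hand_example(self):
        # x = (0, 2): mean 1, median 1, population SD 1; y, z constant
        topo, traj = _one_atom_trajectory([0.0, 2.0])
        sel = select_atoms(topo, "all-heavy")
        m = subtrajectory_statistics(traj, [range(0, 2)], "coordinate", sel)
        stats = dict(zip(m.column_names, m.values[0]))
        assert stats["s1_x_mean"] == stats["s1_x_median"] == stats["s1_x_sd"] == 1.0
        assert stats["s1_y_mean"] == 5.0 and stats["s1_y_sd"] == 0.0

    def test_constant_coordinates(self):
        topo, traj = _one_atom_trajectory([3.0, 3.0, 3.0])
        sel = select_atoms(topo, "all-heavy")
        m = subtrajectory_statistics(traj, [range(0, 3)], "rigidity", sel)
        assert np.all(m.values == 0)

    def test_column_count_laws(self, small_trajectory):
        sel = select_atoms(small_trajectory.topology, "all-heavy")
        ranges = split_subtrajectories(300, 12)  # S = 25
        rig = subtrajectory_statistics(small_trajectory, ranges, "rigidity", sel)
        coord = subtrajectory_statistics(small_trajectory, ranges, "coordinate", sel)
        assert rig.values.shape[1] == 3 * 25
        assert coord.values.shape[1] == 9 * 25
        charges = gasteiger_charges(small_trajectory.topology)
        assert assemble_feature_matrix(rig, charges, sel).values.shape[1] == 76
        assert assemble_feature_matrix(coord, charges, sel).values.shape[1] == 226


def _peoe_oracle(elements, bonds, n_iter=12):
    """Independent partial-equalization-of-orbital-electronegativity iteration."""
    params = {  # a, b, c for the sp3 forms
        "H": (7.17, 6.24, -0.56),
        "C": (7.98, 9.18, 1.88),
        "N": (11.54, 10.82, 1.36),
        "O": (14.18, 12.92, 1.39),
    }
    chi_plus = {
        el: (20.02 if el == "H" else sum(params[el])) for el in params
    }
    q = np.zeros(len(elements))
    for n in range(1, n_iter + 1):
        a = np.array([params[e][0] for e in elements])
        b = np.array([params[e][1] for e in elements])
        c = np.array([params[e][2] for e in elements])
        chi = a + b * q + c * q**2
        dq = np.zeros_like(q)
        for i, j in bonds:
            lo, hi = (i, j) if chi[i] < chi[j] else (j, i)
            flow = (chi[hi] - chi[lo]) / chi_plus[elements[lo]] * 0.5**n
            dq[lo] += flow
            dq[hi] -= flow
        q += dq
    return q


def _ethanol_topology():
    elements = ["C", "C", "O", "H", "H", "H", "H", "H", "H"]
    bonds = [(0, 1), (1, 2), (0, 3), (0, 4), (0, 5), (1, 6), (1, 7), (2, 8)]
    atoms = [
        Atom(i, f"{el}{i}", el, 0) for i, el in enumerate(elements)
    ]
    return Topology(atoms=atoms, residues=[Residue(0, "EOH", 1)], bonds=bonds), elements, bonds


class TestGasteigerCharges:
    def test_neutral_molecule_conserves_charge(self):
        topo, _, _ = _ethanol_topology()
        assert abs(gasteiger_charges(topo).sum()) < 1e-3

    def test_methane_hydrogens_symmetric(self):
        atoms = [Atom(0, "C", "C", 0)] + [Atom(i, f"H{i}", "H", 0) for i in range(1, 5)]
        topo = Topology(
            atoms=atoms, residues=[Residue(0, "CH4", 1)],
            bonds=[(0, i) for i in range(1, 5)],
        )
        q = gasteiger_charges(topo)
        assert np.allclose(q[1:], q[1])
        assert abs(q.sum()) < 1e-3

    def test_ethanol_matches_peoe_oracle(self):
        topo, elements, bonds = _ethanol_topology()
        got = gasteiger_charges(topo)
        oracle = _peoe_oracle(elements, bonds)
        # oxygen is the most negative atom in both routes
        assert int(np.argmin(got)) == int(np.argmin(oracle)) == 2
        assert np.corrcoef(got, oracle)[0, 1] > 0.9

    def test_frame_independent(self):
        topo = fixtures.synth_topology(4)
        assert np.array_equal(gasteiger_charges(topo), gasteiger_charges(topo))


class TestMinmaxStandardize:
    def test_basic_column(self):
        out = minmax_standardize(np.array([[1.0], [3.0], [5.0]]))
        assert np.allclose(out.ravel(), [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        out = minmax_standardize(np.array([[7.0, 1.0], [7.0, 2.0]]))
        assert np.all(out[:, 0] == 0)

    def test_bounds(self):
        X = np.random.default_rng(1).normal(size=(40, 6))
        out = minmax_standardize(X)
        assert np.allclose(out.min(0), 0) and np.allclose(out.max(0), 1)


def _pca_oracle(X, k):
    """Eigendecomposition-of-covariance PCA with the package's sign convention."""
    Xc = X - X.mean(0)
    C = np.cov(Xc, rowvar=False)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    V = V[:, order[:k]]
    for j in range(k):
        i = np.abs(V[:, j]).argmax()
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return Xc @ V


class TestPCAProject:
    def test_rank_one_explains_everything(self):
        col = np.random.default_rng(0).normal(size=20)
        X = np.column_stack([col, 2 * col])
        scores, k, evr = pca_project(X, variance=0.95)
        assert k == 1
        assert evr[0] > 1 - 1e-12

    def test_scores_covariance_diagonal_nonincreasing(self):
        X = np.random.default_rng(3).normal(size=(30, 5))
        scores, k, _ = pca_project(X, n_components=5)
        C = np.cov(scores, rowvar=False)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 1e-10
        assert np.all(np.diff(np.diag(C)) <= 1e-10)

    @pytest.mark.parametrize("shape", [(20, 6), (50, 10)])
    def test_matches_covariance_eigendecomposition_oracle(self, shape):
        X = np.random.default_rng(7).normal(size=shape)
        k = shape[1] - 2
        scores, _, _ = pca_project(X, n_components=k)
        assert np.abs(scores - _pca_oracle(X, k)).max() < 1e-8

    def test_fixed_count_beyond_rank_rejected(self):
        col = np.random.default_rng(0).normal(size=10)
        X = np.column_stack([col, col, col])
        with pytest.raises(ValueError, match="rank"):
            pca_project(X, n_components=2)


class TestRs3DDPD:
    def test_length_law_and_gap_zero_blocks(self):
        traj = fixtures.anisotropic_trajectory(seed=0)
        msa = fixtures.synth_msa(
            {"T": "A" * 32}, gap_plan={"T": {5, 17}}, pad_to=60
        )
        vec = compute_rs3ddpd(traj, msa, "T")
        assert len(vec) == 5 * 60
        blocks = vec.values.reshape(60, 5)
        for col in msa.gap_columns("T"):
            assert np.all(blocks[col - 1] == 0)
        nonzero_cols = {c + 1 for c in range(60) if np.any(blocks[c] != 0)}
        assert nonzero_cols == set(msa.map_for("T"))

    def test_feature_names_position_major(self):
        traj = fixtures.anisotropic_trajectory(seed=0)
        msa = fixtures.synth_msa({"T": "A" * 32}, pad_to=40)
        vec = compute_rs3ddpd(traj, msa, "T")
        assert vec.feature_names[:6] == [
            "AA1_PC1", "AA1_PC2", "AA1_PC3", "AA1_PC4", "AA1_PC5", "AA2_PC1",
        ]

    def test_bit_determinism_and_target_identity(self):
        traj = fixtures.anisotropic_trajectory(seed=5)
        msa = fixtures.synth_msa({"T1": "A" * 32, "T2": "A" * 32}, pad_to=40)
        a = compute_rs3ddpd(traj, msa, "T1")
        b = compute_rs3ddpd(traj, msa, "T1")
        c = compute_rs3ddpd(traj, msa, "T2")
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.values, c.values)  # identical topology+trajectory

    def test_element_swap_changes_descriptor(self):
        # same geometry, one atom's element changed: the charge channel must
        # make the descriptor differ -- it is not a pure transform of geometry
        traj = fixtures.anisotropic_trajectory(seed=2)
        topo = traj.topology
        swapped_atoms = [
            Atom(a.index, a.name, "O" if a.index == 0 else a.element, a.residue_index)
            for a in topo.atoms
        ]
        topo2 = Topology(
            atoms=swapped_atoms, residues=topo.residues, bonds=topo.bonds
        )
        traj2 = Trajectory(xyz=traj.xyz.copy(), topology=topo2)
        msa = fixtures.synth_msa({"T": "A" * 32}, pad_to=40)
        a = compute_rs3ddpd(traj, msa, "T")
        b = compute_rs3ddpd(traj2, msa, "T")
        assert not np.allclose(a.values, b.values)

    def test_residue_count_mismatch(self):
        traj = fixtures.anisotropic_trajectory(seed=0)  # 32 residues
        msa = fixtures.synth_msa({"T": "ACDE"}, pad_to=10)
        with pytest.raises(ValueError, match="ungapped"):
            compute_rs3ddpd(traj, msa, "T")

    def test_too_few_residues_for_residue_pca(self):
        topo = fixtures.synth_topology(3)
        traj = fixtures.synth_trajectory(
            topo, fixtures.FluctuationProfile(sigma=np.full(3, 0.1), n_frames=200, seed=0)
        )
        msa = fixtures.synth_msa({"T": "AAA"}, pad_to=5)
        with pytest.raises(ValueError):
            compute_rs3ddpd(traj, msa, "T")


class TestPs3DDPD:
    def test_ten_component_fixture_gives_30_features(self):
        vectors = compute_ps3ddpd(fixtures.variance_structured_targets(seed=0))
        for vec in vectors.values():
            assert len(vec) == 30
            assert vec.feature_names[:3] == ["PC1_avg", "PC1_median", "PC1_sd"]

    def test_permutation_equivariance(self):
        targets = fixtures.variance_structured_targets(seed=1)
        a = compute_ps3ddpd(dict(targets))
        b = compute_ps3ddpd(dict(reversed(list(targets.items()))))
        for tid in targets:
            assert np.array_equal(a[tid].values, b[tid].values)

    def test_rank_one_stack_gives_length_three(self):
        # static trajectories, constant charges, reference varying along x only
        tmpl = fixtures.ResidueTemplate("UNK", ("C1", "C2"), ("C", "C"), ((0, 1),), (1, 0))
        per_target = {}
        for g, tid in enumerate(["A", "B"]):
            topo = fixtures.synth_topology(8, template=tmpl, cyclic=True)
            ref = np.zeros((topo.n_atoms, 3))
            ref[:, 0] = np.arange(topo.n_atoms) + 10 * g
            per_target[tid] = fixtures.synth_trajectory(
                topo,
                fixtures.FluctuationProfile(
                    sigma=np.zeros(8), n_frames=200, reference=ref
                ),
            )
        vectors = compute_ps3ddpd(per_target)
        assert all(len(v) == 3 for v in vectors.values())

    def test_unequal_lengths_truncate_to_shared_subtrajectories(self):
        targets = fixtures.variance_structured_targets(seed=3)  # both F=200
        longer = dict(targets)
        t0 = longer["T00"]
        # append 100 extra frames to one target; the shared S stays 2
        extra = np.repeat(t0.xyz[-1:], 100, axis=0)
        longer["T00"] = Trajectory(
            xyz=np.concatenate([t0.xyz, extra]), topology=t0.topology
        )
        a = compute_ps3ddpd(targets)
        b = compute_ps3ddpd(longer)
        for tid in targets:
            assert np.array_equal(a[tid].values, b[tid].values)

    def test_single_target_rejected(self):
        targets = fixtures.variance_structured_targets(seed=0)
        only = {"T00": targets["T00"]}
        with pytest.raises(ValueError, match="2 targets"):
            compute_ps3ddpd(only)

    def test_config_defaults(self):
        rs, ps = DescriptorConfig.rs_default(), DescriptorConfig.ps_default()
        assert (rs.mode, rs.frame_split, rs.atom_variance, rs.residue_pcs) == (
            "rigidity", 100, 0.95, 5,
        )
        assert ps.mode == "coordinate"
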