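"""Superposition, clustering, conformational entropy, and RMSF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from exflex.binding import R_KCAL_PER_MOL_K
from exflex.synthetic import EnsembleScenario, generate_ensemble
from exflex.trajflex import (
    ConformerTrajectory,
    cluster,
    conf_entropy,
    flex_report,
    pairwise_rmsd,
    rmsd_to_reference,
    rmsf,
    superpose,
)


def random_rigid_copies(base, n, rng):
    """Frames that are random rotations + translations of one structure."""
    rots = Rotation.random(n, random_state=rng).as_matrix()
    trans = rng.standard_normal((n, 1, 3)) * 20
    return np.einsum("fij,aj->fai", rots, base) + trans


def make_traj(coords, groups=None, names=None):
    n_atoms = coords.shape[1]
    return ConformerTrajectory(
        coords=coords,
        atom_names=np.array(names if names is not None else ["CA"] * n_atoms, dtype=object),
        atom_groups=np.array(groups if groups is not None else ["ligand"] * n_atoms, dtype=object),
    )


@pytest.fixture(scope="module")
def base_structure():
    rng = np.random.default_rng(0)
    return rng.standard_normal((25, 3)) * 6


class TestSuperpose:
    def test_rigid_motion_removed(self, base_structure):
        rng = np.random.default_rng(1)
        traj = make_traj(random_rigid_copies(base_structure, 20, rng))
        aligned = superpose(traj)
        d = pairwise_rmsd(aligned)
        assert d.max() < 1e-8

    def test_idempotent_on_aligned_trajectory(self, base_structure):
        rng = np.random.default_rng(2)
        coords = base_structure[None] + 0.05 * rng.standard_normal((10, 25, 3))
        aligned = superpose(make_traj(coords))
        again = superpose(aligned)
        assert np.allclose(again.coords, aligned.coords, atol=1e-6)

    def test_optimal_rotation_matches_independent_solver(self, base_structure):
        """Per-pair minimum RMSD agrees with scipy's Kabsch solver."""
        rng = np.random.default_rng(3)
        frames = random_rigid_copies(base_structure, 50, rng)
        frames += 0.2 * rng.standard_normal(frames.shape)
        ours = rmsd_to_reference(frames, base_structure)
        for i in range(0, 50, 7):
            a = frames[i] - frames[i].mean(axis=0)
            b = base_structure - base_structure.mean(axis=0)
            rot, rssd = Rotation.align_vectors(b, a)
            want = rssd / np.sqrt(len(b))
            assert ours[i] == pytest.approx(want, rel=1e-6, abs=1e-9)

    def test_superposition_never_increases_rmsd(self, base_structure):
        rng = np.random.default_rng(4)
        frames = random_rigid_copies(base_structure, 100, rng)
        frames += rng.standard_normal(frames.shape)
        fitted = rmsd_to_reference(frames, base_structure, superimpose=True)
        raw = np.sqrt(
            np.mean(
                np.sum(
                    ((frames - frames.mean(axis=1, keepdims=True))
                     - (base_structure - base_structure.mean(axis=0))) ** 2,
                    axis=2,
                ),
                axis=1,
            )
        )
        assert np.all(fitted <= raw + 1e-12)

    def test_degenerate_selection_rejected(self):
        line = np.stack([np.linspace(0, 10, 5), np.zeros(5), np.zeros(5)], axis=1)
        traj = make_traj(np.repeat(line[None], 3, axis=0))
        with pytest.raises(ValueError):
            superpose(traj)


class TestPairwiseRmsd:
    def test_identical_and_translated_frames_are_zero(self, base_structure):
        coords = np.stack([base_structure, base_structure, base_structure + 5.0])
        d = pairwise_rmsd(make_traj(coords))
        assert np.allclose(d, 0.0, atol=1e-10)

    def test_two_atom_toy_closed_form(self):
        # two atoms on the x-axis, lengths 2 and 4: optimal alignment leaves
        # each atom 0.5 A from its partner -> RMSD = 0.5... worked by hand:
        # centred coords (+-1) vs (+-2); best rotation is identity; per-atom
        # deviation 1 -> RMSD = 1.
        f1 = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        f2 = np.array([[-2.0, 0, 0], [2.0, 0, 0]])
        d = pairwise_rmsd(make_traj(np.stack([f1, f2])))
        assert d[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert d[0, 1] == d[1, 0] and d[0, 0] == 0.0


class TestCluster:
    def test_all_identical_frames_single_cluster(self, base_structure):
        traj = make_traj(np.repeat(base_structure[None], 8, axis=0))
        res = cluster(traj, cutoff=2.0)
        assert res.n_clusters == 1
        assert res.populations.tolist() == [1.0]

    def test_two_state_populations_within_3sigma(self, small_two_state_traj):
        scn, traj = small_two_state_traj
        res = cluster(traj, cutoff=2.0)
        assert res.n_clusters == 2
        sigma = np.sqrt(0.7 * 0.3 / traj.n_frames)
        assert abs(res.populations.max() - 0.7) <= 3 * sigma

    def test_leader_definitional_invariants(self, small_two_state_traj):
        """Seed-seed RMSD > cutoff; every frame within cutoff of its seed."""
        _, traj = small_two_state_traj
        sub = ConformerTrajectory(
            coords=traj.coords[:500],
            atom_names=traj.atom_names,
            atom_groups=traj.atom_groups,
        )
        res = cluster(sub, cutoff=2.0)
        sel = sub.coords
        seeds = res.seeds
        for i, si in enumerate(seeds):
            d = rmsd_to_reference(sel[res.labels == i], sel[si])
            assert np.all(d <= 2.0 + 1e-9)
            for sj in seeds[:i]:
                assert rmsd_to_reference(sel[si][None], sel[sj])[0] > 2.0

    def test_linkage_methods_agree_on_separated_states(self, small_two_state_traj):
        _, traj = small_two_state_traj
        sub = ConformerTrajectory(
            coords=traj.coords[:300],
            atom_names=traj.atom_names,
            atom_groups=traj.atom_groups,
        )
        lead = cluster(sub, cutoff=2.0, method="leader")
        single = cluster(sub, cutoff=2.0, method="single")
        avg = cluster(sub, cutoff=2.0, method="average")
        assert lead.n_clusters == single.n_clusters == avg.n_clusters == 2
        assert np.array_equal(lead.labels, single.labels)

    def test_empty_selection_rejected(self, small_two_state_traj):
        _, traj = small_two_state_traj
        with pytest.raises(ValueError):
            cluster(traj, cutoff=2.0, selection=np.array([], dtype=int))


class TestConfEntropy:
    def test_single_cluster_zero(self):
        assert conf_entropy([1.0]) == 0.0

    def test_uniform_four_clusters(self):
        # R*300K = 0.5962 kcal/mol; S = RT ln 4 = 0.826
        assert conf_entropy([0.25] * 4, 300.0) == pytest.approx(0.826, abs=5e-4)

    def test_two_cluster_skewed(self):
        assert conf_entropy([0.9, 0.1], 300.0) == pytest.approx(0.1938, abs=5e-4)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            conf_entropy([0.7, 0.2])

    def test_upper_bound_RTlnN(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(6))
            s = conf_entropy(p, 300.0)
            assert 0.0 <= s <= R_KCAL_PER_MOL_K * 300.0 * np.log(6) + 1e-12

    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=8), st.integers(0, 2))
    @settings(max_examples=100, derandomize=True)
    def test_merging_clusters_never_increases_entropy(self, weights, which):
        p = np.asarray(weights) / np.sum(weights)
        merged = np.delete(p, which)
        merged[0] += p[which]
        assert conf_entropy(merged) <= conf_entropy(p) + 1e-12

    def test_label_permutation_invariant(self):
        p = [0.5, 0.3, 0.2]
        assert conf_entropy(p) == conf_entropy(p[::-1])


class TestRmsf:
    def test_static_trajectory_zero(self, base_structure):
        traj = make_traj(np.repeat(base_structure[None], 5, axis=0))
        assert np.allclose(rmsf(traj), 0.0)

    def test_isotropic_jitter_sigma_sqrt3(self, base_structure):
        """sigma = 0.1 A per coordinate -> RMSF = 0.1 sqrt(3) (chi distribution
        mean square); Monte-Carlo at 50k frames, already-aligned frames."""
        rng = np.random.default_rng(8)
        coords = base_structure[None] + 0.1 * rng.standard_normal((50_000, 25, 3))
        vals = rmsf(make_traj(coords))
        assert vals.mean() == pytest.approx(0.1 * np.sqrt(3), rel=0.03)

    def test_rotation_translation_invariance_of_report(self, small_two_state_traj):
        """Entropy and RMSF are unchanged when every frame of the ensemble is
        rotated and translated by one global rigid motion."""
        _, traj = small_two_state_traj
        sub = ConformerTrajectory(
            coords=traj.coords[:2000],
            atom_names=traj.atom_names,
            atom_groups=traj.atom_groups,
        )
        rep1 = flex_report(sub)
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        moved = ConformerTrajectory(
            coords=np.einsum("ij,faj->fai", rot, sub.coords) + np.array([10.0, -5.0, 3.0]),
            atom_names=sub.atom_names,
            atom_groups=sub.atom_groups,
        )
        rep2 = flex_report(moved)
        assert rep2.S_conf_total == pytest.approx(rep1.S_conf_total, abs=1e-12)
        assert np.allclose(rep2.rmsf, rep1.rmsf, atol=1e-8)


class TestFlexReport:
    def test_rigid_complex_all_zero(self, mc18_templates):
        templates, names, groups = mc18_templates
        scn = EnsembleScenario(
            state_templates=templates[:1],
            state_populations=np.array([1.0]),
            atom_groups=groups,
            atom_names=names,
            jitter_sd=0.0,
            n_frames=50,
            seed=0,
        )
        rep = flex_report(generate_ensemble(scn))
        assert rep.S_conf_total == pytest.approx(0.0, abs=1e-12)
        assert rep.S_conf_ligand == pytest.approx(0.0, abs=1e-12)
        assert rep.S_conf_receptor == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rep.rmsf, 0.0)

    def test_ligand_only_switching_attributed_to_ligand(self, small_two_state_traj):
        """Receptor is identical across states: receptor entropy ~ 0 and the
        ligand entropy equals the complex entropy."""
        scn, traj = small_two_state_traj
        rep = flex_report(traj)
        assert rep.S_conf_receptor == pytest.approx(0.0, abs=1e-9)
        assert rep.S_conf_ligand == pytest.approx(rep.S_conf_total, rel=1e-9)

    def test_entropy_recovers_ground_truth(self, small_two_state_traj):
        scn, traj = small_two_state_traj
        rep = flex_report(traj)
        want = conf_entropy(scn.state_populations, rep.temperature)
        assert rep.S_conf_total == pytest.approx(want, rel=0.02)

    def test_missing_group_labels_rejected(self, base_structure):
        traj = make_traj(np.repeat(base_structure[None], 5, axis=0))  # ligand only
        with pytest.raises(ValueError):
            flex_report(traj)
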