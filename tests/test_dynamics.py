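"""Superposition, covariance PCA and projection: closed-form pairs, a
random-rotation brute-force oracle, and planted-mode recovery."""

import numpy as np
import pytest

from ugdyn import (
    Atom,
    Structure,
    Trajectory,
    align_trajectory,
    compute_pca,
    fuse_trajectories,
    kabsch_superpose,
    make_cc_trajectory,
    make_conformer,
    make_mode_trajectory,
    project,
    rmsd_matched,
)
from ugdyn._geom import random_rotation
from ugdyn.dynamics import common_calpha_selection
from ugdyn.errors import DegenerateGeometryError, SelectionError

from conftest import apply_rigid, rigid_transform


def rot_z(deg):
    r = np.radians(deg)
    return np.array([[np.cos(r), -np.sin(r), 0],
                     [np.sin(r), np.cos(r), 0],
                     [0, 0, 1.0]])


class TestKabsch:
    def test_identical_sets(self, rng):
        X = rng.normal(0, 10, (20, 3))
        res = kabsch_superpose(X, X)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
        assert res.n_atoms == 20

    def test_recovers_90_degree_rotation(self, rng):
        X = rng.normal(0, 10, (15, 3))
        R = rot_z(90)
        res = kabsch_superpose(X, X @ R.T)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(res.rotation, R, atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_beats_random_rotation_oracle(self, rng):
        """The closed-form fit must be at least as good as 10^4 random
        rotations applied brute-force (translation solved exactly)."""
        X = rng.normal(0, 5, (50, 3))
        Y = X @ rot_z(37).T + rng.normal(0, 1.0, (50, 3)) + [4, -2, 7]
        fit = kabsch_superpose(X, Y)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        best = np.inf
        for _ in range(10_000):
            R = random_rotation(rng)
            best = min(best, ((Xc @ R.T - Yc) ** 2).sum(axis=1).mean())
        assert fit.rmsd <= np.sqrt(best) + 1e-12

    def test_too_few_or_collinear_atoms_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestRmsdMatched:
    def test_structure_vs_itself(self, conformer):
        st, _ = conformer
        rmsd, n = rmsd_matched(st, st, "A", "A")
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert n == len([a for a in st.atoms if a.name == "CA"])

    def test_matches_only_common_residues(self, conformer):
        st, _ = conformer
        half = Structure([a for a in st.atoms if a.residue_number % 2 == 0],
                         entry_id="half")
        _, n = rmsd_matched(st, half, "A", "A")
        assert n == len(half.atoms)

    def test_planted_displacement_closed_form(self, rng):
        """Half the atoms carry a displacement of magnitude d arranged so
        the optimal superposition is the identity (displaced points come
        in duplicated +dz/-dz pairs: zero net translation and a symmetric
        cross-covariance): RMSD = d / sqrt(2)."""
        d = 2.0
        m = 100
        P = rng.normal(0, 20, (m, 3))
        Q = rng.normal(0, 20, (2 * m, 3))
        X = np.vstack([P, P, Q])              # 4m atoms, half displaced
        Y = X.copy()
        Y[:m, 2] += d
        Y[m:2 * m, 2] -= d
        fit = kabsch_superpose(X, Y)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-6)
        assert fit.rmsd == pytest.approx(d / np.sqrt(2), abs=1e-6)
        atoms = [Atom("C", "CA", X[i], i + 1, "ALA", "A")
                 for i in range(len(X))]
        sa = Structure(atoms)
        rmsd, n = rmsd_matched(sa, sa.with_coords(Y), "A", "A")
        assert n == len(X)
        assert rmsd == pytest.approx(d / np.sqrt(2), abs=1e-6)

    def test_too_few_common_residues(self, conformer):
        st, _ = conformer
        tiny = Structure(st.atoms[:2], entry_id="tiny")
        with pytest.raises(SelectionError):
            rmsd_matched(st, tiny, "A", "A")


class TestAlignment:
    def test_rigid_body_motion_collapses_to_one_conformer(self, conformer, rng):
        st, _ = conformer
        frames = [apply_rigid(st, *rigid_transform(rng)).coords_array()
                  for _ in range(6)]
        traj = Trajectory(st, frames)
        aligned = align_trajectory(traj)
        ref = aligned.frames[0]
        for f in aligned.frames[1:]:
            assert np.abs(f - ref).max() < 1e-6

    def test_aligned_trajectory_is_fixed_point(self):
        traj, _ = make_cc_trajectory(
            40 + 3 * np.sin(np.linspace(0, 4 * np.pi, 40)), 120.0, 0.0, seed=1,
            n_atoms_per_domain=5)
        once = align_trajectory(traj)
        twice = align_trajectory(once)
        for a, b in zip(once.frames, twice.frames):
            assert np.abs(a - b).max() < 1e-5

    def test_alignment_preserves_internal_variance(self):
        """Rigid-body jitter on top of a planted internal mode: after
        alignment the total variance matches the planted internal
        variance within 5%."""
        rng = np.random.default_rng(3)
        st, _ = make_conformer((40.0, 120.0, 0.0), seed=2, n_atoms_per_domain=5)
        base = st.coords_array()
        n = base.shape[0]
        # a genuinely internal mode: orthogonal to the six rigid-body
        # generators (translations and infinitesimal rotations), so the
        # superposition cannot absorb any of its variance
        centered = base - base.mean(axis=0)
        gens = []
        for k in range(3):
            t = np.zeros((n, 3))
            t[:, k] = 1.0
            gens.append(t.ravel())
            axis = np.zeros(3)
            axis[k] = 1.0
            gens.append(np.cross(axis, centered).ravel())
        mode = rng.normal(0, 1, 3 * n)
        for g in gens:
            g = g / np.linalg.norm(g)
            mode -= np.dot(mode, g) * g
        mode = (mode / np.linalg.norm(mode)).reshape(n, 3)
        amps = rng.normal(0, 2.0, 300)
        frames = []
        for a in amps:
            internal = base + a * mode
            R = random_rotation(rng)
            frames.append(internal @ R.T + rng.uniform(-30, 30, 3))
        aligned = align_trajectory(Trajectory(st, frames))
        X = np.array([f.ravel() for f in aligned.frames])
        total_var = ((X - X.mean(axis=0)) ** 2).sum(axis=1).mean()
        planted_var = amps.var()
        assert total_var == pytest.approx(planted_var, rel=0.05)


class TestFusion:
    def test_self_fusion_doubles_frames_keeps_variance(self):
        traj, _ = make_cc_trajectory(
            40 + 2 * np.sin(np.linspace(0, 6.28, 50)), 120.0, 0.0, seed=5,
            n_atoms_per_domain=5)
        fused = fuse_trajectories([traj, traj])
        assert fused.n_frames == 2 * traj.n_frames
        X1 = np.array([f.ravel() for f in traj.frames])
        X2 = np.array([f.ravel() for f in fused.frames])
        assert X2.var(axis=0).sum() == pytest.approx(X1.var(axis=0).sum(), rel=1e-9)

    def test_four_single_frame_trajectories(self):
        st, _ = make_conformer((40, 120, 0), seed=0, n_atoms_per_domain=4)
        trajs = []
        for k in range(4):
            stk, _ = make_conformer((40 + k, 120, 0), seed=0, n_atoms_per_domain=4)
            trajs.append(Trajectory(stk, [stk.coords_array()]))
        fused = fuse_trajectories(trajs)
        assert fused.n_frames == 4
        assert fused.source_labels is not None and len(fused.source_labels) == 4

    def test_four_runs_make_canonical_ensemble(self):
        """Four 1500-frame runs fuse into the canonical 6000-frame ensemble."""
        trajs = []
        for k in range(4):
            t, _ = make_cc_trajectory(40.0 + k, 120.0, 0.0, n_frames=1500,
                                      seed=k, n_atoms_per_domain=4)
            trajs.append(t)
        fused = fuse_trajectories(trajs)
        assert fused.n_frames == 6000

    def test_missing_selection_atom_named(self):
        st, _ = make_conformer((40, 120, 0), seed=0, n_atoms_per_domain=4)
        traj = Trajectory(st, [st.coords_array()])
        sel = common_calpha_selection([traj]) + [("Z", 1, "CA")]
        with pytest.raises(SelectionError, match="Z"):
            fuse_trajectories([traj, traj], sel)


class TestPCA:
    def test_single_planted_mode(self, rng):
        base = rng.normal(0, 15, (60, 3))
        mode = rng.normal(0, 1, (60, 3))
        amps = rng.normal(0, 3.0, 500)
        traj, Q = make_mode_trajectory(base, [mode], [amps], seed=1)
        pcs = compute_pca(traj)
        cos = abs(np.dot(pcs.eigenvectors[0], Q[0]))
        assert cos > 0.999
        # rank-1 ensemble: residual components are numerically zero and
        # may be dropped entirely
        if len(pcs.eigenvalues) > 1:
            assert pcs.eigenvalues[1] / pcs.eigenvalues[0] < 1e-6

    def test_two_modes_variance_ratio_and_subspace(self, rng):
        base = rng.normal(0, 15, (60, 3))
        m1 = rng.normal(0, 1, (60, 3))
        m2 = rng.normal(0, 1, (60, 3))
        a1 = rng.normal(0, 2.0, 4000)
        a2 = rng.normal(0, 1.0, 4000)
        traj, Q = make_mode_trajectory(base, [m1, m2], [a1, a2], seed=2)
        pcs = compute_pca(traj, n_components=2)
        ratio = pcs.eigenvalues[0] / pcs.eigenvalues[1]
        assert ratio == pytest.approx(4.0, abs=0.5)
        # principal 2-subspace contains the planted plane: largest
        # principal angle < 5 degrees
        M = Q @ pcs.eigenvectors[:2].T
        angles = np.degrees(np.arccos(np.clip(np.linalg.svd(M)[1], -1, 1)))
        assert angles.max() < 5.0

    def test_isotropic_noise_flat_spectrum(self, rng):
        base = rng.normal(0, 15, (50, 3))
        frames = [base + rng.normal(0, 1.0, base.shape) for _ in range(5000)]
        atoms = [Atom("C", "CA", base[i], i + 1, "ALA", "A")
                 for i in range(50)]
        traj = Trajectory(Structure(atoms), frames)
        pcs = compute_pca(traj)
        assert pcs.eigenvalues[0] / pcs.eigenvalues[-1] < 2.0

    def test_eigenvalues_sum_to_total_variance(self):
        traj, _ = make_cc_trajectory(
            40 + 3 * np.sin(np.linspace(0, 12.5, 300)),
            120 + 5 * np.sin(np.linspace(0, 25, 300)), 0.0,
            noise_sigma=0.1, seed=6, n_atoms_per_domain=5)
        aligned = align_trajectory(traj)
        pcs = compute_pca(aligned)
        X = np.array([f.ravel() for f in aligned.frames])
        total = ((X - X.mean(axis=0)) ** 2).sum(axis=1).mean()
        assert pcs.eigenvalues.sum() == pytest.approx(total, rel=1e-6)

    def test_orthonormal_descending_nonnegative(self):
        traj, _ = make_cc_trajectory(
            40 + 3 * np.sin(np.linspace(0, 12.5, 200)), 120.0, 0.0,
            noise_sigma=0.2, seed=7, n_atoms_per_domain=5)
        pcs = compute_pca(align_trajectory(traj), n_components=8)
        G = pcs.eigenvectors @ pcs.eigenvectors.T
        np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-8)
        assert np.all(np.diff(pcs.eigenvalues) <= 1e-12)
        assert np.all(pcs.eigenvalues >= 0)

    def test_unaligned_input_warns(self, conformer, rng):
        st, _ = conformer
        frames = [st.coords_array() + [30 * k, 0, 0] for k in range(5)]
        with pytest.warns(UserWarning, match="align"):
            compute_pca(Trajectory(st, frames))

    def test_sign_convention_deterministic(self, rng):
        base = rng.normal(0, 10, (30, 3))
        mode = rng.normal(0, 1, (30, 3))
        amps = rng.normal(0, 2, 200)
        traj, _ = make_mode_trajectory(base, [mode], [amps], seed=3)
        # flipping the planted mode must not flip the reported PC
        traj2, _ = make_mode_trajectory(base, [-mode], [-amps], seed=3)
        p1 = compute_pca(traj).eigenvectors[0]
        p2 = compute_pca(traj2).eigenvectors[0]
        np.testing.assert_allclose(p1, p2, atol=1e-6)


class TestProjection:
    @pytest.fixture()
    def planted(self, rng):
        base = rng.normal(0, 15, (40, 3))
        m1 = rng.normal(0, 1, (40, 3))
        m2 = rng.normal(0, 1, (40, 3))
        t = np.arange(600)
        a1 = 3 * np.sin(2 * np.pi * t / 150)
        a2 = 1.5 * np.sin(2 * np.pi * t / 37)
        traj, Q = make_mode_trajectory(base, [m1, m2], [a1, a2], seed=4)
        return traj, Q, a1, compute_pca(traj, n_components=2)

    def test_mean_structure_projects_to_origin(self, planted):
        traj, _, _, pcs = planted
        mean_struct = traj.topology.with_coords(
            pcs.mean_coords.reshape(-1, 3))
        p = project(pcs, mean_struct)
        np.testing.assert_allclose(p, 0.0, atol=1e-8)

    def test_mean_plus_eigenvector_projects_to_c(self, planted):
        _, _, _, pcs = planted
        c = 2.5
        x = pcs.mean_coords + c * pcs.eigenvectors[1]
        p = project(pcs, x, components=[1, 2])
        np.testing.assert_allclose(p[0], [0.0, c], atol=1e-8)

    def test_sinusoid_projection_correlates(self, planted):
        traj, _, a1, pcs = planted
        p = project(pcs, traj, components=[1])[:, 0]
        r = abs(np.corrcoef(p, a1)[0, 1])
        assert r > 0.99

    def test_structure_with_gaps_projects_approximately(self, planted):
        traj, _, a1, pcs = planted
        frame_idx = 37
        full = traj.at_frame(frame_idx)
        gapped = Structure([a for a in full.atoms if a.residue_number % 7],
                           entry_id="gapped")
        p_full = project(pcs, full)[0]
        p_gap = project(pcs, gapped)[0]
        # restricted projection is an approximation; direction must agree
        assert np.sign(p_gap[0]) == np.sign(p_full[0])
        assert p_gap[0] == pytest.approx(p_full[0], rel=0.3, abs=0.3)

    def test_selection_mismatch_errors(self, planted):
        _, _, _, pcs = planted
        with pytest.raises(SelectionError):
            project(pcs, np.zeros(5))

    def test_cc1_series_tracks_pc1_on_clamp_trajectory(self):
        """A clamping-dominated trajectory puts the clamp coordinate on
        the first essential mode."""
        t = np.arange(800)
        cc1 = 40 + 4 * np.sin(2 * np.pi * t / 200)
        traj, truth = make_cc_trajectory(cc1, 120.0, 10.0, noise_sigma=0.05,
                                         seed=8, n_atoms_per_domain=6)
        aligned = align_trajectory(traj)
        pcs = compute_pca(aligned, n_components=2)
        p1 = project(pcs, aligned, components=[1])[:, 0]
        r = abs(np.corrcoef(p1, truth["cc1"])[0, 1])
        assert r > 0.9
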