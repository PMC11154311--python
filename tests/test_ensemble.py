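"""Superposition, RMSD/RMSF, PCA, and cross-correlation statistics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rasstates.ensemble import (
    core_fit_indices,
    cross_correlation,
    pca,
    rmsd_series,
    rmsf_by_state,
    superpose,
)
from rasstates.errors import DataError


def random_structure(n=30, seed=0):
    return np.random.default_rng(seed).normal(scale=5.0, size=(n, 3))


class TestSuperpose:
    def test_identity(self):
        ref = random_structure()
        res = superpose(ref, ref)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_copy_rmsd_zero(self, seed):
        ref = random_structure(seed=seed)
        rot = Rotation.random(random_state=seed).as_matrix()
        mobile = ref @ rot.T + np.array([4.0, -2.0, 9.0])
        assert superpose(mobile, ref).rmsd == pytest.approx(0.0, abs=1e-9)

    def test_four_point_toy_matches_independent_solver(self):
        """Cross-check against scipy's Kabsch solver on a noisy 4-point set."""
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(4, 3))
        rot = Rotation.random(random_state=7).as_matrix()
        mobile = ref @ rot.T + 2.0 + rng.normal(scale=0.3, size=(4, 3))
        res = superpose(mobile, ref)
        mc, rc = mobile.mean(0), ref.mean(0)
        r_scipy, _ = Rotation.align_vectors(ref - rc, mobile - mc)
        moved = (mobile - mc) @ r_scipy.as_matrix().T + rc
        rmsd_scipy = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
        assert res.rmsd == pytest.approx(rmsd_scipy, abs=1e-8)

    def test_report_set_may_differ_from_fit_set(self):
        ref = random_structure(n=20, seed=9)
        mobile = ref.copy()
        mobile[15:] += 3.0  # perturb only the report set
        res = superpose(mobile, ref, fit_set=np.arange(15), report_set=np.arange(15, 20))
        assert res.rmsd == pytest.approx(3.0 * np.sqrt(3), abs=1e-9)

    def test_degenerate_fit_sets_rejected(self):
        ref = random_structure()
        with pytest.raises(DataError, match=">= 3"):
            superpose(ref, ref, fit_set=[0, 1])
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DataError, match="collinear"):
            superpose(line, line)


class TestRMSDSeries:
    def test_static_trajectory_is_zero(self):
        ref = random_structure()
        traj = np.repeat(ref[None], 5, axis=0)
        np.testing.assert_allclose(rmsd_series(traj, ref), 0.0, atol=1e-9)

    def test_switch_rmsd_exceeds_core_on_switch_perturbed_frames(self):
        rng = np.random.default_rng(2)
        n_res = 50
        resids = np.arange(1, n_res + 1)
        ref = random_structure(n=n_res, seed=3)
        core = core_fit_indices(resids, switch_i=(30, 40), switch_ii=(58, 76))
        si = np.setdiff1d(np.arange(n_res), core)
        frames = np.repeat(ref[None], 10, axis=0)
        frames[:, si] += rng.normal(scale=2.5, size=(10, len(si), 3))
        frames[:, core] += rng.normal(scale=0.1, size=(10, len(core), 3))
        rmsd_si = rmsd_series(frames, ref, fit_set=core, report_set=si)
        rmsd_core = rmsd_series(frames, ref, fit_set=core, report_set=core)
        assert np.all(rmsd_si > rmsd_core)


class TestRMSF:
    @staticmethod
    def labels(n, state="S1"):
        return np.full(n, state, dtype=object)

    def test_static_frames_zero_profile(self):
        ref = random_structure()
        frames = np.repeat(ref[None], 6, axis=0)
        prof = rmsf_by_state(frames, self.labels(6), "S1")
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-10)

    def test_two_point_oscillation_closed_form(self):
        """One residue hopping +/-a along x has RMSF exactly a, rest 0."""
        a = 0.75
        ref = random_structure(n=12, seed=1)
        frames = np.repeat(ref[None], 8, axis=0)
        frames[::2, 5, 0] += a
        frames[1::2, 5, 0] -= a
        fit = np.setdiff1d(np.arange(12), [5])
        prof = rmsf_by_state(frames, self.labels(8), "S1", fit_set=fit)
        assert prof.values[5] == pytest.approx(a, abs=1e-8)
        others = np.delete(prof.values, 5)
        np.testing.assert_allclose(others, 0.0, atol=1e-8)

    def test_pooled_equals_per_trajectory_for_identical_blocks(self):
        rng = np.random.default_rng(6)
        frames = random_structure(n=10, seed=2)[None] + rng.normal(
            scale=0.5, size=(40, 10, 3)
        )
        single = rmsf_by_state(frames, self.labels(40), "S1")
        pooled = rmsf_by_state(
            [frames, frames], [self.labels(40), self.labels(40)], "S1"
        )
        np.testing.assert_allclose(pooled.values, single.values, atol=1e-10)
        assert pooled.n_trajectories == 2

    def test_invariance_to_global_rigid_motion(self):
        rng = np.random.default_rng(3)
        frames = random_structure(n=15, seed=4)[None] + rng.normal(
            scale=0.4, size=(25, 15, 3)
        )
        prof0 = rmsf_by_state(frames, self.labels(25), "S1")
        moved = np.empty_like(frames)
        for k in range(len(frames)):
            rot = Rotation.random(random_state=100 + k).as_matrix()
            moved[k] = frames[k] @ rot.T + rng.normal(scale=20.0, size=3)
        prof1 = rmsf_by_state(moved, self.labels(25), "S1")
        np.testing.assert_allclose(prof1.values, prof0.values, atol=1e-8)

    def test_absent_state_named_in_error(self):
        frames = np.repeat(random_structure()[None], 4, axis=0)
        with pytest.raises(DataError, match="S2_OZ"):
            rmsf_by_state(frames, self.labels(4, "S1"), "S2_OZ")


class TestPCA:
    def test_rank_one_displacement(self):
        ref = random_structure(n=20, seed=0)
        direction = np.zeros((20, 3))
        direction[4] = [1.0, 0.0, 0.0]
        direction /= np.linalg.norm(direction)
        amplitudes = np.linspace(-2, 2, 9)
        frames = ref[None] + amplitudes[:, None, None] * direction[None]
        fit = np.setdiff1d(np.arange(20), [4])
        res = pca(frames, fit_set=fit)
        assert res.eigenvalues[0] > 1e-6
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)
        cos = abs(res.eigenvectors[:, 0] @ direction.ravel())
        assert cos > 1 - 1e-8

    def test_trace_identity_and_orthonormal_modes(self):
        rng = np.random.default_rng(11)
        frames = random_structure(n=15, seed=5)[None] + rng.normal(
            scale=0.7, size=(60, 15, 3)
        )
        res = pca(frames, n_modes=10)
        gram = res.eigenvectors.T @ res.eigenvectors
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12) and res.eigenvalues[-1] >= 0
        # trace identity: eigenvalue sum equals total Calpha variance
        assert res.eigenvalues.sum() == pytest.approx(res.cov_trace, rel=1e-6)

    def test_isotropic_noise_gives_flat_spectrum(self):
        """Isotropic Gaussian displacements: eigenvalues flat within the
        chi-square sampling spread of the empirical covariance."""
        rng = np.random.default_rng(21)
        n_frames, n_res, sigma = 3000, 8, 1.0
        ref = random_structure(n=n_res, seed=8) * 100.0  # well-separated
        frames = ref[None] + rng.normal(scale=sigma, size=(n_frames, n_res, 3))
        res = pca(frames, n_modes=3 * n_res)
        lam = res.eigenvalues
        # superposition absorbs 6 rigid-body degrees of freedom
        bulk = lam[: 3 * n_res - 6]
        spread = 3.0 * sigma**2 * np.sqrt(2.0 / n_frames) * 4.0
        assert bulk.max() - bulk.min() < max(spread, 0.25 * sigma**2)

    def test_zero_component_residue_has_zero_mobility(self):
        ref = random_structure(n=10, seed=3)
        direction = np.zeros((10, 3))
        direction[2] = [0.0, 1.0, 0.0]
        frames = ref[None] + np.linspace(-1, 1, 7)[:, None, None] * direction[None]
        fit = np.setdiff1d(np.arange(10), [2])
        res = pca(frames, fit_set=fit)
        assert res.mobility[5, 0] == pytest.approx(0.0, abs=1e-9)
        assert res.mobility[2, 0] > 0

    def test_fewer_than_two_frames_rejected(self):
        with pytest.raises(DataError):
            pca(random_structure()[None])


class TestCrossCorrelation:
    def test_common_translation_perfectly_correlated(self):
        ref = random_structure(n=6, seed=1)
        shifts = np.random.default_rng(0).normal(size=(50, 1, 3))
        frames = ref[None] + shifts
        mat = cross_correlation(frames, superpose_frames=False).matrix
        np.testing.assert_allclose(mat, 1.0, atol=1e-10)

    def test_anti_correlated_pair(self):
        ref = random_structure(n=4, seed=2)
        amp = np.random.default_rng(1).normal(size=50)
        frames = np.repeat(ref[None], 50, axis=0)
        frames[:, 0, 0] += amp
        frames[:, 1, 0] -= amp
        frames[:, 2:, 1] += np.random.default_rng(2).normal(size=(50, 2))
        mat = cross_correlation(frames, superpose_frames=False).matrix
        assert mat[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_independent_motions_decorrelate(self):
        rng = np.random.default_rng(9)
        n_frames = 4000
        frames = random_structure(n=6, seed=4)[None] * 50 + rng.normal(
            size=(n_frames, 6, 3)
        )
        mat = cross_correlation(frames, superpose_frames=False).matrix
        off = mat[~np.eye(6, dtype=bool)]
        assert np.all(np.abs(off) < 3.0 / np.sqrt(n_frames) * 3)

    def test_matrix_contract(self):
        rng = np.random.default_rng(13)
        frames = random_structure(n=12, seed=6)[None] + rng.normal(
            scale=0.5, size=(30, 12, 3)
        )
        mat = cross_correlation(frames).matrix
        np.testing.assert_allclose(mat, mat.T, atol=0)
        np.testing.assert_allclose(np.diag(mat), 1.0, atol=1e-10)
        assert mat.min() >= -1.0 and mat.max() <= 1.0

    def test_zero_variance_residue_zeroed_with_warning(self):
        rng = np.random.default_rng(14)
        frames = np.repeat(random_structure(n=5, seed=7)[None], 40, axis=0)
        frames[:, :4] += rng.normal(scale=0.5, size=(40, 4, 3))
        with pytest.warns(UserWarning, match="zero variance"):
            mat = cross_correlation(frames, superpose_frames=False).matrix
        np.testing.assert_allclose(mat[4, :4], 0.0, atol=0)
        assert mat[4, 4] == 1.0
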