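"""Online similarity matching, trajectory smoothing, population binning."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikesight.ephys_features import SpikeTrain
from spikesight.manifold import (
    PopulationActivityMatrix,
    SMAState,
    TrajectorySegment,
    bin_population_activity,
    gaussian_kernel,
    run_sma,
    sma_step,
    smooth_trajectory,
    subspace_alignment_error,
)
from spikesight.synthetic import synth_latent_session


def anisotropic_gaussian(n, d=10, top=2, ratio=10.0, seed=0):
    rng = np.random.default_rng(seed)
    evals = np.ones(d)
    evals[:top] = ratio
    Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    return rng.standard_normal((n, d)) @ (Q @ np.diag(np.sqrt(evals))).T


class TestSmaStep:
    def test_eta_zero_freezes_state_exactly(self):
        state = SMAState.initialize(5, 2, seed=0, learning_rate=0.0)
        W0, M0 = state.W.copy(), state.M.copy()
        x = np.random.default_rng(1).standard_normal(5)
        y = sma_step(state, x)
        np.testing.assert_array_equal(state.W, W0)
        np.testing.assert_array_equal(state.M, M0)
        np.testing.assert_allclose(y, np.linalg.solve(M0, W0 @ x), atol=1e-12)

    def test_zero_input_gives_zero_output_and_pure_decay(self):
        state = SMAState.initialize(4, 2, seed=0, learning_rate=0.1)
        W0, M0 = state.W.copy(), state.M.copy()
        y = sma_step(state, np.zeros(4))
        np.testing.assert_array_equal(y, 0.0)
        np.testing.assert_allclose(state.W, W0 * 0.9, atol=1e-12)
        np.testing.assert_allclose(state.M, M0 * 0.9, atol=1e-12)

    def test_scalar_constant_input_converges_to_fixed_point(self):
        """d_in = d_out = 1: the scalar recursion run independently must agree."""
        c = 2.0
        state = SMAState(W=np.array([[0.3]]), M=np.array([[1.0]]), learning_rate=0.05)
        w, m = 0.3, 1.0  # independent scalar iteration
        ys, ys_oracle = [], []
        for _ in range(2000):
            ys.append(sma_step(state, np.array([c]))[0])
            y = w * c / m
            w += 0.05 * (y * c - w)
            m += 0.05 * (y * y - m)
            ys_oracle.append(y)
        np.testing.assert_allclose(ys, ys_oracle, atol=1e-10)
        assert abs(ys[-1] - ys[-2]) < 1e-6  # converged to a fixed multiple of c

    def test_m_stays_symmetric_positive_diagonal(self):
        state = SMAState.initialize(6, 3, seed=2, learning_rate=1e-2)
        rng = np.random.default_rng(3)
        for _ in range(500):
            sma_step(state, rng.standard_normal(6))
            np.testing.assert_allclose(state.M, state.M.T, atol=1e-12)
            assert np.all(np.diag(state.M) > 0)

    def test_non_finite_input_rejected(self):
        state = SMAState.initialize(3, 2)
        with pytest.raises(ValueError, match="invalid input"):
            sma_step(state, np.array([1.0, np.nan, 0.0]))


class TestRunSma:
    def test_deterministic_given_seed(self):
        activity, _ = synth_latent_session(d_latent=2, n_units=8, mixing_seed=1, duration=50.0)
        t1, s1 = run_sma(activity, d_out=2, seed=4)
        t2, s2 = run_sma(activity, d_out=2, seed=4)
        np.testing.assert_array_equal(t1.coords, t2.coords)
        np.testing.assert_array_equal(s1.W, s2.W)

    def test_dimension_error(self):
        activity, _ = synth_latent_session(d_latent=2, n_units=4, duration=10.0)
        with pytest.raises(ValueError, match="dimension error"):
            run_sma(activity, d_out=9)

    def test_low_rank_data_reconstructed_from_learned_subspace(self):
        # exact rank-2 inputs: after convergence the learned subspace explains them
        activity, _ = synth_latent_session(
            d_latent=2, n_units=10, mixing_seed=0, noise_sd=0.0, duration=400.0, poisson=False
        )
        _, state = run_sma(activity, d_out=2, learning_rate=5e-3, seed=0, n_passes=3)
        F = state.forward_map()
        basis, _ = np.linalg.qr(F.T)
        X = activity.counts
        resid = X - (X @ basis) @ basis.T
        rel_err = np.linalg.norm(resid) / np.linalg.norm(X)
        assert rel_err < 0.05

    def test_isotropic_input_has_no_preferred_subspace(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((3000, 8))
        activity = PopulationActivityMatrix(
            bin_times=np.arange(3000) * 0.1 + 0.05, counts=X, bin_width=0.1
        )
        _, state = run_sma(activity, d_out=2, learning_rate=5e-3, seed=0)
        # alignment to any fixed 2-D subspace keeps fluctuating: compare two halves
        _, state2 = run_sma(activity, d_out=2, learning_rate=5e-3, seed=0, n_passes=2)
        err = subspace_alignment_error(state, X)
        assert err > 0.05  # no convergence to the (arbitrary) top-2 PCA plane


class TestSmoothing:
    def test_constant_trajectory_unchanged(self):
        traj = TrajectorySegment(np.arange(50) * 0.1, np.full((50, 2), 3.7))
        out = smooth_trajectory(traj, 0.5)
        np.testing.assert_allclose(out.coords, 3.7, atol=1e-12)

    def test_impulse_becomes_normalized_gaussian(self):
        coords = np.zeros((201, 1))
        coords[100] = 1.0
        traj = TrajectorySegment(np.arange(201) * 0.1, coords)
        out = smooth_trajectory(traj, 0.5)
        kernel = gaussian_kernel(5.0)
        half = kernel.size // 2
        np.testing.assert_allclose(out.coords[100 - half : 100 + half + 1, 0], kernel, atol=1e-12)
        np.testing.assert_allclose(out.coords.sum(), 1.0, atol=1e-10)

    def test_matches_dense_convolution_oracle(self):
        rng = np.random.default_rng(7)
        coords = rng.standard_normal((120, 3))
        traj = TrajectorySegment(np.arange(120) * 0.05, coords)
        out = smooth_trajectory(traj, 0.2)
        kernel = gaussian_kernel(0.2 / 0.05)
        half = kernel.size // 2
        expected = np.empty_like(coords)
        for d in range(3):
            padded = np.pad(coords[:, d], half, mode="reflect")
            for t in range(120):
                expected[t, d] = sum(
                    padded[t + half - j] * kernel[half + j] for j in range(-half, half + 1)
                )
        np.testing.assert_allclose(out.coords, expected, atol=1e-10)

    def test_sigma_zero_is_identity(self):
        traj = TrajectorySegment(np.arange(10) * 0.1, np.random.default_rng(0).standard_normal((10, 2)))
        np.testing.assert_array_equal(smooth_trajectory(traj, 0.0).coords, traj.coords)

    def test_non_uniform_bins_rejected(self):
        traj = TrajectorySegment(np.array([0.0, 0.1, 0.3]), np.zeros((3, 1)))
        with pytest.raises(ValueError, match="resample required"):
            smooth_trajectory(traj, 0.1)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.1, 10.0))
    def test_kernel_sums_to_one(self, sigma):
        assert abs(gaussian_kernel(sigma).sum() - 1.0) < 1e-12

    def test_smoothing_commutes_with_adding_constant(self):
        rng = np.random.default_rng(8)
        coords = rng.standard_normal((80, 2))
        traj = TrajectorySegment(np.arange(80) * 0.1, coords)
        shifted = TrajectorySegment(traj.times, coords + 5.0)
        np.testing.assert_allclose(
            smooth_trajectory(shifted, 0.3).coords,
            smooth_trajectory(traj, 0.3).coords + 5.0,
            atol=1e-10,
        )


class TestBinning:
    def make_record(self, times, label, duration=2.0):
        import spikesight as ss

        rec = ss.synth_neuron(ss.DEFAULT_ARCHETYPES["SST"], duration=duration, seed=0)
        train = SpikeTrain(rec.unit_id, np.asarray(times), duration=duration, sampling_rate=3e4)
        rec = copy.copy(rec)
        rec.spike_train = train
        rec.label = label
        return rec

    def test_worked_example(self):
        rec = self.make_record([0.1, 0.15, 1.2], "SST")
        mats = bin_population_activity([rec], bin_width_s=1.0)
        np.testing.assert_array_equal(mats["Inhibitory"].counts[:, 0], [2, 1])

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        recs = [
            self.make_record(np.sort(rng.uniform(0, 1.999, 30)), label, duration=2.0)
            for label in ("Pyramidal", "SST", "GABA_nonSST")
        ]
        mats = bin_population_activity(recs, bin_width_s=0.1)
        total = sum(m.counts.sum() for m in mats.values())
        assert total == 90

    def test_matches_brute_force_histogram(self):
        rng = np.random.default_rng(4)
        times = np.sort(rng.uniform(0, 9.99, 500))
        rec = self.make_record(times, "Pyramidal", duration=10.0)
        mats = bin_population_activity([rec], bin_width_s=0.25)
        expected = np.histogram(times, bins=np.arange(0, 10.25, 0.25))[0]
        np.testing.assert_array_equal(mats["Pyramidal"].counts[:, 0], expected)

    def test_inhibitory_subtypes_pooled(self):
        recs = [
            self.make_record([0.5], "SST"),
            self.make_record([0.6], "GABA_nonSST"),
            self.make_record([0.7], "Pyramidal"),
            self.make_record([0.8], None),
        ]
        mats = bin_population_activity(recs, bin_width_s=1.0)
        assert mats["Inhibitory"].n_units == 2
        assert mats["Unknown"].n_units == 1


class TestSubspaceAlignment:
    def test_identity_construction_is_zero(self):
        X = anisotropic_gaussian(2000, seed=1)
        cov = np.cov(X.T)
        _, evecs = np.linalg.eigh(cov)
        U = evecs[:, ::-1][:, :2]
        state = SMAState(W=U.T, M=np.eye(2))
        assert subspace_alignment_error(state, X) < 1e-8

    def test_orthogonal_complement_is_one(self):
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.standard_normal((10, 10)))
        signal, ortho = Q[:, :2], Q[:, 2:4]
        latent = rng.standard_normal((3000, 2)) * 5.0
        X = latent @ signal.T + 0.01 * rng.standard_normal((3000, 10))
        state = SMAState(W=ortho.T, M=np.eye(2))
        assert subspace_alignment_error(state, X) > 0.99

    def test_trained_state_recovers_principal_subspace(self):
        X = anisotropic_gaussian(5000, seed=3)
        state = SMAState.initialize(10, 2, seed=0, learning_rate=1e-3)
        errs = []
        for i, x in enumerate(X):
            sma_step(state, x)
            if (i + 1) % 500 == 0:
                errs.append(subspace_alignment_error(state, X))
        assert errs[-1] < 0.1
        # decreasing trend over 10-fold checkpoints, allowing stochastic jitter
        assert errs[-1] < errs[0]
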