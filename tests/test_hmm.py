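"""Scanpath HMM machinery: stationary distribution, transition entropy,
constrained re-estimation, BIC mixture selection, spatial statistics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazephysio as gp
from gazephysio.hmm import FitInfo
from gazephysio.model import ScanpathHMM
from gazephysio.types import GaussianMixture2D, HeatMap

from .conftest import isotropic_mixture, two_state_hmm

A_REF = np.array([[0.9, 0.1], [0.3, 0.7]])


def h2(p):
    """Binary entropy, bits."""
    if p in (0.0, 1.0):
        return 0.0
    return -p * np.log2(p) - (1 - p) * np.log2(1 - p)


class TestSteadyState:
    def test_uniform_chain_is_symmetric(self):
        pi = gp.steady_state(np.full((2, 2), 0.5))
        assert np.allclose(pi, [0.5, 0.5])

    def test_reference_chain(self):
        pi = gp.steady_state(A_REF)
        assert np.allclose(pi, [0.75, 0.25], atol=1e-12)
        # cross-check by power iteration
        v = np.array([0.5, 0.5])
        for _ in range(200):
            v = v @ A_REF
        assert np.allclose(pi, v, atol=1e-10)

    def test_absorbing_chain_warns(self):
        with pytest.warns(UserWarning, match="reducible"):
            pi = gp.steady_state(np.eye(2))
        assert pi.sum() == pytest.approx(1.0)
        with pytest.warns(UserWarning, match="absorbing"):
            pi = gp.steady_state(np.array([[1.0, 0.0], [0.5, 0.5]]))
        assert np.allclose(pi, [1.0, 0.0])

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            gp.steady_state(np.array([[0.9, 0.2], [0.3, 0.7]]))


class TestTransitionEntropy:
    def test_uniform_chain_one_bit(self):
        assert gp.transition_entropy(np.full((2, 2), 0.5)) == 1.0

    def test_deterministic_chain_zero_bits(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert gp.transition_entropy(np.eye(2)) == 0.0

    def test_reference_chain_value(self):
        # pi = (0.75, 0.25): H = 0.75*h2(0.9) + 0.25*h2(0.7)
        expected = 0.75 * h2(0.9) + 0.25 * h2(0.7)
        assert expected == pytest.approx(0.572, abs=5e-4)
        assert gp.transition_entropy(A_REF, np.array([0.75, 0.25])) == pytest.approx(
            expected, abs=1e-12
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gp.transition_entropy(A_REF, np.array([1.0]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_bruteforce_and_is_bounded(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.dirichlet((1.0, 1.0), size=2)
        pi = gp.steady_state(A)
        assert np.allclose(pi @ A, pi, atol=1e-10)
        brute = -sum(
            pi[i] * A[i, j] * np.log2(A[i, j])
            for i in range(2)
            for j in range(2)
            if A[i, j] > 0
        )
        h = gp.transition_entropy(A, pi)
        assert h == pytest.approx(brute, abs=1e-12)
        assert 0.0 <= h <= 1.0


class TestFitGmmBic:
    @pytest.fixture(scope="class")
    @staticmethod
    def three_clusters():
        rng = np.random.default_rng(0)
        centers = np.array([[100.0, 100.0], [500.0, 100.0], [300.0, 500.0]])
        return np.vstack(
            [c + rng.normal(0, 10.0, size=(80, 2)) for c in centers]
        )

    def test_selects_three_components(self, three_clusters):
        mix, m = gp.fit_gmm_bic(three_clusters, k_min=1, k_max=6, seed=0)
        assert m == 3
        assert mix.n_components == 3

    def test_single_cloud_selects_one(self):
        rng = np.random.default_rng(1)
        pts = rng.normal([300.0, 300.0], 20.0, size=(200, 2))
        _, m = gp.fit_gmm_bic(pts, k_min=1, k_max=4, seed=0)
        assert m == 1

    def test_deterministic_given_seed(self, three_clusters):
        m1, _ = gp.fit_gmm_bic(three_clusters, 1, 5, seed=3)
        m2, _ = gp.fit_gmm_bic(three_clusters, 1, 5, seed=3)
        assert np.array_equal(m1.weights, m2.weights)
        assert np.array_equal(m1.means, m2.means)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            gp.fit_gmm_bic(np.zeros((5, 2)), 1, 3)


class TestReweightMixture:
    @pytest.fixture(scope="class")
    @staticmethod
    def mixture():
        return isotropic_mixture(
            [[100.0, 100.0], [500.0, 500.0]], sd=20.0, weights=[0.5, 0.5]
        )

    def test_single_component_data(self, mixture):
        rng = np.random.default_rng(0)
        pts = rng.normal([100.0, 100.0], 20.0, size=(500, 2))
        w = gp.reweight_mixture(mixture, pts)
        assert w[0] == pytest.approx(1.0, abs=1e-3)

    def test_recovers_generating_weights(self):
        gen = isotropic_mixture(
            [[100.0, 100.0], [500.0, 500.0]], sd=20.0, weights=[0.7, 0.3]
        )
        rng = np.random.default_rng(1)
        pts = gen.sample(5000, rng)
        start = isotropic_mixture(
            [[100.0, 100.0], [500.0, 500.0]], sd=20.0, weights=[0.5, 0.5]
        )
        w = gp.reweight_mixture(start, pts)
        assert np.allclose(w, [0.7, 0.3], atol=0.02)

    def test_means_covariances_untouched(self, mixture):
        means0 = mixture.means.copy()
        covs0 = mixture.covariances.copy()
        rng = np.random.default_rng(2)
        gp.reweight_mixture(mixture, mixture.sample(200, rng))
        assert np.array_equal(mixture.means, means0)
        assert np.array_equal(mixture.covariances, covs0)

    def test_empty_points_rejected(self, mixture):
        with pytest.raises(ValueError):
            gp.reweight_mixture(mixture, np.empty((0, 2)))


class TestTrainHMM:
    @pytest.fixture(scope="class")
    @staticmethod
    def observations():
        hmm = two_state_hmm(A_REF)
        pts, _ = gp.generate_from_hmm(hmm, 3000, seed=0)
        return pts

    def test_fixed_point_at_generating_parameters(self, observations):
        init = two_state_hmm(A_REF)
        fitted, info = gp.train_hmm(observations, init, seed=0)
        # at (near) the generating parameters EM converges almost at once:
        # everything after the first sample-MLE adjustment step is tiny
        assert info.converged and info.n_iter <= 20
        lls = info.log_likelihoods
        assert lls[-1] - lls[1] < lls[1] - lls[0]
        assert np.abs(fitted.transmat - A_REF).max() < 0.05

    def test_monotone_loglikelihood(self, observations):
        init = two_state_hmm(np.array([[0.6, 0.4], [0.4, 0.6]]))
        _, info = gp.train_hmm(observations, init, seed=0, max_iter=50)
        diffs = np.diff(info.log_likelihoods)
        assert np.all(diffs >= -1e-6 * np.abs(info.log_likelihoods[:-1]))

    def test_transition_recovery(self, observations):
        init = two_state_hmm(np.array([[0.6, 0.4], [0.4, 0.6]]))
        fitted, _ = gp.train_hmm(observations, init, seed=0)
        assert np.abs(fitted.transmat - A_REF).max() < 0.05

    def test_deterministic(self, observations):
        m = ScanpathHMM(observations, n_components=(2, 4))
        r1 = m.fit(seed=5)
        r2 = m.fit(seed=5)
        assert np.array_equal(r1.transmat, r2.transmat)
        assert r1.log_likelihood == r2.log_likelihood

    def test_too_few_observations_rejected(self):
        init = two_state_hmm(A_REF)
        with pytest.raises(ValueError):
            gp.train_hmm(np.zeros((50, 2)), init)

    def test_matches_hmmlearn_likelihood(self, observations):
        """Independent cross-check: hmmlearn's GaussianHMM on the same data
        reaches the same ballpark likelihood and transition structure for
        single-Gaussian emissions."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        init = gp.GazeHMM(
            emissions=(
                isotropic_mixture([[460.0, 340.0]], sd=40.0),
                isotropic_mixture([[480.0, 360.0]], sd=300.0),
            ),
            transmat=np.array([[0.8, 0.2], [0.2, 0.8]]),
            startprob=np.array([0.5, 0.5]),
        )
        ours, info = gp.train_hmm(observations, init, seed=0)

        ref = hmmlearn.GaussianHMM(
            n_components=2, covariance_type="full", n_iter=500, tol=1e-5,
            init_params="", params="stmc",
        )
        ref.startprob_ = init.startprob.copy()
        ref.transmat_ = init.transmat.copy()
        ref.means_ = np.array([[460.0, 340.0], [480.0, 360.0]])
        ref.covars_ = np.array([np.eye(2) * 40.0**2, np.eye(2) * 300.0**2])
        ref.fit(observations)
        assert info.log_likelihood == pytest.approx(
            ref.score(observations), rel=1e-3
        )
        # same chain up to state permutation
        perm = [0, 1] if ref.covars_[0][0, 0] < ref.covars_[1][0, 0] else [1, 0]
        assert np.allclose(
            ours.transmat, ref.transmat_[np.ix_(perm, perm)], atol=0.05
        )


class TestReestimateTransitions:
    def test_absorbing_segment(self):
        hmm = two_state_hmm(np.array([[0.8, 0.2], [0.3, 0.7]]))
        gen = two_state_hmm(np.eye(2), startprob=[1.0, 0.0])
        pts, _ = gp.generate_from_hmm(gen, 600, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            A = gp.reestimate_transitions(hmm, pts)
        assert A[0, 0] == pytest.approx(1.0, abs=1e-2)

    def test_window_scale_recovery(self):
        hmm = two_state_hmm(np.array([[0.6, 0.4], [0.4, 0.6]]))
        gen = two_state_hmm(A_REF)
        pts, _ = gp.generate_from_hmm(gen, 514, seed=2)  # one 3-min window
        A = gp.reestimate_transitions(hmm, pts)
        assert np.abs(A - A_REF).max() < 0.05

    def test_emissions_and_startprob_frozen(self):
        hmm = two_state_hmm(np.array([[0.8, 0.2], [0.3, 0.7]]))
        before = [
            (g.weights.copy(), g.means.copy(), g.covariances.copy())
            for g in hmm.emissions
        ]
        p0 = hmm.startprob.copy()
        pts, _ = gp.generate_from_hmm(hmm, 400, seed=3)
        gp.reestimate_transitions(hmm, pts)
        for g, (w, m, c) in zip(hmm.emissions, before):
            assert np.array_equal(g.weights, w)
            assert np.array_equal(g.means, m)
            assert np.array_equal(g.covariances, c)
        assert np.array_equal(hmm.startprob, p0)

    def test_rows_stochastic_after_reestimation(self):
        hmm = two_state_hmm(np.array([[0.8, 0.2], [0.3, 0.7]]))
        pts, _ = gp.generate_from_hmm(hmm, 500, seed=4)
        A = gp.reestimate_transitions(hmm, pts)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-9)
        pi = gp.steady_state(A)
        assert np.allclose(pi @ A, pi, atol=1e-8)


class TestHeatmapKL:
    def _hm(self, probs):
        g = np.asarray(probs, dtype=float).reshape(1, -1)
        return HeatMap(g, 10.0)

    def test_identical_maps_zero(self):
        p = self._hm([0.3, 0.7])
        assert gp.heatmap_kl(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_pixel_example(self):
        p = self._hm([0.5, 0.5])
        q = self._hm([0.75, 0.25])
        expected = 0.5 * np.log2(0.5 / 0.75) + 0.5 * np.log2(0.5 / 0.25)
        assert expected == pytest.approx(0.2075, abs=1e-4)
        assert gp.heatmap_kl(p, q) == pytest.approx(expected, abs=1e-12)

    def test_nonnegativity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random(16)
            b = rng.random(16)
            assert gp.heatmap_kl(self._hm(a / a.sum()), self._hm(b / b.sum())) >= 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gp.heatmap_kl(self._hm([1.0]), self._hm([0.5, 0.5]))


class TestBetweenClusterCovDet:
    def test_identical_means_zero(self):
        m = np.tile([3.0, 4.0], (3, 1))
        assert gp.between_cluster_cov_det(np.full(3, 1 / 3), m) == 0.0

    def test_two_collinear_clusters_rank_deficient(self):
        det = gp.between_cluster_cov_det(
            np.array([0.5, 0.5]), np.array([[0.0, 0.0], [10.0, 0.0]])
        )
        assert det == pytest.approx(0.0, abs=1e-12)

    def test_three_cluster_hand_value(self):
        # Sigma_b = [[2/9, -1/9], [-1/9, 2/9]] -> det = 1/27
        det = gp.between_cluster_cov_det(
            np.full(3, 1 / 3), np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        )
        assert det == pytest.approx(1.0 / 27.0, abs=1e-12)

    def test_single_cluster_warns(self):
        with pytest.warns(UserWarning):
            assert gp.between_cluster_cov_det(np.array([1.0]), np.array([[1.0, 2.0]])) == 0.0

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            gp.between_cluster_cov_det(np.array([0.5, 0.6]), np.zeros((2, 2)))


class TestGenerateFromHmm:
    def test_empirical_transitions_match(self):
        hmm = two_state_hmm(A_REF)
        _, states = gp.generate_from_hmm(hmm, 10_000, seed=0)
        emp = np.array(
            [
                [np.mean(states[1:][states[:-1] == i] == j) for j in (0, 1)]
                for i in (0, 1)
            ]
        )
        assert np.abs(emp - A_REF).max() < 0.02

    def test_deterministic(self):
        hmm = two_state_hmm(A_REF)
        p1, s1 = gp.generate_from_hmm(hmm, 100, seed=9)
        p2, s2 = gp.generate_from_hmm(hmm, 100, seed=9)
        assert np.array_equal(p1, p2)
        assert np.array_equal(s1, s2)


class TestResultsObject:
    def test_summary_and_kl(self):
        hmm = two_state_hmm(A_REF)
        pts, _ = gp.generate_from_hmm(hmm, 1500, seed=1)
        res = ScanpathHMM(pts, n_components=(2, 4), image_dims=(960, 720)).fit(seed=0)
        text = res.summary()
        assert "transition entropy" in text
        assert isinstance(res.fit_info, FitInfo)
        # model-generated heatmap is close in KL to a measured-style heatmap
        # of the training data
        from .conftest import make_trajectory

        measured = gp.compute_heatmap(
            make_trajectory(np.clip(pts, 0, [959.9, 719.9]))
        )
        kl = res.kl_from(measured, n=5000, seed=2)
        assert 0.0 <= kl < 2.0
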