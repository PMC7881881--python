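"""Two-state scanpath HMM: training, constrained re-estimation, transition
entropy and related spatial statistics.

The model assumes the gaze sample (or fixation centroid) at step ``t`` is
emitted by a hidden state ``s_t in {central, peripheral}``, each with its own
Gaussian-mixture emission density, and that the state sequence is a Markov
chain with transition matrix ``A = [a_ij]``.  The gaze transition entropy

    H = -sum_i pi_i sum_j a_ij log2 a_ij        (0*log 0 = 0)

weights each row entropy by the stationary distribution ``pi`` and is bounded
by ``log2(n_states)`` = 1 bit for two states.  Lower values indicate more
deliberative, focused scanning; the maximum is reached for uniform
transition probabilities and the minimum (0 bits) for deterministic rows.

Training is Baum-Welch (EM) with log-space forward-backward.  The
subject-independent model is trained on pooled data; per-window transition
probabilities are then re-estimated with emissions and initial state
probabilities frozen, which is the constrained E/M cycle implemented by
:func:`reestimate_transitions`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .types import GaussianMixture2D, GazeHMM, HeatMap

__all__ = [
    "steady_state",
    "transition_entropy",
    "train_hmm",
    "reestimate_transitions",
    "fit_gmm_bic",
    "reweight_mixture",
    "generate_from_hmm",
    "heatmap_kl",
    "between_cluster_cov_det",
    "FitInfo",
]

COV_EIGVAL_FLOOR = 1.0  # px^2 — numerical floor on emission covariances


# ---------------------------------------------------------------------------
# Markov-chain statistics
# ---------------------------------------------------------------------------

def steady_state(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Solves ``pi @ A = pi`` with ``sum(pi) = 1`` via the null space of
    ``A.T - I``.  For a reducible chain (an off-diagonal entry of 0) the
    stationary distribution is not unique; the point mass on the absorbing
    state is returned with a warning.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("A must be square")
    if np.any(A < 0) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("A must be row-stochastic")

    if n == 2:
        a12, a21 = A[0, 1], A[1, 0]
        if a12 == 0.0 and a21 == 0.0:
            warnings.warn(
                "transition matrix is reducible (both states absorbing); "
                "returning point mass on state 0",
                stacklevel=2,
            )
            return np.array([1.0, 0.0])
        if a12 == 0.0 or a21 == 0.0:
            absorbing = 0 if a12 == 0.0 else 1
            warnings.warn(
                "transition matrix is reducible; returning the absorbing-state "
                "point mass",
                stacklevel=2,
            )
            pi = np.zeros(2)
            pi[absorbing] = 1.0
            return pi
        pi = np.array([a21, a12]) / (a12 + a21)
        return pi

    # general n: least squares on [A^T - I; 1] pi = [0; 1]
    M = np.vstack([A.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def transition_entropy(A: np.ndarray, pi: np.ndarray | None = None) -> float:
    """Stationary-weighted entropy of the transition rows, in bits.

    ``H = -sum_i pi_i sum_j a_ij log2 a_ij`` with the ``0*log 0 = 0``
    convention.  If ``pi`` is omitted it is computed from ``A``.
    """
    A = np.asarray(A, dtype=float)
    if pi is None:
        pi = steady_state(A)
    pi = np.asarray(pi, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if pi.shape != (A.shape[0],):
        raise ValueError("pi dimension must match A")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(A > 0, A * np.log2(np.where(A > 0, A, 1.0)), 0.0)
    return float(-(pi @ terms.sum(axis=1))) + 0.0


# ---------------------------------------------------------------------------
# Baum-Welch with per-state GMM emissions
# ---------------------------------------------------------------------------

@dataclass
class FitInfo:
    """Convergence record of an EM fit."""

    log_likelihoods: np.ndarray
    converged: bool
    n_iter: int

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihoods[-1])


def _emission_loglik(hmm: GazeHMM, X: np.ndarray):
    """Per-state mixture log-likelihoods.

    Returns ``logB`` of shape (n, 2) and the per-component log joints
    ``log c_im + log N_im(x)`` as a list of (n, K_i) arrays.
    """
    comp_logs = []
    logB = np.empty((len(X), hmm.n_states))
    for i, gm in enumerate(hmm.emissions):
        with np.errstate(divide="ignore"):
            logw = np.where(gm.weights > 0, np.log(gm.weights), -np.inf)
        lj = gm.component_logpdf(X) + logw
        comp_logs.append(lj)
        logB[:, i] = logsumexp(lj, axis=1)
    return logB, comp_logs


def _forward_backward(log_start, log_A, logB):
    """Scaled forward-backward (per-step normalization; numerically
    equivalent to the log-space recursion).

    Returns (loglik, gamma, xi_sum) where gamma is (n, 2) posterior state
    probabilities and xi_sum the (2, 2) expected transition counts.
    """
    n, S = logB.shape
    A = np.exp(log_A)
    start = np.exp(log_start)
    # per-step max-shift keeps exp(logB) in range
    m = logB.max(axis=1)
    B = np.exp(logB - m[:, None])

    alpha = np.empty((n, S))
    c = np.empty(n)
    a = start * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + m.sum())

    beta = np.empty((n, S))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi_sum = np.zeros((S, S))
    if n > 1:
        w = B[1:] * beta[1:] / c[1:, None]
        xi_sum = A * (alpha[:-1].T @ w)
    return loglik, gamma, xi_sum


def _floor_cov(cov: np.ndarray, floor: float = COV_EIGVAL_FLOOR) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _em(
    hmm: GazeHMM,
    X: np.ndarray,
    update: str,
    tol: float = 1e-5,
    max_iter: int = 500,
):
    """Generic EM over a GazeHMM.

    ``update`` is a subset of ``"tpwmc"``: transitions, startprob, weights,
    means, covariances.  Parameters not listed are left bit-identical.
    Log-likelihood is monotone non-decreasing across iterations (checked).
    """
    hmm = hmm.copy()
    X = np.asarray(X, dtype=float)
    with np.errstate(divide="ignore"):
        log_A = np.log(np.where(hmm.transmat > 0, hmm.transmat, 1e-300))
        log_start = np.log(np.where(hmm.startprob > 0, hmm.startprob, 1e-300))

    lls = []
    converged = False
    for it in range(max_iter):
        logB, comp_logs = _emission_loglik(hmm, X)
        loglik, gamma, xi_sum = _forward_backward(log_start, log_A, logB)
        if not np.isfinite(loglik):
            raise FloatingPointError(
                "non-finite likelihood during EM (degenerate emission component)"
            )
        lls.append(loglik)
        if len(lls) > 1:
            if lls[-1] < lls[-2] - 1e-8 * max(1.0, abs(lls[-2])):
                warnings.warn(
                    f"EM log-likelihood decreased at iteration {it}", stacklevel=2
                )
            # convergence on the per-observation log-likelihood change
            if abs(lls[-1] - lls[-2]) / len(X) < tol:
                converged = True
                break

        if "t" in update:
            row = xi_sum.sum(axis=1, keepdims=True)
            occupancy = gamma[:-1].sum(axis=0)
            newA = hmm.transmat.copy()
            for i in range(hmm.n_states):
                if occupancy[i] < 1.0:
                    warnings.warn(
                        f"state {i} expected occupancy < 1; keeping prior "
                        "transition row",
                        stacklevel=2,
                    )
                elif row[i, 0] > 0:
                    newA[i] = xi_sum[i] / row[i, 0]
            hmm.transmat = newA
            with np.errstate(divide="ignore"):
                log_A = np.log(np.where(newA > 0, newA, 1e-300))
        if "p" in update:
            hmm.startprob = gamma[0] / gamma[0].sum()
            log_start = np.log(np.where(hmm.startprob > 0, hmm.startprob, 1e-300))

        if any(c in update for c in "wmc"):
            for i, gm in enumerate(hmm.emissions):
                lj = comp_logs[i]
                # responsibilities within state i, scaled by state posterior
                r = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
                r *= gamma[:, i][:, None]
                nk = r.sum(axis=0)
                if "w" in update:
                    total = nk.sum()
                    if total > 0:
                        gm.weights = nk / total
                if "m" in update or "c" in update:
                    safe = np.maximum(nk, 1e-12)
                    new_means = (r.T @ X) / safe[:, None]
                    if "m" in update:
                        gm.means = new_means
                    if "c" in update:
                        for k in range(gm.n_components):
                            d = X - gm.means[k]
                            cov = (r[:, k][:, None] * d).T @ d / safe[k]
                            gm.covariances[k] = _floor_cov(cov)
    else:
        it = max_iter - 1

    return hmm, FitInfo(np.asarray(lls), converged, it + 1)


def train_hmm(
    observations: np.ndarray,
    init: GazeHMM,
    seed: int | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
    update: str = "tpwmc",
):
    """Full Baum-Welch fit of a two-state scanpath HMM.

    Parameters
    ----------
    observations : (n, 2) array
        Gaze observations, by default fixation centroids (one observation per
        fixation).
    init : GazeHMM
        Starting model.  Means/covariances are typically seeded from heatmap
        structure; weights, transitions and start probabilities may be random
        (use :func:`gazephysio.model.random_init`).
    seed : int, optional
        Unused directly (EM is deterministic given ``init``); accepted so the
        caller's seed-threading is explicit.

    Returns
    -------
    (GazeHMM, FitInfo)
    """
    X = np.asarray(observations, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("observations must be (n, 2)")
    if len(X) < 100:
        raise ValueError("need at least 100 observations to train")
    return _em(init, X, update=update, tol=tol, max_iter=max_iter)


def reestimate_transitions(
    hmm: GazeHMM,
    observations: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> np.ndarray:
    """Re-estimate the transition matrix on a data segment, keeping the GMM
    emissions and initial state probabilities frozen.

    If a state's expected occupancy in the segment is below one observation
    its row cannot be estimated; the row from ``hmm`` is kept and a warning
    issued.

    Returns the new 2x2 row-stochastic transition matrix; ``hmm`` is not
    modified.
    """
    X = np.asarray(observations, dtype=float)
    if len(X) < 2:
        raise ValueError("segment too short to re-estimate transitions")
    fitted, _ = _em(hmm, X, update="t", tol=tol, max_iter=max_iter)
    return fitted.transmat


# ---------------------------------------------------------------------------
# GMM region-of-interest modeling
# ---------------------------------------------------------------------------

def fit_gmm_bic(
    points: np.ndarray,
    k_min: int = 1,
    k_max: int = 20,
    seed: int | None = None,
    n_init: int = 3,
    max_retries: int = 3,
):
    """Fit GMMs for each candidate component count and return the one
    minimizing the Bayesian information criterion.

    BIC = -2 logL + n_params ln(n); the penalty guards against over-fitting
    with too many regions of interest.

    Returns
    -------
    (GaussianMixture2D, int)
        The selected mixture and its component count.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.mixture import GaussianMixture as _SkGMM

    X = np.asarray(points, dtype=float)
    if len(X) < 10 * k_max:
        raise ValueError(f"need at least {10 * k_max} points for k_max={k_max}")

    best = None
    best_bic = np.inf
    best_k = None
    for k in range(k_min, k_max + 1):
        fit = None
        for attempt in range(max_retries):
            gm = _SkGMM(
                n_components=k,
                covariance_type="full",
                n_init=n_init,
                random_state=None if seed is None else seed + attempt,
                reg_covar=1e-3,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gm.fit(X)
            # reject collapsed components (vanishing weight or covariance)
            if gm.weights_.min() > 1e-6 and all(
                np.linalg.eigvalsh(c).min() > 1e-6 for c in gm.covariances_
            ):
                fit = gm
                break
        if fit is None:
            raise RuntimeError(f"degenerate GMM fit for M={k} after retries")
        bic = fit.bic(X)
        if bic < best_bic:
            best_bic = bic
            best = fit
            best_k = k
    mix = GaussianMixture2D(best.weights_, best.means_, best.covariances_)
    return mix, best_k


def reweight_mixture(
    gmm: GaussianMixture2D,
    points: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> np.ndarray:
    """EM over mixture weights only, with means and covariances frozen.

    Used to compare groups: a shared set of regions of interest is fit once,
    then each group gets its own weights over the same components.  The input
    ``gmm`` is not modified; the new weight vector is returned.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.size == 0:
        raise ValueError("cannot reweight on an empty point set")
    comp = gmm.component_logpdf(X)  # (n, K)
    w = gmm.weights.copy()
    prev_ll = -np.inf
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            logw = np.where(w > 0, np.log(w), -np.inf)
        lj = comp + logw
        norm = logsumexp(lj, axis=1)
        ll = float(norm.sum())
        w = np.exp(lj - norm[:, None]).mean(axis=0)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return w / w.sum()


# ---------------------------------------------------------------------------
# Simulation and spatial statistics
# ---------------------------------------------------------------------------

def generate_from_hmm(hmm: GazeHMM, n: int, seed: int | None = None):
    """Ancestral sampling: draw a state path, then one emission per step.

    Returns (points, states) with ``points`` of shape (n, 2).
    """
    rng = np.random.default_rng(seed)
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(hmm.n_states, p=hmm.startprob)
    for t in range(1, n):
        states[t] = rng.choice(hmm.n_states, p=hmm.transmat[states[t - 1]])
    points = np.empty((n, 2))
    for i in range(hmm.n_states):
        mask = states == i
        if mask.any():
            points[mask] = hmm.emissions[i].sample(int(mask.sum()), rng)
    return points, states


def heatmap_kl(p: HeatMap, q: HeatMap, floor: float = 1e-12) -> float:
    """Kullback-Leibler divergence KL(p || q) between two heatmaps, in bits.

    ``q`` is floored at ``floor`` and renormalized so that the support of
    ``p`` is contained in the support of ``q``; KL is then finite and
    nonnegative, zero iff p == q.
    """
    if p.grid.shape != q.grid.shape:
        raise ValueError("heatmap dimensions must match")
    P = p.grid.ravel()
    Q = np.maximum(q.grid.ravel(), floor)
    Q = Q / Q.sum()
    mask = P > 0
    return float(np.sum(P[mask] * np.log2(P[mask] / Q[mask])))


def between_cluster_cov_det(weights: np.ndarray, means: np.ndarray) -> float:
    """Determinant of the weighted between-cluster covariance matrix (px^4).

    ``Sigma_b = sum_i pi_i (m_i - m_bar)(m_i - m_bar)^T`` with
    ``m_bar = sum_i pi_i m_i``.  Larger determinants correspond to more
    spatially spread cluster structure.
    """
    w = np.asarray(weights, dtype=float)
    m = np.asarray(means, dtype=float)
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    if len(w) < 2:
        warnings.warn("single cluster: between-cluster spread is 0", stacklevel=2)
        return 0.0
    mbar = w @ m
    d = m - mbar
    sigma_b = (w[:, None] * d).T @ d
    det = float(np.linalg.det(sigma_b))
    return max(det, 0.0)
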