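"""Model/Results interface for the two-state scanpath HMM.

``ScanpathHMM`` is built from data (fixation centroids, or a gaze trajectory
via :meth:`ScanpathHMM.from_trajectory`); ``fit`` runs Baum-Welch and
returns a ``ScanpathHMMResults`` carrying the estimated parameters,
convergence diagnostics, the transition entropy, and simulation / heatmap /
plotting helpers::

    model = ScanpathHMM.from_trajectory(traj, n_components=(4, 9))
    res = model.fit(seed=0)
    print(res.summary())
    H = res.transition_entropy           # bits
    A_w = res.reestimate_transitions(window_centroids)

Emission means and covariances are seeded by k-means on the observations
split into a central and a peripheral shell (standing in for manual
initialization from heatmap inspection); mixture weights, transition and
initial state probabilities are initialized randomly from the seed.
"""

from __future__ import annotations

import numpy as np

from . import hmm as _hmm
from .metrics import compute_heatmap, segment_fixations
from .types import GaussianMixture2D, GazeHMM, GazeTrajectory, HeatMap

__all__ = ["ScanpathHMM", "ScanpathHMMResults"]


def _kmeans_mixture(points: np.ndarray, k: int, seed: int) -> GaussianMixture2D:
    from sklearn.cluster import KMeans

    k = min(k, len(points))
    km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(points)
    means = km.cluster_centers_
    covs = []
    for j in range(k):
        pts = points[km.labels_ == j]
        if len(pts) > 2:
            cov = np.cov(pts.T) + np.eye(2) * _hmm.COV_EIGVAL_FLOOR
        else:
            cov = np.eye(2) * 50.0**2
        covs.append(_hmm._floor_cov(cov))
    return GaussianMixture2D(
        weights=np.full(k, 1.0 / k), means=means, covariances=np.asarray(covs)
    )


class ScanpathHMM:
    """Two-state (central/peripheral) scanpath model specification.

    Parameters
    ----------
    observations : (n, 2) array
        Gaze observations; by default one fixation centroid per fixation.
    n_components : tuple of int
        GMM component counts (central, peripheral).  The defaults used for
        the two scenes are (4, 9) for the courtyard-like and (3, 12) for the
        garden-like scene.
    image_dims : (width, height), optional
        Scene-image size in pixels; defaults to the observation bounding box.
    """

    def __init__(self, observations, n_components=(4, 9), image_dims=None):
        X = np.asarray(observations, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("observations must be (n, 2)")
        self.observations = X
        self.n_components = tuple(int(c) for c in n_components)
        if len(self.n_components) != 2 or min(self.n_components) < 1:
            raise ValueError("n_components must be two positive counts")
        if image_dims is None:
            image_dims = (
                int(np.ceil(X[:, 0].max())) + 1,
                int(np.ceil(X[:, 1].max())) + 1,
            )
        self.image_dims = tuple(image_dims)

    @classmethod
    def from_trajectory(
        cls,
        traj: GazeTrajectory,
        n_components=(4, 9),
        granularity: str = "fixation",
    ) -> "ScanpathHMM":
        """Build the model from a gaze trajectory.

        ``granularity='fixation'`` (default) segments the trajectory and uses
        one observation per fixation centroid; ``'sample'`` uses every valid
        gaze sample.
        """
        if granularity == "fixation":
            fs = segment_fixations(traj)
            X = np.asarray([f.centroid for f in fs.fixations])
        elif granularity == "sample":
            _, X = traj.valid_samples()
        else:
            raise ValueError("granularity must be 'fixation' or 'sample'")
        return cls(X, n_components=n_components, image_dims=traj.image_dims)

    def with_components(self, n_components) -> "ScanpathHMM":
        """Same data, different per-state component counts (for the
        robustness sweep)."""
        return ScanpathHMM(self.observations, n_components, self.image_dims)

    # -- initialization -----------------------------------------------------

    def _initial_model(self, seed: int) -> GazeHMM:
        rng = np.random.default_rng(seed)
        X = self.observations
        center = X.mean(axis=0)
        dist = np.linalg.norm(X - center, axis=1)
        # split central/peripheral shells by 2-means on the distances (a
        # median split would drown the peripheral shell in central mass
        # whenever the central state dominates occupancy)
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=4, random_state=seed).fit(
            dist[:, None]
        )
        inner = int(np.argmin(km.cluster_centers_.ravel()))
        central_pts = X[km.labels_ == inner]
        periph_pts = X[km.labels_ != inner]
        n_c, n_p = self.n_components
        if len(central_pts) < n_c or len(periph_pts) < n_p:
            central_pts = X[dist <= np.median(dist)]
            periph_pts = X[dist > np.median(dist)]
        central = _kmeans_mixture(central_pts, n_c, int(rng.integers(2**31 - 1)))
        periph = _kmeans_mixture(periph_pts, n_p, int(rng.integers(2**31 - 1)))
        # weights / transitions / start probabilities: random init
        for gm in (central, periph):
            w = rng.dirichlet(np.full(gm.n_components, 5.0))
            gm.weights = w
        A = rng.dirichlet((8.0, 2.0), size=2)
        A[1] = A[1][::-1]  # make both states sticky on average
        p = rng.dirichlet((1.0, 1.0))
        return GazeHMM(emissions=(central, periph), transmat=A, startprob=p)

    def fit(
        self,
        seed: int = 0,
        init: GazeHMM | None = None,
        tol: float = 1e-5,
        max_iter: int = 500,
    ) -> "ScanpathHMMResults":
        """Baum-Welch fit; returns a results object."""
        init = init or self._initial_model(seed)
        fitted, info = _hmm.train_hmm(
            self.observations, init, seed=seed, tol=tol, max_iter=max_iter
        )
        fitted = self._canonicalize(fitted)
        return ScanpathHMMResults(self, fitted, info)

    def _canonicalize(self, hmm: GazeHMM) -> GazeHMM:
        """Order states so index 0 is the central state (emission means
        closest, on weighted average, to the data centroid)."""
        center = self.observations.mean(axis=0)
        spread = [
            float(gm.weights @ np.linalg.norm(gm.means - center, axis=1))
            for gm in hmm.emissions
        ]
        if spread[0] <= spread[1]:
            return hmm
        perm = [1, 0]
        return GazeHMM(
            emissions=tuple(hmm.emissions[i] for i in perm),
            transmat=hmm.transmat[np.ix_(perm, perm)],
            startprob=hmm.startprob[perm],
        )


class ScanpathHMMResults:
    """Fitted scanpath HMM: parameters, diagnostics, derived statistics."""

    def __init__(self, model: ScanpathHMM, params: GazeHMM, fit_info):
        self.model = model
        self.params = params
        self.fit_info = fit_info

    # -- derived quantities -------------------------------------------------

    @property
    def transmat(self) -> np.ndarray:
        return self.params.transmat

    @property
    def stationary_distribution(self) -> np.ndarray:
        return _hmm.steady_state(self.params.transmat)

    @property
    def transition_entropy(self) -> float:
        """Gaze transition entropy of the fitted chain, in bits."""
        return _hmm.transition_entropy(self.transmat, self.stationary_distribution)

    @property
    def log_likelihood(self) -> float:
        return self.fit_info.log_likelihood

    def reestimate_transitions(self, segment) -> np.ndarray:
        """Transition matrix re-estimated on a data segment with emissions
        and initial state probabilities frozen."""
        return _hmm.reestimate_transitions(self.params, np.asarray(segment, float))

    def window_entropy(self, segment) -> float:
        """Transition entropy of a window: frozen-emission re-estimation of
        the transition matrix on the segment, then stationary-weighted
        entropy."""
        A = self.reestimate_transitions(segment)
        return _hmm.transition_entropy(A, _hmm.steady_state(A))

    # -- simulation / heatmaps ---------------------------------------------

    def simulate(self, n: int, seed: int | None = None):
        """Ancestral sampling of ``n`` observations from the fitted model."""
        return _hmm.generate_from_hmm(self.params, n, seed=seed)

    def generated_heatmap(self, n: int = 20000, sigma: float = 10.0,
                          seed: int | None = None) -> HeatMap:
        """Heatmap of a model-generated scanpath (for comparison with the
        measured heatmap via :func:`gazephysio.hmm.heatmap_kl`)."""
        pts, _ = self.simulate(n, seed=seed)
        w, h = self.model.image_dims
        pts = np.clip(pts, [0, 0], [w - 1e-6, h - 1e-6])
        traj = GazeTrajectory(
            t=np.arange(len(pts), dtype=float),
            xy=pts,
            valid=np.ones(len(pts), dtype=bool),
            image_dims=(w, h),
        )
        return compute_heatmap(traj, sigma=sigma)

    def kl_from(self, measured: HeatMap, n: int = 20000,
                seed: int | None = None) -> float:
        """KL(measured || generated) in bits."""
        return _hmm.heatmap_kl(
            measured, self.generated_heatmap(n=n, sigma=measured.sigma, seed=seed)
        )

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        A = self.transmat
        pi = self.stationary_distribution
        lines = [
            "Two-state scanpath HMM",
            "=" * 54,
            f"observations:        {len(self.model.observations)}",
            f"components (C, P):   {self.model.n_components}",
            f"log-likelihood:      {self.log_likelihood:.3f}",
            f"EM iterations:       {self.fit_info.n_iter}"
            f" (converged: {self.fit_info.converged})",
            "-" * 54,
            "transition matrix A (rows: from central, peripheral):",
            f"  [{A[0, 0]:.4f}  {A[0, 1]:.4f}]",
            f"  [{A[1, 0]:.4f}  {A[1, 1]:.4f}]",
            f"stationary distribution pi: [{pi[0]:.4f}  {pi[1]:.4f}]",
            f"transition entropy:  {self.transition_entropy:.4f} bits",
            "=" * 54,
        ]
        return "\n".join(lines)

    def plot_heatmap(self, heatmap: HeatMap | None = None, ax=None):
        """Render a heatmap (measured or model-generated) as an image."""
        import matplotlib.pyplot as plt

        hm = heatmap or self.generated_heatmap()
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(hm.grid, origin="upper", cmap="jet")
        ax.set_xlabel("x (px)")
        ax.set_ylabel("y (px)")
        ax.figure.colorbar(im, ax=ax, label="gaze mass")
        return ax
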