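"""Core in-memory containers shared across the package.

Coordinates follow the image convention: 0-based pixel indices, origin at the
top-left corner, x rightward, y downward.  Heatmap grids are indexed
``grid[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaussianMixture2D",
    "GazeHMM",
    "GazeTrajectory",
    "HeatMap",
    "Fixation",
    "Saccade",
    "FixationSequence",
    "PhysioRecord",
]

_WEIGHT_TOL = 1e-9


@dataclass
class GaussianMixture2D:
    """A 2-D Gaussian mixture: weights ``c_m``, means ``m_m`` (px) and full
    covariances ``Sigma_m`` (px^2)."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, 2)
    covariances: np.ndarray  # (K, 2, 2)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.means.shape != (self.n_components, 2):
            raise ValueError("means must have shape (K, 2)")
        if self.covariances.shape != (self.n_components, 2, 2):
            raise ValueError("covariances must have shape (K, 2, 2)")
        self.validate()

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def validate(self) -> None:
        if np.any(self.weights < -_WEIGHT_TOL):
            raise ValueError("mixture weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                f"mixture weights must sum to 1 (got {self.weights.sum()!r})"
            )
        for k, cov in enumerate(self.covariances):
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValueError(f"covariance {k} is not symmetric")
            eigvals = np.linalg.eigvalsh(cov)
            if eigvals.min() <= 0:
                raise ValueError(
                    f"covariance {k} is not positive definite "
                    f"(min eigenvalue {eigvals.min():.3g})"
                )

    def component_logpdf(self, x: np.ndarray) -> np.ndarray:
        """Per-component log density, shape ``(n, K)``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        diff = x[:, None, :] - self.means[None, :, :]  # (n, K, 2)
        inv = np.linalg.inv(self.covariances)
        maha = np.einsum("nki,kij,nkj->nk", diff, inv, diff)
        _, logdet = np.linalg.slogdet(self.covariances)
        return -np.log(2.0 * np.pi) - 0.5 * logdet[None, :] - 0.5 * maha

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        """Mixture log density, shape ``(n,)``."""
        comp = self.component_logpdf(x)
        with np.errstate(divide="ignore"):
            logw = np.where(self.weights > 0, np.log(self.weights), -np.inf)
        from scipy.special import logsumexp

        return logsumexp(comp + logw, axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comps = rng.choice(self.n_components, size=n, p=self.weights)
        out = np.empty((n, 2))
        for k in range(self.n_components):
            mask = comps == k
            m = int(mask.sum())
            if m:
                out[mask] = rng.multivariate_normal(
                    self.means[k], self.covariances[k], size=m
                )
        return out

    def copy(self) -> "GaussianMixture2D":
        return GaussianMixture2D(
            self.weights.copy(), self.means.copy(), self.covariances.copy()
        )


@dataclass
class GazeHMM:
    """Two-state scanpath model: a central and a peripheral state, each with a
    GMM emission density, joined by a row-stochastic transition matrix.

    Attributes
    ----------
    emissions : tuple of GaussianMixture2D
        One mixture per state; index 0 is the central state by convention.
    transmat : (2, 2) ndarray
        ``a_ij = p(s_t = j | s_{t-1} = i)``; rows sum to 1.
    startprob : (2,) ndarray
        Initial state probabilities ``p_i``.
    """

    emissions: tuple
    transmat: np.ndarray
    startprob: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.emissions = tuple(self.emissions)
        self.transmat = np.asarray(self.transmat, dtype=float)
        if self.startprob is None:
            self.startprob = np.full(self.n_states, 1.0 / self.n_states)
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.emissions)

    def validate(self) -> None:
        n = self.n_states
        if n != 2:
            raise ValueError("GazeHMM supports exactly 2 states")
        if self.transmat.shape != (n, n):
            raise ValueError("transmat must be 2x2")
        if np.any(self.transmat < -_WEIGHT_TOL):
            raise ValueError("transition probabilities must be nonnegative")
        rows = self.transmat.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=_WEIGHT_TOL):
            raise ValueError(f"rows of transmat must sum to 1 (got {rows})")
        if abs(self.startprob.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError("startprob must sum to 1")

    @property
    def stationary(self) -> np.ndarray:
        from .hmm import steady_state

        return steady_state(self.transmat)

    def copy(self) -> "GazeHMM":
        return GazeHMM(
            tuple(e.copy() for e in self.emissions),
            self.transmat.copy(),
            self.startprob.copy(),
        )


@dataclass
class GazeTrajectory:
    """Timestamped 2-D gaze samples in scene-image pixel coordinates."""

    t: np.ndarray  # (n,) seconds, strictly increasing
    xy: np.ndarray  # (n, 2) pixels
    valid: np.ndarray  # (n,) bool
    image_dims: tuple  # (width, height) pixels

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.xy) == len(self.valid)):
            raise ValueError("t, xy and valid must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            bad = int(np.argmax(np.diff(self.t) <= 0))
            raise ValueError(f"timestamps must be strictly increasing (row {bad + 1})")
        w, h = self.image_dims
        v = self.xy[self.valid]
        if v.size and (
            v[:, 0].min() < 0
            or v[:, 0].max() >= w
            or v[:, 1].min() < 0
            or v[:, 1].max() >= h
        ):
            raise ValueError("valid samples must lie within the image frame")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_samples(self) -> tuple:
        """(t, xy) restricted to valid samples."""
        return self.t[self.valid], self.xy[self.valid]


@dataclass
class HeatMap:
    """Normalized probability mass over the scene-image pixel grid
    (``grid[y, x]``)."""

    grid: np.ndarray  # (height, width), nonnegative, sums to 1
    sigma: float  # kernel SD in pixels

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("heatmap grid must be 2-D")
        if np.any(self.grid < 0):
            raise ValueError("heatmap mass must be nonnegative")

    @property
    def image_dims(self) -> tuple:
        h, w = self.grid.shape
        return (w, h)

    def is_normalized(self, tol: float = 1e-9) -> bool:
        return abs(float(self.grid.sum()) - 1.0) <= tol


@dataclass
class Fixation:
    start: float  # s
    end: float  # s
    centroid: np.ndarray  # (2,) px

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0


@dataclass
class Saccade:
    onset: float  # s
    amplitude: float  # px


@dataclass
class FixationSequence:
    """Time-ordered fixations and the saccades linking them."""

    fixations: list
    saccades: list

    def __post_init__(self) -> None:
        for a, b in zip(self.fixations, self.fixations[1:]):
            if b.start < a.end:
                raise ValueError("fixations must be non-overlapping and ordered")
        if any(s.amplitude < 0 for s in self.saccades):
            raise ValueError("saccade amplitudes must be nonnegative")


_CHANNELS = ("ECG", "GSR", "BVP")


@dataclass
class PhysioRecord:
    """Uniformly sampled physiological channel (mV for ECG, uS for GSR)."""

    values: np.ndarray
    rate: float  # Hz
    channel: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {_CHANNELS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("channel values must be finite")

    @property
    def duration(self) -> float:
        return len(self.values) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate
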