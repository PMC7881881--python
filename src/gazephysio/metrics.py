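"""Per-trajectory gaze descriptors.

Four descriptors are computed from a gaze trajectory:

* the gaze heatmap — each valid sample contributes an isotropic Gaussian
  kernel (default SD 10 px) on the pixel grid, normalized to unit mass;
* spatial entropy — the Shannon entropy of that heatmap in bits, an index of
  how spatially distributed viewing was;
* fixation/saccade segmentation by a two-state velocity HMM decoded with the
  Viterbi path (the I-HMM approach);
* mean fixation duration (focus) and mean saccade amplitude (spatial
  exploration).
"""

from __future__ import annotations

import numpy as np

from .types import Fixation, FixationSequence, GazeTrajectory, HeatMap, Saccade

__all__ = [
    "compute_heatmap",
    "spatial_entropy",
    "segment_fixations",
    "gaze_summary",
]

DEFAULT_SIGMA = 10.0  # px
KERNEL_TRUNCATION = 4.0  # kernels truncated at +-4 sigma
MIN_FIXATION_MS = 100.0
MAX_BRIDGE_GAP_MS = 75.0  # a fixation cannot bridge an invalid run longer than this
MIN_REFIXATION_SHIFT_PX = 12.0  # smallest centroid shift treated as a new fixation


def compute_heatmap(traj: GazeTrajectory, sigma: float = DEFAULT_SIGMA) -> HeatMap:
    """Kernel-density gaze heatmap over the pixel grid.

    Each valid sample adds an isotropic Gaussian of SD ``sigma`` centered at
    the sample; the accumulated mass is normalized to 1.  Kernels are
    truncated at +-4 sigma (the omitted tail mass is ~1e-4 of a kernel and
    removed by the final normalization).  Invalid samples are ignored.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    w, h = traj.image_dims
    _, xy = traj.valid_samples()
    if len(xy) == 0:
        raise ValueError("heatmap requires at least one valid sample")

    grid = np.zeros((int(h), int(w)))
    r = int(np.ceil(KERNEL_TRUNCATION * sigma))
    offsets = np.arange(-r, r + 1)
    for x, y in xy:
        xi = int(round(x))
        yi = int(round(y))
        # kernel evaluated at pixel centers, at the exact (sub-pixel) sample
        kx = np.exp(-((offsets + xi - x) ** 2) / (2 * sigma**2))
        ky = np.exp(-((offsets + yi - y) ** 2) / (2 * sigma**2))
        x0, x1 = max(xi - r, 0), min(xi + r + 1, int(w))
        y0, y1 = max(yi - r, 0), min(yi + r + 1, int(h))
        grid[y0:y1, x0:x1] += np.outer(
            ky[y0 - (yi - r) : y1 - (yi - r)], kx[x0 - (xi - r) : x1 - (xi - r)]
        )
    grid /= grid.sum()
    return HeatMap(grid=grid, sigma=float(sigma))


def spatial_entropy(hm: HeatMap) -> float:
    """Shannon entropy of a normalized heatmap, in bits.

    Uses the ``0*log 0 = 0`` convention; the result lies in
    ``[0, log2(width*height)]``.
    """
    if not hm.is_normalized():
        raise ValueError("heatmap must be normalized to unit mass")
    p = hm.grid.ravel()
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


# ---------------------------------------------------------------------------
# Fixation / saccade segmentation
# ---------------------------------------------------------------------------

def _velocity_viterbi(speeds: np.ndarray, fix_scale: float, sac_scale: float,
                      stay_fix: float = 0.95, stay_sac: float = 0.5) -> np.ndarray:
    """Viterbi decoding of a two-state (fixation=0, saccade=1) HMM on sample
    speeds, with half-normal emission densities.

    The fixation state has a small speed scale, the saccade state a large
    one.  Transitions are asymmetric: the fixation state is sticky, the
    saccade state is not — at 60 Hz a saccade occupies only one or two
    inter-sample segments, so a sticky saccade state would over-penalize
    legitimate single-segment jumps.
    """
    with np.errstate(divide="ignore"):
        logb = np.stack(
            [
                -0.5 * (speeds / fix_scale) ** 2 - np.log(fix_scale),
                -0.5 * (speeds / sac_scale) ** 2 - np.log(sac_scale),
            ],
            axis=1,
        )
    log_A = np.log(
        np.array([[stay_fix, 1 - stay_fix], [1 - stay_sac, stay_sac]])
    )
    log_pi = np.log(np.array([0.5, 0.5]))

    n = len(speeds)
    delta = np.empty((n, 2))
    psi = np.zeros((n, 2), dtype=int)
    delta[0] = log_pi + logb[0]
    for t in range(1, n):
        cand = delta[t - 1][:, None] + log_A
        psi[t] = np.argmax(cand, axis=0)
        delta[t] = cand[psi[t], [0, 1]] + logb[t]
    states = np.empty(n, dtype=int)
    states[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return states


def _split_refixations(xy, a, b, min_side=3,
                       shift_px=MIN_REFIXATION_SHIFT_PX):
    """Recursively split a candidate fixation run [a, b] (inclusive sample
    indices) at the point maximizing the distance between the left and right
    sub-centroids, when that distance exceeds ``shift_px``.

    Small re-fixations move the eye by less than the single-sample velocity
    test can resolve against jitter; averaging the samples on each side of a
    candidate change point recovers them with far better signal-to-noise.
    """
    n = b - a + 1
    if n < 2 * min_side:
        return [(a, b)]
    pts = xy[a : b + 1]
    cum = np.cumsum(pts, axis=0)
    ks = np.arange(min_side, n - min_side + 1)
    left = cum[ks - 1] / ks[:, None]
    right = (cum[-1] - cum[ks - 1]) / (n - ks)[:, None]
    d = np.linalg.norm(left - right, axis=1)
    j = int(np.argmax(d))
    if d[j] <= shift_px:
        return [(a, b)]
    split = a + int(ks[j])  # first sample of the right part
    return _split_refixations(xy, a, split - 1, min_side, shift_px) + \
        _split_refixations(xy, split, b, min_side, shift_px)


def segment_fixations(
    traj: GazeTrajectory,
    min_fixation_ms: float = MIN_FIXATION_MS,
    max_gap_ms: float = MAX_BRIDGE_GAP_MS,
) -> FixationSequence:
    """Separate a gaze trajectory into fixations and saccades.

    Speeds between adjacent valid samples are decoded by a two-state velocity
    HMM (Viterbi path); runs of fixation-labeled samples become fixations,
    each inter-fixation jump one saccade whose amplitude is the Euclidean
    distance between adjacent fixation centroids.  Fixations shorter than
    ``min_fixation_ms`` are discarded, and a fixation never bridges an
    invalid run longer than ``max_gap_ms``.
    """
    t_all = traj.t
    valid = traj.valid
    idx = np.flatnonzero(valid)
    if len(idx) < 2:
        raise ValueError("segmentation requires at least 2 valid samples")
    t = t_all[idx]
    xy = traj.xy[idx]

    dt = np.diff(t)
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    speeds = disp / dt  # px/s between consecutive valid samples

    # emission scales set adaptively: fixation scale from the lower half of
    # the speed distribution, saccade scale well above it
    fix_scale = max(float(np.percentile(speeds, 50)) * 1.5, 1e-3)
    sac_scale = max(float(np.percentile(speeds, 99)), 8 * fix_scale)
    move_states = _velocity_viterbi(speeds, fix_scale, sac_scale)

    # sample-level fixation labels: sample is in a fixation if an adjacent
    # inter-sample segment is fixation-labeled
    fix_sample = np.zeros(len(idx), dtype=bool)
    fix_sample[:-1] |= move_states == 0
    fix_sample[1:] |= move_states == 0

    # break fixation runs across long invalid gaps and across saccade
    # segments; a short bridged gap still breaks the run when gaze re-appears
    # somewhere else (a blink that hid a saccade)
    gap = dt * 1000.0 > max_gap_ms
    sample_gap = np.diff(idx) > 1
    displaced = disp > 30.0  # px: beyond within-fixation jitter
    breaks = (move_states == 1) | gap | (sample_gap & displaced)

    fixations = []
    run_start = 0
    for k in range(len(idx)):
        is_last = k == len(idx) - 1
        broken = (not is_last) and breaks[k]
        if is_last or broken:
            end = k
            if fix_sample[run_start] and end > run_start:
                for a, b in _split_refixations(xy, run_start, end):
                    dur_ms = (t[b] - t[a]) * 1000.0
                    if dur_ms >= min_fixation_ms:
                        fixations.append(
                            Fixation(
                                start=float(t[a]),
                                end=float(t[b]),
                                centroid=xy[a : b + 1].mean(axis=0),
                            )
                        )
            run_start = k + 1
    saccades = [
        Saccade(
            onset=float(a.end),
            amplitude=float(np.linalg.norm(b.centroid - a.centroid)),
        )
        for a, b in zip(fixations, fixations[1:])
    ]
    return FixationSequence(fixations=fixations, saccades=saccades)


def gaze_summary(fs: FixationSequence):
    """Mean fixation duration (ms) and mean saccade amplitude (px)."""
    if not fs.fixations:
        raise ValueError("no fixations to summarize")
    mean_dur = float(np.mean([f.duration_ms for f in fs.fixations]))
    mean_amp = (
        float(np.mean([s.amplitude for s in fs.saccades])) if fs.saccades else np.nan
    )
    return mean_dur, mean_amp
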