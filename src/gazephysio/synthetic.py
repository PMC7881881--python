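"""Synthetic gaze + physiology sessions and cohorts with known ground truth.

The generator emulates the study conditions downstream stages are built for:
a 3-minute baseline followed by a 15-minute free-viewing period, gaze sampled
at 60 Hz by a scene camera (960x720 px), ECG at 2048 Hz, GSR at 256 Hz, and
~20% of gaze samples lost to blinks and look-aways.  Gaze dynamics follow a
two-state (central/peripheral) scanpath HMM at fixation granularity: a new
emission draw per fixation, isotropic jitter within fixations, instantaneous
jumps between them.  Every generated quantity is returned as ground truth so
recovery tests need no external data.

Cohorts are generated at the per-window metrics level (fixation-granularity
Markov chains per three-minute window, physiology deltas as calibrated
noise) with a controllable coupling between transition entropy and ΔHR, so
the pooled Pearson correlation has a known design value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import steady_state, transition_entropy
from .types import GaussianMixture2D, GazeHMM, GazeTrajectory, PhysioRecord

__all__ = [
    "SessionConfig",
    "GroundTruth",
    "Session",
    "default_scene_hmm",
    "simulate_gaze",
    "simulate_ecg",
    "simulate_gsr",
    "simulate_session",
    "simulate_cohort",
    "CohortTruth",
]

FIXATION_JITTER_SD = 3.0  # px, within-fixation dispersion
FIXATION_GAMMA_SHAPE = 4.0  # gamma shape for fixation durations
BLINK_MEAN_MS = 200.0  # mean contiguous dropout run
DEFAULT_FIXATION_MS = 350.0


@dataclass
class SessionConfig:
    """Recording geometry, rates and session timing."""

    image_width: int = 960
    image_height: int = 720
    gaze_rate: float = 60.0
    ecg_rate: float = 2048.0
    gsr_rate: float = 256.0
    baseline_duration: float = 180.0
    viewing_duration: float = 900.0
    dropout_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.gaze_rate, self.ecg_rate, self.gsr_rate) <= 0:
            raise ValueError("all sampling rates must be positive")
        if min(self.baseline_duration, self.viewing_duration) <= 0:
            raise ValueError("durations must be positive")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")

    @property
    def image_dims(self) -> tuple:
        return (self.image_width, self.image_height)


@dataclass
class GroundTruth:
    """Everything the generator knows, for recovery tests."""

    hmm: GazeHMM = None
    fixation_intervals: list = field(default_factory=list)  # (start, end) s
    fixation_states: np.ndarray = None
    fixation_centroids: np.ndarray = None
    mean_rr: float = float("nan")  # ms
    rmssd_true: float = float("nan")  # ms
    scl_level: float = float("nan")  # uS
    beat_times: np.ndarray = None  # s
    coupling_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.beat_times is not None:
            bt = np.asarray(self.beat_times, dtype=float)
            if len(bt) > 1 and np.any(np.diff(bt) <= 0):
                raise ValueError("beat_times must be strictly increasing")
        if np.isfinite(self.rmssd_true) and self.rmssd_true < 0:
            raise ValueError("rmssd_true must be nonnegative")


@dataclass
class Session:
    gaze: GazeTrajectory
    ecg: PhysioRecord
    gsr: PhysioRecord
    truth: GroundTruth
    config: SessionConfig
    scene: str


# ---------------------------------------------------------------------------
# Scene models
# ---------------------------------------------------------------------------

# default component counts per state (central, peripheral) per scene
SCENE_COMPONENTS = {"courtyard": (4, 9), "garden": (3, 12)}


def default_scene_hmm(
    config: SessionConfig,
    scene: str = "courtyard",
    transmat: np.ndarray | None = None,
    seed: int = 0,
) -> GazeHMM:
    """A plausible two-state scanpath model for a scene.

    The central state's components sit near the image center; the peripheral
    state's components ring the image margin.  The garden-like scene gets a
    stickier (lower-entropy) chain than the courtyard-like scene by default.
    """
    if scene not in SCENE_COMPONENTS:
        raise ValueError(f"unknown scene {scene!r}")
    rng = np.random.default_rng(seed)
    w, h = config.image_dims
    cx, cy = w / 2.0, h / 2.0
    n_central, n_periph = SCENE_COMPONENTS[scene]

    ang = np.linspace(0, 2 * np.pi, n_central, endpoint=False)
    central_means = np.column_stack(
        [cx + 0.08 * w * np.cos(ang), cy + 0.08 * h * np.sin(ang)]
    )
    central = GaussianMixture2D(
        weights=np.full(n_central, 1.0 / n_central),
        means=central_means,
        covariances=np.tile(np.diag([40.0**2, 35.0**2]), (n_central, 1, 1)),
    )
    ang = rng.permutation(np.linspace(0, 2 * np.pi, n_periph, endpoint=False))
    periph_means = np.column_stack(
        [cx + 0.38 * w * np.cos(ang), cy + 0.38 * h * np.sin(ang)]
    )
    periph = GaussianMixture2D(
        weights=np.full(n_periph, 1.0 / n_periph),
        means=periph_means,
        covariances=np.tile(np.diag([55.0**2, 45.0**2]), (n_periph, 1, 1)),
    )
    if transmat is None:
        transmat = (
            np.array([[0.80, 0.20], [0.35, 0.65]])
            if scene == "courtyard"
            else np.array([[0.90, 0.10], [0.20, 0.80]])
        )
    return GazeHMM(
        emissions=(central, periph),
        transmat=np.asarray(transmat, dtype=float),
        startprob=steady_state(np.asarray(transmat, dtype=float)),
    )


# ---------------------------------------------------------------------------
# Gaze simulation
# ---------------------------------------------------------------------------

def _blink_mask(n: int, rate: float, dropout: float, rng) -> np.ndarray:
    """Invalid-sample mask built from alternating valid gaps and blink-like
    runs (gamma-distributed lengths, blink mean 200 ms)."""
    invalid = np.zeros(n, dtype=bool)
    if dropout <= 0:
        return invalid
    blink_mean = BLINK_MEAN_MS / 1000.0 * rate  # samples
    gap_mean = blink_mean * (1.0 - dropout) / dropout
    shape = FIXATION_GAMMA_SHAPE
    pos = rng.gamma(shape, gap_mean / shape)  # start inside a valid gap
    while pos < n:
        blen = max(rng.gamma(shape, blink_mean / shape), 1.0)
        i0, i1 = int(round(pos)), min(int(round(pos + blen)), n)
        invalid[i0:i1] = True
        pos += blen + max(rng.gamma(shape, gap_mean / shape), 1.0)
    return invalid


def simulate_gaze(
    hmm: GazeHMM,
    config: SessionConfig,
    fixation_duration_mean: float = DEFAULT_FIXATION_MS,
    seed: int | None = None,
    duration: float | None = None,
):
    """Generate a gaze trajectory from a scanpath HMM at fixation granularity.

    A state path is drawn from the chain, one fixation per step; fixation
    durations are gamma with the given mean (ms); the fixation centroid is a
    draw from the state's emission GMM; samples within a fixation get
    isotropic Gaussian jitter (SD 3 px); the jump between fixations is
    instantaneous (one-sample transition).  ``dropout_fraction`` of samples
    are flagged invalid in contiguous blink-like runs.

    Returns
    -------
    (GazeTrajectory, GroundTruth)
    """
    w, h = config.image_dims
    for i, gm in enumerate(hmm.emissions):
        if (
            gm.means[:, 0].min() < 0
            or gm.means[:, 0].max() >= w
            or gm.means[:, 1].min() < 0
            or gm.means[:, 1].max() >= h
        ):
            raise ValueError(f"emission components of state {i} lie outside the image")

    rng = np.random.default_rng(seed)
    duration = config.viewing_duration if duration is None else float(duration)
    mean_s = fixation_duration_mean / 1000.0
    shape = FIXATION_GAMMA_SHAPE

    # fixation-level state path and timing
    starts, ends, states, centroids = [], [], [], []
    t = 0.0
    s = int(rng.choice(hmm.n_states, p=hmm.startprob))
    while t < duration:
        dur = rng.gamma(shape, mean_s / shape)
        dur = max(dur, 2.0 / config.gaze_rate)
        c = hmm.emissions[s].sample(1, rng)[0]
        for _ in range(100):
            if 0 <= c[0] < w and 0 <= c[1] < h:
                break
            c = hmm.emissions[s].sample(1, rng)[0]
        else:
            c = np.clip(c, [0, 0], [w - 1e-6, h - 1e-6])
        starts.append(t)
        ends.append(min(t + dur, duration))
        states.append(s)
        centroids.append(c)
        t += dur
        s = int(rng.choice(hmm.n_states, p=hmm.transmat[s]))

    centroids = np.asarray(centroids)
    states = np.asarray(states, dtype=int)

    # sample grid
    n = int(round(duration * config.gaze_rate))
    tt = np.arange(n) / config.gaze_rate
    fix_idx = np.searchsorted(np.asarray(starts), tt, side="right") - 1
    xy = centroids[fix_idx] + rng.normal(0.0, FIXATION_JITTER_SD, size=(n, 2))
    xy[:, 0] = np.clip(xy[:, 0], 0, w - 1e-6)
    xy[:, 1] = np.clip(xy[:, 1], 0, h - 1e-6)

    invalid = _blink_mask(n, config.gaze_rate, config.dropout_fraction, rng)
    traj = GazeTrajectory(t=tt, xy=xy, valid=~invalid, image_dims=(w, h))
    truth = GroundTruth(
        hmm=hmm.copy(),
        fixation_intervals=list(zip(starts, ends)),
        fixation_states=states,
        fixation_centroids=centroids,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Physiological channels
# ---------------------------------------------------------------------------

# PQRST wave template: (offset s, amplitude mV, width s)
_PQRST = (
    (-0.20, 0.12, 0.025),
    (-0.030, -0.15, 0.010),
    (0.0, 1.00, 0.012),
    (0.030, -0.25, 0.010),
    (0.25, 0.30, 0.045),
)


def simulate_ecg(
    mean_rr: float,
    rmssd_target: float,
    duration: float,
    rate: float = 2048.0,
    seed: int | None = None,
):
    """Synthetic ECG: a PQRST template (sum of Gaussians) at each beat.

    RR intervals are ``mean_rr`` (ms) plus zero-mean Gaussian perturbations
    rescaled so the realized RMSSD of the generated RR series equals
    ``rmssd_target`` (ms).  Returns the record and the exact beat times.
    """
    if rate < 100:
        raise ValueError("rate too low to resolve QRS (< 100 Hz)")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rmssd_target < 0:
        raise ValueError("rmssd_target must be nonnegative")
    if mean_rr <= 2 * rmssd_target:
        raise ValueError("mean_rr must exceed 2 * rmssd_target")

    rng = np.random.default_rng(seed)
    n_beats = int(np.ceil(duration * 1000.0 / mean_rr)) + 2
    if rmssd_target == 0 or n_beats < 3:
        rr = np.full(n_beats, mean_rr)
    else:
        e = rng.normal(0.0, rmssd_target / np.sqrt(2.0), size=n_beats)
        d = np.diff(e)
        realized = np.sqrt(np.mean(d**2))
        e *= rmssd_target / realized  # exact-RMSSD rescale
        rr = mean_rr + e
        rr = np.clip(rr, 0.3 * mean_rr, None)

    beat_times = 0.4 + np.cumsum(rr) / 1000.0
    beat_times = beat_times[beat_times < duration - 0.05]

    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    for b in beat_times:
        for off, amp, width in _PQRST:
            lo = max(int((b + off - 5 * width) * rate), 0)
            hi = min(int((b + off + 5 * width) * rate) + 1, n)
            if hi > lo:
                x[lo:hi] += amp * np.exp(
                    -((t[lo:hi] - b - off) ** 2) / (2 * width**2)
                )
    rec = PhysioRecord(values=x, rate=rate, channel="ECG")
    return rec, beat_times


def simulate_gsr(
    scl_level: float,
    drift_slope: float = 0.0,
    duration: float = 180.0,
    rate: float = 256.0,
    seed: int | None = None,
    noise_sd: float = 0.02,
) -> PhysioRecord:
    """Tonic skin conductance: level (uS) + linear drift (uS/min) + noise."""
    if scl_level < 0:
        raise ValueError("scl_level must be nonnegative")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = scl_level + drift_slope * t / 60.0
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)
    return PhysioRecord(values=x, rate=rate, channel="GSR")


def simulate_session(
    config: SessionConfig | None = None,
    scene: str = "courtyard",
    hmm: GazeHMM | None = None,
    mean_rr: float = 800.0,
    rmssd_target: float = 35.0,
    scl_level: float = 5.0,
    scl_drift: float = 0.05,
    seed: int | None = None,
) -> Session:
    """A full synchronized session: baseline + viewing, all three channels.

    Gaze covers the viewing period (t=0 at curtain opening); ECG and GSR
    cover baseline + viewing with t=0 at the start of the baseline.
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(seed)
    s_gaze, s_ecg, s_gsr = rng.integers(0, 2**31 - 1, size=3)
    hmm = hmm or default_scene_hmm(config, scene, seed=int(s_gaze))
    total = config.baseline_duration + config.viewing_duration
    gaze, truth = simulate_gaze(hmm, config, seed=int(s_gaze))
    ecg, beats = simulate_ecg(
        mean_rr, rmssd_target, total, config.ecg_rate, seed=int(s_ecg)
    )
    gsr = simulate_gsr(
        scl_level, scl_drift, total, config.gsr_rate, seed=int(s_gsr)
    )
    truth.mean_rr = mean_rr
    truth.rmssd_true = rmssd_target
    truth.scl_level = scl_level
    truth.beat_times = beats
    return Session(gaze=gaze, ecg=ecg, gsr=gsr, truth=truth, config=config, scene=scene)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Design values of a generated cohort."""

    coupling_slope: float
    expected_r: float
    base_transmats: dict
    effect_sizes: dict
    entropy_sd: float
    hr_noise_sd: float


def _chain_entropies(transmats: np.ndarray, n_fix: int, rng) -> np.ndarray:
    """Empirical transition entropy of one simulated fixation-granularity
    chain per row.

    ``transmats`` has shape (n, 2, 2).  Each chain runs ``n_fix`` steps from
    its stationary distribution; the entropy is computed from the empirical
    transition matrix (rows with no visits fall back to the design row).
    """
    A = np.asarray(transmats, dtype=float)
    n = A.shape[0]
    a12, a21 = A[:, 0, 1], A[:, 1, 0]
    pi1 = np.where(a12 + a21 > 0, a21 / (a12 + a21), 0.5)
    s = (rng.random(n) >= pi1).astype(np.int8)  # 0=central, 1=peripheral
    counts = np.zeros((n, 4), dtype=np.int64)  # n11, n12, n21, n22
    rows = np.arange(n)
    for _ in range(n_fix - 1):
        p_to1 = A[rows, s, 1]
        new = (rng.random(n) < p_to1).astype(np.int8)
        counts[rows, 2 * s + new] += 1
        s = new

    from1 = counts[:, 0] + counts[:, 1]
    from2 = counts[:, 2] + counts[:, 3]
    e12 = np.where(from1 > 0, counts[:, 1] / np.maximum(from1, 1), a12)
    e21 = np.where(from2 > 0, counts[:, 2] / np.maximum(from2, 1), a21)

    def h2(p):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = -p * np.log2(np.where(p > 0, p, 1.0)) - (1 - p) * np.log2(
                np.where(p < 1, 1 - p, 1.0)
            )
        return out

    denom = e12 + e21
    p1 = np.where(denom > 0, e21 / np.where(denom > 0, denom, 1.0), 1.0)
    return p1 * h2(e12) + (1 - p1) * h2(e21)


def simulate_cohort(
    n_subjects: int = 38,
    n_female: int | None = None,
    scenes: tuple = ("courtyard", "garden"),
    modalities: tuple = ("direct",),
    n_windows: int = 5,
    window_duration: float = 180.0,
    fixation_duration_mean: float = DEFAULT_FIXATION_MS,
    effect_sizes: dict | None = None,
    coupling_slope: float | None = None,
    target_r: float | None = None,
    hr_noise_sd: float = 2.5,
    seed: int | None = None,
):
    """Generate a multi-subject cohort of per-window metrics with known
    ground truth.

    Each subject x scene x modality cell contributes ``n_windows``
    three-minute windows.  Per-window transition entropy comes from a
    simulated fixation-granularity Markov chain (per-subject transition
    logits jittered around the scene's base chain), and ΔHR is linked to the
    entropy through ``coupling_slope`` (bpm per bit) plus Gaussian noise —
    so the pooled Pearson correlation has a known design value.  Passing
    ``target_r`` instead calibrates the slope against the realized entropy
    spread to give that population correlation.  ``effect_sizes`` maps a
    metric name to ``{factor: shift}``; the shift is added at the second
    factor level (garden / M / photo).

    Returns
    -------
    (pandas.DataFrame, CohortTruth)
    """
    if target_r is not None and coupling_slope is not None:
        raise ValueError("give either coupling_slope or target_r, not both")
    effect_sizes = effect_sizes or {}
    rng = np.random.default_rng(seed)
    if n_female is None:
        # study proportion: 11 of 38
        n_female = max(int(round(n_subjects * 11 / 38)), 1)
    if not 0 < n_female < n_subjects:
        raise ValueError("n_female must be strictly between 0 and n_subjects")

    base_A = {
        "courtyard": np.array([[0.80, 0.20], [0.35, 0.65]]),
        "garden": np.array([[0.90, 0.10], [0.20, 0.80]]),
    }
    genders = np.array(["F"] * n_female + ["M"] * (n_subjects - n_female))

    rows = []
    transmats = []
    for subj in range(n_subjects):
        # per-subject deviation of the transition logits (stable across
        # scenes/windows: a subject-level scanning style)
        logit_jit = rng.normal(0.0, 0.25, size=2)
        for scene in scenes:
            for modality in modalities:
                A0 = base_A[scene]
                a12 = 1.0 / (1.0 + np.exp(-(np.log(A0[0, 1] / A0[0, 0]) + logit_jit[0])))
                a21 = 1.0 / (1.0 + np.exp(-(np.log(A0[1, 0] / A0[1, 1]) + logit_jit[1])))
                A = np.array([[1 - a12, a12], [a21, 1 - a21]])
                for w in range(n_windows):
                    rows.append(
                        {
                            "subject": subj,
                            "gender": genders[subj],
                            "scene": scene,
                            "modality": modality,
                            "window_index": w + 1,
                        }
                    )
                    transmats.append(A)
    df = pd.DataFrame(rows)
    transmats = np.asarray(transmats)
    n = len(df)

    n_fix = max(int(round(window_duration / (fixation_duration_mean / 1000.0))), 2)
    H = _chain_entropies(transmats, n_fix, rng)
    df["transition_entropy"] = H

    # second-level factor indicators for effect shifts
    lev2 = {
        "scene": (df["scene"] == scenes[-1]).to_numpy(float) if len(scenes) > 1 else np.zeros(n),
        "gender": (df["gender"] == "M").to_numpy(float),
        "modality": (df["modality"] == modalities[-1]).to_numpy(float)
        if len(modalities) > 1
        else np.zeros(n),
    }

    def shifts(metric: str) -> np.ndarray:
        out = np.zeros(n)
        for factor, delta in effect_sizes.get(metric, {}).items():
            out += delta * lev2[factor]
        return out

    # metric noise is iid across rows: pooled windows are treated as
    # independent observations downstream, and the calibration properties
    # (type-I rate, designed pooled r) are stated under that regime
    df["fixation_duration"] = (
        350.0 + rng.normal(0, 50.0, n) + shifts("fixation_duration")
    )
    df["saccade_amplitude"] = np.clip(
        110.0 + rng.normal(0, 30.0, n) + shifts("saccade_amplitude"), 1.0, None
    )
    df["spatial_entropy"] = 16.3 + rng.normal(0, 0.5, n) + shifts("spatial_entropy")
    df["transition_entropy"] += shifts("transition_entropy")
    df["transition_entropy"] = df["transition_entropy"].clip(0.0, 1.0)

    Hc = df["transition_entropy"].to_numpy() - df["transition_entropy"].mean()
    sd_H = float(Hc.std(ddof=1))
    if target_r is not None:
        slope = hr_noise_sd * target_r / (sd_H * np.sqrt(1.0 - target_r**2))
    else:
        slope = float(coupling_slope or 0.0)
    expected_r = slope * sd_H / np.hypot(slope * sd_H, hr_noise_sd)

    df["delta_hr"] = slope * Hc + rng.normal(0, hr_noise_sd, n) + shifts("delta_hr")
    df["delta_rmssd"] = rng.normal(0, 8.0, n) + shifts("delta_rmssd")
    df["delta_scl"] = rng.normal(0, 0.5, n) + shifts("delta_scl")

    truth = CohortTruth(
        coupling_slope=slope,
        expected_r=float(expected_r),
        base_transmats={k: v.copy() for k, v in base_A.items()},
        effect_sizes=effect_sizes,
        entropy_sd=sd_H,
        hr_noise_sd=hr_noise_sd,
    )
    return df, truth
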