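import numpy as np
import pytest

from gazephysio.synthetic import SessionConfig, default_scene_hmm, simulate_gaze
from gazephysio.types import GaussianMixture2D, GazeHMM, GazeTrajectory


@pytest.fixture(scope="session")
def short_config():
    """A 2-minute viewing session: enough fixations to fit the HMM, fast to
    generate."""
    return SessionConfig(viewing_duration=120.0, baseline_duration=30.0)


@pytest.fixture(scope="session")
def courtyard_hmm(short_config):
    return default_scene_hmm(short_config, "courtyard", seed=1)


@pytest.fixture(scope="session")
def short_session(short_config, courtyard_hmm):
    """(trajectory, ground truth) for a 2-minute viewing with default
    dropout."""
    return simulate_gaze(courtyard_hmm, short_config, seed=7)


def make_trajectory(xy, rate=60.0, image_dims=(960, 720), valid=None):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return GazeTrajectory(
        t=np.arange(n) / rate, xy=xy, valid=np.asarray(valid, bool),
        image_dims=image_dims,
    )


def isotropic_mixture(means, sd=30.0, weights=None):
    means = np.asarray(means, dtype=float)
    k = len(means)
    if weights is None:
        weights = np.full(k, 1.0 / k)
    covs = np.tile(np.eye(2) * sd**2, (k, 1, 1))
    return GaussianMixture2D(np.asarray(weights, float), means, covs)


def two_state_hmm(transmat, startprob=None, sd=30.0):
    """Well-separated two-state model on a 960x720 frame."""
    central = isotropic_mixture([[480.0, 360.0], [430.0, 320.0]], sd=sd)
    periph = isotropic_mixture(
        [[120.0, 120.0], [840.0, 120.0], [120.0, 600.0], [840.0, 600.0]], sd=sd
    )
    return GazeHMM(
        emissions=(central, periph),
        transmat=np.asarray(transmat, float),
        startprob=startprob,
    )
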