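"""File formats and pipeline configuration.

Gaze and physiology tables travel as CSV with ``#``-prefixed header
metadata; scanpath models and ground truth as JSON; configuration as YAML.
Every writer stamps the output with the SHA-256 hash of the configuration
that produced it, so runs are traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import GaussianMixture2D, GazeHMM, GazeTrajectory, PhysioRecord

__all__ = [
    "PipelineConfig",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_physio_csv",
    "write_physio_csv",
    "model_to_json",
    "model_from_json",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass
class PipelineConfig:
    """End-to-end settings; the defaults are the study's stated ones:
    heatmap kernel SD 10 px, 180 s windows, per-scene component counts
    (4, 9) and (3, 12)."""

    heatmap_sigma: float = 10.0
    window_length: float = 180.0
    components: dict = field(
        default_factory=lambda: {"courtyard": [4, 9], "garden": [3, 12]}
    )
    gaze_rate: float = 60.0
    ecg_rate: float = 2048.0
    gsr_rate: float = 256.0
    image_width: int = 960
    image_height: int = 720
    baseline_duration: float = 180.0
    viewing_duration: float = 900.0
    dropout_fraction: float = 0.20
    seed: int = 0
    mixture_sweep_factors: tuple = (0.75, 1.0, 1.25)
    ss_type: int = 3
    correlation_mode: str = "pooled"  # or "by_subject"
    holm: bool = False

    def __post_init__(self) -> None:
        self.mixture_sweep_factors = tuple(self.mixture_sweep_factors)

    def sha(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _header_lines(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


# ---------------------------------------------------------------------------
# Gaze CSV
# ---------------------------------------------------------------------------

GAZE_COLUMNS = ["t_s", "x_px", "y_px", "valid"]


def write_gaze_csv(traj: GazeTrajectory, path, config_sha: str = "") -> None:
    w, h = traj.image_dims
    df = pd.DataFrame(
        {
            "t_s": traj.t,
            "x_px": traj.xy[:, 0],
            "y_px": traj.xy[:, 1],
            "valid": traj.valid.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(
            _header_lines(
                {"image_width": w, "image_height": h, "config_sha": config_sha}
            )
        )
        df.to_csv(fh, index=False)


def read_gaze_csv(path) -> GazeTrajectory:
    """Read a gaze table; validates columns and strict time monotonicity,
    reporting the offending row on failure."""
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze CSV {path} missing columns {missing}")
    t = df["t_s"].to_numpy(float)
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(
                f"non-monotonic timestamps in {path} at data row {bad[0] + 1}"
            )
    w = int(meta.get("image_width", int(np.ceil(df["x_px"].max())) + 1))
    h = int(meta.get("image_height", int(np.ceil(df["y_px"].max())) + 1))
    return GazeTrajectory(
        t=t,
        xy=df[["x_px", "y_px"]].to_numpy(float),
        valid=df["valid"].to_numpy().astype(bool),
        image_dims=(w, h),
    )


# ---------------------------------------------------------------------------
# Physio CSV
# ---------------------------------------------------------------------------

def write_physio_csv(rec: PhysioRecord, path, config_sha: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(
            _header_lines(
                {"rate_hz": rec.rate, "channel": rec.channel, "config_sha": config_sha}
            )
        )
        pd.DataFrame({"value": rec.values}).to_csv(fh, index=False)


def read_physio_csv(path) -> PhysioRecord:
    meta = _read_meta(path)
    if "rate_hz" not in meta:
        raise ValueError(f"physio CSV {path} is missing the rate_hz header")
    df = pd.read_csv(path, comment="#")
    if "value" not in df.columns:
        raise ValueError(f"physio CSV {path} missing 'value' column")
    return PhysioRecord(
        values=df["value"].to_numpy(float),
        rate=float(meta["rate_hz"]),
        channel=meta.get("channel", "ECG"),
    )


# ---------------------------------------------------------------------------
# Model / ground-truth JSON
# ---------------------------------------------------------------------------

def model_to_json(hmm: GazeHMM, path=None, config_sha: str = ""):
    doc = {
        "config_sha": config_sha,
        "states": [
            {
                "weights": gm.weights.tolist(),
                "means": gm.means.tolist(),
                "covariances": gm.covariances.tolist(),
            }
            for gm in hmm.emissions
        ],
        "transmat": hmm.transmat.tolist(),
        "startprob": hmm.startprob.tolist(),
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def model_from_json(source) -> GazeHMM:
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text())
    else:
        doc = source
    emissions = tuple(
        GaussianMixture2D(
            np.asarray(s["weights"]),
            np.asarray(s["means"]),
            np.asarray(s["covariances"]),
        )
        for s in doc["states"]
    )
    return GazeHMM(
        emissions=emissions,
        transmat=np.asarray(doc["transmat"]),
        startprob=np.asarray(doc["startprob"]),
    )


def write_ground_truth(truth, path, config_sha: str = "") -> None:
    doc = {
        "config_sha": config_sha,
        "fixation_intervals": [list(map(float, ab)) for ab in truth.fixation_intervals],
        "fixation_states": None
        if truth.fixation_states is None
        else truth.fixation_states.tolist(),
        "mean_rr": truth.mean_rr,
        "rmssd_true": truth.rmssd_true,
        "scl_level": truth.scl_level,
        "beat_times": None if truth.beat_times is None else truth.beat_times.tolist(),
        "coupling_slope": truth.coupling_slope,
        "hmm": None if truth.hmm is None else model_to_json(truth.hmm),
    }
    Path(path).write_text(json.dumps(doc))


def read_ground_truth(path):
    from .synthetic import GroundTruth

    doc = json.loads(Path(path).read_text())
    return GroundTruth(
        hmm=None if doc["hmm"] is None else model_from_json(doc["hmm"]),
        fixation_intervals=[tuple(ab) for ab in doc["fixation_intervals"]],
        fixation_states=None
        if doc["fixation_states"] is None
        else np.asarray(doc["fixation_states"]),
        mean_rr=doc["mean_rr"],
        rmssd_true=doc["rmssd_true"],
        scl_level=doc["scl_level"],
        beat_times=None if doc["beat_times"] is None else np.asarray(doc["beat_times"]),
        coupling_slope=doc["coupling_slope"],
    )
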