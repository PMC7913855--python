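"""Signal conditioning for glove recordings.

The conditioning chain mirrors standard practice for goniometric hand data:
zero-phase low-pass filtering (2nd-order Butterworth, 5 Hz cut-off, applied
forward and backward), trimming of the static lead-in/lead-out the task
protocol produces, time-normalisation of every task to a fixed frame count so
all tasks weigh equally in the subject-level analysis, and per-DoF
z-standardisation so joints with small ranges of motion are not swamped by
large-amplitude joints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .dof import DOF_NAMES, N_DOF
from .errors import (
    DegenerateDoFError,
    NoMotionError,
    ParameterError,
    RecordingTooShortError,
)
from .io import JointAngleRecording

DEFAULT_CUTOFF_HZ = 5.0
DEFAULT_FILTER_ORDER = 2
DEFAULT_VEL_THRESHOLD_DEG_S = 2.0
DEFAULT_MIN_RUN_S = 0.2
DEFAULT_RESAMPLE_FRAMES = 1000


def lowpass_filter(
    rec: JointAngleRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> JointAngleRecording:
    """Zero-phase Butterworth low-pass filter each DoF trace.

    The filter is applied forward and backward (``filtfilt``) so the effective
    magnitude response is the squared Butterworth response and the phase is
    zero. Edges are handled by odd reflection over five cut-off periods on
    each side, long enough for the filter transient to decay below 1e-6 deg
    so the conditioning chain is idempotent on its own output.
    """
    if cutoff_hz <= 0 or rec.sample_rate <= 2 * cutoff_hz:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz requires sample rate > {2 * cutoff_hz} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.sample_rate, output="sos")
    min_frames = 3 * (2 * order + 1)
    if rec.n_frames <= min_frames:
        raise RecordingTooShortError(
            f"recording too short for two-pass filtering: {rec.n_frames} frames "
            f"<= minimum {min_frames}"
        )
    padlen = min(
        int(np.ceil(5.0 * rec.sample_rate / cutoff_hz)), rec.n_frames - 1
    )
    filtered = signal.sosfiltfilt(sos, rec.angles, axis=0, padlen=padlen)
    return rec.with_angles(filtered)


def _static_mask(rec: JointAngleRecording, vel_threshold_deg_s: float) -> np.ndarray:
    """True where every DoF's absolute angular velocity is below threshold."""
    vel = np.gradient(rec.angles, 1.0 / rec.sample_rate, axis=0)
    return np.all(np.abs(vel) < vel_threshold_deg_s, axis=1)


def trim_static(
    rec: JointAngleRecording,
    vel_threshold_deg_s: float = DEFAULT_VEL_THRESHOLD_DEG_S,
    min_run_s: float = DEFAULT_MIN_RUN_S,
) -> JointAngleRecording:
    """Trim static lead-in and lead-out frames.

    A frame is static when every DoF's absolute angular velocity stays below
    ``vel_threshold_deg_s``. The maximal leading and trailing static runs are
    removed, but only if they last at least ``min_run_s`` (shorter pauses are
    kept, to avoid nibbling at genuine movement onsets). Interior frames are
    never touched.

    Raises
    ------
    NoMotionError
        If no frame anywhere in the recording exceeds the velocity threshold.
    """
    if vel_threshold_deg_s <= 0 or min_run_s < 0:
        raise ParameterError("vel_threshold_deg_s must be > 0 and min_run_s >= 0")
    static = _static_mask(rec, vel_threshold_deg_s)
    if static.all():
        raise NoMotionError(
            f"no motion detected in recording {rec.subject_id}/{rec.task_id}"
        )
    moving = np.flatnonzero(~static)
    start, stop = int(moving[0]), int(moving[-1]) + 1
    min_run = int(round(min_run_s * rec.sample_rate))
    if start < min_run:
        start = 0
    if rec.n_frames - stop < min_run:
        stop = rec.n_frames
    return rec.with_angles(rec.angles[start:stop])


def resample_to(
    rec: JointAngleRecording, n_frames: int = DEFAULT_RESAMPLE_FRAMES
) -> JointAngleRecording:
    """Linearly interpolate every DoF trace onto ``n_frames`` equally spaced points.

    The new grid spans the original duration, so the first and last samples are
    preserved exactly. The nominal sample rate is rescaled accordingly.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    if rec.n_frames < 2:
        raise RecordingTooShortError("need >= 2 frames to resample")
    old_t = np.arange(rec.n_frames, dtype=float)
    new_t = np.linspace(0.0, rec.n_frames - 1, n_frames)
    out = np.empty((n_frames, N_DOF))
    for j in range(N_DOF):
        out[:, j] = np.interp(new_t, old_t, rec.angles[:, j])
    new_rate = rec.sample_rate * (n_frames - 1) / (rec.n_frames - 1)
    return JointAngleRecording(rec.subject_id, rec.task_id, out, new_rate)


@dataclass
class NormalizationParams:
    """Per-DoF mean and SD (degrees) over a subject's concatenated tasks."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (N_DOF,) or self.sd.shape != (N_DOF,):
            raise ParameterError(f"mean and sd must have shape ({N_DOF},)")
        if not np.all(self.sd > 0):
            raise DegenerateDoFError("every SD must be > 0")

    def destandardize(self, std_matrix: np.ndarray) -> np.ndarray:
        """Invert standardisation: rows of ``std_matrix`` back to degrees."""
        return std_matrix * self.sd[:, None] + self.mean[:, None]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"label": DOF_NAMES, "mean": self.mean, "sd": self.sd}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "NormalizationParams":
        df = pd.read_csv(path).set_index("label").loc[list(DOF_NAMES)]
        return cls(df["mean"].to_numpy(), df["sd"].to_numpy())


def zscore_concat(recs) -> tuple[np.ndarray, NormalizationParams]:
    """Concatenate one subject's tasks and z-standardise each DoF.

    Parameters
    ----------
    recs:
        Recordings of a single subject, each already resampled to a common
        frame count (typically 1000).

    Returns
    -------
    A ``16 x (frames * n_tasks)`` matrix whose rows have mean 0 and SD 1, and
    the :class:`NormalizationParams` that undo the transform.

    Raises
    ------
    DegenerateDoFError
        If any DoF is constant across the concatenation (a missing channel
    would silently corrupt the fixed 16-label contract downstream).
    """
    recs = list(recs)
    if not recs:
        raise ParameterError("need at least one recording")
    subjects = {r.subject_id for r in recs}
    if len(subjects) != 1:
        raise ParameterError(f"recordings span multiple subjects: {sorted(subjects)}")
    lengths = {r.n_frames for r in recs}
    if len(lengths) != 1:
        raise ParameterError("all recordings must share one frame count; resample first")
    data = np.concatenate([r.angles for r in recs], axis=0).T  # 16 x N
    mean = data.mean(axis=1)
    sd = data.std(axis=1)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        names = [DOF_NAMES[i] for i in zero]
        raise DegenerateDoFError(f"degenerate DoF (zero variance): {names}")
    std = (data - mean[:, None]) / sd[:, None]
    return std, NormalizationParams(mean, sd)


def preprocess_recording(
    rec: JointAngleRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    vel_threshold_deg_s: float = DEFAULT_VEL_THRESHOLD_DEG_S,
    min_run_s: float = DEFAULT_MIN_RUN_S,
    n_frames: int | None = None,
) -> JointAngleRecording:
    """Filter, trim and (optionally) time-normalise one recording."""
    out = lowpass_filter(rec, cutoff_hz=cutoff_hz, order=order)
    out = trim_static(out, vel_threshold_deg_s=vel_threshold_deg_s, min_run_s=min_run_s)
    if n_frames is not None:
        out = resample_to(out, n_frames)
    return out
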