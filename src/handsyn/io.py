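"""Reading and writing joint-angle recordings as delimited text.

The on-disk layout is one long-format table (CSV or TSV) with a header: a
subject column, a task column, and one column per canonical DoF, all angles in
degrees relative to the flat-hand reference posture. A column map lets
differently named source files (e.g. the deposited glove datasets) be remapped
without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dof import DOF_NAMES, N_DOF
from .errors import FormatError, ParameterError

DEFAULT_SAMPLE_RATE = 100.0


@dataclass
class JointAngleRecording:
    """One subject performing one task: a frames x 16 matrix of angles (degrees).

    Columns follow the canonical DoF order; all values are finite.
    """

    subject_id: str
    task_id: str
    angles: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != N_DOF:
            raise ParameterError(
                f"angles must be a frames x {N_DOF} matrix, got shape {self.angles.shape}"
            )
        if not np.all(np.isfinite(self.angles)):
            raise ParameterError(
                f"non-finite angle in recording {self.subject_id}/{self.task_id}"
            )
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) / self.sample_rate

    def with_angles(self, angles: np.ndarray) -> "JointAngleRecording":
        return replace(self, angles=np.asarray(angles, dtype=float))


@dataclass
class ColumnMap:
    """Mapping from the canonical column roles to the source file's headers."""

    subject: str = "subject"
    task: str = "task"
    dof: dict = field(default_factory=lambda: {n: n for n in DOF_NAMES})

    @classmethod
    def from_file(cls, path) -> "ColumnMap":
        """Load a column map from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        dof = dict(data.get("dof", {}))
        missing = set(DOF_NAMES) - set(dof)
        if missing and dof:
            raise FormatError(f"column map missing DoF entries: {sorted(missing)}")
        return cls(
            subject=data.get("subject", "subject"),
            task=data.get("task", "task"),
            dof=dof or {n: n for n in DOF_NAMES},
        )


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_recordings(
    path,
    layout: ColumnMap | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> list[JointAngleRecording]:
    """Read all recordings from one delimited-text file.

    Returns one :class:`JointAngleRecording` per (subject, task) pair, in file
    order, with columns reordered into canonical DoF order.

    Raises
    ------
    FormatError
        If a required column is missing or a cell is non-numeric (the error
        names the offending column / row).
    """
    layout = layout or ColumnMap()
    df = pd.read_csv(path, sep=_sep_for(path))
    required = [layout.subject, layout.task] + [layout.dof[n] for n in DOF_NAMES]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")

    angle_cols = [layout.dof[n] for n in DOF_NAMES]
    for col in angle_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value in column '{col}' at data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise FormatError(f"{path}: missing value in column '{col}' at data row {row}")
        df[col] = numeric

    recordings = []
    # sort=False keeps the file's own (subject, task) order
    for (subj, task), grp in df.groupby([layout.subject, layout.task], sort=False):
        recordings.append(
            JointAngleRecording(
                subject_id=str(subj),
                task_id=str(task),
                angles=grp[angle_cols].to_numpy(dtype=float),
                sample_rate=sample_rate,
            )
        )
    return recordings


def write_recordings(recordings, path, layout: ColumnMap | None = None) -> None:
    """Write recordings to one delimited-text file in the documented layout."""
    layout = layout or ColumnMap()
    frames = []
    for rec in recordings:
        df = pd.DataFrame(rec.angles, columns=[layout.dof[n] for n in DOF_NAMES])
        df.insert(0, layout.task, rec.task_id)
        df.insert(0, layout.subject, rec.subject_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep=_sep_for(path), index=False)


def group_by_subject(recordings) -> dict[str, list[JointAngleRecording]]:
    """Group a flat recording list by subject, preserving task order."""
    groups: dict[str, list[JointAngleRecording]] = {}
    for rec in recordings:
        groups.setdefault(rec.subject_id, []).append(rec)
    return groups
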