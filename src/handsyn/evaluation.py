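"""Held-out evaluation of a fitted estimator bank.

The bank is applied to every frame of an evaluation dataset (filtered and
trimmed, but at native frame counts: time-normalisation exists only to equalise
task weights during synergy extraction). Errors are reported as RMSE in
degrees — globally (all frames of all subjects pooled, one value per joint)
and per activity (all subjects' frames of that activity pooled) — and as a
percentage of each joint's range of motion (RoM), where RoM is the pooled
max minus min over all frames of both the training and the evaluation
datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dof import DOF_NAMES, dof_index
from .errors import DegenerateDoFError, ParameterError
from .estimation import LinearEstimatorBank, estimate_from_full

logger = logging.getLogger(__name__)


@dataclass
class RoMTable:
    """Per-DoF range of motion in degrees (pooled max - pooled min)."""

    rom: pd.Series

    def __post_init__(self) -> None:
        self.rom = self.rom.reindex(list(DOF_NAMES))
        if self.rom.isna().any() or not (self.rom > 0).all():
            raise DegenerateDoFError("every RoM must be finite and > 0")

    def __getitem__(self, name: str) -> float:
        return float(self.rom[name])

    def to_csv(self, path) -> None:
        self.rom.rename("rom_deg").rename_axis("label").to_csv(path)


def rom_table(datasets) -> RoMTable:
    """Pooled per-DoF range of motion over one or more recording collections."""
    lo = np.full(16, np.inf)
    hi = np.full(16, -np.inf)
    n = 0
    for collection in datasets:
        for rec in collection:
            lo = np.minimum(lo, rec.angles.min(axis=0))
            hi = np.maximum(hi, rec.angles.max(axis=0))
            n += 1
    if n == 0:
        raise ParameterError("need at least one recording")
    rng = hi - lo
    flat = np.flatnonzero(rng <= 0)
    if flat.size:
        raise DegenerateDoFError(
            f"degenerate RoM (no motion) for: {[DOF_NAMES[i] for i in flat]}"
        )
    return RoMTable(pd.Series(rng, index=list(DOF_NAMES)))


@dataclass
class ErrorReport:
    """Global and per-activity estimation errors.

    ``global_rmse``: per estimated DoF, degrees. ``global_pct_rom``: the same
    as % of RoM. ``per_activity_rmse`` / ``per_activity_pct_rom``: activity x
    DoF tables; the %RoM table carries an ``AVG`` column (mean across DoF).
    """

    global_rmse: pd.Series
    global_pct_rom: pd.Series
    per_activity_rmse: pd.DataFrame
    per_activity_pct_rom: pd.DataFrame
    n_frames: int

    def save(self, global_path, per_activity_path) -> None:
        pd.DataFrame(
            {"rmse_deg": self.global_rmse, "pct_rom": self.global_pct_rom}
        ).rename_axis("label").to_csv(global_path)
        out = self.per_activity_rmse.add_suffix("_deg").join(
            self.per_activity_pct_rom.add_suffix("_pct")
        )
        out.rename_axis("activity").to_csv(per_activity_path)


def evaluate(bank: LinearEstimatorBank, dataset, rom: RoMTable) -> ErrorReport:
    """Estimate every non-representative DoF on every frame and score errors.

    ``dataset`` is an iterable of preprocessed recordings (filtered/trimmed,
    native frame counts). Activities with zero frames are skipped with a
    warning. Global RMSE pools all frames; per-activity RMSE pools all
    subjects' frames of that activity, so the global squared error is the
    frame-count-weighted mean of the per-activity squared errors.
    """
    est_labels = bank.estimated_labels
    est_idx = [dof_index(n) for n in est_labels]

    sq_by_task: dict[str, np.ndarray] = {}
    n_by_task: dict[str, int] = {}
    for rec in dataset:
        if rec.n_frames == 0:
            logger.warning(
                "skipping empty activity %s/%s", rec.subject_id, rec.task_id
            )
            continue
        est = estimate_from_full(bank, rec.angles)
        sq = np.sum((est - rec.angles[:, est_idx]) ** 2, axis=0)
        sq_by_task[rec.task_id] = sq_by_task.get(rec.task_id, 0.0) + sq
        n_by_task[rec.task_id] = n_by_task.get(rec.task_id, 0) + rec.n_frames
    if not n_by_task:
        raise ParameterError("no frames to evaluate")

    tasks = list(sq_by_task)
    per_act = pd.DataFrame(
        {t: np.sqrt(sq_by_task[t] / n_by_task[t]) for t in tasks},
        index=est_labels,
    ).T
    total_sq = sum(sq_by_task.values())
    total_n = sum(n_by_task.values())
    global_rmse = pd.Series(np.sqrt(total_sq / total_n), index=est_labels)

    rom_vec = pd.Series({n: rom[n] for n in est_labels})
    pct = 100.0 * per_act / rom_vec
    pct["AVG"] = pct.mean(axis=1)
    return ErrorReport(
        global_rmse=global_rmse,
        global_pct_rom=100.0 * global_rmse / rom_vec,
        per_activity_rmse=per_act,
        per_activity_pct_rom=pct,
        n_frames=total_n,
    )


def export_traces(bank: LinearEstimatorBank, recording, path=None) -> pd.DataFrame:
    """Long-format (frame, dof, recorded, estimated) table for trace plots."""
    est = estimate_from_full(bank, recording.angles)
    rows = []
    for j, name in enumerate(bank.estimated_labels):
        rec_col = recording.angles[:, dof_index(name)]
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(recording.n_frames),
                    "dof": name,
                    "recorded": rec_col,
                    "estimated": est[:, j],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    if path is not None:
        df.to_csv(path, index=False)
    return df
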