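"""Linear estimation of non-recorded joint angles.

Every non-representative joint angle is modelled, frame by frame, as an affine
combination of the recorded (representative) angles:

    ang_est[i] = intercept + sum_k ang_rep[k, i] * x[k]

The intercept and coefficients x(k) minimise the sum of squared differences
between estimated and recorded angles over all pooled training frames. The
model is affine, so the least-squares fit has the closed-form OLS solution,
computed here with an SVD-based (rank-revealing) solver on raw angles in
degrees. Candidate representative sets are scored by their mean RMSE across
estimated DoF and the lowest-error combination is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dof import DOF_NAMES, N_DOF, dof_index
from .errors import DegenerateDesignError, ParameterError
from .selection import RepresentativeSet

MAX_CONDITION = 1e10


@dataclass
class LinearEstimatorBank:
    """Fitted affine estimators for every non-representative DoF.

    ``coefficients`` is (n_estimated x n_representative); row order follows
    ``estimated_labels``, column order ``representative_labels``.
    """

    representative_labels: list[str]
    estimated_labels: list[str]
    intercepts: np.ndarray
    coefficients: np.ndarray
    n_training_frames: int = 0
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        rep, est = set(self.representative_labels), set(self.estimated_labels)
        if rep & est or rep | est != set(DOF_NAMES):
            raise ParameterError(
                "representative and estimated labels must partition the 16 DoF"
            )
        if self.coefficients.shape != (len(self.estimated_labels), len(rep)):
            raise ParameterError("coefficient matrix shape mismatch")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.coefficients,
            index=self.estimated_labels,
            columns=self.representative_labels,
        )
        df.insert(0, "Intercept", self.intercepts)
        df.index.name = "estimated"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "LinearEstimatorBank":
        df = pd.read_csv(path, index_col=0)
        rep = [c for c in df.columns if c != "Intercept"]
        return cls(
            representative_labels=rep,
            estimated_labels=list(df.index),
            intercepts=df["Intercept"].to_numpy(),
            coefficients=df[rep].to_numpy(),
        )


@dataclass
class CombinationScore:
    """Training RMSE per estimated DoF and its mean, for one candidate set."""

    rep_set: RepresentativeSet
    per_dof_rmse: dict[str, float]
    mean_rmse: float


def fit_estimators(
    rep_set: RepresentativeSet,
    frames: np.ndarray,
    dataset_id: str = "",
    max_condition: float = MAX_CONDITION,
) -> LinearEstimatorBank:
    """Ordinary least squares fit of every estimated DoF on the representatives.

    Parameters
    ----------
    rep_set:
        The recorded DoF.
    frames:
        Pooled training frames, shape (N, 16), degrees, canonical column
        order (unstandardized: the fit is on raw angles).

    Raises
    ------
    DegenerateDesignError
        If the design (intercept + representative columns) has condition
        number above ``max_condition`` (collinear representative angles).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2 or frames.shape[1] != N_DOF:
        raise ParameterError(f"frames must be N x {N_DOF}")
    if frames.shape[0] < rep_set.n + 1:
        raise ParameterError("need more frames than parameters")

    rep_labels = rep_set.labels
    est_labels = rep_set.estimated_labels
    rep_idx = [dof_index(n) for n in rep_labels]
    est_idx = [dof_index(n) for n in est_labels]

    design = np.column_stack([np.ones(frames.shape[0]), frames[:, rep_idx]])
    cond = np.linalg.cond(design)
    if not np.isfinite(cond) or cond > max_condition:
        raise DegenerateDesignError(
            f"degenerate design: condition number {cond:.3g} exceeds {max_condition:.0e}"
        )
    beta, *_ = np.linalg.lstsq(design, frames[:, est_idx], rcond=None)
    return LinearEstimatorBank(
        representative_labels=rep_labels,
        estimated_labels=est_labels,
        intercepts=beta[0],
        coefficients=beta[1:].T,
        n_training_frames=frames.shape[0],
        dataset_id=dataset_id,
    )


def estimate_angles(bank: LinearEstimatorBank, rep_frames: np.ndarray) -> np.ndarray:
    """Apply the affine estimators to representative-angle frames.

    ``rep_frames`` is (N x n) with columns in ``bank.representative_labels``
    order; returns (N x n_estimated) in ``bank.estimated_labels`` order.
    """
    rep_frames = np.asarray(rep_frames, dtype=float)
    if rep_frames.ndim != 2 or rep_frames.shape[1] != len(bank.representative_labels):
        raise ParameterError(
            f"rep_frames must have {len(bank.representative_labels)} columns "
            "matching the bank's representative labels"
        )
    return rep_frames @ bank.coefficients.T + bank.intercepts


def estimate_from_full(bank: LinearEstimatorBank, frames: np.ndarray) -> np.ndarray:
    """Convenience: slice the representative columns out of full 16-DoF frames."""
    idx = [dof_index(n) for n in bank.representative_labels]
    return estimate_angles(bank, np.asarray(frames, dtype=float)[:, idx])


def rmse(est: np.ndarray, rec: np.ndarray) -> float:
    """Root-mean-square error between estimated and recorded traces (degrees)."""
    est = np.asarray(est, dtype=float).ravel()
    rec = np.asarray(rec, dtype=float).ravel()
    if est.size == 0 or est.size != rec.size:
        raise ParameterError("est and rec must be equal-length, non-empty")
    return float(np.sqrt(np.mean((est - rec) ** 2)))


def score_combination(
    rep_set: RepresentativeSet, frames: np.ndarray, dataset_id: str = ""
) -> tuple[LinearEstimatorBank, CombinationScore]:
    """Fit one combination and score it on its own training frames."""
    bank = fit_estimators(rep_set, frames, dataset_id=dataset_id)
    est = estimate_from_full(bank, frames)
    per_dof = {
        name: rmse(est[:, j], frames[:, dof_index(name)])
        for j, name in enumerate(bank.estimated_labels)
    }
    return bank, CombinationScore(
        rep_set=rep_set,
        per_dof_rmse=per_dof,
        mean_rmse=float(np.mean(list(per_dof.values()))),
    )


def score_and_select(combos, frames: np.ndarray, dataset_id: str = ""):
    """Score every candidate combination; return scores, the best set, its bank.

    The best combination minimises the mean training RMSE across its estimated
    DoF; ties break deterministically by enumeration order.
    """
    combos = list(combos)
    if not combos:
        raise ParameterError("need at least one combination")
    scores, banks = [], []
    for i, combo in enumerate(combos):
        try:
            bank, score = score_combination(combo, frames, dataset_id=dataset_id)
        except DegenerateDesignError as exc:
            raise DegenerateDesignError(f"combination {i + 1}: {exc}") from exc
        scores.append(score)
        banks.append(bank)
    best = int(np.argmin([s.mean_rmse for s in scores]))
    return scores, combos[best], banks[best]


def scores_to_frame(scores) -> pd.DataFrame:
    """Per-combination RMSE table (row = case, column = estimated DoF + mean)."""
    all_est = [n for n in DOF_NAMES if any(n in s.per_dof_rmse for s in scores)]
    rows = []
    for i, s in enumerate(scores):
        row = {"case": i + 1, "candidates": " ".join(s.rep_set.chosen_candidates)}
        for n in all_est:
            row[n] = s.per_dof_rmse.get(n, np.nan)
        row["mean_rmse"] = s.mean_rmse
        rows.append(row)
    return pd.DataFrame(rows)
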