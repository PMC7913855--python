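"""Per-subject kinematic synergy extraction.

A subject's synergies are the principal components of their standardized
joint-angle ensemble: PCA on the correlation structure of the 16 x N z-scored
matrix, retaining the smallest number of leading components whose cumulative
variance reaches the threshold (default 95%), followed by a Varimax rotation
of the loading matrix. Because the input rows are standardized, the loadings
(eigenvectors scaled by the square roots of the eigenvalues) are the
correlation coefficients (CC) between each rotated component and each joint
angle, which makes them comparable across subjects and joints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dof import DOF_NAMES, N_DOF
from .errors import ParameterError, ThresholdUnreachableError

DEFAULT_VAR_THRESHOLD = 0.95


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a p x k loading matrix.

    Finds the orthogonal k x k matrix R maximising the varimax criterion (the
    summed column-variances of the squared loadings) for ``loadings @ R``.
    With Kaiser normalisation the rows are scaled to unit communality before
    rotating and rescaled afterwards, the common default in factor-analysis
    practice.

    Returns the rotated loadings and the rotation matrix R.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    comm = np.sqrt(np.sum(L**2, axis=1))
    if kaiser_normalize:
        safe = np.where(comm > 0, comm, 1.0)
        L = L / safe[:, None]
    # Kaiser's pairwise planar rotations: each 2-column subproblem has the
    # closed-form optimum phi = atan2(D - 2AB/p, C - (A^2 - B^2)/p) / 4,
    # swept over all column pairs until the criterion stops improving.
    R = np.eye(k)
    work = L.copy()

    def criterion(M):
        sq = M**2
        return float(np.sum(sq**2) - np.sum(np.sum(sq, axis=0) ** 2) / p)

    crit = criterion(work)
    for _ in range(max_iter):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = work[:, i], work[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, Bs = np.sum(u), np.sum(v)
                C = np.sum(u**2 - v**2)
                D = np.sum(2.0 * u * v)
                num = D - 2.0 * A * Bs / p
                den = C - (A**2 - Bs**2) / p
                phi = 0.25 * np.arctan2(num, den)
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                work[:, [i, j]] = work[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        new_crit = criterion(work)
        if new_crit - crit <= tol * max(abs(crit), 1.0):
            break
        crit = new_crit
    out = work
    if kaiser_normalize:
        out = out * comm[:, None]
    return out, R


@dataclass
class SubjectSynergySet:
    """A subject's retained, rotated synergies as CC loading vectors.

    ``loadings`` is 16 x k; column j holds the correlation of rotated
    component j with each joint angle. ``variance_explained`` holds the
    fraction of total variance per rotated component (sum of squared loadings
    over 16); components are sorted by decreasing variance explained.
    """

    subject_id: str
    loadings: np.ndarray
    variance_explained: np.ndarray
    total_variance_explained: float = field(init=False)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        if self.loadings.ndim != 2 or self.loadings.shape[0] != N_DOF:
            raise ParameterError("loadings must be 16 x k")
        if np.max(np.abs(self.loadings)) > 1 + 1e-9:
            raise ParameterError("|CC| loadings must not exceed 1")
        self.total_variance_explained = float(np.sum(self.variance_explained))

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_csv(self, path) -> None:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        df = pd.DataFrame(self.loadings, index=list(DOF_NAMES), columns=cols)
        df.index.name = f"subject:{self.subject_id}"
        df.loc["variance_explained"] = self.variance_explained
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SubjectSynergySet":
        df = pd.read_csv(path, index_col=0)
        subject = str(df.index.name).removeprefix("subject:")
        var = df.loc["variance_explained"].to_numpy(dtype=float)
        load = df.loc[list(DOF_NAMES)].to_numpy(dtype=float)
        return cls(subject, load, var)


def _fix_column_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-magnitude entry is positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def extract_synergies(
    std_matrix: np.ndarray,
    subject_id: str = "",
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
    fixed_k: int | None = None,
) -> SubjectSynergySet:
    """Extract a subject's rotated synergies from a standardized 16 x N matrix.

    Components are retained before rotation: k is the smallest count of
    leading eigen-components of the correlation matrix whose cumulative
    variance reaches ``var_threshold`` (rotation does not change the retained
    subspace or its total variance). ``fixed_k`` overrides the rule for exact
    reproduction of analyses that fixed the component count.

    Raises
    ------
    ParameterError
        If ``var_threshold`` is outside (0, 1] or the rows are not standardized.
    ThresholdUnreachableError
        If the input is rank deficient in a way that leaves the threshold
        unreachable.
    """
    X = np.asarray(std_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] != N_DOF:
        raise ParameterError(f"std_matrix must be {N_DOF} x N")
    if not 0 < var_threshold <= 1:
        raise ParameterError("var_threshold must be in (0, 1]")
    n = X.shape[1]
    if n < 2:
        raise ParameterError("need at least 2 frames")
    if np.max(np.abs(X.mean(axis=1))) > 1e-6 or np.max(np.abs(X.std(axis=1) - 1)) > 1e-6:
        raise ParameterError("rows must be standardized (mean 0, SD 1)")

    corr = (X @ X.T) / n
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    frac = eigval / N_DOF
    cum = np.cumsum(frac)
    if fixed_k is not None:
        if not 1 <= fixed_k <= N_DOF:
            raise ParameterError("fixed_k must be in 1..16")
        k = fixed_k
    else:
        reach = np.flatnonzero(cum >= var_threshold - 1e-12)
        if reach.size == 0:
            raise ThresholdUnreachableError(
                f"cumulative variance tops out at {cum[-1]:.6f} < {var_threshold}"
            )
        k = int(reach[0]) + 1

    loadings = eigvec[:, :k] * np.sqrt(eigval[:k])[None, :]
    rotated, _ = varimax(loadings)
    var_rot = np.sum(rotated**2, axis=0) / N_DOF
    order = np.argsort(var_rot)[::-1]
    rotated = _fix_column_signs(rotated[:, order])
    # numerical guard: correlations can overshoot 1 by float error
    rotated = np.clip(rotated, -1.0, 1.0)
    return SubjectSynergySet(subject_id, rotated, var_rot[order])
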