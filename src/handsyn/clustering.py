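"""Cross-subject clustering of synergy loading vectors.

All subjects' rotated components are pooled and grouped by hierarchical
complete-linkage (farthest-neighbour) clustering, with the angle between
loading vectors as the pairwise distance. The angle uses the absolute cosine,
because a loading vector and its negation describe the same synergy. The
partition is chosen by the subject-uniqueness rule: the minimum number of
clusters such that no cluster contains two synergies from the same subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dof import DOF_NAMES, N_DOF
from .errors import ConsistencyError, ParameterError, UnseparableMembersError

CC_PREDOMINANT = 0.4  # |averaged CC| above which a DoF counts as predominant


@dataclass
class PooledPC:
    """One subject's rotated component, pooled for cross-subject clustering."""

    subject_id: str
    component_index: int
    loading: np.ndarray
    variance_explained: float

    def __post_init__(self) -> None:
        self.loading = np.asarray(self.loading, dtype=float)
        if self.loading.shape != (N_DOF,) or not np.all(np.isfinite(self.loading)):
            raise ParameterError("loading must be 16 finite values")
        if not np.any(self.loading):
            raise ParameterError("loading must not be all zero")


def pool_synergies(synergy_sets) -> list[PooledPC]:
    """Flatten per-subject synergy sets into one pooled component list."""
    pooled = []
    for s in synergy_sets:
        for j in range(s.n_components):
            pooled.append(
                PooledPC(s.subject_id, j, s.loadings[:, j], float(s.variance_explained[j]))
            )
    return pooled


def pc_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two loading vectors in degrees, in [0, 90].

    Uses ``arccos(|u.v| / (||u|| ||v||))`` so that a component and its
    negation are at distance zero (they are the same synergy).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ParameterError("pc_angle is undefined for a zero vector")
    c = abs(float(np.dot(u, v))) / (nu * nv)
    return float(np.degrees(np.arccos(min(c, 1.0))))


def angle_distance_matrix(pcs) -> np.ndarray:
    """Full symmetric matrix of pairwise pc_angle distances (degrees)."""
    U = np.stack([p.loading for p in pcs], axis=1)
    norms = np.linalg.norm(U, axis=0)
    if np.any(norms == 0):
        raise ParameterError("zero loading vector in pool")
    C = np.abs(U.T @ U) / np.outer(norms, norms)
    np.clip(C, 0.0, 1.0, out=C)
    D = np.degrees(np.arccos(C))
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def complete_linkage(pcs) -> np.ndarray:
    """Complete-linkage merge tree over pooled components.

    Returns a standard ``(n-1) x 4`` linkage array (member indices, merge
    height in degrees, cluster size) with non-decreasing merge heights.
    """
    pcs = list(pcs)
    if len(pcs) < 2:
        raise ParameterError("need at least 2 pooled components to cluster")
    D = angle_distance_matrix(pcs)
    return hierarchy.linkage(squareform(D, checks=False), method="complete")


@dataclass
class SynergyCluster:
    """One cross-subject synergy: its members and sign-aligned mean loading."""

    members: list
    averaged_pc: np.ndarray
    subject_fraction: float
    mean_variance_explained: float

    @property
    def subject_ids(self) -> set:
        return {m.subject_id for m in self.members}

    def predominant_dofs(self, threshold: float = CC_PREDOMINANT) -> list[str]:
        """DoF with |averaged CC| above ``threshold``, by descending |CC|."""
        cc = np.abs(self.averaged_pc)
        idx = np.flatnonzero(cc > threshold)
        return [DOF_NAMES[i] for i in idx[np.argsort(cc[idx])[::-1]]]


def summarize_cluster(members, n_subjects_total: int | None = None) -> SynergyCluster:
    """Average a cluster's members into one representative loading.

    Members are sign-aligned to the member with the largest variance explained
    (any member whose dot product with that anchor is negative is flipped)
    before the element-wise mean, so that antipodal loadings reinforce rather
    than cancel.
    """
    members = list(members)
    if not members:
        raise ParameterError("cluster must have at least one member")
    anchor = max(members, key=lambda m: m.variance_explained).loading
    aligned = [
        m.loading if float(np.dot(m.loading, anchor)) >= 0 else -m.loading
        for m in members
    ]
    averaged = np.mean(aligned, axis=0)
    subjects = {m.subject_id for m in members}
    total = n_subjects_total if n_subjects_total else len(subjects)
    return SynergyCluster(
        members=members,
        averaged_pc=averaged,
        subject_fraction=len(subjects) / total,
        mean_variance_explained=float(np.mean([m.variance_explained for m in members])),
    )


@dataclass
class ClusterPartition:
    """The selected flat partition plus the full merge tree it was cut from."""

    clusters: list = field(default_factory=list)
    cut_distance: float = 0.0
    linkage_tree: np.ndarray | None = None
    labels: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def select_partition(tree: np.ndarray, pcs) -> ClusterPartition:
    """Cut the merge tree by the subject-uniqueness rule.

    Scans candidate partitions from coarsest (1 cluster) to finest and returns
    the first whose every cluster holds at most one component per subject.
    ``cut_distance`` is reported as the height of the first merge the cut
    undoes, rounded to 1 degree (the conventional way a dendrogram cut-off is
    quoted); selection itself is count-based.

    Raises
    ------
    UnseparableMembersError
        If one subject contributed two identical loadings (distance 0): no cut
        can ever separate them.
    """
    pcs = list(pcs)
    n = len(pcs)
    if tree.shape != (n - 1, 4):
        raise ParameterError("tree does not match the pooled component list")

    D = angle_distance_matrix(pcs)
    subj = [p.subject_id for p in pcs]
    for i in range(n):
        for j in range(i + 1, n):
            if subj[i] == subj[j] and D[i, j] <= 1e-9:
                raise UnseparableMembersError(
                    f"subject {subj[i]} contributed two identical components "
                    f"({pcs[i].component_index} and {pcs[j].component_index})"
                )

    n_subjects_total = len(set(subj))
    for c in range(1, n + 1):
        labels = hierarchy.cut_tree(tree, n_clusters=c).ravel()
        ok = True
        for lab in np.unique(labels):
            ids = [subj[i] for i in np.flatnonzero(labels == lab)]
            if len(ids) != len(set(ids)):
                ok = False
                break
        if ok:
            if c == 1:
                cut = float(np.round(tree[-1, 2]))
            else:
                cut = float(np.round(tree[n - c, 2]))
            clusters = [
                summarize_cluster(
                    [pcs[i] for i in np.flatnonzero(labels == lab)], n_subjects_total
                )
                for lab in np.unique(labels)
            ]
            return ClusterPartition(
                clusters=clusters, cut_distance=cut, linkage_tree=tree, labels=labels
            )
    raise ConsistencyError("no valid partition found (unreachable for a strict hierarchy)")


def cluster_synergies(synergy_sets) -> ClusterPartition:
    """Pool, cluster and cut in one call."""
    pcs = pool_synergies(synergy_sets)
    tree = complete_linkage(pcs)
    return select_partition(tree, pcs)


def partition_to_frames(partition: ClusterPartition) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Membership and cluster-summary tables for CSV export."""
    rows = []
    for cid, cluster in enumerate(partition.clusters):
        for m in cluster.members:
            rows.append(
                {"subject": m.subject_id, "component": m.component_index, "cluster": cid}
            )
    members = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "cluster": range(partition.n_clusters),
            "subject_pct": [100 * c.subject_fraction for c in partition.clusters],
            "mean_variance_explained": [
                c.mean_variance_explained for c in partition.clusters
            ],
            "predominant_dof": [
                " ".join(c.predominant_dofs()) for c in partition.clusters
            ],
        }
    )
    for i, name in enumerate(DOF_NAMES):
        summary[f"cc_{name}"] = [c.averaged_pc[i] for c in partition.clusters]
    return members, summary


def linkage_to_frame(tree: np.ndarray) -> pd.DataFrame:
    """Flat merge list (child indices + height in degrees) for export."""
    return pd.DataFrame(tree, columns=["child_a", "child_b", "height_deg", "size"])
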