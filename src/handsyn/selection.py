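"""Classification of synergy clusters and enumeration of representative sets.

Each cross-subject synergy cluster is read off its averaged loading vector:

* clusters present in too few subjects are discarded as idiosyncratic;
* a cluster whose averaged loading has exactly one |CC| > 0.8 with every
  other |CC| < 0.3 describes the independent motion of a single DoF — that
  DoF must be recorded;
* every other cluster describes a coordination; all DoF with |CC| > 0.4 are
  candidates to represent it, and clusters whose candidate sets overlap are
  pooled into one coordination group (they are the same coordination carried
  with different weights by different subjects).

A nominally independent cluster whose DoF also shows up among a coordination
cluster's candidates is demoted to candidate status: its motion is not in fact
independent of the rest of the hand.

A representative set is then all independent DoF plus exactly one candidate
per coordination group; all such combinations are enumerated for scoring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dof import DOF_NAMES, canonical_sort
from .errors import ConsistencyError, ParameterError
from .clustering import ClusterPartition

CC_HIGH = 0.8  # single-DoF predominance
CC_LOW = 0.3  # everything else must stay below this for independence
CC_CANDIDATE = 0.4  # candidate threshold inside a coordination
MIN_SUBJECT_FRACTION = 0.10


@dataclass
class CoordinationGroup:
    """A pooled coordination: contributing cluster ids and its candidate DoF."""

    cluster_ids: list[int]
    candidates: list[str]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ConsistencyError(
                f"coordination group from clusters {self.cluster_ids} has no candidates"
            )


@dataclass
class RepresentativeSet:
    """The DoF to record: independent DoF plus one candidate per group."""

    independent: list[str]
    chosen_candidates: list[str]
    n: int = field(init=False)

    def __post_init__(self) -> None:
        labels = self.labels
        if len(labels) != len(set(labels)):
            raise ConsistencyError(f"duplicate labels in representative set: {labels}")
        self.n = len(labels)

    @property
    def labels(self) -> list[str]:
        """All recorded DoF in canonical column order."""
        return canonical_sort(self.independent + self.chosen_candidates)

    @property
    def estimated_labels(self) -> list[str]:
        """The complementary (estimated) DoF in canonical order."""
        rep = set(self.labels)
        return [n for n in DOF_NAMES if n not in rep]


def classify_clusters(
    partition: ClusterPartition,
    min_subject_fraction: float = MIN_SUBJECT_FRACTION,
    cc_high: float = CC_HIGH,
    cc_low: float = CC_LOW,
    cc_candidate: float = CC_CANDIDATE,
):
    """Split clusters into independent DoF, coordination groups and discards.

    Returns ``(independent, groups, discarded)`` where ``independent`` is a
    canonically sorted DoF list, ``groups`` a list of
    :class:`CoordinationGroup` in cluster-discovery order, and ``discarded``
    the ids of clusters below the subject-presence floor.

    All thresholds compare absolute CC values with strict inequalities; the
    classification is therefore invariant to global sign flips of any
    cluster's averaged loading.
    """
    if not 0 <= min_subject_fraction <= 1:
        raise ParameterError("min_subject_fraction must be in [0, 1]")

    discarded: list[int] = []
    singles: dict[int, str] = {}  # cluster id -> its single predominant DoF
    coord_candidates: dict[int, list[str]] = {}

    for cid, cluster in enumerate(partition.clusters):
        if cluster.subject_fraction < min_subject_fraction:
            discarded.append(cid)
            continue
        cc = np.abs(cluster.averaged_pc)
        high = np.flatnonzero(cc > cc_high)
        if high.size == 1 and np.all(np.delete(cc, high[0]) < cc_low):
            singles[cid] = DOF_NAMES[int(high[0])]
        else:
            cands = [DOF_NAMES[i] for i in np.flatnonzero(cc > cc_candidate)]
            if not cands:
                raise ConsistencyError(
                    f"cluster {cid} is neither independent nor has any |CC| > "
                    f"{cc_candidate}; cannot classify"
                )
            coord_candidates[cid] = cands

    # Demote singles whose DoF reappears inside a coordination, to fixpoint:
    # a demoted cluster becomes a coordination cluster and may pull in others.
    changed = True
    while changed:
        changed = False
        pooled = set(itertools.chain.from_iterable(coord_candidates.values()))
        for cid, dof in list(singles.items()):
            if dof in pooled:
                cc = np.abs(partition.clusters[cid].averaged_pc)
                coord_candidates[cid] = [
                    DOF_NAMES[i] for i in np.flatnonzero(cc > cc_candidate)
                ]
                del singles[cid]
                changed = True

    # Merge coordination clusters with overlapping candidate sets (union-find).
    parent = {cid: cid for cid in coord_candidates}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ids = sorted(coord_candidates)
    for a, b in itertools.combinations(ids, 2):
        if set(coord_candidates[a]) & set(coord_candidates[b]):
            parent[find(b)] = find(a)

    merged: dict[int, list[int]] = {}
    for cid in ids:
        merged.setdefault(find(cid), []).append(cid)

    groups = []
    for root in sorted(merged):
        members = sorted(merged[root])
        cands = set(itertools.chain.from_iterable(coord_candidates[c] for c in members))
        groups.append(CoordinationGroup(members, canonical_sort(cands)))

    independent = canonical_sort(singles.values())
    if len(independent) != len(set(independent)):
        raise ConsistencyError(f"duplicate independent DoF: {independent}")
    overlap = set(independent) & set(
        itertools.chain.from_iterable(g.candidates for g in groups)
    )
    if overlap:
        raise ConsistencyError(
            f"DoF classified both independent and candidate: {sorted(overlap)}"
        )
    return independent, groups, discarded


def enumerate_combinations(independent, groups) -> list[RepresentativeSet]:
    """All representative sets: one candidate per group, plus all independents.

    Ordering is deterministic: groups in discovery order, candidates within a
    group in canonical DoF order.
    """
    for g in groups:
        if not g.candidates:
            raise ConsistencyError("coordination group with no candidates")
    combos = []
    for choice in itertools.product(*(g.candidates for g in groups)):
        combos.append(RepresentativeSet(list(independent), list(choice)))
    return combos


def classification_to_frame(independent, groups, discarded) -> pd.DataFrame:
    """Classification report table (one row per DoF role)."""
    rows = [{"role": "independent", "group": "", "dof": d} for d in independent]
    for gi, g in enumerate(groups):
        for d in g.candidates:
            rows.append(
                {"role": "candidate", "group": f"group{gi + 1}", "dof": d}
            )
    for cid in discarded:
        rows.append({"role": "discarded_cluster", "group": str(cid), "dof": ""})
    return pd.DataFrame(rows)


def combinations_to_frame(combos) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(combos):
        rows.append(
            {
                "case": i + 1,
                "candidates": " ".join(c.chosen_candidates),
                "representative": " ".join(c.labels),
                "n": c.n,
            }
        )
    return pd.DataFrame(rows)
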