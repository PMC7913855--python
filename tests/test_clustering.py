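"""Cross-subject clustering: inter-component angles, complete linkage,
subject-uniqueness partition rule, cluster averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from handsyn import (
    PooledPC,
    complete_linkage,
    pc_angle,
    select_partition,
    summarize_cluster,
)
from handsyn.clustering import angle_distance_matrix
from handsyn.errors import ParameterError, UnseparableMembersError


def _pc(subject, index, loading, var=0.1):
    return PooledPC(subject, index, np.asarray(loading, dtype=float), var)


def _unit(i, n=16):
    v = np.zeros(n)
    v[i] = 1.0
    return v


class TestPCAngle:
    def test_identity_is_zero(self):
        u = np.arange(1.0, 17.0)
        assert pc_angle(u, u) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_is_ninety(self):
        assert pc_angle(_unit(0), _unit(1)) == pytest.approx(90.0)

    def test_negation_is_zero(self):
        u = np.arange(1.0, 17.0)
        assert pc_angle(u, -u) == pytest.approx(0.0, abs=1e-9)

    def test_planar_forty_five(self):
        u = _unit(0)
        v = _unit(0) + _unit(1)
        assert pc_angle(u, v) == pytest.approx(45.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ParameterError):
            pc_angle(np.zeros(16), _unit(0))

    vectors = hnp.arrays(
        np.float64,
        16,
        elements=st.floats(-1, 1, allow_nan=False, width=32),
    ).filter(lambda v: np.linalg.norm(v) > 1e-3)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(u=vectors, v=vectors)
    def test_sign_invariant_symmetric_bounded(self, u, v):
        a = pc_angle(u, v)
        assert 0.0 <= a <= 90.0
        assert a == pytest.approx(pc_angle(v, u), abs=1e-9)
        assert a == pytest.approx(pc_angle(-u, v), abs=1e-9)
        # arccos loses absolute precision near collinearity; 1e-4 deg slack
        assert a == pytest.approx(pc_angle(2.5 * u, v), abs=1e-4)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(u=vectors, scale=st.floats(0.1, 5.0))
    def test_zero_iff_collinear(self, u, scale):
        assert pc_angle(u, -scale * u) < 1e-3


def brute_force_complete_linkage(D):
    """O(n^3) reference: repeatedly merge the pair of clusters whose farthest
    members are closest. Returns the flat partition for every cluster count."""
    n = D.shape[0]
    clusters = [{i} for i in range(n)]
    partitions = {n: [set(c) for c in clusters]}
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(D[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
        heights.append(d)
        partitions[len(clusters)] = [set(c) for c in clusters]
    return partitions, heights


def _as_sets(labels):
    return {frozenset(np.flatnonzero(labels == lab)) for lab in np.unique(labels)}


class TestCompleteLinkage:
    def test_three_point_geometry(self):
        """Pairwise angles (5, 5, 80): the close pair merges first and the
        final merge sits at the farthest-neighbour distance."""
        a = _unit(0)
        b = np.cos(np.radians(5)) * _unit(0) + np.sin(np.radians(5)) * _unit(1)
        c = np.cos(np.radians(80)) * _unit(0) + np.sin(np.radians(80)) * _unit(1)
        pcs = [_pc("s1", 0, a), _pc("s2", 0, b), _pc("s3", 0, c)]
        tree = complete_linkage(pcs)
        assert tree[0, 2] == pytest.approx(5.0, abs=1e-6)
        assert tree[1, 2] == pytest.approx(80.0, abs=1e-6)
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}

    def test_duplicates_merge_at_zero(self):
        pcs = [_pc("s1", 0, _unit(3)), _pc("s2", 0, _unit(3))]
        tree = complete_linkage(pcs)
        assert tree[0, 2] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_reference(self, seed):
        """Tree over random loadings reproduces the exhaustive O(n^3)
        farthest-neighbour reference at every cluster count."""
        rng = np.random.default_rng(seed)
        pcs = [_pc(f"s{i}", 0, rng.normal(size=16)) for i in range(10)]
        D = angle_distance_matrix(pcs)
        tree = complete_linkage(pcs)
        ref_partitions, ref_heights = brute_force_complete_linkage(D)
        assert np.allclose(sorted(tree[:, 2]), sorted(ref_heights), atol=1e-9)
        from scipy.cluster.hierarchy import cut_tree

        for k in range(1, 11):
            ours = _as_sets(cut_tree(tree, n_clusters=k).ravel())
            theirs = {frozenset(c) for c in ref_partitions[k]}
            assert ours == theirs

    def test_merge_heights_non_decreasing(self, rng):
        pcs = [_pc(f"s{i}", 0, rng.normal(size=16)) for i in range(15)]
        tree = complete_linkage(pcs)
        assert np.all(np.diff(tree[:, 2]) >= -1e-12)


class TestSelectPartition:
    def _two_synergy_cohort(self):
        """2 subjects x 2 PCs: cross-subject pairs ~10 deg apart, within-subject
        pairs ~85 deg. Exhaustive check says the valid minimum is 2 clusters."""
        base1, base2 = _unit(0), _unit(8)
        tilt = lambda v, axis, deg: (
            np.cos(np.radians(deg)) * v + np.sin(np.radians(deg)) * axis
        )
        pcs = [
            _pc("s1", 0, base1, 0.5),
            _pc("s1", 1, base2, 0.4),
            _pc("s2", 0, tilt(base1, _unit(1), 10), 0.5),
            _pc("s2", 1, tilt(base2, _unit(9), 10), 0.4),
        ]
        return pcs

    def test_two_subject_two_synergy_geometry(self):
        pcs = self._two_synergy_cohort()
        part = select_partition(complete_linkage(pcs), pcs)
        assert part.n_clusters == 2
        for cluster in part.clusters:
            assert len(cluster.members) == 2
            assert len(cluster.subject_ids) == 2

    def test_one_pc_per_subject_collapses_to_one_cluster(self):
        pcs = [
            _pc(f"s{i}", 0, np.cos(np.radians(i)) * _unit(0) + np.sin(np.radians(i)) * _unit(1))
            for i in range(5)
        ]
        part = select_partition(complete_linkage(pcs), pcs)
        assert part.n_clusters == 1

    def test_selected_partition_respects_subject_uniqueness(self, rng):
        pcs = [
            _pc(f"s{i % 4}", i // 4, rng.normal(size=16)) for i in range(20)
        ]
        part = select_partition(complete_linkage(pcs), pcs)
        for cluster in part.clusters:
            ids = [m.subject_id for m in cluster.members]
            assert len(ids) == len(set(ids))

    def test_refining_the_cut_never_breaks_uniqueness(self, rng):
        """Monotonicity: every partition finer than the selected one also
        satisfies the subject-uniqueness constraint."""
        from scipy.cluster.hierarchy import cut_tree

        pcs = [_pc(f"s{i % 3}", i // 3, rng.normal(size=16)) for i in range(12)]
        tree = complete_linkage(pcs)
        part = select_partition(tree, pcs)
        subj = [p.subject_id for p in pcs]
        for k in range(part.n_clusters, len(pcs) + 1):
            labels = cut_tree(tree, n_clusters=k).ravel()
            for lab in np.unique(labels):
                ids = [subj[i] for i in np.flatnonzero(labels == lab)]
                assert len(ids) == len(set(ids))

    def test_identical_same_subject_pcs_unseparable(self):
        pcs = [
            _pc("s1", 0, _unit(0)),
            _pc("s1", 1, _unit(0)),
            _pc("s2", 0, _unit(8)),
        ]
        with pytest.raises(UnseparableMembersError):
            select_partition(complete_linkage(pcs), pcs)

    def test_cut_distance_reported_as_first_undone_merge(self):
        pcs = self._two_synergy_cohort()
        tree = complete_linkage(pcs)
        part = select_partition(tree, pcs)
        # 2 clusters undo only the final merge
        assert part.cut_distance == pytest.approx(round(tree[-1, 2]))


class TestSummarizeCluster:
    def test_single_member_average_is_member(self):
        m = _pc("s1", 0, np.linspace(-1, 1, 16))
        cluster = summarize_cluster([m], n_subjects_total=4)
        assert np.allclose(cluster.averaged_pc, m.loading)
        assert cluster.subject_fraction == pytest.approx(0.25)

    def test_antipodal_members_align_before_averaging(self):
        v = np.linspace(-1, 1, 16)
        members = [_pc("s1", 0, v, var=0.5), _pc("s2", 0, -v, var=0.3)]
        cluster = summarize_cluster(members)
        assert np.allclose(cluster.averaged_pc, v)

    def test_alignment_anchor_is_highest_variance_member(self):
        v = np.linspace(-1, 1, 16)
        members = [_pc("s1", 0, -v, var=0.9), _pc("s2", 0, v, var=0.1)]
        cluster = summarize_cluster(members)
        assert np.allclose(cluster.averaged_pc, -v)

    def test_mean_variance_and_subject_fraction(self):
        members = [
            _pc("s1", 0, _unit(0), var=0.2),
            _pc("s2", 0, _unit(0), var=0.4),
            _pc("s2", 1, _unit(0) * 0.9 + _unit(1) * 0.1, var=0.6),
        ]
        cluster = summarize_cluster(members, n_subjects_total=4)
        assert cluster.mean_variance_explained == pytest.approx(0.4)
        assert cluster.subject_fraction == pytest.approx(0.5)

    def test_predominant_dofs_sorted_by_loading(self):
        v = np.zeros(16)
        v[[7, 9, 11]] = [0.5, 0.9, -0.7]
        cluster = summarize_cluster([_pc("s1", 0, v)])
        assert cluster.predominant_dofs() == ["PIP4F", "PIP5F", "PIP3F"]


def test_synthetic_cohort_partition_recovers_planted_synergies(default_cohort):
    """On the default jittered cohort the partition has exactly m + p clusters
    and every averaged loading points at a planted direction (within 20 deg)."""
    from handsyn import cluster_synergies, extract_synergies, zscore_concat
    from handsyn.io import group_by_subject
    from handsyn.preprocess import preprocess_recording

    recs, truth = default_cohort
    sets = []
    for subject, group in group_by_subject(recs).items():
        pp = [preprocess_recording(r, n_frames=1000) for r in group]
        std, _ = zscore_concat(pp)
        sets.append(extract_synergies(std, subject))
    part = cluster_synergies(sets)
    assert part.n_clusters == truth.n_latent
    planted = truth.config.planted_directions()
    for cluster in part.clusters:
        best = min(
            pc_angle(cluster.averaged_pc, planted[:, j])
            for j in range(planted.shape[1])
        )
        assert best <= 20.0
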