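"""Tag clustering, quantification, expression filters and consensus merge."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from promkit.clustering import (
    TagCluster,
    aggregate_consensus,
    cluster_and_quantify,
    cluster_ctss_distclu,
    filter_clusters,
    normalize_tpm,
    quantify_cluster,
    replicate_consistency_filter,
)
from promkit.io_formats import CtssTable


def brute_force_distclu(positions, max_dist):
    """Independent O(n^2) transitive-closure merge oracle."""
    positions = sorted(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) < max_dist:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted((min(g), max(g)) for g in groups.values())


def spans(positions, max_dist):
    positions = np.sort(np.asarray(positions))
    return [
        (int(positions[s]), int(positions[e - 1]))
        for s, e in cluster_ctss_distclu(positions, max_dist=max_dist)
    ]


class TestDistclu:
    def test_singleton(self):
        assert spans([100], 20) == [(100, 100)]

    def test_example_three_positions(self):
        # 110-100 = 10 < 20 merges; 140-110 = 30 >= 20 splits
        assert spans([100, 110, 140], 20) == [(100, 110), (140, 140)]

    def test_strict_inequality_boundary(self):
        # mutual distance < 20: diff 19 merges, diff 20 does not
        assert spans([100, 119], 20) == [(100, 119)]
        assert spans([100, 120], 20) == [(100, 100), (120, 120)]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cluster_ctss_distclu(np.array([5, 5, 9]), max_dist=20)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 51))
            pos = rng.choice(500, size=n, replace=False) + 1
            max_dist = int(rng.integers(1, 40))
            assert spans(pos, max_dist) == brute_force_distclu(pos, max_dist)


class TestQuantify:
    def test_hand_computed_181(self):
        # counts {1, 8, 1}: cumulative fractions 0.1 / 0.9 / 1.0
        tc = quantify_cluster([10, 11, 12], [1, 8, 1], strand="+")
        assert (tc.q_low_pos, tc.q_up_pos, tc.iqw) == (10, 11, 2)
        assert tc.dominant_pos == 11
        assert tc.tag_count == 10

    def test_single_position(self):
        tc = quantify_cluster([7], [4], strand="+")
        assert tc.iqw == 1 and tc.dominant_pos == 7

    def test_uniform_counts(self):
        tc = quantify_cluster(np.arange(1, 11), np.ones(10, int), strand="+")
        assert (tc.q_low_pos, tc.q_up_pos, tc.iqw) == (1, 9, 9)

    def test_dominant_tie_breaks_five_prime(self):
        plus = quantify_cluster([10, 11], [5, 5], strand="+")
        minus = quantify_cluster([10, 11], [5, 5], strand="-")
        assert plus.dominant_pos == 10
        assert minus.dominant_pos == 11

    def test_minus_strand_quantiles_mirror(self):
        plus = quantify_cluster([10, 11, 12], [1, 8, 1], strand="+")
        minus = quantify_cluster([10, 11, 12], [1, 8, 1], strand="-")
        assert minus.iqw == plus.iqw == 2
        assert (minus.q_low_pos, minus.q_up_pos) == (12, 11)

    def test_full_quantile_range_is_cluster_width(self):
        tc = quantify_cluster([1, 5, 9], [2, 3, 4], strand="+", q_low=0.0, q_up=1.0)
        assert tc.iqw == tc.end - tc.start + 1 == 9

    def test_empty_cluster_is_error(self):
        with pytest.raises(ValueError):
            quantify_cluster([], [], strand="+")

    @given(
        st.lists(
            st.tuples(st.integers(1, 300), st.integers(1, 50)),
            min_size=1,
            max_size=30,
            unique_by=lambda t: t[0],
        ),
        st.floats(0.0, 0.5),
        st.floats(0.5, 1.0),
    )
    def test_iqw_monotone_in_quantile_span(self, items, q_low, q_up):
        pos = [p for p, _ in items]
        cnt = [c for _, c in items]
        inner = quantify_cluster(pos, cnt, strand="+", q_low=q_low, q_up=q_up)
        outer = quantify_cluster(pos, cnt, strand="+", q_low=0.0, q_up=1.0)
        assert 1 <= inner.iqw <= outer.iqw
        assert outer.iqw == max(pos) - min(pos) + 1


class TestTpmAndFilters:
    def test_tpm_definition(self):
        df = pd.DataFrame({"chrom": ["c1"], "pos": [5], "strand": ["+"], "count": [10]})
        out = normalize_tpm(CtssTable(df=df, library_size=1_000_000))
        assert out["tpm"].tolist() == [10.0]

    def test_tpm_hand_computed(self):
        df = pd.DataFrame(
            {"chrom": ["c1", "c1"], "pos": [5, 9], "strand": ["+", "+"], "count": [5, 15]}
        )
        out = normalize_tpm(CtssTable(df=df, library_size=2_000_000))
        assert out["tpm"].tolist() == [2.5, 7.5]

    def test_zero_library_is_error(self):
        df = pd.DataFrame({"chrom": ["c1"], "pos": [5], "strand": ["+"], "count": [1]})
        t = CtssTable(df=df)
        t.library_size = 0
        with pytest.raises(ValueError):
            normalize_tpm(t)

    @staticmethod
    def _tc(width, tpm):
        return TagCluster(
            chrom="c1", strand="+", start=100, end=100 + width - 1, sample="s",
            tag_count=1, tpm=tpm, dominant_pos=100, dominant_count=1,
            q_low_pos=100, q_up_pos=100 + width - 1, iqw=width,
        )

    def test_filter_boundaries(self):
        # singleton below / at the TPM-5 floor; wide cluster below / at 0.1
        assert filter_clusters([self._tc(1, 4.9)]) == []
        assert len(filter_clusters([self._tc(1, 5.0)])) == 1
        assert filter_clusters([self._tc(30, 0.09)]) == []
        assert len(filter_clusters([self._tc(30, 0.1)])) == 1


class TestReplicateFilter:
    def test_identity_kept(self):
        assert replicate_consistency_filter([(100, 199)], [(100, 199)]) == [(100, 199)]

    def test_half_overlap_dropped(self):
        assert replicate_consistency_filter([(100, 199)], [(150, 249)]) == []

    def test_95_percent_coverage_kept(self):
        kept = replicate_consistency_filter([(100, 199)], [(105, 199)])
        assert kept == [(100, 199)]

    def test_bad_fraction_is_error(self):
        with pytest.raises(ValueError):
            replicate_consistency_filter([(1, 2)], [(1, 2)], min_fraction=0.0)


def _tc(chrom, strand, start, end, tpm, dominant=None, sample="s"):
    dominant = dominant if dominant is not None else start
    return TagCluster(
        chrom=chrom, strand=strand, start=start, end=end, sample=sample,
        tag_count=int(tpm), tpm=tpm, dominant_pos=dominant, dominant_count=1,
        q_low_pos=start, q_up_pos=end, iqw=end - start + 1,
        positions=np.arange(start, end + 1),
        counts=np.ones(end - start + 1, dtype=np.int64),
    )


class TestConsensus:
    def test_gap_below_threshold_merges(self):
        out = aggregate_consensus(
            {"s1": [_tc("c1", "+", 100, 120, 5.0)], "s2": [_tc("c1", "+", 150, 160, 2.0)]}
        )
        assert len(out) == 1
        c = out[0]
        assert (c.start, c.end) == (100, 160)
        assert c.tpm == {"s1": 5.0, "s2": 2.0}
        assert c.dominant_stage == "s1"

    def test_gap_at_threshold_does_not_merge(self):
        # inter-interval gap of exactly 100 bases stays split (strict <)
        out = aggregate_consensus(
            {"s1": [_tc("c1", "+", 100, 120, 5.0)], "s2": [_tc("c1", "+", 221, 240, 2.0)]}
        )
        assert len(out) == 2
        out2 = aggregate_consensus(
            {"s1": [_tc("c1", "+", 100, 120, 5.0)], "s2": [_tc("c1", "+", 220, 240, 2.0)]}
        )
        assert len(out2) == 1

    def test_stage_absent_gets_zero_tpm(self):
        out = aggregate_consensus(
            {"s1": [_tc("c1", "+", 100, 120, 5.0)], "s2": [], "s3": []}
        )
        assert out[0].tpm == {"s1": 5.0, "s2": 0.0, "s3": 0.0}

    def test_merge_is_stage_order_independent(self):
        stages = {
            "s1": [_tc("c1", "+", 100, 120, 5.0), _tc("c1", "+", 400, 420, 1.0)],
            "s2": [_tc("c1", "+", 150, 160, 2.0)],
            "s3": [_tc("c1", "-", 100, 130, 3.0)],
        }
        a = aggregate_consensus(dict(stages))
        b = aggregate_consensus(dict(reversed(list(stages.items()))))
        assert [(c.chrom, c.strand, c.start, c.end, c.tpm, c.dominant_pos) for c in a] == [
            (c.chrom, c.strand, c.start, c.end, c.tpm, c.dominant_pos) for c in b
        ]

    def test_per_stage_tpm_conserves_member_tpm(self):
        stages = {
            "s1": [_tc("c1", "+", 100, 120, 5.0), _tc("c1", "+", 140, 150, 2.5)],
            "s2": [_tc("c1", "+", 150, 160, 2.0)],
        }
        (c,) = aggregate_consensus(stages)
        assert c.tpm["s1"] == pytest.approx(7.5)
        assert c.tpm["s2"] == pytest.approx(2.0)


class TestConservation:
    def test_tag_counts_conserved_through_clustering(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(5000, size=300, replace=False)) + 1
        cnt = rng.integers(1, 60, size=300)
        df = pd.DataFrame(
            {"chrom": "c1", "pos": pos, "strand": "+", "count": cnt}
        )
        table = CtssTable(df=df)
        tcs = cluster_and_quantify(table, max_dist=20)
        assert sum(tc.tag_count for tc in tcs) == int(cnt.sum())
        # every cluster's tag_count equals the sum of its member CTSS counts
        for tc in tcs:
            member = df[(df["pos"] >= tc.start) & (df["pos"] <= tc.end)]
            assert tc.tag_count == int(member["count"].sum())
            assert tc.start <= tc.dominant_pos <= tc.end
            assert 1 <= tc.iqw <= tc.end - tc.start + 1
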