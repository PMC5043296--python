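import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokit.io import JunctionRecord, SampleSheet
from allokit.splicing import (
    classify_events,
    cluster_usage,
    detect_nagnag,
    filter_junctions,
    preference_scores,
    usage_profile,
)


def J(chrom, start, end, strand="+", counts=(20, 20)):
    return JunctionRecord(chrom, start, end, strand, tuple(counts))


@pytest.fixture
def sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "library": ["L1", "L2"],
                "tissue": ["leaf", "leaf"],
                "replicate": [1, 2],
                "group": ["vegetative", "vegetative"],
            }
        )
    )


class TestFilter:
    @pytest.mark.parametrize(
        "counts,kept", [((9, 9, 9), False), ((0, 10, 0), True), ((), False)]
    )
    def test_max_support_threshold(self, counts, kept):
        junctions = [J("c", 1, 2, counts=counts)] if counts else []
        result = filter_junctions(
            [J("c", 1, 2, counts=counts)] if counts else []
        )
        assert bool(result) is kept

    def test_empty_input(self):
        assert filter_junctions([]) == []


class TestClassification:
    def test_shared_start_pair_is_alt_acceptor_on_plus(self):
        events = classify_events([J("c", 100, 200), J("c", 100, 300)])
        assert len(events) == 1
        event = events[0]
        assert event.event_class == "alt_acceptor"
        assert event.coordinate_class == "shared_start"
        assert event.shared == 100
        assert event.alternatives == (200, 300)

    def test_shared_start_pair_is_alt_donor_on_minus(self):
        events = classify_events(
            [J("c", 100, 200, "-"), J("c", 100, 300, "-")]
        )
        assert events[0].event_class == "alt_donor"

    def test_shared_end_pair_is_alt_donor_on_plus(self):
        events = classify_events([J("c", 100, 300), J("c", 150, 300)])
        assert events[0].event_class == "alt_donor"
        assert events[0].coordinate_class == "shared_end"

    def test_unknown_strand_treated_as_plus(self):
        events = classify_events([J("c", 100, 200, "?"), J("c", 100, 300, "?")])
        assert events[0].event_class == "alt_acceptor"

    def test_exon_skip_triplet(self):
        events = classify_events(
            [J("c", 100, 200), J("c", 250, 400), J("c", 100, 400)]
        )
        assert len(events) == 1
        event = events[0]
        assert event.event_class == "exon_skip"
        assert (event.skipped_exon.start, event.skipped_exon.end) == (200, 250)
        assert set(event.members) == {
            ("c", 100, 200),
            ("c", 250, 400),
            ("c", 100, 400),
        }

    def test_skip_consumes_member_pairs_making_counts_additive(self):
        # triplet plus one extra shared-start partner: the extra pair
        # (100,200)/(100,500) is still reported, the two triplet pairs are not
        junctions = [
            J("c", 100, 200),
            J("c", 250, 400),
            J("c", 100, 400),
            J("c", 100, 500),
        ]
        events = classify_events(junctions)
        classes = sorted(e.coordinate_class for e in events)
        assert classes.count("skip") == 1
        shared_start = [e for e in events if e.coordinate_class == "shared_start"]
        assert {e.alternatives for e in shared_start} == {(200, 500), (400, 500)}

    def test_input_order_invariance(self):
        junctions = [
            J("c", 100, 200),
            J("c", 250, 400),
            J("c", 100, 400),
            J("c", 700, 900, "-"),
            J("c", 750, 900, "-"),
        ]
        forward = classify_events(junctions)
        backward = classify_events(list(reversed(junctions)))
        assert forward == backward

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.permutations(list(range(6))))
    def test_order_invariance_property(self, order):
        junctions = [
            J("c", 100, 200),
            J("c", 100, 300),
            J("c", 400, 600),
            J("c", 450, 600),
            J("c", 100, 600),
            J("d", 10, 90, "-"),
        ]
        shuffled = [junctions[i] for i in order]
        assert classify_events(shuffled) == classify_events(junctions)


class TestNagnag:
    def _acceptor_pair(self, e1, e2, strand="+", s=10):
        if strand == "+":
            return [J("c", s, e1, strand), J("c", s, e2, strand)]
        return [J("c", e1, 300, strand), J("c", e2, 300, strand)]

    def test_plus_strand_motif_match(self):
        genome = {"c": "N" * 17 + "TAGCAG" + "N" * 77}
        events = classify_events(self._acceptor_pair(20, 23))
        flagged = detect_nagnag(events, genome)
        assert flagged[0].nagnag is True
        assert flagged[0].motif == "TAGCAG"

    def test_four_bp_apart_not_candidate(self):
        genome = {"c": "N" * 100}
        events = classify_events(self._acceptor_pair(20, 24))
        assert detect_nagnag(events, genome)[0].nagnag is False
        assert detect_nagnag(events, genome)[0].motif is None

    def test_non_motif_window_not_flagged(self):
        genome = {"c": "N" * 17 + "TAGCAT" + "N" * 77}
        events = classify_events(self._acceptor_pair(20, 23))
        flagged = detect_nagnag(events, genome)
        assert flagged[0].nagnag is False
        assert flagged[0].motif == "TAGCAT"

    def test_minus_strand_mirrored_window(self):
        # acceptor = intron start on minus; window [s1, s1+6) reverse
        # complemented: CTGCTA reads TAGCAG in transcript orientation
        genome = {"c": "N" * 40 + "CTGCTA" + "N" * 300}
        events = classify_events(self._acceptor_pair(40, 43, strand="-"))
        flagged = detect_nagnag(events, genome)
        assert flagged[0].event_class == "alt_acceptor"
        assert flagged[0].nagnag is True
        assert flagged[0].motif == "TAGCAG"

    def test_out_of_bounds_window_skipped(self, caplog):
        genome = {"c": "N" * 4}
        events = classify_events(self._acceptor_pair(2, 5))
        with caplog.at_level("WARNING"):
            flagged = detect_nagnag(events, genome)
        assert flagged[0].nagnag is False


class TestUsage:
    def test_skip_retention_only(self, sheet):
        junctions = [
            J("c", 100, 200, counts=(5, 0)),
            J("c", 250, 400, counts=(7, 0)),
            J("c", 100, 400, counts=(0, 0)),
        ]
        events = classify_events(junctions)
        cats, nums = usage_profile(events, junctions, sheet)
        assert cats.iloc[0]["leaf"] == "first_only"
        assert nums.iloc[0]["leaf"] == 1.0

    def test_all_zero_is_none_and_missing(self, sheet):
        junctions = [
            J("c", 100, 200, counts=(0, 0)),
            J("c", 250, 400, counts=(0, 0)),
            J("c", 100, 400, counts=(0, 0)),
        ]
        events = classify_events(junctions)
        cats, nums = usage_profile(events, junctions, sheet)
        assert cats.iloc[0]["leaf"] == "none"
        assert np.isnan(nums.iloc[0]["leaf"])

    def test_balanced_usage(self, sheet):
        junctions = [
            J("c", 100, 200, counts=(6, 6)),
            J("c", 250, 400, counts=(6, 6)),
            J("c", 100, 400, counts=(6, 6)),
        ]
        events = classify_events(junctions)
        cats, nums = usage_profile(events, junctions, sheet)
        assert cats.iloc[0]["leaf"] == "both"
        assert nums.iloc[0]["leaf"] == pytest.approx(0.5)


class TestPreference:
    def test_log2_retain_over_skip(self, sheet):
        junctions = [
            J("c", 100, 200, counts=(8, 0)),
            J("c", 250, 400, counts=(8, 0)),
            J("c", 100, 400, counts=(2, 0)),
        ]
        events = classify_events(junctions)
        prefs = preference_scores(events, junctions, sheet)
        assert prefs.iloc[0]["value"] == pytest.approx(2.0)

    def test_balanced_is_zero(self, sheet):
        junctions = [
            J("c", 100, 200, counts=(4, 0)),
            J("c", 100, 300, counts=(4, 0)),
        ]
        events = classify_events(junctions)
        prefs = preference_scores(events, junctions, sheet)
        assert prefs.iloc[0]["value"] == 0.0

    def test_zero_support_no_score_without_pseudocount(self, sheet):
        junctions = [
            J("c", 100, 200, counts=(8, 0)),
            J("c", 100, 300, counts=(0, 0)),
        ]
        events = classify_events(junctions)
        assert preference_scores(events, junctions, sheet).empty


class TestClustering:
    def test_identical_columns_merge_first(self):
        matrix = pd.DataFrame(
            {"t1": [0.1, 0.9, 0.5], "t2": [0.1, 0.9, 0.5], "t3": [0.9, 0.1, 0.2]},
            index=["e1", "e2", "e3"],
        )
        result = cluster_usage(matrix)
        first_merge = result.col_linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == 0.0

    def test_three_points_on_line_merge_order(self):
        matrix = pd.DataFrame(
            {"t1": [0.0, 1.0, 10.0], "t2": [0.0, 1.0, 10.0]},
            index=["a", "b", "c"],
        )
        result = cluster_usage(matrix)
        assert {int(result.row_linkage[0][0]), int(result.row_linkage[0][1])} == {0, 1}

    def test_row_permutation_keeps_topology(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(
            rng.random((6, 4)), index=list("abcdef"), columns=list("wxyz")
        )
        permuted = matrix.sample(frac=1, random_state=2)
        r1 = cluster_usage(matrix)
        r2 = cluster_usage(permuted)
        from scipy.cluster.hierarchy import cut_tree

        def partitions(result, index):
            cut = cut_tree(result.row_linkage, n_clusters=3).ravel()
            groups = {}
            for name, cluster in zip(index, cut):
                groups.setdefault(cluster, set()).add(name)
            return {frozenset(g) for g in groups.values()}

        assert partitions(r1, matrix.index) == partitions(r2, permuted.index)
        assert r1.col_order == r2.col_order

    def test_all_missing_row_dropped(self, caplog):
        matrix = pd.DataFrame(
            {"t1": [0.1, np.nan, 0.3], "t2": [0.4, np.nan, 0.2]},
            index=["a", "b", "c"],
        )
        with caplog.at_level("WARNING"):
            result = cluster_usage(matrix)
        assert set(result.row_order) == {"a", "c"}
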