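"""Merging, filtering, best-N selection and splitting.

The merge implementation is checked against a brute-force oracle that
repeatedly unions any interval pair within the merge distance until a
fixpoint is reached.
"""

import random

import pytest
from hypothesis import given, settings, strategies as st

from tehits import (ConfigurationError, FilterParams, MergePolicy,
                    SplitMode, Strand, apply_filters, merge_hits,
                    select_best, split_hits)

from conftest import make_hit


def brute_force_merge(intervals, distance):
    """Union-to-fixpoint oracle on bare (start, end) intervals."""
    pool = [tuple(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                a, b = pool[i], pool[j]
                lo, hi = (a, b) if a[0] <= b[0] else (b, a)
                gap = hi[0] - lo[1] - 1
                if gap <= distance:
                    merged = (min(a[0], b[0]), max(a[1], b[1]))
                    pool = [pool[k] for k in range(len(pool))
                            if k not in (i, j)] + [merged]
                    changed = True
                    break
            if changed:
                break
    return sorted(pool)


def covered_bases(intervals):
    out = set()
    for s, e in intervals:
        out.update(range(s, e + 1))
    return out


class TestMerge:
    def test_within_distance(self):
        hits = [make_hit(start=100, end=200), make_hit(start=250, end=400)]
        out = merge_hits(hits, MergePolicy(distance=100))
        assert [(h.seq_start, h.seq_end) for h in out] == [(100, 400)]
        assert out[0].merged_count == 2

    def test_directly_adjacent_merge_at_distance_zero(self):
        hits = [make_hit(start=100, end=200), make_hit(start=201, end=300)]
        out = merge_hits(hits, MergePolicy(distance=0))
        assert [(h.seq_start, h.seq_end) for h in out] == [(100, 300)]

    def test_beyond_distance_left_alone(self):
        hits = [make_hit(start=100, end=200), make_hit(start=400, end=500)]
        out = merge_hits(hits, MergePolicy(distance=100))
        assert len(out) == 2

    def test_score_aggregation(self):
        hits = [make_hit(start=100, end=200, mismatches=3, gaps=1,
                         bit_score=80.0, e_value=1e-10),
                make_hit(start=150, end=300, mismatches=2, gaps=0,
                         bit_score=120.0, e_value=1e-30)]
        (m,) = merge_hits(hits, MergePolicy(distance=0))
        assert m.mismatches == 5 and m.gaps == 1
        assert m.bit_score == 120.0 and m.e_value == 1e-30

    def test_buckets_respect_group_and_strand(self):
        hits = [make_hit(start=100, end=200, label="A"),
                make_hit(start=150, end=250, label="B"),
                make_hit(start=160, end=260, label="A",
                         strand=Strand.MINUS)]
        out = merge_hits(hits, MergePolicy(distance=0))
        assert len(out) == 3  # different label or strand: never merged

    def test_permissive_policy_merges_across_groups(self):
        hits = [make_hit(start=100, end=200, label="A"),
                make_hit(start=150, end=250, label="B")]
        out = merge_hits(hits, MergePolicy(
            distance=0, require_same_group=False))
        assert len(out) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(1, 50)
        distance = rng.choice([0, 1, 10, 100])
        hits = []
        for _ in range(n):
            s = rng.randint(1, 5000)
            hits.append(make_hit(start=s, end=s + rng.randint(0, 400)))
        out = merge_hits(hits, MergePolicy(distance=distance))
        got = [(h.seq_start, h.seq_end) for h in out]
        expected = brute_force_merge(
            [(h.seq_start, h.seq_end) for h in hits], distance)
        assert got == expected

    @given(st.lists(st.tuples(st.integers(1, 2000), st.integers(0, 200)),
                    min_size=1, max_size=40),
           st.integers(0, 150))
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_coverage_conserving(self, raw, distance):
        hits = [make_hit(start=s, end=s + span) for s, span in raw]
        once = merge_hits(hits, MergePolicy(distance=distance))
        twice = merge_hits(
            [make_hit(start=h.seq_start, end=h.seq_end) for h in once],
            MergePolicy(distance=distance))
        assert ([(h.seq_start, h.seq_end) for h in once]
                == [(h.seq_start, h.seq_end) for h in twice])
        assert (covered_bases((h.seq_start, h.seq_end) for h in once)
                >= covered_bases((s, s + sp) for s, sp in raw))
        if distance == 0:
            # at distance 0 merging adds no new bases: exact conservation
            assert (covered_bases((h.seq_start, h.seq_end) for h in once)
                    == covered_bases((s, s + sp) for s, sp in raw))

    def test_merged_count_conserved(self):
        hits = [make_hit(start=s, end=s + 50) for s in (1, 40, 80, 500)]
        out = merge_hits(hits, MergePolicy(distance=0))
        assert sum(h.merged_count for h in out) == len(hits)


class TestFilters:
    def test_length_thresholds(self):
        hits = [make_hit(start=1, end=150), make_hit(start=1, end=80)]
        out = apply_filters(hits, FilterParams(min_length=100))
        assert [h.seq_length for h in out] == [150]

    def test_bit_score_threshold(self):
        hits = [make_hit(bit_score=95.0, e_value=1e-5),
                make_hit(bit_score=130.0, e_value=1e-9)]
        out = apply_filters(hits, FilterParams(min_bit_score=100.0))
        assert [h.bit_score for h in out] == [130.0]

    def test_empty_params_are_identity(self):
        hits = [make_hit(start=1, end=10), make_hit(start=5, end=6)]
        assert apply_filters(hits, FilterParams()) == hits

    def test_threshold_on_absent_field_is_configuration_error(self):
        hits = [make_hit()]  # no bit score (RepeatMasker-like)
        with pytest.raises(ConfigurationError, match="min_bit_score"):
            apply_filters(hits, FilterParams(min_bit_score=50.0))

    @given(st.integers(0, 300), st.integers(0, 300))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_in_min_length(self, loose, delta):
        rng = random.Random(42)
        hits = [make_hit(start=1, end=rng.randint(1, 400))
                for _ in range(30)]
        kept_loose = apply_filters(hits, FilterParams(min_length=loose))
        kept_tight = apply_filters(
            hits, FilterParams(min_length=loose + delta))
        assert len(kept_tight) <= len(kept_loose)


class TestSelectBest:
    def test_keeps_smallest_e_values(self):
        hits = [make_hit(start=1, end=9, e_value=1e-10, bit_score=50.0),
                make_hit(start=20, end=29, e_value=1e-5, bit_score=40.0),
                make_hit(start=40, end=49, e_value=1e-20, bit_score=90.0)]
        out = select_best(hits, 2)
        assert [h.e_value for h in out] == [1e-10, 1e-20]  # input order

    def test_saturating_n(self):
        hits = [make_hit(start=1, end=9, e_value=1e-3)]
        assert select_best(hits, 10) == hits

    def test_per_group_semantics(self):
        hits = ([make_hit(start=i * 10 + 1, end=i * 10 + 5, label="A",
                          e_value=10.0 ** -i) for i in range(5)]
                + [make_hit(start=i * 10 + 1, end=i * 10 + 5, label="B",
                            e_value=10.0 ** -i) for i in range(5)])
        out = select_best(hits, 1)
        assert len(out) == 2
        assert {h.group_label for h in out} == {"A", "B"}

    def test_ties_broken_by_bit_score(self):
        hits = [make_hit(start=1, end=9, e_value=1e-5, bit_score=40.0),
                make_hit(start=20, end=29, e_value=1e-5, bit_score=90.0)]
        (winner,) = select_best(hits, 1)
        assert winner.bit_score == 90.0

    def test_requires_e_values(self):
        with pytest.raises(ConfigurationError):
            select_best([make_hit()], 1)


class TestSplit:
    def test_by_query_partition(self):
        hits = [make_hit(label="TE1"), make_hit(label="TE1", start=300,
                                                end=400),
                make_hit(label="TE2")]
        groups = split_hits(hits, SplitMode.BY_QUERY)
        assert {k: len(g) for k, g in groups.items()} == {"TE1": 2, "TE2": 1}

    def test_by_type_uses_family_component(self):
        hits = [make_hit(label="L1MA4#LINE/L1"),
                make_hit(label="L1PA7#LINE/L1", start=300, end=400),
                make_hit(label="AluY#SINE/Alu")]
        groups = split_hits(hits, SplitMode.BY_TYPE)
        assert {k: len(g) for k, g in groups.items()} == {"LINE/L1": 2,
                                                          "SINE/Alu": 1}

    def test_by_type_without_family_labels_rejected(self):
        with pytest.raises(ConfigurationError):
            split_hits([make_hit(label="TE1")], SplitMode.BY_TYPE)

    def test_empty_input(self):
        assert split_hits([], SplitMode.BY_QUERY) == {}

    def test_partition_sums_to_input(self):
        rng = random.Random(5)
        hits = [make_hit(label=f"TE{rng.randint(1, 4)}",
                         start=i * 10 + 1, end=i * 10 + 6)
                for i in range(40)]
        groups = split_hits(hits, SplitMode.BY_QUERY)
        assert sum(len(g) for g in groups.values()) == len(hits)
        all_ids = [h.hit_id for g in groups.values() for h in g]
        assert sorted(all_ids) == sorted(h.hit_id for h in hits)
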