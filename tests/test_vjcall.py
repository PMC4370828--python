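"""Local V/J alignment, encompassing reads, couple counting and ranking."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ighclone.align import revcomp
from ighclone.germline import GermlineSet
from ighclone.partition import PairedRead
from ighclone.vjcall import (
    EncompassingRead,
    LocalAlignment,
    NoRearrangementError,
    VJCouple,
    aggregate_by_subgroup,
    align_local,
    count_vj_couples,
    find_encompassing_reads,
    main_clone,
    rpkm_like,
)
from tests.conftest import make_segment

_BASES = "ACGT"


def _rand_seq(rng, n):
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _hit(read_id, mate, segment, seg=(0, 30), read=(0, 30), score=30):
    return LocalAlignment(
        read_id=read_id,
        mate=mate,
        segment=segment,
        seg_start=seg[0],
        seg_end=seg[1],
        read_start=read[0],
        read_end=read[1],
        strand="+",
        identity=1.0,
        score=score,
    )


class TestAlignLocal:
    def test_prefix_match_full_identity(self):
        rng = np.random.default_rng(0)
        seg = _rand_seq(rng, 120)
        hits = align_local(seg[:40], {"IGHV1-1*01": seg})
        assert len(hits) == 1
        h = hits[0]
        assert (h.seg_start, h.seg_end, h.identity, h.strand) == (0, 40, 1.0, "+")

    def test_minus_strand_reported(self):
        rng = np.random.default_rng(1)
        seg = _rand_seq(rng, 100)
        hits = align_local(revcomp(seg[10:60]), {"IGHV1-1*01": seg})
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_sibling_alleles_both_hit_at_default_identity(self):
        """Alleles ~1 nt apart in the aligned span both report hits."""
        rng = np.random.default_rng(2)
        a = _rand_seq(rng, 100)
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        hits = align_local(a[20:80], {"IGHV1-1*01": a, "IGHV1-1*02": b}, min_identity=0.95)
        assert {h.segment for h in hits} == {"IGHV1-1*01", "IGHV1-1*02"}

    def test_short_common_stretch_below_min_length(self):
        rng = np.random.default_rng(3)
        seg = _rand_seq(rng, 80)
        mate = seg[30:45] + "A" * 40  # longest shared stretch 15 nt
        assert align_local(mate, {"IGHV1-1*01": seg}, min_length=20, k=12) == []

    def test_identity_threshold_filters(self):
        rng = np.random.default_rng(4)
        seg = _rand_seq(rng, 60)
        mate = list(seg)
        for i in range(14, 60, 15):
            mate[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mate[i]]
        assert align_local("".join(mate), {"IGHV1-1*01": seg}, min_identity=0.99) == []


class TestEncompassing:
    def _germline(self):
        rng = np.random.default_rng(5)
        self.v = _rand_seq(rng, 150)
        self.j = _rand_seq(rng, 60)
        v_set = GermlineSet.from_segments([make_segment("IGHV1-1*01", self.v)]).v_segments
        j_set = GermlineSet.from_segments([make_segment("IGHJ1*01", self.j)]).j_segments
        return v_set, j_set

    def test_v_and_j_on_opposite_mates(self):
        v_set, j_set = self._germline()
        pair = PairedRead("r1", self.v[:50], revcomp(self.j[:50]))
        recs = find_encompassing_reads([pair], v_set, j_set)
        assert len(recs) == 1
        assert recs[0].v_mate == 1 and {h.segment for h in recs[0].j_hits} == {"IGHJ1*01"}

    def test_both_mates_on_v_is_not_encompassing(self):
        v_set, j_set = self._germline()
        pair = PairedRead("r1", self.v[:50], revcomp(self.v[60:110]))
        assert find_encompassing_reads([pair], v_set, j_set) == []

    def test_multiple_v_hits_carried(self):
        rng = np.random.default_rng(6)
        v1 = _rand_seq(rng, 120)
        v2 = v1[:60] + ("A" if v1[60] != "A" else "C") + v1[61:]
        v_set = GermlineSet.from_segments(
            [make_segment("IGHV1-1*01", v1), make_segment("IGHV1-1*02", v2)]
        ).v_segments
        j = _rand_seq(rng, 60)
        j_set = GermlineSet.from_segments([make_segment("IGHJ1*01", j)]).j_segments
        pair = PairedRead("r1", v1[20:90], revcomp(j[:50]))
        recs = find_encompassing_reads([pair], v_set, j_set)
        assert len(recs) == 1
        assert {h.segment for h in recs[0].v_hits} == {"IGHV1-1*01", "IGHV1-1*02"}


class TestCoupleCounting:
    def test_same_couple_multiple_positions_counts_once(self):
        rec = EncompassingRead(
            read_id="r1",
            v_mate=1,
            v_hits=(
                _hit("r1", 1, "IGHV1-1*01", seg=(0, 30)),
                _hit("r1", 1, "IGHV1-1*01", seg=(40, 70)),
            ),
            j_hits=(_hit("r1", 2, "IGHJ1*01"),),
        )
        couples = count_vj_couples([rec])
        assert [(c.v_name, c.j_name, c.count) for c in couples] == [
            ("IGHV1-1*01", "IGHJ1*01", 1)
        ]

    def test_read_supporting_two_couples_counts_in_both(self):
        rec = EncompassingRead(
            read_id="r1",
            v_mate=1,
            v_hits=(_hit("r1", 1, "IGHV1-1*01"), _hit("r1", 1, "IGHV2-2*01")),
            j_hits=(_hit("r1", 2, "IGHJ1*01"),),
        )
        couples = count_vj_couples([rec])
        assert {(c.v_name, c.count) for c in couples} == {
            ("IGHV1-1*01", 1),
            ("IGHV2-2*01", 1),
        }

    def test_empty_input(self):
        assert count_vj_couples([]) == []

    def test_matches_bruteforce_enumeration(self):
        """Set-semantics counting equals triple enumeration + dedup."""
        rng = np.random.default_rng(8)
        v_names = [f"IGHV{i}-{i}*01" for i in range(1, 6)]
        j_names = [f"IGHJ{i}*01" for i in range(1, 4)]
        records = []
        for r in range(300):
            rid = f"r{rng.integers(0, 120)}"  # shared ids force deduplication
            v_hits = tuple(
                _hit(rid, 1, v_names[i])
                for i in set(rng.integers(0, 5, size=rng.integers(1, 4)))
            )
            j_hits = tuple(
                _hit(rid, 2, j_names[i])
                for i in set(rng.integers(0, 3, size=rng.integers(1, 3)))
            )
            records.append(
                EncompassingRead(read_id=rid, v_mate=1, v_hits=v_hits, j_hits=j_hits)
            )
        expected: dict[tuple[str, str], set[str]] = {}
        for rec in records:
            for vh in rec.v_hits:
                for jh in rec.j_hits:
                    expected.setdefault((vh.segment, jh.segment), set()).add(rec.read_id)
        got = {(c.v_name, c.j_name): set(c.supporting_reads) for c in count_vj_couples(records)}
        assert got == expected
        counts = [c.count for c in count_vj_couples(records)]
        assert counts == sorted(counts, reverse=True)


class TestRpkmLike:
    def test_exact_values(self):
        assert rpkm_like(0, 10) == 0.0
        assert rpkm_like(2, 10**6) == 2000.0

    def test_scaling_halves_scores_keeps_ranking(self):
        counts = [50, 20, 5]
        s1 = [rpkm_like(c, 10**6) for c in counts]
        s2 = [rpkm_like(c, 2 * 10**6) for c in counts]
        assert all(a == 2 * b for a, b in zip(s1, s2))
        assert sorted(s1, reverse=True) == s1 and sorted(s2, reverse=True) == s2

    def test_errors(self):
        with pytest.raises(ValueError):
            rpkm_like(1, 0)
        with pytest.raises(ValueError):
            rpkm_like(11, 10)


class TestSubgroupAggregation:
    def _couples(self):
        return [
            VJCouple("IGHV2-70*11", "IGHJ4*02", frozenset({"a", "b"})),
            VJCouple("IGHV2-70*01", "IGHJ4*02", frozenset({"b", "c"})),
            VJCouple("IGHV3-1*01", "IGHJ4*02", frozenset({"x"})),
        ]

    def test_union_merges_without_double_counting(self):
        agg = aggregate_by_subgroup(self._couples())
        top = agg[0]
        assert (top.v_name, top.j_name, top.count) == ("IGHV2", "IGHJ4", 3)

    def test_sum_mode_adds_allele_counts(self):
        agg = aggregate_by_subgroup(self._couples(), method="sum")
        assert agg[0].supporting_reads == frozenset({"a", "b", "c"})

    def test_distinct_subgroups_stay_separate(self):
        agg = aggregate_by_subgroup(self._couples())
        assert {(c.v_name, c.j_name) for c in agg} == {
            ("IGHV2", "IGHJ4"),
            ("IGHV3", "IGHJ4"),
        }

    def test_union_count_bounded_by_read_universe(self):
        agg = aggregate_by_subgroup(self._couples())
        universe = {"a", "b", "c", "x"}
        assert all(c.count <= len(universe) for c in agg)


class TestMainClone:
    def _couple(self, v, j, n):
        return VJCouple(v, j, frozenset(f"{v}{j}{i}" for i in range(n)))

    def test_ratio(self):
        couples = [
            self._couple("IGHV1-1*01", "IGHJ1*01", 10),
            self._couple("IGHV2-2*01", "IGHJ1*01", 4),
            self._couple("IGHV3-3*01", "IGHJ1*01", 1),
        ]
        call = main_clone(couples)
        assert call.couple.v_name == "IGHV1-1*01"
        assert call.ratio == 2.5 and not call.tie

    def test_single_couple_ratio_undefined(self):
        call = main_clone([self._couple("IGHV1-1*01", "IGHJ1*01", 3)])
        assert math.isinf(call.ratio)

    def test_tie_flagged_lexicographic_winner(self):
        couples = count_vj_couples(
            [
                EncompassingRead(
                    "r1", 1, (_hit("r1", 1, "IGHV2-2*01"),), (_hit("r1", 2, "IGHJ1*01"),)
                ),
                EncompassingRead(
                    "r2", 1, (_hit("r2", 1, "IGHV1-1*01"),), (_hit("r2", 2, "IGHJ1*01"),)
                ),
            ]
        )
        call = main_clone(couples)
        assert call.couple.v_name == "IGHV1-1*01" and call.tie

    def test_empty_raises(self):
        with pytest.raises(NoRearrangementError):
            main_clone([])
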