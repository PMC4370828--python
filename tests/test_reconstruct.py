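"""Virtual-reference assembly, scoring, junction annotation and coverage."""

from __future__ import annotations

import numpy as np
import pytest

from ighclone import run_analysis
from ighclone.partition import PairedRead
from ighclone.reconstruct import (
    AnnotationError,
    BridgingRead,
    ReconstructionError,
    VirtualReference,
    annotate_junctions,
    build_virtual_reference,
    classify_d_overlap,
    coverage_profile,
    dedupe_references,
    score_references,
)
from ighclone.simulate import truth_junctions
from ighclone.vjcall import LocalAlignment

_BASES = "ACGT"


def _rand_seq(rng, n):
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _aln(segment, seg, read, read_id="r1", mate=1):
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
        score=read[1] - read[0],
    )


@pytest.mark.parametrize(
    "a, b, case",
    [
        ((0, 6), (4, 9), "overlap"),
        ((0, 4), (6, 10), "non_overlap"),
        ((0, 4), (4, 8), "non_overlap"),  # abutting intervals do not intersect
    ],
)
def test_classify_d_overlap(a, b, case):
    assert classify_d_overlap(a, b) == case


class TestBuildVirtualReference:
    def test_overlap_case_recomposes_toy_transcript(self, toy_germline):
        """V=ACGTACGT, D=TTTT, J=CCCCCC with trims (2,1,1,2), n1=GG, n2=A:
        both mates cover the junctions; the reference equals the transcript."""
        tx = "ACGTACGGTTACCCC"
        read = BridgingRead(
            read_id="r1",
            v_mate_seq=tx,
            j_mate_seq=tx,
            v_hit=_aln("IGHV1-1*01", (0, 6), (0, 6)),
            d_hit_v_mate=_aln("IGHD1-1*01", (1, 3), (8, 10)),
            d_hit_j_mate=_aln("IGHD1-1*01", (1, 3), (8, 10), mate=2),
            j_hit=_aln("IGHJ1*01", (2, 6), (11, 15), mate=2),
            case="overlap",
        )
        ref = build_virtual_reference(read, toy_germline)
        assert ref.sequence == tx
        assert ref.span("VD_junction") == (6, 8)
        assert ref.span("DJ_junction") == (10, 11)

    def test_zero_length_junctions_give_plain_concatenation(self, toy_germline):
        tx = "ACGTACGT" + "TTTT" + "CCCCCC"
        read = BridgingRead(
            read_id="r1",
            v_mate_seq=tx,
            j_mate_seq=tx,
            v_hit=_aln("IGHV1-1*01", (0, 8), (0, 8)),
            d_hit_v_mate=_aln("IGHD1-1*01", (0, 4), (8, 12)),
            d_hit_j_mate=_aln("IGHD1-1*01", (0, 4), (8, 12), mate=2),
            j_hit=_aln("IGHJ1*01", (0, 6), (12, 18), mate=2),
            case="overlap",
        )
        ref = build_virtual_reference(read, toy_germline)
        assert ref.sequence == tx
        assert ref.span("VD_junction") == (8, 8)

    def test_non_overlap_interior_base_from_germline(self, toy_germline):
        """Mates covering D[0,2) and D[3,4): the interior base D[2:3] must
        come from the germline D sequence."""
        tx = "ACGTAC" + "GG" + "TTTT" + "A" + "CCCC"  # full D, trims (2,0,0,2)
        v_mate = tx[:10]  # ACGTACGGTT : V..D[0:2)
        j_mate = tx[11:]  # TACCCC    : D[3:4)..J
        read = BridgingRead(
            read_id="r1",
            v_mate_seq=v_mate,
            j_mate_seq=j_mate,
            v_hit=_aln("IGHV1-1*01", (0, 6), (0, 6)),
            d_hit_v_mate=_aln("IGHD1-1*01", (0, 2), (8, 10)),
            d_hit_j_mate=_aln("IGHD1-1*01", (3, 4), (0, 1), mate=2),
            j_hit=_aln("IGHJ1*01", (2, 6), (2, 6), mate=2),
            case="non_overlap",
        )
        ref = build_virtual_reference(read, toy_germline)
        assert ref.sequence == tx
        d_start, d_end = ref.span("D_part")
        assert ref.sequence[d_start:d_end] == "TTTT"

    def test_span_tiling_enforced(self):
        with pytest.raises(ValueError, match="tile"):
            VirtualReference(
                source_read_id="r1",
                sequence="ACGT",
                spans=(
                    ("V_part", 0, 2),
                    ("VD_junction", 3, 3),  # gap at position 2
                    ("D_part", 3, 4),
                    ("DJ_junction", 4, 4),
                    ("J_part", 4, 4),
                ),
                v_name="IGHV1-1*01",
                d_name="IGHD1-1*01",
                j_name="IGHJ1*01",
            )


class TestScoring:
    def _refs(self, rng):
        seq_a = _rand_seq(rng, 200)
        seq_b = _rand_seq(rng, 200)
        mk = lambda rid, seq: VirtualReference(
            source_read_id=rid,
            sequence=seq,
            spans=(
                ("V_part", 0, 100),
                ("VD_junction", 100, 102),
                ("D_part", 102, 120),
                ("DJ_junction", 120, 122),
                ("J_part", 122, 200),
            ),
            v_name="IGHV1-1*01",
            d_name="IGHD1-1*01",
            j_name="IGHJ1*01",
        )
        return mk("a", seq_a), mk("b", seq_b)

    def test_support_counts_pairs_and_sorts(self):
        rng = np.random.default_rng(0)
        ra, rb = self._refs(rng)
        pairs = [
            PairedRead("p1", ra.sequence[10:70], ra.sequence[100:160]),
            PairedRead("p2", ra.sequence[50:110], _rand_seq(rng, 60)),
            PairedRead("p3", _rand_seq(rng, 60), _rand_seq(rng, 60)),
        ]
        scored, alignments = score_references([ra, rb], pairs, total_reads=1000)
        by_id = {r.source_read_id: r for r in scored}
        assert by_id["a"].support == 2
        assert by_id["b"].support == 0 and by_id["b"].score == 0.0
        assert by_id["a"].score == 2 / 1000 * 1e9
        assert scored[0].source_read_id == "a"
        assert len(alignments["a"]) >= 2

    def test_no_references_raises(self):
        with pytest.raises(ReconstructionError):
            score_references([], [], total_reads=10)

    def test_dedupe_keeps_smallest_source_id(self):
        rng = np.random.default_rng(1)
        ra, rb = self._refs(rng)
        import dataclasses

        dup = dataclasses.replace(ra, source_read_id="z")
        kept = dedupe_references([dup, ra, rb])
        assert [r.source_read_id for r in kept] == ["a", "b"]


class TestAnnotateJunctions:
    def test_identity_case(self, toy_germline):
        v = "ACGTACGTACGTACGTACGT"
        d = "TTTTTTTTTT"
        j = "CCCCCCCCCCCCCCCC"
        ann = annotate_junctions(v + d + j, v, d, j)
        assert (ann.deleted_v3, ann.deleted_d5, ann.deleted_d3, ann.deleted_j5) == (0, 0, 0, 0)
        assert ann.inserted_vd == "" and ann.inserted_dj == ""

    def test_matches_simulator_truth_across_seeds(self, synthetic_germline):
        """Two independent canonical-parse implementations agree on the
        truth transcripts, and the annotation invariant recomposes."""
        from ighclone.simulate import SimulationConfig, simulate_rearrangement

        cfg = SimulationConfig()
        for seed in range(20):
            ev = simulate_rearrangement(synthetic_germline, cfg, np.random.default_rng(seed))
            v = synthetic_germline.get(ev.v_name).sequence
            d = synthetic_germline.get(ev.d_name).sequence
            j = synthetic_germline.get(ev.j_name).sequence
            ann = annotate_junctions(ev.transcript, v, d, j)
            truth = truth_junctions(ev, synthetic_germline)
            assert ann.deleted_v3 == truth["deleted_v3"]
            assert ann.deleted_d5 == truth["deleted_d5"]
            assert ann.deleted_d3 == truth["deleted_d3"]
            assert ann.deleted_j5 == truth["deleted_j5"]
            assert ann.inserted_vd == truth["inserted_vd"]
            assert ann.inserted_dj == truth["inserted_dj"]
            assert ann.reassemble(v, d, j) == ev.transcript

    def test_unrecognizable_anchor_raises(self):
        rng = np.random.default_rng(5)
        v, d, j = _rand_seq(rng, 60), _rand_seq(rng, 20), _rand_seq(rng, 40)
        with pytest.raises(AnnotationError, match="anchor"):
            annotate_junctions(_rand_seq(rng, 120), v, d, j)


class TestCoverage:
    def _ref(self):
        return VirtualReference(
            source_read_id="r1",
            sequence="A" * 50,
            spans=(
                ("V_part", 0, 20),
                ("VD_junction", 20, 22),
                ("D_part", 22, 30),
                ("DJ_junction", 30, 32),
                ("J_part", 32, 50),
            ),
            v_name="IGHV1-1*01",
            d_name="IGHD1-1*01",
            j_name="IGHJ1*01",
        )

    def test_no_reads_gives_zero_track(self):
        depth = coverage_profile(self._ref(), [])
        assert depth.shape == (50,) and not depth.any()

    def test_depth_sums_to_aligned_bases(self):
        hits = [_aln("r1", (0, 30), (0, 30)), _aln("r1", (10, 50), (0, 40))]
        depth = coverage_profile(self._ref(), hits)
        assert depth.sum() == 30 + 40
        assert depth[0] == 1 and depth[15] == 2 and depth[45] == 1


def test_round_trip_from_simulation(small_sample, synthetic_germline):
    """End-to-end: the top reference equals the simulated transcript and its
    annotation reproduces the canonical truth, at error rate 0."""
    res = run_analysis(small_sample.pairs, synthetic_germline)
    truth_event = small_sample.main_event
    assert res.main_reference is not None, res.reconstruction_failure
    assert res.main_reference.sequence == truth_event.transcript
    truth = truth_junctions(truth_event, synthetic_germline)
    ann = res.annotation
    assert ann is not None
    assert ann.deleted_v3 == truth["deleted_v3"]
    assert ann.deleted_j5 == truth["deleted_j5"]
    assert len(ann.inserted_vd) == len(truth["inserted_vd"])
    assert len(ann.inserted_dj) == len(truth["inserted_dj"])
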