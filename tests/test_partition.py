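"""Mismatch-bounded end-to-end mapping and read-pair partitioning."""

from __future__ import annotations

import numpy as np
import pytest

from ighclone.align import UngappedAligner, align_ungapped, revcomp
from ighclone.partition import (
    PairedRead,
    ingest_sam,
    partition_reads,
    whole_reference_locus,
)

_BASES = "ACGT"


def _rand_seq(rng, n):
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def test_exact_hit_reported_at_position():
    rng = np.random.default_rng(0)
    ref = _rand_seq(rng, 400)
    mate = ref[137:197]
    res = align_ungapped(mate, {"chrA": ref})
    assert not res.suppressed
    assert [(h.target, h.start, h.strand, h.mismatches) for h in res.hits] == [
        ("chrA", 137, "+", 0)
    ]


def test_reverse_strand_hit():
    rng = np.random.default_rng(1)
    ref = _rand_seq(rng, 300)
    mate = revcomp(ref[50:110])
    res = align_ungapped(mate, {"chrA": ref})
    assert [(h.start, h.strand) for h in res.hits] == [(50, "-")]


def test_too_many_mismatches_reports_nothing():
    rng = np.random.default_rng(2)
    ref = _rand_seq(rng, 200)
    mate = list(ref[60:120])
    for pos in (5, 25, 45):  # 3 substitutions > max_mismatches=2
        mate[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mate[pos]]
    res = align_ungapped("".join(mate), {"chrA": ref}, max_mismatches=2)
    assert res.hits == () and not res.suppressed


def test_best_stratum_excludes_worse_placements():
    rng = np.random.default_rng(3)
    mate = _rand_seq(rng, 40)
    near = mate[:10] + ("A" if mate[10] != "A" else "C") + mate[11:]
    ref = {"exact": _rand_seq(rng, 20) + mate + _rand_seq(rng, 20), "near": "G" * 15 + near + "G" * 15}
    res = align_ungapped(mate, ref)
    assert {h.target for h in res.hits} == {"exact"}
    assert all(h.mismatches == 0 for h in res.hits)


def test_excess_placements_are_suppressed():
    rng = np.random.default_rng(4)
    unit = _rand_seq(rng, 30)
    res = align_ungapped(unit, {"tandem": unit * 11})
    assert res.suppressed and res.hits == ()
    res10 = align_ungapped(unit, {"tandem": unit * 10})
    assert not res10.suppressed and len(res10.hits) == 10


def test_empty_reference_rejected():
    with pytest.raises(ValueError):
        UngappedAligner({})


def _sliding_window_oracle(mate, reference, max_mismatches, max_report):
    """Exhaustive placement scan (independent of the pigeonhole path)."""
    found = []
    arr_mate = {
        "+": np.frombuffer(mate.encode(), dtype=np.uint8),
        "-": np.frombuffer(revcomp(mate).encode(), dtype=np.uint8),
    }
    for name, seq in sorted(reference.items()):
        if len(seq) < len(mate):
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, len(mate))
        for strand in ("+", "-"):
            mm = (windows != arr_mate[strand]).sum(axis=1)
            for pos in np.nonzero(mm <= max_mismatches)[0]:
                found.append((name, int(pos), strand, int(mm[pos])))
    if not found:
        return set(), False
    best = min(f[3] for f in found)
    stratum = sorted((n, p, s) for n, p, s, m in found if m == best)
    if len(stratum) > max_report:
        return set(), True
    return set(stratum), False


def test_pigeonhole_matches_sliding_window_oracle():
    rng = np.random.default_rng(7)
    ref = {"chr1": _rand_seq(rng, 2000), "chr2": _rand_seq(rng, 1500)}
    aligner = UngappedAligner(ref, max_mismatches=2, max_report=10)
    mates = []
    for _ in range(15):  # planted with 0-3 substitutions, both strands
        src = ref["chr1"] if rng.random() < 0.5 else ref["chr2"]
        pos = int(rng.integers(0, len(src) - 50))
        m = list(src[pos : pos + 50])
        for _ in range(int(rng.integers(0, 4))):
            i = int(rng.integers(0, 50))
            m[i] = _BASES[int(rng.integers(0, 4))]
        mate = "".join(m)
        mates.append(mate if rng.random() < 0.5 else revcomp(mate))
    mates.extend(_rand_seq(rng, 50) for _ in range(5))
    for mate in mates:
        got = aligner.map_mate(mate)
        exp_hits, exp_sup = _sliding_window_oracle(mate, ref, 2, 10)
        assert got.suppressed == exp_sup
        assert {(h.target, h.start, h.strand) for h in got.hits} == exp_hits


def _pair(read_id, m1, m2):
    return PairedRead(read_id=read_id, mate1_seq=m1, mate2_seq=m2)


def test_partition_classes_and_totality():
    rng = np.random.default_rng(9)
    locus_seq = _rand_seq(rng, 500)
    decoy_seq = _rand_seq(rng, 500)
    reference = {"locus": locus_seq, "decoy": decoy_seq}
    locus = [("locus", 0, 500)]
    pairs = [
        _pair("unmappable", _rand_seq(rng, 60), _rand_seq(rng, 60)),
        _pair("in_locus", locus_seq[10:70], revcomp(locus_seq[100:160])),
        _pair("off_locus", decoy_seq[10:70], revcomp(decoy_seq[200:260])),
        _pair("half", locus_seq[30:90], _rand_seq(rng, 60)),
    ]
    result = partition_reads(pairs, reference, locus)
    assert result.vdj_unmapped == {"unmappable"}
    assert result.vdj_mapped == {"in_locus", "half"}
    assert result.discarded == {"off_locus"}
    result.assert_total({p.read_id for p in pairs})


def test_one_unaligned_mate_flag():
    rng = np.random.default_rng(10)
    seq = _rand_seq(rng, 300)
    pairs = [_pair("half", seq[0:60], _rand_seq(rng, 60))]
    strict = partition_reads(pairs, {"locus": seq}, [("locus", 0, 300)])
    relaxed = partition_reads(
        pairs, {"locus": seq}, [("locus", 0, 300)], require_both_unaligned=False
    )
    assert strict.vdj_mapped == {"half"}
    assert relaxed.vdj_unmapped == {"half"}


def test_simulated_junction_pairs_land_in_unmapped(small_sample, synthetic_germline):
    """Error-free pairs whose mates both straddle a V(D)J boundary cannot be
    placed end-to-end on the germline and must join the unmapped dataset.
    (Pairs are exempt when a mate's junction overhang happens to match the
    germline continuation within the mismatch bound, so the check uses a
    generous 12 nt overhang.)"""
    reference = synthetic_germline.sequences()
    result = partition_reads(
        [p for p in small_sample.pairs], reference, whole_reference_locus(reference)
    )
    events = dict(small_sample.events)
    checked = 0
    for truth in small_sample.truth:
        ev = events[truth.clone_label]
        g = synthetic_germline
        v_part = len(g.get(ev.v_name).sequence) - ev.trim_v3
        j_start = len(ev.transcript) - (
            len(g.get(ev.j_name).sequence) - ev.trim_j5
        )
        m1 = (truth.fragment_start, truth.fragment_start + 100)
        m2 = (truth.fragment_end - 100, truth.fragment_end)

        def straddles(iv):
            return (iv[0] + 12 <= v_part <= iv[1] - 12) or (
                iv[0] + 12 <= j_start <= iv[1] - 12
            )
        if straddles(m1) and straddles(m2):
            checked += 1
            assert truth.read_id in result.vdj_unmapped
    assert checked > 10


def _write_sam(path, records):
    header = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:locus\tLN:1000\n"
    path.write_text(header + "".join(records))


def test_ingest_sam_classification(tmp_path, recwarn):
    sam = tmp_path / "aln.sam"
    seq = "A" * 50
    rows = [
        # both mates unmapped -> vdj_unmapped
        f"u\t77\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n",
        f"u\t141\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n",
        # mate overlapping the locus [100, 200) by exactly one base -> mapped
        f"m\t99\tlocus\t52\t60\t50M\t=\t300\t0\t{seq}\t*\n",  # 0-based [51,101)
        f"m\t147\tlocus\t301\t60\t50M\t=\t52\t0\t{seq}\t*\n",
        # mate aligned entirely before the locus -> discarded
        f"d\t99\tlocus\t10\t60\t50M\t=\t10\t0\t{seq}\t*\n",
        f"d\t147\tlocus\t10\t60\t50M\t=\t10\t0\t{seq}\t*\n",
        # unpaired record -> discarded with a warning
        f"solo\t73\tlocus\t500\t60\t50M\t*\t0\t0\t{seq}\t*\n",
    ]
    _write_sam(sam, rows)
    result = ingest_sam(sam, [("locus", 100, 200)])
    assert result.vdj_unmapped == {"u"}
    assert result.vdj_mapped == {"m"}
    assert result.discarded == {"d", "solo"}
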