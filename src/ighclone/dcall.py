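"""D allele identification for the most supported VJ couples.

Diversity segments are short and heavily polymorphic, so the D call uses a
stricter contract than the VJ stage: only mates of encompassing reads that
are *not fully explained* by their V or J alignment are considered, a hit
requires a perfect seed of at least 10 nt shared between mate and D
segment, and each mate reports at most one alignment.  Per couple, the D
segment supported by the most mates wins (lexicographic tie-break, flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .align import KmerIndex, best_on_diagonal, revcomp
from .germline import GeneSegment
from .partition import PairedRead
from .vjcall import EncompassingRead, LocalAlignment, VJCouple


@dataclass
class PipelineConfig:
    """Stage parameters shared across the pipeline.

    Defaults: 2 mismatches / 10 reported placements for the end-to-end
    partitioning mapper, a 10 nt minimum perfect seed and one reported
    alignment per mate for the D stage, identity 0.95 over >= 20 nt for
    local V/J hits, and a reporting depth of 5 clones.
    """

    max_mismatches: int = 2
    max_report: int = 10
    min_seed: int = 10
    top_n_couples: int = 5
    min_identity: float = 0.95
    min_length: int = 20
    kmer: int = 12
    total_reads: int | None = None
    seed: int = 0
    subgroup_method: str = "union"
    require_both_unaligned: bool = True

    def __post_init__(self) -> None:
        for name in ("max_mismatches", "max_report", "min_seed", "top_n_couples",
                     "min_length", "kmer"):
            if getattr(self, name) < 1 and name != "max_mismatches":
                raise ValueError(f"{name} must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


class DFlag(str, Enum):
    ASSIGNED = "assigned"
    NO_D_EVIDENCE = "no_d_evidence"
    TIE = "tie"


@dataclass
class Clone:
    """A VJ couple together with its D assignment."""

    vj: VJCouple
    d_name: str | None
    d_support: dict[str, int] = field(default_factory=dict)
    d_flag: DFlag = DFlag.NO_D_EVIDENCE


@dataclass(frozen=True)
class PartialMate:
    """A mate of an encompassing read not fully covered by its V/J hit."""

    read_id: str
    mate: int
    seq: str


def select_partial_mates(
    encompassing: Iterable[EncompassingRead],
    pairs_by_id: Mapping[str, PairedRead],
) -> list[PartialMate]:
    """Mates whose best V/J local alignment leaves an uncovered flank.

    Coverage is taken as the longest aligned span among the mate's recorded
    V/J hits (across all role assignments of the read); a mate is selected
    when that span is strictly shorter than the mate, i.e. at least one
    flanking nucleotide is unexplained.
    """
    coverage: dict[tuple[str, int], int] = {}
    for rec in encompassing:
        for hit in rec.v_hits + rec.j_hits:
            key = (rec.read_id, hit.mate)
            coverage[key] = max(coverage.get(key, 0), hit.length)
    out = []
    for (read_id, mate), covered in sorted(coverage.items()):
        seq = pairs_by_id[read_id].mate(mate)
        if covered < len(seq):
            out.append(PartialMate(read_id=read_id, mate=mate, seq=seq))
    return out


class SeededDAligner:
    """Seeded single-hit aligner against the D segment set.

    A hit exists iff mate and segment share an exact substring of at least
    ``min_seed`` nt on either strand (found via an exact ``min_seed``-mer
    index, which is equivalent: any exact run of length >= min_seed contains
    such a k-mer).  Candidates are extended ungapped (+1/-1) along their
    diagonal; the single best-scoring extension is reported, ties broken
    lexicographically on segment name, then '+' strand, then 5'-most
    placement.
    """

    def __init__(self, d_set: Mapping[str, GeneSegment] | Mapping[str, str], min_seed: int = 10):
        seqs = {
            name: (seg.sequence if isinstance(seg, GeneSegment) else seg)
            for name, seg in d_set.items()
        }
        if not seqs:
            raise ValueError("empty D segment set")
        self.min_seed = min_seed
        self.index = KmerIndex(seqs, min_seed)

    def align(self, mate_seq: str, read_id: str = "", mate: int = 0) -> LocalAlignment | None:
        mate_seq = mate_seq.upper()
        best: tuple[tuple, LocalAlignment] | None = None
        for strand in ("+", "-"):
            oriented = mate_seq if strand == "+" else revcomp(mate_seq)
            for segment, diag in sorted(self.index.diagonals(oriented)):
                hit = best_on_diagonal(oriented, self.index.seqs[segment], diag)
                if hit is None:
                    continue
                rank = (-hit.score, segment, strand, hit.t_start, hit.q_start)
                if best is None or rank < best[0]:
                    best = (
                        rank,
                        LocalAlignment(
                            read_id=read_id,
                            mate=mate,
                            segment=segment,
                            seg_start=hit.t_start,
                            seg_end=hit.t_end,
                            read_start=hit.q_start,
                            read_end=hit.q_end,
                            strand=strand,
                            identity=hit.identity,
                            score=hit.score,
                        ),
                    )
        return None if best is None else best[1]


def align_seeded(
    mate: str,
    d_set: Mapping[str, GeneSegment] | Mapping[str, str],
    min_seed: int = 10,
) -> LocalAlignment | None:
    """One-shot convenience wrapper around :class:`SeededDAligner`."""
    return SeededDAligner(d_set, min_seed).align(mate)


def assign_d(
    couple: VJCouple,
    partial_mates: Sequence[PartialMate],
    d_set: Mapping[str, GeneSegment] | Mapping[str, str],
    min_seed: int = 10,
    aligner: SeededDAligner | None = None,
    d_hits: Mapping[tuple[str, int], LocalAlignment | None] | None = None,
) -> Clone:
    """Pick the D segment most supported by the couple's partial mates.

    Each partial mate belonging to one of the couple's supporting reads
    contributes one unit to its (single) reported D segment.  The argmax is
    assigned; an exact support tie resolves to the lexicographically
    smaller name and is flagged.
    """
    if aligner is None and d_hits is None:
        aligner = SeededDAligner(d_set, min_seed)
    support: dict[str, int] = {}
    for pm in partial_mates:
        if pm.read_id not in couple.supporting_reads:
            continue
        if d_hits is not None:
            hit = d_hits.get((pm.read_id, pm.mate))
        else:
            hit = aligner.align(pm.seq, pm.read_id, pm.mate)
        if hit is not None:
            support[hit.segment] = support.get(hit.segment, 0) + 1
    if not support:
        return Clone(vj=couple, d_name=None, d_support={}, d_flag=DFlag.NO_D_EVIDENCE)
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    top_name, top_count = ranked[0]
    tie = len(ranked) > 1 and ranked[1][1] == top_count
    return Clone(
        vj=couple,
        d_name=top_name,
        d_support=dict(sorted(support.items())),
        d_flag=DFlag.TIE if tie else DFlag.ASSIGNED,
    )
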