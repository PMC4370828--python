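"""VJ couple detection, counting, ranking and subgroup aggregation.

A *VJ encompassing read* is a pair with one mate locally aligned on a V
segment and the other on a J segment; it is the unit of clone
quantification.  Couples are counted with two deduplication rules: a read
supporting the same couple at several positions counts once (homology
inside a segment must not inflate support), while a read supporting several
couples counts once for each (polymorphism across alleles makes the correct
assignment undecidable at this stage).  Counts are normalized by a
coverage-independent RPKM-like score — supporting reads over total reads
times 1e9, with no per-length normalization because V/D/J spans are
comparable to or shorter than a single mate — and can be aggregated from
allele to subgroup level, where monoclonality is assessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .align import KmerIndex, best_on_diagonal, revcomp
from .germline import GeneSegment, parse_segment_name
from .partition import PairedRead


@dataclass(frozen=True)
class LocalAlignment:
    """A local (ungapped) placement of one mate on one segment.

    ``read_start``/``read_end`` refer to the mate *as oriented by strand*:
    for a ``-`` hit they index the reverse complement of the stored mate
    sequence.  All intervals are 0-based half-open.
    """

    read_id: str
    mate: int
    segment: str
    seg_start: int
    seg_end: int
    read_start: int
    read_end: int
    strand: str
    identity: float
    score: int

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


class LocalAligner:
    """k-mer-seeded ungapped local aligner against a segment set.

    Candidate (segment, diagonal) pairs are seeded by exact k-mers on both
    strands; each candidate diagonal is scanned for its max-scoring
    (+1 match / -1 mismatch) stretch.  The best-scoring placement per
    (mate, segment) is retained and then filtered by identity and aligned
    length.  The defaults (identity >= 0.95 over >= 20 nt, k = 12) resolve
    alleles down to ~1 % divergence while still reporting hits on both
    members of a 98-99 % allele pair, which is the behaviour the couple
    deduplication rules expect.
    """

    def __init__(
        self,
        segments: Mapping[str, GeneSegment] | Mapping[str, str],
        min_identity: float = 0.95,
        min_length: int = 20,
        k: int = 12,
    ):
        seqs = {
            name: (seg.sequence if isinstance(seg, GeneSegment) else seg)
            for name, seg in segments.items()
        }
        if not seqs:
            raise ValueError("empty segment set")
        self.min_identity = min_identity
        self.min_length = min_length
        self.index = KmerIndex(seqs, k)

    def align(self, mate_seq: str, read_id: str = "", mate: int = 0) -> list[LocalAlignment]:
        mate_seq = mate_seq.upper()
        best: dict[str, tuple[tuple, LocalAlignment]] = {}
        for strand in ("+", "-"):
            oriented = mate_seq if strand == "+" else revcomp(mate_seq)
            for segment, diag in sorted(self.index.diagonals(oriented)):
                hit = best_on_diagonal(oriented, self.index.seqs[segment], diag)
                if hit is None:
                    continue
                # Deterministic preference: score, then '+' strand, then
                # 5'-most placement on the segment.
                rank = (-hit.score, strand, hit.t_start, hit.q_start)
                aln = LocalAlignment(
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
                )
                if segment not in best or rank < best[segment][0]:
                    best[segment] = (rank, aln)
        return [
            aln
            for _, aln in (best[seg] for seg in sorted(best))
            if aln.length >= self.min_length and aln.identity >= self.min_identity
        ]


def align_local(
    mate: str,
    segments: Mapping[str, GeneSegment] | Mapping[str, str],
    min_identity: float = 0.95,
    min_length: int = 20,
    k: int = 12,
) -> list[LocalAlignment]:
    """One-shot convenience wrapper around :class:`LocalAligner`."""
    return LocalAligner(segments, min_identity, min_length, k).align(mate)


@dataclass(frozen=True)
class EncompassingRead:
    """A pair with one mate on V and the other on J (one role assignment).

    When both mates hit both segment types, both valid role assignments are
    emitted as separate records; read-level set semantics downstream keep
    the couple counts honest.
    """

    read_id: str
    v_mate: int
    v_hits: tuple[LocalAlignment, ...]
    j_hits: tuple[LocalAlignment, ...]

    def __post_init__(self) -> None:
        if not self.v_hits or not self.j_hits:
            raise ValueError("encompassing read requires V and J hits")
        if any(h.mate != self.v_mate for h in self.v_hits) or any(
            h.mate == self.v_mate for h in self.j_hits
        ):
            raise ValueError("V and J hits must come from different mates")

    @property
    def j_mate(self) -> int:
        return 3 - self.v_mate


def find_encompassing_reads(
    pairs: Sequence[PairedRead],
    v_set: Mapping[str, GeneSegment],
    j_set: Mapping[str, GeneSegment],
    min_identity: float = 0.95,
    min_length: int = 20,
    k: int = 12,
) -> list[EncompassingRead]:
    """Detect VJ encompassing pairs by local alignment on V and J sets.

    Mates may be totally or partially covered by their segment hit.  A role
    assignment (which mate is the V mate) is valid when that mate has >= 1 V
    hit and the other has >= 1 J hit; every valid assignment is emitted.
    """
    v_aligner = LocalAligner(v_set, min_identity, min_length, k)
    j_aligner = LocalAligner(j_set, min_identity, min_length, k)
    records: list[EncompassingRead] = []
    for pair in pairs:
        v_hits = {
            m: tuple(v_aligner.align(pair.mate(m), pair.read_id, m)) for m in (1, 2)
        }
        j_hits = {
            m: tuple(j_aligner.align(pair.mate(m), pair.read_id, m)) for m in (1, 2)
        }
        for v_mate in (1, 2):
            if v_hits[v_mate] and j_hits[3 - v_mate]:
                records.append(
                    EncompassingRead(
                        read_id=pair.read_id,
                        v_mate=v_mate,
                        v_hits=v_hits[v_mate],
                        j_hits=j_hits[3 - v_mate],
                    )
                )
    records.sort(key=lambda r: (r.read_id, r.v_mate))
    return records


@dataclass(frozen=True)
class VJCouple:
    """A (V, J) rearrangement with its supporting-read set and score.

    At allele level the labels are formatted allele names; after subgroup
    aggregation they are subgroup tokens (e.g. ``IGHV2``).
    """

    v_name: str
    j_name: str
    supporting_reads: frozenset[str]
    score: float = 0.0
    tie: bool = False

    @property
    def count(self) -> int:
        return len(self.supporting_reads)


def rpkm_like(count: int, total_reads: int) -> float:
    """Coverage-independent clone score: ``count / total_reads * 1e9``.

    The usual per-length normalization is deliberately absent: V, D and J
    spans are comparable to (or shorter than) one mate, so dividing by them
    would distort comparisons between clones.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if count < 0 or count > total_reads:
        raise ValueError("count must be within [0, total_reads]")
    return count / total_reads * 1e9


def count_vj_couples(
    encompassing: Iterable[EncompassingRead],
    total_reads: int | None = None,
) -> list[VJCouple]:
    """Count supporting reads per VJ couple under the deduplication rules.

    Set semantics enforce once-per-read counting within a couple; a read
    implying several couples contributes to each.  Output is sorted by count
    descending, ties broken lexicographically on (v_name, j_name).
    """
    support: dict[tuple[str, str], set[str]] = {}
    for rec in encompassing:
        for v_hit in rec.v_hits:
            for j_hit in rec.j_hits:
                support.setdefault((v_hit.segment, j_hit.segment), set()).add(rec.read_id)
    couples = [
        VJCouple(
            v_name=v,
            j_name=j,
            supporting_reads=frozenset(reads),
            score=rpkm_like(len(reads), total_reads) if total_reads else 0.0,
        )
        for (v, j), reads in support.items()
    ]
    couples.sort(key=lambda c: (-c.count, c.v_name, c.j_name))
    return couples


def _subgroup(label: str) -> str:
    return parse_segment_name(label).subgroup


def aggregate_by_subgroup(
    couples: Sequence[VJCouple],
    total_reads: int | None = None,
    method: str = "union",
) -> list[VJCouple]:
    """Merge couples sharing (V subgroup, J subgroup).

    ``union`` (default) takes the union of supporting-read sets, so a read
    multimapping across alleles of a subgroup is never double-counted;
    ``sum`` adds allele-level counts instead (available for comparison).
    """
    if method not in ("union", "sum"):
        raise ValueError("method must be 'union' or 'sum'")
    merged: dict[tuple[str, str], set[str]] = {}
    sums: dict[tuple[str, str], int] = {}
    for c in couples:
        key = (_subgroup(c.v_name), _subgroup(c.j_name))
        merged.setdefault(key, set()).update(c.supporting_reads)
        sums[key] = sums.get(key, 0) + c.count
    out = []
    for (v_sub, j_sub), reads in merged.items():
        count = len(reads) if method == "union" else sums[(v_sub, j_sub)]
        out.append(
            VJCouple(
                v_name=v_sub,
                j_name=j_sub,
                supporting_reads=frozenset(reads),
                score=rpkm_like(count, total_reads) if total_reads else 0.0,
            )
        )
    if method == "union":
        out.sort(key=lambda c: (-c.count, c.v_name, c.j_name))
    else:
        out.sort(key=lambda c: (-sums[(c.v_name, c.j_name)], c.v_name, c.j_name))
    return out


@dataclass(frozen=True)
class MainCloneCall:
    """Top-ranked couple with the top-1/top-2 monoclonality ratio."""

    couple: VJCouple
    ratio: float  # inf when there is no second couple
    tie: bool


class NoRearrangementError(RuntimeError):
    pass


def main_clone(couples: Sequence[VJCouple]) -> MainCloneCall:
    """Return the most supported couple and the monoclonality statistic.

    The couple list must already be sorted (as produced by
    :func:`count_vj_couples` / :func:`aggregate_by_subgroup`); ties at the
    top resolve to the lexicographically smaller (v, j) and are flagged.
    """
    if not couples:
        raise NoRearrangementError("no rearrangement detected")
    top = couples[0]
    if len(couples) == 1:
        return MainCloneCall(couple=top, ratio=math.inf, tie=False)
    second = couples[1]
    tie = second.count == top.count
    ratio = top.count / second.count if second.count else math.inf
    return MainCloneCall(couple=replace(top, tie=tie), ratio=ratio, tie=tie)
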