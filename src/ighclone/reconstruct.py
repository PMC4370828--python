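"""Main-clone sequence reconstruction from junction-bridging read pairs.

A *bridging read* is an encompassing pair whose two mates both carry a hit
on the rearranged D segment: one mate spans the VD junction, the other the
DJ junction.  From each bridging read a *virtual reference* is assembled:
read-derived bases across the junctions and the D remnant (germline-filled
between the mates when their D intervals do not overlap), extended outward
through the full germline V and J sequences.  Virtual references are then
scored by re-mapping the initially VDJ-unmapped reads onto them with the
RPKM-like measure, the top-scoring reference is taken as the main-clone
sequence, and its junctions are annotated against the naive germline
concatenation (deleted counts per boundary, inserted strings per junction;
N and P additions are reported together, undistinguished).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import KmerIndex, best_on_diagonal, common_prefix_len, common_suffix_len, revcomp
from .dcall import Clone
from .germline import GermlineSet
from .partition import PairedRead
from .vjcall import EncompassingRead, LocalAlignment, LocalAligner, rpkm_like

logger = logging.getLogger(__name__)

SPAN_LABELS = ("V_part", "VD_junction", "D_part", "DJ_junction", "J_part")


class ReconstructionError(RuntimeError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class VirtualReference:
    """A candidate main-clone sequence with labeled spans.

    ``spans`` tiles the sequence with the five labeled intervals in fixed
    order (junction spans may be empty).
    """

    source_read_id: str
    sequence: str
    spans: tuple[tuple[str, int, int], ...]
    v_name: str
    d_name: str
    j_name: str
    support: int = 0
    score: float = 0.0
    tie: bool = False

    def __post_init__(self) -> None:
        labels = tuple(label for label, _, _ in self.spans)
        if labels != SPAN_LABELS:
            raise ValueError(f"spans must be labeled {SPAN_LABELS}, got {labels}")
        cursor = 0
        for label, start, end in self.spans:
            if start != cursor or end < start:
                raise ValueError(f"spans do not tile the sequence at {label}")
            cursor = end
        if cursor != len(self.sequence):
            raise ValueError("spans do not cover the full sequence")

    def span(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.spans:
            if lab == label:
                return start, end
        raise KeyError(label)


@dataclass(frozen=True)
class JunctionAnnotation:
    """Junction edits relative to naive V+D+J concatenation.

    The reconstruction invariant holds by construction:
    ``V[:-deleted_v3] + inserted_vd + D[deleted_d5:len(D)-deleted_d3] +
    inserted_dj + J[deleted_j5:]`` equals the annotated sequence.
    """

    inserted_vd: str
    inserted_dj: str
    deleted_v3: int
    deleted_d5: int
    deleted_d3: int
    deleted_j5: int

    def reassemble(self, v_seq: str, d_seq: str, j_seq: str) -> str:
        return (
            v_seq[: len(v_seq) - self.deleted_v3]
            + self.inserted_vd
            + d_seq[self.deleted_d5 : len(d_seq) - self.deleted_d3]
            + self.inserted_dj
            + j_seq[self.deleted_j5 :]
        )


@dataclass(frozen=True)
class BridgingRead:
    """An encompassing read whose two mates both hit the rearranged D.

    Mate sequences are stored in transcript (sense) orientation; all hit
    coordinates refer to these oriented sequences.
    """

    read_id: str
    v_mate_seq: str
    j_mate_seq: str
    v_hit: LocalAlignment
    d_hit_v_mate: LocalAlignment
    d_hit_j_mate: LocalAlignment
    j_hit: LocalAlignment
    case: str  # "overlap" | "non_overlap"


def classify_d_overlap(
    interval_a: tuple[int, int], interval_b: tuple[int, int]
) -> str:
    """Overlap case iff the two mates' D intervals intersect."""
    (a1, b1), (a2, b2) = interval_a, interval_b
    return "overlap" if a2 < b1 and a1 < b2 else "non_overlap"


def _forward_seeded(seq: str, index: KmerIndex, read_id: str, mate: int) -> LocalAlignment | None:
    """Single-strand seeded alignment of an oriented mate on one D segment."""
    best: tuple[tuple, LocalAlignment] | None = None
    for segment, diag in sorted(index.diagonals(seq)):
        hit = best_on_diagonal(seq, index.seqs[segment], diag)
        if hit is None:
            continue
        rank = (-hit.score, segment, hit.t_start, hit.q_start)
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
                    strand="+",
                    identity=hit.identity,
                    score=hit.score,
                ),
            )
    return None if best is None else best[1]


def _best_named_hit(hits: Sequence[LocalAlignment], name: str) -> LocalAlignment | None:
    named = [h for h in hits if h.segment == name]
    if not named:
        return None
    return min(named, key=lambda h: (-h.score, h.strand, h.seg_start, h.read_start))


def _trim_left(aln: LocalAlignment, new_read_start: int) -> LocalAlignment:
    """Move the alignment's left edge right (attribution overlap resolution).

    Identity/score are left stale on purpose: the trimmed hit is only used
    for coordinate arithmetic during reference assembly.
    """
    shift = new_read_start - aln.read_start
    return replace(aln, read_start=new_read_start, seg_start=aln.seg_start + shift)


def _trim_right(aln: LocalAlignment, new_read_end: int) -> LocalAlignment:
    shift = aln.read_end - new_read_end
    return replace(aln, read_end=new_read_end, seg_end=aln.seg_end - shift)


def refine_segment_allele(
    encompassing: Iterable[EncompassingRead],
    supporting_reads: frozenset[str] | set[str],
    candidate_alleles: Sequence[str],
    side: str,
) -> str:
    """Pick the germline allele best supported by the clone's reads.

    Sibling alleles (98-99 % identity) multimap at the couple-counting
    identity threshold, so the top couple's allele label can be a sibling of
    the truly rearranged one.  For reference assembly the extension allele
    is therefore chosen by voting: each supporting read votes for the
    candidate allele with the strictly best local alignment score on the
    relevant mate (reads that cannot tell the candidates apart abstain).
    Ties across alleles resolve lexicographically.
    """
    if side not in ("v", "j"):
        raise ValueError("side must be 'v' or 'j'")
    candidates = set(candidate_alleles)
    votes: dict[str, int] = {name: 0 for name in candidates}
    voted: set[str] = set()
    for rec in encompassing:
        if rec.read_id not in supporting_reads or rec.read_id in voted:
            continue
        hits = [
            h
            for h in (rec.v_hits if side == "v" else rec.j_hits)
            if h.segment in candidates
        ]
        if not hits:
            continue
        best_score = max(h.score for h in hits)
        best = {h.segment for h in hits if h.score == best_score}
        if len(best) == 1:
            votes[next(iter(best))] += 1
            voted.add(rec.read_id)
    return min(votes, key=lambda name: (-votes[name], name))


def select_bridging_reads(
    encompassing: Iterable[EncompassingRead],
    pairs_by_id: Mapping[str, PairedRead],
    clone: Clone,
    germline: GermlineSet,
    min_seed: int = 10,
) -> tuple[list[BridgingRead], dict[str, int]]:
    """Find the clone's reads whose both mates partially map on its D.

    For each encompassing read supporting the clone's VJ couple, the mates
    are oriented by their V/J hit strand, re-aligned (forward strand,
    ``min_seed`` perfect seed) against the assigned D segment, and kept when
    both mates carry a D hit in a geometry consistent with a V-D-J
    transcript (V before D on the V mate, D before J on the J mate, the V
    mate covering the 5' side of D).  Inconsistent reads are skipped with a
    tallied reason.
    """
    if clone.d_name is None:
        raise ReconstructionError("clone has no assigned D segment")
    d_seq = germline.get(clone.d_name).sequence
    d_index = KmerIndex({clone.d_name: d_seq}, min_seed)
    v_name = clone.vj.v_name
    j_name = clone.vj.j_name
    skipped = {"no_d_on_v_mate": 0, "no_d_on_j_mate": 0, "inconsistent_order": 0}
    bridging: list[BridgingRead] = []
    for rec in encompassing:
        if rec.read_id not in clone.vj.supporting_reads:
            continue
        v_hit = _best_named_hit(rec.v_hits, v_name)
        j_hit = _best_named_hit(rec.j_hits, j_name)
        if v_hit is None or j_hit is None:
            continue
        pair = pairs_by_id[rec.read_id]
        v_seq = pair.mate(rec.v_mate)
        j_seq = pair.mate(rec.j_mate)
        if v_hit.strand == "-":
            v_seq = revcomp(v_seq)
        if j_hit.strand == "-":
            j_seq = revcomp(j_seq)
        d1 = _forward_seeded(v_seq, d_index, rec.read_id, rec.v_mate)
        if d1 is None:
            skipped["no_d_on_v_mate"] += 1
            continue
        d2 = _forward_seeded(j_seq, d_index, rec.read_id, rec.j_mate)
        if d2 is None:
            skipped["no_d_on_j_mate"] += 1
            continue
        # Chance matches can extend two attributions over the same read
        # bases (a junction base equal to the adjacent germline base belongs
        # to either); trim overlapping attributions at the boundaries — the
        # assembled sequence is identical under any cut of an overlap.
        if d1.read_start < v_hit.read_end:
            d1 = _trim_left(d1, v_hit.read_end)
        if d2.read_end > j_hit.read_start:
            d2 = _trim_right(d2, j_hit.read_start)
        if d1.read_start >= d1.read_end or d2.read_start >= d2.read_end:
            skipped["inconsistent_order"] += 1
            continue
        if d2.seg_end <= d1.seg_start and d1.seg_end > d2.seg_start:
            # j-mate D evidence strictly 5' of the v-mate's: not a V-D-J
            # geometry this read can support.
            skipped["inconsistent_order"] += 1
            logger.debug("read %s skipped: inconsistent V-D-J geometry", rec.read_id)
            continue
        if d1.seg_end > d2.seg_start:
            # Overlap splice point must stay within the j-mate's J-ward span.
            r2 = d2.read_start + (d1.seg_end - d2.seg_start)
            if max(r2, d2.read_end) > j_hit.read_end:
                skipped["inconsistent_order"] += 1
                continue
        bridging.append(
            BridgingRead(
                read_id=rec.read_id,
                v_mate_seq=v_seq,
                j_mate_seq=j_seq,
                v_hit=v_hit,
                d_hit_v_mate=d1,
                d_hit_j_mate=d2,
                j_hit=j_hit,
                case=classify_d_overlap(
                    (d1.seg_start, d1.seg_end), (d2.seg_start, d2.seg_end)
                ),
            )
        )
    bridging.sort(key=lambda b: b.read_id)
    return bridging, skipped


def build_virtual_reference(read: BridgingRead, germline: GermlineSet) -> VirtualReference:
    """Assemble the candidate main-clone sequence from one bridging read.

    The V part is the germline V up to the read-supported V end (read bases
    where covered), the junctions are taken verbatim from the reads, the D
    part is read-derived (germline-filled between the mates in the
    non-overlap case), and the J part runs from the read-supported J start
    through the full germline J.
    """
    gv = germline.get(read.v_hit.segment).sequence
    gd = germline.get(read.d_hit_v_mate.segment).sequence
    gj = germline.get(read.j_hit.segment).sequence
    v_hit, d1, d2, j_hit = read.v_hit, read.d_hit_v_mate, read.d_hit_j_mate, read.j_hit

    v_part = gv[: v_hit.seg_start] + read.v_mate_seq[v_hit.read_start : v_hit.read_end]
    vd_junction = read.v_mate_seq[v_hit.read_end : d1.read_start]
    if d1.seg_end <= d2.seg_start:
        # Mates disjoint on D: the uncovered interior comes from germline.
        d_part = (
            read.v_mate_seq[d1.read_start : d1.read_end]
            + gd[d1.seg_end : d2.seg_start]
            + read.j_mate_seq[d2.read_start : d2.read_end]
        )
        dj_from = d2.read_end
    else:
        # Overlapping D evidence: splice the j-mate in at the v-mate's D
        # end using the shared D coordinate system (the whole mate lies on
        # one transcript diagonal, so positions past the hit are valid too).
        r2 = d2.read_start + (d1.seg_end - d2.seg_start)
        dj_from = max(r2, d2.read_end)
        d_part = (
            read.v_mate_seq[d1.read_start : d1.read_end]
            + read.j_mate_seq[r2:dj_from]
        )
    j_from = max(j_hit.read_start, dj_from)
    dj_junction = read.j_mate_seq[dj_from:j_from]
    j_part = read.j_mate_seq[j_from : j_hit.read_end] + gj[j_hit.seg_end :]

    parts = (v_part, vd_junction, d_part, dj_junction, j_part)
    spans = []
    cursor = 0
    for label, part in zip(SPAN_LABELS, parts):
        spans.append((label, cursor, cursor + len(part)))
        cursor += len(part)
    return VirtualReference(
        source_read_id=read.read_id,
        sequence="".join(parts),
        spans=tuple(spans),
        v_name=v_hit.segment,
        d_name=d1.segment,
        j_name=j_hit.segment,
    )


def dedupe_references(references: Sequence[VirtualReference]) -> list[VirtualReference]:
    """Collapse identical sequences, keeping the smallest source read id."""
    by_seq: dict[str, VirtualReference] = {}
    for ref in sorted(references, key=lambda r: r.source_read_id):
        by_seq.setdefault(ref.sequence, ref)
    return sorted(by_seq.values(), key=lambda r: r.source_read_id)


def score_references(
    references: Sequence[VirtualReference],
    vdj_unmapped: Sequence[PairedRead],
    total_reads: int,
    min_identity: float = 0.95,
    min_length: int = 20,
    k: int = 12,
    count_unit: str = "pairs",
) -> tuple[list[VirtualReference], dict[str, list[LocalAlignment]]]:
    """Score references by re-mapping the initially VDJ-unmapped reads.

    Support is the number of unmapped read pairs with at least one mate
    locally aligned to the reference at ``min_identity`` over
    ``min_length`` (``count_unit='mates'`` counts mates instead); the score
    is the RPKM-like measure with the library size as denominator.  Output
    is sorted by score descending with lexicographic tie-break on the
    source read id (ties flagged); the supporting alignments per reference
    are returned for coverage profiling.
    """
    if not references:
        raise ReconstructionError("no virtual references to score")
    if count_unit not in ("pairs", "mates"):
        raise ValueError("count_unit must be 'pairs' or 'mates'")
    aligner = LocalAligner(
        {ref.source_read_id: ref.sequence for ref in references},
        min_identity=min_identity,
        min_length=min_length,
        k=k,
    )
    support: dict[str, set[str | tuple[str, int]]] = {ref.source_read_id: set() for ref in references}
    alignments: dict[str, list[LocalAlignment]] = {ref.source_read_id: [] for ref in references}
    for pair in vdj_unmapped:
        for mate in (1, 2):
            for hit in aligner.align(pair.mate(mate), pair.read_id, mate):
                key = pair.read_id if count_unit == "pairs" else (pair.read_id, mate)
                support[hit.segment].add(key)
                alignments[hit.segment].append(hit)
    scored = [
        replace(
            ref,
            support=len(support[ref.source_read_id]),
            score=rpkm_like(len(support[ref.source_read_id]), total_reads),
        )
        for ref in references
    ]
    scored.sort(key=lambda r: (-r.score, r.source_read_id))
    if len(scored) > 1 and scored[0].score == scored[1].score:
        scored[0] = replace(scored[0], tie=True)
    return scored, alignments


def reconstruct_main_clone(
    clone: Clone,
    encompassing: Iterable[EncompassingRead],
    pairs_by_id: Mapping[str, PairedRead],
    germline: GermlineSet,
    vdj_unmapped: Sequence[PairedRead],
    total_reads: int,
    min_seed: int = 10,
    min_identity: float = 0.95,
    min_length: int = 20,
    k: int = 12,
) -> tuple[VirtualReference, list[VirtualReference], dict[str, list[LocalAlignment]]]:
    """Build, score and select the main-clone virtual reference.

    Returns the top-scored reference, the full scored list (identical
    sequences collapsed) and the supporting alignments per reference.
    Raises :class:`ReconstructionError` with diagnostics when no bridging
    read yields a reference.
    """
    bridging, skipped = select_bridging_reads(
        encompassing, pairs_by_id, clone, germline, min_seed=min_seed
    )
    if not bridging:
        raise ReconstructionError(
            f"reconstruction impossible: 0 bridging reads for couple "
            f"({clone.vj.v_name}, {clone.vj.j_name}); skipped={skipped}"
        )
    references = dedupe_references(
        [build_virtual_reference(read, germline) for read in bridging]
    )
    scored, alignments = score_references(
        references,
        vdj_unmapped,
        total_reads,
        min_identity=min_identity,
        min_length=min_length,
        k=k,
    )
    return scored[0], scored, alignments


def annotate_junctions(
    reconstructed: str,
    v_seq: str,
    d_seq: str,
    j_seq: str,
    min_anchor: int = 15,
) -> JunctionAnnotation:
    """Annotate a reconstructed sequence against naive V+D+J concatenation.

    Deletions are germline length minus the matched prefix/suffix length at
    each boundary (maximal attribution: the V match is the longest common
    prefix, the J match the longest common suffix, and the D remnant the
    longest germline-D substring found between them, preferring the smaller
    5' trim then the leftmost placement on ties).  Inserted strings are the
    remaining junction bases; P additions are not distinguished from N.
    Raises :class:`AnnotationError` when either anchor is shorter than
    ``min_anchor`` nucleotides.
    """
    v_len = common_prefix_len(reconstructed, v_seq)
    j_len = min(common_suffix_len(reconstructed, j_seq), len(reconstructed) - v_len)
    if v_len < min_anchor:
        raise AnnotationError(
            f"V prefix anchor too short ({v_len} < {min_anchor} nt): "
            "sequence does not start with the named V segment"
        )
    if j_len < min_anchor:
        raise AnnotationError(
            f"J suffix anchor too short ({j_len} < {min_anchor} nt): "
            "sequence does not end with the named J segment"
        )
    middle = reconstructed[v_len : len(reconstructed) - j_len]
    placement: tuple[int, int, int] | None = None  # (length, trim_d5, offset)
    for length in range(min(len(d_seq), len(middle)), 0, -1):
        for t5 in range(len(d_seq) - length + 1):
            offset = middle.find(d_seq[t5 : t5 + length])
            if offset >= 0:
                placement = (length, t5, offset)
                break
        if placement is not None:
            break
    if placement is None:
        placement = (0, len(d_seq), len(middle))
    length, t5, offset = placement
    return JunctionAnnotation(
        inserted_vd=middle[:offset],
        inserted_dj=middle[offset + length :],
        deleted_v3=len(v_seq) - v_len,
        deleted_d5=t5,
        deleted_d3=len(d_seq) - t5 - length,
        deleted_j5=len(j_seq) - j_len,
    )


def coverage_profile(
    reference: VirtualReference, alignments: Iterable[LocalAlignment]
) -> np.ndarray:
    """Per-base read depth over the reference from its supporting hits."""
    depth = np.zeros(len(reference.sequence), dtype=np.int64)
    for aln in alignments:
        depth[aln.seg_start : aln.seg_end] += 1
    return depth


def write_bedgraph(
    depth: np.ndarray, contig: str, path: str
) -> None:
    """Emit a depth track as BedGraph (runs of equal depth merged)."""
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[start]:
                fh.write(f"{contig}\t{start}\t{i}\t{int(depth[start])}\n")
                start = i
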