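"""Internal alignment kernels shared by the pipeline stages.

All alignments in this package are ungapped: the sequencing-error model is
substitution-only, and the quantities the pipeline consumes (segment
membership, junction boundaries, mismatch counts) are defined on ungapped
placements.  Three kernels live here:

* an exact k-mer index used to seed candidate (target, diagonal) pairs,
* a max-scoring-subarray scan (+1 match / -1 mismatch) along one diagonal,
  which yields the best local ungapped alignment on that diagonal,
* a pigeonhole-seeded end-to-end placement search with a mismatch bound.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


class KmerIndex:
    """Exact k-mer index over a named set of sequences.

    Lookup returns every (name, diagonal) pair for which the query shares at
    least one exact k-mer with the named sequence on that diagonal, where
    ``diagonal = target_pos - query_pos``.
    """

    def __init__(self, seqs: Mapping[str, str], k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.seqs = dict(seqs)
        index: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(self.seqs):
            s = self.seqs[name]
            for i in range(len(s) - k + 1):
                index.setdefault(s[i : i + k], []).append((name, i))
        self._index = index

    def diagonals(self, query: str) -> set[tuple[str, int]]:
        k = self.k
        out: set[tuple[str, int]] = set()
        get = self._index.get
        for i in range(len(query) - k + 1):
            hits = get(query[i : i + k])
            if hits:
                for name, pos in hits:
                    out.add((name, pos - i))
        return out


@dataclass(frozen=True)
class DiagonalHit:
    """Best local ungapped alignment along one query/target diagonal."""

    score: int
    matches: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity(self) -> float:
        return self.matches / self.length


def best_on_diagonal(query: str, target: str, diag: int) -> DiagonalHit | None:
    """Max-scoring (+1/-1) contiguous stretch along diagonal ``diag``.

    Returns None if the diagonal has no overlap or no matching base.  Ties on
    score prefer the shorter stretch (fewer mismatched columns, hence higher
    identity), then the smaller query start, so the result is deterministic.
    """
    q_lo = max(0, -diag)
    q_hi = min(len(query), len(target) - diag)
    if q_hi <= q_lo:
        return None
    best_score = 0
    best = None  # (score, length, q_start, q_end, matches)
    cur = 0
    cur_m = 0
    start = q_lo
    for q in range(q_lo, q_hi):
        if cur < 0:
            cur = 0
            cur_m = 0
            start = q
        if query[q] == target[q + diag]:
            cur += 1
            cur_m += 1
        else:
            cur -= 1
        if cur > 0:
            length = q + 1 - start
            if (
                best is None
                or cur > best_score
                or (cur == best_score and (length, start) < (best[1], best[2]))
            ):
                best_score = cur
                best = (cur, length, start, q + 1, cur_m)
    if best is None:
        return None
    _, _, qs, qe, m = best
    # A zero-sum prefix (equal matches and mismatches) contributes nothing
    # to the score but dilutes identity; drop it so the reported window is
    # the minimal one achieving the maximal score.
    cum = 0
    new_qs = qs
    for q in range(qs, qe):
        cum += 1 if query[q] == target[q + diag] else -1
        if cum == 0:
            new_qs = q + 1
    if new_qs != qs:
        qs = new_qs
        m = sum(query[q] == target[q + diag] for q in range(qs, qe))
    return DiagonalHit(
        score=best_score, matches=m, q_start=qs, q_end=qe, t_start=qs + diag, t_end=qe + diag
    )


@dataclass(frozen=True)
class EndToEndHit:
    """Full-length placement of a mate on a reference contig."""

    target: str
    start: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class UngappedResult:
    """Outcome of mismatch-bounded end-to-end mapping of one mate.

    ``suppressed`` marks mates whose best-stratum placement count exceeded
    the reporting cap; such mates carry no hits and are treated as unaligned
    downstream.
    """

    hits: tuple[EndToEndHit, ...]
    suppressed: bool

    @property
    def aligned(self) -> bool:
        return bool(self.hits)


class UngappedAligner:
    """Mismatch-bounded end-to-end placement against a reference set.

    Placements on both strands with at most ``max_mismatches`` mismatches are
    found with a pigeonhole seed (a placement with <= m mismatches must carry
    an exact chunk of length ``read_len // (m + 1)``), then restricted to the
    best-mismatch stratum.  If the stratum holds more than ``max_report``
    placements the mate is reported as suppressed.  Contigs shorter than the
    mate are skipped.
    """

    def __init__(self, reference: Mapping[str, str], max_mismatches: int = 2, max_report: int = 10):
        if not reference:
            raise ValueError("empty reference")
        self.reference = {name: seq.upper() for name, seq in sorted(reference.items())}
        self.max_mismatches = int(max_mismatches)
        self.max_report = int(max_report)
        self._indexes: dict[int, KmerIndex] = {}

    def _index_for(self, read_len: int) -> KmerIndex | None:
        if read_len not in self._indexes:
            k = read_len // (self.max_mismatches + 1)
            if k < 1:
                raise ValueError("mate too short for the mismatch bound")
            usable = {n: s for n, s in self.reference.items() if len(s) >= read_len}
            self._indexes[read_len] = KmerIndex(usable, k) if usable else None
        return self._indexes[read_len]

    def map_mate(self, seq: str) -> UngappedResult:
        seq = seq.upper()
        index = self._index_for(len(seq))
        if index is None:
            return UngappedResult(hits=(), suppressed=False)
        k = index.k
        n_chunks = self.max_mismatches + 1
        found: dict[tuple[str, int, str], int] = {}
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            candidates: set[tuple[str, int]] = set()
            for c in range(n_chunks):
                off = c * k
                chunk = q[off : off + k]
                for name, pos in index._index.get(chunk, ()):
                    start = pos - off
                    if 0 <= start <= len(index.seqs[name]) - len(q):
                        candidates.add((name, start))
            for name, start in candidates:
                key = (name, start, strand)
                if key in found:
                    continue
                mm = hamming(q, index.seqs[name][start : start + len(q)])
                if mm <= self.max_mismatches:
                    found[key] = mm
        if not found:
            return UngappedResult(hits=(), suppressed=False)
        best = min(found.values())
        stratum = sorted(key for key, mm in found.items() if mm == best)
        if len(stratum) > self.max_report:
            return UngappedResult(hits=(), suppressed=True)
        hits = tuple(
            EndToEndHit(target=name, start=start, strand=strand, mismatches=best)
            for name, start, strand in stratum
        )
        return UngappedResult(hits=hits, suppressed=False)


def align_ungapped(
    mate: str,
    reference: Mapping[str, str],
    max_mismatches: int = 2,
    max_report: int = 10,
) -> UngappedResult:
    """One-shot convenience wrapper around :class:`UngappedAligner`."""
    return UngappedAligner(reference, max_mismatches, max_report).map_mate(mate)


def common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def iter_kmers(seq: str, k: int) -> Iterable[tuple[int, str]]:
    for i in range(len(seq) - k + 1):
        yield i, seq[i : i + k]
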