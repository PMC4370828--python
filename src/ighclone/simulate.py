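"""Truth-annotated V(D)J recombination and paired-end read simulator.

The generative model follows the biology of heavy-chain rearrangement: one
V, one D and one J germline segment are joined after exonuclease trimming
(3' end of V, both ends of D, 5' end of J), with non-templated N nucleotides
added by TdT at the VD and DJ junctions and short palindromic (P) additions
possible at untrimmed ends.  A sample is a mixture of one dominant clone and
a polyclonal background; reads are 100 bp paired-end with substitution
errors, and every pair carries a truth record so each downstream pipeline
stage can be checked against ground truth.

Junction truth is stored in *canonical* form: the raw enzymatic draws are
not identifiable from the transcript (an inserted base equal to the next
germline base cannot be told apart from no trimming), so the truth table
records the maximal-germline-attribution parse of each junction, which is
the quantity any sequence-based annotator can recover.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import common_prefix_len, common_suffix_len, revcomp
from .germline import GermlineSet
from .partition import PairedRead

_BASES = "ACGT"


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimulationConfig:
    """Tunable parameters of the read/recombination generator.

    Defaults describe a 100 bp paired-end RNA-seq library over the V(D)J
    span of the recombined transcript: fragment lengths are drawn from a
    normal (mean 200, sd 40) truncated to [read_length, transcript length],
    so overlapping mates — the substrate of junction bridging — occur at a
    realistic rate.  Trim and N-insertion lengths are uniform integers on
    the configured ranges (inclusive); P additions occur with probability
    ``p_probability`` at each untrimmed end with length uniform on
    ``p_length_range``.
    """

    clone_fractions: dict[str, float] | None = None
    n_pairs: int = 1000
    read_length: int = 100
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 40.0
    substitution_error_rate: float = 0.0
    seed: int = 0
    trim_range: tuple[int, int] = (0, 6)
    n_insert_range: tuple[int, int] = (0, 6)
    p_probability: float = 0.5
    p_length_range: tuple[int, int] = (1, 3)

    def validate_fractions(self) -> dict[str, float]:
        if not self.clone_fractions:
            raise SimulationError("clone_fractions not set")
        total = sum(self.clone_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"clone fractions sum to {total}, expected 1")
        return self.clone_fractions


@dataclass(frozen=True)
class RecombinationEvent:
    """One recombined transcript with the full generative record.

    ``transcript`` always equals ``trimmed V + p_v + n1 + p_d5 + trimmed D +
    p_d3 + n2 + p_j + trimmed J``; P strings are non-empty only where the
    adjacent trim is zero.
    """

    v_name: str
    d_name: str
    j_name: str
    trim_v3: int
    trim_d5: int
    trim_d3: int
    trim_j5: int
    n1_seq: str
    n2_seq: str
    p_v: str
    p_d5: str
    p_d3: str
    p_j: str
    transcript: str

    def assemble(self, germline: GermlineSet) -> str:
        """Recompose the transcript from parts (used to assert the invariant)."""
        v = germline.get(self.v_name).sequence
        d = germline.get(self.d_name).sequence
        j = germline.get(self.j_name).sequence
        trimmed_v = v[: len(v) - self.trim_v3]
        trimmed_d = d[self.trim_d5 : len(d) - self.trim_d3]
        trimmed_j = j[self.trim_j5 :]
        return (
            trimmed_v
            + self.p_v
            + self.n1_seq
            + self.p_d5
            + trimmed_d
            + self.p_d3
            + self.n2_seq
            + self.p_j
            + trimmed_j
        )


def _draw_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def simulate_rearrangement(
    germline: GermlineSet, config: SimulationConfig, rng: np.random.Generator
) -> RecombinationEvent:
    """Draw one V(D)J recombination event.

    Segments are chosen uniformly; trims come from ``config.trim_range``
    (the configuration is rejected if the range reaches a chosen segment's
    length, and D trims are redrawn until they leave at least one D base);
    N strings are uniform random bases; P additions are the reverse
    complement of the adjacent terminal bases and occur only at untrimmed
    ends.
    """
    v_keys = sorted(germline.v_segments)
    d_keys = sorted(germline.d_segments)
    j_keys = sorted(germline.j_segments)
    if not (v_keys and d_keys and j_keys):
        raise SimulationError("germline set must contain V, D and J segments")
    v = germline.v_segments[v_keys[int(rng.integers(len(v_keys)))]]
    d = germline.d_segments[d_keys[int(rng.integers(len(d_keys)))]]
    j = germline.j_segments[j_keys[int(rng.integers(len(j_keys)))]]

    t_lo, t_hi = config.trim_range
    for seg in (v, d, j):
        if t_hi >= len(seg.sequence):
            raise SimulationError(
                f"trim range {config.trim_range} reaches length of {seg.key} "
                f"({len(seg.sequence)} nt)"
            )
    trim_v3 = _draw_int(rng, t_lo, t_hi)
    for _ in range(1000):
        trim_d5 = _draw_int(rng, t_lo, t_hi)
        trim_d3 = _draw_int(rng, t_lo, t_hi)
        if trim_d5 + trim_d3 < len(d.sequence):
            break
    else:  # pragma: no cover - requires pathological ranges
        raise SimulationError(f"cannot trim {d.key} within its length")
    trim_j5 = _draw_int(rng, t_lo, t_hi)

    n1 = _random_bases(rng, _draw_int(rng, *config.n_insert_range))
    n2 = _random_bases(rng, _draw_int(rng, *config.n_insert_range))

    def p_string(seq: str, end: str) -> str:
        """P addition: reverse complement of the adjacent terminal bases
        (the last bases at a 3' end, the first bases at a 5' end)."""
        if rng.random() >= config.p_probability:
            return ""
        plen = min(_draw_int(rng, *config.p_length_range), len(seq))
        return revcomp(seq[-plen:]) if end == "3" else revcomp(seq[:plen])

    # Draw order is fixed (V end, D 5', D 3', J start) for determinism.
    p_v = p_string(v.sequence, "3") if trim_v3 == 0 else ""
    p_d5 = p_string(d.sequence, "5") if trim_d5 == 0 else ""
    p_d3 = p_string(d.sequence, "3") if trim_d3 == 0 else ""
    p_j = p_string(j.sequence, "5") if trim_j5 == 0 else ""

    event = RecombinationEvent(
        v_name=v.key,
        d_name=d.key,
        j_name=j.key,
        trim_v3=trim_v3,
        trim_d5=trim_d5,
        trim_d3=trim_d3,
        trim_j5=trim_j5,
        n1_seq=n1,
        n2_seq=n2,
        p_v=p_v,
        p_d5=p_d5,
        p_d3=p_d3,
        p_j=p_j,
        transcript="",
    )
    return replace(event, transcript=event.assemble(germline))


def simulate_background(
    germline: GermlineSet,
    n_clones: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[str, RecombinationEvent]]:
    """Polyclonal background: ``n_clones`` events with distinct (V, D, J)
    triples (when the germline set is large enough to allow it)."""
    if n_clones < 1:
        raise SimulationError("n_clones must be >= 1")
    events: list[tuple[str, RecombinationEvent]] = []
    seen: set[tuple[str, str, str]] = set()
    width = max(3, len(str(n_clones - 1)))
    for i in range(n_clones):
        event = simulate_rearrangement(germline, config, rng)
        for _ in range(200):
            triple = (event.v_name, event.d_name, event.j_name)
            if triple not in seen:
                break
            event = simulate_rearrangement(germline, config, rng)
        seen.add((event.v_name, event.d_name, event.j_name))
        events.append((f"bg{i:0{width}d}", event))
    return events


def largest_remainder_allocation(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Exact integer allocation of ``n`` items by largest remainder.

    Deterministic: remainders tie-break on label order.  The result always
    sums to ``n`` exactly, so clone read counts carry no sampling noise.
    """
    labels = sorted(fractions)
    quotas = {lab: fractions[lab] * n for lab in labels}
    counts = {lab: int(np.floor(quotas[lab])) for lab in labels}
    remaining = n - sum(counts.values())
    order = sorted(labels, key=lambda lab: (-(quotas[lab] - counts[lab]), lab))
    for lab in order[:remaining]:
        counts[lab] += 1
    return counts


@dataclass(frozen=True)
class TruthRecord:
    """Per-pair ground truth: source clone, fragment and injected errors."""

    read_id: str
    clone_label: str
    v_name: str
    d_name: str
    j_name: str
    fragment_start: int
    fragment_end: int
    errors_mate1: tuple[int, ...]
    errors_mate2: tuple[int, ...]


def _apply_errors(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, tuple[int, ...]]:
    if rate <= 0:
        return seq, ()
    mask = rng.random(len(seq)) < rate
    positions = tuple(int(i) for i in np.nonzero(mask)[0])
    if not positions:
        return seq, ()
    out = list(seq)
    for i in positions:
        choices = [b for b in _BASES if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out), positions


def simulate_reads(
    transcripts: Sequence[tuple[str, RecombinationEvent]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[PairedRead], list[TruthRecord]]:
    """Draw paired-end reads from a labeled transcript pool.

    Pairs are allocated to clones by exact largest-remainder rounding of
    ``config.clone_fractions``.  Fragment lengths follow a truncated normal
    on [read_length, transcript length]; mate1 is the forward (left) end of
    the fragment and mate2 the reverse-complemented right end.  Substitution
    errors are injected per base at ``substitution_error_rate`` and their
    offsets recorded in the truth table.
    """
    fractions = config.validate_fractions()
    by_label = dict(transcripts)
    missing = sorted(set(fractions) - set(by_label))
    if missing:
        raise SimulationError(f"clone_fractions refer to unknown labels: {missing}")
    rl = config.read_length
    for label in sorted(fractions):
        if len(by_label[label].transcript) < rl:
            raise SimulationError(
                f"transcript {label} is shorter ({len(by_label[label].transcript)} nt) "
                f"than the read length ({rl} nt)"
            )
    counts = largest_remainder_allocation(fractions, config.n_pairs)
    pairs: list[PairedRead] = []
    truth: list[TruthRecord] = []
    for label in sorted(fractions):
        event = by_label[label]
        tlen = len(event.transcript)
        for idx in range(counts[label]):
            frag = 0
            for _ in range(100):
                frag = int(round(rng.normal(config.fragment_length_mean, config.fragment_length_sd)))
                if rl <= frag <= tlen:
                    break
            frag = min(max(frag, rl), tlen)
            start = int(rng.integers(0, tlen - frag + 1))
            end = start + frag
            mate1 = event.transcript[start : start + rl]
            mate2 = revcomp(event.transcript[end - rl : end])
            mate1, err1 = _apply_errors(rng, mate1, config.substitution_error_rate)
            mate2, err2 = _apply_errors(rng, mate2, config.substitution_error_rate)
            read_id = f"{label}.{idx:06d}"
            pairs.append(
                PairedRead(
                    read_id=read_id,
                    mate1_seq=mate1,
                    mate2_seq=mate2,
                    mate1_qual="I" * len(mate1),
                    mate2_qual="I" * len(mate2),
                )
            )
            truth.append(
                TruthRecord(
                    read_id=read_id,
                    clone_label=label,
                    v_name=event.v_name,
                    d_name=event.d_name,
                    j_name=event.j_name,
                    fragment_start=start,
                    fragment_end=end,
                    errors_mate1=err1,
                    errors_mate2=err2,
                )
            )
    return pairs, truth


# ---------------------------------------------------------------------------
# Canonical junction truth
# ---------------------------------------------------------------------------


def canonical_parse(
    transcript: str, v_seq: str, d_seq: str, j_seq: str
) -> dict[str, object]:
    """Maximal-germline-attribution parse of a recombined sequence.

    V attribution is the longest common prefix with the germline V, J the
    longest common suffix with the germline J (capped so the two cannot
    overlap), and the D remnant is the longest substring of the germline D
    occurring in the remaining middle (ties: smallest 5' trim, then leftmost
    placement; a zero-length match assigns the whole middle to the VD
    insertion).  Any annotator working from sequence alone can recover at
    most this parse, so it is what the truth table stores.
    """
    v_len = common_prefix_len(transcript, v_seq)
    j_len = min(common_suffix_len(transcript, j_seq), len(transcript) - v_len)
    middle = transcript[v_len : len(transcript) - j_len]
    best = (0, len(d_seq), len(middle))  # (match length, trim_d5, middle offset)
    for t5 in range(len(d_seq)):
        for start in range(len(middle)):
            length = 0
            while (
                t5 + length < len(d_seq)
                and start + length < len(middle)
                and d_seq[t5 + length] == middle[start + length]
            ):
                length += 1
            cand = (length, t5, start)
            if (cand[0], -cand[1], -cand[2]) > (best[0], -best[1], -best[2]):
                best = cand
    length, t5, start = best
    if length == 0:
        t5, start = len(d_seq), len(middle)
    return {
        "deleted_v3": len(v_seq) - v_len,
        "deleted_d5": t5,
        "deleted_d3": len(d_seq) - t5 - length,
        "deleted_j5": len(j_seq) - j_len,
        "inserted_vd": middle[:start],
        "inserted_dj": middle[start + length :],
    }


def truth_junctions(event: RecombinationEvent, germline: GermlineSet) -> dict[str, object]:
    """Canonical junction annotation of an event's transcript."""
    return canonical_parse(
        event.transcript,
        germline.get(event.v_name).sequence,
        germline.get(event.d_name).sequence,
        germline.get(event.j_name).sequence,
    )


# ---------------------------------------------------------------------------
# Whole-sample convenience and file I/O
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSample:
    """A complete simulated sample: pool, reads and truth."""

    germline: GermlineSet
    events: list[tuple[str, RecombinationEvent]]
    pairs: list[PairedRead]
    truth: list[TruthRecord]
    config: SimulationConfig

    @property
    def main_event(self) -> RecombinationEvent:
        return dict(self.events)["main"]


def simulate_sample(
    germline: GermlineSet,
    n_pairs: int,
    main_fraction: float,
    n_background: int,
    seed: int,
    config: SimulationConfig | None = None,
) -> SimulatedSample:
    """Simulate one dominant clone over a polyclonal background.

    The main clone receives ``main_fraction`` of the pairs; the remainder is
    split evenly over ``n_background`` distinct background rearrangements.
    Fully deterministic for fixed arguments.
    """
    if not 0 < main_fraction <= 1:
        raise SimulationError("main_fraction must be in (0, 1]")
    base = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    main = simulate_rearrangement(germline, base, rng)
    background = simulate_background(germline, n_background, base, rng)
    fractions = {"main": main_fraction}
    for label, _ in background:
        fractions[label] = (1.0 - main_fraction) / n_background
    cfg = replace(base, clone_fractions=fractions, n_pairs=n_pairs, seed=seed)
    events = [("main", main)] + background
    pairs, truth = simulate_reads(events, cfg, rng)
    return SimulatedSample(
        germline=germline, events=events, pairs=pairs, truth=truth, config=cfg
    )


def write_fastq_pair(
    pairs: Iterable[PairedRead], path1: str | Path, path2: str | Path
) -> None:
    """Write the two mate files with /1 and /2 id suffixes."""

    def records(mate: int):
        for p in pairs_list:
            seq = p.mate1_seq if mate == 1 else p.mate2_seq
            qual = (p.mate1_qual if mate == 1 else p.mate2_qual) or "I" * len(seq)
            rec = SeqRecord(Seq(seq), id=f"{p.read_id}/{mate}", description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            yield rec

    pairs_list = list(pairs)
    SeqIO.write(records(1), str(path1), "fastq")
    SeqIO.write(records(2), str(path2), "fastq")


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[PairedRead]:
    """Read two mate FASTQ files into paired reads (ids matched by order,
    /1 and /2 suffixes stripped)."""

    def strip(rid: str) -> str:
        return rid[:-2] if rid.endswith(("/1", "/2")) else rid

    recs1 = list(SeqIO.parse(str(path1), "fastq"))
    recs2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError("mate files differ in record count")
    pairs = []
    for r1, r2 in zip(recs1, recs2):
        id1, id2 = strip(r1.id), strip(r2.id)
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {r1.id} vs {r2.id}")
        pairs.append(
            PairedRead(
                read_id=id1,
                mate1_seq=str(r1.seq).upper(),
                mate2_seq=str(r2.seq).upper(),
                mate1_qual="".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"]),
                mate2_qual="".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


TRUTH_COLUMNS = [
    "read_id",
    "clone_label",
    "v_name",
    "d_name",
    "j_name",
    "fragment_start",
    "fragment_end",
    "errors_mate1",
    "errors_mate2",
]

CLONE_TRUTH_COLUMNS = [
    "clone_label",
    "v_name",
    "d_name",
    "j_name",
    "transcript",
    "deleted_v3",
    "deleted_d5",
    "deleted_d3",
    "deleted_j5",
    "inserted_vd",
    "inserted_dj",
]


def write_truth(truth: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for t in truth:
            writer.writerow(
                [
                    t.read_id,
                    t.clone_label,
                    t.v_name,
                    t.d_name,
                    t.j_name,
                    t.fragment_start,
                    t.fragment_end,
                    ",".join(map(str, t.errors_mate1)),
                    ",".join(map(str, t.errors_mate2)),
                ]
            )


def write_clone_truth(
    events: Sequence[tuple[str, RecombinationEvent]],
    germline: GermlineSet,
    path: str | Path,
) -> None:
    """Clone-level truth: transcript plus canonical junction annotation."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CLONE_TRUTH_COLUMNS)
        for label, event in events:
            ann = truth_junctions(event, germline)
            writer.writerow(
                [
                    label,
                    event.v_name,
                    event.d_name,
                    event.j_name,
                    event.transcript,
                    ann["deleted_v3"],
                    ann["deleted_d5"],
                    ann["deleted_d3"],
                    ann["deleted_j5"],
                    ann["inserted_vd"],
                    ann["inserted_dj"],
                ]
            )
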