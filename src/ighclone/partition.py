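"""Read partitioning: split pairs into VDJ-unmapped / VDJ-mapped / discarded.

Junction-spanning reads cannot be placed end-to-end on a reference that
lacks the recombined transcript, so an exhaustive mismatch-bounded mapper
separates them (the *VDJ unmapped* dataset) from reads that place inside the
IGH V(D)J locus (the *VDJ mapped* dataset); everything else is discarded.
The reference may be a genome with a locus interval set, or simply the
germline segment sequences themselves standing in for the locus.  A SAM
ingestion path accepts externally produced alignments under the same
classification contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pysam

from .align import UngappedAligner, UngappedResult, align_ungapped  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

LocusInterval = tuple[str, int, int]


@dataclass(frozen=True)
class PairedRead:
    """Two mates of one read pair (sequences as sequenced, 5'->3')."""

    read_id: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str | None = None
    mate2_qual: str | None = None

    def __post_init__(self) -> None:
        if not self.mate1_seq or not self.mate2_seq:
            raise ValueError(f"empty mate sequence in pair {self.read_id}")
        for seq, qual in ((self.mate1_seq, self.mate1_qual), (self.mate2_seq, self.mate2_qual)):
            if qual is not None and len(qual) != len(seq):
                raise ValueError(f"quality/sequence length mismatch in pair {self.read_id}")

    def mate(self, index: int) -> str:
        if index == 1:
            return self.mate1_seq
        if index == 2:
            return self.mate2_seq
        raise ValueError("mate index must be 1 or 2")


@dataclass
class PartitionResult:
    """Disjoint cover of the input read ids by the three partition classes."""

    vdj_unmapped: set[str]
    vdj_mapped: set[str]
    discarded: set[str]

    def classes(self) -> dict[str, set[str]]:
        return {
            "vdj_unmapped": self.vdj_unmapped,
            "vdj_mapped": self.vdj_mapped,
            "discarded": self.discarded,
        }

    def assert_total(self, input_ids: set[str]) -> None:
        """Assert the three classes disjointly cover ``input_ids``."""
        union = self.vdj_unmapped | self.vdj_mapped | self.discarded
        overlap = (
            (self.vdj_unmapped & self.vdj_mapped)
            | (self.vdj_unmapped & self.discarded)
            | (self.vdj_mapped & self.discarded)
        )
        if overlap:
            raise AssertionError(f"partition classes overlap on {sorted(overlap)[:5]}")
        if union != input_ids:
            raise AssertionError(
                f"partition does not cover input: missing {sorted(input_ids - union)[:5]}, "
                f"extra {sorted(union - input_ids)[:5]}"
            )

    @property
    def candidate_ids(self) -> set[str]:
        """Reads fed to the VJ calling stage (unmapped plus locus-mapped)."""
        return self.vdj_unmapped | self.vdj_mapped


def whole_reference_locus(reference: Mapping[str, str]) -> list[LocusInterval]:
    """Locus intervals covering every contig (germline-as-reference mode)."""
    return [(name, 0, len(seq)) for name, seq in sorted(reference.items())]


def _overlaps_locus(
    target: str, start: int, end: int, locus: Sequence[LocusInterval]
) -> bool:
    for contig, lo, hi in locus:
        if contig == target and start < hi and lo < end:
            return True
    return False


def partition_reads(
    reads: Sequence[PairedRead],
    reference: Mapping[str, str],
    locus: Sequence[LocusInterval] | None = None,
    max_mismatches: int = 2,
    max_report: int = 10,
    require_both_unaligned: bool = True,
) -> PartitionResult:
    """Classify read pairs by mismatch-bounded end-to-end placement.

    A pair is *vdj_unmapped* when no mate receives any reported placement
    (with ``require_both_unaligned=False``, when at least one mate is
    unreported); otherwise it is *vdj_mapped* if any placement overlaps a
    locus interval (half-open intersection) and *discarded* if all its
    placements fall outside the locus.  When ``locus`` is None every contig
    counts as locus (germline segments standing in for the locus).
    """
    aligner = UngappedAligner(reference, max_mismatches=max_mismatches, max_report=max_report)
    if locus is None:
        locus = whole_reference_locus(reference)
    result = PartitionResult(vdj_unmapped=set(), vdj_mapped=set(), discarded=set())
    for pair in reads:
        res1 = aligner.map_mate(pair.mate1_seq)
        res2 = aligner.map_mate(pair.mate2_seq)
        unaligned = (not res1.aligned, not res2.aligned)
        is_unmapped = all(unaligned) if require_both_unaligned else any(unaligned)
        if is_unmapped:
            result.vdj_unmapped.add(pair.read_id)
            continue
        hits = list(res1.hits) + list(res2.hits)
        in_locus = any(
            _overlaps_locus(h.target, h.start, h.start + len(pair.mate(m)), locus)
            for h, m in [(h, 1) for h in res1.hits] + [(h, 2) for h in res2.hits]
        )
        if hits and in_locus:
            result.vdj_mapped.add(pair.read_id)
        else:
            result.discarded.add(pair.read_id)
    result.assert_total({p.read_id for p in reads})
    return result


def ingest_sam(
    path: str | Path,
    locus: Sequence[LocusInterval],
    require_both_unaligned: bool = True,
) -> PartitionResult:
    """Classify pairs from a SAM/BAM file under the partition contract.

    Uses primary alignment flags; mates are matched by query name.  Records
    without a resolvable mate raise a warning and are discarded.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    by_name: dict[str, dict[int, tuple[bool, str | None, int, int]]] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate_index = 2 if rec.is_read2 else 1
            if rec.is_unmapped:
                info = (False, None, 0, 0)
            else:
                info = (True, rec.reference_name, rec.reference_start, rec.reference_end)
            by_name.setdefault(rec.query_name, {})[mate_index] = info

    result = PartitionResult(vdj_unmapped=set(), vdj_mapped=set(), discarded=set())
    for name in sorted(by_name):
        mates = by_name[name]
        if len(mates) != 2:
            logger.warning("unpaired SAM record %s: discarded", name)
            result.discarded.add(name)
            continue
        unaligned = [not mates[i][0] for i in (1, 2)]
        is_unmapped = all(unaligned) if require_both_unaligned else any(unaligned)
        if is_unmapped:
            result.vdj_unmapped.add(name)
            continue
        in_locus = any(
            mapped and _overlaps_locus(contig, start, end, locus)
            for mapped, contig, start, end in (mates[1], mates[2])
        )
        if in_locus:
            result.vdj_mapped.add(name)
        else:
            result.discarded.add(name)
    result.assert_total(set(by_name))
    return result


def write_partition(result: PartitionResult, outdir: str | Path, prefix: str = "partition") -> None:
    """Write the three id-list files plus a summary TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cls, ids in result.classes().items():
        with open(outdir / f"{prefix}.{cls}.ids", "w") as fh:
            for rid in sorted(ids):
                fh.write(rid + "\n")
    with open(outdir / f"{prefix}.summary.tsv", "w") as fh:
        fh.write("class\tn_pairs\n")
        for cls, ids in result.classes().items():
            fh.write(f"{cls}\t{len(ids)}\n")
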