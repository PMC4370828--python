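"""Pipeline orchestration and report emission.

Runs the four analysis stages in order — partition, VJ calling, D calling,
reconstruction — over an in-memory set of read pairs and a germline set,
and writes the report bundle: allele- and subgroup-level clone tables, the
main-clone FASTA with junction annotation, the scored reference table, a
coverage track and a run manifest.  Identical inputs and seed produce a
byte-identical bundle; the manifest therefore records deterministic
per-stage counters (never wall-clock data) alongside the configuration
snapshot and input digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .dcall import (
    Clone,
    PipelineConfig,
    SeededDAligner,
    assign_d,
    select_partial_mates,
)
from .germline import GermlineSet, load_germline_set, parse_segment_name
from .partition import (
    PairedRead,
    PartitionResult,
    ingest_sam,
    partition_reads,
    whole_reference_locus,
    write_partition,
)
from .reconstruct import (
    JunctionAnnotation,
    ReconstructionError,
    VirtualReference,
    annotate_junctions,
    coverage_profile,
    reconstruct_main_clone,
    write_bedgraph,
)
from .vjcall import (
    MainCloneCall,
    VJCouple,
    aggregate_by_subgroup,
    count_vj_couples,
    find_encompassing_reads,
    main_clone,
)

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """Everything the pipeline computed on one sample."""

    config: PipelineConfig
    total_reads: int
    partition: PartitionResult
    n_encompassing: int
    couples: list[VJCouple]
    subgroup_couples: list[VJCouple]
    main_allele: MainCloneCall | None
    main_subgroup: MainCloneCall | None
    clones: list[Clone]
    references: list[VirtualReference] = field(default_factory=list)
    main_reference: VirtualReference | None = None
    annotation: JunctionAnnotation | None = None
    coverage: object = None
    reconstruction_failure: str | None = None
    counters: dict[str, int] = field(default_factory=dict)


def _refine_clone_alleles(clone: Clone, encompassing, germline: GermlineSet) -> Clone:
    """Resolve sibling-allele ambiguity before reference assembly.

    Couple counting deliberately multimaps across alleles at ~98-99 %
    identity, so the top couple's labels may name a sibling of the truly
    rearranged allele.  The germline used to extend the virtual reference
    is therefore re-chosen per side by best-scoring-hit voting over the
    clone's supporting reads (see
    :func:`ighclone.reconstruct.refine_segment_allele`).
    """
    from dataclasses import replace as _replace

    from .reconstruct import refine_segment_allele

    v_name = parse_segment_name(clone.vj.v_name)
    j_name = parse_segment_name(clone.vj.j_name)
    v_candidates = [
        key
        for key, seg in sorted(germline.v_segments.items())
        if (seg.name.subgroup, seg.name.gene) == (v_name.subgroup, v_name.gene)
    ]
    j_candidates = [
        key
        for key, seg in sorted(germline.j_segments.items())
        if seg.name.subgroup == j_name.subgroup
    ]
    refined_v = refine_segment_allele(
        encompassing, clone.vj.supporting_reads, v_candidates, "v"
    )
    refined_j = refine_segment_allele(
        encompassing, clone.vj.supporting_reads, j_candidates, "j"
    )
    if (refined_v, refined_j) == (clone.vj.v_name, clone.vj.j_name):
        return clone
    return _replace(
        clone, vj=_replace(clone.vj, v_name=refined_v, j_name=refined_j)
    )


def run_analysis(
    pairs: Sequence[PairedRead],
    germline: GermlineSet,
    config: PipelineConfig | None = None,
    reference: Mapping[str, str] | None = None,
    locus: Sequence[tuple[str, int, int]] | None = None,
    partition: PartitionResult | None = None,
) -> RunResult:
    """Run partition -> VJ call -> D call -> reconstruction on read pairs.

    ``reference``/``locus`` default to the germline segment sequences
    standing in for the IGH locus; a precomputed ``partition`` (e.g. from
    SAM ingestion) bypasses the internal end-to-end mapper.
    """
    config = config or PipelineConfig()
    total_reads = config.total_reads or len(pairs)
    pairs_by_id = {p.read_id: p for p in pairs}
    if len(pairs_by_id) != len(pairs):
        raise ValueError("duplicate read ids in input")

    if partition is None:
        if reference is None:
            reference = germline.sequences()
            locus = whole_reference_locus(reference)
        partition = partition_reads(
            pairs,
            reference,
            locus,
            max_mismatches=config.max_mismatches,
            max_report=config.max_report,
            require_both_unaligned=config.require_both_unaligned,
        )

    candidates = [p for p in pairs if p.read_id in partition.candidate_ids]
    encompassing = find_encompassing_reads(
        candidates,
        germline.v_segments,
        germline.j_segments,
        min_identity=config.min_identity,
        min_length=config.min_length,
        k=config.kmer,
    )
    couples = count_vj_couples(encompassing, total_reads=total_reads)
    subgroup_couples = aggregate_by_subgroup(
        couples, total_reads=total_reads, method=config.subgroup_method
    )
    main_allele = main_clone(couples) if couples else None
    main_sub = main_clone(subgroup_couples) if subgroup_couples else None

    partial = select_partial_mates(encompassing, pairs_by_id)
    d_aligner = SeededDAligner(germline.d_segments, config.min_seed)
    d_hits = {(pm.read_id, pm.mate): d_aligner.align(pm.seq, pm.read_id, pm.mate) for pm in partial}
    clones = [
        assign_d(c, partial, germline.d_segments, config.min_seed, d_hits=d_hits)
        for c in couples[: config.top_n_couples]
    ]

    references: list[VirtualReference] = []
    main_reference = None
    annotation = None
    coverage = None
    failure = None
    if clones and clones[0].d_name is not None:
        unmapped_pairs = [p for p in pairs if p.read_id in partition.vdj_unmapped]
        try:
            recon_clone = _refine_clone_alleles(clones[0], encompassing, germline)
            main_reference, references, alignments = reconstruct_main_clone(
                recon_clone,
                encompassing,
                pairs_by_id,
                germline,
                unmapped_pairs,
                total_reads,
                min_seed=config.min_seed,
                min_identity=config.min_identity,
                min_length=config.min_length,
                k=config.kmer,
            )
            annotation = annotate_junctions(
                main_reference.sequence,
                germline.get(main_reference.v_name).sequence,
                germline.get(main_reference.d_name).sequence,
                germline.get(main_reference.j_name).sequence,
            )
            coverage = coverage_profile(
                main_reference, alignments[main_reference.source_read_id]
            )
        except ReconstructionError as exc:
            failure = str(exc)
            logger.warning("reconstruction failed: %s", exc)
    elif clones:
        failure = "no D evidence for the main clone"

    counters = {
        "n_pairs_in": len(pairs),
        "n_vdj_unmapped": len(partition.vdj_unmapped),
        "n_vdj_mapped": len(partition.vdj_mapped),
        "n_discarded": len(partition.discarded),
        "n_encompassing_records": len(encompassing),
        "n_encompassing_reads": len({r.read_id for r in encompassing}),
        "n_couples": len(couples),
        "n_partial_mates": len(partial),
        "n_references": len(references),
    }
    return RunResult(
        config=config,
        total_reads=total_reads,
        partition=partition,
        n_encompassing=counters["n_encompassing_reads"],
        couples=couples,
        subgroup_couples=subgroup_couples,
        main_allele=main_allele,
        main_subgroup=main_sub,
        clones=clones,
        references=references,
        main_reference=main_reference,
        annotation=annotation,
        coverage=coverage,
        reconstruction_failure=failure,
        counters=counters,
    )


def report_monoclonality(result: RunResult) -> dict[str, object]:
    """Summary record: top-1/top-2 ratios and the top-5 clone table.

    A ratio of ``inf`` (serialized as null) marks a sample with a single
    detected couple; a tie flag marks equal top counts.
    """

    def fmt(call: MainCloneCall | None) -> dict[str, object]:
        if call is None:
            return {"v": None, "j": None, "count": 0, "ratio": None, "tie": False}
        return {
            "v": call.couple.v_name,
            "j": call.couple.j_name,
            "count": call.couple.count,
            "ratio": None if math.isinf(call.ratio) else round(call.ratio, 4),
            "tie": call.tie,
        }

    return {
        "allele_level": fmt(result.main_allele),
        "subgroup_level": fmt(result.main_subgroup),
        "top5": [
            {"v": c.v_name, "j": c.j_name, "count": c.count, "score": c.score}
            for c in result.couples[:5]
        ],
    }


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


def _clone_table(result: RunResult) -> pd.DataFrame:
    rows = []
    d_by_couple = {(c.vj.v_name, c.vj.j_name): c for c in result.clones}
    for rank, c in enumerate(result.couples, start=1):
        dcall_ = d_by_couple.get((c.v_name, c.j_name))
        rows.append(
            {
                "rank": rank,
                "v_name": c.v_name,
                "j_name": c.j_name,
                "v_subgroup": parse_segment_name(c.v_name).subgroup,
                "j_subgroup": parse_segment_name(c.j_name).subgroup,
                "count": c.count,
                "rpkm_like": c.score,
                "tie_flag": c.tie,
                "d_name": dcall_.d_name if dcall_ else None,
                "d_support_top": (
                    dcall_.d_support.get(dcall_.d_name, 0) if dcall_ and dcall_.d_name else 0
                ),
                "d_flag": dcall_.d_flag.value if dcall_ else "",
            }
        )
    return pd.DataFrame(rows)


def _subgroup_table(result: RunResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": i,
                "v_subgroup": c.v_name,
                "j_subgroup": c.j_name,
                "count": c.count,
                "rpkm_like": c.score,
            }
            for i, c in enumerate(result.subgroup_couples, start=1)
        ]
    )


def _reference_table(result: RunResult) -> pd.DataFrame:
    rows = []
    for ref in result.references:
        row = {
            "source_read_id": ref.source_read_id,
            "score": ref.score,
            "support": ref.support,
            "length": len(ref.sequence),
            "tie": ref.tie,
        }
        for label, start, end in ref.spans:
            row[f"{label}_start"] = start
            row[f"{label}_end"] = end
        rows.append(row)
    return pd.DataFrame(rows)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(
    result: RunResult,
    outdir: str | Path,
    input_digests: Mapping[str, str] | None = None,
) -> None:
    """Write the report bundle into ``outdir`` (created if needed).

    The bundle is a pure function of inputs, configuration and seed: file
    contents contain no timestamps or wall-clock data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    write_partition(result.partition, outdir)
    _clone_table(result).to_csv(outdir / "clones.tsv", sep="\t", index=False)
    _subgroup_table(result).to_csv(outdir / "subgroup_clones.tsv", sep="\t", index=False)
    _reference_table(result).to_csv(outdir / "references.tsv", sep="\t", index=False)

    with open(outdir / "monoclonality.json", "w") as fh:
        json.dump(report_monoclonality(result), fh, indent=2, sort_keys=True)
        fh.write("\n")

    if result.main_reference is not None:
        ref = result.main_reference
        ann = result.annotation
        header = (
            f">main_clone source_read={ref.source_read_id} "
            f"v={ref.v_name} d={ref.d_name} j={ref.j_name} "
            f"support={ref.support} score={ref.score:.4f}"
        )
        if ann is not None:
            header += (
                f" del_v3={ann.deleted_v3} del_d5={ann.deleted_d5}"
                f" del_d3={ann.deleted_d3} del_j5={ann.deleted_j5}"
                f" ins_vd={ann.inserted_vd or '-'} ins_dj={ann.inserted_dj or '-'}"
            )
        with open(outdir / "main_clone.fasta", "w") as fh:
            fh.write(header + "\n")
            seq = ref.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
        if ann is not None:
            with open(outdir / "junctions.json", "w") as fh:
                json.dump(asdict(ann), fh, indent=2, sort_keys=True)
                fh.write("\n")
        if result.coverage is not None:
            write_bedgraph(result.coverage, "main_clone", str(outdir / "coverage.bedgraph"))
    elif result.reconstruction_failure:
        with open(outdir / "reconstruction_failed.txt", "w") as fh:
            fh.write(result.reconstruction_failure + "\n")

    manifest = {
        "tool": "ighclone",
        "version": __version__,
        "config": asdict(result.config),
        "total_reads": result.total_reads,
        "seed": result.config.seed,
        "input_digests": dict(sorted((input_digests or {}).items())),
        "stage_counters": dict(sorted(result.counters.items())),
    }
    tmp = outdir / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, outdir / "manifest.json")


def run_pipeline(
    fastq1: str | Path,
    fastq2: str | Path,
    v_fasta: str | Path,
    d_fasta: str | Path,
    j_fasta: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    sam: str | Path | None = None,
    locus_bed: str | Path | None = None,
) -> RunResult:
    """File-level entry point: load inputs, run all stages, write the bundle.

    With ``sam`` given, the partition stage ingests the precomputed
    alignments (the locus then comes from ``locus_bed``) instead of running
    the internal mapper.  Missing input files raise before any computation.
    """
    from .simulate import read_fastq_pair  # local import; simulate pulls partition

    for path in (fastq1, fastq2, v_fasta, d_fasta, j_fasta):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    config = config or PipelineConfig()
    germline = load_germline_set(v_fasta, d_fasta, j_fasta)
    pairs = read_fastq_pair(fastq1, fastq2)

    partition = None
    locus = None
    if sam is not None:
        if locus_bed is None:
            raise ValueError("SAM ingestion requires a locus BED file")
        intervals = _read_bed_intervals(locus_bed)
        partition = ingest_sam(sam, intervals, require_both_unaligned=config.require_both_unaligned)

    result = run_analysis(pairs, germline, config, locus=locus, partition=partition)
    digests = {
        str(Path(p).name): sha256_file(p)
        for p in (fastq1, fastq2, v_fasta, d_fasta, j_fasta)
    }
    if sam is not None:
        digests[str(Path(sam).name)] = sha256_file(sam)
    write_report(result, outdir, input_digests=digests)
    return result


def _read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            out.append((cols[0], int(cols[1]), int(cols[2])))
    return out
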