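# Methods

## Model of the data

An IGH variable-region transcript is modeled as

```
trimmed V + p_v + n1 + p_d5 + trimmed D + p_d3 + n2 + p_j + trimmed J
```

where trimming removes bases from the 3' end of V, both ends of D and the
5' end of J; `n1`/`n2` are non-templated TdT additions; and each P string
is the reverse complement of the adjacent terminal bases, present only
where the adjacent end is untrimmed (hairpin opening leaves no palindrome
once the end is resected). A sample is a mixture of one dominant clone and
a polyclonal background of distinct rearrangements; reads are 100 bp
paired-end with substitution errors. All sequences are kept in transcript
(sense) orientation — the IGH locus is genomically minus-strand, so
genomic ingestion reverse-complements once at load time — and all
coordinates are 0-based half-open.

## Simulator parameters and defaults

| parameter | default | why |
|---|---|---|
| read length | 100 nt | short-read paired-end regime the method targets |
| fragment length | normal(200, 40), truncated to [read length, transcript length] | a realistic RNA-seq insert distribution over the V(D)J span; overlapping mates occur at a realistic rate, and junction-bridging pairs (both mates touching D) exist. A mean near 400 — appropriate for full-length mRNA libraries — would make bridging pairs essentially impossible on a ~360 nt V(D)J span, because a ~15–35 nt D can only be touched by both mates when they overlap |
| trims | uniform integers 0–6 per end | unstated in the literature at this granularity; config-exposed |
| N lengths | uniform integers 0–6 | same |
| P additions | probability 0.5 per untrimmed end, length uniform 1–3 | operationalizes "very short" palindromic additions; config-exposed |
| substitution error | 0 (tests choose 0 or 0.005) | Illumina-like; no indel errors, matching the ungapped alignment contracts |
| V/D/J lengths | 280–320 / 22–37 / 45–60 nt | near real IGH spans. The D minimum is held at 22 nt so that with worst-case trimming (6+6) the remnant stays ≥ 10 nt, the seeded D-aligner's detection limit: the generator's default conditions keep the D call and reconstruction well-posed by construction |
| germline structure | genes with allele pairs; allele divergence 0.015, within-subgroup gene divergence 0.08 | reproduces the two homology scales of IGH: ~98–99 % sibling alleles (multimapping across couples) and ~92 % same-subgroup genes |

Pair allocation across clones uses exact largest-remainder rounding, so
clone read counts carry no sampling noise; mate1 is always the forward
(left) fragment end and mate2 the reverse-complemented right end. The
truth table records, per pair, the source clone, fragment interval and
injected error offsets.

**Canonical junction truth.** The raw enzymatic draws are not identifiable
from sequence: an inserted base equal to the next germline base cannot be
distinguished from no trimming. The truth table therefore stores the
*canonical maximal-attribution parse* — longest germline-V prefix, longest
germline-J suffix, then the longest germline-D substring in the remaining
middle (ties: smallest 5' trim, then leftmost). `simulate.canonical_parse`
and `reconstruct.annotate_junctions` implement this definition
independently (brute force vs. longest-substring search) and are tested
against each other.

**What the simulator does not model:** somatic hypermutation, indel
sequencing errors, quality-score structure, D-less VJ joints, chimeric or
duplicate fragments, expression of non-IGH genes. Passing tests therefore
demonstrate correctness of the junction arithmetic, the counting rules and
the ranking logic under the stated noise model — not robustness to
hypermutated repertoires or library artifacts.

## Pipeline stages and numerical choices

**Alignment kernels.** All alignments are ungapped. End-to-end placement
(partition stage) uses a pigeonhole seed — a placement with ≤ m mismatches
must contain an exact chunk of length `read_len // (m+1)` — followed by
full verification; only the best-mismatch stratum is reported, at most 10
placements, otherwise the mate is suppressed and treated as unaligned
(defaults: 2 mismatches, 10 placements, both exposed). Local alignment
(V/J and reference scoring) seeds candidate (segment, diagonal) pairs with
exact 12-mers on both strands and takes the maximal-scoring (+1/−1)
stretch per diagonal. On score ties the *shorter* window wins and zero-sum
prefixes are dropped, so the reported window is the minimal one achieving
the maximal score — otherwise a junction flank that chance-matches half
its bases dilutes identity below threshold and junction-proximal hits are
lost. Identity ≥ 0.95 over ≥ 20 nt is required for a V/J hit: loose
enough that ~99 %-identical sibling alleles both report (the counting
rules depend on that), strict enough to separate subgroups. The D stage
requires an exact 10 nt seed (found via a 10-mer index, which is exactly
equivalent to a longest-common-substring ≥ 10 test) and reports one best
extension per mate, ties broken lexicographically.

**Counting.** Couple support is a *set* of read ids — one count per read
per couple regardless of how many position pairs support it — and a read
listing several couples counts in each. Subgroup aggregation unions the
read sets (a summing mode exists for comparison). The RPKM-like score is
`support / total_reads × 1e9` with the per-length normalization
deliberately removed: V/D/J spans are comparable to or shorter than one
mate, so length normalization would distort comparisons. `total_reads` is
the number of input read pairs. Ties anywhere resolve lexicographically on
formatted names and are flagged.

**Reconstruction.** Only reads supporting the top couple whose both mates
carry a D hit (on the assigned D, forward orientation after orienting each
mate by its V/J hit strand) are used. Overlapping attributions at the
V→D and D→J boundaries — a junction base equal to the adjacent germline
base extends either hit — are resolved by trimming at the boundary; the
assembled sequence is invariant under the cut choice. The two mates' D
evidence is spliced in a shared diagonal coordinate system, which handles
every overlap relation (including one mate's D evidence containing the
other's); mates disjoint on D are germline-filled between their covered
intervals. References extend through the full germline V and J; trimming
is inferred afterwards by the annotator rather than committed during
construction. Identical reference sequences are collapsed (smallest
source read id kept) before scoring; support counts unmapped *pairs* (a
mates mode exists), and the score reuses the RPKM-like form with library
size as denominator — the form printed for couple sorting, reused here as
an interpretation since reference scoring is only described as "an
RPKM measure".

**Sibling-allele refinement.** Because couple counting multimaps by
design, the top couple's allele labels are arbitrary within a sibling set
(the counts tie up to background noise). Extending a reference with the
wrong sibling would silently corrupt the read-uncovered germline prefix.
Before assembly, the V and J alleles are therefore re-chosen by voting:
each supporting read votes for the candidate allele with the strictly
best local score on the relevant mate; reads that cannot distinguish the
candidates abstain; ties resolve lexicographically. The clone table
itself is left as counted — refinement feeds only reference assembly and
annotation. D alleles need no extra step: the per-mate single-best-hit
rule already votes, and the only D germline bases entering a reference
are the (usually empty) fill between disjoint mates.

**Annotation.** `annotate_junctions` computes the canonical parse of the
reconstructed sequence against the named germline segments and errors out
if either the V prefix or J suffix anchor is shorter than 15 nt. When the
D remnant matches nowhere, the whole middle is reported as VD insertion
with the D fully deleted — a convention, flagged by the all-deleted D
counts.

## Degenerate inputs and edge behaviour

Empty reference sets, zero `total_reads`, counts exceeding the library
size, malformed allele labels, duplicate FASTA names, transcripts shorter
than the read length, and trim distributions reaching a segment length all
raise typed errors naming the offending object. A sample with no
encompassing reads yields an explicit "no rearrangement detected" error;
a main clone without D evidence or bridging reads yields a reconstruction
failure carrying the bridging diagnostics instead of a sequence. The
partition stage asserts on every run that its three classes disjointly
cover the input ids.

## Determinism

Every random draw flows through a single seeded generator; dictionary and
set iterations are sorted before use; the report bundle (tables, FASTA,
BedGraph, manifest) contains no timestamps or wall-clock data, so
identical inputs and seed reproduce it byte-for-byte. The manifest
records the configuration snapshot, input digests and deterministic
per-stage counters. The `--threads` flag is accepted for interface
compatibility; execution is single-threaded, which makes the
independence-of-parallelism contract trivial.

## Validation-study sizes

The self-validation battery (`ighclone.validation`, used by the test
suite and `scripts/acceptance.py`) runs twenty samples of 5,000 read
pairs each per condition — large enough that the main clone yields
several hundred encompassing reads and tens of bridging reads per sample,
small enough that the full battery completes in a few minutes on one
CPU. Recovery is scored at subgroup level for the VJ couple and at gene
level for D: with allele pairs at 98–99 % identity, sibling alleles of a
22–37 nt D segment are frequently byte-identical (and their trimmed
remnants more often still), so allele-level truth matching is not a
well-posed target at these study conditions, while gene-level identity
is.

## Known limitations

- Substitution-only alignment: indels in reads or somatic hypermutation
  clusters will break placements rather than gap them.
- Only the IGH locus and a single dominant clone are modeled; light
  chains, TCR loci and subclone structure are out of scope.
- The D call is undefined (and flagged) when the trimmed D remnant is
  shorter than the 10 nt seed — a limit of the method, inherited by any
  data with heavy D resection.
- The SAM ingestion path classifies pairs by flags and locus overlap
  only; it does not re-examine alignments.
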