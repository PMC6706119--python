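# Methods

## Problem and scope

Given a reference genome (FASTA, lowercase = soft-masked repeats), gene
models (refGene table or BED12) and a target query (gene symbol, transcript
ID, genomic region, or a raw DNA sequence placed by exact match), crisprkit
enumerates SpCas9 candidate guides, measures each guide's genome-wide
off-target landscape within a mismatch budget, scores specificity and
(optionally) efficiency, and exports a design table. Everything runs on
desk-scale genomes and per-region queries; FM-index scaling to full
mammalian genomes, spacer/protospacer bulges, chromatin accessibility and
network services (Blat-style fuzzy placement, REST lookups) are out of
scope.

## Coordinates and query resolution

Internally everything is 0-based half-open. The colon region dialect
`chrX:NNNNN-NNNNN` is treated as 1-based inclusive (the genome-browser
convention) and converted on parse; BED input passes through unchanged.
Gene and transcript lookup is case-insensitive; an identifier matching two
different genes is an error, never a silent pick. Raw DNA queries (capped
at 20 000 bases) are placed by exact match of the sequence and its reverse
complement; zero or multiple occurrences are errors because a guide designed
against an ambiguous locus is not actionable.

## Candidate scanning

A site is `guide_length` spacer bases (20, or 18 for truncated guides)
followed 3' by a PAM matching NGG. Minus-strand sites are found as the
reverse-complement pattern (CCN…) on the forward text. The spacer must lie
inside the queried interval; the PAM may use genome context just beyond it,
since a guide at an exon edge still has its genomic PAM. Sites containing N
are dropped. Soft-masked candidates are *kept but flagged* `in_repeat`:
whether repeat guides are usable is a policy question, so exclusion happens
in the filter layer, while masked *off-target* loci are excluded by default
(configurable) — repeat-derived hits are unmappable noise for specificity.
Overlapping sites are all reported; CRISPR sites legitimately overlap.

## Off-target enumeration

All windows (both strands) whose 3'-adjacent 3-mer is NGG or NAG are
potential off-target loci; the PAM class is recorded per hit so NAG-specific
post-processing stays possible. Search is pigeonhole seed-and-verify: the
spacer is partitioned into `budget + 1` contiguous, near-even blocks; any
occurrence within the budget must match one block exactly, so candidate
windows are collected from per-block hash tables and verified by full
Hamming comparison. This is exact within the budget — no heuristics — and
is cross-checked in the test suite against an independent brute-force scan
of every window (the central correctness property, exercised on hundreds of
random genomes). Default budgets: 4 mismatches for 20-nt guides, 3 for
18-nt guides (off-target counts grow rapidly with the budget, and truncated
guides with >3 mismatches rarely cleave detectably).

Self-exclusion is by locus identity, not sequence: a perfect duplicate
elsewhere is a genuine 0-mismatch off-target. Mismatch positions are
1-based from the PAM-distal (5') end, matching the weight-vector ordering.

## Specificity scoring

Per hit: `s = Π_p (1 − M[p]) · D · 1/n²` with
`D = 1/(((L−1−d̄)/(L−1))·4 + 1)` and `d̄ = (max−min)/(n−1)` the mean
consecutive-mismatch spacing; for `n ≤ 1` the spacing is undefined and we
take `D = 1` (the limit behaviour — a lone mismatch has no clustering).
`M` is the 20-value empirical mismatch-weight vector; truncated guides use
its last 18 values with `L = 18`. The aggregate is
`10000/(100 + 100·Σ s_h)` over all hits excluding the on-target self-hit —
including it would cap every guide at 50, which contradicts the ≥ 50 filter
preset being meaningful. NAG hits enter with a configurable multiplier,
default 1.0 (no published down-weighting is assumed); the multiplier is
applied per hit so alternatives are pure post-processing.

## Efficiency scoring

A linear sequence model: intercept plus one coefficient per (window
position, nucleotide), over a window of upstream flank + spacer + PAM +
downstream flank (default geometry 4+20+3+3 = 30 nt, but the geometry is
declared in the coefficient TSV header and travels with the model — it is
never hard-coded). Minus-strand contexts are reverse-complemented before
scoring. A site whose window runs off a contig is scored *missing*, not 0:
zero is a meaningful model output, absence is not. Real published
coefficient sets are not shipped; the TSV interface and toy models are.

## Annotation and filters

"Exonic" means ≥ 1 spacer base overlaps ≥ 1 exon base (PAM excluded —
cleavage lies inside the spacer). Exon ranks come from the composite gene
model (union of all transcript exons, numbered in transcription direction)
or from a single transcript's exons when a transcript ID was the query;
coordinate queries report no exon rank. The four batch presets: exonic
only; specificity ≥ 50 (inclusive); efficiency > 0 (strict); closest
mismatch > 1 (strict). Guides with *no* off-target hits pass the mismatch
predicate vacuously — absence of similar sequence is maximal specificity —
and print their closest mismatch as `> 4` (or `> 3` at budget 3).
Histograms are colon-joined counts over bins 0..budget, e.g. `0:0:0:0:4`.

## Batch export

The 100-entry batch cap is enforced in the library with an explicit
override flag (it protects shared runs; it is not a method limit).
Per-entry resolution failures are collected and reported at the end rather
than aborting the batch. CSV locations use the 1-based colon dialect
(display convention); BED stays 0-based half-open and is emitted sorted
(chrom lexicographic, start numeric), ready for bgzip/tabix. Scores are
exported rounded to 2 decimals but kept full-precision internally. The
GuideID wire format `<assembly>_<chrom>_<start0>_<strand>_<length>` is this
package's own invention: deterministic, injective over those fields, and
re-parseable.

## Synthetic fixtures — what a green test establishes

`crisprkit.fixtures` generates uniform-composition random genomes (default
GC 0.5, seeded NumPy generator), plants guides, off-target copies at exact
Hamming distances, soft-masked blocks and simple gene models, then
*verifies* the plant by brute force: the enumerated hit set of every guide
must equal the declared set exactly, otherwise the genome is regenerated
(bounded rejection sampling; the manifest is therefore the unique ground
truth). Typical test genomes are 1.5–8 kb — large enough for incidental
PAM windows, small enough for the exhaustive oracle. These fixtures emulate
coordinate bookkeeping, strandedness, masking and Hamming structure; they do
not emulate real genome composition (repeat families, CpG islands, homology
clusters), so green tests establish algorithmic correctness, not predictions
about off-target load in hg19-scale genomes.

## Numerical and degenerate-input choices

- All sequence comparison is case-insensitive; case only carries the
  repeat flag.
- A window carrying both NGG and NAG readings cannot exist (one PAM per
  window); overlapping windows are distinct hits, deduplicated by
  (locus, strand).
- Budget 0 degenerates to exact matching (one seed = the whole spacer);
  budget ≥ guide length makes the Hamming bound vacuous.
- An empty hit list aggregates to exactly 100; the aggregate is strictly
  decreasing in every added hit.
- Promoter choice (U6/T7) is accepted and echoed as metadata only: no
  sequence rule is applied because none is established.

## Known limitations

Pure-Python search: fine for ≤ 100 kb fixtures and per-gene queries, not
for whole-genome precomputation. Hamming-only alignment (no bulges).
Specificity weights are SpCas9-specific; no Cas variant vectors. The
efficiency interface ships without trained coefficients.
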