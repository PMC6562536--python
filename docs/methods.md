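# Methods

This note documents the models, rules and numerical choices behind
`cisreg`, the assumptions they rest on, and what the synthetic study does
and does not establish about real data.

## Coordinate conventions

All in-memory coordinates are 0-based half-open (BED-style). GTF (1-based
inclusive) is converted at the I/O boundary: the TSS of a + strand gene is
its 0-based `start`, of a − strand gene `end − 1`. Chain files keep the
UCSC convention, including reverse-strand target coordinates expressed
from the far end of the chromosome; reflection onto the forward strand
happens only in the mapper. Every overlap predicate in the package is
"≥ 1 bp on half-open intervals" — the weakest reading, applied uniformly.

## Peak quality control

Narrow peaks with Poisson *p* > 0.01 and broad peaks with *p* > 0.1 are
removed; boundary values (exactly 0.01 / 0.1) survive because only strictly
greater values are filtered. RPM is reads-per-million over an interval,
computed by integrating a bedGraph-backed per-base read density and
dividing by the library size declared in the track's `# total_reads=`
header — taking the total from a header rather than re-summing the track
keeps RPM well-defined for partial or peak-masked tracks. Partial bins are
pro-rated by overlap fraction, so RPM is additive over disjoint intervals
and agrees with per-base summation to ≤ 1e-9 relative error. The
enrichment rule keeps a peak iff RPM_IP ≥ 2·RPM_input **and**
RPM_IP − RPM_input > 1 (a difference of exactly 1 fails). RPM is computed
from read counts, not fragment counts.

Replicate QC computes Pearson *r* between 10 kb-binned read counts; bins
that are zero in both replicates are retained (dropping them would inflate
*r* on sparse marks). Replicate pooling itself is upstream of this
package; pooled coverage is an input.

## Element classification

* **promoter** — every QC-passed H3K4me3 peak. An optional
  `restrict_promoters_to_tss` flag confines promoters to TSS-window
  overlaps; it is off by default, since requiring it would conflate the
  promoter definition with the broad-domain rule.
* **active / poised promoter** — promoters with / without ≥ 1 bp H3K27ac
  overlap; the two classes partition the promoter set.
* **enhancer** — H3K27ac peaks with zero H3K4me3 overlap and zero overlap
  with any TSS window (2.5 kb upstream, 1.5 kb downstream, strand-aware,
  clipped at chromosome bounds). "Outside" is read as zero overlap, the
  strictest exclusion. H3K27ac peaks that fail the enhancer rules without
  touching H3K4me3 are reported as unclassified rather than dropped.
* **broad H3K4me3 domain** — TSS-window-overlapping H3K4me3 peak whose
  *original* width exceeds 4 kb (width 4,000 exactly is not broad).
  Width is measured before any standardization: measuring it on the 2 kb
  standardized form would make the rule unsatisfiable.

Inputs are sorted internally, so class counts are invariant under input
permutation. Top-enhancer ranking sorts by H3K27ac RPM descending with a
(chrom, start) tie-break, making the ranking stable across runs.

## Super-enhancers

Stitching joins enhancers whose gap is ≤ 12,500 bp on the same chromosome
(transitive closure; the boundary convention is fixed here because
reference implementations leave it implementation-defined). TSS-proximal
exclusion before stitching is off by default — elements reaching this
stage are already TSS-depleted by the enhancer definition — and available
behind a flag for standalone use. Region signal is
Σ(RPM_IP − RPM_input) over constituent intervals only; stitched gaps
contribute nothing. Negative signals (input exceeding IP) are flagged.

The cutoff is geometric: with ranks scaled to x ∈ [0, 1] and signals to
y ∈ [0, 1], the cutoff index is argmax(x − y) — the tangent point where
the scaled curve's slope reaches 1 — and regions with signal strictly
above the cutoff signal are super-enhancers. Ties resolve to the highest
index (fewest super-enhancers, the conservative choice); an all-equal
signal vector has no elbow and yields zero super-enhancers with a warning.
On heavy-tailed signal (Pareto tail index 1.5, n = 2,000) the called
fraction stays below 10% of stitched regions.

Gene assignment defaults to *overlap-then-nearest*: all genes whose TSS
lies inside the stitched interval, else the single nearest TSS by
midpoint distance, ties to the lexicographically first gene id. A pure
nearest-TSS mode is available; the same nearest rule (and tie-break) is
used for generic element–gene linkage.

## Cross-species conservation

Elements are standardized to 2 kb centered on their summits before any
cross-species comparison; windows are clipped (not dropped) at chromosome
bounds with a recorded flag, since dropping would silently bias telomeric
elements. The enrichment filter is re-applied to the standardized forms;
re-filtering can only shrink the set.

Mapping follows liftOver semantics: an interval maps iff at least
`min_match` (default 0.2) of its bases fall in the aligned blocks of a
single chain; the aligned-base count equals what per-base mapping would
give, and the target interval is the forward-strand span of the mapped
bases. Hits whose qualifying bases split across chains are rejected unless
`allow_multiple` is set (mirroring liftOver's default rejection of split
hits). Mapping is one-way (source → target); a reciprocal check was
considered and left out of the default path because the classification
below already conditions on the target annotation.

Status assignment: unmapped → un-conserved; mapped with ≥ 1 bp overlap
with a *same-class* target element → functionally conserved; mapped
otherwise → sequence-only conserved. The three statuses partition every
element set. If a class is absent from the target annotation entirely, all
its mapped elements become sequence-only and a warning is raised.

Distance analyses measure element midpoint to nearest TSS on the same
chromosome. The distance comparison between functionally and
sequence-only conserved enhancers uses the two-sample KS test plus a
control band of 100 random draws (default 4,000 elements per draw, without
replacement within a draw; the demo scales the draw size to half the
element pool, since a draw the size of the pool would be degenerate).

The chromatin-state overlay assigns, per element per tissue, the category
of the state segment with the largest overlap (ties: leftmost segment,
then label) — largest-overlap rather than any-overlap keeps the
element × tissue matrix single-valued. Uncovered tissues read "other". An
element counts as regulatory if any tissue yields primary DNase, weak
enhancer or active enhancer. The category map (state label → category) is
user-supplied; no fixed 25-state model is assumed. The matrix is one-hot
encoded and k-means clustered (k = 100, fixed seed, rows renumbered by
cluster size) for presentation.

## Expression

Quantile normalization maps every column onto the per-rank across-column
mean of sorted values; tied values within a column receive the mean of the
tied ranks' reference values. With ties this deliberately trades the exact
"all sorted columns identical" identity for rank symmetry (the tie group
gets one shared value); on tie-free data the identity is exact and the
transform is idempotent. Normalization operates on TPM.

DE classification: |log₂fold| ≥ 2 (inclusive, as printed), *p* < 0.001 and
FDR < 0.01 (both strict). FDR is consumed from the input table or computed
by Benjamini–Hochberg on the supplied p-values behind a flag; the
negative-binomial model that produces per-gene p-values is out of scope —
statistics are consumed, or synthesized by the generator.

Group comparisons use the Wilcoxon rank-sum test: exact null enumeration
when the smaller group has ≤ 8 observations and the pooled sample is
tie-free, otherwise the normal approximation with tie correction and
without continuity correction (so a perfectly centered statistic gives
p = 1 exactly). The ≤ 8 switch keeps the exact path verifiable against
full enumeration while remaining fast.

## Core regulatory circuitry

Motif occurrence is a log-odds scan: score = Σ log₂(p_base/q_base) over
motif positions, both strands, N contributing 0; a hit is a window scoring
at least the threshold. The default threshold is 6 bits; this replaces a
p-value-calibrated scanner, whose null distribution depends on machinery
outside this package's scope, with a transparent, configurable statistic.
The end-to-end demo scans its planted 10-mers at 12 bits (a planted exact
occurrence scores ≈ 19.6 bits; 12 bits excludes almost all chance matches
in random sequence). Constituent sequences may be extended ±500 bp behind
a flag.

A TF is a CRC candidate if a super-enhancer is assigned to it and it is
expressed (≥ 1 TPM). A candidate is a node iff its own motif hits its own
constituents (auto-regulation); A→B iff A's motif hits B's constituents;
circuitries are the maximal cliques of the mutual (bidirectional) graph,
enumerated exactly (Bron–Kerbosch via networkx) with a 64-node cap — real
CRC graphs are an order of magnitude smaller. Cross-species comparison
intersects clique-member TF names case-insensitively via the one-to-one
orthology table, and reports both the all-species shared fraction and the
at-least-two-species shared fraction, because "consistent across species"
admits both readings.

## Synthetic study design

The generator emulates every input at desk scale. Defaults define the
study conditions: 2 chromosomes × 3 Mb, 200 non-overlapping stranded
genes, 200 H3K4me3 peaks (90% at TSS, ~5% wider than 4 kb), 300 H3K27ac
peaks (85% TSS-distal), 26 super-enhancer loci (clusters of 3–4 strong
enhancers placed just outside a target gene's TSS window), planted
conservation fractions 0.30 functional / 0.55 sequence-only, chain
coverage 0.9 with indels and one reverse-strand chain, Pareto tail
exponent 1.5 for typical-enhancer signal, a +2 log₂ expression shift on
super-enhancer target genes (+1.5 for active-promoter genes, +1 for
broad-domain genes), 78% of sequence-only elements planted regulatory in
at least one of six tissues (kidney weighted heaviest), multiplicative
coverage noise σ = 0.05, and 10 bp coverage bins. These sizes make the
whole study run in seconds while leaving every geometric feature (elbow,
TSS windows, chain gaps) well-resolved; the controlled conservation
experiment scales to 5,000 elements on 2 × 30 Mb where binomial sampling
error on a fraction is ±0.006 (1 SD).

Structural choices that make planted truth exact: super-enhancer loci are
kept non-adjacent and surrounded by a stitch-distance guard so clusters
never merge with each other or bridge to a neighboring gene; conservation
statuses are planted per connected component of overlapping elements
(overlapping elements map to overlapping targets, so independent statuses
would contradict each other); in the slot-based chain mode each element
owns one aligned block (mappable) or one chain gap (un-mappable), making
every per-element status exact by construction. Coverage is deposited so
that with zero noise the RPM recomputed from the track equals the peak
record exactly; with noise, per-bin multiplicative factors perturb it
within σ. All sub-generators draw from `(seed, stream)`-seeded Generators,
so identical configs give byte-identical files and changing one stage's
draws never perturbs another's.

What the synthetic study does **not** establish: realistic nucleotide
composition, read-level noise (no aligner or duplication artifacts, no
Poisson peak-caller model), realistic chain geometry (blocks are clean and
colinear), biological correlation structure between marks, or realistic
motif content (planted k-mers, not JASPAR-like information content).
Passing tests therefore demonstrate the correctness of the rules and their
boundary behavior, and end-to-end recovery of planted parameters — not
performance on real ChIP-seq, where peak calling and alignment quality
dominate.

## Degenerate inputs and numerical notes

Empty gene sets make the enhancer definition undefined and are rejected
(the CLI exits 2); an empty annotation file yields zero TSS records rather
than a parse error. All-equal elbow signals, candidate TFs without PWMs,
classes absent from target annotations, and tissues without covering
segments each produce a defined, warned-about result instead of an
exception. Chain files are validated on load (block sums against declared
spans, named chain id in the error). Floating-point comparisons in tests
use ≤ 1e-9 relative tolerance against per-base or enumeration oracles;
boundary rules (p = 0.01, width 4,000, RPM difference 1, gap 12,500) are
asserted exactly.
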