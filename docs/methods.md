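# Methods

This note records the statistical model behind circkit, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical decisions a maintainer would want written down.

## Discovery model

A back-splice junction is an ordered pair (acceptor_start, donor_end) on one
chromosome with acceptor_start < donor_end; internally all coordinates are
0-based, half-open, forward-strand, with the strand carried separately. A
junction-spanning read decomposes into a 5′ segment mapping genomically
*downstream* of its 3′ segment — the reverse of linear splicing.

The split aligner is exact and exhaustive: for every breakpoint leaving both
segments ≥ `anchor_min` (default 20 nt) it enumerates all exact occurrences
of both segments in both read orientations and keeps same-chromosome,
reversed-order pairs with span ≤ `max_span` (100 kb). The split stage is
exact by design — its evidence is a literal sequence joint, and tolerating
mismatches there mostly admits artifacts; 20-nt anchors make exact matches
near-unique at the genome sizes this implementation targets (the aligner is
a string scan, not an indexed aligner — see Limitations). A read whose
placements map to more than one junction *after shift-canonicalization* is
discarded as ambiguous: specificity is preferred over recall throughout.
Reads related by sliding the breakpoint across junction-straddling repeats
are one placement; the canonical representative takes the most negative
valid shift.

Splice-signal refinement enumerates breakpoint shifts s ∈ [−5, +5] for which
the read still matches both loci exactly (the transferred bases must agree
between the two loci), and accepts the first shift, ordered by (|s|, sign
with negative first), that puts GT immediately 3′ of the donor and AG
immediately 5′ of the acceptor. Strand is inferred from signal orientation:
GT..AG on the forward strand means a plus-strand junction; the forward-strand
pattern CT-before/AC-after is the reverse-complement reading of a minus-
strand GT‑AG intron pair. If no GT‑AG exists at any valid shift, AT‑AC
(minor spliceosome) is tried the same way; otherwise the junction keeps its
unshifted coordinates with `signal_class="other"`. Flanking windows
containing N are classified `other` without a signal search. Refinement is
idempotent: a refined junction re-refines to itself (s = 0 is always valid
and already carries the signal).

Candidates need ≥ `min_reads` (2) supporting reads — counted after collapsing
identical sequences (PCR-duplicate removal) — in at least one sample.
Non-GT‑AG candidates are retained, flagged, for the dinucleotide-enrichment
and signal-class diagnostics, and excluded from the catalog.

## Circular fraction

With donor probe *d* = last 20 exonic nt ending at the donor and acceptor
probe *a* = first 20 exonic nt from the acceptor (both read off the circle's
spliced sequence in transcript orientation, so they may cross internal exon
joints), a read counts toward:

- n_donor if it contains *d* with ≥20 read nt remaining 3′ of it;
- n_acceptor if it contains *a* with ≥20 read nt 5′ of it;
- n_junction if it contains the back-spliced 40-mer *d‖a*.

Matching is exact substring in both read orientations, at most once per read
per counter; n_junction ≤ min(n_donor, n_acceptor) holds by construction
because a junction read satisfies both sequence-space rules. The statistic

    f̂ = n_junction / (n_donor + n_acceptor − n_junction + 1)

lies in [0, 1); the +1 keeps it defined at zero evidence and shrinks it
slightly toward 0 (n/(n+1) for a pure circle). The denominator is the number
of distinct boundary-informative reads, so conditional on that number,
n_junction is binomial and exact binomial intervals apply — this is the
basis of the parameter-recovery tests. Exons shorter than the probe truncate
the probes, with a warning.

The catalog filter keeps GT‑AG junctions with f̂ ≥ `min_fraction` (0.10) in
≥ `min_samples` (2) samples; a high-fraction sublist collects circles with
f̂ ≥ 0.5 in most samples where both boundaries show any availability.
Abundance is inferred as f̂ × gene FPKM (gene = merged exonic union of all
transcripts sharing the gene id; fragments overlapping two genes count for
both), and the circRNA share of the transcriptome as Σ f̂·FPKM·L over
Σ FPKM·L for expressed (FPKM ≥ 0.1) coding genes.

## What the simulator states, exactly

`true_fraction` f is defined as the estimand of the statistic above: every
boundary-informative read is a junction read with probability f. A linear
molecule exposes two informative windows (donor and acceptor) where a circle
exposes one (the junction), so a molecule-level circular proportion m yields
an expected statistic of m/(2−m); the generator therefore converts f to
molecule proportion m = 2f/(1+f) when weighting templates. The limits
coincide (f=0 ⇒ no circles, f=1 ⇒ no linear molecules), and conditional on
the informative-read count the junction-read count is Binomial(n, f), which
the recovery tests exploit.

Fragments are allocated across templates proportionally to molecules ×
*valid fragment-start positions* — the full period for a circular template
(realized as three tandem copies of the spliced circle, so a fragment can
start anywhere in one period and run across the junction), but L − F + 1
positions for a linear template of length L at fragment length F. Weighting
by raw length instead would over-represent the boundary windows of short
linear templates by L/(L−F) and bias f̂ downward; this was measured and
fixed during development.

A second, physical edge effect remains deliberately in the model: an
informative window lying within a fragment length of a linear transcript's
end loses part of its read coverage (fragments cannot extend past the end),
which biases f̂ upward when the flanking exons are short. Real libraries
have the same geometry. Calibration-sensitive tests therefore build genes
whose flanking exons exceed fragment + read length (320–380 nt); the
simulator default (120–180 nt, ~80-nt introns, 5 exons, fragment
200 ± 20 nt, 100-nt reads) remains a realistic mammalian-exon-scale world
in which recovery is approximate rather than exactly binomial.

Other modeled behaviors: poly(A) selection removes circular templates
entirely (circles have no poly(A) tail), driving every circular fraction to
exactly 0 downstream. Intron retention is per-molecule all-or-none at rate
r: a retained circular template keeps all internal introns. The
trans-splicing contaminant for a gene is the linear transcript with the
circularizing exon block repeated (…e1 e2 e3 **e1 e2 e3** e4…): its reads
reproduce the back-splice junction word exactly, but the molecule is linear,
polyadenylated, and its junction-read mates can map beyond the block. RPF
reads (30 nt) are drawn only from linear spliced transcripts — the ground
truth that no ribosome crosses a circular junction. Sequencing errors are
off by default (the discovery stage allows ≤2 mismatches full-length and 0
in the split stage); an error rate is configurable. Quality-score realism,
GC bias and isoform-abundance realism are out of scope. A green test on this
world establishes the correctness of the estimators and rules under
error-free, uniform-coverage sampling — not robustness to real-library
artifacts.

## Mate analyses

Trans-splicing: only circles shorter than `maxlen_trans` (400 nt, from the
~200-nt insert) are informative. Mates of junction-spanning reads are mapped
contiguously with the same contract as the linear prefilter (≤2 mismatches,
unique best placement; ambiguous or splice-straddling mates are dropped) and
categorized on the junction's strand: inside_circle, intron (inside but
overlapping intronic bases), neighbor_exon (outside, on an annotated exon of
the host gene), upstream_of_acceptor / downstream_of_donor (outside,
elsewhere), other (boundary-straddling or different chromosome). The three
outside categories constitute trans-splicing evidence.

Intron retention: mates are classified by sequence at each internal splice
site of the circle — a 20-mer of exon end + next exon (spliced) versus exon
end + intron start *and* intron end + next exon (retained). Probing both
intron ends matters: a fragment anchored on the back-splice junction can
reach the spliced joint from either side of the circle, and only with both
retained words does the retained template have the same two reachable
configurations, keeping intron/(intron+exon) unbiased for r. This
sequence-level classifier replaces genomic mate mapping because mates that
span spliced joints cannot map contiguously, which would otherwise silently
discard exactly the spliced-template evidence. Pre-mRNA is not simulated; on
real data, pre-mRNA fragments would inflate retained counts for circles
co-extracted with their nascent transcripts.

## Specificity

The score of a profile p over T samples is max_t (1 − √JSD(p, e_t)) with
base-2 Jensen–Shannon divergence (0·log 0 := 0), computed via scipy's
`jensenshannon` (which returns √JSD). It is 1 exactly for indicator
profiles and decreases monotonically toward uniform. The linear control
cohort matches the circRNA set's distribution of total junction-spanning
reads in unit-width log2(total+1) bins, sampled without replacement per bin
(with replacement, with a warning, when a bin runs short); counts rather
than FPKM are matched because junction-spanning read totals are the
confounder. The maximum over samples (rather than a designated tissue) is
the standard form of the cited score. The circular-fraction matrix keeps
junctions with donor and acceptor availability ≥5 reads in every sample and
reports pairwise Spearman ρ; clustering/heatmaps are out of scope.

## Conservation

Gene-level: a 2×2 table over one-to-one orthologs (circRNA present/absent in
each species) with conditional proportions, odds ratio and Fisher's exact
p. Splice-site level: both junction boundaries are mapped through the
coordinate table (offset within the containing interval, reversed on strand
flip); boundaries matching a target circle within ±2 nt are
`same_splice_sites` (tolerance absorbs cross-species mapping round-off),
interval overlap alone is `partial_overlap`, otherwise `no_overlap`;
junctions with an unmappable boundary are reported separately as
`unmappable`. Fraction correlation averages f̂ over samples with ≥1 read of
donor and acceptor availability, then Spearman.

Codon-position tests use the host transcript's CDS: the codon position of a
base is (its index within the spliced CDS mod 3) + 1 in transcript
orientation, propagated across exons. Circular coding exons are compared to
the nearest upstream and downstream coding exons outside the circle, paired
per circRNA, with two-sided Wilcoxon signed-rank tests per position (the
paired form of the rank test); exons with >50% missing track coverage are
excluded, and paired differences below 1e−10 are treated as ties. The
matched-cohort null draws 1,000 control sets from the linear-exon pool
matching the circ set's mean position-1&2 score distribution in 0.25-wide
bins and places the circ set's position-3 mean as a percentile among the
cohort means.

## Translation

Probes are 20-mers, 10 nt each side of (i) the circular junction, (ii) the
donor's annotated linear junction, (iii) the acceptor's annotated linear
junction, all from spliced sequence; circles without an annotated linear
partner exon on both sides are excluded, as are probe sets whose circular
20-mer (or its reverse complement) occurs contiguously anywhere in the
genome (paralog risk: a junction word that also exists contiguously cannot
distinguish a circle from an adjacent duplication). Counting is read-level, both
orientations. The RPF "circular fraction" treats availability at each side
as inclusive of the junction evidence — n_d = linear_donor + circ, n_a =
linear_acceptor + circ, n_j = circ — giving circ/(circ + linear_donor +
linear_acceptor + 1): zero when no read crosses the circular junction,
approaching 1 for a pure circle, and consistent with the quantification
statistic (a disjoint-count denominator would go nonpositive for fractions
above one third). Eligibility requires RPF reads at both linear junctions.

## miRNA sites and clusters

Site words for a family with seed = mature nucleotides 2–8 (DNA space):
7mer‑m8 = reverse complement of the seed, 8mer = 7mer‑m8 + A, 7mer‑A1 =
reverse complement of positions 2–7 + A. Counting is anchored on the shared
6-mer core, each occurrence classified into exactly one class with 8mer
precedence, so totals never double-count. Sites are not counted across the
circular junction by default; `wrap_junction` appends the first 7 nt for
circle-aware scanning. The null permutes each family's 8mer uniformly over
permutations that preserve mononucleotide composition, CG-dinucleotide count
(counted on the linear word) and the terminal A — controls with similar
expected genome-wide abundance — re-derives the 7mers from the permuted
8mer, and re-runs counting over 1,000 cohorts, reporting per-pair null means
and the max envelope. A word with no valid alternative permutation (e.g.
poly-A) is kept, with a warning. Crosslink clusters are consumed as
intervals; density is clusters overlapping an exon set per exonic kb, paired
circular vs neighboring coding exons with a signed-rank test, and clusters
are assigned to every family whose site word occurs in the cluster sequence.

## Defaults (all configurable via `RunConfig` / CLI flags)

| parameter | default | rationale |
|---|---|---|
| linear-pass mismatches | 2 | tolerate sequencing error in the full-length pass |
| split-stage mismatches | 0 | the junction word is the evidence; mismatches admit artifacts |
| anchor_min | 20 nt | matches the 20-nt probes; near-unique exact matches |
| max_span | 100 kb | upper bound on plausible single-gene back-splices |
| signal window / shift | 10 nt / ±5 nt | search window for GT/AG; tie-break toward negative s |
| min_reads | 2 | independent-read support floor |
| probe_len | 20 nt | long enough to be unique, short enough to fit reads |
| min_fraction / min_samples | 0.10 / 2 | catalog quality filter |
| fragment length | 200 ± 20 nt | paired-end insert size emulated; sd ~10% chosen |
| read length | 100 nt | typical paired-end read length |
| trans-splice max circle | 400 nt | 2× the insert: mates of longer circles cannot escape |
| retention window | 200 nt | one insert length around the back-spliced boundaries |
| cf-matrix availability | ≥5 reads, all samples | fraction well-measured in every sample |
| expressed-gene FPKM | 0.1 | expressed-gene floor for abundance comparisons |
| boundary tolerance (cross-species) | ±2 nt | cross-species mapping round-off |
| permutation cohorts | 1,000 | null-distribution resolution |

## Known limitations

- The aligner is an exact string scan intended for the kilobase-to-megabase
  genomes of the tests and simulator, not an FM-index aligner for full
  mammalian genomes.
- Gapped or mismatched split alignment is out of scope by design; sequencing
  errors on the junction word cost sensitivity.
- Split (spliced) mates are not mapped in the trans-splicing analysis; the
  retention estimator works at the sequence level instead.
- Multi-mapping resolution is "discard ambiguous"; no EM reassignment.
- The catalog filter at the f = 0.1 boundary is intrinsically noisy at
  moderate depth: an estimate for a junction planted exactly at the
  threshold falls on either side with near-even odds per sample.
- Single-exon circles have no internal splice site, so their intron
  retention is undefined (reported NaN), and retention evidence requires
  circles short enough for mates of junction reads to reach internal splice
  sites.
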