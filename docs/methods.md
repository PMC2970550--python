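# Methods

## The statistical model

The differential-expression caller treats each RNA-seq library as a
multinomial draw over genes: gene g occupies a fraction f_g of the
transcriptome, and a library of N reads yields counts
k_g ~ Binomial(N, f_g) marginally.  To compare a haploid/tetraploid
pair without replicates, the caller plugs the haploid frequency
f_h = k_h/N_h into a binomial model for the tetraploid count and
evaluates the one-sided tail in the observed direction:

    p_t|h = P(X ≤ k_t),  X ~ Binomial(N_t, f_h)   if f_t ≤ f_h
    p_t|h = P(X ≥ k_t)                            otherwise

and reciprocally for the haploid count under the tetraploid frequency
(with the opposite tail).  A gene passes when it is expressed (count
≥ 15 in at least one sample of the pair) and both reciprocal tails are
below α = 0.001.  Tails are computed through scipy's regularised
incomplete-beta implementation, stable for library totals up to at
least 1e8; a zero reference frequency uses the conventions
P(X ≤ k | f=0) = 1 and P(X ≥ k | f=0) = 0 for k > 0.

**The plug-in test is anti-conservative.**  Because the reference
frequency is itself an equally noisy estimate, the implicit z-statistic
compares a difference with variance ≈ 2µ against a threshold calibrated
for variance µ.  Under a no-signal simulation the per-pair pass rate at
α = 0.001 sits at the few-percent level at any depth (the acceptance
script measures it on 10,000 genes), far above α.  This is a property
of the method, not of the implementation, and it is the reason the
pipeline never reports per-pair candidates as final calls: the
replicate-overlap stage below removes essentially all of them (the
null simulation's final list is empty).

## Replicate overlap

Per-pair candidates are split by direction (repressed/induced in the
tetraploid) and ranked by frequency fold change f_t/f_h — ascending for
repressed, descending for induced, ties broken lexicographically.  A
pseudocount of 0.5 replaces a zero count for ranking only, never for
p-values.  Equal numbers (top-N) of candidates from the two replicate
pairs are intersected; the chance level of an overlap of m among two
random size-n subsets of the B-gene expressed background is the
hypergeometric upper tail P(|A∩B| ≥ m), and the selected top-N is the
largest value on a grid (default 10, 20, …, 200) keeping that tail
below p_max = 1e-10.  The full (top-N, overlap, p) curve is retained in
every report.  When no grid value qualifies the replicates are declared
inconsistent and the final list is empty.  Final calls are summarised
as mean ± sample SD (ddof = 1) of the fold change across pairs; a
single pair reports SD 0 with an explicit flag.

Fractional counts produced by 1/n multi-map weighting are floored to
integers before the binomial model (which is defined on integer
counts); fold changes use the unfloored values.  Repressed and induced
genes are kept as separate ranked lists through the whole procedure; a
combined ranking by |log2 fold| is available
(`ploidyseq.de.combined_ranking`) for workflows that want one list.

## Gene-set enrichment

Enrichment of a query list against the expressed background uses the
hypergeometric upper tail P(X ≥ a) for a query members of a K-gene
term over an N-gene background.  Term assignments are consumed as flat,
pre-propagated sets (GMT or two-column TSV) restricted to the
background; no ontology-graph propagation is performed.  Raw p-values
are reported sorted ascending, with a Bonferroni factor equal to the
number of terms tested (capped at 1) alongside — never substituted.
Terms with no query member are suppressed, matching term-finder
convention.  Query genes outside the background are dropped with a
logged warning.

## Promoter motif scanning

A gene's promoter runs from 50 bp downstream of the annotated coding
start (the coding-start base is the first downstream base) upstream to
the nearest edge of the closest annotated feature lying strictly
upstream, or 5 kb, whichever is nearer.  Features of any type and on
either strand bound the promoter; features overlapping the coding start
are skipped when locating the boundary; minus-strand genes are
mirrored and intervals are clipped at contig edges.  The upstream
extent therefore equals the intergenic gap when a neighbour sits within
5 kb, and exactly 5,000 otherwise.

Motifs are width-W log-likelihood matrices over A,C,G,T whose maximum
score (sum of per-position maxima) is positive and whose zero point
corresponds to the background model.  A promoter's score is the best
W-window sum over both strands (regulatory motifs are
orientation-ambiguous); ambiguous bases score the per-position minimum,
which cannot create a spurious match.  Probability matrices are
converted to natural-log likelihood ratios against a configurable
background (default uniform 0.25, pseudocount 1e-3), preserving the
zero-equals-background property.

Match cutoffs are swept over the 15-point grid
{0.30, 0.35, …, 1.00} × max score (a score exactly at threshold
matches).  At each cutoff the motif frequency in the query set is
tested against the frequency among all genes with a valid promoter by
a one-sided binomial upper tail; the cutoff with the smallest p wins,
ties resolving toward the smaller cutoff, and the whole grid curve is
reported.  Surviving motifs must jointly satisfy p ≤ 0.005, set
frequency ≥ 0.25 and set/background frequency fold ≥ 1.5 (all bounds
inclusive).  The grid sweep inflates the per-motif false-positive rate
relative to a fixed cutoff; the frequency and fold filters absorb this,
and the seeded null scans in the acceptance script quantify the
residual rate.

## Synthetic data generator

The generator emulates the study design it is meant to test: two
replicate pairs of haploid/tetraploid libraries at 9×10⁶ reads per
sample, ~6,000 genes, and a planted set of 60 fold-changed genes
(defaults; alternating folds 0.25 and 4).  Per-gene expression
frequencies are log-normal (σ = 1.5 in log space) and normalised —
the real transcriptome's shape is unknown, and any heavy-tailed choice
exercises the same code paths; log-normal is conventional.  Counts are
drawn multinomially per sample rather than per-gene binomially so
library totals are exact, matching the frequency denominator the
caller uses.  Planted folds multiply the tetraploid frequencies, which
are then renormalised; with the default ~1% of transcript mass planted
the compositional shift on null genes is negligible, but planting a
large mass fraction makes every null gene systematically shifted — a
real property of relative-abundance data, exercised deliberately in
one test.

The toy genome packs alternating-strand genes (lengths uniform
900–1,500 bp) separated by uniform 200–6,000 bp gaps, so some genes
have upstream neighbours nearer than 5 kb and some farther; every 25th
gene also receives a small feature straddling its coding start to
exercise the skip rule.  Motif planting overwrites promoter sequence
in place (no indels, coordinates stable) with the matrix's consensus
on a random strand; target promoters receive a site with probability
0.8 by default, others at 0.05.  One integer seed determines every
output byte; sub-generators draw from streams derived via
`numpy.random.SeedSequence(seed, salt)`.

What the generator does *not* emulate: read-level artefacts
(sequencing error, mappability, GC bias), gene-length effects on
counts, overdispersion beyond multinomial sampling, and real promoter
base composition.  Passing tests therefore demonstrate correctness of
the inference machinery under the model's own assumptions, not
robustness to those artefacts.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| expressed threshold | 15 counts | minimum count (in ≥ 1 sample) to enter the background |
| α | 0.001 | per-tail significance for candidate calls |
| pseudocount | 0.5 | zero-count replacement, fold ranking only |
| p_max | 1e-10 | replicate-overlap significance bound |
| top-N grid | 10…200 step 10 | candidate list depths tried |
| cutoff grid | 0.30…1.00 step 0.05 | motif score cutoffs, × max score |
| motif filters | p ≤ 0.005, freq ≥ 0.25, fold ≥ 1.5 | all inclusive |
| promoter | 50 bp down, ≤ 5 kb up | first-upstream-feature rule |

The expressed rule is deliberately permissive ("at least one sample"):
genes silenced in one ploidy — which include the strongest genuine
signals, such as mating genes off in tetraploids — must stay eligible.
The denominator for frequencies is the library's total mapped-read
count as recorded in each table header; whether that total counts all
uniquely mapped reads or only in-feature reads is a property of the
upstream counting step, and tables carry whichever total they were
built with.

## Numerical and design choices

* Internal coordinates are 0-based half-open; GFF3 I/O converts to and
  from 1-based inclusive.
* Read-to-feature assignment uses hit-midpoint containment,
  strand-agnostic — unambiguous for partial overlaps.
* Tail probabilities come from scipy (`binom.cdf`/`sf`,
  `hypergeom.sf`); the test suite checks them against independent
  exact-rational-summation and exhaustive-enumeration oracles to 1e-9
  relative error.
* Tie-breaks are lexicographic on gene id everywhere a ranking is cut.
* Degenerate inputs (empty tables, zero-length promoters after
  clipping, grids with no feasible point, motifs with no matches
  anywhere) raise typed errors rather than returning sentinel values.

## Problem sizes used in tests and acceptance

The test suite runs the generator at reduced scale (hundreds of genes,
1e5–1e6 reads) chosen so that every statistical property being asserted
has comfortable margins at that size; the acceptance script runs the
study-scale configuration (6,000 genes, 9×10⁶ reads) for the headline
experiment, 10,000 genes at 1e6 reads for the null, 200 simulations for
fold sensitivity, and 20 seeded scans of 5,000 promoters each for motif
recovery.

## Known limitations

* The reciprocal binomial test's anti-conservativeness (above) means
  per-pair candidate lists must never be interpreted alone.
* No dispersion modelling or shrinkage: biological replicates beyond
  the two-pair overlap design are not exploited.
* Enrichment consumes flat gene sets; GO graph structure is out of
  scope.
* Motif scanning assumes a position-independent background; dinucleotide
  composition is not modelled.
* SAM/BAM alignments are not parsed directly; hits are consumed from a
  BED-like TSV (see `ploidyseq.counts.read_alignment_hits` for the
  expected columns and a samtools one-liner).
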