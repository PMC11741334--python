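# Methods

## The error model and the calling test

`mosaicall` treats somatic SNV detection in bulk DNA without a matched
normal as an outlier-detection problem against a sequencing-error null.
At a germline homozygous-reference site *i* with filtered depth DP_i, the
alternative allele count is modelled hierarchically:

    AC_i | p_j ~ Binomial(DP_i, p_j)
    p_j       ~ Beta(alpha_j, beta_j)
    AC_i      ~ BetaBinomial(DP_i, alpha_j, beta_j)   (marginally)

The Beta layer absorbs site-to-site variation of the error rate that a
single binomial cannot: overdispersion from local sequence composition,
mapping ambiguity and library chemistry. Error rates depend strongly on
the flanking bases, so the model is stratified by substitution-context
class *j*: trinucleotide contexts collapsed to a pyrimidine reference
(6 changes x 4 x 4 flanks = 96 classes), each with its own (alpha_j,
beta_j).

The test statistic at a site is the observed alternative allele count; the
p-value is the exact upper tail P(AC >= ac_obs) under the fitted null of
the site's class, and a site is a candidate when p < 1e-8 (strict). The
inclusive tail makes the p-value super-uniform (valid) under the null.
Sites with ac = 0 get p = 1.

### Numerical choices

- The tail is computed by direct log-space summation of the pmf from
  ac_obs to DP (log-gamma/log-beta terms combined with logsumexp). We do
  not compute 1 minus the lower tail: that subtraction destroys relative
  precision exactly in the regime the caller thresholds on (p << 1), while
  direct summation keeps ~1e-13 relative error (verified against 60-digit
  arithmetic) at O(DP) cost.
- Maximum likelihood runs on (log alpha, log beta) with L-BFGS-B, bounded
  in [1e-8, 1e8], started from method-of-moments estimates; when the
  sample variance shows no overdispersion the start is the near-binomial
  parameterisation (alpha+beta = 1e6 at the observed mean). Identical
  (ac, dp) pairs are collapsed to weighted likelihood terms, so fitting
  1e5 sites costs the same as fitting the handful of distinct pairs.
- Classes with fewer than 100 sites fall back to the pooled all-class fit
  and are flagged; all-zero classes return a boundary fit (mean error at
  the 1e-8 bound) flagged "degenerate".
- Sites with ac = 0 enter the likelihood (excluding them would bias the
  mean error upward). A zero-alt site carries zero counts of every
  alternative allele, so it informs all three classes that share its
  context; sites with ac > 0 inform only their own class.
- The mean error alpha/(alpha+beta) is well identified everywhere; the
  shape split between alpha and beta is weakly identified when errors are
  rare (most sites contribute only "zero or one error"), which matters for
  deep tails — see the simulation discussion below.

## Counting and pre-filters

Reads are discarded whole if: mapping quality < 20; SAM flags fail the
require/exclude masks (proper pair required; unmapped, secondary,
QC-fail, duplicate and supplementary excluded, mask 3844); the alignment
contains any indel operation; the mismatch fraction exceeds 0.1; or the
soft-clipped fraction exceeds 0.5. The mismatch fraction is
(NM - inserted - deleted bases) / aligned M length — the denominator is a
package choice, as is dropping reads that lack an NM tag (with a distinct
reason). Soft-clip fraction uses the full read length including clips.

Surviving reads contribute bases with base quality >= 20 that are not
within 5 bases of either read end. End trimming masks by read coordinate
(the sequenced read, not the reference projection) and never rewrites
alignments. Overlapping mate pairs are counted once per read — there is no
mate-overlap deduplication, so fragments with overlapping mates can
contribute a base twice; this is a documented caveat of the counting
stage. A site is emitted when filtered depth >= 10 and at most one
distinct non-reference base is observed; contexts containing N are
skipped. Output positions are 1-based; BED inputs are 0-based half-open
and converted only at the I/O boundary.

## Callable regions and sample QC

Callable regions are padded (10 bp) capture targets on autosomes minus a
union of exclusion masks. Donor-level reference-homozygous sites require
>= 95% of non-missing tissues (depth > 10) called hom-ref; the
non-missing denominator is a package choice where the source is ambiguous.
The per-sample depth mask keeps sites with 10 <= depth <= 5 x median
(both bounds inclusive; lower median for even counts); the kept-base count
is the denominator of the normalized burden (mutations per Mb). Genetic
sex is checked as the chrY coverage fraction normalized by the chrX
coverage fraction over non-PAR targets: > 0.8 male, < 0.2 female,
otherwise ambiguous.

## Post-filters

Candidates pass through, in order: two-sided Fisher exact strand-bias test
(drop at p < 0.01); minimum evidence (ac >= 3 and VAF >= 0.005, both
inclusive); distance > 5 bp from same-donor germline variants (<= 5 drops);
no overlap with population variants at AF > 1e-4 (indels drop their whole
REF footprint); no flanking homopolymer of 5 identical reference bases
immediately up- or downstream; nearest same-sample call >= 20 bp away
(both members of a closer pair drop); not a candidate (p < 1e-8) in two or
more donors; at least one supporting read from a second aligner (calls
absent from the evidence table count as zero, with a distinct reason); and
no overlap with any donor's germline variants. The distance and recurrence
rules are evaluated on the pre-battery candidate set, which makes the
battery idempotent and its final output independent of filter order; only
the attrition attribution depends on order. The attrition report's input
counts telescope by construction.

The Fisher test sidedness is not documented in the original description;
two-sided is the conservative choice for a symmetric artifact hypothesis.

## The mixture simulation

Power and FDR are estimated on simulated mixed samples emulating a minor
cell population spiked into a major one. At each of 1e5 background sites,
ac ~ BetaBinomial(depth, 0.5, beta) with mean error 1e-4 (beta chosen to
match); at each of 500 truth sites, ac = round(freq x depth) — halves away
from zero — plus an independent background draw (errors do not vanish at
somatic loci; the sum is capped at depth). If freq x depth rounds to zero
the truth site keeps background counts only and the power loss is real.
The null is fitted pooled (no contexts) on the background sites, matching
how mixed samples are analysed. The default grid — somatic fractions 1% to
10% in 0.25% steps, depths {50, 100, 300, 500}, 10 iterations — enumerates
1,480 mixed samples. Power = called somatic / total somatic;
FDR = called background / total called (0 when nothing is called).

What the parametric background does *not* emulate: real capture data
contain recurrent artifact sites and context-specific error bursts far
outside a single Beta-binomial, which in practice inflate low-depth FDR
toward 100% while leaving candidate thresholds loose. Absolute FDR at
depth <= 100 from this generator is therefore optimistic and should not be
read as an estimate for real exomes; power and the orderings across
frequency and depth transfer.

### Sensitivity at depth 50

At somatic fraction 7.5% and depth 50 the truth signal is ac = 4, and the
true null tail P(AC >= 4) = 2.4e-9 sits only four-fold below the 1e-8
threshold. The tail of a fitted null is driven by the rare multi-error
background sites — about 3.6 expected sites with ac = 2 and 0.03 with
ac = 3 per 1e5 sites — so the maximum-likelihood tail estimate at this
depth has sampling variability spanning the threshold: a run that happens
to draw an ac = 3 site fits a heavier tail and calls nothing at the truth
sites. Roughly one run in five lands on that side; the median power over
seeds is 1.0 at every depth, and depths 100/300/500 give power 1.0 in
every run. This is a finite-background property of the benchmark (1e5
background sites per run), not of the caller: larger background panels
tighten the fitted tail. The benchmark sizes (1e5 background sites, 500
truth sites, 10 seeds per depth) are the package's standard desk-scale
configuration.

## Synthetic cohorts and fixtures

The cohort generator builds a random reference, per-sample count tables
with context-dependent Beta-binomial error (defaults: mean 1e-4,
alpha 0.5, overridable per context), Gamma-Poisson depths around a 140x
mean (matching a post-QC high-coverage exome), heterozygous germline sites
per donor, injected somatic variants at chosen VAFs, technical-replicate
pairs conditioned on a shared truth, and small valid SAM files for
end-to-end tests of the counting stage. All outputs are deterministic
under a single root seed, with per-stream seeds derived by seed-sequence
spawning.

## Cohort statistics

- **Cluster scan**: each gene's CDS is split into non-overlapping 50-bp
  windows; the expected count per window is lambda = (n_gene / L) x width
  (uniform spread of the gene's own mutations), the p-value is the exact
  Poisson upper tail, and BH adjustment runs across all windows of all
  tested genes (significant at q <= 0.10). Windowing is 0-based; the final
  partial window is retained with lambda scaled to its true width.
- **Spectrum**: proportions over the 6 and 96 pyrimidine-collapsed
  classes; the per-sample CpG>T fraction is the share of C>T calls with a
  3' G. Empty denominators give NaN, never 0.
- **Sharing**: a variant is shared when observed in >= 2 tissues of one
  donor (sharing never crosses donors); its germ-layer pattern is single-
  or multi-layer from the carrying tissues' layers. Per-layer summaries
  count a shared variant once in each layer it touches; layer differences
  are tested by chi-square (overall and one-vs-rest, no continuity
  correction), with empty layers excluded.
- **Missense/synonymous ratio nulls**: five placement models re-draw each
  observed coding mutation uniformly over the eligible (site, alt) pairs
  of its gene — any change anywhere; same REF>ALT change; same
  trinucleotide context; same flanking bases; or context and change
  combined. Effects are classified by the standard codon table; placements
  creating a stop are nonsense and excluded from both ratio terms.
  Mutations whose required context is absent from the gene are re-drawn
  context-blind and counted.
- **Orthogonal support**: fraction of discovery calls with >= 1
  alt-supporting read in a replicate or matched RNA sample; zero-coverage
  validation rows count as unsupported but are also reported as a separate
  not-covered class; rates stratify by validation coverage and discovery
  VAF.
- **Region enrichment**: chi-square (no continuity correction) on the 2x2
  called-by-annotated table over sufficiently covered loci, plus a
  redistribution test: calls are re-placed uniformly without replacement
  across covered loci (7,000 iterations by default) and the p-value is the
  fraction of iterations reaching the observed annotated-call count. On
  exchangeable loci this equals the hypergeometric upper tail, which the
  tests verify.
- **Deleteriousness**: CADD >= 30 (inclusive), with unscored records
  excluded from proportions and tallied separately.

## Known limitations

- No mate-overlap deduplication in counting (see above).
- Indels and multi-nucleotide variants are out of scope end to end.
- The second-aligner evidence is consumed as a table; the package does not
  run an aligner.
- The per-class Beta shape is weakly identified at shallow depth; tail
  probabilities near the calling threshold inherit that variance (see the
  depth-50 discussion).
- Germline genotyping is consumed from VCF; the package does not
  re-implement joint genotyping or PAR annotation.
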