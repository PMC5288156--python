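# Methods

This note documents the models behind `concordkit`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical conventions a maintainer should know.

## Detection power

A somatic caller operating a likelihood-ratio rule is modelled as follows.
At depth *n*, reads supporting a variant of allele fraction *f* are
Binomial(*n*, *p*(*f*)) with

    p(f) = f (1 − e) + (1 − f) e / 3,

where *e* is the per-base error rate and the *e*/3 term is the chance that
an error produces the specific variant base.  For a candidate supporting
count *k* the variant hypothesis sets *f* to its MLE *k*/*n*, and the site
is callable when

    LOD(k, n) = log10[ B(k; n, p(k/n)) / B(k; n, p(0)) ]  ≥  θ

for the smallest *k* ≥ *k*₀.  Power is the probability of reaching that
count, P(K ≥ k*), plus a fractional credit d·P(K = k*−1) with
d = 1 − (θ − LOD(k*−1)) / (LOD(k*) − LOD(k*−1)).  Without the credit,
power is a sawtooth in depth: every unit increment of k* drops the tail by
one pmf term, producing dips of up to ~0.2 at low allele fractions.  The
credit removes the sawtooth (measured residual non-monotonicity is at
machine precision) and matches the published power calculation of the
LOD-caller family this model follows.  Set `PowerParams(interpolate=False)`
for the plain tail.

Defaults — `error_rate=1e-3`, `lod_threshold=6.3`, `min_alt_reads=3`,
`power_cutoff=0.8` — are the conventional operating point of that caller
family; all are config-exposed.  No contamination, strand-bias or
mapping-quality terms are modelled.

The expected allele fraction of a clonal mutation in a bulk sample folds
in purity α, local total copy number *C* in tumor cells, and multiplicity
*m* (mutated copies): f = α·m / (2(1−α) + α·C).  When no copy-number
context is available the conservative heterozygous-diploid default
(C=2, m=1) applies.

A locus with no depth record is **unassessable**, a distinct outcome:
missing coverage must never be silently scored as "not powered".

Convention: the powered/unpowered partition of one center's calls uses the
*evaluating* (other) center's coverage and purity context, since the
question is whether that center could have seen the variant.  This choice
is echoed in the pipeline report metadata.

## Purity estimation

Clonal heterozygous SNVs in copy-neutral regions sit at allele fraction
α/2 in a sample of purity α.  Alt counts at such sites are modelled as a
J-component binomial mixture with component means constrained to (0, 0.5];
EM with deterministic quantile-block initialization (sorted raw AFs split
into J equal-count blocks) makes the fit reproducible and order-invariant
without random restarts.  Convergence: log-likelihood improvement < 1e-8
or 500 iterations; the EM ascent property is asserted every iteration.

The purity estimate is α̂ = min(1, 2·max μⱼ) over components of weight ≥
`min_component_weight` (default 0.15).  The weight floor exists because EM
on finite data occasionally fits a low-weight "tail absorber" component
slightly above the clonal cluster; taking the unrestricted max then biases
α̂ upward by more than the estimator's actual noise.  The clonal cluster
by construction carries substantial weight, so the floor cannot exclude
it.  Subclonal mutations fall into lower-mean components and never affect
the max.

J is selected by BIC over {1, 2, 3} by default (`n_components=J` forces a
value).  On purely clonal data BIC almost always selects J=1, which avoids
spuriously splitting a single AF cluster; with a genuine subclone the
second component is worth its BIC penalty and is recovered (tests plant a
30% subclone at cancer-cell fraction 0.4 and check the component near
α·CCF/2).

Assumptions and limits: sites must be pre-filtered to copy-neutral regions
(the pipeline uses its own CBS segmentation, flagging sites in segments
with |mean| ≤ 0.2); allosomal sites should be excluded for male samples;
no joint purity/ploidy or integer copy-number inference is attempted.
At 300 sites and 150X, recovery error is ~±0.02 across seeds; the tests
enforce ±0.05.

## Variant matching and cross-validation

Variant identity is the exact normalized (chrom, pos, ref, alt) key.
Normalization right-trims then left-trims shared bases and, when a
reference context is supplied, left-aligns indels by the standard
shift-left algorithm; it is idempotent (property-tested on random
alleles).  No fuzzy or window-based indel matching is attempted — matching
stays deterministic and auditable.

Each origin call is then exactly one of: concordant, powered-missed,
underpowered, unassessable.  The cross-validation rate is
concordant / (concordant + powered-missed) and is reported as undefined
(never 0 or 1) when the denominator is empty.  By default only calls
flagged nonsynonymous enter (`nonsynonymous_only=False` to disable),
since comparative mutation burdens are conventionally quoted for
nonsynonymous variants.

The separate discordance examination filters private calls to depth ≥ 30
and AF ≥ 0.1 — calls solid enough that power cannot explain their absence
— and reports the class breakdown; the indel share is additionally given
as an integer percent, the convention used in comparative reports.

## Copy number

Copy ratios: per target, log2(tumor depth / median normal depth), after
median-centering the tumor track (removes library-size scale).  Targets
whose median normal depth is below 10 are masked rather than divided by
~zero.  A matched-normal run is the one-normal special case.  No
GC-content or mappability correction is applied — the synthetic data has
no GC structure; this is an extension point for real data.

CBS: per chromosome, find the arc (i, j] maximizing

    |mean_in − mean_out| / sqrt(1/k + 1/(n−k)),

a two-sample t statistic up to the global variance factor, which is
split-invariant and therefore omitted.  The split is accepted when its
statistic beats the 1−α quantile of the same maximal statistic under
random permutation of target order within the piece (seeded generator;
`n_perm=1000`, `alpha=0.01`, `min_width=2` by default — the usual
practice values, all exposed).  Accepted cuts recurse.  The permutation
loop early-stops once enough exceedances accumulate to rule out
significance, which is what makes deep recursion affordable; constant
pieces are recognized and never permuted.  The first-split search is
verified against exhaustive enumeration on short tracks; note an arc and
its complement carry identical statistics, so equivalence is on induced
cuts, not (i, j) labels.

Gene calls: a gene's value is the n-target-weighted mean of overlapping
segment means; amplification above log2(4) = 2.0, deletion below
log2(0.5) = −1.0 (both strict), with shallower gain/loss reporting
thresholds at ±0.3.  The ±0.3 values are reporting conveniences with no
canonical source, unlike the focal-event thresholds; adjust via
`CnaThresholds`.

## Transcriptome

RPKM = 10⁹ · count / (total_mapped · length).  When total mapped reads is
not supplied, the table's count sum is used; this changes only the overall
scale, which Pearson correlation on the log scale ignores.  Expression
concordance is Pearson r on log2(RPKM + 1) over the gene intersection
(offset and linear-scale mode exposed); r and r² are both returned, with
zero-variance inputs flagged rather than propagated as NaN.

Fusion identity is the ordered (5′ gene, 3′ gene) symbol pair — gene-level
matching, no breakpoint coordinates, no symbol-alias resolution; inputs
must share a namespace.  The dual-caller set is the intersection of two
callers' pairs within one center; the cross-center validation rate
compares that set against the other center's calls pooled over its
callers (a dual-only comparison is available via flag).  An empty
dual-caller set makes the rate "not assessable".

## Coverage audits

Mean target coverage is base-weighted (the hybrid-selection convention),
so targets of unequal length contribute by their size.  Threshold
fractions are the share of targeted bases at or above the cutoff, at the
profile's per-target resolution; the panel-wide fraction equals the
base-weighted mean of per-gene fractions (tested invariant).  The
low-coverage flag is strictly below threshold: a gene at exactly 50X is
not flagged.  The packaged ACMG-56 symbol list is the standard
incidental-findings panel; interval mappings are always user-supplied, so
synthetic runs need no genome annotation.

## Synthetic data generator

The generator is the package's ground truth: an artificial exome
(default 2 chromosomes × 1000 targets of 150 bp, spaced 300 bp), one
mutation per target at most (loci unique by construction), ten targets
per synthetic gene.

Study conditions encoded in the defaults: purity 0.76 (the middle of the
three study purities 0.86/0.76/0.58, which the tests and acceptance runs
sweep explicitly); a few hundred clonal mutations with indel proportion
0.15; mean target coverage 265X vs 150X for the two centers (inside the
observed 120–270X spread, deliberately unequal); negative-binomial depth
with dispersion 8 (real exome depth is overdispersed; dispersion 8 gives
a coefficient of variation ≈ 0.35 at 150X); binomial alt reads at the
purity/CN-adjusted allele fraction; a 3-alt-read caller floor matching the
power model's default; SNV calling sensitivity 0.97 and indel sensitivity
0.80 per center, the latter encoding the empirically indel-enriched
inter-center discordance; per-center private-mutation fractions default 0
(two pieces of one metastasis differ by sampling; the fraction is a free
knob, not a measured value).  Mutations planted in homozygously deleted
regions contribute zero alt reads — no copies remain to observe.

Expression: truth log2 abundances Normal(5, 2); each center adds
independent Normal(0, σ) noise with σ chosen by the attenuation identity
r = s²/(s² + σ²) so that the default replicate concordance is r² ≈ 0.8;
counts are derived from the noised RPKM at a nominal 50M mapped reads.
Fusions: each caller at each center detects each true fusion
independently at its sensitivity (default 0.8), with optional
novel-gene-pair false positives.

All randomness flows from a single master seed through named substreams
(`SeedSequence` spawn keys), so outputs are reproducible per stream and
independent across streams.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: read-level artifacts (alignment error,
strand bias, FFPE damage), GC/mappability structure in coverage, correlated
caller errors (caller misses here are independent coins, while real
callers share failure modes around repeats), transcript-isoform structure,
and real gene annotation.  Recovery results on synthetic data bound the
statistical behavior of the estimators, not the end-to-end accuracy of a
sequencing pipeline.

## Pipeline

Stage order: inputs → copy number → purity (CN segments feed copy-neutral
site selection) → powered cross-validation both directions → match/
discordance/panel → expression → fusions → germline audit → comparative
event rows.  A failing stage is recorded and the rest still run; reports
are deterministic given inputs and seed (timestamp off by default), with
input checksums echoed for audit.  One-sided events render as "N.D."
(not detected) in the tabular output.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to exercise the
estimators' operating ranges: 300–500 targets per chromosome, 150–400
mutations, 5000 genes for expression concordance, 20 replicate seeds for
purity recovery, 1000 CBS permutations where the permutation test itself
is under test and 100–300 where it is background machinery.
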