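# Methods

## Model and procedure

The pipeline treats sequencing evidence at a variant locus as a pair of
counts per sample: mutant reads out of total reads.  Allele frequency (AF)
is the mutant-read fraction; nothing below the count level (alignment,
mouse-read subtraction, base calling) is modelled — counts are the input.

### Somatic calling and exclusion

A point mutation is *called* in a sample when the locus is covered ≥20-fold
and ≥2 reads carry the mutant allele.  Frameshifts are exempt from the
coverage floor (≥2 mutant reads suffice) because indel-supporting reads are
themselves strong evidence of the event.  *Absence* is never inferred from
missing data: certifying that a sample lacks a mutation requires an explicit
observation with zero mutant reads at ≥20-fold coverage.  The same logic
drives the somatic filter: a variant is somatic only when the germline
sample shows zero mutant reads at ≥20×.  The threshold choice is symmetric
with the de novo certification rule; variants whose germline coverage is
below the floor are dropped with a logged reason rather than guessed at.
dbSNP-common variants (population MAF >1%, carried as an input flag) and
presumed-neutral consequence classes (synonymous, intronic, UTR, in-frame
indels) are excluded before classification.

### Per-arm resistance classification

Each (somatic mutation, adapted arm) pair receives exactly one status.
De novo and completely depleted are definition-forced from the calling and
absence-certification rules.  Pairs present on both sides (≥1 mutant read at
≥20× in each) enter the shared branch: a two-sided Fisher exact test on
[[parental mutant, parental reference], [adapted mutant, adapted reference]]
with Benjamini–Hochberg adjustment across the shared tests *within the arm*,
and a shift is reported only when q < 0.05 **and** |ΔAF| ≥ 0.10 (10
percentage points).  Everything else — missing observations, sub-threshold
coverage — is `undetermined`.

Decisions taken where the design was genuinely open:

* **FDR scope.** Adjustment is per arm, not pooled across arms: each arm is
  an independent comparison against the same parental sample.  The level is
  a parameter (`fdr_level`).
* **Fisher sidedness.** Two-sided under the standard "total probability of
  tables no more likely than the observed" definition (what
  `scipy.stats.fisher_exact` computes); the direction of a significant shift
  is then read off the sign of ΔAF.  This keeps one test per pair instead of
  two directional tests.
* **The 10% rule** is an absolute AF difference (0.10 in fraction units),
  not a relative change, and it post-filters significant tests rather than
  gating which pairs are tested.  Both interpretations are recorded in the
  run report.
* **Absence certification on the adapted side** (for completely depleted)
  uses the same ≥20× rule as the parental side for de novo.
* **Multi-allelic VCF records** are split into one variant per alternate
  allele; the per-allele AD depths carry over unchanged.

### Deleteriousness consensus

Frameshift, nonsense and canonical splice-site mutations are deleterious
unconditionally.  A missense mutation is deleterious only when *both* SIFT
and PolyPhen-2 call it damaging; PolyPhen-2's probably/possibly-damaging
grades both collapse to "damaging" (configurable upstream of the consensus),
and missing predictions default to non-deleterious — the deleterious set is
kept specific at the cost of sensitivity.  Category deleterious fractions
are compared with the pooled-variance two-proportion z-test without
continuity correction; with this variant the two-sided p at z = 2.08 is
0.0375, i.e. the printed three-decimal value 0.037 at that z presumes an
unrounded statistic.  A degenerate pooled proportion (0 or 1) means both
groups are identical in outcome; z is reported as 0 with p = 1 and a
warning rather than NaN.

### Pathway over-representation

One-sided (over-representation) Fisher exact test per pathway on the 2×2
membership table restricted to the annotation universe, BH-adjusted across
all pathways in the collection.  The universe defaults to the union of all
annotated genes and can be overridden with an explicit list (e.g. all
exome-covered genes); the counts a+b+c+d always partition the universe.

### Drug-sensitivity random-set null

Per-gene PCC with a drug's log-IC50 profile over pairwise-complete cell
lines; two-sided p from the exact t transform t = r√((n−2)/(1−r²)); genes
with fewer than 3 complete pairs are omitted.  The null draws 1000 gene sets
of the query's effective size (after intersection with genes having defined
correlations) uniformly from those genes, without replacement within a set;
sets may overlap each other and the query, since nothing in the sampling
scheme excludes that.  The enrichment test ranks the query PCCs against the
pooled null PCCs with a one-sided Mann–Whitney ("query smaller"); an
alternative empirical mode (fraction of null sets whose median PCC is below
the query median, add-one corrected) is available.  Mann–Whitney p-values
use exact enumeration when both groups have ≤8 tie-free values and the
normal approximation with tie correction otherwise.  The "FDR <5% negative
PCC threshold" reported for plots is the least-extreme PCC among genes with
negative PCC and q below the level.

### Amplicon error model

The per-base error rate is pooled across all amplicon positions not flagged
as mutated or polymorphic: total non-reference calls over total calls, which
equals the coverage-weighted mean of per-position mismatch rates.  A
per-position mode exists for diagnostics.  Substitutions observed at an AF
below the pooled rate are below the detection limit; at exactly the rate the
call is "detected" (only strictly-below is uncallable).  Indel backgrounds
are treated as negligible, so any positive indel AF is reported as detected.
The Phred >30 quality floor applies upstream, when the pileup counts are
produced.

## Synthetic data: what it emulates, what it does not

The cohort generator emulates the exome regime of the modeled study: a
germline sample, a parental PDX and four treatment-adapted PDXs (cisplatin,
fluorouracil, lurbinectedin, olaparib) at mean coverage 80×.  Coverage is
negative-binomial (dispersion 0.1 — mild overdispersion typical of capture
data; 0 selects Poisson) and mutant reads are binomial at the variant's true
AF.  The default cohort plants 187 somatic mutations with the study's
headline structure — 64 de novo (55 private to one arm), 43 depleted
variants each completely depleted in ≥1 arm (36 shared by all four arms, 19
of those also partially depleted in some arm), 22 enriched (17 private) and
58 always-unchanged shared mutations — plus 25 germline contaminants, 25
dbSNP-common variants and 25 excluded-consequence variants that the filters
must remove.  Consequence counts are exact (6 frameshift, 7 nonsense, 1
splice site, 173 missense) and per-family deleterious fractions target
0.60 / 0.70 / 0.50 / 0.40 / 0.50 for de novo / enriched / completely
depleted / partially depleted / unchanged.  True AFs default to 0 → 0.30
(de novo), 0.40 → 0 or 0.15 (completely/partially depleted), 0.05 → 0.30
(enriched) and 0.30 → 0.30 (unchanged); the 0.40 → 0.15 partial depletion is
chosen to be comfortably detectable at 80× after FDR, which keeps the
noise-free defaults exactly recoverable.

A `noise_free` mode replaces every draw by its rounded expectation, so the
planted structure is recovered deterministically — that mode defines the
golden tests and the acceptance quantities.

The expression simulator draws a standard-normal IC50 profile per cell line
and gives each planted gene bivariate-normal expression with correlation ρ
(default −0.4 over 200 cell lines, set size 20) to it; background genes are
independent.  The amplicon simulator plants a background substitution rate
(default 0.002) and a configurable mutation list (defaults include an AF
0.001 mutation below the detection limit and an indel) over 500 positions at
2000× mean coverage; the deep-sequencing regime it mirrors ran far deeper,
and both scale parameters are configurable.

What the generators do *not* emulate — and therefore what green tests do not
establish about real data: sequence context and mapping artefacts,
mouse-read contamination, strand bias, subclonal structure or copy-number
change (true AFs are fixed per variant), correlated errors between samples,
and non-normal expression/IC50 marginals.  Recovery results quantify the
statistical machinery under the stated sampling model, nothing more.

## Numerical choices

* BH adjustment delegates to `statsmodels` (`fdr_bh`); ties in p resolve by
  stable sort, so equal p-values share an adjusted value and input order is
  preserved.
* Fisher p-values delegate to `scipy.stats.fisher_exact`; the test suite
  checks both against independent hypergeometric enumeration (exhaustively
  for all 2×2 tables with both margins ≤14, on a seeded random sample of
  tables with margins ≤30 — sizes chosen to keep the suite fast while
  covering the count regime the classifier actually sees).
* Pearson p-values clip r into [−1, 1] and guard the t transform against
  division by zero at |r| = 1 (p underflows to 0 there, which is the correct
  limit).
* Empty shared branches, empty somatic sets and zero-coverage observations
  are legal inputs and produce empty results or `undetermined`/`None`
  fields, never exceptions; contract violations (e.g. Fisher on a
  sub-threshold observation) raise typed errors.
* Simulations in the test suite use reduced problem sizes (tens of variants,
  ≤300 null sets, ≤10 seeds per property) — large enough for the asserted
  monotonicities and calibration bounds at 3-sigma Monte-Carlo slack; the
  acceptance script uses the full default conditions (187 mutations,
  1000-set null, 200 cell lines, 10⁶ amplicon base calls).

## Known limitations

* No clonality or copy-number deconvolution: AF shifts are interpreted
  marginally per variant.
* The Fisher test treats reads as independent draws; duplicate or
  overlapping-pair reads would overstate significance.
* The per-arm FDR scope means cross-arm multiplicity is uncontrolled by
  design (each arm is its own comparison).
* The random-set null conditions on the observed correlation structure of
  the expression panel; it calibrates set-level enrichment, not per-gene
  significance.
* GSEA-style rank enrichment and survival analyses are out of scope; the
  pipeline emits TSVs that external tools can consume.
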