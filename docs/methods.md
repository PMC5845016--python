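# Methods

## Statistical model

### Empirical-Bayes moderated one-sample t

Each feature (phosphosite or protein) contributes per-replicate log2 SILAC
ratios; the null hypothesis is mean zero. The per-feature sample variance s²
with df = n−1 degrees of freedom is modeled as scaled chi-square around a
true variance drawn from a scaled inverse chi-square prior with parameters
(d₀, s₀²). Under this hierarchy

    E[log s²]   = log s₀² + ψ(df/2) − log(df/2) − ψ(d₀/2) + log(d₀/2)
    Var[log s²] = ψ′(df/2) + ψ′(d₀/2)

with ψ, ψ′ the digamma and trigamma functions. The hyperparameters are
estimated by moment matching: the excess of the observed variance of log s²
over the mean ψ′(df/2) term identifies ψ′(d₀/2), inverted by Newton
iteration (monotone and convex, started at the 0.5 + 1/x moment bound); s₀²
follows from the matched mean. When the empirical excess is non-positive
d₀ = ∞ and every posterior variance equals s₀² (the fully-shrunk, z-like
limit). The posterior variance is the df-weighted average
s̃² = (d₀ s₀² + df s²)/(d₀ + df) and t̃ = mean/√(s̃²/n) is referred to a
Student t with d₀ + df degrees of freedom.

Numerical choices: a variance floor of 1e−8 is applied before taking logs
(exact replicate ties would otherwise produce log 0); an input whose
variances are *all* zero is rejected as ill-posed rather than floored.
Features observed in a single replicate are excluded from hyperparameter
estimation and flagged untested (a posterior-only mode can score them
against s₀² with d₀ degrees of freedom, off by default). The implementation
is validated against an independent bisection solver of the same moment
equations and against a frozen `limma::eBayes` reference (agreement ≤ 1e−9
on the fixture).

Calibration note: at two replicates all features share one estimated
(d₀, s₀²), so null rejection fractions are slightly over-dispersed relative
to the binomial and mildly conservative on average (measured mean type-I
rate 0.91% at nominal 1% over repeated draws); this is a property of the
moment-based fit itself, shared with the reference implementation.

### Regulation hierarchy

UV regulation is called two-sided at raw p < 0.01 with direction from the
sign of the mean (q-values are reported alongside; the raw-p convention is
the calling criterion, and an optional absolute log2 threshold can be
stacked). Dependency on a kinase is evaluated only where it is defined:
p38 dependency among UV-up sites, MK2/3/5 dependency among p38-dependent
sites. The tested quantity is the per-replicate difference of inhibitor and
UV log2 ratios — algebraically the log2 ratio of the inhibitor channel over
the UV channel — tested one-sided (negative = dependent) at the same alpha.
Hyperparameters for the difference test are pooled across all sites with
two or more paired observations, not just the called stratum, for a stabler
prior. Sites below the localization-probability cutoff (default 0.75) are
excluded before testing; the peptide-score filters used upstream of such
tables cannot be reproduced from site-level input.

Degenerate inputs: a ratio matrix with no replicate variance anywhere (e.g.
all zeros) yields all-'ns' calls rather than an error, and identical
UV/inhibitor contrasts yield zero dependent sites.

### Percentage display

Published regulation tables mix two printing conventions: 153/13,091 is
printed as 1.2% (half-up rounding) while 138/538 is printed as 25.6%
(truncation; rounding would give 25.7). `summarize_fractions` therefore
reports each fraction with the exact value plus one-decimal truncated,
one-decimal rounded, and integer half-up forms, leaving the choice explicit
rather than baking in a single convention that cannot reproduce both.

### Rank statistics

The Wilcoxon rank-sum test uses mid-ranks, the tie-corrected normal
approximation and a ±0.5 continuity correction, switching to exact
enumeration of all group assignments when the pooled sample size is ≤ 12
(enumeration permutes the observed values, so ties are handled exactly).
One-sided tail probabilities from the approximation agree with enumeration
within 0.01 at the switch point; the two-sided 2·min(tails) construction
doubles that worst case. The Siegel–Tukey test assigns alternating extreme
ranks (1 to the smallest value, 2–3 to the two largest, 4–5 to the next two
smallest, …), drops the single middle observation when the pooled count is
odd, mid-ranks ties, and applies the rank-sum machinery to the resulting
scores; a sample with larger spread collects the small extreme ranks, which
fixes the direction of the one-sided alternatives. Spearman correlation
uses mid-ranks with the t approximation, or full permutation enumeration
for n ≤ 9.

### Motif analysis

Foreground/background comparison follows the iceLogo reference-set model:
for each (position, residue) cell, z = (f_fg − f_bg)/√(f_bg(1−f_bg)/n_fg)
with a two-sided normal p, no multiple-testing correction by default
(matching the tool's convention; BH is switchable). The background is the
set of all quantified sites' windows, not a proteome model. Terminal '_'
padding is tallied separately and never counted as a residue.

The 14-3-3 scorer is a deliberately transparent rule-based surrogate for
consensus-based predictors, not a reimplementation of any trained model: it
scores mode I (R−3, S/T/aromatic−2, P+2), mode II (R−4 or R−3, P+2) and a
relaxed arginine-anchor rule (R−3 with S−2) and is calibrated only in the
sense that the NELFE phosphosite contexts reported as predictor-positive
score positive under it. Its output should be read as a motif annotation,
not a binding-affinity prediction.

### Occupancy

occupancy = (1 − 1/r)·100% for the phosphatase-treated / untreated
unmodified-peptide ratio r. Ratios below 1 are physically impossible and
flagged invalid (NaN) instead of clamped to zero so that QC can count how
often noise drives the estimator out of range. With multiplicative
log-normal noise of CV c the estimator's mean bias is −100(1−o)(e^{c²/2}−1)
(≈ −0.06 points at c = 0.05) and its mean absolute error is
≈ 100·E[1−o]·c·√(2/π); the tests check both against these analytic values.

### Gene-set enrichment

One-sided hypergeometric upper tail P(X ≥ k) for overlap k between a query
of size n and a set of size K inside a universe of size N; the Fisher
variant routes through the 2×2 exact test, which has the identical
one-sided tail. Sets are intersected with the universe and filtered to
3 ≤ K ≤ 1000 members by default; identifiers are uppercased and
deduplicated; BH across retained sets. The recommended universes are
all-quantified proteins for proteomics enrichment and all polymerase-bound
genes for release enrichment.

### Polymerase release ratio

For each gene the TSS window spans −300..+1000 bp and the downstream window
+1000..+3000 bp relative to the TSS in transcription direction (minus-strand
genes mirror around the TSS coordinate). Window signal is mean per-base
coverage normalized to RPKM; because the normalizer is computed from
coverage mass, the nominal read length cancels and PRR is invariant to
library depth. PRR = log2((E_down + ε)/(E_TSS + ε)) with ε = 0.1 RPKM — no
pseudocount is prescribed by the windows themselves, and 0.1 keeps silent
windows finite while remaining ≪ any signal that passes the TSS filter; the
value is recorded in output metadata. Eligibility requires gene length
> 3000 bp (the downstream window must lie inside the gene) and TSS signal
≥ 1 RPKM in the untreated condition (the same 1-RPKM convention applied to
the companion nascent-transcription filter; "highest signal on the TSS" is
not otherwise quantified, so the threshold is exposed as a parameter).

Replicates: PRR is computed per replicate and averaged, rather than pooling
reads, which keeps replicate variance available for the per-gene
differential test — a replicate-paired moderated t on ΔPRR = PRR_UV −
PRR_mock with BH correction. Region-level differential-binding machinery is
deliberately not reproduced; this per-gene construction is the package's
own defined substitute and is what the recovery tests validate. The global
condition comparison is the Wilcoxon rank-sum on per-gene mean PRRs. The
degenerate identical-track case short-circuits to p = 1 (all deltas exactly
zero carry no evidence). Metagene profiles average strand-oriented
normalized coverage in 100 bins over ±2 kb around the TSS, across genes and
then replicates.

## Synthetic data

The generators emulate the modeled experimental conditions and expose every planted label:

- **Phospho experiment** (defaults: 13,091 sites, 2 replicates): 4% of
  sites UV-up with a fixed +1.5 log2 effect; 26% of the up stratum
  p38-dependent; 60% of those MK-dependent; a disjoint 17% "ATR-substrate"
  stratum inside the up fraction. Replicate noise is Normal(0, 0.35²) in
  log2 space, independent across replicates and conditions; the inhibitor
  contrasts carry the effect unless the site is planted dependent on that
  kinase. Windows are uniform random amino acids with the phosphoacceptor
  centered (85% S / 13% T / 2% Y); MK-dependent windows receive the exact
  LXRQXS/T consensus characters, ATR-substrate windows S/TQ, other
  positions remain uniform. Localization probabilities are U(0.75, 1) with
  a 5% stratum below the cutoff, planted independently of regulation so
  the filter does not distort recovered fractions.
- **Pulldown** (2000 proteins): exactly 384 interactors with +2.0 log2 bait
  enrichment, of which exactly 108 (28%) lose enrichment under p38
  inhibition; same replicate noise model.
- **Pol II coverage** (500 genes, lengths U(1–30 kb), half minus-strand,
  placed non-overlapping with 2 kb gaps): expected coverage = uniform gene
  body (2 reads/bp) + Gaussian TSS peak (height 30, SD 200 bp, centered
  +100 bp downstream in transcription direction), Poisson-sampled per
  replicate. UV release multiplies the body rate beyond +1000 bp by
  2^ΔPRR (default ΔPRR = 1) for a 30% gene subset, so the planted shift
  acts purely on the downstream window and the estimator can be scored for
  bias directly.
- **Occupancy** (500 sites): planted o ~ U(0.1, 0.9) per condition,
  r = 1/(1−o) with 5% CV log-normal noise.

All randomness flows through a single `numpy.random.default_rng(seed)` per
simulator call, giving byte-identical outputs for equal seeds across
platforms.

What the simulators do **not** model — and hence what passing recovery
tests do not show about real data: inter-replicate and inter-site
correlation (real SILAC replicates share systematic components), missing
values and intensity-dependent variance, down-regulated strata, realistic
amino-acid background composition (uniform here, so background motif
frequencies sit near 1/20), peptide-level evidence, chromatin-domain
structure, fragment-length effects and mappability in coverage, and any
relationship between expression level and pausing. Recovery results
therefore validate the estimators' correctness under their stated noise
models, not real dataset-level counts, which depend on the underlying
raw data.

## Problem sizes and defaults

| Parameter | Default | Where |
|---|---|---|
| alpha, phospho calls (raw p) | 0.01 | regulation tiers |
| alpha, interactome | 0.05 | pulldown calling |
| localization cutoff | 0.75 | site filter |
| effect / replicate SD (log2) | 1.5 / 0.35 | phospho simulator |
| PRR windows | −300..+1000, +1000..+3000 bp | `WindowSpec` |
| min gene length / TSS filter | 3000 bp / 1 RPKM | `WindowSpec` |
| PRR pseudocount ε | 0.1 RPKM | `WindowSpec` |
| exact-test switch points | pooled n ≤ 12 (rank-sum), n ≤ 9 (Spearman) | rank tests |

The test suite and the acceptance script run the phospho pipeline at the
full 13,091-site design and the coverage pipeline at 500 genes; these sizes
give 3-SE recovery bands of about ±0.5 percentage points on the up-fraction
and ±0.01 on mean ΔPRR, tight enough to detect estimator bias while keeping
a full run in seconds.

## Known limitations

- Dependency calling operationalizes "significantly decreased after
  inhibition" as a one-sided moderated t on the per-replicate channel
  difference; other contrast constructions (e.g. fold-change thresholds,
  between-experiment carryover of calls) are possible and would shift the
  recovered fractions slightly. Calls are made within-experiment only.
- The iceLogo z model treats the background as fixed; with small
  backgrounds the significance calls are anti-conservative.
- The 14-3-3 scorer is a motif annotation rule, not a trained predictor.
- The per-gene differential-PRR p-values rest on two replicate deltas plus
  shrinkage; they rank genes well (recovery tests) but should not be read
  as calibrated gene-level inference at this replicate count.
- BAM input is out of scope; coverage arrives as bedGraph.
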