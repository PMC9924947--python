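# Methods

This note documents the statistical model behind `stresslink`, the
defaults and why they were chosen, what the synthetic cohort does and
does not emulate, and the numerical conventions used throughout.

## The analysis model

The pipeline treats a mutant-panel study as three linked layers.

**Survival layer.** Each (strain, assay) arm is a set of right-censored
individual observations. Curves are estimated with the Kaplan–Meier
product-limit estimator; censored animals at an event time are counted as
at risk at that time and removed afterwards (right-continuous
convention), and tied deaths use the exact hypergeometric variance term.
Two endpoint kinds summarize an arm: the restricted mean survival time
(area under the KM curve up to the largest observed time; without
censoring this is the arithmetic mean of death times) and the fraction
alive at a fixed time, in which animals censored at or before the time
point are removed from the denominator because they carry no information
about survival past it. Two-sample comparisons use the Mantel–Cox
log-rank test or the Gehan–Breslow–Wilcoxon test (a weighted log-rank
with weight equal to the number at risk, emphasizing early differences).
Fixed-time proportion endpoints measured in ≥ 3 replicates are compared
across the panel by one-way ANOVA with Dunnett's many-to-one adjustment
over replicate-level proportions; a strain with its own dedicated
rearing-temperature control is compared with that control by Student's
*t*-test instead, since it does not share the Dunnett family's control
arm. Dunnett-adjusted p-values come from the equicorrelated
multivariate-*t* distribution via randomized integration with a fixed
internal seed (714025), so repeated calls are reproducible; the
homogeneous-variance assumption of the classical procedure applies.

**Phenotype layer.** Lifespan extension is 100·(x̄ₘ − x̄꜀)/x̄꜀ per cent.
"Average" lifespan defaults to the mean (the restricted mean under
censoring) rather than the median; this is configurable. A direction
call per assay is *increased*/*decreased* when the endpoint differs from
control in that direction with p < α (default α = 0.05, matching the
significance level at which the emulated study's figure asterisks begin),
otherwise *unchanged*. Per-assay relative scores divide by the panel
maximum (best strain = 100 %); the combined stress survival score is
their unweighted mean, which keeps the score on a 0–100 scale and ranks
strains identically to a sum. The resistance count is the number of
assays called *increased* (0–6 on the default panel). Missing assays are
excluded with a logged warning, never imputed.

**Association and overlap layer.** Phenotype–lifespan relationships are
simple OLS regressions (slope p from the *t* distribution on n − 2 df;
R² equals the squared Pearson correlation). Gene–phenotype correlation
uses per-strain expression summaries — either the mean over replicates of
log2(normalized count + 1), or that mean minus the matched control's mean
(log2 fold-change mode, the default in the pipeline since it references
each strain to its own rearing control). Pearson correlation is the
default; Spearman is available by flag. Significance defaults to raw
p < 0.05 per phenotype: with ~10 strains the per-gene test has so few
degrees of freedom that stringent FDR control would empty the lists, and
the emulated study's reported list sizes (hundreds to thousands of genes
out of ~20k) are consistent only with a permissive rule. BH q-value
gating is available where error control matters (see *Recovery testing*
below). Overlap of two gene sets A, B in a universe of N genes is
summarized by the expected chance overlap |A||B|/N, the observed/expected
ratio ("fold enrichment"), the upper-tail hypergeometric probability
P(X ≥ k), and percent overlap k/|A| with A the designated reference set
(the stress-correlated set, by convention). The universe defaults to all
genes passing the expression filter (mean normalized count ≥ 1 in at
least one strain) because overlap ratios are sensitive to the universe
and the detected-gene set is the defensible default; it can be overridden
with an explicit list.

**Differential expression.** The DE stage is deliberately simple: size
factors by median-of-ratios (falling back to upper-quartile scaling with
a warning when no gene is expressed in every sample), then a per-gene
linear model on log2(normalized + 1) — Welch's *t* without the batch
covariate, an additive strain + batch model with it — with BH correction
at FDR 0.01. It does not fit a negative-binomial GLM or shrink
dispersions; studies that require a count-model engine can import its
output table through `import_external_de`, which validates columns and
recomputes BH q-values when only raw p-values are supplied. The
pseudocount (default 1 on the normalized scale) keeps fold-changes
finite; significance is gated on FDR only, with no fold-change threshold.

## The synthetic cohort

The generator emulates the design of a nine-mutant longevity panel:
strains with fractional lifespan effects {0.263 … 1.384} over a 20-day
wild-type mean, a second wild-type control reared at 25 °C during
development for one strain (`glp-1` by default), six stress assays with
assay-scale baselines (hours for heat/acute oxidative/osmotic/anoxia,
days for chronic oxidative/bacterial), 60 animals per arm split over 3
replicates, and 6 RNA-seq replicates per strain in 2 batches.

Latent structure: each strain has a lifespan trait L (its configured
effect), a shared robustness factor R = L, and independent
stress-specific factors U per assay drawn uniformly on ±half the largest
lifespan effect — symmetric about zero so that a mutant can also show
*decreased* resistance to individual stressors, as long-lived mutants do
in practice. The stress trait for assay a is T_a = w_a·R + (1 − w_a)·U_a;
the mixing weight w_a dials how much of that stressor's resistance is
shared with longevity (default 0.5–0.95 across assays, highest for the
bacterial-pathogen analog so that it shows the strongest
stress–longevity coupling; `shared_weight` overrides all assays at once,
with w = 1 giving fully shared and w = 0 fully stress-specific
structure). Death times are Weibull with shape 3 (roughly sigmoidal
survival curves, as in worm assays; shape 1 would give an unrealistically
flat exponential hazard) and scale set so the arm mean is
baseline_a·(1 + c_a·T_a). Censoring is independent and uniform over each
animal's own observation window (probability = `censor_rate`, default
0.05), the simplest ignorable mechanism.

Expression: per-gene baseline means are log-normal (meanlog 5.5,
sdlog 1.5; median ≈ 245 counts), emulating gene-level counts at roughly
25 M-read bulk library depth. Planted modules couple genes to the
latents — shared drivers to R, lifespan-only genes to L, stress-specific
genes to U_a, null genes to nothing — via
mean = baseline·2^(β·x + batch offset) with β = `effect_size` (default
1 log2 unit per unit trait) and batch offsets spanning 0.2 log2 units
assigned round-robin across replicates. Counts are negative binomial
with Var = μ + φμ² (φ = 0.1 by default; φ → 0 recovers Poisson).
Randomness is drawn from one stream per (strain, assay) and per stage,
each derived from the master seed, so output is byte-identical across
runs and independent of generation order.

What the generator does **not** emulate: read-level sequencing artifacts,
gene–gene correlation beyond module co-regulation, assay-specific hazard
shapes (one Weibull shape for all assays), informative censoring,
developmental-temperature physiology beyond the control-arm bookkeeping,
and any sequence content. Passing recovery tests therefore demonstrate
that the statistical machinery is sound under the declared model, not
that real data meet its assumptions.

## Recovery testing and calibration choices

The acceptance suite (tests/test_acceptance.py, mirrored by
scripts/acceptance.py) checks five statistical properties at study scale;
problem sizes were chosen so the full suite completes in a few minutes.

* **Type-I error**: 2000 null simulations at n = 40/arm for log-rank,
  Gehan–Wilcoxon and Welch's *t* (per-test rejection at α = 0.05) and for
  Dunnett (family-wise error over 3 null groups), each required to fall
  in the 95 % binomial band [0.037, 0.063].
* **Oracle agreement**: the hypergeometric tail against a 10⁵-draw
  permutation estimate (within 3 Monte-Carlo SE); the log-rank χ² p
  against a 10⁴-shuffle permutation p (within 0.02 at n = 30/arm); the
  restricted mean against exact step-function areas.
* **Null enrichment**: 10⁴ random set pairs give a mean O/E ratio in
  [0.98, 1.02] and ≤ nominal fraction of p < 0.05.
* **Module recovery**: a fully shared cohort (10 strains, 6 replicates,
  5000 genes, 200 shared drivers at β = 1, φ = 0.1). Recovery uses the
  BH rule at FDR 0.2 — the level that controls exactly the quantity being
  bounded (false-discovery proportion ≤ 0.2); the raw-p default would
  admit ~110 positive-direction null genes against ~280 true ones, and
  BH at 0.05 costs sensitivity with only 10 strains of leverage.
  Genes counted as true discoveries are those with nonzero generative
  coupling to the measured trait, which at w = 1 includes the
  lifespan-only module. Observed sensitivity ≈ 0.95 with FDP ≈ 0.05,
  and the stress-correlated vs lifespan-correlated positive sets overlap
  many-fold above chance (O/E ≈ 16, p ≪ 10⁻³). On no-coupling,
  no-shared-factor null cohorts the direction-agnostic overlap ratio is
  centred on 1; the direction-specific null ratio is biased above 1 in
  small panels because two phenotype vectors measured on the same 10
  strains are chance-correlated, a small-sample effect worth remembering
  when interpreting real overlap ratios.
* **Resistance count vs longevity**: a 0–6 count over 9 strains is a
  coarse, noisy regressor, so the positive relationship is assessed over
  5 replicate cohorts (median slope positive, Fisher-combined slope
  p < 0.05) rather than on a single draw.

The acceptance script also recomputes the resistance-count regression
from the published nine-mutant panel summary (per-assay direction calls
and lifespan extensions), giving R² ≈ 0.69 on the main-panel calls.

## Numerical conventions and degenerate inputs

Hypergeometric tails are computed by the survival function in log space
and are stable for universes beyond 10⁴ genes; an overlap larger than
min(|A|, |B|) is an impossible event with probability 0. BH adjustment
rejects p-values outside [0, 1]. Zero-variance genes are excluded from
correlation with a warning; a constant regressor is an error; a constant
response returns R² = 0, p = 1. Two identical constant groups give
t = 0, p = 1 by convention. Empty DE sets produce flagged enrichment
rows rather than NaN-driven downstream failures. Tables are written
tab-delimited with 6 significant digits; p-values use scientific
notation so they never round to zero.

## Known limitations

The DE stage's log-scale linear model is anti-conservative for very low
counts relative to a count model; the import path exists for that reason.
Dunnett's procedure assumes homogeneous variances across arms.
Replicate-level proportions entering ANOVA are treated as approximately
normal, which is coarse for small replicate counts. With ~10 strains,
per-gene correlation p-values rest on few degrees of freedom, and overlap
ratios between sets selected against correlated phenotypes are inflated
by chance phenotype collinearity — both are properties of the design, not
of the implementation, and both motivate the permissive default
significance rule being clearly separated from the FDR-controlled
recovery rule.
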