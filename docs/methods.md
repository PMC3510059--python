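# Methods

This note documents the statistical models behind `popreseq`, the
synthetic-cohort generator's assumptions, the parameter defaults and why
they were chosen, and the numerical decisions that matter when reading
results.

## The analysis problem

Resequencing one gene in an entire population cohort yields (i) the
spectrum of variants — most of them carried by one or two individuals —
and (ii) per-carrier phenotypes that can be compared against the whole
population.  The package quantifies three things: how variant discovery
saturates with sample size; whether carriers of rare variants deviate
from the population distribution of a trait; and how much of that
picture an extreme-phenotype sequencing design (sequencing only the
trait tails) would have recovered.  A fourth stage asks whether carrier
status predicts myocardial infarction, which matters because a gene can
be pleiotropic: a variant may raise disease risk (e.g. through an
amyloidosis channel) while leaving the screened lipid trait untouched,
making it invisible to any trait-extremes design.

## Discovery saturation curves

Under a uniformly random resequencing order, the probability that a
variant with c carriers among N individuals is discovered within the
first n is 1 − C(N−c, n)/C(N, n).  By linearity of expectation the
expected cumulative count is the sum over variants, independent of any
dependence between carrier sets.  The exact curve is computed with
log-gamma binomials; singletons give exactly E[D(n)] = S·n/N, the
asymptotically linear regime visible in real data.  The Monte-Carlo
variant averages over M random permutations (default M = 1,000, seed
mandatory) and carries the empirical standard error; an observed-order
curve for a single fixed enrollment is also provided, since a single
sequencing campaign draws one realization, not the expectation.

MAF strata: `common` is strictly MAF > 1% (a variant at exactly 1% is
rare); `singleton` is MAC = 1 regardless of N.  Custom break points are
a parameter.

## Percentile normalization and the carrier z-test

Percentiles are assigned within sex × 10-year age band (20–29 … 70–79,
80+) × study.  The convention is 100·(rank − 0.5)/n with mid-rank ties:
symmetric, mean exactly 50 in untied strata, and invariant under any
monotone transformation of the trait.  Strata smaller than two members
get percentile 50 with a warning.

The carrier z-test compares the mean percentile x̄ of k carriers to 50
using the continuous-uniform null variance σ₀² = 100²/12:
z = (x̄ − 50)/√(σ₀²/k), two-sided normal p.  Finite-stratum corrections
to σ₀² are ignored; at cohort sizes in the tens of thousands they are
negligible relative to sampling noise in k ≤ 50 carriers.  The test is
verified to hold its 5% level within binomial 3·SE over 400 null
replicates for k ∈ {5, 10, 50}.

Raw-scale contrasts use the Mann-Whitney U test (continuous) and
Fisher's exact test (binary).  Carriers are excluded from their own
noncarrier comparison group, but the percentile reference is always the
whole cohort.  Burden collapsing unions carriers over a variant group
(an individual carrying variants in two groups counts in both), with
optional exclusions (e.g. removing a suspect variant to see whether the
group signal survives).  Variance explained is OLS of the raw trait on
0/1/2 allele counts, R² = 1 − RSS/TSS; the null inflation of R² (≈
p/N for p predictors) is real and visible at small R², so group R²
values below ~p/N should not be over-read.  P-values are reported raw
(uncorrected), matching standard practice for these per-variant tables;
consumers needing family-wise control should apply it downstream.

## Extreme-phenotype screen

At cutoff q the screened set is {percentile ≤ q} ∪ {percentile ≥
100−q}; boundary ties are included.  A variant is detected if ≥1 carrier
is screened (carrier status, not allele count), and classified
exclusively-low / exclusively-high / both.  At q = 50 the screen is the
whole cohort and the classification degenerates to a median split, so
detection is total by construction.  Detected sets are nested in q, and
capture is frequency-biased: singletons are captured less often than
common variants at every q < 50, which is the structural weakness of
tails-only designs for rare variants.

The low/high asymmetry test is, by default, the exact two-sided binomial
sign test of the exclusive-low vs exclusive-high counts against 0.5.
An exact 2×2 construction (nonsynonymous vs synonymous × low vs high,
Fisher) is provided as an alternative; the two can disagree on small
tables (e.g. counts (4,1): sign test 0.375, 2×2 Fisher 1.0), and no
reconciliation is attempted — the method used is always recorded.

Concordance between the screen's predicted direction (low/high/none)
and the population z-test (significant-low / significant-high / null at
α = 0.05) is reported as a confusion table; variants undetected by the
screen are tabulated separately as `not_screened` rather than being
scored as predictions.

## Survival model

MI follow-up is analysed with Cox proportional hazards on the **age**
axis with delayed entry: an individual contributes to risk sets only for
entry_age < t ≤ exit_age.  Age adjustment is therefore structural; sex
is always a covariate, and the multifactorial set adds diabetes,
hypertension and smoking.  Individuals with an MI before entry are
excluded (and counted) before fitting.  Ties are handled with the
Breslow approximation — ages are rounded to 0.1 year in synthetic data,
so ties are rare — and the optimizer is lifelines' `CoxPHFitter` run at
tight precision (1e-9), which matches a hand-written grid-search
maximizer of the left-truncated partial likelihood to 1e-4 on a fixed
6-record fixture.  Constant covariates are dropped before fitting (the
partial likelihood carries no information about them and they make the
Hessian singular).  Complete separation (all events on one side of the
carrier flag) is flagged with a warning; the estimate is unbounded and
the CI degenerate, which the output shows honestly rather than masking.
Ignoring left truncation on data where carriers enter late biases the
hazard ratio downward; a regression test constructs such data and checks
the naive and truncation-aware fits separate beyond CI overlap.

## Synthetic cohort generator

The generator emulates two Danish-style general-population lipid
cohorts.  What it reproduces, and the defaults:

- **Demographics** — exam ages uniform on 20–82 (a registry-style adult
  enrollment range with a small 80+ tail), 56% female; ages rounded to
  0.1 year.
- **apoA-I** — lognormal with log-scale SD 0.20, which reproduces the
  observed IQR/median ratio of ~0.27 (e.g. 123–161 around a median of
  140 mg/dL).  Sex/age structure enters as log-scale shifts (women +8%,
  +2% per decade); the percentile normalization removes these exactly,
  so only their existence matters and the values are free parameters.
  The whole-cohort median is rescaled to the configured value
  (140 mg/dL for the discovery-style cohort; set 156 for a
  validation-style cohort).
- **HDL cholesterol** — affine in the *no-effect* apoA-I plus
  independent Gaussian noise sized so the null population attains the
  target correlation (default 0.83, recovered within ±0.03 at
  N ≥ 10,000); HDL median 1.5 mmol/L, SD 0.45.  Setting the target
  correlation to 1 gives an exactly affine HDL.
- **Variant effects** — additive per minor allele on the measurement
  scale (observed carriers are almost all heterozygous; a homozygote
  gets twice the effect).  apoA-I and HDL channels are separate, and a
  variant may carry an MI log-hazard-ratio with zero lipid effect (the
  amyloidosis-like channel).
- **Other lipids** — total cholesterol and triglycerides are weakly
  correlated nuisance lipids; LDL follows the Friedewald equation
  LDL = TC − HDL − TG/2.2 (mmol/L) when TG ≤ 4.0 mmol/L and is drawn
  from a configured distribution (N(3.6, 1.0), truncated at 0)
  otherwise, mimicking direct measurement.
- **Allele frequencies** — rare variants draw minor-allele counts from a
  discrete 1/i^shape spectrum truncated strictly below 1% MAF in a
  reference sample of 10,330; common variants draw log-uniformly on
  (1.2%, 50%].  The operation's default shape is 1 (the neutral
  expectation, and the form the curve oracles assume).  The bundled
  40-variant default panel draws its rare tail at shape 2.2: truncating
  1/i below 1% MAF over-weights mid-frequency counts, whereas observed
  human gene spectra are steeper than 1/i (population growth), and
  shape 2.2 makes the panel singleton-dominated (~40–45% of observed
  variants in ≤2 carriers), matching the regime the analyses target.
- **Follow-up** — Gompertz baseline hazard for MI (5×10⁻⁵/yr at age 20,
  doubling every 8 years, giving ~10% cumulative risk by age 80), scaled
  by exp(Σ carried log-HRs); event ages drawn by inverting the
  cumulative hazard conditional on survival to entry (left truncation by
  construction); administrative censoring at entry + follow-up (default
  24 years, giving ~10% events over the default age structure).  A
  prior-MI flag is set independently with probability 0.5% to exercise
  the exclusion filter.
- **Reproducibility** — a config's seed feeds independent child streams
  (demographics, genotypes, phenotypes, follow-up); fixing the seed
  fixes every output byte, and the pipeline's written tables are
  byte-identical across reruns.

What the generator does **not** emulate: linkage disequilibrium and
haplotypes (each variant is an independent marker; a haplotype-tagging
promoter variant is represented as a single marker), genotyping or
sequencing error, assortative or family structure, secular trends in
lipids, death or emigration as competing censoring, and any real
relationship between functional class and effect size beyond what a
panel specifies.  Passing tests therefore demonstrate that the analysis
machinery is correct and calibrated under the stated model — not that
the model captures every feature of real cohort data.

## Problem sizes used in checks

The statistical suites run at deliberately chosen scales: discovery-
curve Monte-Carlo vs exact at N = 2,000 with M = 1,000 permutations;
percentile uniformity and z-test level at N = 10,330 with 400 null
replicates; hazard-ratio recovery at N = 10,000 per replicate with ~320
carriers and ~450 events — the same carrier-count and carrier-event
information content as the motivating 55,000-person combined analysis,
which is what determines the precision of the estimate — over 100
replicates with 95% CI coverage required in ≥90.

## Numerical and formatting choices

- Exact curve via log-gamma binomial coefficients; terms with n > N−c
  are exactly 1.
- Percentages destined for printed-style tables round half-up (42.5 →
  43), not banker's rounding.
- Serialized percentiles carry 4 decimals and p-values 4 significant
  digits in scientific notation, so regression tests can compare output
  files byte-for-byte.
- The sign test uses `scipy.stats.binomtest` (exact, two-sided); at
  p = 0.5 this equals the symmetric two-tail sum.
- VCF dialect: one ALT per record, diploid unphased GT, free-text
  contig; multi-allelic records are rejected rather than split, since
  the analyses need only carrier status per variant.

## Known limitations

- The z-test's uniform null variance is the convention adopted here; the
  historical method it descends from is isolated behind one function
  (`percentiles.heterozygote_ztest`) for easy replacement.
- OLS R² for rare-variant groups is noise-dominated below ~p/N.
- The Cox stage fits one carrier group at a time (no joint model of
  overlapping groups) and has no competing risks or time-varying
  covariates.
- With very few carriers the carrier *median* percentile is a noisy
  statistic: a −39 mg/dL effect with ~12 carriers puts the median below
  the 10th percentile in only ~80% of replicates, although the z-test
  detects the shift in ~98%.  Conclusions about individual rare variants
  should rest on the test, not the median position.
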