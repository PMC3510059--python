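# popreseq

Analytics for **population-based resequencing of a single gene**, built
around the question: what do you learn by resequencing an entire
population cohort that you would miss by sequencing only the phenotypic
extremes?  The motivating setting is a major HDL gene (apolipoprotein
A-I) resequenced in a ~10,000-person general-population study and
validated in a ~45,000-person study, but every stage is generic over a
cohort table + variant genotypes.

The package covers five stages, plus a synthetic-cohort generator that
reproduces the statistical structure the analyses assume, so the whole
pipeline is testable without access to any real cohort:

1. **Variant spectrum** — MAF stratification (common / rare / singleton),
   the site-frequency spectrum, Hardy-Weinberg χ² tests, and variant
   *discovery saturation curves*: the expected number of distinct
   variants found after resequencing *n* of *N* individuals,

   E[D(n)] = Σ_v [ 1 − C(N−c_v, n) / C(N, n) ],

   with c_v the carrier count of variant v (exact hypergeometric form,
   plus a permutation Monte-Carlo with standard errors).
2. **Percentile phenotypes** — trait values converted to percentiles
   within sex × 10-year age band × study strata; carriers of a variant
   compared to the population median with the z-test
   z = (x̄ − 50) / √(σ₀²/k), σ₀² = 100²/12; carrier/noncarrier
   contrasts (Mann-Whitney / Fisher), burden collapsing over variant
   groups, and variance explained by allele-count OLS.
3. **Extreme-phenotype screen** — which variants would a
   tails-only sequencing design (percentile ≤ q or ≥ 100−q) have
   detected, classified exclusively-low / exclusively-high / both /
   undetected, with capture fractions and an exact binomial sign test of
   low/high asymmetry.
4. **MI survival** — left-truncated Cox regression of myocardial
   infarction on carrier status with **age as the time scale** (delayed
   entry; prior-MI exclusion; Breslow ties; sex or multifactorial
   adjustment).
5. **Cohort I/O + pipeline** — TSV cohort tables, a small VCF v4.2
   dialect for genotypes (`INFO/FCLASS` functional class, diploid GT),
   YAML configs, and a CLI (`popreseq run|simulate|spectrum|percentiles|extremes|survival`).

## Worked example

Generate a 10,330-person cohort carrying the default 40-variant panel
(singleton-dominated rare spectrum, seven common non-coding variants,
four lipid-effect variants and one lipid-silent MI-risk variant) and run
every stage:

```python
from popreseq import GeneratorConfig, PipelineConfig, run_pipeline
from popreseq.synthetic import default_variant_panel

config = PipelineConfig(
    seed=1,
    generator=GeneratorConfig(
        n_individuals=10_330, seed=1,
        variant_specs=default_variant_panel(seed=1),
    ),
    mc_replicates=200,
)
bundle = run_pipeline(config)
```

Selected output (printed by the snippet in `bundle.tables`):

```
variants: 31 | in <=2 carriers: 14 (45%)
             k  median_percentile       p
variant_id
LOF_severe   3             2.1800  0.0127
AMY_mild    13            24.6401  0.0422
AMY_silent  40            62.5987  0.2644
      q  detected  missed_pct  asymmetry_p
0   1.0        11        65.0       0.6250
1   5.0        18        42.0       0.5078
2  10.0        20        35.0       0.5488
3  20.0        23        26.0       1.0000
4  50.0        31         0.0       0.5811
       hazard_ratio  ci_low  ci_high  n_events
group
NS             1.06    0.59     1.93      1382
```

Reading this: 31 of the 40 planted variants were polymorphic in this
draw and nearly half sit in ≤2 carriers.  The severe loss-of-function
variant's three carriers have a median apoA-I percentile of 2.2
(z-test p = 0.013); the lipid-silent risk variant's carriers sit near
the median (p = 0.26), exactly the kind of variant an apoA-I-extremes
design cannot see.  A tails-only screen at the 1st percentile would have
missed 65% of the variants, and still 26% at the 20th.  The NS carrier
hazard ratio is estimated from all carriers of nonsynonymous variants —
here dominated by the planted lipid-silent risk variant.  (The
synonymous-group fit is flagged for complete separation in this draw:
its few carriers had no MI events.)

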