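# Methods

## The estimand: familial standardized incidence ratios

Given a set of genotyped index patients (probands) linked to a
population genealogy and a cancer registry, the quantity of interest
is the relative risk of cancer in their first- and second-degree
relatives,

    RR = O / E,

where `O` is the number of distinct relatives with at least one
registry record of the site in question and `E` is the expected
number under indirect standardization: the reference population is
stratified into cohorts of (sex, born-in-state flag, 5-year birth
block), each cohort's lifetime incidence proportion `r_c` is computed
as distinct cases over persons, and

    E = Σ_c  n_c · r_c

with `n_c` the number of relatives falling in cohort `c`. This is a
*person-count* standardization, not a person-year one: rates are
cumulative proportions and relatives contribute unit weight. Under
the null hypothesis RR ≤ 1, `O` is treated as Poisson with mean `E`,
giving the one-sided p-value `P(X ≥ O)`.

### Relative degree

Genetic convention: first degree = parents, children, full siblings
(both parents recorded and shared); second degree = grandparents,
grandchildren, aunts/uncles (full siblings of a parent),
nieces/nephews (children of full siblings), and half-siblings
(exactly one shared recorded parent). Spouses are never relatives.
When a closer and a farther path coexist the closer degree wins, so
the two relations are disjoint and symmetric. Missing parents
terminate traversal silently — genealogy records are incomplete by
nature — and an individual with a single recorded parent is traversed
through that parent only.

Probands qualify for analysis only with at least `min_generations`
(default 3) of recorded genealogy, measured as the deepest recorded
*ancestor* chain counting self (a founder is 1, a recorded
grandparent gives 3). Within a genotype group, relatives of several
probands are counted once; a person related to probands in both
groups appears in each group's set, and the groups are analyzed
independently. Probands themselves are excluded from relative sets
and from the rate-table denominators; everyone else in the genealogy
contributes to the reference rates.

### Inference conventions

Two conventions are deliberately non-standard because they are what
the reference results use; both are flagged in output metadata and
exposed as configuration:

* **Zero observed cases** report `p = P(X = 0) = exp(−E)` rather than
  the literal upper-tail value of 1.
* **Confidence interval**: the lower bound is the one-sided 95% exact
  limit `χ²(α_low, 2O) / 2E` with `α_low = 0.05`; the upper bound is
  the two-sided 97.5% exact limit `χ²(1 − α_high, 2(O+1)) / 2E` with
  `α_high = 0.025`. At `O = 0` the interval is
  `(0, −ln(α_low)/E)`. This mixed convention reproduces every
  checkable published interval; property tests bind the chi-square
  quantile forms to the Poisson tail equations at 1e−8.

No multiple-testing adjustment is applied. Rows with five or fewer
observed cases are masked in rendered tables (`<=5*` for observed and
expected), mirroring small-cell suppression rules in registry-based
research; RR, p and CI remain visible. When a site has `E = 0`
(possible at simulation scale with a small reference population) the
row carries NaN estimates rather than being dropped.

## Genotype concordance

Tumor (somatic) DNA is scored against blood (germline) DNA as truth.
Calls per person: a germline *carrier* needs one replicate whose two
runs both detect the G allele (AG/GG); a germline *noncarrier* needs
no such replicate plus at least one fully concordant AA replicate —
the conservative symmetric completion of the positive rule, which only
defines the carrier side; a somatic *carrier* needs a single
G-detecting run. Indeterminate persons are excluded (logged).
Sensitivity, specificity and accuracy get exact binomial
(Clopper–Pearson) intervals. Predictive values use Bayes' formula at
an external prevalence (default 0.40, the carrier fraction among
IDH-mutant glioma patients — the population where the somatic assay
would be deployed) rather than the 2×2 column totals; with the sample
prevalence plugged in, the formulas reduce to the raw-table values, a
property under test. PPV/NPV intervals are not emitted: no exact
method reproduces a published analog, and the point estimates are
prevalence-dependent.

For patients lacking blood DNA, germline status may be imputed from
the somatic call behind an explicit flag
(`resolve_carrier_status(..., impute_from_somatic=True)`), which is
how the study-scale scenario resolves its somatic-only probands.

## The synthetic world

The generator replaces a restricted multimillion-person genealogy, so
its defaults state a scaled study world rather than tunable knobs:

| parameter | default | why |
| --- | --- | --- |
| `n_founder_couples` / `n_generations` | 150 / 4 | ≈5,000-person reference population: large enough for stable common-site rates at desk scale |
| `mean_offspring` | Poisson(2.5) | mid-century completed fertility |
| `g_allele_frequency` | 0.0408 | gives an 8% carrier fraction under Hardy–Weinberg, the published general-population figure |
| `baseline_rates` | brain 1.3e−3, oligodendroglioma 1.2e−4, colorectal 4e−3, thyroid 2.1e−3, prostate 1.75e−2 (men), other 4e−2 | per-person proportions on the scale implied by the published expected counts per 140–436 relatives |
| `cohort_trend_per_decade` | 0.10 around 1950 | earlier cohorts accumulate more lifetime incidence within a fixed registry era |
| `planted_rr` | FDR-of-carrier ANY 1.72, SDR 1.50 | the published point estimates |
| `somatic_false_negative` / `_false_positive` | 0.143 / 0.042 | one minus published sensitivity/specificity |
| `germline_run_discordance` | 0.05 | a few discordant replicates per plate, as reported qualitatively; two replicates make person-level indeterminacy rare (p² ≈ 0.25%) |
| probands | 102 genotyped, 41 linked, 44% carriers, source mix 43/21/38 somatic/germline/both | the study's sample accounting |

Generations are discrete and non-overlapping; mates are generated as
new unrelated founders, so the synthetic pedigree is outbred and
degree classification unambiguous (consistent with the low-drift,
average-consanguinity source population). Risk is planted directly on
group membership (relatives of carrier probands), not through a
mechanistic penetrance model: the planted multiplier *is* the
quantity the pipeline estimates, which makes recovery tests sharp. A
multiplier keyed to `ANY` scales all sites; multipliers compose
multiplicatively for persons in several groups; probabilities are
clipped at 1 with a warning. Unlinked probands are emitted as
parentless genealogy records so the generation filter is exercised.
All randomness flows from the single config seed and every writer is
byte-deterministic under it.

**What the generator does not emulate:** overlapping generations,
migration and death censoring of registry coverage, assortative
mating, age-at-onset structure (diagnosis years are uniform over
adult life), linkage disequilibrium with neighboring risk variants,
and real registry coding noise. A green simulation test therefore
establishes that the estimator recovers the generative law it
assumes — not that the assumptions hold in any real registry.

### Known bias at simulation scale

Reference rates are computed from the whole linked population, as in
the source analysis. In a 6.5M-person database the carriers'
relatives are a negligible fraction of every cohort; at simulation
scale they are not, so their planted excess leaks into the rate-table
denominators and biases RR̂ downward by roughly the planted excess
times the relative-set fraction of the population (≈5% relative bias
at 3,600 relatives in a 70,000-person world, mean RR̂ ≈ 1.60 for a
planted 1.7). The recovery test documents and absorbs this (mean
absolute error ≈ 0.12 against its 0.15 bound) rather than changing
the rate definition, which would diverge from the method under test.

## Numerical choices

* Exact Poisson and binomial bounds go through `scipy.stats` chi-square
  and beta quantiles; tests verify the tail-equation roots to 1e−8 and
  the tail computation against direct summation to 1e−12.
* Birth blocks anchor at multiples of the block width
  (`year − year mod width`); individuals with unknown birth year are
  excluded from rates, expected counts and registry simulation, with
  logged counts.
* Rendering rounds RR/CI to 2 decimals, p to 3, expected counts to 2;
  full precision is carried internally.
* Empty cohort cells simply contribute no rate (treated as 0 with a
  zero denominator); `E = 0` rows yield NaN inference rather than an
  error so whole tables never fail on one rare site.

## Limitations

Person-count standardization ignores differential follow-up within
cohorts; no competing risks; kinship stops at degree 2; the masked-row
conventions are reverse-engineered from published output and flagged
as such in the code; predictive-value intervals are intentionally
absent.
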