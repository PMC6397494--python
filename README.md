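# kinrisk

Familial cancer-risk estimation from population genealogies, for
genetic-epidemiology analyses of the kind run on large linked
genealogy + cancer-registry resources: enumerate the first- and
second-degree relatives of genotyped index patients (probands),
compute cohort-standardized expected cancer counts, and test for
excess familial risk with exact Poisson inference. A companion module
scores how well tumor (somatic) DNA predicts germline genotype, and a
forward-time simulator generates complete synthetic studies —
genealogy, genotypes, registry, assay — because the real resources of
this kind are access-restricted.

## The statistic

For a relative set R of a proband group, partitioned over cohorts
c = (sex, birth-state flag, 5-year birth block) with reference
incidence proportions r_c for a cancer site:

    E = Σ_c n_c · r_c          (indirect standardization)
    RR = O / E                 (standardized incidence ratio)
    p  = P(X ≥ O),  X ~ Poisson(E)     (one-sided, null RR ≤ 1)
    CI = ( χ²_{0.05, 2O} / 2E ,  χ²_{0.975, 2(O+1)} / 2E )

with the zero-count conventions p = e^(−E) and CI = (0, −ln 0.05 / E).
Somatic-vs-germline concordance reports sensitivity/specificity/
accuracy with exact Clopper–Pearson intervals and prevalence-adjusted
predictive values (Bayes, default prevalence 0.40). Rows with ≤5
observed cases are masked (`<=5*`) in rendered tables, the standard
small-cell suppression rule. See `docs/methods.md` for conventions,
assumptions and limitations.

## Worked example

The inference engine is a deterministic function of the observed and
expected counts, so it can be used directly:

```python
>>> from kinrisk import relative_risk, poisson_one_sided_p, exact_poisson_ci
>>> obs, exp = 13, 7.56        # any cancer among 140 first-degree relatives
>>> round(relative_risk(obs, exp), 2)
1.72
>>> round(poisson_one_sided_p(obs, exp), 3)
0.045
>>> [round(x, 2) for x in exact_poisson_ci(obs, exp)]
[1.02, 2.94]
```

Read: relatives of this carrier group developed 1.72× the cancers
expected from their cohorts' reference rates, an excess unlikely
under the null (one-sided p = 0.045), with exact 95% bounds 1.02–2.94.

A full synthetic study from the shell:

```sh
kinrisk simulate --seed 1 --out run/
kinrisk report --indir run/ --out run/
cat run/sir_noncarrier_degree1.tsv
```

```text
site	obs	exp	p_one_sided	rr	ci_low	ci_high	masked
ANY	6	5.41	0.456	1.11	0.48	2.41	0
BRAIN	<=5*	<=5*	0.109	8.64	0.44	48.17	1
OLIGODENDROGLIOMA	<=5*	<=5*	0.964	0.00	0.00	81.88	1
COLORECTAL	<=5*	<=5*	0.721	0.00	0.00	9.15	1
THYROID	<=5*	<=5*	0.269	3.20	0.16	17.82	1
PROSTATE	<=5*	<=5*	0.516	0.00	0.00	4.53	1
OTHER	<=5*	<=5*	0.566	1.00	0.34	2.56	1
```

Six of the noncarrier probands' first-degree relatives developed a
cancer against 5.41 expected — no familial excess (RR 1.11,
p = 0.456) — while rarer sites are suppressed under the ≤5 rule with
their inference still visible. `run/concordance.txt` holds the paired
somatic/germline 2×2 table and accuracy statistics for the same
simulated assay.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the default-scenario pipeline from scratch — simulates the
study-scale world at the given seed, resolves proband genotypes from
the assay records, builds the cohort rate table and all four
familial-risk tables, and prints them together with the concordance
report — then writes the results JSON to `--out`.
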