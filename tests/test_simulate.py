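"""The synthetic-study generator: determinism and generative laws."""

import numpy as np
import pytest

from kinrisk.cohorts import ANY_SITE
from kinrisk.genealogy import Individual, Pedigree, generations_linked
from kinrisk.simulate import (
    SimulationConfig,
    allele_freq_for_carrier_fraction,
    null_config,
    simulate_assay,
    simulate_pedigree,
    simulate_registry,
    simulate_study,
    study_config,
    transmit_genotypes,
)
from kinrisk.concordance import confusion, resolve_calls
from kinrisk import io as kio


class TestConfig:
    def test_defaults_state_the_study_world(self):
        cfg = SimulationConfig()
        assert cfg.n_probands == 102
        assert cfg.n_linked_probands == 41
        # allele frequency tuned to an 8% carrier fraction
        f = cfg.g_allele_frequency
        assert 1 - (1 - f) ** 2 == pytest.approx(0.08)
        assert cfg.somatic_false_negative == pytest.approx(1 - 0.857)
        assert cfg.somatic_false_positive == pytest.approx(1 - 0.958)

    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_generations=0)
        with pytest.raises(ValueError):
            SimulationConfig(g_allele_frequency=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(somatic_false_negative=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(planted_rr={("carrier_fdr", "ANY"): -1})
        with pytest.raises(ValueError):
            SimulationConfig(n_probands=10, n_linked_probands=11)

    def test_carrier_fraction_inversion(self):
        f = allele_freq_for_carrier_fraction(0.3)
        assert 1 - (1 - f) ** 2 == pytest.approx(0.3)


class TestPedigree:
    def test_single_generation_is_founders_only(self):
        cfg = SimulationConfig(n_generations=1, n_founder_couples=5)
        ped, gens = simulate_pedigree(cfg)
        assert len(gens) == 1 and len(ped) == 10
        assert all(generations_linked(ped, p) == 1 for p in ped)

    def test_nonfounders_have_two_recorded_parents(self):
        ped, gens = simulate_pedigree(SimulationConfig(
            n_founder_couples=8, n_generations=3, seed=4))
        founder_gen = set(gens[0])
        for pid in ped:
            ind = ped.individual(pid)
            n_par = len(ind.parent_ids)
            assert n_par in (0, 2)
            if pid in founder_gen:
                assert n_par == 0

    def test_birth_years_increase_by_generation(self):
        cfg = SimulationConfig(n_founder_couples=10, n_generations=4, seed=2,
                               missing_birth_year_rate=0.0)
        ped, gens = simulate_pedigree(cfg)
        means = []
        for gen in gens:
            years = [ped.individual(p).birth_year for p in gen]
            means.append(np.mean(years))
        assert all(b - a > 15 for a, b in zip(means, means[1:]))

    def test_fixed_seed_reproduces_csv_byte_identically(self, tmp_path):
        cfg = SimulationConfig(n_founder_couples=6, n_generations=3, seed=11)
        for name in ("a", "b"):
            ped, _ = simulate_pedigree(cfg)
            kio.write_genealogy(ped, tmp_path / f"{name}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_mean_offspring_matches_configuration(self):
        cfg = SimulationConfig(n_founder_couples=200, n_generations=2,
                               mean_offspring=2.5, seed=3)
        ped, gens = simulate_pedigree(cfg)
        mean = len(gens[1]) / 200  # no spouses in the final generation
        se = np.sqrt(2.5 / 200)
        assert abs(mean - 2.5) < 3 * se


class TestGenotypes:
    def test_mendelian_homozygote_parents(self):
        ped = Pedigree([
            Individual("f", sex="M"), Individual("m", sex="F"),
            Individual("c", "f", "m", "F"),
        ])
        # force founder draws: frequency 0 -> AA, frequency 1 -> GG
        assert transmit_genotypes(ped, 0.0, seed=0)["c"] == "AA"
        assert transmit_genotypes(ped, 1.0, seed=0)["c"] == "GG"

    def test_het_by_hom_cross_transmits_half(self):
        n = 10_000
        inds = [Individual("f", sex="M"), Individual("m", sex="F")]
        inds += [Individual(f"c{i}", "f", "m", "F") for i in range(n)]
        ped = Pedigree(inds)
        # pick a seed whose founder draws give f=AG, m=AA at freq 0.5
        for seed in range(50):
            gts = transmit_genotypes(ped, 0.5, seed=seed)
            if gts["f"] == "AG" and gts["m"] == "AA":
                break
        else:
            pytest.fail("no seed produced the AG x AA cross")
        frac_ag = np.mean([gts[f"c{i}"] == "AG" for i in range(n)])
        assert abs(frac_ag - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_founders_follow_hardy_weinberg(self):
        n_c = 10_000
        ped, _ = simulate_pedigree(SimulationConfig(
            n_founder_couples=n_c, n_generations=1, seed=8))
        f = allele_freq_for_carrier_fraction(0.08)
        gts = transmit_genotypes(ped, f, seed=9)
        carrier = np.mean([g != "AA" for g in gts.values()])
        target = 2 * f * (1 - f) + f ** 2
        assert abs(carrier - target) < 3 * np.sqrt(target * (1 - target) / (2 * n_c))


class TestRegistry:
    def _flat_world(self, n=12_000, seed=5):
        inds = [
            Individual(f"p{i}", sex="F", birth_year=1950, born_in_state=True)
            for i in range(n)
        ]
        return Pedigree(inds)

    def test_null_incidence_matches_baseline(self):
        p = 0.04
        cfg = SimulationConfig(
            baseline_rates={"X": p}, planted_rr={}, cohort_pivot_year=1950,
        )
        ped = self._flat_world()
        rng = np.random.default_rng(6)
        recs = simulate_registry(ped, cfg, {}, rng)
        rate = len({r.person_id for r in recs}) / len(ped)
        assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / len(ped))

    def test_zero_baseline_means_no_records(self):
        cfg = SimulationConfig(baseline_rates={"X": 0.0}, planted_rr={})
        recs = simulate_registry(
            self._flat_world(1000), cfg, {}, np.random.default_rng(0))
        assert recs == []

    def test_planted_group_risk_multiplies_incidence(self):
        p, rr = 0.04, 1.7
        ped = self._flat_world()
        members = {p_ for i, p_ in enumerate(ped) if i % 2 == 0}
        cfg = SimulationConfig(
            baseline_rates={"X": p}, cohort_pivot_year=1950,
            planted_rr={("carrier_fdr", ANY_SITE): rr},
        )
        recs = simulate_registry(ped, cfg, {"carrier_fdr": members},
                                 np.random.default_rng(7))
        cases = {r.person_id for r in recs}
        in_rate = len(cases & members) / len(members)
        out_rate = len(cases - members) / (len(ped) - len(members))
        n = len(members)
        assert abs(in_rate - rr * p) < 3 * np.sqrt(rr * p / n)
        assert abs(out_rate - p) < 3 * np.sqrt(p / n)

    def test_sex_specific_site_spares_other_sex(self):
        inds = [Individual(f"m{i}", sex="M", birth_year=1950) for i in range(200)]
        inds += [Individual(f"f{i}", sex="F", birth_year=1950) for i in range(200)]
        cfg = SimulationConfig(baseline_rates={"PROSTATE": 0.5}, planted_rr={})
        recs = simulate_registry(Pedigree(inds), cfg, {},
                                 np.random.default_rng(1))
        assert recs and all(r.person_id.startswith("m") for r in recs)

    def test_diagnosis_year_within_lifespan(self):
        cfg = SimulationConfig(baseline_rates={"X": 0.5}, planted_rr={})
        ped, _ = simulate_pedigree(SimulationConfig(
            n_founder_couples=50, n_generations=2, seed=13))
        recs = simulate_registry(ped, cfg, {}, np.random.default_rng(2))
        for r in recs:
            ind = ped.individual(r.person_id)
            assert r.diagnosis_year >= ind.birth_year
            if ind.death_year is not None:
                assert r.diagnosis_year <= ind.death_year


class TestAssay:
    def _genotypes(self, n_carrier, n_noncarrier):
        gts = {f"c{i}": "AG" for i in range(n_carrier)}
        gts |= {f"n{i}": "AA" for i in range(n_noncarrier)}
        sources = {p: "both" for p in gts}
        return gts, sources

    def test_zero_error_rates_give_perfect_concordance(self):
        gts, sources = self._genotypes(50, 50)
        cfg = SimulationConfig(somatic_false_negative=0.0,
                               somatic_false_positive=0.0,
                               germline_run_discordance=0.0)
        recs = simulate_assay(gts, sources, cfg, np.random.default_rng(3))
        cm = confusion(resolve_calls(recs))
        assert (cm.fn, cm.fp) == (0, 0)
        assert cm.n == 100

    def test_error_rates_recover_published_sensitivity(self):
        n = 5000
        gts, sources = self._genotypes(n, n)
        cfg = SimulationConfig()  # defaults: fn 0.143, fp 0.042
        recs = simulate_assay(gts, sources, cfg, np.random.default_rng(4))
        cm = confusion(resolve_calls(recs))
        sens, spec = cm.sensitivity, cm.specificity
        assert abs(sens - 0.857) < 3 * np.sqrt(0.857 * 0.143 / n)
        assert abs(spec - 0.958) < 3 * np.sqrt(0.958 * 0.042 / n)

    def test_fixed_seed_reproduces_assay_csv(self, tmp_path):
        gts, sources = self._genotypes(20, 20)
        cfg = SimulationConfig()
        for name in ("a", "b"):
            recs = simulate_assay(gts, sources, cfg, np.random.default_rng(5))
            kio.write_assay(recs, tmp_path / f"{name}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


class TestWholeStudy:
    def test_study_scale_bookkeeping(self):
        study = simulate_study(study_config(seed=1))
        assert len(study.proband_ids) == 102
        assert len(study.linked_proband_ids) == 41
        n_carriers = sum(
            1 for p in study.linked_proband_ids if "G" in study.genotypes[p]
        )
        assert n_carriers == 18
        # source mix honored
        from collections import Counter
        mix = Counter(study.proband_sources.values())
        assert mix == {"somatic": 43, "germline": 21, "both": 38}
        # probands never appear in their own planted relative groups
        assert not (study.groups["carrier_fdr"] & set(study.proband_ids))

    def test_study_is_deterministic_under_seed(self):
        a = simulate_study(null_config(seed=42, n_founder_couples=10))
        b = simulate_study(null_config(seed=42, n_founder_couples=10))
        assert a.genotypes == b.genotypes
        assert a.registry == b.registry
        assert a.assay_records == b.assay_records
        c = simulate_study(null_config(seed=43, n_founder_couples=10))
        assert c.registry != a.registry
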