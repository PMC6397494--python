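"""Synthetic genealogy, genotype, cancer-registry and assay generator.

The real study drew on a restricted population genealogy linked to a
state cancer registry; nothing from it can be redistributed.  This
module generates data with the statistical structure that the analysis
assumes, so every pipeline stage is testable:

* a multi-generation pedigree with discrete, non-overlapping
  generations; mates are new unrelated founders, so no inbreeding
  arises and relationship degrees are unambiguous;
* Mendelian transmission of a biallelic SNP whose founder genotypes
  follow Hardy-Weinberg at a configurable G-allele frequency (default
  tuned so ~8% of founders carry at least one G allele, the published
  general-population carrier fraction);
* per-person cancer incidence as independent Bernoulli draws per site
  with cohort-structured baseline proportions, multiplied by planted
  relative risks for configured groups (e.g. first-degree relatives of
  carrier probands) — risk is planted on group membership directly,
  which is exactly the quantity the pipeline estimates, making
  recovery tests sharp;
* a paired somatic/germline genotyping assay whose call-level error
  rates default to the published sensitivity and specificity.

Everything is reproducible from the single config seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohorts import ANY_SITE, RegistryRecord, assign_cohort
from .concordance import AssayRecord
from .genealogy import Individual, Pedigree, generations_linked

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "allele_freq_for_carrier_fraction",
    "simulate_pedigree",
    "transmit_genotypes",
    "choose_probands",
    "simulate_registry",
    "simulate_assay",
    "simulate_study",
    "null_config",
    "study_config",
]

logger = logging.getLogger(__name__)

#: Planted-risk group labels understood by :func:`simulate_registry`.
CARRIER_FDR = "carrier_fdr"
CARRIER_SDR = "carrier_sdr"
PROBAND = "proband"

#: Per-site lifetime incidence proportions consistent in scale with the
#: study's printed expected counts (per-person over the registry era).
DEFAULT_BASELINE_RATES: dict[str, float] = {
    "BRAIN": 0.0013,
    "OLIGODENDROGLIOMA": 0.00012,
    "COLORECTAL": 0.0040,
    "THYROID": 0.0021,
    "PROSTATE": 0.0175,  # males only
    "OTHER": 0.0400,
}

SEX_SPECIFIC_SITES: dict[str, str] = {"PROSTATE": "M"}


def allele_freq_for_carrier_fraction(carrier_fraction: float) -> float:
    """Allele frequency f with 1 - (1-f)^2 equal to the target carrier
    (AG or GG) fraction under Hardy-Weinberg."""
    if not 0.0 <= carrier_fraction < 1.0:
        raise ValueError("carrier fraction must be in [0, 1)")
    return 1.0 - math.sqrt(1.0 - carrier_fraction)


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters.

    The defaults state the study-scale world: 102 genotyped probands
    of whom 41 link to three-generation genealogies, ~44% of linked
    probands carrying the risk allele, assay error rates at one minus
    the published sensitivity/specificity, and planted familial
    relative risks of 1.72 (first degree) and 1.50 (second degree) on
    any cancer for relatives of carriers.
    """

    seed: int = 0
    n_founder_couples: int = 150
    n_generations: int = 4
    mean_offspring: float = 2.5
    founder_birth_year: int = 1920
    generation_gap: float = 28.0
    missing_birth_year_rate: float = 0.01
    #: G-allele frequency; default gives an 8% carrier fraction.
    g_allele_frequency: float = allele_freq_for_carrier_fraction(0.08)
    baseline_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RATES)
    )
    #: Linear cohort trend per decade of birth (earlier cohorts have
    #: more accumulated lifetime incidence in a fixed registry era).
    cohort_trend_per_decade: float = 0.10
    cohort_pivot_year: int = 1950
    planted_rr: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            (CARRIER_FDR, ANY_SITE): 1.72,
            (CARRIER_SDR, ANY_SITE): 1.50,
        }
    )
    somatic_false_negative: float = 1 - 0.857
    somatic_false_positive: float = 1 - 0.958
    germline_run_discordance: float = 0.05
    germline_replicates: int = 2
    n_probands: int = 102
    n_linked_probands: int = 41
    proband_carrier_prevalence: float = 18 / 41
    #: DNA-source counts (somatic-only, germline-only, both); scaled
    #: proportionally if they do not sum to n_probands.
    source_mix: Mapping[str, int] = field(
        default_factory=lambda: {"somatic": 43, "germline": 21, "both": 38}
    )

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 0.0 <= self.g_allele_frequency <= 1.0:
            raise ValueError("g_allele_frequency must be in [0, 1]")
        for p in (
            self.somatic_false_negative,
            self.somatic_false_positive,
            self.germline_run_discordance,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("assay error rates must be in [0, 1]")
        for mult in self.planted_rr.values():
            if mult < 0:
                raise ValueError("planted multipliers must be >= 0")
        if self.n_linked_probands > self.n_probands:
            raise ValueError("n_linked_probands cannot exceed n_probands")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.baseline_rates)


def null_config(**overrides) -> SimulationConfig:
    """Study-scale world with no planted familial risk."""
    return replace(SimulationConfig(planted_rr={}), **overrides)


def study_config(**overrides) -> SimulationConfig:
    """The default, study-scale world."""
    return replace(SimulationConfig(), **overrides)


@dataclass
class SimulatedStudy:
    """Everything one simulated study produces, plus the bookkeeping
    (true genotypes, planted group membership) that tests need."""

    config: SimulationConfig
    pedigree: Pedigree
    genotypes: dict[str, str]
    proband_ids: list[str]
    proband_sources: dict[str, str]  # person -> somatic/germline/both
    linked_proband_ids: list[str]
    registry: list[RegistryRecord]
    assay_records: list[AssayRecord]
    groups: dict[str, set[str]]


# ---------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------

def simulate_pedigree(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[Pedigree, list[list[str]]]:
    """Forward-time pedigree with discrete generations.

    Returns the pedigree and the generation membership lists (spouses
    marrying into a generation are listed with it; they are founders
    in the genealogical sense, having no recorded parents).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:06d}"

    def birth(mean: float) -> Optional[int]:
        if rng.random() < config.missing_birth_year_rate:
            return None
        return int(round(rng.normal(mean, 3.0)))

    def death(by: Optional[int]) -> Optional[int]:
        if by is None:
            return None
        dy = by + int(round(max(1.0, rng.normal(74.0, 12.0))))
        return dy if dy <= 2015 else None

    individuals: list[Individual] = []
    generations: list[list[str]] = []

    def make_person(
        sex: str, mean_by: float, father: Optional[str], mother: Optional[str],
        in_state_p: float,
    ) -> Individual:
        by = birth(mean_by)
        ind = Individual(
            person_id=new_id(),
            father_id=father,
            mother_id=mother,
            sex=sex,
            birth_year=by,
            born_in_state=bool(rng.random() < in_state_p),
            death_year=death(by),
        )
        individuals.append(ind)
        return ind

    # founder generation: couples
    couples: list[tuple[Individual, Individual]] = []
    gen0: list[str] = []
    for _ in range(config.n_founder_couples):
        h = make_person("M", config.founder_birth_year, None, None, 0.7)
        w = make_person("F", config.founder_birth_year, None, None, 0.7)
        couples.append((h, w))
        gen0.extend([h.person_id, w.person_id])
    generations.append(gen0)

    for g in range(1, config.n_generations):
        gen_ids: list[str] = []
        next_couples: list[tuple[Individual, Individual]] = []
        mean_by = config.founder_birth_year + g * config.generation_gap
        for father, mother in couples:
            n_kids = rng.poisson(config.mean_offspring)
            for _ in range(n_kids):
                sex = "M" if rng.random() < 0.5 else "F"
                child = make_person(
                    sex, mean_by, father.person_id, mother.person_id, 0.9
                )
                gen_ids.append(child.person_id)
                if g < config.n_generations - 1:
                    spouse = make_person(
                        "F" if sex == "M" else "M", mean_by, None, None, 0.6
                    )
                    gen_ids.append(spouse.person_id)
                    pair = (child, spouse) if sex == "M" else (spouse, child)
                    next_couples.append(pair)
        if not gen_ids:
            logger.warning("generation %d is empty (fertility too low?)", g)
        generations.append(gen_ids)
        couples = next_couples

    return Pedigree(individuals), generations


# ---------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------

_ALLELES = {"AA": ("A", "A"), "AG": ("A", "G"), "GG": ("G", "G")}


def transmit_genotypes(
    ped: Pedigree,
    g_allele_frequency: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, str]:
    """Founder genotypes under Hardy-Weinberg; descendants draw one
    allele uniformly from each parent.  Individuals with one recorded
    parent draw the missing allele from the population frequency."""
    rng = np.random.default_rng(seed) if rng is None else rng
    f = g_allele_frequency
    genotypes: dict[str, str] = {}

    def founder_gt() -> str:
        u = rng.random()
        if u < (1 - f) ** 2:
            return "AA"
        if u < (1 - f) ** 2 + 2 * f * (1 - f):
            return "AG"
        return "GG"

    def parent_allele(pid: Optional[str]) -> str:
        if pid is None:
            return "G" if rng.random() < f else "A"
        a1, a2 = _ALLELES[resolve(pid)]
        return a1 if rng.random() < 0.5 else a2

    def resolve(pid: str) -> str:
        if pid in genotypes:
            return genotypes[pid]
        ind = ped.individual(pid)
        if ind.father_id is None and ind.mother_id is None:
            gt = founder_gt()
        else:
            alleles = sorted([parent_allele(ind.father_id),
                              parent_allele(ind.mother_id)])
            gt = "".join(alleles)
        genotypes[pid] = gt
        return gt

    # resolve in insertion order (parents precede children in the
    # generator's output; recursion depth is bounded by generations)
    for pid in ped:
        resolve(pid)
    return genotypes


def is_carrier(genotype: str) -> bool:
    return "G" in genotype


# ---------------------------------------------------------------------
# probands
# ---------------------------------------------------------------------

def choose_probands(
    ped: Pedigree,
    genotypes: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[str], list[str], dict[str, str]]:
    """Select genotyped patients.

    Linked probands come from individuals with at least three
    generations of genealogy, enriched for carriers to the configured
    prevalence (glioma patients are strongly enriched relative to the
    population).  The remaining probands emulate record-linkage
    failures: new parentless individuals appended to the genealogy.

    Returns (all proband ids, linked proband ids, source assignment).
    Because unlinked probands are new records, the returned pedigree
    membership changes; callers use the pedigree from
    :func:`simulate_study`, which handles this.
    """
    pool = [
        pid for pid in ped
        if generations_linked(ped, pid) >= 3 and pid in genotypes
    ]
    carriers = [p for p in pool if is_carrier(genotypes[p])]
    noncarr = [p for p in pool if not is_carrier(genotypes[p])]
    n_link = min(config.n_linked_probands, len(pool))
    n_carr = min(int(round(config.proband_carrier_prevalence * n_link)),
                 len(carriers))
    n_non = min(n_link - n_carr, len(noncarr))
    linked = list(rng.choice(carriers, size=n_carr, replace=False)) + list(
        rng.choice(noncarr, size=n_non, replace=False)
    )
    linked = [str(p) for p in linked]
    if len(linked) < config.n_linked_probands:
        logger.warning(
            "only %d of %d requested linked probands available",
            len(linked), config.n_linked_probands,
        )

    n_unlinked = config.n_probands - len(linked)
    unlinked = [f"U{k:06d}" for k in range(1, n_unlinked + 1)]

    probands = linked + unlinked
    # source mix assigned in a random order, proportional to config
    mix = dict(config.source_mix)
    total = sum(mix.values())
    counts = {
        src: int(round(n * config.n_probands / total)) for src, n in mix.items()
    }
    while sum(counts.values()) > config.n_probands:
        counts[max(counts, key=counts.get)] -= 1
    while sum(counts.values()) < config.n_probands:
        counts[min(counts, key=counts.get)] += 1
    order = list(rng.permutation(probands))
    sources: dict[str, str] = {}
    i = 0
    for src in ("somatic", "germline", "both"):
        for pid in order[i:i + counts.get(src, 0)]:
            sources[str(pid)] = src
        i += counts.get(src, 0)
    return probands, linked, sources


# ---------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------

def simulate_registry(
    ped: Pedigree,
    config: SimulationConfig,
    groups: Mapping[str, set[str]],
    rng: np.random.Generator,
) -> list[RegistryRecord]:
    """Bernoulli incidence per person and site.

    The per-person probability is the cohort-adjusted baseline times
    the product of planted multipliers for every group the person
    belongs to (a multiplier on ``ANY`` scales all sites).
    Probabilities exceeding 1 are clipped with a log message.
    """
    records: list[RegistryRecord] = []
    clipped = 0
    for pid in ped:
        ind = ped.individual(pid)
        key = assign_cohort(ind, 5)
        if key is None:
            continue  # uncohortable people get no registry record
        decade_offset = (config.cohort_pivot_year - key.birth_block) / 10.0
        cohort_factor = max(
            0.0, 1.0 + config.cohort_trend_per_decade * decade_offset
        )
        mult = 1.0
        for gname, members in groups.items():
            if pid in members:
                mult *= config.planted_rr.get((gname, ANY_SITE), 1.0)
        for site, base in config.baseline_rates.items():
            req_sex = SEX_SPECIFIC_SITES.get(site)
            if req_sex is not None and ind.sex != req_sex:
                continue
            site_mult = mult
            for gname, members in groups.items():
                if pid in members:
                    site_mult *= config.planted_rr.get((gname, site), 1.0)
            p = base * cohort_factor * site_mult
            if p > 1.0:
                p = 1.0
                clipped += 1
            if rng.random() < p:
                by = ind.birth_year
                dy = by + int(rng.integers(30, 80))
                if ind.death_year is not None:
                    dy = min(dy, ind.death_year)
                records.append(RegistryRecord(pid, site, dy))
    if clipped:
        logger.warning("clipped %d per-person probabilities to 1", clipped)
    return records


# ---------------------------------------------------------------------
# assay
# ---------------------------------------------------------------------

def simulate_assay(
    genotypes: Mapping[str, str],
    sources: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[AssayRecord]:
    """Emit per-proband germline and/or somatic assay records.

    Somatic calls flip carrier -> noncarrier with the false-negative
    rate and noncarrier -> carrier with the false-positive rate (at
    the call level, matching how assay accuracy was scored).  Germline
    run pairs discord (second run fails) at the configured rate; with
    two replicates a person is indeterminate only when all replicates
    discord.
    """
    records: list[AssayRecord] = []
    for pid in sources:
        gt = genotypes[pid]
        src = sources[pid]
        if src in ("germline", "both"):
            for rep in range(1, config.germline_replicates + 1):
                if rng.random() < config.germline_run_discordance:
                    run1, run2 = gt, "fail"
                else:
                    run1 = run2 = gt
                records.append(
                    AssayRecord(f"{pid}-G", pid, "germline", rep, run1, run2)
                )
        if src in ("somatic", "both"):
            if is_carrier(gt):
                observed = "AA" if rng.random() < config.somatic_false_negative else gt
            else:
                observed = "AG" if rng.random() < config.somatic_false_positive else gt
            records.append(
                AssayRecord(f"{pid}-S", pid, "somatic", 1, observed, observed)
            )
    return records


# ---------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------

def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one complete synthetic study, deterministically from
    the config seed: pedigree, genotypes, proband selection (with
    unlinked patients appended as parentless genealogy records),
    planted-risk groups, registry, and assay records."""
    from .genealogy import first_degree_relatives, second_degree_relatives

    rng = np.random.default_rng(config.seed)
    ped, _ = simulate_pedigree(config, rng)
    genotypes = transmit_genotypes(ped, config.g_allele_frequency, rng=rng)
    probands, linked, sources = choose_probands(ped, genotypes, config, rng)

    # unlinked probands become parentless records in the genealogy
    unlinked = [p for p in probands if p not in ped]
    extra = []
    for pid in unlinked:
        by = int(round(rng.normal(
            config.founder_birth_year
            + (config.n_generations - 1) * config.generation_gap, 5.0)))
        extra.append(Individual(
            person_id=pid, sex="M" if rng.random() < 0.5 else "F",
            birth_year=by, born_in_state=bool(rng.random() < 0.5),
        ))
    if extra:
        ped = Pedigree(list(ped.individuals.values()) + extra)
    for pid in unlinked:
        genotypes[pid] = (
            "AG" if rng.random() < config.proband_carrier_prevalence else "AA"
        )

    carrier_pb = [p for p in linked if is_carrier(genotypes[p])]
    groups: dict[str, set[str]] = {
        PROBAND: set(probands),
        CARRIER_FDR: set().union(
            *(first_degree_relatives(ped, p) for p in carrier_pb), set()
        ) - set(probands),
        CARRIER_SDR: set().union(
            *(second_degree_relatives(ped, p) for p in carrier_pb), set()
        ) - set(probands),
    }
    registry = simulate_registry(ped, config, groups, rng)
    assay = simulate_assay(genotypes, sources, config, rng)
    return SimulatedStudy(
        config=config,
        pedigree=ped,
        genotypes=genotypes,
        proband_ids=probands,
        proband_sources=sources,
        linked_proband_ids=linked,
        registry=registry,
        assay_records=assay,
        groups=groups,
    )
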