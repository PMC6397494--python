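"""Cohort-specific incidence rates and observed/expected counts.

Indirect standardization: the reference population is stratified into
cohorts of (sex, born-in-state flag, 5-year birth block), a
lifetime-cumulative incidence proportion is computed per cohort and
cancer site, and the expected case count for a relative set is the sum
over cohorts of (number of relatives in cohort) x (cohort rate).

Rates are proportions of *persons* (cases / persons), not person-year
rates: the expected count is built by multiplying relative counts by
rates.  Individuals with unknown birth year cannot be assigned a
cohort and are excluded from numerator and denominator alike, with a
logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

from .genealogy import Pedigree

__all__ = [
    "ANY_SITE",
    "CohortKey",
    "RegistryRecord",
    "RateTable",
    "assign_cohort",
    "compute_rate_table",
    "expected_count",
    "observed_count",
]

logger = logging.getLogger(__name__)

#: Pseudo-site aggregating all configured sites ("any cancer").
ANY_SITE = "ANY"


class CohortKey(NamedTuple):
    """One stratum of the standardization: sex, in-state birth, and the
    start year of the birth block (a multiple of the block width under
    the default anchoring)."""

    sex: str
    born_in_state: bool
    birth_block: int


@dataclass(frozen=True)
class RegistryRecord:
    """One cancer-registry entry (first primary per site per person is
    what the counting rules use; duplicates are harmless)."""

    person_id: str
    site_code: str
    diagnosis_year: Optional[int] = None


@dataclass
class RateTable:
    """Per-(cohort, site) incidence proportions with denominators."""

    rates: dict[tuple[CohortKey, str], float] = field(default_factory=dict)
    denominators: dict[CohortKey, int] = field(default_factory=dict)
    sites: tuple[str, ...] = ()
    block_width: int = 5
    n_uncohortable: int = 0

    def rate(self, cohort: CohortKey, site: str) -> float:
        return self.rates.get((cohort, site), 0.0)


def assign_cohort(ind, block_width: int = 5) -> Optional[CohortKey]:
    """Map an individual to its standardization stratum.

    Returns ``None`` (the explicit "uncohortable" signal) when the
    birth year is unknown; callers exclude and count such individuals.
    """
    if block_width < 1:
        raise ValueError("block_width must be >= 1")
    if ind.birth_year is None:
        return None
    block = ind.birth_year - ind.birth_year % block_width
    return CohortKey(ind.sex, bool(ind.born_in_state), block)


def _persons_with_site(
    registry: Iterable[RegistryRecord], sites: Sequence[str]
) -> dict[str, set[str]]:
    """site -> set of distinct persons with >= 1 record of that site.

    ``ANY`` collects persons with a record of any configured site.
    """
    siteset = set(sites)
    by_site: dict[str, set[str]] = {s: set() for s in siteset | {ANY_SITE}}
    for rec in registry:
        if rec.site_code in siteset:
            by_site[rec.site_code].add(rec.person_id)
            by_site[ANY_SITE].add(rec.person_id)
    return by_site


def compute_rate_table(
    pop: Pedigree,
    registry: Iterable[RegistryRecord],
    sites: Sequence[str],
    block_width: int = 5,
    exclude: Iterable[str] = (),
) -> RateTable:
    """Cohort-specific incidence proportions from the whole linked
    population.

    ``exclude`` removes persons (typically the probands themselves)
    from the denominators and numerators; everyone else in the
    pedigree, relatives of other probands included, contributes.
    """
    sites = [s for s in sites if s != ANY_SITE]
    if not sites:
        raise ValueError("need at least one concrete site")
    excluded = set(exclude)
    cases = _persons_with_site(registry, sites)

    members: dict[CohortKey, list[str]] = {}
    n_uncohortable = 0
    for pid, ind in pop.individuals.items():
        if pid in excluded:
            continue
        key = assign_cohort(ind, block_width)
        if key is None:
            n_uncohortable += 1
            continue
        members.setdefault(key, []).append(pid)
    if n_uncohortable:
        logger.info(
            "excluded %d individuals with unknown birth year from rate table",
            n_uncohortable,
        )

    table = RateTable(
        sites=tuple(sites), block_width=block_width, n_uncohortable=n_uncohortable
    )
    for key, pids in members.items():
        denom = len(pids)
        table.denominators[key] = denom
        pidset = set(pids)
        for site in list(sites) + [ANY_SITE]:
            table.rates[(key, site)] = len(cases[site] & pidset) / denom
    return table


def expected_count(
    relatives: Iterable[str], ped: Pedigree, table: RateTable, site: str
) -> float:
    """Sum over cohorts of (relatives in cohort) x (cohort rate).

    Equivalently the sum of per-person cohort rates; additive over any
    partition of the relative set.  Relatives without a birth year are
    skipped (uncohortable) with a log message; unknown ids raise.
    """
    total = 0.0
    skipped = 0
    for pid in relatives:
        key = assign_cohort(ped.individual(pid), table.block_width)
        if key is None:
            skipped += 1
            continue
        total += table.rate(key, site)
    if skipped:
        logger.info("expected_count: skipped %d uncohortable relatives", skipped)
    return total


def observed_count(
    relatives: Iterable[str],
    registry: Iterable[RegistryRecord],
    site: str,
    sites: Sequence[str] = (),
) -> int:
    """Number of distinct relatives with at least one registry record
    of ``site``.  For ``ANY``, a record of any site in ``sites`` (or of
    any site at all when ``sites`` is empty) counts.
    """
    relset = set(relatives)
    hit: set[str] = set()
    siteset = set(sites)
    for rec in registry:
        if rec.person_id not in relset:
            continue
        if site == ANY_SITE:
            if not siteset or rec.site_code in siteset:
                hit.add(rec.person_id)
        elif rec.site_code == site:
            hit.add(rec.person_id)
    return len(hit)
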