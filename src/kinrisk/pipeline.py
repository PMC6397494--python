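"""High-level drivers tying the pipeline stages together.

One call takes a genealogy, registry and resolved proband genotypes
and produces the four familial-risk tables (carrier / noncarrier x
first / second degree), applying the eligibility filter, building the
cohort rate table with probands excluded from its denominators, and
masking small counts for rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .cohorts import RateTable, RegistryRecord, compute_rate_table
from .genealogy import Pedigree, Proband, eligible_probands
from .inference import SIRResult, mask_small_counts, run_familial_risk

__all__ = ["AnalysisSettings", "familial_risk_tables"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisSettings:
    """Tunable analysis parameters with the study's defaults."""

    block_width: int = 5
    min_generations: int = 3
    mask_threshold: int = 5
    alpha_low: float = 0.05
    alpha_high: float = 0.025
    prevalence: float = 0.40


def familial_risk_tables(
    ped: Pedigree,
    registry: Iterable[RegistryRecord],
    probands: Sequence[Proband],
    sites: Sequence[str],
    settings: AnalysisSettings = AnalysisSettings(),
    rate_table: Optional[RateTable] = None,
) -> dict[tuple[str, int], list[SIRResult]]:
    """All four familial-risk tables, masked for rendering.

    Probands failing the generation-linkage bar are dropped (logged,
    like samples failing record linkage); every genotyped proband is
    excluded from rate denominators and relative sets.
    """
    registry = list(registry)
    all_ids = [pb.person_id for pb in probands]
    eligible = eligible_probands(ped, probands, settings.min_generations)
    n_dropped = len(probands) - len(eligible)
    if n_dropped:
        logger.info(
            "%d of %d probands lack %d generations of genealogy and are excluded",
            n_dropped, len(probands), settings.min_generations,
        )
    if not eligible:
        raise ValueError("no probands pass the generation-linkage filter")

    if rate_table is None:
        rate_table = compute_rate_table(
            ped, registry, sites, settings.block_width, exclude=all_ids
        )

    carriers = [pb for pb in eligible if pb.g_allele_carrier]
    noncarriers = [pb for pb in eligible if not pb.g_allele_carrier]
    tables: dict[tuple[str, int], list[SIRResult]] = {}
    for group, members in (("carrier", carriers), ("noncarrier", noncarriers)):
        for degree in (1, 2):
            rows = run_familial_risk(
                members, ped, registry, rate_table, degree, sites,
                group=group, all_proband_ids=all_ids,
                alpha_low=settings.alpha_low, alpha_high=settings.alpha_high,
            )
            tables[(group, degree)] = mask_small_counts(
                rows, settings.mask_threshold
            )
    return tables
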