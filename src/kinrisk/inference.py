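"""Relative-risk estimation and exact Poisson inference for
observed-versus-expected counts (standardized incidence ratios).

The estimand is RR = O/E where O is the observed number of distinct
relatives with a given cancer and E the cohort-standardized expected
number.  Under the null RR <= 1, O ~ Poisson(E), and the one-sided
p-value is the upper tail P(X >= O).

Conventions (each exposed as configuration):

* zero observed cases report P(X = 0) = exp(-E) instead of the
  literal upper-tail value of 1; the flag ``zero_p_is_point_mass``
  marks those rows;
* the confidence interval mixes one-sided and two-sided exact bounds:
  lower = one-sided 95% exact lower limit chi2(alpha_low, 2*O)/(2E),
  upper = two-sided 97.5% exact upper limit
  chi2(1 - alpha_high, 2*(O+1))/(2E); for O = 0 the upper bound is the
  one-sided 95% limit -ln(alpha_low)/E and the lower bound is 0.

Small observed counts (<= 5 by default) are masked in rendered output
to protect anonymity; the ratio, p-value and interval remain visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from scipy.stats import chi2, poisson

from .cohorts import ANY_SITE, RateTable, expected_count, observed_count
from .genealogy import (
    Pedigree,
    Proband,
    first_degree_relatives,
    second_degree_relatives,
)

__all__ = [
    "SIRResult",
    "relative_risk",
    "poisson_one_sided_p",
    "exact_poisson_ci",
    "run_familial_risk",
    "mask_small_counts",
    "group_relative_sets",
]


@dataclass(frozen=True)
class SIRResult:
    """One row of a familial-risk table."""

    site: str
    degree: int  # 1 or 2
    group: str  # "carrier" or "noncarrier"
    obs: int
    exp: float
    rr: float
    p_one_sided: float
    ci_low: float
    ci_high: float
    masked: bool = False
    n_relatives: int = 0
    zero_p_is_point_mass: bool = False


def relative_risk(obs: int, exp: float) -> float:
    """Observed over expected; 0/E is 0 by convention."""
    if exp <= 0:
        raise ValueError("expected count must be positive")
    return obs / exp


def poisson_one_sided_p(obs: int, exp: float) -> float:
    """One-sided probability against the null RR <= 1.

    P(X >= obs) for X ~ Poisson(exp) when obs >= 1.  For obs = 0 the
    reported value is P(X = 0) = exp(-exp) rather than the literal
    tail probability of 1 (the convention used in the published
    zero-count rows).
    """
    if obs < 0:
        raise ValueError("observed count must be >= 0")
    if exp <= 0:
        raise ValueError("expected count must be positive")
    if obs == 0:
        return math.exp(-exp)
    return float(poisson.sf(obs - 1, exp))


def exact_poisson_ci(
    obs: int,
    exp: float,
    alpha_low: float = 0.05,
    alpha_high: float = 0.025,
) -> tuple[float, float]:
    """Exact (chi-square quantile) confidence bounds for RR = O/E.

    The lower bound solves P(X >= obs | lambda = low*E) = alpha_low,
    the upper bound solves P(X <= obs | lambda = high*E) = alpha_high;
    both have the classical closed form via chi-square quantiles.  At
    obs = 0 the lower bound is 0 and the upper bound is the one-sided
    -ln(alpha_low)/E.
    """
    if obs < 0:
        raise ValueError("observed count must be >= 0")
    if exp <= 0:
        raise ValueError("expected count must be positive")
    if obs == 0:
        return 0.0, -math.log(alpha_low) / exp
    low = float(chi2.ppf(alpha_low, 2 * obs)) / (2 * exp)
    high = float(chi2.ppf(1 - alpha_high, 2 * (obs + 1))) / (2 * exp)
    return low, high


def group_relative_sets(
    probands: Sequence[Proband], ped: Pedigree, degree: int
) -> set[str]:
    """Deduplicated union of relative sets over a proband group.

    A person related to several probands in the group is counted once;
    probands themselves (from the given list) are never relatives.
    """
    if degree == 1:
        enum = first_degree_relatives
    elif degree == 2:
        enum = second_degree_relatives
    else:
        raise ValueError("degree must be 1 or 2")
    union: set[str] = set()
    for pb in probands:
        union |= enum(ped, pb.person_id)
    return union - {pb.person_id for pb in probands}


def _build_row(
    site: str, degree: int, group: str, obs: int, exp: float, n_rel: int,
    alpha_low: float, alpha_high: float,
) -> SIRResult:
    if exp > 0:
        rr = relative_risk(obs, exp)
        p = poisson_one_sided_p(obs, exp)
        lo, hi = exact_poisson_ci(obs, exp, alpha_low, alpha_high)
    else:  # no expected cases in these cohorts; estimates undefined
        rr = p = lo = hi = float("nan")
    return SIRResult(
        site=site,
        degree=degree,
        group=group,
        obs=obs,
        exp=exp,
        rr=rr,
        p_one_sided=p,
        ci_low=lo,
        ci_high=hi,
        n_relatives=n_rel,
        zero_p_is_point_mass=(obs == 0 and exp > 0),
    )


def run_familial_risk(
    probands: Sequence[Proband],
    ped: Pedigree,
    registry: Iterable,
    table: RateTable,
    degree: int,
    sites: Sequence[str],
    group: str = "carrier",
    all_proband_ids: Iterable[str] = (),
    alpha_low: float = 0.05,
    alpha_high: float = 0.025,
) -> list[SIRResult]:
    """One familial-risk table: per-site observed/expected counts and
    exact inference over the deduplicated union of the group's
    relatives of the given degree.

    ``probands`` are the group's members (pre-split by resolved
    carrier status); ``all_proband_ids`` may list every genotyped
    proband so that no proband is ever counted as a relative.
    """
    registry = list(registry)
    relatives = group_relative_sets(probands, ped, degree) - set(all_proband_ids)
    site_list = [s for s in sites if s != ANY_SITE]
    rows = []
    for site in [ANY_SITE] + site_list:
        obs = observed_count(relatives, registry, site, sites=site_list)
        exp = expected_count(relatives, ped, table, site)
        rows.append(
            _build_row(site, degree, group, obs, exp, len(relatives),
                       alpha_low, alpha_high)
        )
    return rows


def mask_small_counts(
    results: Iterable[SIRResult], threshold: int = 5
) -> list[SIRResult]:
    """Flag rows with obs <= threshold for suppression of the exact
    observed and expected counts in rendered output.  RR, p-value and
    interval remain reportable."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [replace(r, masked=(r.obs <= threshold)) for r in results]
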