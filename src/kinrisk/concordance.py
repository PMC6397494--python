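"""Genotype call resolution and somatic-versus-germline concordance.

Each person may have several assay samples, each with replicates, each
replicate scored in two runs (calls AA / AG / GG / fail).  Resolution
rules differ by tissue source:

* germline (blood) — *carrier* requires at least one replicate in
  which both runs detect the G allele (call in {AG, GG});
  *noncarrier* requires no such replicate plus at least one fully
  concordant AA replicate; anything else is *indeterminate*.
* somatic (tumor)  — *carrier* if any single run of any replicate
  detects the G allele; *noncarrier* if every non-failed run is AA and
  at least one informative run exists; otherwise *indeterminate*.

The germline call is treated as truth when both are available, giving
a 2x2 confusion matrix, sensitivity/specificity/accuracy with exact
binomial (Clopper-Pearson) intervals, and prevalence-adjusted
predictive values via Bayes' formula.  PPV/NPV intervals are
deliberately not computed (no exact method reproduces a published
analog; the point estimates are prevalence-dependent).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from scipy.stats import beta

__all__ = [
    "AssayRecord",
    "ConfusionMatrix",
    "DiagnosticReport",
    "CARRIER",
    "NONCARRIER",
    "INDETERMINATE",
    "call_germline",
    "call_somatic",
    "resolve_calls",
    "resolve_carrier_status",
    "confusion",
    "clopper_pearson",
    "predictive_values",
    "diagnostic_report",
]

logger = logging.getLogger(__name__)

CARRIER = "carrier"
NONCARRIER = "noncarrier"
INDETERMINATE = "indeterminate"

_G_CALLS = frozenset({"AG", "GG"})
_VALID_CALLS = frozenset({"AA", "AG", "GG", "fail"})


@dataclass(frozen=True)
class AssayRecord:
    """One replicate of one sample: two genotyping runs."""

    sample_id: str
    person_id: str
    source: str  # "germline" or "somatic"
    replicate: int
    run1_call: str
    run2_call: str

    def __post_init__(self) -> None:
        if self.source not in ("germline", "somatic"):
            raise ValueError(f"source must be germline/somatic, got {self.source!r}")
        for c in (self.run1_call, self.run2_call):
            if c not in _VALID_CALLS:
                raise ValueError(f"invalid call {c!r}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Somatic call (test) against germline call (truth)."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.fp + self.tn)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


@dataclass(frozen=True)
class DiagnosticReport:
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    ppv: float
    npv: float
    prevalence_used: float
    matrix: ConfusionMatrix


def call_germline(records: Iterable[AssayRecord]) -> str:
    """Resolve a person's germline carrier status from blood assays."""
    recs = [r for r in records if r.source == "germline"]
    if not recs:
        raise ValueError("no germline records for this person")
    has_concordant_aa = False
    for r in recs:
        if r.run1_call in _G_CALLS and r.run2_call in _G_CALLS:
            return CARRIER
        if r.run1_call == "AA" and r.run2_call == "AA":
            has_concordant_aa = True
    return NONCARRIER if has_concordant_aa else INDETERMINATE


def call_somatic(records: Iterable[AssayRecord]) -> str:
    """Resolve a person's somatic (tumor) carrier status; a single
    G-detecting run suffices for a positive call."""
    recs = [r for r in records if r.source == "somatic"]
    if not recs:
        raise ValueError("no somatic records for this person")
    informative = 0
    for r in recs:
        for call in (r.run1_call, r.run2_call):
            if call in _G_CALLS:
                return CARRIER
            if call != "fail":
                informative += 1
    return NONCARRIER if informative else INDETERMINATE


def resolve_calls(
    records: Iterable[AssayRecord],
) -> dict[str, tuple[Optional[str], Optional[str]]]:
    """Per-person (germline_call, somatic_call); ``None`` where the
    person has no records from that source."""
    by_person: dict[str, list[AssayRecord]] = {}
    for rec in records:
        by_person.setdefault(rec.person_id, []).append(rec)
    out = {}
    for pid, recs in by_person.items():
        g = call_germline(recs) if any(r.source == "germline" for r in recs) else None
        s = call_somatic(recs) if any(r.source == "somatic" for r in recs) else None
        out[pid] = (g, s)
    return out


def resolve_carrier_status(
    records: Iterable[AssayRecord], impute_from_somatic: bool = True
) -> dict[str, str]:
    """Final per-person carrier status for downstream familial analysis.

    Germline wins when determinate.  With ``impute_from_somatic``
    (the published practice for patients lacking blood DNA), a
    determinate somatic call stands in where no usable germline call
    exists.  Persons left indeterminate are dropped with a log entry.
    """
    out: dict[str, str] = {}
    dropped = 0
    for pid, (g, s) in resolve_calls(records).items():
        status = g if g in (CARRIER, NONCARRIER) else None
        if status is None and impute_from_somatic and s in (CARRIER, NONCARRIER):
            status = s
        if status is None:
            dropped += 1
            continue
        out[pid] = status
    if dropped:
        logger.info("dropped %d persons with indeterminate genotype", dropped)
    return out


def confusion(
    calls: Mapping[str, tuple[Optional[str], Optional[str]]]
) -> ConfusionMatrix:
    """2x2 table over persons with determinate calls from both
    sources; others are excluded with a log entry."""
    tp = fn = fp = tn = 0
    excluded = 0
    for pid, (g, s) in calls.items():
        if g not in (CARRIER, NONCARRIER) or s not in (CARRIER, NONCARRIER):
            excluded += 1
            continue
        if g == CARRIER:
            if s == CARRIER:
                tp += 1
            else:
                fn += 1
        else:
            if s == CARRIER:
                fp += 1
            else:
                tn += 1
    if excluded:
        logger.info("confusion: excluded %d unpaired/indeterminate persons", excluded)
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def predictive_values(
    sens: float, spec: float, prevalence: float
) -> tuple[float, float]:
    """Prevalence-adjusted PPV and NPV via Bayes' formula.

    Degenerate denominators (e.g. prevalence 0 with perfect
    specificity) return the natural limit with a warning.
    """
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    pos = sens * prevalence + (1 - spec) * (1 - prevalence)
    neg = (1 - sens) * prevalence + spec * (1 - prevalence)
    if pos > 0:
        ppv = sens * prevalence / pos
    else:
        warnings.warn("no positive results possible; PPV set to its limit 1.0")
        ppv = 1.0
    if neg > 0:
        npv = spec * (1 - prevalence) / neg
    else:
        warnings.warn("no negative results possible; NPV set to its limit 1.0")
        npv = 1.0
    return ppv, npv


def diagnostic_report(
    cm: ConfusionMatrix, prevalence: float = 0.40, conf: float = 0.95
) -> DiagnosticReport:
    """Summary statistics for the somatic-vs-germline comparison.

    ``prevalence`` defaults to the carrier fraction among IDH-mutant
    glioma patients (about 40%), the population in which the somatic
    assay would be deployed; predictive values use it via Bayes rather
    than the raw column totals of the 2x2 table.
    """
    sens, spec, acc = cm.sensitivity, cm.specificity, cm.accuracy
    ppv, npv = predictive_values(sens, spec, prevalence)
    return DiagnosticReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        sensitivity_ci=clopper_pearson(cm.tp, cm.tp + cm.fn, conf),
        specificity_ci=clopper_pearson(cm.tn, cm.fp + cm.tn, conf),
        accuracy_ci=clopper_pearson(cm.tp + cm.tn, cm.n, conf),
        ppv=ppv,
        npv=npv,
        prevalence_used=prevalence,
        matrix=cm,
    )
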