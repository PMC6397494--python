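"""CSV readers/writers for the four input tables and TSV renderers
for the output reports.

Formats:

* genealogy:  ``person_id,father_id,mother_id,sex,birth_year,born_in_state,death_year``
  (empty field = unknown; sex M/F; born_in_state 0/1)
* registry:   ``person_id,site_code,diagnosis_year``
* probands:   ``person_id,g_allele_carrier``
* assay:      ``sample_id,person_id,source,replicate,run1_call,run2_call``

Familial-risk tables render with the small-count suppression rule:
rows with five or fewer observed cases print ``<=5*`` in the observed
and expected columns, while the ratio, p-value and interval stay.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .cohorts import RegistryRecord
from .concordance import AssayRecord, DiagnosticReport
from .genealogy import Individual, Pedigree, Proband
from .inference import SIRResult

__all__ = [
    "read_genealogy",
    "write_genealogy",
    "read_registry",
    "write_registry",
    "read_probands",
    "write_probands",
    "read_assay",
    "write_assay",
    "render_sir_table",
    "render_diagnostic_report",
]

PathLike = Union[str, Path]


def _opt_int(v) -> Optional[int]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return int(v)


def read_genealogy(path: PathLike) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    inds = []
    for row in df.itertuples(index=False):
        inds.append(Individual(
            person_id=row.person_id,
            father_id=row.father_id or None,
            mother_id=row.mother_id or None,
            sex=row.sex,
            birth_year=_opt_int(row.birth_year),
            born_in_state=None if row.born_in_state == "" else row.born_in_state == "1",
            death_year=_opt_int(row.death_year),
        ))
    return Pedigree(inds)


def write_genealogy(ped: Pedigree, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "father_id", "mother_id", "sex",
                    "birth_year", "born_in_state", "death_year"])
        for pid in ped:
            ind = ped.individual(pid)
            w.writerow([
                ind.person_id,
                ind.father_id or "",
                ind.mother_id or "",
                ind.sex,
                "" if ind.birth_year is None else ind.birth_year,
                "" if ind.born_in_state is None else int(ind.born_in_state),
                "" if ind.death_year is None else ind.death_year,
            ])


def read_registry(path: PathLike) -> list[RegistryRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        RegistryRecord(r.person_id, r.site_code, _opt_int(r.diagnosis_year))
        for r in df.itertuples(index=False)
    ]


def write_registry(records: Iterable[RegistryRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "site_code", "diagnosis_year"])
        for rec in records:
            w.writerow([rec.person_id, rec.site_code,
                        "" if rec.diagnosis_year is None else rec.diagnosis_year])


def read_probands(path: PathLike) -> list[Proband]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        source = getattr(r, "genotype_source", "germline") or "germline"
        out.append(Proband(r.person_id, r.g_allele_carrier == "1", source))
    return out


def write_probands(probands: Iterable[Proband], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "g_allele_carrier", "genotype_source"])
        for pb in probands:
            w.writerow([pb.person_id, int(pb.g_allele_carrier), pb.genotype_source])


def read_assay(path: PathLike) -> list[AssayRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        AssayRecord(r.sample_id, r.person_id, r.source, int(r.replicate),
                    r.run1_call, r.run2_call)
        for r in df.itertuples(index=False)
    ]


def write_assay(records: Iterable[AssayRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "person_id", "source", "replicate",
                    "run1_call", "run2_call"])
        for rec in records:
            w.writerow([rec.sample_id, rec.person_id, rec.source,
                        rec.replicate, rec.run1_call, rec.run2_call])


# ---------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------

_MASK = "<=5*"


def _fmt(x: float, nd: int) -> str:
    return "nan" if math.isnan(x) else f"{x:.{nd}f}"


def render_sir_table(results: Sequence[SIRResult]) -> str:
    """TSV rendering of one familial-risk table.

    RR and CI print to 2 decimals, the p-value to 3, the expected
    count to 2 — masked rows show ``<=5*`` for observed and expected.
    """
    lines = ["site\tobs\texp\tp_one_sided\trr\tci_low\tci_high\tmasked"]
    for r in results:
        obs = _MASK if r.masked else str(r.obs)
        exp = _MASK if r.masked else _fmt(r.exp, 2)
        lines.append("\t".join([
            r.site, obs, exp, _fmt(r.p_one_sided, 3), _fmt(r.rr, 2),
            _fmt(r.ci_low, 2), _fmt(r.ci_high, 2), str(int(r.masked)),
        ]))
    return "\n".join(lines) + "\n"


def render_diagnostic_report(rep: DiagnosticReport) -> str:
    """Human-readable concordance report with the 2x2 table block."""
    cm = rep.matrix
    pct = lambda x: f"{100 * x:.1f}%"
    ci = lambda lo_hi: f"{100 * lo_hi[0]:.1f}-{100 * lo_hi[1]:.1f}%"
    lines = [
        "somatic call vs germline truth (n = %d)" % cm.n,
        "",
        "\t\tgermline+\tgermline-",
        f"somatic+\t{cm.tp}\t{cm.fp}",
        f"somatic-\t{cm.fn}\t{cm.tn}",
        "",
        f"sensitivity\t{pct(rep.sensitivity)}\t(CI {ci(rep.sensitivity_ci)})",
        f"specificity\t{pct(rep.specificity)}\t(CI {ci(rep.specificity_ci)})",
        f"accuracy\t{pct(rep.accuracy)}\t(CI {ci(rep.accuracy_ci)})",
        f"ppv\t{pct(rep.ppv)}\t(prevalence {rep.prevalence_used:.2f})",
        f"npv\t{pct(rep.npv)}\t(prevalence {rep.prevalence_used:.2f})",
    ]
    return "\n".join(lines) + "\n"
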