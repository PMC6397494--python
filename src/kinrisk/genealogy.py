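"""Genealogy data model and first/second-degree relative enumeration.

A pedigree is a collection of individuals with optional father/mother
links. Relative degree follows the standard genetic convention:

* first degree  — parents, children, and *full* siblings (both parents
  recorded and shared);
* second degree — grandparents, grandchildren, aunts/uncles (full
  siblings of a parent), nieces/nephews (children of full siblings),
  and half-siblings (exactly one shared recorded parent).

Spouses are not relatives (no genetic path).  When both a first- and a
second-degree path exist, the closer degree wins.  Missing parents
terminate traversal silently: genealogy databases are incomplete by
nature, and an individual with a single recorded parent is traversed
through that parent only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "Individual",
    "Pedigree",
    "Proband",
    "PedigreeError",
    "first_degree_relatives",
    "second_degree_relatives",
    "generations_linked",
    "eligible_probands",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or unknown person ids."""


@dataclass(frozen=True)
class Individual:
    """One genealogy record.

    Parameters
    ----------
    person_id : str
        Unique identifier within the pedigree.
    father_id, mother_id : str or None
        Parent identifiers; ``None`` means unknown/unrecorded.
    sex : {"M", "F"}
    birth_year : int or None
    born_in_state : bool or None
        Whether the person was born in the reference state; one of
        the three cohort-stratification axes.
    death_year : int or None
    """

    person_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "F"
    birth_year: Optional[int] = None
    born_in_state: Optional[bool] = None
    death_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise PedigreeError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if (
            self.birth_year is not None
            and self.death_year is not None
            and self.birth_year > self.death_year
        ):
            raise PedigreeError(
                f"{self.person_id}: birth_year {self.birth_year} after "
                f"death_year {self.death_year}"
            )

    @property
    def parent_ids(self) -> tuple[str, ...]:
        return tuple(p for p in (self.father_id, self.mother_id) if p is not None)


@dataclass(frozen=True)
class Proband:
    """A genotyped index patient.

    ``g_allele_carrier`` is a *resolved* per-person call (see the
    concordance module), not raw assay run data.
    """

    person_id: str
    g_allele_carrier: bool
    genotype_source: str = "germline"  # {germline, somatic, both}


class Pedigree:
    """Parent-child graph over a set of :class:`Individual` records.

    Validates on construction: person ids unique, parent references
    resolve, and the parent graph is acyclic (no one is their own
    ancestor).  Maintains a child index (parent id -> set of child ids)
    that is exactly the inverse of the recorded parent fields.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.person_id in self._individuals:
                raise PedigreeError(f"duplicate person_id {ind.person_id!r}")
            self._individuals[ind.person_id] = ind

        self._children: dict[str, set[str]] = {}
        for ind in self._individuals.values():
            for pid in ind.parent_ids:
                if pid not in self._individuals:
                    raise PedigreeError(
                        f"{ind.person_id}: parent {pid!r} not in pedigree"
                    )
                self._children.setdefault(pid, set()).add(ind.person_id)

        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative DFS over parent links; colors: 0 unseen, 1 active, 2 done
        color = dict.fromkeys(self._individuals, 0)
        for start in self._individuals:
            if color[start]:
                continue
            stack: list[tuple[str, Iterator[str]]] = [
                (start, iter(self._individuals[start].parent_ids))
            ]
            color[start] = 1
            while stack:
                node, parents = stack[-1]
                nxt = next(parents, None)
                if nxt is None:
                    color[node] = 2
                    stack.pop()
                elif color[nxt] == 1:
                    raise PedigreeError(f"{nxt!r} is its own ancestor")
                elif color[nxt] == 0:
                    color[nxt] = 1
                    stack.append((nxt, iter(self._individuals[nxt].parent_ids)))

    # -- basic access ---------------------------------------------------
    def __len__(self) -> int:
        return len(self._individuals)

    def __contains__(self, person_id: str) -> bool:
        return person_id in self._individuals

    def __iter__(self) -> Iterator[str]:
        return iter(self._individuals)

    def individual(self, person_id: str) -> Individual:
        try:
            return self._individuals[person_id]
        except KeyError:
            raise PedigreeError(f"unknown person_id {person_id!r}") from None

    @property
    def individuals(self) -> dict[str, Individual]:
        return dict(self._individuals)

    def parents(self, person_id: str) -> set[str]:
        return set(self.individual(person_id).parent_ids)

    def children(self, person_id: str) -> set[str]:
        self.individual(person_id)  # raise on unknown id
        return set(self._children.get(person_id, ()))

    def full_siblings(self, person_id: str) -> set[str]:
        """Siblings sharing *both* recorded parents with ``person_id``."""
        ind = self.individual(person_id)
        if ind.father_id is None or ind.mother_id is None:
            return set()
        sibs = set()
        for cid in self._children.get(ind.father_id, ()):
            if cid == person_id:
                continue
            other = self._individuals[cid]
            if other.father_id == ind.father_id and other.mother_id == ind.mother_id:
                sibs.add(cid)
        return sibs

    def half_siblings(self, person_id: str) -> set[str]:
        """Siblings sharing exactly one recorded parent."""
        ind = self.individual(person_id)
        out: set[str] = set()
        for pid in ind.parent_ids:
            out |= self._children.get(pid, set())
        out.discard(person_id)
        return out - self.full_siblings(person_id)


def first_degree_relatives(ped: Pedigree, person_id: str) -> set[str]:
    """Parents, full siblings, and children of ``person_id``."""
    rel = ped.parents(person_id) | ped.children(person_id)
    rel |= ped.full_siblings(person_id)
    rel.discard(person_id)
    return rel


def second_degree_relatives(ped: Pedigree, person_id: str) -> set[str]:
    """Grandparents, grandchildren, aunts/uncles, nieces/nephews, and
    half-siblings of ``person_id``.

    Disjoint from :func:`first_degree_relatives`: when a closer path
    exists the pair is classified first degree only.
    """
    rel: set[str] = set()
    for p in ped.parents(person_id):
        rel |= ped.parents(p)          # grandparents
        rel |= ped.full_siblings(p)    # aunts/uncles
    for c in ped.children(person_id):
        rel |= ped.children(c)         # grandchildren
    for s in ped.full_siblings(person_id):
        rel |= ped.children(s)         # nieces/nephews
    rel |= ped.half_siblings(person_id)
    rel.discard(person_id)
    return rel - first_degree_relatives(ped, person_id)


def generations_linked(ped: Pedigree, person_id: str) -> int:
    """Depth of the deepest recorded ancestor chain, counting self.

    A founder is 1; someone with a recorded parent is >= 2; a recorded
    grandparent gives >= 3, the eligibility bar used for familial
    analysis.
    """
    ped.individual(person_id)
    depth: dict[str, int] = {}

    def _depth(pid: str) -> int:
        if pid in depth:
            return depth[pid]
        stack = [pid]
        while stack:
            cur = stack[-1]
            pending = [
                p for p in ped.individual(cur).parent_ids if p not in depth
            ]
            if pending:
                stack.extend(pending)
                continue
            stack.pop()
            parent_depths = [depth[p] for p in ped.individual(cur).parent_ids]
            depth[cur] = 1 + max(parent_depths, default=0)
        return depth[pid]

    return _depth(person_id)


def eligible_probands(
    ped: Pedigree, probands: Iterable[Proband], min_generations: int = 3
) -> list[Proband]:
    """Keep probands with at least ``min_generations`` of recorded
    genealogy (order preserved).  Probands absent from the pedigree are
    dropped: they are the analog of samples that failed record linkage.
    """
    if min_generations < 1:
        raise ValueError("min_generations must be >= 1")
    kept = []
    for pb in probands:
        if pb.person_id not in ped:
            continue
        if generations_linked(ped, pb.person_id) >= min_generations:
            kept.append(pb)
    return kept
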