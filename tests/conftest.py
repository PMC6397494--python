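"""Shared fixtures and the independent relative-degree oracle.

The oracle enumerates relative categories by naive scans over the raw
parent fields (no child index, no Pedigree machinery), so it shares no
code with the traversal implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from kinrisk.genealogy import Individual, Pedigree


@pytest.fixture
def three_gen():
    """Two grandparent couples, one parent couple, three children."""
    inds = [
        Individual("gf1", sex="M", birth_year=1900, born_in_state=True),
        Individual("gm1", sex="F", birth_year=1902, born_in_state=True),
        Individual("gf2", sex="M", birth_year=1898, born_in_state=False),
        Individual("gm2", sex="F", birth_year=1901, born_in_state=True),
        Individual("dad", "gf1", "gm1", "M", 1925, True),
        Individual("mom", "gf2", "gm2", "F", 1927, True),
        Individual("c1", "dad", "mom", "F", 1950, True),
        Individual("c2", "dad", "mom", "M", 1952, True),
        Individual("c3", "dad", "mom", "F", 1955, False),
    ]
    return Pedigree(inds)


# ---------------------------------------------------------------------
# independent degree oracle
# ---------------------------------------------------------------------

def oracle_relatives(individuals):
    """id -> (first-degree set, second-degree set) by naive definition
    scans over raw parent fields."""
    par = {i.person_id: (i.father_id, i.mother_id) for i in individuals}
    ids = list(par)

    def parents(a):
        return {p for p in par[a] if p is not None}

    def children(a):
        return {b for b in ids if a in par[b]}

    def fullsibs(a):
        f, m = par[a]
        if f is None or m is None:
            return set()
        return {b for b in ids if b != a and par[b] == (f, m)}

    def halfsibs(a):
        out = set()
        for b in ids:
            if b == a:
                continue
            shared = parents(a) & parents(b)
            if shared and b not in fullsibs(a):
                out.add(b)
        return out

    result = {}
    for a in ids:
        fdr = parents(a) | children(a) | fullsibs(a)
        sdr = set()
        for p in parents(a):
            sdr |= parents(p) | fullsibs(p)
        for c in children(a):
            sdr |= children(c)
        for s in fullsibs(a):
            sdr |= children(s)
        sdr |= halfsibs(a)
        sdr -= fdr | {a}
        fdr -= {a}
        result[a] = (fdr, sdr)
    return result


def random_individuals(rng: np.random.Generator, n_gen=3, gen_size=12,
                       p_missing=0.15):
    """Random layered pedigree allowing half-siblings, single-parent
    links and (occasionally) inbreeding via within-generation mate
    reuse.  Always acyclic: parents come from the previous layer."""
    individuals = []
    prev_m: list[str] = []
    prev_f: list[str] = []
    counter = 0
    for g in range(n_gen):
        cur_m, cur_f = [], []
        for _ in range(int(rng.integers(max(2, gen_size // 2), gen_size + 1))):
            counter += 1
            pid = f"p{g}_{counter}"
            father = mother = None
            if prev_m and rng.random() > p_missing:
                father = prev_m[int(rng.integers(len(prev_m)))]
            if prev_f and rng.random() > p_missing:
                mother = prev_f[int(rng.integers(len(prev_f)))]
            sex = "M" if rng.random() < 0.5 else "F"
            (cur_m if sex == "M" else cur_f).append(pid)
            individuals.append(Individual(
                pid, father, mother, sex, birth_year=1900 + 30 * g
            ))
        prev_m, prev_f = cur_m, cur_f
    return individuals
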