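"""Shared fixtures: small hand-built pedigrees and generator helpers."""

import io

import numpy as np
import pytest
from hypothesis import settings

from resilink.pedigree import Individual, Pedigree, read_pedigree

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

TRIO_PED = """\
FAM1 F 0 0 1 1
FAM1 M 0 0 2 1
FAM1 C F M 1 2
"""


@pytest.fixture
def trio():
    return read_pedigree(io.StringIO(TRIO_PED))


@pytest.fixture
def cousin_pedigree():
    """First cousins and their consanguineous child (one marriage loop)."""
    mem = [
        Individual(id="GF", sex="male"),
        Individual(id="GM", sex="female"),
        Individual(id="P1", father_id="GF", mother_id="GM", sex="male"),
        Individual(id="P2", father_id="GF", mother_id="GM", sex="female"),
        Individual(id="S1", sex="female", is_marry_in=True),
        Individual(id="S2", sex="male", is_marry_in=True),
        Individual(id="C1", father_id="P1", mother_id="S1", sex="male"),
        Individual(id="C2", father_id="S2", mother_id="P2", sex="female"),
        Individual(id="X", father_id="C1", mother_id="C2"),
    ]
    return Pedigree("CONSANG", mem)


def random_pedigree(n_members: int, seed: int) -> Pedigree:
    """Random multi-generation zero-loop pedigree of exactly n_members."""
    rng = np.random.default_rng(seed)
    mem = [Individual(id="A", sex="male"), Individual(id="B", sex="female")]
    couples = [("A", "B")]
    i = 2
    while len(mem) < n_members:
        fa, mo = couples[rng.integers(len(couples))]
        c = Individual(
            id=f"I{i}", father_id=fa, mother_id=mo,
            sex="male" if rng.random() < 0.5 else "female",
        )
        mem.append(c)
        i += 1
        if len(mem) < n_members and rng.random() < 0.5:
            sp = Individual(
                id=f"I{i}", sex="female" if c.sex == "male" else "male",
                is_marry_in=True,
            )
            mem.append(sp)
            i += 1
            couples.append((c.id, sp.id) if c.sex == "male" else (sp.id, c.id))
    return Pedigree(f"R{seed}", mem)


def branching_pedigree(n_branches: int = 4, kids_per: int = 4) -> Pedigree:
    """Founder couple, n_branches children with marry-in spouses, grandchildren."""
    mem = [Individual(id="F0", sex="male"), Individual(id="M0", sex="female")]
    for b in range(n_branches):
        child_sex = "male" if b % 2 == 0 else "female"
        mem.append(Individual(id=f"B{b}", father_id="F0", mother_id="M0", sex=child_sex))
        mem.append(Individual(
            id=f"S{b}", sex="female" if child_sex == "male" else "male", is_marry_in=True,
        ))
        for k in range(kids_per):
            fa, mo = (f"B{b}", f"S{b}") if child_sex == "male" else (f"S{b}", f"B{b}")
            mem.append(Individual(
                id=f"K{b}_{k}", father_id=fa, mother_id=mo,
                sex="male" if k % 2 == 0 else "female",
            ))
    return Pedigree("BRANCH", mem)
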