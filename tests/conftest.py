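"""Shared pedigree fixtures and small synthetic-pedigree builders."""

from __future__ import annotations

import numpy as np
import pytest

from founderseq.pedigree import IndividualRecord, Pedigree


def ind(iid, father=None, mother=None, sex="unknown", affection="unknown"):
    return IndividualRecord(
        id=iid, father_id=father, mother_id=mother, sex=sex, affection=affection
    )


@pytest.fixture
def trio():
    return Pedigree(
        [
            ind("dad", sex="male"),
            ind("mum", sex="female"),
            ind("kid", "dad", "mum"),
        ]
    )


@pytest.fixture
def nuclear_family():
    return Pedigree(
        [
            ind("dad", sex="male"),
            ind("mum", sex="female"),
            ind("c1", "dad", "mum", sex="male"),
            ind("c2", "dad", "mum", sex="female"),
            ind("c3", "dad", "mum", sex="male"),
        ]
    )


@pytest.fixture
def cousin_pedigree():
    """Two sib parents' children marry out; their children are first cousins;
    a final child of first-cousin parents is inbred with h = 1/16."""
    return Pedigree(
        [
            ind("gf", sex="male"),
            ind("gm", sex="female"),
            ind("s1", "gf", "gm", sex="male"),
            ind("s2", "gf", "gm", sex="female"),
            ind("w1", sex="female"),
            ind("h2", sex="male"),
            ind("cousin_a", "s1", "w1", sex="male"),
            ind("cousin_b", "h2", "s2", sex="female"),
            ind("inbred_child", "cousin_a", "cousin_b"),
        ]
    )


def random_pedigree(rng: np.random.Generator, n_founder_couples=3, generations=3,
                    offspring_mean=2.0, tag="P") -> Pedigree:
    """Small random pedigree for property tests (married-in spouses, Poisson kids)."""
    counter = 0
    individuals = []

    def add(sex, father=None, mother=None):
        nonlocal counter
        counter += 1
        iid = f"{tag}{counter:03d}"
        individuals.append(
            IndividualRecord(id=iid, father_id=father, mother_id=mother, sex=sex)
        )
        return iid

    couples = [(add("male"), add("female")) for _ in range(n_founder_couples)]
    for gen in range(1, generations):
        children = []
        for f, m in couples:
            for _ in range(max(1, rng.poisson(offspring_mean))):
                sex = "male" if rng.random() < 0.5 else "female"
                children.append((add(sex, f, m), sex))
        if gen == generations - 1:
            break
        couples = []
        for iid, sex in children:
            spouse = add("female" if sex == "male" else "male")
            couples.append((iid, spouse) if sex == "male" else (spouse, iid))
    return Pedigree(individuals, family_id=tag)


@pytest.fixture
def five_generation_pedigree():
    """Deterministic 40-individual, 5-generation pedigree for round-trip tests."""
    rng = np.random.default_rng(2024)
    for _ in range(50):
        ped = random_pedigree(rng, n_founder_couples=2, generations=5,
                              offspring_mean=1.3, tag="G")
        if len(ped) >= 40 and ped.n_generations() == 5:
            return Pedigree(ped.individuals[:], family_id="G")
    raise RuntimeError("could not build the fixture pedigree")
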