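"""Shared fixtures: small pedigrees and a cached synthetic herd."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from sgekit.model import GroupedPhenotypes
from sgekit.relatedness import Pedigree
from sgekit.simulate import SimulationScenario, simulate_dataset


@pytest.fixture
def trio():
    return Pedigree.from_records(
        [("s", None, None), ("d", None, None), ("x", "s", "d")]
    )


@pytest.fixture
def fullsib_mating():
    """Founder pair, two full-sib offspring, and their inbred child."""
    return Pedigree.from_records([
        ("s", None, None), ("d", None, None),
        ("a", "s", "d"), ("b", "s", "d"), ("i", "a", "b"),
    ])


def random_pedigree(n: int, seed: int, p_parent: float = 0.75) -> Pedigree:
    """Ordered random pedigree: later animals may take earlier parents."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        sire = dam = None
        if i >= 2 and rng.random() < p_parent:
            sire = f"a{rng.integers(i)}"
            if rng.random() < 0.9:
                dam = f"a{rng.integers(i)}"
                if dam == sire:
                    dam = None
        rows.append((f"a{i}", sire, dam))
    return Pedigree.from_records(rows, reorder=False)


def exact_kinship(ped: Pedigree):
    """Recursive coancestry oracle in exact rational arithmetic.

    f(i,i) = (1 + f(sire, dam))/2; f(i,j) for a younger i is the mean of
    its parents' coancestries with j (unknown parents contribute 0).
    The numerator relationship is A_ij = 2 f(i,j).
    """
    n = ped.n
    cache: dict[tuple[int, int], Fraction] = {}

    def f(i: int, j: int) -> Fraction:
        if i < 0 or j < 0:
            return Fraction(0)
        if i < j:
            i, j = j, i
        if (i, j) in cache:
            return cache[i, j]
        if i == j:
            val = Fraction(1, 2) * (1 + f(ped.sire[i], ped.dam[i]))
        else:
            val = Fraction(1, 2) * (f(ped.sire[i], j) + f(ped.dam[i], j))
        cache[i, j] = val
        return val

    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = float(2 * f(i, j))
    return A


@pytest.fixture(scope="session")
def small_herd():
    """One cached 300-animal herd with genotypes for cross-module tests."""
    scen = SimulationScenario(n_animals=300, n_markers=700, n_chromosomes=3,
                              seed=77)
    return simulate_dataset(scen, with_genotypes=True)


def toy_phenotypes(n_groups: int = 2, group_size: int = 3, seed: int = 0):
    """Minimal hand-sized grouped dataset with a matching pedigree.

    All groups share one size so the size-class and year-month dummies are
    empty and X is just intercept + sex + age: convenient for dense-oracle
    comparisons.
    """
    rng = np.random.default_rng(seed)
    n = n_groups * group_size
    rows = []
    recs = []
    for i in range(n):
        rows.append((f"p{i}", None, None))
    for i in range(n):
        a = f"x{i}"
        sire, dam = f"p{2*(i % (n//2))}", f"p{2*(i % (n//2))+1}"
        rows.append((a, sire, dam))
        recs.append({
            "animal": a, "y": float(rng.normal(100, 10)),
            "yearmonth": "ym0", "sex": "M",
            "pen": f"pen{i % 2}", "group": f"g{i // group_size}",
            "litter": f"lit{i % (n//2)}", "dam": dam,
            "age": float(rng.uniform(140, 170)),
        })
    ped = Pedigree.from_records(rows, reorder=False)
    return ped, GroupedPhenotypes(pd.DataFrame(recs))
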