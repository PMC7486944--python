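"""Synthetic pedigrees, groups, genotypes and phenotypes with known truth.

The generator emulates the structure of a grower-pig performance test:
discrete-generation pedigrees with litters of ~4.1 piglets and dams that
produce several litters, same-sex housing groups of 4-13 animals averaging
6.8, pens that house many successive groups, a fixed-effect layer (birth
year-month, sex, group-size class, age-at-target-weight covariate) and
trait records assembled exactly by the extended animal model

    y = X b + Z_D a_D + Z_S a_S + W c + V g + T pe + U l + Q k + e

with (a_D, a_S) ~ MVN(0, C (x) A) simulated down the pedigree, the
litter/early-life pair (l, k) from its 2x2 covariance, and the default
(co)variance magnitudes matching the growth-trait analysis this package
implements (direct 2235, social 16, their covariance 43, pen 43, group 227,
maternal permanent 48, litter 218, early-life 17, their covariance 36,
residual 3299 (g/day)^2).  Genotypes are gene-dropped through the pedigree
(Hardy-Weinberg founders, optional per-chromosome linkage) and QTL can be
planted by giving single markers a fraction of the direct genetic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GroupedPhenotypes, VarianceComponents, dilution
from .relatedness import GenotypeMatrix, Pedigree, build_A

__all__ = [
    "SimulationScenario",
    "SimulatedTruth",
    "SimulatedDataset",
    "simulate_pedigree",
    "simulate_groups",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
]

REFERENCE_COMPONENTS = VarianceComponents(
    var_aD=2235.0, var_aS=16.0, cov_aDaS=43.0, var_c=43.0, var_g=227.0,
    var_pe=48.0, var_l=218.0, var_k=17.0, cov_lk=36.0, var_e=3299.0,
)


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic dataset.

    Defaults mirror the population the model targets: groups of 4-13
    same-sex animals with mean size 6.8 (SD ~1.9), litters averaging 4.12
    piglets with dams producing ~3 litters each, pens reused by ~32 groups,
    and the default (co)variance components above.
    """

    n_animals: int = 1500
    n_founders: int = 260
    n_generations: int = 3
    mean_family_size: float = 4.12
    litters_per_dam: float = 3.2
    litters_per_sire: float = 8.0
    group_size_min: int = 4
    group_size_max: int = 13
    group_size_mean: float = 6.8
    group_size_sd: float = 1.9
    n_pens: int | None = None
    n_yearmonth: int = 12
    n_markers: int = 1000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 10_000_000
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    linked: bool = False
    components: VarianceComponents = field(
        default_factory=lambda: REFERENCE_COMPONENTS
    )
    planted_qtl: list[tuple[int, float]] = field(default_factory=list)
    intercept: float = 804.0
    yearmonth_sd: float = 25.0
    sex_sd: float = 20.0
    size_class_sd: float = 10.0
    age_range: tuple[float, float] = (135.0, 175.0)
    age_slope: float = -2.0
    seed: int = 20191709

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least two founders")
        if self.mean_family_size < 1:
            raise ValueError("mean family size must be at least 1")
        if sum(f for _, f in self.planted_qtl) > 1:
            raise ValueError("planted QTL fractions must sum to <= 1")

    def rng(self) -> np.random.Generator:
        return np.random.Generator(np.random.PCG64(self.seed))


@dataclass
class SimulatedTruth:
    """The generative draws behind one synthetic dataset."""

    a_D: np.ndarray  # per pedigree animal
    a_S: np.ndarray
    tbv: np.ndarray
    litter_effects: pd.DataFrame  # litter, l, k
    pen_effects: dict
    group_effects: dict
    dam_effects: dict
    residuals: np.ndarray
    marker_effects: np.ndarray | None
    components: VarianceComponents
    mean_group_size: float


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    meta: pd.DataFrame
    phenotypes: GroupedPhenotypes
    genotypes: GenotypeMatrix | None
    truth: SimulatedTruth


def simulate_pedigree(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> tuple[Pedigree, pd.DataFrame]:
    """Discrete-generation pedigree with litters and repeated-dam matings.

    Returns the ordered pedigree plus a per-animal metadata frame (sex,
    generation, litter, dam).  Founders form generation 0; each later
    generation is produced by litters whose sire and dam are drawn at
    random from the previous generation, so a dam typically contributes
    several litters (distinct litter identifiers, shared dam identifier).
    """
    rng = rng or scenario.rng()
    n_sires = scenario.n_founders // 2
    n_dams = scenario.n_founders - n_sires
    ids = [f"F{i:05d}" for i in range(scenario.n_founders)]
    rows = [(a, None, None) for a in ids]
    meta = [
        {"animal": a, "sex": "M" if i < n_sires else "F", "generation": 0,
         "litter": None, "dam": None}
        for i, a in enumerate(ids)
    ]
    if scenario.n_generations == 0:
        return Pedigree.from_records(rows, reorder=False), pd.DataFrame(meta)
    per_gen = scenario.n_animals // scenario.n_generations
    males = ids[:n_sires]
    females = ids[n_sires:]
    counter = 0
    litter_counter = 0
    for gen in range(1, scenario.n_generations + 1):
        n_off = per_gen if gen < scenario.n_generations else (
            scenario.n_animals - per_gen * (scenario.n_generations - 1)
        )
        # breeding pools sized so dams average ~litters_per_dam litters
        # (and sires ~litters_per_sire), as in a nucleus herd
        n_lit = max(1, round(n_off / scenario.mean_family_size))
        dam_pool = list(rng.choice(
            females, size=min(len(females),
                              max(2, round(n_lit / scenario.litters_per_dam))),
            replace=False))
        sire_pool = list(rng.choice(
            males, size=min(len(males),
                            max(2, round(n_lit / scenario.litters_per_sire))),
            replace=False))
        new_males: list[str] = []
        new_females: list[str] = []
        made = 0
        while made < n_off:
            size = 1 + rng.poisson(scenario.mean_family_size - 1.0)
            size = int(min(size, n_off - made)) or 1
            sire = sire_pool[rng.integers(len(sire_pool))]
            dam = dam_pool[rng.integers(len(dam_pool))]
            litter = f"L{litter_counter:05d}"
            litter_counter += 1
            for _ in range(size):
                a = f"A{counter:05d}"
                counter += 1
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append((a, sire, dam))
                meta.append({"animal": a, "sex": sex, "generation": gen,
                             "litter": litter, "dam": dam})
                (new_males if sex == "M" else new_females).append(a)
                made += 1
        if new_males:
            males = new_males
        if new_females:
            females = new_females
    ped = Pedigree.from_records(rows, reorder=False)
    return ped, pd.DataFrame(meta)


def _draw_group_sizes(n: int, scenario: SimulationScenario,
                      rng: np.random.Generator) -> list[int]:
    """Sizes in [min, max] from a discretised normal, summing exactly to n."""
    lo, hi = scenario.group_size_min, scenario.group_size_max
    support = np.arange(lo, hi + 1)
    probs = np.exp(-0.5 * ((support - scenario.group_size_mean)
                           / scenario.group_size_sd) ** 2)
    probs /= probs.sum()
    sizes: list[int] = []
    left = n
    while left > 0:
        s = int(rng.choice(support, p=probs))
        if left - s < 0:
            s = left
        elif 0 < left - s < lo:
            # avoid leaving an impossible remainder
            s = left if left <= hi else left - lo
        sizes.append(s)
        left -= s
    # repair undersized tail groups by borrowing from the largest
    while sizes and sizes[-1] < 2:
        small = sizes.pop()
        sizes[int(np.argmax(sizes))] += small
    return sizes


def simulate_groups(
    meta: pd.DataFrame,
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign phenotyped animals (non-founders) to same-sex groups and pens.

    Groups are filled within (generation, sex) from a litter-ordered queue,
    so each group spans a handful of contemporaneous litters and usually
    contains littermates -- as when performance-test pens are stocked from
    the farrowing batch.  Each group is housed in a pen, with pens recycled
    across groups so one pen hosts many successive groups.
    """
    rng = rng or scenario.rng()
    meta = meta.copy()
    meta["group"] = None
    meta["pen"] = None
    phen = meta[meta["generation"] > 0]
    group_counter = 0
    assignments: dict[str, str] = {}
    for (_, _), block in phen.groupby(["generation", "sex"]):
        litters = block["litter"].unique().tolist()
        rng.shuffle(litters)
        order = {lit: j for j, lit in enumerate(litters)}
        animals = block.sort_values(
            by="litter", key=lambda s: s.map(order), kind="stable"
        )["animal"].tolist()
        for size in _draw_group_sizes(len(animals), scenario, rng):
            gid = f"G{group_counter:05d}"
            group_counter += 1
            for a in animals[:size]:
                assignments[a] = gid
            animals = animals[size:]
    n_groups = group_counter
    n_pens = scenario.n_pens or max(6, round(n_groups / 32))
    meta["group"] = meta["animal"].map(assignments)
    gnum = (
        meta.loc[meta["group"].notna(), "group"]
        .str.removeprefix("G").astype(int)
    )
    meta.loc[meta["group"].notna(), "pen"] = (
        "P" + (gnum % n_pens).astype(str).str.zfill(3)
    )
    return meta


def simulate_genotypes(
    pedigree: Pedigree,
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Gene-drop SNP genotypes for every pedigree animal.

    Founders are Hardy-Weinberg draws at per-marker frequencies sampled
    uniformly from ``allele_freq_range``; descendants inherit one allele
    per parent, independently per marker unless ``scenario.linked`` turns
    on per-chromosome recombination (Haldane map, 1 cM/Mb).
    """
    rng = rng or scenario.rng()
    m = scenario.n_markers
    n = pedigree.n
    per_chrom = np.full(scenario.n_chromosomes, m // scenario.n_chromosomes)
    per_chrom[: m % scenario.n_chromosomes] += 1
    chroms = np.repeat(np.arange(1, scenario.n_chromosomes + 1), per_chrom)
    bp = np.concatenate([
        np.sort(rng.choice(
            np.arange(1, scenario.chromosome_length_bp + 1), size=k,
            replace=False))
        for k in per_chrom
    ])
    p = rng.uniform(*scenario.allele_freq_range, size=m)
    marker_map = pd.DataFrame({
        "marker": [f"M{i:05d}" for i in range(m)],
        "chrom": chroms.astype(str),
        "bp": bp,
        "founder_freq": p,  # base-population frequency, kept for validation
    })

    hap = np.zeros((n, 2, m), dtype=np.int8)
    if scenario.linked:
        dist_mb = np.diff(bp) / 1e6
        new_chrom = np.diff(chroms) != 0
        rec = 0.5 * (1.0 - np.exp(-0.02 * dist_mb))
        rec[new_chrom] = 0.5
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        for which, parent in ((0, s), (1, d)):
            if parent < 0:
                hap[i, which] = rng.random(m) < p
            else:
                if scenario.linked:
                    switch = rng.random(m - 1) < rec
                    strand = (np.concatenate([[0], np.cumsum(switch)])
                              + rng.integers(2)) % 2
                else:
                    strand = rng.integers(0, 2, size=m)
                hap[i, which] = hap[parent, strand, np.arange(m)]
    dosages = hap.sum(axis=1).astype(float)
    return GenotypeMatrix(dosages=dosages, animal_ids=list(pedigree.ids),
                          marker_map=marker_map)


def _chol_psd(C: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix; tolerates zero variances."""
    w, V = np.linalg.eigh(C)
    if np.min(w) < -1e-8 * max(np.max(w), 1.0):
        raise ValueError("genetic covariance matrix is not positive "
                         "semidefinite")
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_phenotypes(
    pedigree: Pedigree,
    meta: pd.DataFrame,
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    genotypes: GenotypeMatrix | None = None,
) -> tuple[GroupedPhenotypes, SimulatedTruth]:
    """Assemble trait records by the model equation, keeping all the truth.

    (a_D, a_S) are simulated down the pedigree so their joint distribution
    is MVN(0, C (x) A); when QTL are planted, the flagged markers carry the
    requested fractions of the direct genetic variance and the polygenic
    remainder is scaled down accordingly.  Social and early-life terms are
    delivered individually through the group structure with the same
    dilution weights the design matrices use.
    """
    rng = rng or scenario.rng()
    comp = scenario.components
    n = pedigree.n

    qtl_frac = sum(f for _, f in scenario.planted_qtl)
    marker_effects = None
    genic_D = np.zeros(n)
    if scenario.planted_qtl:
        if genotypes is None:
            raise ValueError("planted QTL require simulated genotypes")
        Z = genotypes.centred()
        marker_effects = np.zeros(genotypes.n_markers)
        for midx, frac in scenario.planted_qtl:
            zvar = float(np.var(Z[:, midx], ddof=1))
            if zvar == 0:
                raise ValueError(f"planted QTL marker {midx} is monomorphic")
            effect = np.sqrt(frac * comp.var_aD / zvar)
            marker_effects[midx] = effect * (1 if rng.random() < 0.5 else -1)
        genic_D = Z @ marker_effects

    C_poly = np.array([
        [(1.0 - qtl_frac) * comp.var_aD, comp.cov_aDaS],
        [comp.cov_aDaS, comp.var_aS],
    ])
    L = _chol_psd(C_poly)
    F = np.diag(build_A(pedigree)) - 1.0
    a = np.zeros((n, 2))
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s >= 0 and d >= 0:
            mid = 0.5 * (a[s] + a[d])
            mvar = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            par = s if s >= 0 else d
            mid = 0.5 * a[par]
            mvar = 0.75 - 0.25 * F[par]
        else:
            mid = np.zeros(2)
            mvar = 1.0
        a[i] = mid + np.sqrt(mvar) * (L @ rng.standard_normal(2))
    a_D = a[:, 0] + genic_D
    a_S = a[:, 1]

    phen = meta[meta["group"].notna()].copy().reset_index(drop=True)
    if phen.empty:
        raise ValueError("no grouped animals: run simulate_groups first")
    sizes = phen.groupby("group")["animal"].transform("size")
    phen["group_size"] = sizes
    nbar = float(phen.groupby("group")["animal"].size().mean())

    litters = list(pd.unique(phen["litter"]))
    Sig = np.array([[comp.var_l, comp.cov_lk], [comp.cov_lk, comp.var_k]])
    lk = rng.standard_normal((len(litters), 2)) @ _chol_psd(Sig).T
    lk_map = {lit: lk[j] for j, lit in enumerate(litters)}
    pens = list(pd.unique(phen["pen"]))
    groups = list(pd.unique(phen["group"]))
    dams = list(pd.unique(phen["dam"]))
    c_map = {pid: rng.normal(0, np.sqrt(comp.var_c)) for pid in pens}
    g_map = {gid: rng.normal(0, np.sqrt(comp.var_g)) for gid in groups}
    pe_map = {did: rng.normal(0, np.sqrt(comp.var_pe)) for did in dams}

    ym_levels = [f"YM{j:03d}" for j in range(scenario.n_yearmonth)]
    ym_eff = {lev: rng.normal(0, scenario.yearmonth_sd) for lev in ym_levels}
    litter_ym = {lit: ym_levels[j % len(ym_levels)]
                 for j, lit in enumerate(litters)}
    sex_eff = {"M": rng.normal(0, scenario.sex_sd),
               "F": rng.normal(0, scenario.sex_sd)}
    size_eff = {int(sz): rng.normal(0, scenario.size_class_sd)
                for sz in sorted(phen["group_size"].unique())}

    phen["yearmonth"] = phen["litter"].map(litter_ym)
    phen["age"] = rng.uniform(*scenario.age_range, size=len(phen))

    ped_idx = pedigree.index_of(phen["animal"])
    e = rng.normal(0, np.sqrt(comp.var_e), size=len(phen))
    members = phen.groupby("group").indices
    social = np.zeros(len(phen))
    early = np.zeros(len(phen))
    litter_arr = phen["litter"].to_numpy()
    size_arr = phen["group_size"].to_numpy()
    for _, idx in members.items():
        for i in idx:
            d_i = dilution(int(size_arr[i]), nbar)
            for j in idx:
                if j == i:
                    continue
                social[i] += d_i * a_S[ped_idx[j]]
                early[i] += d_i * lk_map[litter_arr[j]][1]

    y = (
        scenario.intercept
        + phen["yearmonth"].map(ym_eff).to_numpy()
        + phen["sex"].map(sex_eff).to_numpy()
        + phen["group_size"].map(size_eff).to_numpy()
        + scenario.age_slope * phen["age"].to_numpy()
        + a_D[ped_idx]
        + social
        + phen["pen"].map(c_map).to_numpy()
        + phen["group"].map(g_map).to_numpy()
        + phen["dam"].map(pe_map).to_numpy()
        + np.array([lk_map[lit][0] for lit in litter_arr])
        + early
        + e
    )
    phen["y"] = y
    data = GroupedPhenotypes(phen[["animal", "y", "yearmonth", "sex", "pen",
                                   "group", "litter", "dam", "age"]])
    truth = SimulatedTruth(
        a_D=a_D, a_S=a_S,
        tbv=a_D + (nbar - 1.0) * a_S,
        litter_effects=pd.DataFrame(
            {"litter": litters, "l": lk[:, 0], "k": lk[:, 1]}),
        pen_effects=c_map, group_effects=g_map, dam_effects=pe_map,
        residuals=e, marker_effects=marker_effects, components=comp,
        mean_group_size=nbar,
    )
    return data, truth


def simulate_dataset(
    scenario: SimulationScenario, with_genotypes: bool = False
) -> SimulatedDataset:
    """One call: pedigree -> groups -> (genotypes) -> phenotypes."""
    rng = scenario.rng()
    ped, meta = simulate_pedigree(scenario, rng)
    meta = simulate_groups(meta, scenario, rng)
    genotypes = None
    if with_genotypes or scenario.planted_qtl:
        genotypes = simulate_genotypes(ped, scenario, rng)
    data, truth = simulate_phenotypes(ped, meta, scenario, rng,
                                      genotypes=genotypes)
    return SimulatedDataset(pedigree=ped, meta=meta, phenotypes=data,
                            genotypes=genotypes, truth=truth)
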