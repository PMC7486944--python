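"""Extended animal model with direct and social genetic effects.

The trait model is

    y = X b + Z_D a_D + Z_S a_S + W c + V g + T pe + U l + Q k + e

where ``a_D`` and ``a_S`` are the direct and social (indirect) genetic
effect vectors with joint prior MVN(0, C (x) K) for a 2x2 genetic
(co)variance matrix C and relationship kernel K (pedigree A or single-step
H), ``c``/``g``/``pe`` are iid pen, group and maternal permanent-environment
effects, and ``(l, k)`` are the birth-litter and early-life (group mates'
birth litter) effects with a 2x2 (co)variance across shared litter levels.
Social and early-life incidences carry the dilution weight
``d_i = (mean group size - 1) / (group size_i - 1)`` so that every row of
Z_S sums to ``n_bar - 1`` regardless of group size.

(Co)variance components are estimated by single-site Gibbs sampling
(Gaussian full conditionals for every location effect; inverse-Wishart /
scaled-inverse-chi-square full conditionals for the covariance blocks),
and genetic parameters -- total breeding value variance, phenotypic
variance, classical and total heritability -- follow from the component
draws and the mean group size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ._gibbs import gibbs_sweep

__all__ = [
    "VarianceComponents",
    "GeneticParameters",
    "GroupedPhenotypes",
    "DesignMatrices",
    "ChainConfig",
    "PosteriorChain",
    "MixedModelSolution",
    "dilution",
    "build_design",
    "solve_mme",
    "gibbs_fit",
    "genetic_parameters",
    "total_breeding_values",
    "summarize_chain",
]

COMPONENT_NAMES = (
    "var_aD", "var_aS", "cov_aDaS", "var_c", "var_g",
    "var_pe", "var_l", "var_k", "cov_lk", "var_e",
)


@dataclass(frozen=True)
class VarianceComponents:
    """The model's eight variances and two covariances, in (g/day)^2."""

    var_aD: float
    var_aS: float
    cov_aDaS: float
    var_c: float
    var_g: float
    var_pe: float
    var_l: float
    var_k: float
    cov_lk: float
    var_e: float

    def genetic_cov(self) -> np.ndarray:
        """2x2 direct/social genetic (co)variance matrix C."""
        return np.array([[self.var_aD, self.cov_aDaS],
                         [self.cov_aDaS, self.var_aS]])

    def litter_cov(self) -> np.ndarray:
        """2x2 birth-litter / early-life (co)variance matrix."""
        return np.array([[self.var_l, self.cov_lk],
                         [self.cov_lk, self.var_k]])

    def validate(self) -> None:
        for name in ("var_aD", "var_aS", "var_c", "var_g", "var_pe",
                     "var_l", "var_k", "var_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"variance {name} must be positive")
        for block, lab in ((self.genetic_cov(), "genetic"),
                           (self.litter_cov(), "litter/early-life")):
            if np.linalg.det(block) <= 0:
                raise ValueError(f"{lab} covariance block not positive definite")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in COMPONENT_NAMES])

    @classmethod
    def from_array(cls, a) -> "VarianceComponents":
        return cls(**dict(zip(COMPONENT_NAMES, map(float, a))))


@dataclass(frozen=True)
class GeneticParameters:
    """Derived genetic parameters for a socially affected trait."""

    var_TBV: float
    var_P: float
    h2: float
    T2: float
    r_aDS: float
    r_lk: float


def dilution(group_size: int, mean_group_size: float) -> float:
    """Dilution covariate (mean group size - 1) / (group size - 1).

    Scales each group mate's social contribution so that the summed social
    load is the same for every animal whatever its group size.
    """
    if group_size < 2:
        raise ValueError("group size must be >= 2 for a social model")
    return (mean_group_size - 1.0) / (group_size - 1.0)


class GroupedPhenotypes:
    """Trait records with the grouping structure the social model needs.

    Wraps a DataFrame with columns ``animal, y, yearmonth, sex, pen, group,
    litter, dam, age``; a ``size_class`` fixed-effect level is derived from
    the realised group size.  Every animal belongs to exactly one group and
    all groups have at least two members.
    """

    REQUIRED = ("animal", "y", "yearmonth", "sex", "pen", "group",
                "litter", "dam", "age")

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if df["animal"].duplicated().any():
            raise ValueError("each animal must have exactly one record")
        n_miss = df["age"].isna().sum()
        if n_miss:
            import logging

            logging.getLogger(__name__).warning(
                "dropping %d records with missing age covariate", n_miss
            )
            df = df[df["age"].notna()]
        sizes = df.groupby("group")["animal"].transform("size")
        if (sizes < 2).any():
            bad = df.loc[sizes < 2, "group"].iloc[0]
            raise ValueError(f"singleton group {bad!r}: social model undefined")
        df = df.reset_index(drop=True)
        df["group_size"] = sizes.to_numpy()
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def group_sizes(self) -> pd.Series:
        """Realised size of each group (one entry per group)."""
        return self.records.groupby("group")["animal"].size()

    @property
    def mean_group_size(self) -> float:
        """n_bar: unweighted mean of the realised group sizes."""
        return float(self.group_sizes.mean())


@dataclass
class DesignMatrices:
    """Incidence matrices of the extended animal model (CSR, shared row order).

    ``X`` carries the intercept, treatment-coded fixed-effect dummies and the
    age covariate; ``Z_D``/``Z_S`` index the pedigree (Z_S dilution-weighted,
    zero diagonal); ``W``(pen), ``V``(group), ``T``(dam permanent
    environment), ``U``(own birth litter) and ``Q``(group mates' birth
    litters, dilution-weighted) index their level lists.
    """

    X: np.ndarray
    Z_D: sp.csr_matrix
    Z_S: sp.csr_matrix
    W: sp.csr_matrix
    V: sp.csr_matrix
    T: sp.csr_matrix
    U: sp.csr_matrix
    Q: sp.csr_matrix
    y: np.ndarray
    fixed_names: list[str]
    pen_levels: list
    group_levels: list
    dam_levels: list
    litter_levels: list
    mean_group_size: float
    n_pedigree: int
    animal_pedigree_index: np.ndarray

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    def stacked(self) -> sp.csr_matrix:
        """Full design [X | Z_D | Z_S | W | V | T | U | Q] in equation order."""
        return sp.hstack(
            [sp.csr_matrix(self.X), self.Z_D, self.Z_S, self.W, self.V,
             self.T, self.U, self.Q], format="csr",
        )

    def equation_layout(self) -> dict[str, tuple[int, int]]:
        """(offset, size) of each effect block in the stacked ordering."""
        sizes = [("b", self.X.shape[1]), ("a_D", self.n_pedigree),
                 ("a_S", self.n_pedigree), ("c", len(self.pen_levels)),
                 ("g", len(self.group_levels)), ("pe", len(self.dam_levels)),
                 ("l", len(self.litter_levels)), ("k", len(self.litter_levels))]
        out, off = {}, 0
        for name, size in sizes:
            out[name] = (off, size)
            off += size
        return out


def _dummies(values: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    """Treatment coding: one column per level except the first."""
    levels = sorted(pd.unique(values), key=str)
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((values == lev).to_numpy(dtype=float))
        names.append(f"{prefix}[{lev}]")
    if not cols:
        return np.empty((len(values), 0)), []
    return np.column_stack(cols), names


def _indicator(values: pd.Series) -> tuple[sp.csr_matrix, list]:
    levels = list(pd.unique(values))
    lookup = {lev: j for j, lev in enumerate(levels)}
    n = len(values)
    col = np.array([lookup[v] for v in values])
    mat = sp.csr_matrix((np.ones(n), (np.arange(n), col)),
                        shape=(n, len(levels)))
    return mat, levels


def build_design(data: GroupedPhenotypes, pedigree) -> DesignMatrices:
    """Assemble all incidence matrices for the extended animal model.

    The social incidence Z_S places the dilution weight ``d_i`` of record
    ``i`` on each of its group mates (never on itself), so its row sums are
    exactly ``n_bar - 1``; Q does the same on the mates' birth litters,
    accumulating weights when mates share a litter.
    """
    df = data.records
    nbar = data.mean_group_size
    n = len(df)
    ped_idx = pedigree.index_of(df["animal"])
    if df["litter"].isna().any() or df["dam"].isna().any():
        raise ValueError("every record needs a birth litter and a dam")

    ones = np.ones((n, 1))
    ym, ym_names = _dummies(df["yearmonth"], "yearmonth")
    sx, sx_names = _dummies(df["sex"], "sex")
    sc, sc_names = _dummies(df["group_size"].astype(int), "size")
    age = df["age"].to_numpy(dtype=float)
    age = (age - age.mean())[:, None]  # centred: keeps the MME well-conditioned
    X = np.hstack([ones, ym, sx, sc, age])
    fixed_names = ["intercept", *ym_names, *sx_names, *sc_names, "age_centred"]

    Z_D = sp.csr_matrix((np.ones(n), (np.arange(n), ped_idx)),
                        shape=(n, pedigree.n))
    W, pen_levels = _indicator(df["pen"])
    V, group_levels = _indicator(df["group"])
    T, dam_levels = _indicator(df["dam"])
    U, litter_levels = _indicator(df["litter"])
    lit_lookup = {lev: j for j, lev in enumerate(litter_levels)}

    rows_s, cols_s, vals_s = [], [], []
    rows_q, cols_q, vals_q = [], [], []
    members = df.groupby("group").indices
    gsize = df["group_size"].to_numpy()
    litter_col = df["litter"].to_numpy()
    for _, idx in members.items():
        for i in idx:
            d_i = dilution(int(gsize[i]), nbar)
            for j in idx:
                if j == i:
                    continue
                rows_s.append(i)
                cols_s.append(ped_idx[j])
                vals_s.append(d_i)
                rows_q.append(i)
                cols_q.append(lit_lookup[litter_col[j]])
                vals_q.append(d_i)
    Z_S = sp.csr_matrix((vals_s, (rows_s, cols_s)), shape=(n, pedigree.n))
    Q = sp.csr_matrix((vals_q, (rows_q, cols_q)), shape=(n, len(litter_levels)))
    Q.sum_duplicates()

    return DesignMatrices(
        X=X, Z_D=Z_D, Z_S=Z_S, W=W, V=V, T=T, U=U, Q=Q,
        y=df["y"].to_numpy(dtype=float), fixed_names=fixed_names,
        pen_levels=pen_levels, group_levels=group_levels,
        dam_levels=dam_levels, litter_levels=litter_levels,
        mean_group_size=nbar, n_pedigree=pedigree.n,
        animal_pedigree_index=ped_idx,
    )


def _penalty(design: DesignMatrices, kernel_inv, components: VarianceComponents):
    """Random-effect precision penalty of the mixed-model equations."""
    lay = design.equation_layout()
    n_eq = sum(size for _, size in lay.values())
    K = sp.csr_matrix(kernel_inv)
    Cinv = np.linalg.inv(components.genetic_cov())
    Linv = np.linalg.inv(components.litter_cov())
    blocks = sp.lil_matrix((n_eq, n_eq))

    def put(a, b, mat):
        oa, ob = lay[a][0], lay[b][0]
        blocks[oa:oa + mat.shape[0], ob:ob + mat.shape[1]] = mat

    put("a_D", "a_D", K * Cinv[0, 0])
    put("a_D", "a_S", K * Cinv[0, 1])
    put("a_S", "a_D", K * Cinv[1, 0])
    put("a_S", "a_S", K * Cinv[1, 1])
    nl = lay["l"][1]
    eye_l = sp.identity(nl)
    put("l", "l", eye_l * Linv[0, 0])
    put("l", "k", eye_l * Linv[0, 1])
    put("k", "l", eye_l * Linv[1, 0])
    put("k", "k", eye_l * Linv[1, 1])
    for name, var in (("c", components.var_c), ("g", components.var_g),
                      ("pe", components.var_pe)):
        off, size = lay[name]
        blocks[off:off + size, off:off + size] = sp.identity(size) / var
    return blocks.tocsr()


@dataclass
class MixedModelSolution:
    """BLUE fixed effects and BLUP random-effect solutions."""

    b: np.ndarray
    a_D: np.ndarray
    a_S: np.ndarray
    c: np.ndarray
    g: np.ndarray
    pe: np.ndarray
    l: np.ndarray
    k: np.ndarray
    theta: np.ndarray
    layout: dict[str, tuple[int, int]]


def solve_mme(
    design: DesignMatrices,
    kernel_inv,
    components: VarianceComponents,
) -> MixedModelSolution:
    """Solve Henderson's mixed-model equations for the full model.

    The genetic kernel inverse (``H^-1`` for single-step, ``A^-1`` for
    pedigree-only) enters the (a_D, a_S) penalty as ``C^-1 (x) K^-1``;
    fixed effects are treatment-coded and therefore full rank by
    construction.
    """
    components.validate()
    Wall = design.stacked()
    y = design.y
    lhs = (Wall.T @ Wall) / components.var_e + _penalty(design, kernel_inv,
                                                        components)
    rhs = Wall.T @ y / components.var_e
    theta = splu(lhs.tocsc()).solve(rhs)
    lay = design.equation_layout()
    parts = {name: theta[off:off + size] for name, (off, size) in lay.items()}
    return MixedModelSolution(theta=theta, layout=lay, **parts)


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain settings.

    Defaults are a desk-scale chain (55,000 rounds, 5,000 burn-in, thin 5);
    ``ChainConfig.reference()`` gives the full-scale 550,000 / 50,000 / 50
    schedule that retains 10,000 samples.
    """

    rounds: int = 55_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 20191709

    def __post_init__(self) -> None:
        if self.burn_in >= self.rounds:
            raise ValueError("burn-in must be smaller than the round count")
        if (self.rounds - self.burn_in) % self.thin:
            raise ValueError("(rounds - burn_in) must be divisible by thin")

    @property
    def n_retained(self) -> int:
        return (self.rounds - self.burn_in) // self.thin

    @classmethod
    def reference(cls, seed: int = 20191709) -> "ChainConfig":
        return cls(rounds=550_000, burn_in=50_000, thin=50, seed=seed)


@dataclass(frozen=True)
class GibbsPriors:
    """Vague conjugate priors for the (co)variance blocks.

    Defaults are flat (bounded-improper uniform) on every block, matching
    the common default of animal-breeding Gibbs software: scalar variances
    use the nu = -2, scale 0 limit of the scaled inverse chi-square, and
    the 2x2 blocks use ``wishart_df = -(p + 1) = -3`` with zero scale, so
    the full conditional is IW(q - 3, S).  A proper inverse-Wishart prior
    is available by setting positive ``wishart_df``/``wishart_scale``, but
    note that low-df inverse Wisharts with small scale put ~x^-2 mass near
    zero and will pin weakly identified components (e.g. a small social
    variance) to the origin.
    """

    wishart_df: float = -3.0
    wishart_scale: float = 0.0


@dataclass
class PosteriorChain:
    """Retained (co)variance-component draws from one Gibbs chain."""

    draws: pd.DataFrame
    config: ChainConfig
    mean_group_size: float
    effects_mean: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.draws)

    def posterior_mean(self) -> VarianceComponents:
        return VarianceComponents.from_array(
            self.draws[list(COMPONENT_NAMES)].mean().to_numpy()
        )


def _invwishart_rvs(df: float, scale: np.ndarray, rng) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition (2x2 here)."""
    p = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = math.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    W = L @ A
    X = W @ W.T  # ~ Wishart(df, scale^-1)
    return np.linalg.inv(X)


def gibbs_fit(
    design: DesignMatrices,
    kernel_inv,
    config: ChainConfig | None = None,
    start: VarianceComponents | None = None,
    priors: GibbsPriors | None = None,
    keep_effects: bool = True,
) -> PosteriorChain:
    """Estimate (co)variance components by single-site Gibbs sampling.

    Every location effect is drawn from its scalar Gaussian full
    conditional (one sweep of the mixed-model equations per round); the
    residual and the scalar random-effect variances from scaled inverse
    chi-square full conditionals; the 2x2 genetic and litter/early-life
    blocks from inverse-Wishart full conditionals.  The chain is fully
    reproducible from ``config.seed``.
    """
    config = config or ChainConfig()
    priors = priors or GibbsPriors()
    rng = np.random.Generator(np.random.PCG64(config.seed))

    Wall = design.stacked()
    y = design.y
    n_rec = len(y)
    lay = design.equation_layout()
    n_eq = Wall.shape[1]
    WtW = (Wall.T @ Wall).tocsr()
    WtW.sort_indices()
    rhs = Wall.T @ y
    K = sp.csr_matrix(kernel_inv)
    K.sort_indices()

    if start is None:
        v = float(np.var(y))
        start = VarianceComponents(
            var_aD=v / 4, var_aS=v / 100, cov_aDaS=0.0, var_c=v / 20,
            var_g=v / 20, var_pe=v / 20, var_l=v / 20, var_k=v / 100,
            cov_lk=0.0, var_e=v / 2,
        )
    comp = start
    theta = np.zeros(n_eq)

    off_aD, nped = lay["a_D"]
    off_c, nc = lay["c"]
    off_g, ng = lay["g"]
    off_pe, npe = lay["pe"]
    off_l, nl = lay["l"]

    sl = {name: slice(off, off + size) for name, (off, size) in lay.items()}
    S0 = priors.wishart_scale * np.eye(2)
    nu0 = priors.wishart_df

    kept = np.empty((config.n_retained, len(COMPONENT_NAMES)))
    eff_sum = np.zeros(n_eq) if keep_effects else None
    n_kept = 0

    for it in range(config.rounds):
        Cinv = np.linalg.inv(comp.genetic_cov())
        Linv = np.linalg.inv(comp.litter_cov())
        z = rng.standard_normal(n_eq)
        gibbs_sweep(
            WtW.data, WtW.indices, WtW.indptr, rhs, theta,
            1.0 / comp.var_e, K.data, K.indices, K.indptr,
            nped, off_aD, off_c, nc, off_g, ng, off_pe, npe, off_l, nl,
            Cinv[0, 0], Cinv[0, 1], Cinv[1, 1],
            Linv[0, 0], Linv[0, 1], Linv[1, 1],
            1.0 / comp.var_c, 1.0 / comp.var_g, 1.0 / comp.var_pe, z,
        )
        if not np.isfinite(theta).all():
            raise FloatingPointError(
                f"Gibbs chain diverged at round {it}: non-finite effect draw"
            )

        aD = theta[sl["a_D"]]
        aS = theta[sl["a_S"]]
        KaD = K @ aD
        KaS = K @ aS
        Sgen = np.array([[aD @ KaD, aD @ KaS], [KaD @ aS, aS @ KaS]])
        C_new = _invwishart_rvs(nu0 + nped, Sgen + S0, rng)

        lv = theta[sl["l"]]
        kv = theta[sl["k"]]
        Slit = np.array([[lv @ lv, lv @ kv], [lv @ kv, kv @ kv]])
        L_new = _invwishart_rvs(nu0 + nl, Slit + S0, rng)

        cv = theta[sl["c"]]
        gv = theta[sl["g"]]
        pev = theta[sl["pe"]]
        var_c = (cv @ cv) / rng.chisquare(max(nc - 2, 1))
        var_g = (gv @ gv) / rng.chisquare(max(ng - 2, 1))
        var_pe = (pev @ pev) / rng.chisquare(max(npe - 2, 1))

        e = y - Wall @ theta
        var_e = (e @ e) / rng.chisquare(n_rec - 2)

        comp = VarianceComponents(
            var_aD=C_new[0, 0], var_aS=C_new[1, 1], cov_aDaS=C_new[0, 1],
            var_c=var_c, var_g=var_g, var_pe=var_pe,
            var_l=L_new[0, 0], var_k=L_new[1, 1], cov_lk=L_new[0, 1],
            var_e=var_e,
        )
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept[n_kept] = comp.as_array()
            n_kept += 1
            if keep_effects:
                eff_sum += theta

    draws = pd.DataFrame(kept[:n_kept], columns=list(COMPONENT_NAMES))
    effects_mean = {}
    if keep_effects and n_kept:
        mean_theta = eff_sum / n_kept
        effects_mean = {name: mean_theta[s] for name, s in sl.items()}
    return PosteriorChain(draws=draws, config=config,
                          mean_group_size=design.mean_group_size,
                          effects_mean=effects_mean)


def genetic_parameters(
    components: VarianceComponents, mean_group_size: float
) -> GeneticParameters:
    """Derived genetic parameters from (co)variance components.

    With n the mean group size:

    * sigma^2_TBV = var_aD + 2(n-1) cov_aDaS + (n-1)^2 var_aS
    * sigma^2_P   = var_aD + (n-1) var_aS + var_c + var_g + var_pe
                    + var_l + (n-1) var_k + var_e
    * h^2 = var_aD / sigma^2_P,  T^2 = sigma^2_TBV / sigma^2_P
    * r_aDS and r_lk are the correlations of the two 2x2 blocks.
    """
    components.validate()
    n1 = mean_group_size - 1.0
    var_tbv = (components.var_aD + 2.0 * n1 * components.cov_aDaS
               + n1 * n1 * components.var_aS)
    var_p = (components.var_aD + n1 * components.var_aS + components.var_c
             + components.var_g + components.var_pe + components.var_l
             + n1 * components.var_k + components.var_e)
    return GeneticParameters(
        var_TBV=var_tbv,
        var_P=var_p,
        h2=components.var_aD / var_p,
        T2=var_tbv / var_p,
        r_aDS=components.cov_aDaS
        / math.sqrt(components.var_aD * components.var_aS),
        r_lk=components.cov_lk / math.sqrt(components.var_l * components.var_k),
    )


def total_breeding_values(a_D, a_S, mean_group_size: float) -> np.ndarray:
    """Total breeding values TBV_i = a_D,i + (n - 1) a_S,i."""
    a_D = np.asarray(a_D, dtype=float)
    a_S = np.asarray(a_S, dtype=float)
    if a_D.shape != a_S.shape:
        raise ValueError("direct and social effect vectors differ in length")
    return a_D + (mean_group_size - 1.0) * a_S


def summarize_chain(chain: PosteriorChain) -> pd.DataFrame:
    """Posterior means and SDs of components and derived genetic parameters.

    Genetic parameters are computed per retained draw and then summarised,
    so ratios such as T^2 are posterior means of ratios with their own
    posterior SDs.
    """
    rows = []
    for name in COMPONENT_NAMES:
        col = chain.draws[name]
        rows.append((name, col.mean(), col.std(ddof=1)))
    derived = {f: [] for f in ("var_TBV", "var_P", "h2", "T2", "r_aDS", "r_lk")}
    for _, draw in chain.draws.iterrows():
        gp = genetic_parameters(VarianceComponents.from_array(
            draw[list(COMPONENT_NAMES)].to_numpy()), chain.mean_group_size)
        for f in derived:
            derived[f].append(getattr(gp, f))
    for f, vals in derived.items():
        arr = np.asarray(vals)
        rows.append((f, arr.mean(), arr.std(ddof=1)))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd"])
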