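"""Canned simulation experiments: parameter recovery and QTL detection.

These wire the synthetic generator, the Gibbs sampler and the windowed
single-step GWAS into the two validation designs the package is tested
with:

* ``recovery_experiment`` -- simulate herds of 1,500 grouped animals with
  the default (co)variance components, refit each with the default chain,
  and report per-component central-interval coverage plus the error of the
  posterior-mean heritabilities;
* ``qtl_detection_experiment`` -- plant a single marker carrying a known
  fraction of the direct genetic variance, run the iteratively re-weighted
  single-step GWAS, and report whether the window holding the marker is
  top-ranked and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import QcThresholds, qc_genotypes
from .model import (
    COMPONENT_NAMES,
    ChainConfig,
    VarianceComponents,
    build_design,
    genetic_parameters,
    gibbs_fit,
)
from .relatedness import build_A_inverse
from .simulate import SimulationScenario, simulate_dataset
from .ssgwas import run_ssgwas, window_variance

MONOMORPHIC_ONLY = QcThresholds(
    maf_min=None, marker_call_rate_min=None, animal_call_rate_min=None,
    hwe_p_min=None, drop_sex_chromosomes=False, drop_monomorphic=True,
)


@dataclass
class RecoveryResult:
    """Coverage and heritability errors of one recovery replicate."""

    covered: dict[str, bool]
    h2_error: float
    T2_error: float
    posterior_mean: VarianceComponents
    n_records: int


def recovery_replicate(
    scenario_seed: int,
    chain_seed: int,
    n_animals: int = 1500,
    chain: ChainConfig | None = None,
    interval: float = 0.95,
) -> RecoveryResult:
    """Simulate one herd, refit it, and score the posterior against truth.

    ``covered[name]`` is True when the generating value of that component
    lies inside the central ``interval`` posterior interval; the h2/T2
    errors compare posterior means of per-draw ratios with the values the
    generating components imply at the realised mean group size.
    """
    scen = SimulationScenario(n_animals=n_animals, seed=scenario_seed)
    ds = simulate_dataset(scen)
    design = build_design(ds.phenotypes, ds.pedigree)
    kernel = build_A_inverse(ds.pedigree)
    cfg = chain if chain is not None else ChainConfig(seed=chain_seed)
    post = gibbs_fit(design, kernel, config=cfg, keep_effects=False)
    d = post.draws
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    covered = {}
    for name in COMPONENT_NAMES:
        tv = getattr(scen.components, name)
        covered[name] = bool(
            d[name].quantile(lo_q) <= tv <= d[name].quantile(hi_q)
        )
    nbar = post.mean_group_size
    n1 = nbar - 1.0
    var_p = (d["var_aD"] + n1 * d["var_aS"] + d["var_c"] + d["var_g"]
             + d["var_pe"] + d["var_l"] + n1 * d["var_k"] + d["var_e"])
    h2 = float((d["var_aD"] / var_p).mean())
    t2 = float(((d["var_aD"] + 2 * n1 * d["cov_aDaS"]
                 + n1 * n1 * d["var_aS"]) / var_p).mean())
    truth = genetic_parameters(scen.components, nbar)
    return RecoveryResult(
        covered=covered, h2_error=h2 - truth.h2, T2_error=t2 - truth.T2,
        posterior_mean=post.posterior_mean(), n_records=len(ds.phenotypes),
    )


def recovery_experiment(
    n_replicates: int = 5,
    base_seed: int = 1000,
    n_animals: int = 1500,
) -> pd.DataFrame:
    """Replicate recovery runs; one row per replicate.

    Scenario seeds are ``base_seed + i`` and chain seeds
    ``base_seed + 1000 + i``.
    """
    rows = []
    for i in range(n_replicates):
        res = recovery_replicate(base_seed + i, base_seed + 1000 + i,
                                 n_animals=n_animals)
        rows.append({"replicate": i, "h2_error": res.h2_error,
                     "T2_error": res.T2_error, **res.covered})
    return pd.DataFrame(rows)


@dataclass
class QtlDetectionResult:
    """Outcome of one planted-QTL run."""

    hit: bool                 # QTL window top-ranked and >= threshold
    qtl_window_pct: float     # share on the model-variance scale
    qtl_window_pct_self: float  # share on the self-normalised scale
    top_window: pd.Series = field(repr=False, default=None)


def qtl_detection_replicate(
    seed: int,
    n_animals: int = 1500,
    n_markers: int = 2500,
    n_chromosomes: int = 5,
    qtl_fraction: float = 0.10,
    effect_kind: str = "DGE",
    threshold_pct: float = 0.5,
) -> QtlDetectionResult:
    """Plant one QTL, run the weighted ssGWAS, score window ranking.

    The QTL marker (mid-genome) carries ``qtl_fraction`` of the direct
    genetic variance; all phenotyped animals are genotyped and monomorphic
    markers are QC-dropped before analysis.  Breeding values are solved at
    the generating components (the estimation step is exercised by the
    recovery experiment).
    """
    qtl_index = n_markers // 2
    scen = SimulationScenario(
        n_animals=n_animals, n_markers=n_markers,
        n_chromosomes=n_chromosomes, planted_qtl=[(qtl_index, qtl_fraction)],
        seed=seed,
    )
    ds = simulate_dataset(scen)
    qtl_name = ds.genotypes.marker_map.iloc[qtl_index]["marker"]
    ids = ds.phenotypes.records["animal"].tolist()
    gm, _ = qc_genotypes(ds.genotypes.subset(ids), MONOMORPHIC_ONLY)
    design = build_design(ds.phenotypes, ds.pedigree)
    snp, _ = run_ssgwas(design, ds.pedigree, gm, scen.components,
                        effect_kind=effect_kind)
    Z = gm.centred()
    row = gm.marker_map[gm.marker_map["marker"] == qtl_name].iloc[0]
    sigma2 = (scen.components.var_aD if effect_kind == "DGE"
              else scen.components.var_aS)
    res = window_variance(snp, Z, gm.marker_map, sigma2_a=sigma2,
                          threshold=threshold_pct)
    w = res.windows.sort_values("pct_variance", ascending=False)
    top = w.iloc[0]
    in_top = (top["chrom"] == row["chrom"]
              and top["start"] <= row["bp"] <= top["end"])
    hit = bool(in_top and top["pct_variance"] >= threshold_pct)
    mask = ((res.windows["chrom"] == row["chrom"])
            & (res.windows["start"] <= row["bp"])
            & (row["bp"] <= res.windows["end"]))
    pct = float(res.windows.loc[mask, "pct_variance"].iloc[0])
    res_self = window_variance(snp, Z, gm.marker_map, sigma2_a=None)
    pct_self = float(res_self.windows.loc[mask, "pct_variance"].iloc[0])
    return QtlDetectionResult(hit=hit, qtl_window_pct=pct,
                              qtl_window_pct_self=pct_self, top_window=top)


def qtl_detection_experiment(
    n_replicates: int = 10, base_seed: int = 4000, **kwargs
) -> pd.DataFrame:
    """Replicate planted-QTL runs with seeds ``base_seed + i``."""
    rows = []
    for i in range(n_replicates):
        r = qtl_detection_replicate(base_seed + i, **kwargs)
        rows.append({"replicate": i, "hit": r.hit,
                     "qtl_window_pct": r.qtl_window_pct,
                     "qtl_window_pct_self": r.qtl_window_pct_self})
    return pd.DataFrame(rows)
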