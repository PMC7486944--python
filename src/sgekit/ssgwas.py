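"""Single-step GWAS: SNP effects back-solved from genomic breeding values.

Breeding values of the genotyped animals are converted to per-marker
effects through

    u_hat = D Z' [Z D Z']^-1 a_g

then the per-marker weights are recomputed as ``d_i = u_i^2 2 p_i (1-p_i)``
and rescaled so the weighted total ``sum d_i 2 p_i (1 - p_i)`` is conserved,
G is rebuilt with the new weights, breeding values are re-estimated, and the
loop repeats (two iterations by default).  Additive genetic variance is then
decomposed into non-overlapping 1-Mb map windows and windows explaining at
least 0.5% of it are flagged as QTL.  The procedure is run separately on the
direct (DGE) and social (SGE) genetic effect vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .model import DesignMatrices, VarianceComponents, solve_mme
from .relatedness import GenotypeMatrix, Pedigree, RelationshipSet

__all__ = [
    "SnpEffectSet",
    "SnpWindowResult",
    "backsolve_snp_effects",
    "update_weights",
    "run_ssgwas",
    "window_variance",
    "call_qtl",
]


@dataclass
class SnpEffectSet:
    """Per-marker effect estimates and weights for one effect kind."""

    u_hat: np.ndarray
    weights: np.ndarray
    iteration: int
    effect_kind: str  # "DGE" | "SGE"

    def __post_init__(self) -> None:
        if self.effect_kind not in ("DGE", "SGE"):
            raise ValueError("effect_kind must be 'DGE' or 'SGE'")
        if np.any(self.weights < 0):
            raise ValueError("SNP weights must be non-negative")


@dataclass
class SnpWindowResult:
    """Per-window share of additive genetic variance and QTL flags."""

    windows: pd.DataFrame  # chrom, start, end, n_snps, pct_variance
    threshold: float
    effect_kind: str
    sigma2_a: float

    @property
    def qtl(self) -> pd.DataFrame:
        """Windows meeting the threshold, best first."""
        flagged = self.windows[self.windows["pct_variance"] >= self.threshold]
        return flagged.sort_values("pct_variance", ascending=False).reset_index(
            drop=True
        )


def backsolve_snp_effects(
    Z: np.ndarray,
    weights: np.ndarray,
    a_g: np.ndarray,
    effect_kind: str = "DGE",
    iteration: int = 1,
    A22: np.ndarray | None = None,
    q: float = 1.0,
    eps: float = 0.0,
) -> SnpEffectSet:
    """Convert genomic breeding values to SNP effects.

    Implements ``u_hat = D Z' [Z D Z']^-1 a_g`` for the genotyped animals'
    gene-content matrix Z (rows = animals) and diagonal weights D.  The
    projection identity ``Z u_hat = a_g`` holds whenever Z D Z' has full
    rank.

    With allele frequencies computed from the genotyped sample, Z columns
    are centred and Z D Z' is singular (the all-ones vector is in its null
    space), so the same stabilisation used for G is applied here: with
    ``eps > 0`` and a pedigree block ``A22``, the solve uses
    ``(1 - eps) Z D Z' + (eps / q) A22`` -- the blended genomic matrix on
    the raw Z D Z' scale -- and the projection identity holds up to
    O(eps).  ``eps = 0`` reproduces the printed formula exactly.
    """
    Z = np.asarray(Z, dtype=float)
    a_g = np.asarray(a_g, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if Z.shape[0] != a_g.shape[0]:
        raise ValueError("Z row count must equal the breeding-value length")
    ZD = Z * weights
    gram = ZD @ Z.T
    if eps > 0.0:
        if A22 is None:
            raise ValueError("stabilisation (eps > 0) requires A22")
        gram = (1.0 - eps) * gram + (eps / q) * np.asarray(A22)
    try:
        t = np.linalg.solve(gram, a_g)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "Z D Z' is singular: stabilise with the blending epsilon "
            "(backsolve_snp_effects(..., A22=..., eps=...)) or supply more "
            "informative markers"
        ) from exc
    u = ZD.T @ t
    return SnpEffectSet(u_hat=u, weights=weights, iteration=iteration,
                        effect_kind=effect_kind)


def update_weights(
    u_hat: np.ndarray, freqs: np.ndarray, prev_weights: np.ndarray
) -> np.ndarray:
    """New per-marker weights ``d_i = u_i^2 2 p_i (1 - p_i)``, renormalised.

    The rescaling applies a single constant so the weighted total genetic
    variance ``sum_i d_i 2 p_i (1 - p_i)`` equals its value under the
    previous weights, keeping the implied total variance constant across
    iterations.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    prev_weights = np.asarray(prev_weights, dtype=float)
    if not (u_hat.shape == freqs.shape == prev_weights.shape):
        raise ValueError("effects, frequencies and weights must align")
    het = 2.0 * freqs * (1.0 - freqs)
    raw = u_hat**2 * het
    total_raw = float(raw @ het)
    if total_raw == 0.0:
        raise ValueError("all raw SNP weights are zero: degenerate effects")
    total_prev = float(prev_weights @ het)
    return raw * (total_prev / total_raw)


def run_ssgwas(
    design: DesignMatrices,
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    components: VarianceComponents,
    effect_kind: str = "SGE",
    n_iterations: int = 2,
    eps: float = 0.05,
) -> tuple[SnpEffectSet, "MixedModelSolution"]:  # noqa: F821
    """Iteratively re-weighted single-step GWAS for one effect kind.

    Starting from D = I: solve the mixed-model equations with the current
    single-step kernel, take the genotyped animals' breeding values for
    ``effect_kind``, back-solve SNP effects, update the weights, rebuild G
    (and H^-1), and repeat for ``n_iterations``.  (Co)variance components
    stay fixed at the supplied estimates throughout.
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    Z = genotypes.centred()
    p = genotypes.allele_freqs
    weights = np.ones(genotypes.n_markers)
    snp = None
    sol = None
    for it in range(1, n_iterations + 1):
        rel = RelationshipSet.from_pedigree(pedigree, genotypes,
                                            weights=weights, eps=eps)
        sol = solve_mme(design, rel.H_inv, components)
        vec = sol.a_D if effect_kind == "DGE" else sol.a_S
        a_g = vec[rel.genotyped_index]
        snp = backsolve_snp_effects(Z, weights, a_g, effect_kind=effect_kind,
                                    iteration=it, A22=rel.A22, q=rel.q,
                                    eps=eps)
        if it < n_iterations:
            weights = update_weights(snp.u_hat, p, weights)
    return snp, sol


def window_variance(
    snp_effects: SnpEffectSet,
    Z: np.ndarray,
    marker_map: pd.DataFrame,
    window_bp: int = 1_000_000,
    sigma2_a: float | None = None,
    threshold: float = 0.5,
) -> SnpWindowResult:
    """Share of additive genetic variance explained by 1-Mb map windows.

    For each non-overlapping window (tiles anchored at position 0; markers
    with 1-based positions 1..window_bp fall in the first tile) the genomic
    value ``sum_{j in window} Z_j u_j`` is computed across genotyped animals
    and its variance expressed as a percentage of ``sigma2_a``.  When
    ``sigma2_a`` is omitted the empirical variance of the total genomic
    value is used (self-normalised mode: percentages describe the split of
    the captured variance).
    """
    Z = np.asarray(Z, dtype=float)
    u = snp_effects.u_hat
    if len(marker_map) != Z.shape[1] or len(u) != Z.shape[1]:
        raise ValueError("marker map, Z and effects must align")
    if len(marker_map) == 0:
        raise ValueError("empty genome: no markers to window")
    if sigma2_a is None:
        total = Z @ u
        sigma2_a = float(np.var(total, ddof=1))
    if sigma2_a <= 0:
        raise ValueError("additive genetic variance must be positive")

    bp = marker_map["bp"].to_numpy(dtype=np.int64)
    chrom = marker_map["chrom"].to_numpy()
    widx = (bp - 1) // window_bp
    rows = []
    for ch in pd.unique(chrom):
        on_ch = np.flatnonzero(chrom == ch)
        max_w = int(widx[on_ch].max())
        for w in range(max_w + 1):
            cols = on_ch[widx[on_ch] == w]
            if cols.size:
                gv = Z[:, cols] @ u[cols]
                pct = float(np.var(gv, ddof=1) / sigma2_a * 100.0)
            else:
                pct = 0.0
            rows.append((ch, w * window_bp + 1, (w + 1) * window_bp,
                         int(cols.size), pct))
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "pct_variance"]
    )
    return SnpWindowResult(windows=windows, threshold=threshold,
                           effect_kind=snp_effects.effect_kind,
                           sigma2_a=sigma2_a)


def call_qtl(result: SnpWindowResult, threshold_pct: float = 0.5) -> pd.DataFrame:
    """Windows explaining >= ``threshold_pct`` of additive genetic variance.

    The threshold is inclusive; output is sorted by explained percentage,
    largest first.
    """
    res = _dc_replace(result, threshold=threshold_pct)
    return res.qtl


def decomposition_audit(
    snp_effects: SnpEffectSet, Z: np.ndarray, marker_map: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> tuple[float, float]:
    """Audit: window variances + cross-covariances vs total genomic variance.

    Returns (sum of the full window covariance decomposition, variance of
    the total genomic value); the two are equal up to floating-point error.
    """
    Z = np.asarray(Z, dtype=float)
    u = snp_effects.u_hat
    bp = marker_map["bp"].to_numpy(dtype=np.int64)
    chrom = marker_map["chrom"].to_numpy()
    keys = [(c, (b - 1) // window_bp) for c, b in zip(chrom, bp)]
    uniq = list(dict.fromkeys(keys))
    gvs = []
    for key in uniq:
        cols = np.array([i for i, k in enumerate(keys) if k == key])
        gvs.append(Z[:, cols] @ u[cols])
    G = np.cov(np.stack(gvs), ddof=1)
    total = Z @ u
    return float(np.sum(G)), float(np.var(total, ddof=1))
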