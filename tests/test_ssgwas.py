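"""SNP-effect back-solving, weight iteration and window decomposition."""

import numpy as np
import pandas as pd
import pytest

from sgekit.experiments import MONOMORPHIC_ONLY
from sgekit.io import qc_genotypes
from sgekit.model import build_design, solve_mme
from sgekit.ssgwas import (
    SnpEffectSet,
    backsolve_snp_effects,
    call_qtl,
    decomposition_audit,
    run_ssgwas,
    update_weights,
    window_variance,
)


def _random_instance(n, m, seed):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, m))
    a = rng.normal(size=n)
    return Z, a


class TestBacksolve:
    def test_scalar_closed_form(self):
        snp = backsolve_snp_effects(np.array([[2.0]]), np.array([1.0]),
                                    np.array([3.0]))
        assert snp.u_hat[0] == pytest.approx(3.0 / 2.0)

    def test_zero_breeding_values(self):
        Z, _ = _random_instance(5, 12, 0)
        snp = backsolve_snp_effects(Z, np.ones(12), np.zeros(5))
        assert np.allclose(snp.u_hat, 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_projection_identity(self, seed):
        """Z u_hat reproduces the breeding values exactly."""
        Z, a = _random_instance(15, 40, seed)
        w = np.random.default_rng(seed).uniform(0.2, 3.0, size=40)
        snp = backsolve_snp_effects(Z, w, a)
        assert np.abs(Z @ snp.u_hat - a).max() < 1e-8

    def test_marker_permutation_equivariance(self):
        Z, a = _random_instance(10, 25, 3)
        perm = np.random.default_rng(1).permutation(25)
        u = backsolve_snp_effects(Z, np.ones(25), a).u_hat
        u_p = backsolve_snp_effects(Z[:, perm], np.ones(25), a).u_hat
        assert np.allclose(u_p, u[perm])

    def test_singular_gram_reported(self):
        Z = np.ones((3, 2))  # rank 1 < 3 animals
        with pytest.raises(np.linalg.LinAlgError, match="blending|singular"):
            backsolve_snp_effects(Z, np.ones(2), np.array([1.0, 2.0, 3.0]))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SnpEffectSet(u_hat=np.zeros(2), weights=np.array([1.0, -1.0]),
                         iteration=1, effect_kind="DGE")


class TestWeights:
    def test_symmetric_inputs_give_equal_weights(self):
        u = np.full(6, 0.3)
        p = np.full(6, 0.4)
        w = update_weights(u, p, np.ones(6))
        assert np.allclose(w, w[0])

    def test_single_active_marker_takes_all_mass(self):
        u = np.array([0.0, 2.0, 0.0])
        p = np.full(3, 0.5)
        w = update_weights(u, p, np.ones(3))
        assert w[0] == w[2] == 0.0
        # conservation: w[1]*2p(1-p) must equal the previous total
        assert w[1] * 0.5 == pytest.approx(3 * 0.5)

    def test_total_variance_conserved(self):
        rng = np.random.default_rng(7)
        u = rng.normal(size=100)
        p = rng.uniform(0.05, 0.95, size=100)
        prev = rng.uniform(0.1, 2.0, size=100)
        het = 2 * p * (1 - p)
        new = update_weights(u, p, prev)
        assert abs(new @ het - prev @ het) < 1e-12 * abs(prev @ het)

    def test_all_zero_effects_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            update_weights(np.zeros(4), np.full(4, 0.5), np.ones(4))


@pytest.fixture(scope="module")
def herd(small_herd):
    ids = small_herd.phenotypes.records["animal"].tolist()
    gm, _ = qc_genotypes(small_herd.genotypes.subset(ids), MONOMORPHIC_ONLY)
    design = build_design(small_herd.phenotypes, small_herd.pedigree)
    return small_herd, gm, design


class TestPipeline:
    def test_single_iteration_equals_plain_backsolve(self, herd):
        ds, gm, design = herd
        comp = ds.truth.components
        snp, sol = run_ssgwas(design, ds.pedigree, gm, comp,
                              effect_kind="DGE", n_iterations=1)
        from sgekit.relatedness import RelationshipSet

        rel = RelationshipSet.from_pedigree(ds.pedigree, gm)
        ref_sol = solve_mme(design, rel.H_inv, comp)
        a_g = ref_sol.a_D[rel.genotyped_index]
        ref = backsolve_snp_effects(gm.centred(), np.ones(gm.n_markers), a_g,
                                    A22=rel.A22, q=rel.q, eps=0.05)
        assert np.allclose(snp.u_hat, ref.u_hat)
        assert np.allclose(snp.weights, 1.0)

    def test_projection_holds_through_iterations(self, herd):
        # well-conditioned ratio: many more markers than genotyped animals
        ds, gm_all, design = herd
        ids = ds.phenotypes.records["animal"].tolist()[:100]
        gm, _ = qc_genotypes(gm_all.subset(ids), MONOMORPHIC_ONLY)
        comp = ds.truth.components
        snp, sol = run_ssgwas(design, ds.pedigree, gm, comp,
                              effect_kind="SGE", n_iterations=2)
        from sgekit.relatedness import RelationshipSet

        rel = RelationshipSet.from_pedigree(ds.pedigree, gm,
                                            weights=snp.weights)
        a_g = sol.a_S[rel.genotyped_index]
        # blending (eps = 0.05) perturbs the exact identity by O(eps)
        err = np.abs(gm.centred() @ snp.u_hat - a_g).max()
        assert err < 0.1 * np.abs(a_g).max()

    def test_dge_and_sge_runs_differ(self, herd):
        ds, gm, design = herd
        comp = ds.truth.components
        u_d, _ = run_ssgwas(design, ds.pedigree, gm, comp, effect_kind="DGE")
        u_s, _ = run_ssgwas(design, ds.pedigree, gm, comp, effect_kind="SGE")
        assert not np.allclose(u_d.u_hat, u_s.u_hat)


def _map_for(bps, chroms):
    return pd.DataFrame({"marker": [f"m{i}" for i in range(len(bps))],
                         "chrom": chroms, "bp": bps})


class TestWindows:
    def test_one_window_self_normalised_is_100(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(12, 5))
        u = rng.normal(size=5)
        snp = SnpEffectSet(u, np.ones(5), 1, "DGE")
        mp = _map_for([10, 200, 4000, 60_000, 900_000], ["1"] * 5)
        res = window_variance(snp, Z, mp, sigma2_a=None)
        assert len(res.windows) == 1
        assert res.windows["pct_variance"].iloc[0] == pytest.approx(100.0)

    def test_zero_effects_zero_percent(self):
        Z = np.random.default_rng(1).normal(size=(8, 4))
        snp = SnpEffectSet(np.zeros(4), np.ones(4), 1, "DGE")
        mp = _map_for([1, 2, 1_500_000, 1_500_001], ["1"] * 4)
        res = window_variance(snp, Z, mp, sigma2_a=5.0)
        assert (res.windows["pct_variance"] == 0).all()

    def test_orthogonal_blocks_split_evenly(self):
        """Two engineered blocks with equal variance, zero covariance."""
        n = 8
        v1 = np.array([1.0, -1.0] * 4)
        v2 = np.array([1.0, 1.0, -1.0, -1.0] * 2)
        assert v1 @ v2 == 0
        Z = np.column_stack([v1, v2])
        u = np.ones(2)
        snp = SnpEffectSet(u, np.ones(2), 1, "SGE")
        mp = _map_for([500_000, 1_500_000], ["1", "1"])
        res = window_variance(snp, Z, mp, sigma2_a=None)
        pct = res.windows["pct_variance"].to_numpy()
        assert np.allclose(pct, [50.0, 50.0], atol=1e-6)

    def test_empty_windows_reported_as_zero(self):
        Z = np.random.default_rng(2).normal(size=(6, 2))
        snp = SnpEffectSet(np.ones(2), np.ones(2), 1, "DGE")
        mp = _map_for([5, 2_500_000], ["1", "1"])
        res = window_variance(snp, Z, mp, sigma2_a=1.0)
        assert len(res.windows) == 3
        middle = res.windows.iloc[1]
        assert middle["n_snps"] == 0 and middle["pct_variance"] == 0.0

    def test_empty_genome_rejected(self):
        snp = SnpEffectSet(np.empty(0), np.empty(0), 1, "DGE")
        with pytest.raises(ValueError, match="align|empty"):
            window_variance(snp, np.empty((3, 0)), _map_for([], []),
                            sigma2_a=1.0)

    def test_scaling_breeding_values_leaves_self_normalised_pct(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(10, 6))
        u = rng.normal(size=6)
        mp = _map_for([1, 2, 3, 1_000_001, 1_000_002, 2_000_001], ["1"] * 6)
        p1 = window_variance(SnpEffectSet(u, np.ones(6), 1, "DGE"), Z, mp,
                             sigma2_a=None).windows["pct_variance"]
        p2 = window_variance(SnpEffectSet(3.5 * u, np.ones(6), 1, "DGE"), Z,
                             mp, sigma2_a=None).windows["pct_variance"]
        assert np.allclose(p1, p2)

    def test_decomposition_audit_closes(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(20, 30))
        u = rng.normal(size=30)
        mp = _map_for(list(rng.choice(np.arange(1, 5_000_000), 30,
                                      replace=False)), ["1"] * 30)
        snp = SnpEffectSet(u, np.ones(30), 1, "DGE")
        total_from_blocks, total = decomposition_audit(snp, Z, mp)
        assert total_from_blocks == pytest.approx(total, rel=1e-10)


class TestQtlCalling:
    def _result(self, pcts):
        w = pd.DataFrame({
            "chrom": "1", "start": np.arange(len(pcts)) * 10**6 + 1,
            "end": (np.arange(len(pcts)) + 1) * 10**6,
            "n_snps": 5, "pct_variance": pcts,
        })
        from sgekit.ssgwas import SnpWindowResult

        return SnpWindowResult(windows=w, threshold=0.5, effect_kind="DGE",
                               sigma2_a=1.0)

    def test_all_below_threshold(self):
        assert call_qtl(self._result([0.1, 0.3, 0.49])).empty

    def test_threshold_inclusive(self):
        out = call_qtl(self._result([0.2, 0.5, 0.1]))
        assert len(out) == 1 and out["pct_variance"].iloc[0] == 0.5

    def test_sorted_descending(self):
        out = call_qtl(self._result([0.7, 2.0, 1.1]))
        assert list(out["pct_variance"]) == [2.0, 1.1, 0.7]
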