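"""Design matrices, MME solutions, Gibbs sampler and genetic parameters."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sgekit.model import (
    ChainConfig,
    GroupedPhenotypes,
    VarianceComponents,
    build_design,
    dilution,
    genetic_parameters,
    gibbs_fit,
    solve_mme,
    summarize_chain,
    total_breeding_values,
)
from sgekit.model import PosteriorChain
from sgekit.relatedness import Pedigree, build_A, build_A_inverse
from sgekit.simulate import REFERENCE_COMPONENTS

from conftest import toy_phenotypes

REF = REFERENCE_COMPONENTS  # printed posterior means used as worked examples


class TestDilution:
    def test_mean_sized_group_is_unity(self):
        assert dilution(7, 7.0) == pytest.approx(1.0)

    def test_worked_values(self):
        assert dilution(8, 6.8) == pytest.approx(5.8 / 7)
        assert dilution(2, 6.8) == pytest.approx(5.8)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            dilution(1, 6.8)


class TestDesign:
    def test_social_incidence_structure(self):
        """One group of three distinct litters: two d entries, no self term."""
        ped = Pedigree.from_records(
            [(a, None, None) for a in ("x0", "x1", "x2")])
        df = pd.DataFrame({
            "animal": ["x0", "x1", "x2"], "y": [1.0, 2.0, 3.0],
            "yearmonth": "ym", "sex": "M", "pen": "p", "group": "g",
            "litter": ["l0", "l1", "l2"], "dam": ["d0", "d1", "d2"],
            "age": [150.0, 151.0, 152.0],
        })
        design = build_design(GroupedPhenotypes(df), ped)
        ZS = design.Z_S.toarray()
        assert np.allclose(np.diag(ZS), 0.0)
        assert (ZS > 0).sum() == 6
        d = dilution(3, 3.0)
        assert np.allclose(ZS[ZS > 0], d)

    def test_uniform_group_size_gives_unit_dilution(self):
        ped, data = toy_phenotypes(n_groups=3, group_size=4)
        design = build_design(data, ped)
        vals = design.Z_S.data
        assert np.allclose(vals, 1.0)

    def test_shared_litter_mates_accumulate_in_Q(self):
        """Mates from one litter pile their dilution weight on one column."""
        ped = Pedigree.from_records(
            [(a, None, None) for a in ("x0", "x1", "x2", "x3")])
        df = pd.DataFrame({
            "animal": ["x0", "x1", "x2", "x3"], "y": 1.0,
            "yearmonth": "ym", "sex": "M", "pen": "p", "group": "g",
            "litter": ["la", "lb", "lb", "lb"], "dam": "d",
            "age": 150.0,
        })
        design = build_design(GroupedPhenotypes(df), ped)
        Q = design.Q.toarray()
        lb = design.litter_levels.index("lb")
        la = design.litter_levels.index("la")
        d = dilution(4, 4.0)
        # x0's three mates are all from litter lb
        assert Q[0, lb] == pytest.approx(3 * d)
        assert Q[0, la] == 0
        # x1's mates: x0 (la) + x2, x3 (lb)
        assert Q[1, la] == pytest.approx(d)
        assert Q[1, lb] == pytest.approx(2 * d)

    def test_row_sums_equal_nbar_minus_one(self, small_herd):
        ds = small_herd
        design = build_design(ds.phenotypes, ds.pedigree)
        rs = np.asarray(design.Z_S.sum(axis=1)).ravel()
        assert np.abs(rs - (design.mean_group_size - 1)).max() < 1e-10

    def test_singleton_group_rejected(self):
        ped = Pedigree.from_records([("x0", None, None), ("x1", None, None)])
        df = pd.DataFrame({
            "animal": ["x0", "x1"], "y": 1.0, "yearmonth": "ym", "sex": "M",
            "pen": "p", "group": ["g0", "g1"], "litter": "l", "dam": "d",
            "age": 150.0,
        })
        with pytest.raises(ValueError, match="singleton"):
            GroupedPhenotypes(df)


class TestSolveMME:
    def test_matches_dense_gls_oracle(self):
        """MME solutions equal GLS on the marginal covariance, 6 animals."""
        ped, data = toy_phenotypes(n_groups=2, group_size=3, seed=4)
        design = build_design(data, ped)
        comp = REF
        A = build_A(ped)
        sol = solve_mme(design, build_A_inverse(ped), comp)

        X = design.X
        ZD, ZS = design.Z_D.toarray(), design.Z_S.toarray()
        W, V, T = design.W.toarray(), design.V.toarray(), design.T.toarray()
        U, Q = design.U.toarray(), design.Q.toarray()
        C, S = comp.genetic_cov(), comp.litter_cov()
        Vm = (C[0, 0] * ZD @ A @ ZD.T
              + C[0, 1] * (ZD @ A @ ZS.T + ZS @ A @ ZD.T)
              + C[1, 1] * ZS @ A @ ZS.T
              + comp.var_c * W @ W.T + comp.var_g * V @ V.T
              + comp.var_pe * T @ T.T
              + S[0, 0] * U @ U.T + S[0, 1] * (U @ Q.T + Q @ U.T)
              + S[1, 1] * Q @ Q.T + comp.var_e * np.eye(len(design.y)))
        Vi = np.linalg.inv(Vm)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ design.y)
        r = Vi @ (design.y - X @ b)
        aD = C[0, 0] * A @ ZD.T @ r + C[0, 1] * A @ ZS.T @ r
        aS = C[0, 1] * A @ ZD.T @ r + C[1, 1] * A @ ZS.T @ r
        assert np.abs(b - sol.b).max() < 1e-8
        assert np.abs(aD - sol.a_D).max() < 1e-8
        assert np.abs(aS - sol.a_S).max() < 1e-8

    def test_shrinkage_limit_zero_genetic_variance(self):
        ped, data = toy_phenotypes(n_groups=2, group_size=3, seed=5)
        design = build_design(data, ped)
        tiny = dataclasses.replace(REF, var_aD=1e-8, var_aS=1e-10,
                                   cov_aDaS=0.0)
        sol = solve_mme(design, build_A_inverse(ped), tiny)
        assert np.abs(sol.a_D).max() < 1e-4
        assert np.abs(sol.a_S).max() < 1e-4

    def test_relabelling_invariance(self):
        """Permuting record order leaves per-animal solutions unchanged."""
        ped, data = toy_phenotypes(n_groups=2, group_size=3, seed=6)
        design = build_design(data, ped)
        sol = solve_mme(design, build_A_inverse(ped), REF)
        perm = data.records.sample(frac=1.0, random_state=1)
        design_p = build_design(GroupedPhenotypes(perm), ped)
        sol_p = solve_mme(design_p, build_A_inverse(ped), REF)
        # a_D / a_S indexed by pedigree position: identical vectors
        assert np.abs(sol.a_D - sol_p.a_D).max() < 1e-8
        assert np.abs(sol.a_S - sol_p.a_S).max() < 1e-8


class TestGibbs:
    def test_location_sampling_matches_mme(self):
        """At fixed components the sweep's stationary mean is the MME fit."""
        from scipy import sparse as sp

        from sgekit._gibbs import gibbs_sweep

        ped, data = toy_phenotypes(n_groups=4, group_size=3, seed=7)
        design = build_design(data, ped)
        comp = REF
        Ainv = build_A_inverse(ped)
        sol = solve_mme(design, Ainv, comp)

        Wall = design.stacked()
        WtW = (Wall.T @ Wall).tocsr()
        WtW.sort_indices()
        rhs = Wall.T @ design.y
        K = sp.csr_matrix(Ainv)
        K.sort_indices()
        lay = design.equation_layout()
        off_aD, nped = lay["a_D"]
        off_c, nc = lay["c"]
        off_g, ng = lay["g"]
        off_pe, npe = lay["pe"]
        off_l, nl = lay["l"]
        Cinv = np.linalg.inv(comp.genetic_cov())
        Linv = np.linalg.inv(comp.litter_cov())
        def run(n_iter, stochastic, seed=0):
            rng = np.random.default_rng(seed)
            theta = np.zeros(Wall.shape[1])
            acc = np.zeros_like(theta)
            n_keep = 0
            for it in range(n_iter):
                z = (rng.standard_normal(len(theta)) if stochastic
                     else np.zeros(len(theta)))
                gibbs_sweep(WtW.data, WtW.indices, WtW.indptr, rhs, theta,
                            1.0 / comp.var_e, K.data, K.indices, K.indptr,
                            nped, off_aD, off_c, nc, off_g, ng, off_pe, npe,
                            off_l, nl, Cinv[0, 0], Cinv[0, 1], Cinv[1, 1],
                            Linv[0, 0], Linv[0, 1], Linv[1, 1],
                            1.0 / comp.var_c, 1.0 / comp.var_g,
                            1.0 / comp.var_pe, z)
                if it >= n_iter // 4:
                    acc += theta
                    n_keep += 1
            return theta, acc / n_keep

        # noise-free sweep is Gauss-Seidel: must converge to the MME fit
        theta_gs, _ = run(3000, stochastic=False)
        assert np.abs(theta_gs - sol.theta).max() < 1e-6
        # stochastic sweep: chain mean tracks the MME fit up to MC error
        _, mean = run(8000, stochastic=True)
        for name in ("a_D", "a_S", "c", "g", "pe", "l", "k"):
            off, size = lay[name]
            block_sd = max(np.abs(sol.theta[off:off + size]).max(), 1.0)
            err = np.abs(mean[off:off + size] - sol.theta[off:off + size])
            assert err.max() < block_sd, name

    def test_chain_reproducible_and_bookkept(self):
        ped, data = toy_phenotypes(n_groups=4, group_size=3, seed=8)
        design = build_design(data, ped)
        Ainv = build_A_inverse(ped)
        cfg = ChainConfig(rounds=400, burn_in=100, thin=3, seed=42)
        c1 = gibbs_fit(design, Ainv, config=cfg)
        c2 = gibbs_fit(design, Ainv, config=cfg)
        assert c1.n_retained == cfg.n_retained == 100
        pd.testing.assert_frame_equal(c1.draws, c2.draws)
        c3 = gibbs_fit(design, Ainv, config=dataclasses.replace(cfg, seed=43))
        assert not c3.draws.equals(c1.draws)


class TestGeneticParameters:
    def test_printed_heritabilities(self):
        """The published posterior means reproduce h2, T2, r, sigma2_P."""
        gp = genetic_parameters(REF, 6.8)
        assert round(gp.h2, 2) == 0.36
        assert round(gp.T2, 2) == 0.52
        assert round(gp.r_aDS, 2) == 0.23
        assert round(gp.var_P / 10) * 10 == 6260

    def test_reduces_to_classical_model(self):
        comp = dataclasses.replace(REF, var_aS=1e-12, cov_aDaS=0.0,
                                   var_k=1e-12, cov_lk=0.0)
        gp = genetic_parameters(comp, 6.8)
        assert gp.T2 == pytest.approx(gp.h2, rel=1e-9)
        assert gp.var_TBV == pytest.approx(comp.var_aD, rel=1e-9)

    def test_scale_invariance(self):
        s = 3.7
        scaled = VarianceComponents.from_array(REF.as_array() * s * s)
        g0 = genetic_parameters(REF, 6.8)
        g1 = genetic_parameters(scaled, 6.8)
        assert g1.h2 == pytest.approx(g0.h2)
        assert g1.T2 == pytest.approx(g0.T2)
        assert g1.r_aDS == pytest.approx(g0.r_aDS)
        assert g1.var_P == pytest.approx(g0.var_P * s * s)

    def test_nonpositive_variance_rejected(self):
        bad = dataclasses.replace(REF, var_e=-1.0)
        with pytest.raises(ValueError):
            genetic_parameters(bad, 6.8)


class TestTotalBreedingValues:
    def test_worked_example(self):
        assert total_breeding_values([10.0], [1.0], 6.8)[0] == pytest.approx(
            15.8)

    def test_no_social_component(self):
        a = np.array([1.0, -2.0, 3.0])
        assert np.allclose(total_breeding_values(a, np.zeros(3), 6.8), a)

    def test_variance_identity(self):
        """Empirical var(TBV) equals the variance formula on empirical
        (co)variances."""
        rng = np.random.default_rng(3)
        cov = np.array([[4.0, 0.8], [0.8, 0.5]])
        draws = rng.multivariate_normal([0, 0], cov, size=5000)
        tbv = total_breeding_values(draws[:, 0], draws[:, 1], 6.8)
        emp = np.cov(draws.T)
        n1 = 5.8
        expect = emp[0, 0] + 2 * n1 * emp[0, 1] + n1 * n1 * emp[1, 1]
        assert np.var(tbv, ddof=1) == pytest.approx(expect, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            total_breeding_values([1.0], [1.0, 2.0], 6.8)


class TestChainSummary:
    def test_reference_chain_retains_10000(self):
        assert ChainConfig.reference().n_retained == 10_000

    def test_thin_one_keeps_everything(self):
        assert ChainConfig(rounds=100, burn_in=0, thin=1).n_retained == 100

    def test_invalid_burn_in(self):
        with pytest.raises(ValueError):
            ChainConfig(rounds=100, burn_in=100, thin=1)

    def test_constant_chain_summary(self):
        draws = pd.DataFrame([REF.as_array()] * 10,
                             columns=list(
                                 VarianceComponents.__dataclass_fields__))
        chain = PosteriorChain(draws=draws, config=ChainConfig(
            rounds=100, burn_in=50, thin=5, seed=0), mean_group_size=6.8)
        summ = summarize_chain(chain).set_index("parameter")
        assert summ.loc["var_aD", "sd"] == pytest.approx(0.0)
        assert summ.loc["var_aD", "mean"] == pytest.approx(2235.0)
        assert round(summ.loc["T2", "mean"], 2) == 0.52
        assert round(summ.loc["r_aDS", "mean"], 2) == 0.23
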