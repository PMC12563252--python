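import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from forageblup.reml_core import (
    VarianceComponents,
    anadev,
    build_design,
    em_reml_fit,
    lrt,
    reml_deviance,
    solve_mme,
)
from forageblup.trial_data import TraitSpec, TrialDataset

from conftest import make_trial


def direct_reml_deviance(mm, vc):
    """Independent oracle: -2 restricted log-likelihood evaluated from
    the dense phenotypic covariance matrix V (determinant + quadratic
    form), never touching the Henderson-system code path."""
    X, Z, W, T = (M.toarray() for M in (mm.X, mm.Z, mm.W, mm.T))
    y = mm.y
    V = (
        vc.sigma2_e * np.eye(len(y))
        + vc.sigma2_g * Z @ Z.T
        + vc.sigma2_perm * W @ W.T
        + vc.sigma2_gm * T @ T.T
    )
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    n, p = len(y), X.shape[1]
    return (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + float(r @ Vi @ r)
        + (n - p) * math.log(2 * math.pi)
    )


def anova_components(ds, trait="t"):
    """Method-of-moments oracle for a complete balanced q x b x m trial:
    classical expected-mean-squares equations of the two-way
    repeated-measures RCBD."""
    sub = ds.subset(trait)
    q = sub["genotype"].nunique()
    b = sub["block"].nunique()
    m = sub["harvest"].nunique()
    y = (
        sub.sort_values(["genotype", "block", "harvest"])["value"]
        .to_numpy()
        .reshape(q, b, m)
    )
    gm_ = y.mean()
    yi = y.mean(axis=(1, 2))
    yj = y.mean(axis=(0, 2))
    yk = y.mean(axis=(0, 1))
    yij = y.mean(axis=2)
    yik = y.mean(axis=1)
    yjk = y.mean(axis=0)
    ms_g = b * m * ((yi - gm_) ** 2).sum() / (q - 1)
    ms_gb = m * ((yij - yi[:, None] - yj[None, :] + gm_) ** 2).sum() / ((q - 1) * (b - 1))
    ms_gm = b * ((yik - yi[:, None] - yk[None, :] + gm_) ** 2).sum() / ((q - 1) * (m - 1))
    resid = (
        y
        - yij[:, :, None]
        - yik[:, None, :]
        - yjk[None, :, :]
        + yi[:, None, None]
        + yj[None, :, None]
        + yk[None, None, :]
        - gm_
    )
    ms_res = (resid**2).sum() / ((q - 1) * (b - 1) * (m - 1))
    return np.array(
        [
            (ms_g - ms_gb - ms_gm + ms_res) / (b * m),  # sigma2_g
            (ms_gb - ms_res) / m,  # sigma2_perm
            (ms_gm - ms_res) / b,  # sigma2_gm
            ms_res,  # sigma2_e
        ]
    )


class TestBuildDesign:
    def test_column_counts_complete_2x2x2(self):
        ds = make_trial(2, 2, 2, (1, 1, 1, 1), seed=0)
        mm = build_design(ds, "t")
        assert mm.Z.shape[1] == 2
        assert mm.W.shape[1] == 4
        assert mm.T.shape[1] == 4
        assert mm.rank_x == 4

    def test_missing_plot_gets_no_column(self):
        ds = make_trial(2, 2, 2, (1, 1, 1, 1), seed=0)
        df = ds.data[~((ds.data["genotype"] == "G00") & (ds.data["block"] == "B0"))]
        mm = build_design(TrialDataset(df.reset_index(drop=True), ds.traits), "t")
        assert mm.W.shape[1] == 3

    def test_large_design_column_counts(self):
        rows = [
            (f"G{i:03d}", f"B{j}", f"H{k:02d}", "NT", float(i + j + k))
            for i, j, k in itertools.product(range(84), range(4), range(13))
        ]
        df = pd.DataFrame(rows, columns=["genotype", "block", "harvest", "trait", "value"])
        mm = build_design(TrialDataset(df, {"NT": TraitSpec("NT")}), "NT")
        assert (mm.Z.shape[1], mm.W.shape[1], mm.T.shape[1]) == (84, 336, 1092)

    def test_single_harvest_rejected(self):
        ds = make_trial(3, 2, 2, (1, 1, 1, 1), seed=0)
        df = ds.data[ds.data["harvest"] == "H00"].reset_index(drop=True)
        with pytest.raises(ValueError, match="single harvest"):
            build_design(TrialDataset(df, ds.traits), "t")

    def test_each_row_selects_one_level(self, tiny_trial):
        mm = build_design(tiny_trial, "t")
        for M in (mm.X, mm.Z, mm.W, mm.T):
            assert (np.asarray(M.sum(axis=1)).ravel() == 1).all()


class TestSolveMME:
    def test_matches_dense_block_solve(self, tiny_trial):
        mm = build_design(tiny_trial, "t")
        vc = VarianceComponents(2.0, 2.0, 2.0, 2.0)  # all lambdas = 1
        blup = solve_mme(mm, vc)
        X, Z, W, T = (M.toarray() for M in (mm.X, mm.Z, mm.W, mm.T))
        A = np.hstack([X, Z, W, T])
        C = A.T @ A
        off = X.shape[1]
        for U, lam in ((Z, 1.0), (W, 1.0), (T, 1.0)):
            k = U.shape[1]
            C[off : off + k, off : off + k] += lam * np.eye(k)
            off += k
        sol = np.linalg.solve(C, A.T @ mm.y)
        ours = np.concatenate([blup.m_hat, blup.g_hat, blup.p_hat, blup.i_hat])
        assert np.allclose(sol, ours, atol=1e-10)

    def test_infinite_shrinkage_drives_g_to_zero(self, tiny_trial):
        mm = build_design(tiny_trial, "t")
        vc = VarianceComponents(1e-14, 1.0, 1.0, 2.0)
        blup = solve_mme(mm, vc)
        assert np.abs(blup.g_hat).max() < 1e-8

    def test_balanced_blups_center_at_zero(self, mid_trial):
        mm = build_design(mid_trial, "t")
        blup = solve_mme(mm, VarianceComponents(1.0, 0.5, 0.7, 2.0))
        assert abs(blup.g_hat.sum()) < 1e-8
        assert abs(blup.p_hat.sum()) < 1e-8
        assert abs(blup.i_hat.sum()) < 1e-8

    def test_shrinkage_never_exceeds_fixed_contrast(self, mid_trial):
        # BLUPs are shrunk toward zero relative to the unshrunk
        # (near-fixed) genotype contrasts
        mm = build_design(mid_trial, "t")
        vc = VarianceComponents(1.0, 0.5, 0.7, 2.0)
        shrunk = solve_mme(mm, vc).g_hat
        near_fixed = solve_mme(mm, VarianceComponents(1e8, 0.5, 0.7, 2.0)).g_hat
        assert (np.abs(shrunk) <= np.abs(near_fixed) + 1e-8).all()


class TestRemlDeviance:
    def test_matches_direct_likelihood_oracle(self, tiny_trial):
        mm = build_design(tiny_trial, "t")
        for vc in (
            VarianceComponents(1.3, 0.7, 0.5, 2.0),
            VarianceComponents(0.2, 1.5, 2.5, 0.7),
        ):
            assert abs(reml_deviance(mm, vc) - direct_reml_deviance(mm, vc)) < 1e-6

    def test_location_scale_contract(self, tiny_trial):
        mm = build_design(tiny_trial, "t")
        vc = VarianceComponents(1.3, 0.7, 0.5, 2.0)
        dev = reml_deviance(mm, vc)
        df = tiny_trial.data.assign(value=tiny_trial.data["value"] * 2.0)
        mm2 = build_design(TrialDataset(df, tiny_trial.traits), "t")
        vc2 = VarianceComponents(4 * 1.3, 4 * 0.7, 4 * 0.5, 4 * 2.0)
        n_eff = mm.n_obs - mm.rank_x
        assert np.isclose(reml_deviance(mm2, vc2) - dev, n_eff * math.log(4.0), atol=1e-8)

    def test_fit_is_local_minimum_probe(self, mid_trial):
        fit = em_reml_fit(mid_trial, "t", tol=1e-10, max_iter=5000)
        c = fit.components
        doubled = VarianceComponents(
            2 * c.sigma2_g, 2 * c.sigma2_perm, 2 * c.sigma2_gm, 2 * c.sigma2_e
        )
        mm = build_design(mid_trial, "t")
        assert fit.deviance <= reml_deviance(mm, doubled)


class TestEmReml:
    def test_balanced_equals_anova_method_of_moments(self, mid_trial):
        mom = anova_components(mid_trial)
        assert (mom > 0).all()  # interior solution required for equivalence
        fit = em_reml_fit(mid_trial, "t", tol=1e-12, max_iter=20000)
        est = np.array(
            [
                fit.components.sigma2_g,
                fit.components.sigma2_perm,
                fit.components.sigma2_gm,
                fit.components.sigma2_e,
            ]
        )
        assert fit.converged
        assert np.abs(est - mom).max() < 1e-6

    def test_deviance_matches_numerical_optimum(self, tiny_trial):
        # independent route: scipy optimization of the dense-V restricted
        # likelihood, multi-start Nelder-Mead over log-variances
        mm = build_design(tiny_trial, "t")
        var_y = tiny_trial.data["value"].var()

        def objective(logv):
            return direct_reml_deviance(mm, VarianceComponents(*np.exp(logv)))

        best = np.inf
        for s in range(6):
            rng = np.random.default_rng(s)
            x0 = np.log(np.full(4, var_y / 4)) + rng.normal(0, 1, 4)
            res = scipy.optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000, maxfev=20000),
            )
            best = min(best, res.fun)
        fit = em_reml_fit(tiny_trial, "t", tol=1e-12, max_iter=50000)
        assert fit.deviance <= best + 1e-3
        assert fit.deviance >= best - 1e-3

    def test_constant_response_flags_degenerate(self):
        rows = [
            (f"G{i}", f"B{j}", f"H{k}", "t", 3.0)
            for i, j, k in itertools.product(range(3), range(2), range(2))
        ]
        df = pd.DataFrame(rows, columns=["genotype", "block", "harvest", "trait", "value"])
        ds = TrialDataset(df, {"t": TraitSpec("t")})
        fit = em_reml_fit(ds, "t", max_iter=50)
        assert fit.degenerate
        assert fit.components.sigma2_g <= 1e-10

    def test_non_convergence_is_flag_not_exception(self):
        ds = make_trial(6, 2, 3, (0.0, 0.0, 0.5, 3.0), seed=3)
        fit = em_reml_fit(ds, "t", tol=1e-14, max_iter=3)
        assert not fit.converged
        assert fit.n_iterations == 3

    def test_lambdas_are_exact_component_ratios(self, mid_trial):
        fit = em_reml_fit(mid_trial, "t", tol=1e-10, max_iter=5000)
        c = fit.components
        assert np.isclose(fit.lambdas["g"], c.sigma2_e / c.sigma2_g, rtol=1e-12)
        assert np.isclose(fit.lambdas["i"], c.sigma2_e / c.sigma2_gm, rtol=1e-12)


class TestLrt:
    @pytest.mark.parametrize(
        "dev_red,dev_full,expected,code",
        [
            (36489.74, 36404.77, 84.97, "**"),
            (42801.97, 36404.77, 6397.20, "**"),
            (34234.11, 34132.21, 101.90, "**"),
            (-11264.48, -11662.29, 397.81, "**"),
        ],
    )
    def test_deviance_table_arithmetic(self, dev_red, dev_full, expected, code):
        stat, p, got_code = lrt(dev_red, dev_full)
        assert round(stat, 2) == expected
        assert got_code == code

    def test_identity_gives_zero_and_ns(self):
        stat, p, code = lrt(100.0, 100.0)
        assert stat == 0.0 and p == 1.0 and code == "ns"

    def test_boundary_five_percent_inclusive(self):
        assert lrt(103.84, 100.0)[2] == "*"
        assert lrt(106.63, 100.0)[2] == "**"

    def test_negative_statistic_warns(self):
        with pytest.warns(RuntimeWarning, match="negative"):
            lrt(99.0, 100.0)


class TestAnadev:
    def test_null_genotype_effect_not_significant(self):
        ds = make_trial(15, 3, 4, (0.0, 0.4, 0.8, 2.8), seed=19)
        tab = anadev(ds, "t", tol=1e-7, max_iter=800)
        row = tab.rows.loc["Genotype"]
        assert row["lrt"] < 3.84
        assert row["code"] == "ns"

    def test_strong_effects_detected(self, mid_trial):
        tab = anadev(mid_trial, "t", tol=1e-8, max_iter=2000)
        assert tab.rows.loc["Genotype", "lrt"] > 6.63
        assert tab.rows.loc["Interaction GxM", "lrt"] > 6.63
        assert (tab.rows["lrt"] > -1e-4).all()
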