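"""DWLS estimator: oracles, calibration, indices and difference tests."""

import numpy as np
import pytest

import dualfactor as df
from dualfactor.correlations import mixed_correlation_matrix
from dualfactor.data import ItemDef
from dualfactor.estimator import (fit_indices, fit_model,
                                  modification_indices,
                                  ml_modification_indices,
                                  scaled_difference_test)
from dualfactor.models import build_model, saturated_spec

from conftest import one_factor_config


class TestZeroResidualFixedPoint:
    def test_population_moments_recover_generating_values(self, study_config,
                                                          study_pairs):
        spec = build_model("correlated_factors", study_config.items, study_pairs)
        pop = df.population_stats(study_config)
        fit = fit_model(spec, pop)
        assert fit.chi2_unscaled < 1e-8
        gen = df.config_to_params(study_config)
        for key, want in gen.items():
            if key in fit.params and key[0] in ("lambda", "phi", "rtheta"):
                assert fit.params[key] == pytest.approx(want, abs=1e-4), key

    def test_saturated_model_chi2_zero(self, study_config, stats_2000):
        fit = fit_model(saturated_spec(study_config.items), stats_2000)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)


class TestToyGridOracle:
    def test_dwls_matches_coordinate_grid_search(self):
        """On a 4-item one-factor toy, the quasi-Newton DWLS solution matches
        an independent cyclic grid-refinement minimizer of the same fit
        function to 1e-4."""
        items = [ItemDef(f"t{i}", "ordinal3", "dom") for i in range(1, 5)]
        cfg = one_factor_config(items, [.6, .7, .5, .65], n=3000)
        tab = df.generate_dataset(cfg, seed=42)
        stats = mixed_correlation_matrix(tab)
        spec = build_model("single_instrument", items)
        fit = fit_model(spec, stats)

        corr_keys = [k for k in stats.stat_index if k[0] == "corr"]
        pos = {k: i for i, k in enumerate(stats.stat_index)}
        s = stats.stat_vector()
        w = np.diag(stats.gamma)
        pairs = [(int(a[1][1:]) - 1, int(a[2][1:]) - 1) for a in corr_keys]
        r_obs = np.array([s[pos[k]] for k in corr_keys])
        w_obs = np.array([w[pos[k]] for k in corr_keys])

        def F(lam):
            rho = np.array([lam[i] * lam[j] for i, j in pairs])
            return np.sum((r_obs - rho) ** 2 / w_obs)

        x = np.full(4, 0.5)
        width = 0.5
        for _ in range(40):
            for k in range(4):
                grid = np.clip(x[k] + np.linspace(-width, width, 41),
                               -0.995, 0.995)
                vals = []
                for g in grid:
                    xk = x.copy(); xk[k] = g
                    vals.append(F(xk))
                x[k] = grid[int(np.argmin(vals))]
            width *= 0.6
        lam_fit = np.array([fit.params[("lambda", f"t{i}", "dom")]
                            for i in range(1, 5)])
        assert np.abs(lam_fit - x).max() < 1e-4
        assert fit.chi2_unscaled == pytest.approx(F(x), abs=1e-8)


class TestFitIndices:
    def test_perfect_fit(self):
        rmsea, ci, cfi, _ = fit_indices(145.0, 145, 900.0, 171, 1982)
        assert rmsea == 0.0 and cfi == 1.0 and ci[0] == 0.0

    @pytest.mark.parametrize("chi2,df_,expected", [
        (410.931, 145, 0.030),   # published correlated-factors row
        (535.155, 133, 0.039),   # published S-1(wellbeing) row
        (321.561, 129, 0.027),   # published bifactor row
    ])
    def test_published_rmsea_rows(self, chi2, df_, expected):
        rmsea, _, _, _ = fit_indices(chi2, df_, 5000.0, 171, 1982)
        assert round(rmsea, 3) == expected

    @pytest.mark.parametrize("c,d,n,cb,db,er,ec,et", [
        (100, 50, 500, 800, 66, 0.044766, 0.93188, 0.910082),
        (250.7, 120, 1500, 2200, 150, 0.026955, 0.936244, 0.920305),
        (75, 80, 900, 400, 45, 0.0, 1.0, 1.007923),
        (410.931, 145, 1982, 2000, 171, 0.030427, 0.854603, 0.828532),
        (60, 20, 250, 300, 30, 0.089622, 0.851852, 0.777778),
    ])
    def test_closed_forms_against_hand_computation(self, c, d, n, cb, db,
                                                   er, ec, et):
        rmsea, _, cfi, tli = fit_indices(c, d, cb, db, n)
        assert rmsea == pytest.approx(er, abs=1e-6)
        assert cfi == pytest.approx(ec, abs=1e-6)
        assert tli == pytest.approx(et, abs=1e-6)

    def test_ci_brackets_point_estimate(self):
        rmsea, (lo, hi), _, _ = fit_indices(410.931, 145, 2000.0, 171, 1982)
        assert lo <= rmsea <= hi


class TestSampleFit:
    def test_correct_model_fits_well(self, study_config, study_pairs,
                                     stats_2000):
        spec = build_model("correlated_factors", study_config.items, study_pairs)
        fit = fit_model(spec, stats_2000)
        assert fit.converged
        assert fit.pvalue > 0.001          # adjusted statistic is calibrated
        assert fit.rmsea < 0.02
        assert all(v > 0 for k, v in fit.se.items() if k[0] == "lambda")

    def test_item_order_invariance(self, study_config, study_pairs, table_2000):
        spec = build_model("correlated_factors", study_config.items, study_pairs)
        fit = fit_model(spec, mixed_correlation_matrix(table_2000))
        perm = list(reversed(study_config.items))
        tab_p = table_2000.subset_items([it.name for it in perm])
        spec_p = build_model("correlated_factors", perm, study_pairs)
        fit_p = fit_model(spec_p, mixed_correlation_matrix(tab_p))
        assert fit_p.df == fit.df
        assert fit_p.chi2 == pytest.approx(fit.chi2, abs=1e-4)
        assert fit_p.rmsea == pytest.approx(fit.rmsea, abs=1e-6)

    def test_loading_recovery_over_seeds(self, study_config, study_pairs):
        """Mean absolute loading error below .05 at n = 5000 over 10 seeds."""
        cfg = df.paper_default_config(n=5000)
        spec = build_model("correlated_factors", cfg.items, study_pairs)
        gen = df.config_to_params(cfg)
        errs = []
        for seed in range(1, 11):
            tab = df.generate_dataset(cfg, seed=seed)
            fit = fit_model(spec, mixed_correlation_matrix(tab))
            errs += [abs(fit.params[k] - v) for k, v in gen.items()
                     if k[0] == "lambda"]
        assert np.mean(errs) < 0.05


class TestModificationIndices:
    def test_planted_pair_ranks_first(self, mi_planted_ranks):
        """The omitted generating residual pair tops the candidate ranking in
        every one of 10 seeds."""
        assert mi_planted_ranks == [1] * 10

    def test_null_calibration(self):
        """With no residual structure, the largest index stays below the
        chi-square(1) .99 quantile in at least 8 of 10 seeds."""
        items = [ItemDef(f"q{i}", "ordinal3", "dom") for i in range(1, 6)]
        cfg = one_factor_config(items, [.6, .7, .5, .65, .55], n=2000)
        spec = build_model("single_instrument", items)
        ok = 0
        for seed in range(11, 21):
            tab = df.generate_dataset(cfg, seed=seed)
            fit = fit_model(spec, mixed_correlation_matrix(tab))
            mis, _ = modification_indices(fit)
            ok += max(r["mi"] for r in mis) < 6.634896601021213
        assert ok >= 8

    def test_all_indices_nonnegative(self, study_config, study_pairs,
                                     stats_2000):
        spec = build_model("correlated_factors", study_config.items, study_pairs)
        mis, _ = modification_indices(fit_model(spec, stats_2000))
        assert all(r["mi"] >= 0 for r in mis)


class TestScaledDifference:
    def test_model_against_itself_is_zero(self, study_config, study_pairs,
                                          stats_2000):
        spec = build_model("correlated_factors", study_config.items, study_pairs)
        fit = fit_model(spec, stats_2000)
        t = scaled_difference_test(fit, fit)
        assert t.delta_chi2 == 0.0 and t.delta_df == 0

    def test_correlated_vs_bifactor_delta_df(self, study_config, study_pairs,
                                             stats_2000):
        cf = fit_model(build_model("correlated_factors", study_config.items,
                                   study_pairs), stats_2000)
        bf = fit_model(build_model("bifactor", study_config.items,
                                   study_pairs), stats_2000)
        t = scaled_difference_test(cf, bf)
        assert t.delta_df == 16
        assert t.delta_chi2 >= 0

    def test_type_one_error_calibration(self):
        """Data from the restricted model: rejection rate at alpha = .05 over
        200 scaled-down replicates stays within [.01, .10]."""
        items = [ItemDef(f"q{i}", "ordinal3", "dom") for i in range(1, 7)]
        cfg = one_factor_config(items, [.6, .7, .5, .65, .55, .6], n=1000)
        restricted = build_model("single_instrument", items)
        full = build_model("single_instrument", items, [("q1", "q2")])
        rej = 0
        for rep in range(200):
            tab = df.generate_dataset(cfg, seed=2000 + rep)
            stats = mixed_correlation_matrix(tab)
            t = scaled_difference_test(fit_model(restricted, stats),
                                       fit_model(full, stats))
            rej += t.pvalue < 0.05
        assert 0.01 <= rej / 200 <= 0.10


class TestContinuousMLRoute:
    def test_wellbeing_instrument_df_and_fit(self, table_2000):
        items = [it for it in table_2000.items if it.domain == "wellbeing"]
        sub = table_2000.subset_items([it.name for it in items])
        stats = mixed_correlation_matrix(sub, gamma=False)
        spec = build_model("single_instrument", items, [("wb1", "wb3")])
        fit = fit_model(spec, stats)
        assert fit.method == "ml"
        assert fit.df == 1
        assert fit.rmsea < 0.05
        spec0 = build_model("single_instrument", items)
        assert fit_model(spec0, stats).df == 2

    def test_ml_recovers_standardized_loadings(self, table_2000, study_config):
        items = [it for it in table_2000.items if it.domain == "wellbeing"]
        sub = table_2000.subset_items([it.name for it in items])
        spec = build_model("single_instrument", items, [("wb1", "wb3")])
        fit = fit_model(spec, mixed_correlation_matrix(sub, gamma=False))
        for it in items:
            want = study_config.loadings[it.name]["wellbeing"]
            got = fit.params[("lambda", it.name, "wellbeing")]
            assert got == pytest.approx(want, abs=0.06)

    def test_ml_modification_index_finds_planted_pair(self, table_2000):
        items = [it for it in table_2000.items if it.domain == "wellbeing"]
        sub = table_2000.subset_items([it.name for it in items])
        spec0 = build_model("single_instrument", items)
        fit0 = fit_model(spec0, mixed_correlation_matrix(sub, gamma=False))
        mis, _ = ml_modification_indices(fit0)
        assert set(mis[0]["pair"]) == {"wb1", "wb3"}
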