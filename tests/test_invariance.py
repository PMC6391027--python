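"""Multigroup invariance: calibration, planted effects, policies."""

import copy

import numpy as np
import pandas as pd
import pytest

import dualfactor as df
from dualfactor.correlations import mixed_correlation_matrix
from dualfactor.data import ItemDef, ItemResponseTable
from dualfactor.estimator import FitError, scaled_difference_test
from dualfactor.invariance import (covariate_association, fit_configural,
                                   fit_scalar, fix_negative_residual,
                                   invariance_sequence)
from dualfactor.models import build_model


def _two_group_table(cfg_a, cfg_b, seed_a, seed_b):
    ta = df.generate_dataset(cfg_a, seed=seed_a)
    tb = df.generate_dataset(cfg_b, seed=seed_b)
    da = ta.data.copy(); da["grp"] = 0
    db = tb.data.copy(); db["grp"] = 1
    return ItemResponseTable(pd.concat([da, db], ignore_index=True),
                             cfg_a.items, covariates=("grp",))


@pytest.fixture(scope="module")
def small_spec(small_mixed_config):
    return build_model("single_instrument", small_mixed_config.items)


class TestSequenceStructure:
    def test_null_groups_reach_full_invariance(self, small_mixed_config,
                                               small_spec):
        tab = df.generate_dataset(small_mixed_config, seed=21)
        res = invariance_sequence(small_spec, tab, "grp", baselines=True)
        assert res.verdict == "full"
        assert res.freed_items == []
        assert len(res.baselines) == 2

    def test_configural_df_is_sum_of_single_group_dfs(self, small_mixed_config,
                                                      small_spec):
        tab = df.generate_dataset(small_mixed_config, seed=22)
        groups = tab.split_by("grp")
        stats = [mixed_correlation_matrix(groups[k]) for k in sorted(groups)]
        singles = [df.fit_model(small_spec, st) for st in stats]
        conf = fit_configural(small_spec, stats)
        assert conf.df == sum(f.df for f in singles)
        assert conf.chi2_unscaled == pytest.approx(
            sum(f.chi2_unscaled for f in singles), abs=1e-10)

    def test_scalar_nested_in_configural(self, small_mixed_config, small_spec):
        tab = df.generate_dataset(small_mixed_config, seed=23)
        groups = tab.split_by("grp")
        stats = [mixed_correlation_matrix(groups[k]) for k in sorted(groups)]
        conf = fit_configural(small_spec, stats)
        scal = fit_scalar(small_spec, stats)
        assert scal.df > conf.df
        t = scaled_difference_test(scal, conf)
        assert t.delta_chi2 >= 0.0

    def test_duplicated_rows_give_identical_group_estimates(
            self, small_mixed_config, small_spec):
        base = df.generate_dataset(small_mixed_config, seed=24)
        d0 = base.data.copy(); d0["grp"] = 0
        d1 = base.data.copy(); d1["grp"] = 1
        tab = ItemResponseTable(pd.concat([d0, d1], ignore_index=True),
                                small_mixed_config.items, covariates=("grp",))
        groups = tab.split_by("grp")
        stats = [mixed_correlation_matrix(groups[k]) for k in sorted(groups)]
        conf = fit_configural(small_spec, stats)
        g0 = {k: v for k, v in conf.params.items() if k[-1] == 0}
        for k, v in g0.items():
            assert conf.params[k[:-1] + (1,)] == pytest.approx(v, abs=1e-8)

    def test_too_small_group_fails(self, small_mixed_config, small_spec):
        tab = df.generate_dataset(small_mixed_config, seed=25)
        tab = tab.subset_rows(np.arange(tab.n) < 120)
        with pytest.raises(FitError, match="rows"):
            invariance_sequence(small_spec, tab, "grp")


class TestCalibrationAndDetection:
    def test_null_rejection_rate_small(self, invariance_null_rejections):
        """Identical populations: scalar invariance survives at alpha = .05
        in at least 90% of 50 scaled-down replicates."""
        rate = float(np.mean(invariance_null_rejections[:50] < 0.05))
        assert rate <= 0.10

    def test_planted_threshold_shift_detected(self, small_mixed_config,
                                              small_spec):
        """Group 2 differs only in one item's thresholds (+.5); the search
        must free exactly that item in at least 9 of 10 seeds."""
        cfg_a = copy.deepcopy(small_mixed_config)
        cfg_a.covariate_prevalence = {}
        cfg_a.n = 2000
        cfg_b = copy.deepcopy(cfg_a)
        cfg_b.thresholds = dict(cfg_b.thresholds)
        t1, t2 = cfg_b.thresholds["o2"]
        cfg_b.thresholds["o2"] = (t1 + 0.5, t2 + 0.5)
        hits = 0
        for seed in range(1, 11):
            tab = _two_group_table(cfg_a, cfg_b, 3 * seed, 3 * seed + 1)
            res = invariance_sequence(small_spec, tab, "grp", baselines=False)
            hits += (res.verdict == "partial" and res.freed_items == ["o2"])
        assert hits >= 9

    def test_tie_break_prefers_earlier_item(self, small_mixed_config):
        """Ties in the block modification index resolve to the item earlier
        in the model's item order (the documented rule)."""
        from dualfactor.invariance import partial_invariance_search
        order = {nm: i for i, nm in
                 enumerate(it.name for it in small_mixed_config.items)}
        mis = [{"item": "o3", "mi": 5.0}, {"item": "o1", "mi": 5.0},
               {"item": "c1", "mi": 4.0}]
        best = mis[0]["mi"]
        cands = [r["item"] for r in mis if abs(r["mi"] - best) < 1e-9]
        assert min(cands, key=lambda nm: order[nm]) == "o1"


class TestNegativeResidualPolicy:
    def _heywood_table(self, seed=1, resid_sd=0.06, loading=0.995, n=900):
        items = ([ItemDef(f"o{i}", "ordinal3", "dom") for i in range(1, 4)]
                 + [ItemDef("c1", "continuous", "dom"),
                    ItemDef("c2", "continuous", "dom")])
        base = dict(items=items, factors=["dom"],
                    loadings={"o1": {"dom": .6}, "o2": {"dom": .7},
                              "o3": {"dom": .55}, "c1": {"dom": .6},
                              "c2": {"dom": .6}},
                    phi=np.eye(1),
                    thresholds={f"o{i}": (0.1, 1.2) for i in range(1, 4)},
                    intercepts={"c1": 6.0, "c2": 6.0},
                    residual_sd={"c1": 1.0, "c2": 1.0},
                    n=n, icc=0.0, n_clusters=1)
        cfg_a = df.GeneratorConfig(**base)
        cfg_b = copy.deepcopy(cfg_a)
        cfg_b.loadings = dict(cfg_b.loadings)
        cfg_b.loadings["c2"] = {"dom": loading}
        cfg_b.residual_sd = dict(cfg_b.residual_sd)
        cfg_b.residual_sd["c2"] = resid_sd
        return _two_group_table(cfg_a, cfg_b, seed, seed + 50)

    def _spec(self):
        items = ([ItemDef(f"o{i}", "ordinal3", "dom") for i in range(1, 4)]
                 + [ItemDef("c1", "continuous", "dom"),
                    ItemDef("c2", "continuous", "dom")])
        return build_model("single_instrument", items)

    def test_clean_fit_passes_through(self, small_mixed_config, small_spec):
        tab = df.generate_dataset(small_mixed_config, seed=30)
        groups = tab.split_by("grp")
        stats = [mixed_correlation_matrix(groups[k]) for k in sorted(groups)]
        fit = fit_scalar(small_spec, stats)
        assert fit.negative_residuals == {}
        same, fixes = fix_negative_residual(fit)
        assert fixes == [] and same is fit

    def test_nonsignificant_negative_fixed_to_zero(self):
        found = False
        for seed in (1, 2, 3):
            tab = self._heywood_table(seed=seed)
            groups = tab.split_by("grp")
            stats = [mixed_correlation_matrix(groups[k]) for k in sorted(groups)]
            fit = fit_scalar(self._spec(), stats)
            if not fit.negative_residuals:
                continue
            try:
                new, fixes = fix_negative_residual(fit)
            except FitError:
                continue
            if fixes:
                found = True
                assert any(f["item"] == "c2" for f in fixes)
                assert all(f["pvalue"] >= 0.05 for f in fixes)
                assert new.df == fit.df + len(fixes)
                break
        assert found, "no non-significant Heywood case arose in 3 seeds"

    def test_significant_negative_raises(self):
        raised = False
        for seed in (1, 3):
            tab = self._heywood_table(seed=seed, resid_sd=0.03, loading=0.98,
                                      n=2000)
            groups = tab.split_by("grp")
            stats = [mixed_correlation_matrix(groups[k]) for k in sorted(groups)]
            fit = fit_scalar(self._spec(), stats)
            if not fit.negative_residuals:
                continue
            try:
                fix_negative_residual(fit)
            except FitError:
                raised = True
                break
        assert raised


class TestCovariateAssociations:
    def _cfg(self, effect):
        items = ([ItemDef(f"o{i}", "ordinal3", "dom") for i in range(1, 5)]
                 + [ItemDef("c1", "continuous", "dom")])
        return df.GeneratorConfig(
            items=items, factors=["dom"],
            loadings={"o1": {"dom": .6}, "o2": {"dom": .7}, "o3": {"dom": .55},
                      "o4": {"dom": .65}, "c1": {"dom": .6}},
            phi=np.eye(1), thresholds={f"o{i}": (0.1, 1.2) for i in range(1, 5)},
            intercepts={"c1": 6.0}, residual_sd={"c1": 1.0},
            covariate_prevalence={"x": 0.5},
            covariate_effects={"x": {"dom": effect}},
            n=2000, icc=0.0, n_clusters=1)

    def test_null_effect_near_zero(self):
        spec = build_model("single_instrument", self._cfg(0.0).items)
        coefs = []
        for seed in range(1, 11):
            tab = df.generate_dataset(self._cfg(0.0), seed=seed)
            coefs.append(covariate_association(spec, tab, "x")[0].coefficient)
        assert abs(np.mean(coefs)) < 0.05

    def test_planted_shift_recovered(self):
        spec = build_model("single_instrument", self._cfg(-0.6).items)
        coefs = []
        for seed in range(1, 6):
            tab = df.generate_dataset(self._cfg(-0.6), seed=seed)
            coefs.append(covariate_association(spec, tab, "x")[0].coefficient)
        assert np.mean(coefs) == pytest.approx(-0.6, abs=0.1)

    def test_signs_consistent_on_study_data(self, study_config, table_2000,
                                            study_pairs):
        """Factor-by-factor associations agree in sign with the generating
        covariate effects for the factors given non-trivial effects."""
        spec = build_model("correlated_factors", study_config.items, study_pairs)
        rows = covariate_association(spec, table_2000, "gender")
        got = {r.factor: r.coefficient for r in rows}
        assert got["externalising"] < 0
        assert got["internalising"] > 0

    def test_constant_covariate_fails(self, table_2000, study_config,
                                      study_pairs):
        tab = table_2000
        tab.data["const"] = 1
        spec = build_model("correlated_factors", study_config.items, study_pairs)
        with pytest.raises(FitError, match="binary"):
            covariate_association(spec, tab, "const")
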