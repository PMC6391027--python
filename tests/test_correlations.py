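"""Mixed-correlation estimation: oracles, invariances and Gamma behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr, ndtri

import dualfactor as df
from dualfactor._bvn import bvn_cell_probs
from dualfactor.correlations import (EstimationError, estimate_thresholds,
                                     pairwise_correlation, pearson, polychoric,
                                     polyserial)
from dualfactor.data import ItemDef


def ordinal_from_counts(counts):
    counts = np.asarray(counts, int)
    x = np.concatenate([np.full(counts[i, j], i + 1.0)
                        for i in range(3) for j in range(3)])
    y = np.concatenate([np.full(counts[i, j], j + 1.0)
                        for i in range(3) for j in range(3)])
    return x, y


class TestThresholds:
    def test_median_category_gives_zero(self):
        x = np.repeat([1, 2, 3], [50, 30, 20])
        tau = estimate_thresholds(x)
        assert tau[0] == pytest.approx(0.0, abs=1e-12)
        assert tau[1] == pytest.approx(ndtri(0.8), abs=1e-12)

    def test_uniform_categories_symmetric(self):
        x = np.repeat([1, 2, 3], 10)
        tau = estimate_thresholds(x)
        assert tau[0] == pytest.approx(-0.4307, abs=5e-5)
        assert tau[1] == pytest.approx(+0.4307, abs=5e-5)

    def test_degenerate_margin_names_item(self):
        with pytest.raises(EstimationError, match="worry"):
            estimate_thresholds(np.full(50, 3.0), item="worry")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(1, 300), min_size=3, max_size=3))
    def test_threshold_inverse_roundtrip(self, counts):
        """Normal orthant probabilities of the estimated thresholds recover
        the observed cumulative category proportions, for any margin."""
        x = np.repeat([1.0, 2.0, 3.0], counts)
        tau = estimate_thresholds(x)
        n = sum(counts)
        assert tau[0] < tau[1]
        assert ndtr(tau[0]) == pytest.approx(counts[0] / n, abs=1e-12)
        assert ndtr(tau[1]) == pytest.approx((counts[0] + counts[1]) / n,
                                             abs=1e-12)


class TestPolychoric:
    def test_matches_grid_search_oracle(self):
        """Two-step ML agrees with a brute-force likelihood grid (step 1e-4)."""
        counts = np.array([[20, 10, 5], [10, 20, 10], [5, 10, 20]])
        x, y = ordinal_from_counts(counts)
        tau_x = estimate_thresholds(x)
        tau_y = estimate_thresholds(y)
        grid = np.arange(-0.999, 0.999 + 1e-9, 1e-4)
        ll = (np.log(bvn_cell_probs(tau_x, tau_y, grid))
              * counts[None]).sum(axis=(1, 2))
        rho_grid = grid[np.argmax(ll)]
        est = polychoric(x, y)
        assert est.value == pytest.approx(rho_grid, abs=1e-3)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((50_000, 2))
        x = 1.0 + (z[:, 0] > 0.1) + (z[:, 0] > 1.2)
        y = 1.0 + (z[:, 1] > -0.2) + (z[:, 1] > 1.0)
        assert abs(polychoric(x, y).value) < 0.02

    def test_same_latent_hits_boundary(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(5000)
        x = 1.0 + (z > 0.1) + (z > 1.2)
        est = polychoric(x, x.copy())
        assert est.value >= 0.99
        assert est.boundary

    def test_consistency_over_seeds(self):
        """Mean estimate over 20 seeds at n = 5000 within .02 of truth."""
        for rho in (-0.6, 0.0, 0.3, 0.8):
            cov = np.array([[1, rho], [rho, 1]])
            chol = np.linalg.cholesky(cov)
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(100 + seed)
                z = rng.standard_normal((5000, 2)) @ chol.T
                x = 1.0 + (z[:, 0] > 0.1) + (z[:, 0] > 1.2)
                y = 1.0 + (z[:, 1] > -0.1) + (z[:, 1] > 1.0)
                vals.append(polychoric(x, y).value)
            assert np.mean(vals) == pytest.approx(rho, abs=0.02)


class TestPolyserialAndPearson:
    def test_polyserial_recovers_latent_correlation(self):
        rho = -0.55
        rng = np.random.default_rng(3)
        z = rng.standard_normal((40_000, 2))
        z[:, 1] = rho * z[:, 0] + np.sqrt(1 - rho * rho) * z[:, 1]
        x = 5.0 + 1.5 * z[:, 0]
        y = 1.0 + (z[:, 1] > 0.2) + (z[:, 1] > 1.1)
        assert polyserial(x, y).value == pytest.approx(rho, abs=0.02)

    def test_pearson_equals_textbook_formula(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 200))
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert pearson(x, y).value == pytest.approx(r_hand, abs=1e-14)

    def test_pairwise_dispatch_is_symmetric(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((3000, 2))
        z[:, 1] = 0.5 * z[:, 0] + np.sqrt(0.75) * z[:, 1]
        x = 4 + z[:, 0]
        y = 1.0 + (z[:, 1] > 0) + (z[:, 1] > 1)
        a = pairwise_correlation(x, y, "continuous", "ordinal3")
        b = pairwise_correlation(y, x, "ordinal3", "continuous")
        assert a.value == pytest.approx(b.value, abs=1e-12)
        assert a.method == "polyserial"

    def test_min_pair_n_enforced(self):
        with pytest.raises(EstimationError, match="complete"):
            pearson(np.arange(5.0), np.arange(5.0))


class TestMatrixAndGamma:
    def test_matrix_symmetric_unit_diagonal(self, stats_2000):
        R = stats_2000.corr.to_numpy()
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert np.abs(R).max() <= 1.0

    def test_recovers_population_matrix(self, fidelity_stats_200k):
        _, _, _, R_pop = df.implied_population_moments(
            df.paper_default_config(n=200_000))
        assert np.abs(fidelity_stats_200k.corr.to_numpy() - R_pop).max() < 0.02

    def test_gamma_psd_and_symmetric(self, stats_2000):
        G = stats_2000.gamma
        assert np.allclose(G, G.T)
        assert np.linalg.eigvalsh(G).min() > -1e-10

    def test_gamma_shrinks_like_one_over_n(self, small_mixed_config):
        import copy
        cfg2 = copy.deepcopy(small_mixed_config)
        cfg2.covariate_prevalence = {}
        cfg2.n = 2000
        cfg8 = copy.deepcopy(cfg2)
        cfg8.n = 8000
        g2 = df.mixed_correlation_matrix(df.generate_dataset(cfg2, seed=8)).gamma
        g8 = df.mixed_correlation_matrix(df.generate_dataset(cfg8, seed=9)).gamma
        ratio = np.diag(g8) / np.diag(g2)
        assert np.all(ratio > 0.25 * 0.7)
        assert np.all(ratio < 0.25 * 1.3)

    def test_gamma_against_bootstrap(self, table_2000):
        """Influence-function variances within 25% of a 500-replicate
        nonparametric bootstrap on a reduced item set."""
        sub = table_2000.subset_items(["int1", "int2", "wb1", "wb2"])
        g_if = np.diag(df.mixed_correlation_matrix(sub).gamma)
        g_bs = np.diag(df.bootstrap_gamma(sub, n_boot=500, seed=2))
        rel = np.abs(g_if - g_bs) / g_bs
        assert rel.max() < 0.25


class TestReliability:
    def _table_with_exact_cov(self, cov, n=400, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, len(cov)))
        X -= X.mean(0)
        # whiten empirically, then color to the exact target covariance
        L = np.linalg.cholesky(np.cov(X, rowvar=False, ddof=1))
        X = X @ np.linalg.inv(L).T @ np.linalg.cholesky(np.asarray(cov)).T
        import pandas as pd
        items = [ItemDef(f"v{i}", "continuous", "dom") for i in range(len(cov))]
        frame = pd.DataFrame(np.clip(X + 5.0, 0, 10),
                             columns=[it.name for it in items])
        return df.ItemResponseTable(frame, items, covariates=())

    def test_alpha_closed_form_two_items(self):
        tab = self._table_with_exact_cov([[1, .5], [.5, 1]])
        rel = df.scale_reliability(tab, ["v0", "v1"])
        assert rel.alpha == pytest.approx(2 / 3, abs=1e-9)

    def test_alpha_zero_when_uncorrelated(self):
        tab = self._table_with_exact_cov(np.eye(4))
        rel = df.scale_reliability(tab, ["v0", "v1", "v2", "v3"])
        assert rel.alpha == pytest.approx(0.0, abs=1e-9)

    def test_alpha_one_when_perfectly_correlated(self):
        tab = self._table_with_exact_cov(np.full((3, 3), 1.0) * 0.999
                                         + 0.001 * np.eye(3))
        rel = df.scale_reliability(tab, ["v0", "v1", "v2"])
        assert rel.alpha == pytest.approx(1.0, abs=1e-3)

    def test_item_total_in_range(self, table_2000):
        rel = df.scale_reliability(
            table_2000, [f"int{i}" for i in range(1, 10)])
        assert all(-1 <= v <= 1 for v in rel.item_total.values())
        assert rel.alpha <= 1


class TestICC:
    def test_constant_within_clusters(self):
        values = np.repeat([1.0, 5.0, 9.0], 50)
        clusters = np.repeat([0, 1, 2], 50)
        assert df.intraclass_correlation(values, clusters) == pytest.approx(1.0)

    def test_permuted_labels_near_zero(self):
        rng = np.random.default_rng(6)
        values = rng.standard_normal(20_000)
        clusters = rng.integers(0, 50, 20_000)
        assert df.intraclass_correlation(values, clusters) < 0.01

    def test_variance_ratio_construction(self):
        """Between-variance .05 and within .95 gives ICC about .05.

        Averaged over three replicates: with 100 clusters a single ICC
        estimate has an SE of ~.007, so the mean is the calibrated check."""
        vals = []
        for seed in (7, 8, 9):
            rng = np.random.default_rng(seed)
            clusters = rng.integers(0, 100, 20_000)
            u = rng.normal(0, np.sqrt(0.05), 100)
            values = u[clusters] + rng.normal(0, np.sqrt(0.95), 20_000)
            vals.append(df.intraclass_correlation(values, clusters))
        assert np.mean(vals) == pytest.approx(0.05, abs=0.01)

    def test_single_cluster_fails(self):
        with pytest.raises(EstimationError):
            df.intraclass_correlation(np.arange(10.0), np.zeros(10))
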