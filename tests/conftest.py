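"""Shared fixtures: study configuration, reusable datasets and compact
generator configurations for calibration studies."""

import numpy as np
import pytest

import dualfactor as df
from dualfactor.data import ItemDef


@pytest.fixture(scope="session")
def study_config():
    return df.paper_default_config()


@pytest.fixture(scope="session")
def study_pairs(study_config):
    return [(a, b) for a, b, _ in study_config.residual_pairs]


@pytest.fixture(scope="session")
def table_2000(study_config):
    cfg = df.paper_default_config(n=2000)
    return df.generate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def stats_2000(table_2000):
    return df.mixed_correlation_matrix(table_2000)


@pytest.fixture(scope="session")
def table_50k():
    cfg = df.paper_default_config(n=50_000)
    return df.generate_dataset(cfg, seed=3)


@pytest.fixture(scope="session")
def fidelity_stats_200k():
    """Point estimates of the full mixed matrix at n = 200 000, where the
    entrywise moment-fidelity band is a sharp check (at 50k the max over 171
    polychoric entries is dominated by sampling spread)."""
    cfg = df.paper_default_config(n=200_000)
    tab = df.generate_dataset(cfg, seed=3)
    return df.mixed_correlation_matrix(tab, gamma=False)


def one_factor_config(items, loadings, thresholds=None, n=2000, **kw):
    """Compact single-factor generator used across calibration tests."""
    thr = thresholds or {it.name: (0.1, 1.2) for it in items
                         if it.scale == "ordinal3"}
    return df.GeneratorConfig(
        items=items, factors=["dom"],
        loadings={it.name: {"dom": l} for it, l in zip(items, loadings)},
        phi=np.eye(1), thresholds=thr, n=n, icc=0.0, n_clusters=1, **kw)


@pytest.fixture(scope="session")
def small_mixed_config():
    """One factor, three ordinal + two continuous items, a binary split
    variable with no group differences (null-invariance conditions)."""
    items = ([ItemDef(f"o{i}", "ordinal3", "dom") for i in range(1, 4)]
             + [ItemDef(f"c{i}", "continuous", "dom") for i in range(1, 3)])
    return df.GeneratorConfig(
        items=items, factors=["dom"],
        loadings={"o1": {"dom": .6}, "o2": {"dom": .7}, "o3": {"dom": .55},
                  "c1": {"dom": .65}, "c2": {"dom": .6}},
        phi=np.eye(1),
        thresholds={"o1": (0.1, 1.2), "o2": (-0.1, 1.0), "o3": (0.2, 1.3)},
        intercepts={"c1": 6.0, "c2": 5.5}, residual_sd={"c1": 1.0, "c2": 1.2},
        covariate_prevalence={"grp": 0.5},
        n=1600, icc=0.0, n_clusters=1)


@pytest.fixture(scope="session")
def invariance_null_rejections(small_mixed_config):
    """Scalar-vs-configural rejection count at alpha = .05 over 200 null
    replicates (800 per group).  Session-scoped: shared by the module
    property test and the acceptance criterion."""
    from dualfactor.correlations import mixed_correlation_matrix
    from dualfactor.estimator import scaled_difference_test
    from dualfactor.invariance import fit_configural, fit_scalar
    from dualfactor.models import build_model

    spec = build_model("single_instrument", small_mixed_config.items)
    pvals = []
    for rep in range(200):
        tab = df.generate_dataset(small_mixed_config, seed=1000 + rep)
        groups = tab.split_by("grp")
        stats = [mixed_correlation_matrix(groups[k]) for k in sorted(groups)]
        conf = fit_configural(spec, stats)
        scal = fit_scalar(spec, stats)
        pvals.append(scaled_difference_test(scal, conf).pvalue)
    return np.array(pvals)


@pytest.fixture(scope="session")
def mi_planted_ranks():
    """Rank of the omitted residual pair (int5, int6) among all candidate
    pairs, over 10 seeds at n = 5000 on the internalising instrument."""
    from dualfactor.correlations import mixed_correlation_matrix
    from dualfactor.estimator import fit_model, modification_indices
    from dualfactor.models import build_model

    cfg = df.paper_default_config(n=5000)
    sub = [it for it in cfg.items if it.domain == "internalising"]
    spec = build_model("single_instrument", sub, [("int1", "int3"), ("int7", "int8")])
    ranks = []
    for seed in range(1, 11):
        tab = df.generate_dataset(cfg, seed=seed).subset_items(
            [it.name for it in sub])
        stats = mixed_correlation_matrix(tab)
        fit = fit_model(spec, stats)
        mis, _ = modification_indices(fit)
        pairs = [frozenset(r["pair"]) for r in mis]
        ranks.append(pairs.index(frozenset(("int5", "int6"))) + 1)
    return ranks
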