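"""Limited-information sample statistics for mixed ordinal/continuous items.

This module produces the statistic vector that diagonally-weighted least
squares consumes: per-item thresholds (ordinal) or means/variances
(continuous), the matrix of polychoric / polyserial / Pearson correlations,
and the asymptotic covariance ``Gamma`` of the stacked statistics estimated
from per-observation influence functions of the two-step estimating
equations.  It also hosts the classical descriptive statistics reported for
such instruments: Cronbach's alpha with item-total correlations, and the
one-way ANOVA intraclass correlation.

Estimation conventions
----------------------
* Two-step estimation throughout: univariate margins first (thresholds via
  the inverse-normal of cumulative proportions; continuous means/SDs), then
  each correlation by a one-dimensional likelihood maximization with the
  margins held fixed.
* Pairwise-complete observations for every statistic.
* ``Gamma`` is the finite-sample covariance of the statistic vector (so its
  entries shrink like 1/n); influence functions include the first-step
  correction terms for the estimated margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri

from ._bvn import bvn_cell_probs
from .data import CONTINUOUS, ORDINAL3, ItemDef, ItemResponseTable

RHO_BOUND = 0.999
RHO_TOL = 1e-8
_MIN_PAIR_N = 10


class EstimationError(RuntimeError):
    """Raised when a sample statistic cannot be estimated."""


# ---------------------------------------------------------------------------
# Univariate margins
# ---------------------------------------------------------------------------

def estimate_thresholds(ordinal_responses, item: str = "item") -> np.ndarray:
    """Thresholds of a three-category ordinal item on the latent-normal scale.

    ``tau_c`` is the standard-normal quantile of the cumulative proportion at
    or below category ``c``; an interior cumulative proportion of 0 or 1
    (fewer than two observed categories) is an error.
    """
    x = np.asarray(ordinal_responses, float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise EstimationError(f"item {item!r}: no observed responses")
    cum = np.array([(x <= 1).mean(), (x <= 2).mean()])
    if (cum <= 0.0).any() or (cum >= 1.0).any():
        raise EstimationError(
            f"item {item!r}: degenerate margin (cumulative proportions {cum.round(4)})")
    tau = ndtri(cum)
    return tau


# ---------------------------------------------------------------------------
# Pairwise correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrEstimate:
    value: float
    n: int
    method: str           # "polychoric" | "polyserial" | "pearson"
    boundary: bool = False


def _polychoric_nll_factory(counts: np.ndarray, tau_x: np.ndarray,
                            tau_y: np.ndarray) -> Callable[[float], float]:
    def nll(rho):
        probs = bvn_cell_probs(tau_x, tau_y, np.asarray(rho))
        return -float(np.sum(counts * np.log(probs)))
    return nll


def polychoric(x, y, tau_x: np.ndarray | None = None,
               tau_y: np.ndarray | None = None,
               names: tuple[str, str] = ("x", "y")) -> CorrEstimate:
    """Two-step polychoric correlation of two three-category ordinal items.

    Thresholds are fixed at their (marginal) estimates; the correlation
    maximizes the bivariate-normal contingency-table likelihood over
    pairwise-complete observations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < _MIN_PAIR_N:
        raise EstimationError(f"pair {names}: fewer than {_MIN_PAIR_N} complete observations")
    if tau_x is None:
        tau_x = estimate_thresholds(x, names[0])
    if tau_y is None:
        tau_y = estimate_thresholds(y, names[1])
    counts = _crosstab3(x[ok], y[ok])
    nll = _polychoric_nll_factory(counts, tau_x, tau_y)
    res = minimize_scalar(nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": RHO_TOL})
    if not res.success:
        raise EstimationError(f"pair {names}: polychoric likelihood maximization "
                              f"failed ({res.message})")
    rho = float(res.x)
    boundary = abs(rho) >= RHO_BOUND - 1e-4
    rho = float(np.clip(rho, -RHO_BOUND, RHO_BOUND))
    return CorrEstimate(rho, int(ok.sum()), "polychoric", boundary)


def _crosstab3(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    idx = (x.astype(int) - 1) * 3 + (y.astype(int) - 1)
    return np.bincount(idx, minlength=9).reshape(3, 3).astype(float)


def _polyserial_nll_terms(z: np.ndarray, cat: np.ndarray, tau: np.ndarray,
                          rho: float) -> np.ndarray:
    """Per-observation negative log conditional likelihood, vectorized."""
    s = np.sqrt(max(1.0 - rho * rho, 1e-12))
    hi = np.where(cat < 3, (tau[np.minimum(cat, 2) - 1] - rho * z) / s, np.inf)
    lo = np.where(cat > 1, (tau[np.maximum(cat - 2, 0)] - rho * z) / s, -np.inf)
    p = ndtr(hi) - ndtr(lo)
    return -np.log(np.clip(p, 1e-300, 1.0))


def polyserial(x_cont, y_ord, tau_y: np.ndarray | None = None,
               names: tuple[str, str] = ("x", "y")) -> CorrEstimate:
    """Two-step polyserial correlation (continuous x, 3-category ordinal y).

    The continuous variable is standardized by its sample moments and the
    ordinal thresholds fixed at marginal estimates; the latent correlation
    maximizes the conditional likelihood of the ordinal categories given the
    standardized continuous score.
    """
    x = np.asarray(x_cont, float)
    y = np.asarray(y_ord, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < _MIN_PAIR_N:
        raise EstimationError(f"pair {names}: fewer than {_MIN_PAIR_N} complete observations")
    if tau_y is None:
        tau_y = estimate_thresholds(y, names[1])
    xs = x[~np.isnan(x)]
    mu, sd = xs.mean(), xs.std(ddof=1)
    if sd <= 0:
        raise EstimationError(f"pair {names}: continuous variable is constant")
    z = (x[ok] - mu) / sd
    cat = y[ok].astype(int)

    def nll(rho):
        return float(_polyserial_nll_terms(z, cat, tau_y, float(rho)).sum())

    res = minimize_scalar(nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": RHO_TOL})
    if not res.success:
        raise EstimationError(f"pair {names}: polyserial likelihood maximization "
                              f"failed ({res.message})")
    rho = float(res.x)
    boundary = abs(rho) >= RHO_BOUND - 1e-4
    return CorrEstimate(float(np.clip(rho, -RHO_BOUND, RHO_BOUND)),
                        int(ok.sum()), "polyserial", boundary)


def pearson(x, y, names: tuple[str, str] = ("x", "y")) -> CorrEstimate:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < _MIN_PAIR_N:
        raise EstimationError(f"pair {names}: fewer than {_MIN_PAIR_N} complete observations")
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return CorrEstimate(r, int(ok.sum()), "pearson")


def pairwise_correlation(x, y, x_type: str, y_type: str,
                         names: tuple[str, str] = ("x", "y")) -> CorrEstimate:
    """Dispatch on scale types; symmetric in its arguments."""
    if x_type == ORDINAL3 and y_type == ORDINAL3:
        return polychoric(x, y, names=names)
    if x_type == CONTINUOUS and y_type == CONTINUOUS:
        return pearson(x, y, names=names)
    if x_type == CONTINUOUS:
        return polyserial(x, y, names=names)
    est = polyserial(y, x, names=(names[1], names[0]))
    return CorrEstimate(est.value, est.n, est.method, est.boundary)


# ---------------------------------------------------------------------------
# Full matrix with asymptotic covariance
# ---------------------------------------------------------------------------

@dataclass
class MixedCorrelationResult:
    """Thresholds, moments, mixed correlation matrix and their covariance.

    ``stat_index`` lists the stacked statistics in canonical order:
    ``("tau", item, c)`` for each ordinal item (c = 1, 2), ``("mean", item)``
    then ``("var", item)`` for each continuous item, then ``("corr", a, b)``
    for every item pair (a before b in item order).  ``gamma`` follows the
    same ordering; it is None when covariance estimation was not requested.
    """

    items: list[ItemDef]
    thresholds: dict[str, np.ndarray]
    means: dict[str, float]
    variances: dict[str, float]
    corr: pd.DataFrame
    pair_n: pd.DataFrame
    methods: dict[tuple[str, str], str]
    boundary_pairs: list[tuple[str, str]]
    n: int
    stat_index: list[tuple]
    gamma: np.ndarray | None = None

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    def stat_vector(self) -> np.ndarray:
        vals = []
        R = self.corr.to_numpy()
        pos = {n: i for i, n in enumerate(self.item_names)}
        for key in self.stat_index:
            if key[0] == "tau":
                vals.append(self.thresholds[key[1]][key[2] - 1])
            elif key[0] == "mean":
                vals.append(self.means[key[1]])
            elif key[0] == "var":
                vals.append(self.variances[key[1]])
            else:
                vals.append(R[pos[key[1]], pos[key[2]]])
        return np.array(vals, float)

    def corr_stat_slice(self) -> slice:
        first = next(i for i, k in enumerate(self.stat_index) if k[0] == "corr")
        return slice(first, len(self.stat_index))

    # -- audit serialization ----------------------------------------------
    def write_text(self, path: str | Path) -> None:
        lines = [f"n {self.n}", "# statistic value"]
        s = self.stat_vector()
        for key, v in zip(self.stat_index, s):
            lines.append(" ".join(str(k) for k in key) + f" {v:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


def stat_index_for(items: Sequence[ItemDef]) -> list[tuple]:
    idx: list[tuple] = []
    for it in items:
        if it.scale == ORDINAL3:
            idx.append(("tau", it.name, 1))
            idx.append(("tau", it.name, 2))
    for it in items:
        if it.scale == CONTINUOUS:
            idx.append(("mean", it.name))
    for it in items:
        if it.scale == CONTINUOUS:
            idx.append(("var", it.name))
    names = [it.name for it in items]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            idx.append(("corr", names[i], names[j]))
    return idx


def mixed_correlation_matrix(table: ItemResponseTable,
                             gamma: bool = True) -> MixedCorrelationResult:
    """Estimate the full limited-information statistic set for a table.

    Set ``gamma=False`` to skip the influence-function covariance (useful for
    very large calibration runs where only point estimates are needed).
    """
    items = table.items
    names = table.item_names
    p = len(names)
    X = {it.name: table.responses(it.name) for it in items}

    thresholds: dict[str, np.ndarray] = {}
    means: dict[str, float] = {}
    variances: dict[str, float] = {}
    for it in items:
        x = X[it.name]
        if it.scale == ORDINAL3:
            thresholds[it.name] = estimate_thresholds(x, it.name)
        else:
            obs = x[~np.isnan(x)]
            if obs.std(ddof=1) <= 0:
                raise EstimationError(f"item {it.name!r}: zero variance")
            means[it.name] = float(obs.mean())
            variances[it.name] = float(obs.var(ddof=1))

    R = np.eye(p)
    N = np.full((p, p), table.n)
    methods: dict[tuple[str, str], str] = {}
    boundary: list[tuple[str, str]] = []
    for i in range(p):
        for j in range(i + 1, p):
            a, b = items[i], items[j]
            try:
                if a.scale == ORDINAL3 and b.scale == ORDINAL3:
                    est = polychoric(X[a.name], X[b.name], thresholds[a.name],
                                     thresholds[b.name], names=(a.name, b.name))
                elif a.scale == CONTINUOUS and b.scale == CONTINUOUS:
                    est = pearson(X[a.name], X[b.name], names=(a.name, b.name))
                elif a.scale == CONTINUOUS:
                    est = polyserial(X[a.name], X[b.name], thresholds[b.name],
                                     names=(a.name, b.name))
                else:
                    est = polyserial(X[b.name], X[a.name], thresholds[a.name],
                                     names=(b.name, a.name))
            except EstimationError as exc:
                raise EstimationError(f"pair ({a.name}, {b.name}): {exc}") from exc
            R[i, j] = R[j, i] = est.value
            N[i, j] = N[j, i] = est.n
            methods[(a.name, b.name)] = est.method
            if est.boundary:
                boundary.append((a.name, b.name))

    idx = stat_index_for(items)
    result = MixedCorrelationResult(
        items=list(items), thresholds=thresholds, means=means, variances=variances,
        corr=pd.DataFrame(R, index=names, columns=names),
        pair_n=pd.DataFrame(N, index=names, columns=names),
        methods=methods, boundary_pairs=boundary, n=table.n, stat_index=idx)
    if gamma:
        result.gamma = _influence_gamma(table, result)
    return result


# -- influence functions -----------------------------------------------------

def _threshold_influence(x: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """n x 2 influence columns for the two thresholds (0 where missing)."""
    out = np.zeros((x.size, 2))
    ok = ~np.isnan(x)
    phi = np.exp(-0.5 * tau ** 2) / np.sqrt(2 * np.pi)
    for c in (1, 2):
        pc = ndtr(tau[c - 1])
        out[ok, c - 1] = ((x[ok] <= c).astype(float) - pc) / phi[c - 1]
    return out


def _fd_scores(loglik: Callable[[np.ndarray], np.ndarray], params: np.ndarray,
               h: float = 1e-5) -> np.ndarray:
    """Central-difference per-observation scores, one column per parameter."""
    cols = []
    for k in range(params.size):
        up = params.copy(); up[k] += h
        dn = params.copy(); dn[k] -= h
        cols.append((loglik(up) - loglik(dn)) / (2 * h))
    return np.column_stack(cols)


def _pair_rho_influence(loglik: Callable[[np.ndarray], np.ndarray],
                        params: np.ndarray,
                        nuisance_ifs: np.ndarray) -> np.ndarray:
    """Influence function of a two-step correlation estimate.

    ``loglik(params)`` returns per-(complete)-observation log-likelihood terms
    with params = (rho, nuisance...); ``nuisance_ifs`` holds the influence
    columns of the first-step nuisance estimates over the same observations.
    The first-step correction uses finite-difference derivatives of the mean
    score, so it stays valid away from the exact likelihood optimum.
    """
    scores = _fd_scores(loglik, params)
    s_rho = scores[:, 0]
    m = s_rho.size
    h = 1e-4
    # d(mean score_rho)/d(rho)
    up = params.copy(); up[0] += h
    dn = params.copy(); dn[0] -= h
    a_rr = (_fd_scores(loglik, up, h)[:, 0].mean()
            - _fd_scores(loglik, dn, h)[:, 0].mean()) / (2 * h)
    # d(mean score_rho)/d(nuisance_t)
    a_rt = np.empty(params.size - 1)
    for t in range(1, params.size):
        up = params.copy(); up[t] += h
        dn = params.copy(); dn[t] -= h
        a_rt[t - 1] = (_fd_scores(loglik, up, h)[:, 0].mean()
                       - _fd_scores(loglik, dn, h)[:, 0].mean()) / (2 * h)
    if not np.isfinite(a_rr) or abs(a_rr) < 1e-12:
        raise EstimationError("singular curvature in correlation influence function")
    return -(s_rho + nuisance_ifs @ a_rt) / a_rr


def _influence_gamma(table: ItemResponseTable,
                     res: MixedCorrelationResult) -> np.ndarray:
    n = table.n
    items = res.items
    names = res.item_names
    X = {nm: table.responses(nm) for nm in names}
    obs = {nm: ~np.isnan(X[nm]) for nm in names}

    IF = np.zeros((n, len(res.stat_index)))
    col_of = {key: k for k, key in enumerate(res.stat_index)}

    tau_if: dict[str, np.ndarray] = {}
    mean_if: dict[str, np.ndarray] = {}
    sd_if: dict[str, np.ndarray] = {}
    for it in items:
        x = X[it.name]
        if it.scale == ORDINAL3:
            ti = _threshold_influence(x, res.thresholds[it.name])
            tau_if[it.name] = ti
            IF[:, col_of[("tau", it.name, 1)]] = ti[:, 0]
            IF[:, col_of[("tau", it.name, 2)]] = ti[:, 1]
        else:
            mu = res.means[it.name]
            var = res.variances[it.name]
            mi = np.where(obs[it.name], x - mu, 0.0)
            vi = np.where(obs[it.name], (x - mu) ** 2 - var, 0.0)
            mean_if[it.name] = mi
            sd_if[it.name] = vi / (2 * np.sqrt(var))
            IF[:, col_of[("mean", it.name)]] = mi
            IF[:, col_of[("var", it.name)]] = vi

    Rm = res.corr.to_numpy()
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i], items[j]
            key = ("corr", a.name, b.name)
            ok = obs[a.name] & obs[b.name]
            rho = Rm[i, j]
            if a.scale == ORDINAL3 and b.scale == ORDINAL3:
                xa = X[a.name][ok].astype(int) - 1
                xb = X[b.name][ok].astype(int) - 1
                ta, tb = res.thresholds[a.name], res.thresholds[b.name]

                def loglik(prm, xa=xa, xb=xb):
                    cells = np.log(bvn_cell_probs(prm[1:3], prm[3:5], np.asarray(prm[0])))
                    return cells[xa, xb]

                params = np.array([rho, ta[0], ta[1], tb[0], tb[1]])
                nuis = np.column_stack([tau_if[a.name][ok], tau_if[b.name][ok]])
            elif a.scale == CONTINUOUS and b.scale == CONTINUOUS:
                mu_a, sd_a = res.means[a.name], np.sqrt(res.variances[a.name])
                mu_b, sd_b = res.means[b.name], np.sqrt(res.variances[b.name])
                za = (X[a.name][ok] - mu_a) / sd_a
                zb = (X[b.name][ok] - mu_b) / sd_b
                if_rho = (za * zb - rho
                          - 0.5 * rho * (za ** 2 - 1) - 0.5 * rho * (zb ** 2 - 1))
                IF[np.flatnonzero(ok), col_of[key]] = if_rho
                continue
            else:
                cont, ordn = (a, b) if a.scale == CONTINUOUS else (b, a)
                mu, var = res.means[cont.name], res.variances[cont.name]
                sd = np.sqrt(var)
                xc = X[cont.name][ok]
                cat = X[ordn.name][ok].astype(int)
                tq = res.thresholds[ordn.name]

                def loglik(prm, xc=xc, cat=cat):
                    z = (xc - prm[3]) / prm[4]
                    return -_polyserial_nll_terms(z, cat, prm[1:3], float(prm[0]))

                params = np.array([rho, tq[0], tq[1], mu, sd])
                nuis = np.column_stack([tau_if[ordn.name][ok],
                                        mean_if[cont.name][ok], sd_if[cont.name][ok]])
            if_rho = _pair_rho_influence(loglik, params, nuis)
            IF[np.flatnonzero(ok), col_of[key]] = if_rho

    IF -= IF.mean(axis=0, keepdims=True)
    counts = np.array([_stat_count(k, obs, res) for k in res.stat_index], float)
    gamma = (IF.T @ IF) / np.outer(counts, counts)
    return gamma


def _stat_count(key: tuple, obs: dict, res: MixedCorrelationResult) -> int:
    if key[0] == "corr":
        return int((obs[key[1]] & obs[key[2]]).sum())
    return int(obs[key[1]].sum())


def bootstrap_gamma(table: ItemResponseTable, n_boot: int = 500,
                    seed: int = 0) -> np.ndarray:
    """Nonparametric-bootstrap covariance of the statistic vector (validation
    oracle for the influence-function ``Gamma``)."""
    rng = np.random.default_rng(seed)
    base = mixed_correlation_matrix(table, gamma=False)
    stats = np.empty((n_boot, len(base.stat_index)))
    for b in range(n_boot):
        rows = rng.integers(0, table.n, size=table.n)
        boot = ItemResponseTable(table.data.iloc[rows], table.items,
                                 table.covariates, validate=False)
        stats[b] = mixed_correlation_matrix(boot, gamma=False).stat_vector()
    return np.cov(stats, rowvar=False)


# ---------------------------------------------------------------------------
# Reliability and clustering descriptives
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityResult:
    alpha: float
    item_total: dict[str, float]
    alpha_if_deleted: dict[str, float]


def scale_reliability(table: ItemResponseTable,
                      item_subset: Sequence[str]) -> ReliabilityResult:
    """Cronbach's alpha, item-total correlations and alpha-if-item-deleted.

    Computed on listwise-complete rows of the subset; items are used as
    scored (reverse-keyed items are assumed already re-coded).
    """
    if len(item_subset) < 2:
        raise EstimationError("reliability needs at least two items")
    M = table.data[list(item_subset)].dropna().to_numpy(float)
    if M.shape[0] < 3:
        raise EstimationError("too few listwise-complete rows for reliability")
    total_var = M.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise EstimationError("zero variance of the scale sum")
    k = M.shape[1]
    alpha = k / (k - 1) * (1.0 - M.var(axis=0, ddof=1).sum() / total_var)
    item_total: dict[str, float] = {}
    aid: dict[str, float] = {}
    for j, name in enumerate(item_subset):
        rest = M[:, [c for c in range(k) if c != j]]
        rest_sum = rest.sum(axis=1)
        if rest_sum.var(ddof=1) > 0 and M[:, j].var(ddof=1) > 0:
            item_total[name] = float(np.corrcoef(M[:, j], rest_sum)[0, 1])
        else:
            item_total[name] = np.nan
        rv = rest_sum.var(ddof=1)
        aid[name] = ((k - 1) / (k - 2) * (1.0 - rest.var(axis=0, ddof=1).sum() / rv)
                     if (k > 2 and rv > 0) else np.nan)
    return ReliabilityResult(float(alpha), item_total, aid)


def intraclass_correlation(values, cluster_ids) -> float:
    """One-way random-effects ANOVA ICC(1), truncated below at zero."""
    v = np.asarray(values, float)
    c = np.asarray(cluster_ids)
    ok = ~np.isnan(v)
    v, c = v[ok], c[ok]
    labels, inv = np.unique(c, return_inverse=True)
    if labels.size < 2:
        raise EstimationError("ICC needs at least two clusters")
    counts = np.bincount(inv).astype(float)
    if (counts >= 2).sum() < 2:
        raise EstimationError("ICC needs at least two clusters with two or more members")
    sums = np.bincount(inv, weights=v)
    means = sums / counts
    grand = v.mean()
    n, k = v.size, labels.size
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(np.sum((v - means[inv]) ** 2))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    n0 = (n - np.sum(counts ** 2) / n) / (k - 1)
    icc = (ms_between - ms_within) / (ms_between + (n0 - 1) * ms_within)
    return float(max(icc, 0.0))
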