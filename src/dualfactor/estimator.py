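"""Diagonally weighted least squares estimation of factor models.

The estimator minimizes ``F(theta) = (s - sigma(theta))' W^{-1} (s - sigma(theta))``
where ``s`` stacks the limited-information sample statistics (thresholds,
continuous means/variances, mixed correlations), ``sigma`` is the
model-implied vector, and ``W = diag(Gamma)`` holds the statistics' estimated
variances.  Because margins are saturated in single-group models (free
thresholds, intercepts and variances), they are profiled at their sample
values and the minimization runs over the structural parameters only.

The test statistic is the scaled-and-shifted (mean-and-variance adjusted)
transform of the minimized fit function: with ``U`` the DWLS residual
projector and ``M = U Gamma``,

    T* = sqrt(df / tr(M^2)) * (T - tr(M)) + df,

which matches the first two moments of a chi-square with the model df.
Standard errors use the full sandwich with ``Gamma``.  Continuous-only
models are fitted by normal-theory maximum likelihood on the sample
covariance matrix instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .correlations import MixedCorrelationResult
from .data import CONTINUOUS, ORDINAL3
from .models import (ModelSpec, ModelError, count_parameters, loading_matrix,
                     model_implied_moments, phi_matrix, spec_stat_index)

__all__ = ["FitResult", "fit_model", "fit_indices", "modification_indices",
           "scaled_difference_test", "DifferenceTest"]

_GRAD_TOL = 1e-6
_MAX_ITER = 500
_N_RESTARTS = 3


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    """Estimates, adjusted test statistic and diagnostics of one model fit."""

    spec: ModelSpec
    method: str                     # "dwls" or "ml"
    n: int
    params: dict
    se: dict
    chi2: float                     # adjusted statistic
    df: int
    pvalue: float
    chi2_unscaled: float
    tr_ug: float
    tr_ug2: float
    baseline_chi2: float
    baseline_df: int
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    tli: float
    converged: bool
    n_restarts: int
    gradient_norm: float
    stat_index: list
    sample_stats: np.ndarray
    implied_stats: np.ndarray
    weight_diag: np.ndarray | None = None
    gamma: np.ndarray | None = None
    U: np.ndarray | None = None      # residual projector on the statistic space
    heywood_items: list = field(default_factory=list)
    negative_residuals: dict = field(default_factory=dict)  # item -> (est, se, p)
    zero_residual_items: tuple = ()
    notes: list = field(default_factory=list)

    @property
    def residuals(self) -> np.ndarray:
        return self.sample_stats - self.implied_stats

    def loading(self, item: str, factor: str) -> float:
        return self.params[("lambda", item, factor)]

    def factor_correlation(self, a: str, b: str) -> float:
        if ("phi", a, b) in self.params:
            return self.params[("phi", a, b)]
        return self.params[("phi", b, a)]

    def standardized_loadings(self) -> dict:
        """Completely standardized loadings for every (item, factor) entry."""
        out = {}
        for key, v in self.params.items():
            if key[0] == "lambda":
                out[(key[1], key[2])] = v
        for i, f, v in self.spec.fixed_loadings:
            out[(i, f)] = v
        return out

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "method": self.method,
            "n": self.n,
            "chi2": self.chi2, "df": self.df, "pvalue": self.pvalue,
            "rmsea": self.rmsea, "rmsea_ci": list(self.rmsea_ci),
            "cfi": self.cfi, "tli": self.tli,
            "converged": self.converged,
            "parameters": [
                {"name": "/".join(str(k) for k in key), "estimate": float(v),
                 "se": float(self.se.get(key, np.nan))}
                for key, v in self.params.items()],
            "heywood_items": list(self.heywood_items),
            "notes": list(self.notes),
        }


# ---------------------------------------------------------------------------
# Statistic bookkeeping
# ---------------------------------------------------------------------------

def subset_stats(stats: MixedCorrelationResult, spec: ModelSpec):
    """Sample vector, Gamma and index restricted/reordered to the spec items."""
    missing = set(spec.item_names) - set(stats.item_names)
    if missing:
        raise FitError(f"statistics lack items required by the model: {sorted(missing)}")
    for it in spec.items:
        have = stats.items[stats.item_names.index(it.name)]
        if have.scale != it.scale:
            raise FitError(f"item {it.name!r} is {have.scale} in the data but "
                           f"{it.scale} in the model")
    want = spec_stat_index(spec)
    pos = {key: i for i, key in enumerate(stats.stat_index)}

    def lookup(key):
        if key in pos:
            return pos[key]
        if key[0] == "corr":
            return pos[("corr", key[2], key[1])]
        raise KeyError(key)

    sel = np.array([lookup(k) for k in want])
    s = stats.stat_vector()[sel]
    gamma = stats.gamma[np.ix_(sel, sel)] if stats.gamma is not None else None
    return s, gamma, want


# ---------------------------------------------------------------------------
# Structural parameter vector
# ---------------------------------------------------------------------------

class _Structure:
    """Maps the structural free-parameter vector to implied correlations."""

    def __init__(self, spec: ModelSpec, zero_residual_items: Sequence[str] = ()):
        self.spec = spec
        self.zero = tuple(zero_residual_items)
        self.keys: list[tuple] = []
        self.bounds: list[tuple[float, float]] = []
        gen = spec.general_factor()
        self.start: list[float] = []
        for it_name in self.zero:
            it = spec.item(it_name)
            if it.scale != CONTINUOUS:
                raise ModelError("zero-residual constraints apply to continuous items")
            facs = spec.item_loadings(it_name)
            fpos = [spec.factor_names.index(f) for f in facs]
            # unit-communality constraint needs an orthogonal factor block
            phi_fixed_offdiag = any(
                (a in facs and b in facs) for a, b in spec.phi_free)
            if phi_fixed_offdiag:
                raise ModelError(f"zero-residual constraint on {it_name!r} requires "
                                 "orthogonal factors")
            if len(facs) > 2:
                raise ModelError("zero-residual constraint supports at most two factors")
        for i, f in spec.loadings:
            if i in self.zero:
                continue
            self.keys.append(("lambda", i, f))
            self.bounds.append((-0.995, 0.995))
            if gen is not None and f == gen.name:
                self.start.append(0.5)
            elif spec.item(i).scale == CONTINUOUS and (gen is None):
                self.start.append(0.5)
            else:
                self.start.append(0.3 if gen is not None else 0.5)
        for it_name in self.zero:
            facs = spec.item_loadings(it_name)
            if len(facs) == 2:
                self.keys.append(("angle", it_name))
                self.bounds.append((-np.pi, np.pi))
                self.start.append(np.pi / 4)
            # single-factor item: loading pinned at 1, no free parameter
        for a, b in spec.phi_free:
            self.keys.append(("phi", a, b))
            self.bounds.append((-0.995, 0.995))
            self.start.append(0.0)
        for a, b in spec.residual_pairs:
            self.keys.append(("rtheta", a, b))
            self.bounds.append((-0.9, 0.9))
            self.start.append(0.0)
        self.nI = len(spec.items)
        self._ipos = {it.name: i for i, it in enumerate(spec.items)}
        self._fpos = {f.name: k for k, f in enumerate(spec.factors)}

    @property
    def k(self) -> int:
        return len(self.keys)

    def lambda_phi(self, theta: np.ndarray):
        spec = self.spec
        L = np.zeros((self.nI, len(spec.factors)))
        phi = np.eye(len(spec.factors))
        r: dict[tuple[str, str], float] = {}
        for key, v in zip(self.keys, theta):
            if key[0] == "lambda":
                L[self._ipos[key[1]], self._fpos[key[2]]] = v
            elif key[0] == "phi":
                phi[self._fpos[key[1]], self._fpos[key[2]]] = v
                phi[self._fpos[key[2]], self._fpos[key[1]]] = v
            elif key[0] == "rtheta":
                r[(key[1], key[2])] = v
        for i, f, v in spec.fixed_loadings:
            L[self._ipos[i], self._fpos[f]] = v
        for key, v in zip(self.keys, theta):
            if key[0] == "angle":
                facs = spec.item_loadings(key[1])
                L[self._ipos[key[1]], self._fpos[facs[0]]] = np.cos(v)
                L[self._ipos[key[1]], self._fpos[facs[1]]] = np.sin(v)
        for it_name in self.zero:
            facs = spec.item_loadings(it_name)
            if len(facs) == 1:
                L[self._ipos[it_name], self._fpos[facs[0]]] = 1.0
        return L, phi, r

    def implied_corr_vec(self, theta: np.ndarray, tri: tuple) -> np.ndarray:
        L, phi, r = self.lambda_phi(theta)
        R = L @ phi @ L.T
        for (a, b), v in r.items():
            R[self._ipos[a], self._ipos[b]] += v
            R[self._ipos[b], self._ipos[a]] += v
        return R[tri]

    def communalities(self, theta: np.ndarray) -> np.ndarray:
        L, phi, _ = self.lambda_phi(theta)
        return np.einsum("if,fg,ig->i", L, phi, L)

    def param_dict(self, theta: np.ndarray) -> dict:
        out = dict(zip(self.keys, theta))
        # expand angle parameters into loadings for reporting
        L, _, _ = self.lambda_phi(theta)
        for it_name in self.zero:
            for f in self.spec.item_loadings(it_name):
                out[("lambda", it_name, f)] = L[self._ipos[it_name], self._fpos[f]]
        for key in [k for k in out if k[0] == "angle"]:
            del out[key]
        return out


# ---------------------------------------------------------------------------
# DWLS fit
# ---------------------------------------------------------------------------

def fit_model(spec: ModelSpec, stats: MixedCorrelationResult,
              n: int | None = None, zero_residual_items: Sequence[str] = (),
              mean_variance_adjust: bool = True,
              candidate_mi: bool = False) -> FitResult:
    """Fit a model to limited-information statistics.

    Continuous-only specs are routed to normal-theory maximum likelihood on
    the sample covariance matrix; everything else is DWLS with ``W`` the
    diagonal of ``Gamma``.
    """
    if all(it.scale == CONTINUOUS for it in spec.items):
        return _fit_ml(spec, stats, n=n, zero_residual_items=zero_residual_items)
    if stats.gamma is None:
        raise FitError("DWLS needs the asymptotic covariance of the statistics "
                       "(mixed_correlation_matrix(..., gamma=True))")
    n = stats.n if n is None else n
    s, gamma, stat_index = subset_stats(stats, spec)
    q = len(stat_index)
    corr_sl = slice(next(i for i, k in enumerate(stat_index) if k[0] == "corr"), q)
    w = np.maximum(np.diag(gamma).copy(), 1e-12)
    w_corr = w[corr_sl]
    s_corr = s[corr_sl]

    struct = _Structure(spec, zero_residual_items)
    tri = _tri_indices(spec, stat_index, corr_sl)

    def objective(theta):
        rho = struct.implied_corr_vec(theta, tri)
        e = s_corr - rho
        pen = struct.communalities(theta)
        excess = np.maximum(pen - 0.98, 0.0)
        return float(np.sum(e * e / w_corr) + 1e4 * np.sum(excess ** 2))

    rng = np.random.default_rng(0)
    x0 = np.array(struct.start)
    best = None
    n_restarts = 0
    for attempt in range(_N_RESTARTS + 1):
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=struct.bounds,
                                options={"maxiter": _MAX_ITER, "ftol": 1e-14,
                                         "gtol": _GRAD_TOL})
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        # polish: converged when a restarted quasi-Newton pass cannot improve
        # the fit function (gradient norms scale with n and are no criterion)
        converged = bool(res.success or gnorm < 1e-4)
        for _ in range(3):
            if converged:
                break
            res2 = optimize.minimize(objective, res.x, method="L-BFGS-B",
                                     bounds=struct.bounds,
                                     options={"maxiter": _MAX_ITER,
                                              "ftol": 1e-14, "gtol": _GRAD_TOL})
            improved = res.fun - res2.fun
            if res2.fun <= res.fun:
                res = res2
                gnorm = (float(np.max(np.abs(res.jac)))
                         if res.jac is not None else np.inf)
            converged = bool(res.success or gnorm < 1e-4
                             or improved < 1e-9 * (1.0 + abs(res.fun)))
        if best is None or (converged and not best[2]) or \
                (converged == best[2] and res.fun < best[0].fun):
            best = (res, gnorm, converged)
        if converged:
            break
        n_restarts += 1
        x0 = np.clip(np.array(struct.start)
                     + rng.normal(0, 0.1, struct.k),
                     [b[0] for b in struct.bounds], [b[1] for b in struct.bounds])
    res, gnorm, converged = best
    if not converged:
        raise FitError(f"DWLS minimization did not converge for model "
                       f"{spec.name!r} (gradient max-norm {gnorm:.2e})")
    theta = res.x

    # assemble full parameter set: structural + profiled margins
    params = struct.param_dict(theta)
    se: dict = {}
    for key in stat_index:
        if key[0] == "tau":
            params[("tau", key[1], key[2])] = s[stat_index.index(key)]
        elif key[0] == "mean":
            params[("nu", key[1])] = s[stat_index.index(key)]
        elif key[0] == "var":
            params[("v", key[1])] = s[stat_index.index(key)]
    sigma = s.copy()
    sigma[corr_sl] = struct.implied_corr_vec(theta, tri)
    e_full = s - sigma

    # jacobian of the implied correlations wrt structural parameters
    D = _num_jac(lambda th: struct.implied_corr_vec(th, tri), theta)
    Wc_inv = 1.0 / w_corr
    G = D.T @ (D * Wc_inv[:, None])
    Ginv = np.linalg.pinv(G, rcond=1e-10)
    gamma_corr = gamma[corr_sl, :][:, corr_sl]
    # residual projector on the correlation block
    WD = D * Wc_inv[:, None]
    U_corr = np.diag(Wc_inv) - WD @ Ginv @ WD.T
    U = np.zeros((q, q))
    U[corr_sl, corr_sl.start:] = U_corr

    # sandwich covariance of the structural estimates
    acov = Ginv @ WD.T @ gamma_corr @ WD @ Ginv
    for key, v in zip(struct.keys, np.sqrt(np.maximum(np.diag(acov), 0.0))):
        if key[0] != "angle":
            se[key] = v
    for i, key in enumerate(stat_index):
        if key[0] == "tau":
            se[("tau", key[1], key[2])] = float(np.sqrt(gamma[i, i]))
        elif key[0] == "mean":
            se[("nu", key[1])] = float(np.sqrt(gamma[i, i]))
        elif key[0] == "var":
            se[("v", key[1])] = float(np.sqrt(gamma[i, i]))

    # adjusted test statistic
    pc = count_parameters(spec)
    df = pc.df + len([i for i in zero_residual_items])
    T_u = float(np.sum(e_full[corr_sl] ** 2 / w_corr))
    M = U_corr @ gamma_corr
    tr1 = float(np.trace(M))
    tr2 = float(np.sum(M * M.T))
    chi2 = _adjust(T_u, df, tr1, tr2, mean_variance_adjust)
    pvalue = float(stats_chi2_sf(chi2, df))

    # baseline: independence with free margins
    Tb_u = float(np.sum(s_corr ** 2 / w_corr))
    Mb = np.diag(Wc_inv) @ gamma_corr
    df_b = len(s_corr)
    trb1 = float(np.trace(Mb))
    trb2 = float(np.sum(Mb * Mb.T))
    chi2_b = _adjust(Tb_u, df_b, trb1, trb2, mean_variance_adjust)

    rmsea, ci, cfi, tli = fit_indices(chi2, df, chi2_b, df_b, n)

    heywood = []
    comm = struct.communalities(theta)
    neg = {}
    for i, it in enumerate(spec.items):
        if it.scale == ORDINAL3 and comm[i] >= 1.0:
            heywood.append(it.name)
        if it.scale == CONTINUOUS and it.name not in zero_residual_items:
            psi_std = 1.0 - comm[i] - 0.0
            if psi_std < 0:
                heywood.append(it.name)
                v_tot = params[("v", it.name)]
                neg[it.name] = (psi_std * v_tot, np.nan, np.nan)

    return FitResult(
        spec=spec, method="dwls", n=n, params=params, se=se,
        chi2=chi2, df=df, pvalue=pvalue, chi2_unscaled=T_u,
        tr_ug=tr1, tr_ug2=tr2,
        baseline_chi2=chi2_b, baseline_df=df_b,
        rmsea=rmsea, rmsea_ci=ci, cfi=cfi, tli=tli,
        converged=True, n_restarts=n_restarts, gradient_norm=gnorm,
        stat_index=stat_index, sample_stats=s, implied_stats=sigma,
        weight_diag=w, gamma=gamma, U=U, heywood_items=heywood,
        negative_residuals=neg,
        zero_residual_items=tuple(zero_residual_items))


def _tri_indices(spec: ModelSpec, stat_index, corr_sl) -> tuple:
    ipos = {it.name: i for i, it in enumerate(spec.items)}
    rows, cols = [], []
    for key in stat_index[corr_sl]:
        rows.append(ipos[key[1]])
        cols.append(ipos[key[2]])
    return (np.array(rows), np.array(cols))


def _num_jac(fun, x, h: float = 1e-6) -> np.ndarray:
    f0 = fun(x)
    J = np.empty((f0.size, x.size))
    for k in range(x.size):
        up = x.copy(); up[k] += h
        dn = x.copy(); dn[k] -= h
        J[:, k] = (fun(up) - fun(dn)) / (2 * h)
    return J


def _adjust(T_u: float, df: int, tr1: float, tr2: float,
            mean_variance: bool) -> float:
    if df <= 0:
        return 0.0
    if tr2 <= 0 or tr1 <= 0:
        return max(T_u, 0.0)
    if mean_variance:
        a = np.sqrt(df / tr2)
        return float(max(a * (T_u - tr1) + df, 0.0))
    return float(max(df / tr1 * T_u, 0.0))


def stats_chi2_sf(x: float, df: int) -> float:
    if df <= 0:
        return 1.0
    return float(stats.chi2.sf(x, df))


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------

def fit_indices(chi2: float, df: int, baseline_chi2: float, baseline_df: int,
                n: int):
    """RMSEA (with 90% CI by noncentral chi-square inversion), CFI and TLI.

    RMSEA uses ``n - 1`` in the denominator; the baseline model is
    independence with free margins.
    """
    if df <= 0 or n <= 1:
        return 0.0, (0.0, 0.0), 1.0, 1.0
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    ci = (_rmsea_bound(chi2, df, n, 0.95), _rmsea_bound(chi2, df, n, 0.05))
    num = max(chi2 - df, 0.0)
    den = max(baseline_chi2 - baseline_df, chi2 - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if baseline_df > 0 and baseline_chi2 / baseline_df > 1.0:
        tli = ((baseline_chi2 / baseline_df - chi2 / df)
               / (baseline_chi2 / baseline_df - 1.0))
    else:
        tli = 1.0
    return rmsea, ci, float(cfi), float(tli)


def _rmsea_bound(chi2: float, df: int, n: int, prob: float) -> float:
    """Noncentrality such that P(X <= chi2 | df, nc) = prob, as an RMSEA."""
    if stats.ncx2.cdf(chi2, df, 0.0) < prob:
        return 0.0
    hi = max(chi2 * 2, 10.0)
    while stats.ncx2.cdf(chi2, df, hi) > prob and hi < 1e7:
        hi *= 2
    nc = optimize.brentq(lambda c: stats.ncx2.cdf(chi2, df, c) - prob, 0.0, hi,
                         xtol=1e-8)
    return float(np.sqrt(nc / (df * (n - 1))))


# ---------------------------------------------------------------------------
# Modification indices
# ---------------------------------------------------------------------------

def modification_indices(fit: FitResult, candidates: Sequence[tuple[str, str]] | None = None):
    """Univariate score tests for fixed residual correlations.

    For each candidate pair the statistic is the squared residual-metric
    score divided by its sampling variance under the fitted model
    (``(U Gamma U)`` diagonal), asymptotically chi-square with 1 df; the
    expected parameter change accompanies each index.  Candidates whose score
    variance is numerically singular are skipped with a note.
    """
    if fit.U is None:
        raise FitError("modification indices need a DWLS fit")
    names = fit.spec.item_names
    existing = {frozenset(p) for p in fit.spec.residual_pairs}
    if candidates is None:
        candidates = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]
                      if frozenset((a, b)) not in existing]
    pos = {key: i for i, key in enumerate(fit.stat_index)}
    e = fit.residuals
    w = fit.weight_diag
    UG = fit.U @ fit.gamma
    V = UG @ fit.U.T
    rows = []
    skipped = []
    for a, b in candidates:
        key = ("corr", a, b) if ("corr", a, b) in pos else ("corr", b, a)
        c = pos[key]
        var = V[c, c]
        if var <= 1e-14:
            skipped.append((a, b))
            continue
        score = e[c] / w[c]
        mi = float(score * score / var)
        epc = float(score / fit.U[c, c]) if fit.U[c, c] > 1e-14 else np.nan
        rows.append({"pair": (a, b), "mi": mi, "epc": epc})
    rows.sort(key=lambda r: -r["mi"])
    return rows, skipped


# ---------------------------------------------------------------------------
# Scaled difference testing
# ---------------------------------------------------------------------------

@dataclass
class DifferenceTest:
    delta_chi2: float
    delta_df: int
    pvalue: float
    negative_guarded: bool = False


def scaled_difference_test(fit_restricted: FitResult,
                           fit_full: FitResult) -> DifferenceTest:
    """Satorra-type scaled difference between two nested DWLS fits.

    Both fits must be computed on the same statistic vector.  The unscaled
    difference of fit-function statistics is rescaled using the trace moments
    of the difference of the two residual projectors, then shifted to match a
    chi-square with ``delta_df`` degrees of freedom.  A negative scaled
    difference (a known pathology) is reported as 0 with a flag.
    """
    fr, ff = fit_restricted, fit_full
    if fr.stat_index != ff.stat_index:
        raise FitError("difference test requires fits on the same statistics")
    ddf = fr.df - ff.df
    if ddf < 0:
        raise FitError("restricted model must have more df than the full model")
    if ddf == 0:
        return DifferenceTest(0.0, 0, 1.0)
    if fr.U is None or ff.U is None:
        # unadjusted ML route
        d = max(fr.chi2 - ff.chi2, 0.0)
        return DifferenceTest(d, ddf, stats_chi2_sf(d, ddf))
    D_u = fr.chi2_unscaled - ff.chi2_unscaled
    Ud = fr.U - ff.U
    Md = Ud @ fr.gamma
    trd1 = float(np.trace(Md))
    trd2 = float(np.sum(Md * Md.T))
    guarded = False
    if trd2 <= 0:
        d = 0.0
        guarded = True
    else:
        d = np.sqrt(ddf / trd2) * (D_u - trd1) + ddf
        if d < 0:
            d = 0.0
            guarded = True
    return DifferenceTest(float(d), int(ddf), stats_chi2_sf(float(d), ddf),
                          guarded)


# ---------------------------------------------------------------------------
# Normal-theory ML for continuous-only models
# ---------------------------------------------------------------------------

def _fit_ml(spec: ModelSpec, stats: MixedCorrelationResult,
            n: int | None = None, zero_residual_items: Sequence[str] = ()):
    """Normal-theory ML on the sample covariance matrix (means saturated)."""
    n = stats.n if n is None else n
    names = spec.item_names
    p = len(names)
    sd = np.array([np.sqrt(stats.variances[nm]) for nm in names])
    R = stats.corr.loc[names, names].to_numpy()
    S = R * np.outer(sd, sd)

    keys: list[tuple] = []
    starts: list[float] = []
    bounds: list[tuple] = []
    for i, f in spec.loadings:
        keys.append(("lambda_raw", i, f))
        starts.append(0.7 * sd[names.index(i)])
        bounds.append((-np.inf, np.inf))
    for a, b in spec.phi_free:
        keys.append(("phi", a, b)); starts.append(0.0); bounds.append((-0.99, 0.99))
    for a, b in spec.residual_pairs:
        keys.append(("rtheta", a, b)); starts.append(0.0); bounds.append((-0.9, 0.9))
    zero = set(zero_residual_items)
    for it in spec.items:
        if it.name in zero:
            continue
        keys.append(("psi", it.name))
        starts.append(0.5 * S[names.index(it.name), names.index(it.name)])
        bounds.append((1e-8, np.inf))
    fpos = {f.name: k for k, f in enumerate(spec.factors)}
    ipos = {nm: i for i, nm in enumerate(names)}

    def sigma_of(theta):
        L = np.zeros((p, len(spec.factors)))
        phi = np.eye(len(spec.factors))
        psi = np.zeros(p)
        r = {}
        for key, v in zip(keys, theta):
            if key[0] == "lambda_raw":
                L[ipos[key[1]], fpos[key[2]]] = v
            elif key[0] == "phi":
                phi[fpos[key[1]], fpos[key[2]]] = phi[fpos[key[2]], fpos[key[1]]] = v
            elif key[0] == "psi":
                psi[ipos[key[1]]] = v
            else:
                r[(key[1], key[2])] = v
        for i, f, v in spec.fixed_loadings:
            L[ipos[i], fpos[f]] = v
        Sig = L @ phi @ L.T + np.diag(psi)
        d = np.sqrt(np.maximum(np.diag(Sig), 1e-12))
        for (a, b), v in r.items():
            Sig[ipos[a], ipos[b]] += v * d[ipos[a]] * d[ipos[b]]
            Sig[ipos[b], ipos[a]] = Sig[ipos[a], ipos[b]]
        return Sig

    sign, logdet_S = np.linalg.slogdet(S)

    def fml(theta):
        Sig = sigma_of(theta)
        try:
            c = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            return 1e6
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        inv = np.linalg.inv(Sig)
        return float(logdet + np.sum(inv * S) - logdet_S - p)

    res = optimize.minimize(fml, np.array(starts), method="L-BFGS-B",
                            bounds=[(lo, hi) for lo, hi in bounds],
                            options={"maxiter": _MAX_ITER, "ftol": 1e-14})
    if not res.success and res.fun > 1e-8:
        res2 = optimize.minimize(fml, res.x, method="Nelder-Mead",
                                 options={"maxiter": 5000, "fatol": 1e-12})
        if res2.fun < res.fun:
            res = res2
    theta = res.x
    chi2 = max((n - 1) * res.fun, 0.0)
    pc = count_parameters(spec)
    df = pc.df + len(zero)

    # observed-information standard errors
    H = _num_hess(fml, theta)
    se_vec = np.full(theta.size, np.nan)
    try:
        cov = np.linalg.pinv(0.5 * (n - 1) * H, rcond=1e-10)
        se_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        pass

    params = dict(zip(keys, theta))
    se = dict(zip(keys, se_vec))
    # completely standardized loadings for reporting and downstream indices
    Sig = sigma_of(theta)
    d = np.sqrt(np.diag(Sig))
    for key in list(params):
        if key[0] == "lambda_raw":
            params[("lambda", key[1], key[2])] = params[key] / d[ipos[key[1]]]
    for nm in names:
        params[("nu", nm)] = stats.means[nm]
        params[("v", nm)] = float(Sig[ipos[nm], ipos[nm]])
    for nm in zero:
        params[("psi", nm)] = 0.0

    # baseline: diagonal covariance
    chi2_b = max((n - 1) * float(np.sum(np.log(np.diag(S))) - logdet_S), 0.0)
    df_b = p * (p - 1) // 2
    rmsea, ci, cfi, tli = fit_indices(chi2, df, chi2_b, df_b, n)

    neg = {}
    for key, v in list(params.items()):
        if key[0] == "psi" and v < 0:
            neg[key[1]] = (v, se.get(key, np.nan), np.nan)

    want = spec_stat_index(spec)
    s_vec = np.array([_ml_stat(k, stats, R, names) for k in want])
    sigma_vec = np.array([_ml_stat(k, stats, _cov2corr(Sig), names,
                                   Sig=Sig, ipos=ipos) for k in want])

    return FitResult(
        spec=spec, method="ml", n=n, params=params, se=se,
        chi2=float(chi2), df=df, pvalue=stats_chi2_sf(float(chi2), df),
        chi2_unscaled=float(chi2), tr_ug=float(df), tr_ug2=float(df),
        baseline_chi2=float(chi2_b), baseline_df=df_b,
        rmsea=rmsea, rmsea_ci=ci, cfi=cfi, tli=tli,
        converged=bool(res.success or res.fun < 1e-8),
        n_restarts=0, gradient_norm=np.nan,
        stat_index=want, sample_stats=s_vec, implied_stats=sigma_vec,
        negative_residuals=neg, zero_residual_items=tuple(zero))


def _cov2corr(Sig):
    d = np.sqrt(np.diag(Sig))
    return Sig / np.outer(d, d)


def _ml_stat(key, stats, R, names, Sig=None, ipos=None):
    if key[0] == "mean":
        return stats.means[key[1]]
    if key[0] == "var":
        return Sig[ipos[key[1]], ipos[key[1]]] if Sig is not None else stats.variances[key[1]]
    i, j = names.index(key[1]), names.index(key[2])
    return R[i, j]


def _num_hess(fun, x, h: float = 1e-4) -> np.ndarray:
    k = x.size
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * h * h)
    return H


def ml_modification_indices(fit: FitResult,
                            candidates: Sequence[tuple[str, str]] | None = None):
    """Score-test modification indices for residual covariances, ML route."""
    spec = fit.spec
    names = spec.item_names
    existing = {frozenset(p) for p in spec.residual_pairs}
    if candidates is None:
        candidates = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]
                      if frozenset((a, b)) not in existing]
    rows = []
    for a, b in candidates:
        ext = ModelSpec(spec.items, spec.factors, list(spec.loadings),
                        list(spec.phi_free), list(spec.residual_pairs) + [(a, b)],
                        spec.kind, spec.name, list(spec.fixed_loadings))
        mi = _ml_score_test(fit, ext)
        rows.append({"pair": (a, b), "mi": mi, "epc": np.nan})
    rows.sort(key=lambda r: -r["mi"])
    return rows, []


def _ml_score_test(fit: FitResult, ext_spec: ModelSpec) -> float:
    # refit-free score test via one Newton step is fragile; use the likelihood
    # ratio against a one-step refit, which is asymptotically equivalent
    from .correlations import MixedCorrelationResult  # circular-safe
    stats_obj = _StatsShim(fit)
    new = _fit_ml(ext_spec, stats_obj, n=fit.n,
                  zero_residual_items=fit.zero_residual_items)
    return max(fit.chi2 - new.chi2, 0.0)


class _StatsShim:
    """Minimal stats view reconstructed from a continuous-only fit."""

    def __init__(self, fit: FitResult):
        import pandas as pd
        names = fit.spec.item_names
        self.n = fit.n
        self.items = fit.spec.items
        self.item_names = names
        self.means = {nm: fit.params[("nu", nm)] for nm in names}
        p = len(names)
        R = np.eye(p)
        pos = {k: i for i, k in enumerate(fit.stat_index)}
        self.variances = {}
        for key, i in pos.items():
            if key[0] == "corr":
                a, b = names.index(key[1]), names.index(key[2])
                R[a, b] = R[b, a] = fit.sample_stats[i]
            elif key[0] == "var":
                self.variances[key[1]] = fit.sample_stats[i]
        self.corr = pd.DataFrame(R, index=names, columns=names)
        self.gamma = None
        self.stat_index = fit.stat_index

    def stat_vector(self):
        raise NotImplementedError
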