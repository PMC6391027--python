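"""Multigroup measurement invariance for mixed ordinal/continuous models.

The three-step sequence for categorical indicators:

1. *Baseline* models fitted in each group separately.
2. *Configural*: the same structure in both groups with all loadings,
   thresholds and intercepts free per group (scale factors fixed at 1 and
   factor means at 0 in both groups) — statistically identical to the two
   separate fits, combined into one joint statistic space.
3. *Scalar*: loadings and thresholds/intercepts equated across groups; in
   exchange the second group receives free factor means, free factor
   variances, and free scale (delta) factors for its ordinal items.

Scalar-vs-configural comparison uses the scaled difference test; on
rejection a partial-invariance search frees the loading+threshold block of
the item with the largest (block) modification index until the difference
test is non-significant or a cap is reached.  The module also implements the
policy for inadmissible negative residual variances (fix to zero when
non-significant, fail loudly otherwise) and latent-factor associations with
binary covariates, estimated as the second group's factor-mean differences
under full scalar invariance — the two-group equivalent of regressing each
factor on the binary covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as spstats

from .correlations import MixedCorrelationResult, mixed_correlation_matrix
from .data import CONTINUOUS, ORDINAL3, ItemResponseTable
from .estimator import (DifferenceTest, FitError, FitResult, _num_jac,
                        _adjust, fit_indices, fit_model, scaled_difference_test,
                        stats_chi2_sf, subset_stats)
from .models import ModelSpec, spec_stat_index

__all__ = ["InvarianceResult", "CovariateAssociation", "invariance_sequence",
           "partial_invariance_search", "fix_negative_residual",
           "covariate_association", "fit_configural", "fit_scalar"]


# ---------------------------------------------------------------------------
# Scalar (and partially-invariant) two-group model
# ---------------------------------------------------------------------------

class _ScalarModel:
    """Joint two-group model with loadings/thresholds/intercepts equated.

    ``freed`` items keep group-specific measurement parameters (their group-2
    scale factor is fixed back to 1); ``zero_psi`` pins continuous residual
    variances of specific (item, group) pairs at zero.
    """

    def __init__(self, spec: ModelSpec, stats: Sequence[MixedCorrelationResult],
                 freed: Sequence[str] = (), zero_psi: Sequence[tuple] = ()):
        self.spec = spec
        self.stats = list(stats)
        if len(self.stats) != 2:
            raise FitError("scalar invariance model needs exactly two groups")
        self.freed = tuple(freed)
        self.zero_psi = frozenset(zero_psi)
        self.single_index = spec_stat_index(spec)
        self.stat_index = [(g,) + key for g in (0, 1) for key in self.single_index]
        self._prep()

    def _prep(self):
        spec = self.spec
        self.s_list, self.g_list = [], []
        for st in self.stats:
            s, g, _ = subset_stats(st, spec)
            self.s_list.append(s)
            self.g_list.append(g)
        self.s = np.concatenate(self.s_list)
        q = len(self.single_index)
        self.gamma = np.zeros((2 * q, 2 * q))
        self.gamma[:q, :q] = self.g_list[0]
        self.gamma[q:, q:] = self.g_list[1]
        self.w = np.maximum(np.diag(self.gamma), 1e-12)

        ipos = {it.name: i for i, it in enumerate(spec.items)}
        fpos = {f.name: k for k, f in enumerate(spec.factors)}
        self._ipos, self._fpos = ipos, fpos
        sidx = {key: i for i, key in enumerate(self.single_index)}
        self._sidx = sidx

        keys: list[tuple] = []
        starts: list[float] = []
        bounds: list[tuple] = []
        freed = set(self.freed)

        def add(key, start, lo, hi):
            keys.append(key); starts.append(start); bounds.append((lo, hi))

        gen = spec.general_factor()
        for i, f in spec.loadings:
            it = spec.item(i)
            lam0 = 0.5 if (gen is None or f == gen.name) else 0.3
            if i in freed:
                for g in (0, 1):
                    if it.scale == ORDINAL3:
                        add(("lambda", i, f, g), lam0, -0.995, 0.995)
                    else:
                        sd_g = np.sqrt(self.stats[g].variances[i])
                        add(("lambda_raw", i, f, g), lam0 * sd_g, -np.inf, np.inf)
            else:
                if it.scale == ORDINAL3:
                    add(("lambda", i, f), lam0, -0.995, 0.995)
                else:
                    sd0 = np.sqrt(self.stats[0].variances[i])
                    add(("lambda_raw", i, f), lam0 * sd0, -np.inf, np.inf)
        for it in spec.ordinal_items:
            tau = [self.stats[g].thresholds[it.name] for g in (0, 1)]
            if it.name in freed:
                for g in (0, 1):
                    add(("tau", it.name, 1, g), tau[g][0], -4, 4)
                    add(("tau", it.name, 2, g), tau[g][1], -4, 4)
            else:
                add(("tau", it.name, 1), 0.5 * (tau[0][0] + tau[1][0]), -4, 4)
                add(("tau", it.name, 2), 0.5 * (tau[0][1] + tau[1][1]), -4, 4)
                add(("delta", it.name), 1.0, 0.2, 5.0)
        for it in spec.continuous_items:
            mu = [self.stats[g].means[it.name] for g in (0, 1)]
            if it.name in freed:
                for g in (0, 1):
                    add(("nu", it.name, g), mu[g], -np.inf, np.inf)
            else:
                add(("nu", it.name), 0.5 * (mu[0] + mu[1]), -np.inf, np.inf)
            for g in (0, 1):
                if (it.name, g) not in self.zero_psi:
                    add(("psi", it.name, g),
                        0.5 * self.stats[g].variances[it.name], 1e-6, np.inf)
        for a, b in spec.phi_free:
            for g in (0, 1):
                add(("phi", a, b, g), 0.0, -0.995, 0.995)
        for f in spec.factors:
            add(("phivar", f.name), 1.0, 0.05, 20.0)
            add(("alpha", f.name), 0.0, -5.0, 5.0)
        for a, b in spec.residual_pairs:
            for g in (0, 1):
                add(("rtheta", a, b, g), 0.0, -0.9, 0.9)
        self.keys, self.starts, self.bounds = keys, starts, bounds
        self.kpos = {k: i for i, k in enumerate(keys)}

    @property
    def n_free(self) -> int:
        return len(self.keys)

    @property
    def df(self) -> int:
        return len(self.stat_index) - self.n_free

    # -- implied statistics ------------------------------------------------
    def sigma(self, theta: np.ndarray, deviations: Mapping | None = None) -> np.ndarray:
        spec = self.spec
        ipos, fpos = self._ipos, self._fpos
        nI, nF = len(spec.items), len(spec.factors)
        pv = dict(zip(self.keys, theta))
        dev = dict(deviations or {})
        freed = set(self.freed)

        out = np.empty(len(self.stat_index))
        for g in (0, 1):
            # factor covariance
            phi = np.eye(nF)
            dvar = np.ones(nF)
            if g == 1:
                for f in spec.factors:
                    dvar[fpos[f.name]] = pv[("phivar", f.name)]
            for a, b in spec.phi_free:
                r = pv[("phi", a, b, g)]
                phi[fpos[a], fpos[b]] = phi[fpos[b], fpos[a]] = r
            phi = phi * np.sqrt(np.outer(dvar, dvar))
            alpha = np.zeros(nF)
            if g == 1:
                for f in spec.factors:
                    alpha[fpos[f.name]] = pv[("alpha", f.name)]

            # loading rows (common metric) and per-item scale handling
            L = np.zeros((nI, nF))
            for i, f in spec.loadings:
                it = spec.item(i)
                if i in freed:
                    key = (("lambda", i, f, g) if it.scale == ORDINAL3
                           else ("lambda_raw", i, f, g))
                else:
                    key = (("lambda", i, f) if it.scale == ORDINAL3
                           else ("lambda_raw", i, f))
                L[ipos[i], fpos[f]] = pv[key]
                if g == 1 and ("dlambda", i, f) in dev:
                    L[ipos[i], fpos[f]] += dev[("dlambda", i, f)]
            for i, f, v in spec.fixed_loadings:
                L[ipos[i], fpos[f]] = v

            cov = L @ phi @ L.T
            sd = np.empty(nI)
            for it in spec.items:
                i = ipos[it.name]
                if it.scale == ORDINAL3:
                    if it.name in freed or g == 0:
                        sd[i] = 1.0
                    else:
                        sd[i] = 1.0 / pv[("delta", it.name)]
                else:
                    psi = (0.0 if (it.name, g) in self.zero_psi
                           else pv[("psi", it.name, g)])
                    sd[i] = np.sqrt(max(cov[i, i] + psi, 1e-10))
            R = cov / np.outer(sd, sd)
            for a, b in spec.residual_pairs:
                r = pv[("rtheta", a, b, g)]
                R[ipos[a], ipos[b]] += r
                R[ipos[b], ipos[a]] += r

            base = g * len(self.single_index)
            for key in self.single_index:
                j = base + self._sidx[key]
                if key[0] == "tau":
                    it_name, c = key[1], key[2]
                    i = ipos[it_name]
                    if it_name in freed:
                        out[j] = pv[("tau", it_name, c, g)]
                    else:
                        tau = pv[("tau", it_name, c)]
                        if g == 0:
                            out[j] = tau
                        else:
                            val = (tau - L[i] @ alpha) / sd[i]
                            if ("dtau", it_name, c) in dev:
                                val += dev[("dtau", it_name, c)]
                            out[j] = val
                elif key[0] == "mean":
                    it_name = key[1]
                    i = ipos[it_name]
                    nu = pv[("nu", it_name, g)] if it_name in freed else pv[("nu", it_name)]
                    val = nu + L[i] @ alpha
                    if g == 1 and ("dnu", it_name) in dev:
                        val += dev[("dnu", it_name)]
                    out[j] = val
                elif key[0] == "var":
                    i = ipos[key[1]]
                    out[j] = sd[i] ** 2
                else:
                    out[j] = R[ipos[key[1]], ipos[key[2]]]
        return out

    # -- fitting -----------------------------------------------------------
    def fit(self, x0: np.ndarray | None = None, label: str = "scalar") -> FitResult:
        from scipy import optimize

        winv = 1.0 / self.w

        def objective(theta):
            e = self.s - self.sigma(theta)
            return float(np.sum(e * e * winv))

        x0 = np.array(self.starts) if x0 is None else np.asarray(x0, float)
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=self.bounds,
                                options={"maxiter": 2000, "ftol": 1e-14,
                                         "gtol": 1e-7})
        gnorm = float(np.max(np.abs(res.jac)))
        if not (res.success or gnorm < 1e-2):
            raise FitError(f"{label} invariance model did not converge "
                           f"(gradient max-norm {gnorm:.2e})")
        theta = res.x
        sigma = self.sigma(theta)
        e = self.s - sigma
        T_u = float(np.sum(e * e * winv))

        D = _num_jac(self.sigma, theta)
        WD = D * winv[:, None]
        G = D.T @ WD
        Ginv = np.linalg.pinv(G, rcond=1e-10)
        U = np.diag(winv) - WD @ Ginv @ WD.T
        M = U @ self.gamma
        tr1 = float(np.trace(M))
        tr2 = float(np.sum(M * M.T))
        df = self.df
        chi2 = _adjust(T_u, df, tr1, tr2, True)

        acov = Ginv @ WD.T @ self.gamma @ WD @ Ginv
        se = dict(zip(self.keys, np.sqrt(np.maximum(np.diag(acov), 0.0))))
        params = dict(zip(self.keys, theta))

        # negative-residual diagnostics for continuous items
        neg = {}
        for key, v in params.items():
            if key[0] == "psi" and v <= 2e-6:
                # parameter pinned at its lower bound: treat the unconstrained
                # estimate via the residual-metric score direction
                neg[(key[1], key[2])] = (v, se.get(key, np.nan), np.nan)

        n_total = sum(st.n for st in self.stats)
        chi2_b, df_b = self._baseline()
        rmsea, ci, cfi, tli = fit_indices(chi2, df, chi2_b, df_b, n_total)

        fit = FitResult(
            spec=self.spec, method="dwls-multigroup", n=n_total,
            params=params, se=se, chi2=chi2, df=df,
            pvalue=stats_chi2_sf(chi2, df), chi2_unscaled=T_u,
            tr_ug=tr1, tr_ug2=tr2, baseline_chi2=chi2_b, baseline_df=df_b,
            rmsea=rmsea, rmsea_ci=ci, cfi=cfi, tli=tli,
            converged=True, n_restarts=0, gradient_norm=gnorm,
            stat_index=list(self.stat_index), sample_stats=self.s,
            implied_stats=sigma, weight_diag=self.w, gamma=self.gamma, U=U,
            negative_residuals=neg,
            notes=[f"freed items: {list(self.freed)}"] if self.freed else [])
        fit.model = self  # refit handle for policies/search
        fit.theta = theta
        return fit

    def _baseline(self):
        q = len(self.single_index)
        corr_mask = np.array([key[0] == "corr" for key in self.single_index] * 2)
        winv = 1.0 / self.w
        e = np.where(corr_mask, self.s, 0.0)
        T_b = float(np.sum(e * e * winv))
        Ub = np.diag(np.where(corr_mask, winv, 0.0))
        Mb = Ub @ self.gamma
        df_b = int(corr_mask.sum())
        return _adjust(T_b, df_b, float(np.trace(Mb)), float(np.sum(Mb * Mb.T)),
                       True), df_b


# ---------------------------------------------------------------------------
# Configural model: two separate fits on a joint statistic space
# ---------------------------------------------------------------------------

def fit_configural(spec: ModelSpec, stats: Sequence[MixedCorrelationResult]) -> FitResult:
    """Fit the configural model: identical structure, all parameters free per
    group.  Computed as two single-group fits and assembled on the stacked
    statistic space so that difference tests against the scalar model are
    well defined."""
    fits = [fit_model(spec, st) for st in stats]
    q = len(fits[0].stat_index)
    stat_index = [(g,) + key for g in (0, 1) for key in fits[0].stat_index]
    s = np.concatenate([f.sample_stats for f in fits])
    sigma = np.concatenate([f.implied_stats for f in fits])
    gamma = np.zeros((2 * q, 2 * q))
    U = np.zeros((2 * q, 2 * q))
    for g, f in enumerate(fits):
        sl = slice(g * q, (g + 1) * q)
        gamma[sl, sl] = f.gamma
        U[sl, sl] = f.U
    T_u = sum(f.chi2_unscaled for f in fits)
    tr1 = sum(f.tr_ug for f in fits)
    tr2 = sum(f.tr_ug2 for f in fits)
    df = sum(f.df for f in fits)
    chi2 = _adjust(T_u, df, tr1, tr2, True)
    chi2_b = sum(f.baseline_chi2 for f in fits)
    df_b = sum(f.baseline_df for f in fits)
    n_total = sum(f.n for f in fits)
    rmsea, ci, cfi, tli = fit_indices(chi2, df, chi2_b, df_b, n_total)
    params = {}
    se = {}
    for g, f in enumerate(fits):
        for k, v in f.params.items():
            params[k + (g,)] = v
        for k, v in f.se.items():
            se[k + (g,)] = v
    out = FitResult(
        spec=spec, method="dwls-configural", n=n_total, params=params, se=se,
        chi2=chi2, df=df, pvalue=stats_chi2_sf(chi2, df), chi2_unscaled=T_u,
        tr_ug=tr1, tr_ug2=tr2, baseline_chi2=chi2_b, baseline_df=df_b,
        rmsea=rmsea, rmsea_ci=ci, cfi=cfi, tli=tli, converged=True,
        n_restarts=sum(f.n_restarts for f in fits),
        gradient_norm=max(f.gradient_norm for f in fits),
        stat_index=stat_index, sample_stats=s, implied_stats=sigma,
        weight_diag=np.maximum(np.diag(gamma), 1e-12), gamma=gamma, U=U)
    out.group_fits = fits
    return out


def fit_scalar(spec: ModelSpec, stats: Sequence[MixedCorrelationResult],
               freed: Sequence[str] = (), zero_psi: Sequence[tuple] = (),
               x0: np.ndarray | None = None) -> FitResult:
    return _ScalarModel(spec, stats, freed=freed, zero_psi=zero_psi).fit(x0)


# ---------------------------------------------------------------------------
# Invariance sequence and partial search
# ---------------------------------------------------------------------------

@dataclass
class InvarianceResult:
    group_labels: list
    baselines: list
    configural: FitResult
    scalar: FitResult
    scalar_test: DifferenceTest
    final: FitResult
    final_test: DifferenceTest
    freed_items: list
    search_trail: list
    verdict: str                       # full | partial | rejected
    applied_fixes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        rows = []
        for f, lab in zip(self.baselines, [f"baseline[{g}]" for g in self.group_labels]):
            rows.append({"model": lab, "chi2": f.chi2, "df": f.df,
                         "rmsea": f.rmsea, "cfi": f.cfi, "tli": f.tli})
        for f, lab in ((self.configural, "configural"), (self.scalar, "scalar"),
                       (self.final, "final")):
            rows.append({"model": lab, "chi2": f.chi2, "df": f.df,
                         "rmsea": f.rmsea, "cfi": f.cfi, "tli": f.tli})
        return {"groups": list(map(str, self.group_labels)), "fits": rows,
                "scalar_test": vars(self.scalar_test),
                "final_test": vars(self.final_test),
                "freed_items": list(self.freed_items),
                "verdict": self.verdict,
                "applied_fixes": list(self.applied_fixes)}


def invariance_sequence(spec: ModelSpec, table: ItemResponseTable,
                        group_variable: str, level: float = 0.05,
                        min_group_n: int = 100, max_freed: int = 3,
                        baselines: bool = True) -> InvarianceResult:
    """Run the three-step invariance procedure for a binary grouping variable."""
    groups = table.split_by(group_variable)
    labels = sorted(groups)
    if len(labels) != 2:
        raise FitError(f"invariance testing needs exactly two groups; "
                       f"{group_variable!r} has {len(labels)}")
    for lab in labels:
        if groups[lab].n < min_group_n:
            raise FitError(f"group {group_variable}={lab} has only {groups[lab].n} "
                           f"rows (minimum {min_group_n})")
    stats = [mixed_correlation_matrix(groups[lab]) for lab in labels]
    base_fits = [fit_model(spec, st) for st in stats] if baselines else []
    configural = fit_configural(spec, stats)
    scalar = fit_scalar(spec, stats)
    test = scaled_difference_test(scalar, configural)

    freed: list[str] = []
    trail: list[dict] = []
    final, final_test = scalar, test
    verdict = "full"
    if test.pvalue < level:
        freed, final, final_test, trail = partial_invariance_search(
            scalar, configural, level=level, max_freed=max_freed)
        verdict = "partial" if final_test.pvalue >= level else "rejected"

    fixes = []
    neg = _significant_negative_psi(final)
    if neg:
        final, fixes = fix_negative_residual(final, level=level)
        final_test = scaled_difference_test(final, configural)

    return InvarianceResult(labels, base_fits, configural, scalar, test,
                            final, final_test, freed, trail, verdict, fixes)


def _item_deviation_keys(spec: ModelSpec, item: str) -> list[tuple]:
    it = spec.item(item)
    keys = []
    if it.scale == ORDINAL3:
        keys += [("dtau", item, 1), ("dtau", item, 2)]
    else:
        keys += [("dnu", item)]
    keys += [("dlambda", item, f) for f in spec.item_loadings(item)]
    return keys


def invariance_modification_indices(fit: FitResult) -> list[dict]:
    """Block score test per still-invariant item of a scalar-model fit.

    For each item the candidate directions are group-2 deviations of its
    thresholds (or intercept) and loadings around the equality constraint;
    the block statistic is the quadratic form of the residual-metric scores
    in the inverse of their sampling covariance (directions already spanned
    by free parameters, such as the item's scale factor, contribute zero
    through the projector and are absorbed by the pseudo-inverse)."""
    model: _ScalarModel = fit.model
    theta = fit.theta
    e = fit.residuals
    winv = 1.0 / fit.weight_diag
    UG = fit.U @ fit.gamma
    V_full = UG @ fit.U.T
    rows = []
    for it in model.spec.items:
        if it.name in model.freed:
            continue
        keys = _item_deviation_keys(model.spec, it.name)
        D = np.empty((len(model.stat_index), len(keys)))
        for c, key in enumerate(keys):
            h = 1e-5
            up = model.sigma(theta, {key: h})
            dn = model.sigma(theta, {key: -h})
            D[:, c] = (up - dn) / (2 * h)
        score = D.T @ (winv * e)
        V = D.T @ V_full @ D
        Vinv = np.linalg.pinv(V, rcond=1e-8)
        mi = float(score @ Vinv @ score)
        rows.append({"item": it.name, "mi": mi,
                     "rank": int(np.linalg.matrix_rank(V, tol=1e-8))})
    rows.sort(key=lambda r: (-r["mi"], r["item"]))
    return rows


def partial_invariance_search(scalar_fit: FitResult, configural_fit: FitResult,
                              level: float = 0.05, max_freed: int = 3):
    """Iteratively free the most non-invariant item until the scaled
    difference versus the configural model is non-significant.

    Ties in the modification index break toward the item earlier in the
    model's item order.  Returns (freed items, final fit, final test, trail).
    """
    model: _ScalarModel = scalar_fit.model
    item_order = {nm: i for i, nm in enumerate(model.spec.item_names)}
    freed: list[str] = list(model.freed)
    fit = scalar_fit
    test = scaled_difference_test(fit, configural_fit)
    trail: list[dict] = []
    while test.pvalue < level and len(freed) < max_freed:
        mis = invariance_modification_indices(fit)
        if not mis:
            break
        best_mi = mis[0]["mi"]
        candidates = [r["item"] for r in mis if abs(r["mi"] - best_mi) < 1e-9]
        pick = min(candidates, key=lambda nm: item_order[nm])
        freed.append(pick)
        fit = fit_scalar(model.spec, model.stats, freed=freed,
                         zero_psi=model.zero_psi)
        test = scaled_difference_test(fit, configural_fit)
        trail.append({"freed": pick, "mi": best_mi,
                      "delta_chi2": test.delta_chi2, "delta_df": test.delta_df,
                      "pvalue": test.pvalue})
    return freed, fit, test, trail


# ---------------------------------------------------------------------------
# Negative residual variance policy
# ---------------------------------------------------------------------------

def _psi_estimate_unbounded(fit: FitResult, item: str, g: int):
    """Unconstrained estimate and SE of a continuous residual variance.

    The fitted model bounds psi below at ~0, so a Heywood case surfaces as a
    parameter pinned at the bound; the one-step unconstrained estimate from
    the residual-metric score gives its signed magnitude and a sandwich SE."""
    model: _ScalarModel = fit.model
    key = ("psi", item, g)
    k = model.kpos[key]
    theta = fit.theta
    h = 1e-4
    up = theta.copy(); up[k] += h
    dn = theta.copy(); dn[k] -= h
    d = (model.sigma(up) - model.sigma(dn)) / (2 * h)
    winv = 1.0 / fit.weight_diag
    e = fit.residuals
    num = float(d @ (winv * e))
    den = float(d @ (winv * d))
    step = num / den if den > 0 else 0.0
    est = fit.params[key] + step
    se = fit.se.get(key, np.nan)
    return est, se


def _significant_negative_psi(fit: FitResult) -> list[tuple]:
    return [k for k in getattr(fit, "negative_residuals", {})]


def fix_negative_residual(fit: FitResult, level: float = 0.05):
    """Apply the fix-to-zero policy for negative continuous residual variances.

    For each continuous residual variance whose unconstrained estimate is
    negative: if it is non-significant at ``level`` the model is refitted
    with that variance fixed at zero and the fix recorded; a *significant*
    negative variance is a misspecification signal and raises.  A fit with
    no negative residual variances passes through unchanged.
    """
    model = getattr(fit, "model", None)
    if model is None:
        raise FitError("fix_negative_residual needs a multigroup fit handle")
    offenders = []
    for (item, g) in list(fit.negative_residuals):
        est, se = _psi_estimate_unbounded(fit, item, g)
        if est >= 0:
            continue
        z = est / se if (se and np.isfinite(se) and se > 0) else 0.0
        p = 2 * spstats.norm.sf(abs(z))
        if p < level:
            raise FitError(
                f"residual variance of {item!r} in group {g} is significantly "
                f"negative (estimate {est:.3f}, p = {p:.3g}): model misspecification")
        offenders.append({"item": item, "group": g, "estimate": est,
                          "se": se, "pvalue": p})
    if not offenders:
        return fit, []
    zero = set(model.zero_psi) | {(o["item"], o["group"]) for o in offenders}
    new = fit_scalar(model.spec, model.stats, freed=model.freed, zero_psi=zero)
    new.notes.append("residual variances fixed to zero: "
                     + ", ".join(f"{o['item']}[g{o['group']}]" for o in offenders))
    return new, offenders


# ---------------------------------------------------------------------------
# Covariate associations
# ---------------------------------------------------------------------------

@dataclass
class CovariateAssociation:
    factor: str
    covariate: str
    coefficient: float        # group-difference in reference-group factor SD
    standardized: float       # correlation-metric association
    se: float
    pvalue: float
    significant: bool


def covariate_association(spec: ModelSpec, table: ItemResponseTable,
                          covariate: str, level: float = 0.05,
                          ) -> list[CovariateAssociation]:
    """Latent-factor associations with one binary covariate.

    Fits the scalar-invariant two-group model split by the covariate; the
    second group's factor-mean differences are the (probit-equivalent)
    regression coefficients of each factor on the covariate, expressed in
    reference-group factor-SD units.  The standardized value rescales by the
    covariate SD and the marginal factor SD.
    """
    groups = table.split_by(covariate)
    labels = sorted(groups)
    if len(labels) != 2:
        raise FitError(f"covariate {covariate!r} must be binary; "
                       f"found {len(labels)} levels")
    if any(groups[lab].n < 30 for lab in labels):
        raise FitError(f"covariate {covariate!r} has a level with too few rows")
    stats = [mixed_correlation_matrix(groups[lab]) for lab in labels]
    fit = fit_scalar(spec, stats)
    if fit.negative_residuals:
        fit, _ = fix_negative_residual(fit, level=level)
    p1 = groups[labels[1]].n / table.n
    out = []
    for f in spec.factors:
        a = fit.params[("alpha", f.name)]
        se = fit.se.get(("alpha", f.name), np.nan)
        var2 = fit.params[("phivar", f.name)]
        var_marg = (1 - p1) * 1.0 + p1 * var2 + p1 * (1 - p1) * a * a
        std = a * np.sqrt(p1 * (1 - p1)) / np.sqrt(var_marg)
        z = a / se if (se and np.isfinite(se) and se > 0) else np.nan
        p = 2 * spstats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        out.append(CovariateAssociation(f.name, covariate, float(a), float(std),
                                        float(se), float(p),
                                        bool(np.isfinite(p) and p < level)))
    return out
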