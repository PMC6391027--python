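"""End-to-end orchestration of the dual-factor measurement analysis.

``run_paper_pipeline`` executes the full sequence on one item-response
table: instrument-level CFAs with modification-index screening of
whitelisted residual pairs, reliability descriptives, sum-score
descriptives, the four competing structural models with scaled difference
tests, bifactor dimensionality indices, multigroup invariance for the
binary covariates, and covariate associations on the invariant reduced
models.  Every numeric cell in the report is produced by a stage of the
library; rerunning on identical inputs yields a bit-identical report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .correlations import (intraclass_correlation, mixed_correlation_matrix,
                           scale_reliability)
from .data import CONTINUOUS, ORDINAL3, DataError, ItemResponseTable
from .dimensionality import dimensionality_report
from .estimator import (fit_model, ml_modification_indices,
                        modification_indices, scaled_difference_test)
from .invariance import covariate_association, invariance_sequence
from .models import build_model, count_parameters, drop_items

_ROUND = 3


@dataclass
class PipelineOptions:
    residual_pair_whitelist: list = field(default_factory=list)
    mi_threshold: float = 10.0
    exclude_items: list = field(default_factory=list)
    invariance_groups: list = field(default_factory=lambda: ["gender", "income"])
    level: float = 0.05
    s1_reference: str = "internalising"
    run_invariance: bool = True
    run_associations: bool = True


def descriptives(table: ItemResponseTable) -> dict:
    """Sum-score descriptives and observed correlations, by domain.

    Sum scores use rows complete for all items of that scale (no
    imputation); binary covariates enter the correlation matrix directly, so
    their entries are point-biserial correlations.
    """
    blocks = {}
    sums = {}
    for domain in table.domains():
        names = [it.name for it in table.items_in_domain(domain)]
        M = table.data[names].dropna()
        s = M.sum(axis=1)
        sums[domain] = s
        blocks[domain] = {
            "n_items": len(names), "n_complete": int(len(s)),
            "mean": round(float(s.mean()), _ROUND),
            "sd": round(float(s.std(ddof=1)), _ROUND),
            "min": float(s.min()), "max": float(s.max()),
        }
    cols = {d: sums[d] for d in table.domains()}
    for cov in table.covariates:
        if cov in table.data.columns:
            cols[cov] = table.data[cov]
    frame = pd.DataFrame(cols)
    corr = frame.corr().round(_ROUND)
    return {"scales": blocks,
            "correlations": {c: corr[c].to_dict() for c in corr.columns}}


def _fit_row(fit) -> dict:
    return {"chi2": round(fit.chi2, _ROUND), "df": fit.df,
            "pvalue": round(fit.pvalue, _ROUND),
            "rmsea": round(fit.rmsea, _ROUND),
            "rmsea_ci": [round(v, _ROUND) for v in fit.rmsea_ci],
            "cfi": round(fit.cfi, _ROUND), "tli": round(fit.tli, _ROUND)}


def _instrument_stage(table, items, kind, pairs_whitelist, mi_threshold):
    """Instrument CFA with modification-index screening of whitelisted
    residual pairs: a pair is added only when it is both flagged above the
    threshold and conceptually pre-approved (the whitelist)."""
    spec = build_model(kind, items)
    stats = mixed_correlation_matrix(table.subset_items([it.name for it in items]))
    fit = fit_model(spec, stats)
    added = []
    wl = {frozenset(p) for p in pairs_whitelist}
    if wl:
        mis, _ = (ml_modification_indices(fit) if fit.method == "ml"
                  else modification_indices(fit))
        for row in mis:
            if frozenset(row["pair"]) in wl and row["mi"] >= mi_threshold:
                added.append(tuple(row["pair"]))
        if added:
            spec = build_model(kind, items, residual_pairs=added)
            fit = fit_model(spec, stats)
    return spec, fit, added, stats


def run_paper_pipeline(table: ItemResponseTable,
                       options: PipelineOptions | None = None,
                       seed: int | None = None) -> dict:
    """Run the full analysis sequence; returns the machine-readable report."""
    opt = options or PipelineOptions()
    log: list[str] = []

    if opt.exclude_items:
        table = table.subset_items(
            [n for n in table.item_names if n not in set(opt.exclude_items)])
        log.append(f"excluded items: {opt.exclude_items}")
    _validate_scales(table)

    # -- intraclass correlations ------------------------------------------
    icc = {}
    if "cluster" in table.data.columns:
        for it in table.items:
            x = table.responses(it.name)
            icc[it.name] = round(intraclass_correlation(
                x, table.data["cluster"].to_numpy()), _ROUND)
        log.append(f"ICC range: [{min(icc.values()):.3f}, {max(icc.values()):.3f}]")

    # -- instrument CFAs ---------------------------------------------------
    domains = table.domains()
    symptom_items = [it for it in table.items if it.scale == ORDINAL3]
    wellbeing_items = [it for it in table.items if it.scale == CONTINUOUS]
    wl = [tuple(p) for p in opt.residual_pair_whitelist]
    mm_spec, mm_fit, mm_added, _ = _instrument_stage(
        table, symptom_items, "single_instrument",
        [p for p in wl if all(any(p_i == it.name for it in symptom_items) for p_i in p)],
        opt.mi_threshold)
    wb_spec, wb_fit, wb_added, _ = _instrument_stage(
        table, wellbeing_items, "single_instrument",
        [p for p in wl if all(any(p_i == it.name for it in wellbeing_items) for p_i in p)],
        opt.mi_threshold)
    log.append(f"instrument residual pairs added: {mm_added + wb_added}")
    residual_pairs = mm_added + wb_added

    # -- reliability -------------------------------------------------------
    reliability = {}
    for domain in domains:
        names = [it.name for it in table.items_in_domain(domain)]
        if len(names) >= 2:
            rel = scale_reliability(table, names)
            reliability[domain] = {
                "alpha": round(rel.alpha, _ROUND),
                "item_total": {k: round(v, _ROUND) for k, v in rel.item_total.items()},
                "alpha_if_deleted": {k: (round(v, _ROUND) if np.isfinite(v) else None)
                                     for k, v in rel.alpha_if_deleted.items()},
            }

    # -- four structural models -------------------------------------------
    stats = mixed_correlation_matrix(table)
    specs = {
        "correlated_factors": build_model("correlated_factors", table.items,
                                          residual_pairs),
        "bifactor": build_model("bifactor", table.items, residual_pairs),
    }
    s1_domains = [d for d in domains]
    for d in s1_domains:
        specs[f"s1_{d}"] = build_model("s1", table.items, residual_pairs,
                                       reference_domain=d)
    fits = {k: fit_model(v, stats) for k, v in specs.items()}
    comparison = {}
    bf = fits["bifactor"]
    for k, f in fits.items():
        row = _fit_row(f)
        if k != "bifactor" and f.df > bf.df:
            t = scaled_difference_test(f, bf)
            row["vs_bifactor"] = {"delta_chi2": round(t.delta_chi2, _ROUND),
                                  "delta_df": t.delta_df,
                                  "pvalue": round(t.pvalue, _ROUND)}
        comparison[k] = row

    # -- dimensionality ----------------------------------------------------
    dim = dimensionality_report(fits["bifactor"]).to_dict()
    dim["ecv"] = round(dim["ecv"], _ROUND)
    dim["puc"] = round(dim["puc"], _ROUND)

    # -- invariance --------------------------------------------------------
    invariance = {}
    freed_by_group: dict[str, list] = {}
    if opt.run_invariance:
        for gvar in opt.invariance_groups:
            if gvar not in table.data.columns:
                log.append(f"invariance skipped: no column {gvar!r}")
                continue
            res = invariance_sequence(specs["correlated_factors"], table, gvar,
                                      level=opt.level)
            invariance[gvar] = res.to_dict()
            freed_by_group[gvar] = list(res.freed_items)
            log.append(f"invariance[{gvar}]: {res.verdict}"
                       + (f", freed {res.freed_items}" if res.freed_items else ""))

    # -- covariate associations on invariant reduced model ------------------
    associations = {}
    if opt.run_associations and opt.run_invariance:
        freed_all = sorted({i for v in freed_by_group.values() for i in v})
        assoc_spec = specs["correlated_factors"]
        if freed_all:
            assoc_spec = drop_items(assoc_spec, freed_all)
            log.append(f"associations computed without non-invariant items: {freed_all}")
        for cov in opt.invariance_groups:
            if cov not in table.data.columns:
                continue
            rows = covariate_association(assoc_spec, table, cov, level=opt.level)
            associations[cov] = [
                {"factor": r.factor, "coefficient": round(r.coefficient, _ROUND),
                 "standardized": round(r.standardized, _ROUND),
                 "se": round(r.se, _ROUND), "significant": r.significant}
                for r in rows]

    report = {
        "provenance": _provenance(table, opt, seed),
        "icc": icc,
        "instruments": {
            "symptoms": {"fit": _fit_row(mm_fit), "pairs_added": mm_added,
                         "df": count_parameters(mm_spec).df},
            "wellbeing": {"fit": _fit_row(wb_fit), "pairs_added": wb_added,
                          "df": count_parameters(wb_spec).df},
        },
        "reliability": reliability,
        "descriptives": descriptives(table),
        "model_comparison": comparison,
        "model_df": {k: count_parameters(v).df for k, v in specs.items()},
        "dimensionality": dim,
        "invariance": invariance,
        "associations": associations,
        "log": log,
    }
    return report


def _validate_scales(table: ItemResponseTable) -> None:
    """Halt early when an item's declared scale contradicts its values."""
    for it in table.items:
        x = table.responses(it.name)
        obs = x[~np.isnan(x)]
        if it.scale == CONTINUOUS:
            uniq = np.unique(obs)
            if uniq.size <= 3 and np.all(np.isin(uniq, [1.0, 2.0, 3.0])):
                raise DataError(
                    f"item {it.name!r} is declared continuous but takes only "
                    f"ordinal values {{1,2,3}}: check the item metadata")
        else:
            if obs.size and not np.isin(obs, [1.0, 2.0, 3.0]).all():
                raise DataError(
                    f"item {it.name!r} is declared ordinal but has non-categorical "
                    "values: check the item metadata")


def _provenance(table, opt: PipelineOptions, seed) -> dict:
    h = hashlib.sha256()
    h.update(json.dumps({"items": [it.to_dict() for it in table.items],
                         "options": {k: list(v) if isinstance(v, list) else v
                                     for k, v in vars(opt).items()}},
                        sort_keys=True).encode())
    return {"n": table.n, "config_hash": h.hexdigest()[:16],
            "seed": seed, "package_version": __version__}
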