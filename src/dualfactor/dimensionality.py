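"""Bifactor dimensionality indices: ECV, PUC and the vanishing-factor check.

The explained common variance (ECV) is the share of common variance carried
by the general factor of a bifactor-family solution; the percent of
uncontaminated correlations (PUC) is the fraction of item pairs that span
different group factors and therefore inform only on the general factor.
High PUC (> .80) together with ECV > .60 is the conventional screen for
treating a multidimensional solution as essentially unidimensional.  A
*vanishing* specific factor — most loadings collapsed toward zero once the
general factor absorbs the domain's covariance — is the classic symptom of a
misspecified classical bifactor model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .estimator import FitResult
from .models import GENERAL, SPECIFIC, ModelError

__all__ = ["DimensionalityIndices", "explained_common_variance",
           "percent_uncontaminated_correlations", "vanishing_factor_diagnostic",
           "unidimensionality_decision", "dimensionality_report"]

ECV_THRESHOLD = 0.60
PUC_THRESHOLD = 0.80
UNIDIMENSIONAL = "consider unidimensional"
MULTIDIMENSIONAL = "multidimensional"


@dataclass
class DimensionalityIndices:
    ecv: float
    puc: float
    verdict: str
    specific_summary: dict = field(default_factory=dict)
    vanishing_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"ecv": self.ecv, "puc": self.puc, "verdict": self.verdict,
                "specific_factors": self.specific_summary,
                "vanishing_flags": list(self.vanishing_flags)}


def explained_common_variance(general_loadings: Sequence[float],
                              specific_loadings: Sequence[float]) -> float:
    """ECV = sum(lambda_g^2) / (sum(lambda_g^2) + sum(lambda_s^2)).

    ``general_loadings`` are the completely standardized loadings on the
    general factor (all items); ``specific_loadings`` pools the loadings on
    every specific factor.
    """
    g = np.square(np.asarray(general_loadings, float)).sum()
    s = np.square(np.asarray(specific_loadings, float)).sum()
    if g + s <= 0:
        raise ModelError("ECV undefined: all loadings are zero")
    return float(g / (g + s))


def percent_uncontaminated_correlations(group_sizes: Sequence[int]) -> float:
    """PUC = 1 - (within-group item pairs) / (all item pairs)."""
    sizes = [int(k) for k in group_sizes]
    if any(k < 1 for k in sizes):
        raise ModelError("group sizes must be >= 1")
    p = sum(sizes)
    if p < 2:
        raise ModelError("PUC needs at least two items")
    within = sum(k * (k - 1) // 2 for k in sizes)
    total = p * (p - 1) // 2
    return 1.0 - within / total


def unidimensionality_decision(ecv: float, puc: float) -> str:
    """Advisory verdict: 'consider unidimensional' iff PUC > .80 and
    ECV > .60 (both strict); otherwise 'multidimensional'."""
    if not (0 <= ecv <= 1 and 0 <= puc <= 1):
        raise ModelError("ECV and PUC must lie in [0, 1]")
    if puc > PUC_THRESHOLD and ecv > ECV_THRESHOLD:
        return UNIDIMENSIONAL
    return MULTIDIMENSIONAL


def vanishing_factor_diagnostic(fit: FitResult, loading_threshold: float = 0.3,
                                fraction: float = 0.5,
                                variance_threshold: float = 0.15,
                                factor_variances: Mapping[str, float] | None = None,
                                ) -> list[dict]:
    """Flag specific factors that the general factor has emptied out.

    A specific factor is flagged when the share of its loadings strictly
    below ``loading_threshold`` reaches ``fraction`` (half by default) — a
    loading exactly at the threshold does not count — or, when a freed
    variance estimate for the factor is supplied via ``factor_variances``,
    when that variance falls strictly below ``variance_threshold``.  Returns
    one record per flagged factor with the offending loadings.
    """
    spec = fit.spec
    if spec.general_factor() is None:
        raise ModelError("vanishing-factor diagnostic applies to bifactor-family fits")
    std = fit.standardized_loadings()
    flags = []
    for f in spec.specific_factors():
        lams = {i: std[(i, f.name)] for i in spec.factor_items(f.name)}
        low = {i: v for i, v in lams.items() if abs(v) < loading_threshold}
        fired_loadings = len(low) / len(lams) >= fraction and len(low) > 0
        xi = (factor_variances or {}).get(f.name)
        fired_var = xi is not None and xi < variance_threshold
        if fired_loadings or fired_var:
            flags.append({"factor": f.name, "low_loadings": low,
                          "factor_variance": xi,
                          "trigger": ("loadings" if fired_loadings else "variance")})
    return flags


def dimensionality_report(fit: FitResult, loading_threshold: float = 0.3,
                          fraction: float = 0.5,
                          variance_threshold: float = 0.15) -> DimensionalityIndices:
    """Full dimensionality block for a converged bifactor-family fit."""
    spec = fit.spec
    gen = spec.general_factor()
    if gen is None:
        raise ModelError("dimensionality indices need a bifactor-family fit")
    std = fit.standardized_loadings()
    general = [std[(i, gen.name)] for i in spec.factor_items(gen.name)]
    specific = [std[(i, f.name)] for f in spec.specific_factors()
                for i in spec.factor_items(f.name)]
    ecv = explained_common_variance(general, specific)
    # PUC groups: partition of items by their specific factor, with items
    # lacking a specific factor (the S-1 reference domain) as singletons
    sizes = [len(spec.factor_items(f.name)) for f in spec.specific_factors()]
    covered = {i for f in spec.specific_factors() for i in spec.factor_items(f.name)}
    sizes += [1] * (len(spec.items) - len(covered))
    puc = percent_uncontaminated_correlations(sizes)
    verdict = unidimensionality_decision(ecv, puc)
    flags = vanishing_factor_diagnostic(fit, loading_threshold, fraction,
                                        variance_threshold)
    summary = {}
    for f in spec.specific_factors():
        lams = np.array([std[(i, f.name)] for i in spec.factor_items(f.name)])
        summary[f.name] = {
            "n_items": int(lams.size),
            "loading_range": (float(np.min(lams)), float(np.max(lams))),
            "mean_squared_loading": float(np.mean(lams ** 2)),
            "n_below_threshold": int(np.sum(np.abs(lams) < loading_threshold)),
        }
    return DimensionalityIndices(ecv, puc, verdict, summary,
                                 flags)
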