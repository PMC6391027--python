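"""Declarative confirmatory factor model structures and their bookkeeping.

Four model families are supported, mirroring the dual-factor mental-health
analysis: correlated domain factors, the classical bifactor model (one
general factor plus orthogonal domain-specific factors), S-1 models (a
bifactor model with one domain's specific factor removed so that domain
defines the general factor), and single-instrument CFAs.

Identification convention: all factor variances fixed at 1, all pattern
loadings free, factor means 0 (single group).  Ordinal items are
parameterized with unit total latent variance and no free residual variance
(delta-style), so their free parameters are the loadings and two thresholds;
continuous items add a free intercept and residual variance.  Residual
correlations are parameterized on the correlation scale and add directly to
the implied inter-item correlation.  Under this convention the
degrees-of-freedom arithmetic reproduces the published values for every
single-group model in the source analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .data import CONTINUOUS, ORDINAL3, DataError, ItemDef
from .correlations import stat_index_for

CORRELATED_FACTORS = "correlated_factors"
BIFACTOR = "bifactor"
S1 = "s1"
SINGLE_INSTRUMENT = "single_instrument"

GENERAL = "general"
SPECIFIC = "specific"
DOMAIN = "domain"


class ModelError(ValueError):
    """Raised for inadmissible model structures."""


@dataclass(frozen=True)
class Factor:
    name: str
    kind: str  # general | specific | domain


@dataclass
class ParameterCount:
    n_statistics: int
    n_free_parameters: int

    @property
    def df(self) -> int:
        return self.n_statistics - self.n_free_parameters


@dataclass
class ModelSpec:
    """A factor model: items, factors, free-parameter patterns."""

    items: list[ItemDef]
    factors: list[Factor]
    loadings: list[tuple[str, str]]            # (item, factor) free entries
    phi_free: list[tuple[str, str]]            # free factor correlations
    residual_pairs: list[tuple[str, str]] = field(default_factory=list)
    kind: str = CORRELATED_FACTORS
    name: str = ""
    fixed_loadings: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        inames = [it.name for it in self.items]
        fnames = [f.name for f in self.factors]
        if len(set(inames)) != len(inames) or len(set(fnames)) != len(fnames):
            raise ModelError("duplicate item or factor names")
        loaded = {i for i, _ in self.loadings} | {i for i, _, _ in self.fixed_loadings}
        for it in self.items:
            if it.name not in loaded:
                raise ModelError(f"item {it.name!r} loads on no factor")
        for i, f in list(self.loadings) + [(i, f) for i, f, _ in self.fixed_loadings]:
            if i not in inames or f not in fnames:
                raise ModelError(f"loading ({i!r}, {f!r}) references unknown item/factor")
        for a, b in self.phi_free:
            if a not in fnames or b not in fnames or a == b:
                raise ModelError(f"invalid free factor correlation ({a!r}, {b!r})")
        kinds = {f.kind for f in self.factors}
        if GENERAL in kinds and self.phi_free:
            raise ModelError("bifactor-family models must have all factor "
                             "covariances fixed at zero")
        for a, b in self.residual_pairs:
            if a == b or a not in inames or b not in inames:
                raise ModelError(f"residual pair ({a!r}, {b!r}) must reference "
                                 "two distinct existing items")

    # -- accessors ---------------------------------------------------------
    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def ordinal_items(self) -> list[ItemDef]:
        return [it for it in self.items if it.scale == ORDINAL3]

    @property
    def continuous_items(self) -> list[ItemDef]:
        return [it for it in self.items if it.scale == CONTINUOUS]

    def item(self, name: str) -> ItemDef:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)

    def item_loadings(self, name: str) -> list[str]:
        return [f for i, f in self.loadings if i == name]

    def factor_items(self, fname: str) -> list[str]:
        return [i for i, f in self.loadings if f == fname]

    def general_factor(self) -> Factor | None:
        for f in self.factors:
            if f.kind == GENERAL:
                return f
        return None

    def specific_factors(self) -> list[Factor]:
        return [f for f in self.factors if f.kind == SPECIFIC]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "name": self.name,
            "items": [it.to_dict() for it in self.items],
            "factors": [{"name": f.name, "kind": f.kind} for f in self.factors],
            "loadings": [list(t) for t in self.loadings],
            "phi_free": [list(t) for t in self.phi_free],
            "residual_pairs": [list(t) for t in self.residual_pairs],
            "fixed_loadings": [[i, f, float(v)] for i, f, v in self.fixed_loadings],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            items=[ItemDef.from_dict(x) for x in d["items"]],
            factors=[Factor(x["name"], x["kind"]) for x in d["factors"]],
            loadings=[tuple(t) for t in d["loadings"]],
            phi_free=[tuple(t) for t in d["phi_free"]],
            residual_pairs=[tuple(t) for t in d.get("residual_pairs", [])],
            kind=d.get("kind", CORRELATED_FACTORS),
            name=d.get("name", ""),
            fixed_loadings=[(i, f, float(v)) for i, f, v in d.get("fixed_loadings", [])],
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_model(kind: str, items: Sequence[ItemDef],
                residual_pairs: Sequence[tuple[str, str]] = (),
                reference_domain: str | None = None,
                name: str = "") -> ModelSpec:
    """Construct one of the four supported model structures.

    ``correlated_factors``: one factor per item domain with all factor
    correlations free.  ``bifactor``: one general factor plus one orthogonal
    specific factor per domain; every item loads on the general factor and on
    its domain's specific factor.  ``s1``: the bifactor structure minus the
    specific factor of ``reference_domain`` (that domain's items load only on
    the general factor).  ``single_instrument``: correlated domain factors
    over the items given (one factor if they share a domain).
    """
    items = list(items)
    domains: list[str] = []
    for it in items:
        if it.domain not in domains:
            domains.append(it.domain)
    pairs = [tuple(p) for p in residual_pairs]

    if kind in (CORRELATED_FACTORS, SINGLE_INSTRUMENT):
        factors = [Factor(d, DOMAIN) for d in domains]
        loadings = [(it.name, it.domain) for it in items]
        phi_free = [(domains[i], domains[j]) for i in range(len(domains))
                    for j in range(i + 1, len(domains))]
        return ModelSpec(items, factors, loadings, phi_free, pairs, kind,
                         name or kind)

    if kind == BIFACTOR:
        factors = [Factor(GENERAL, GENERAL)] + [Factor(f"spec_{d}", SPECIFIC)
                                                for d in domains]
        loadings = [(it.name, GENERAL) for it in items]
        loadings += [(it.name, f"spec_{it.domain}") for it in items]
        return ModelSpec(items, factors, loadings, [], pairs, kind, name or kind)

    if kind == S1:
        if reference_domain is None:
            raise ModelError("s1 model needs a reference domain")
        if reference_domain not in domains:
            raise ModelError(f"reference domain {reference_domain!r} absent from items")
        factors = [Factor(GENERAL, GENERAL)] + [
            Factor(f"spec_{d}", SPECIFIC) for d in domains if d != reference_domain]
        loadings = [(it.name, GENERAL) for it in items]
        loadings += [(it.name, f"spec_{it.domain}") for it in items
                     if it.domain != reference_domain]
        return ModelSpec(items, factors, loadings, [], pairs, S1,
                         name or f"s1_{reference_domain}")

    raise ModelError(f"unknown model kind {kind!r}")


def drop_items(spec: ModelSpec, item_names: Iterable[str]) -> ModelSpec:
    """Remove items (and residual pairs touching them) from a model.

    A factor left with fewer than two indicators loses identification and is
    an error, as is dropping an unknown item.
    """
    drop = set(item_names)
    known = set(spec.item_names)
    unknown = drop - known
    if unknown:
        raise ModelError(f"cannot drop unknown items: {sorted(unknown)}")
    items = [it for it in spec.items if it.name not in drop]
    loadings = [(i, f) for i, f in spec.loadings if i not in drop]
    fixed = [(i, f, v) for i, f, v in spec.fixed_loadings if i not in drop]
    pairs = [(a, b) for a, b in spec.residual_pairs
             if a not in drop and b not in drop]
    for f in spec.factors:
        remaining = [i for i, fn in loadings if fn == f.name]
        remaining += [i for i, fn, _ in fixed if fn == f.name]
        if len(remaining) < 2:
            raise ModelError(f"dropping {sorted(drop)} leaves factor {f.name!r} "
                             f"with {len(remaining)} indicator(s)")
    return ModelSpec(items, list(spec.factors), loadings, list(spec.phi_free),
                     pairs, spec.kind, spec.name, fixed_loadings=fixed)


# ---------------------------------------------------------------------------
# Parameter/df accounting
# ---------------------------------------------------------------------------

def count_parameters(spec: ModelSpec) -> ParameterCount:
    """Exact free-parameter and statistic count (single group).

    Statistics: two thresholds per ordinal item, a mean and a variance per
    continuous item, and all p(p-1)/2 correlations.  Free parameters: pattern
    loadings, free factor correlations, residual correlations, and per
    continuous item an intercept and a residual variance; per ordinal item
    its two thresholds.
    """
    p = len(spec.items)
    n_ord = len(spec.ordinal_items)
    n_cont = len(spec.continuous_items)
    n_stats = 2 * n_ord + 2 * n_cont + p * (p - 1) // 2
    n_free = (len(spec.loadings) + len(spec.phi_free) + len(spec.residual_pairs)
              + 2 * n_cont + 2 * n_ord)
    return ParameterCount(n_stats, n_free)


def saturated_spec(items: Sequence[ItemDef]) -> ModelSpec:
    """All pairwise correlations free: a df = 0 reference structure.

    Implemented as one factor per item with the loading fixed at 1 and all
    factor correlations free, which is exactly one free parameter per
    correlation."""
    items = list(items)
    factors = [Factor(f"f_{it.name}", DOMAIN) for it in items]
    fixed = [(it.name, f"f_{it.name}", 1.0) for it in items]
    phi_free = [(factors[i].name, factors[j].name) for i in range(len(items))
                for j in range(i + 1, len(items))]
    return ModelSpec(items, factors, [], phi_free, [], SINGLE_INSTRUMENT,
                     "saturated", fixed_loadings=fixed)


# ---------------------------------------------------------------------------
# Model-implied moments
# ---------------------------------------------------------------------------

@dataclass
class ImpliedMoments:
    thresholds: dict[str, np.ndarray]
    means: dict[str, float]
    variances: dict[str, float]
    corr: np.ndarray          # item order of the spec
    item_names: list[str]

    def stat_vector(self, stat_index: Sequence[tuple]) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.item_names)}
        vals = []
        for key in stat_index:
            if key[0] == "tau":
                vals.append(self.thresholds[key[1]][key[2] - 1])
            elif key[0] == "mean":
                vals.append(self.means[key[1]])
            elif key[0] == "var":
                vals.append(self.variances[key[1]])
            else:
                vals.append(self.corr[pos[key[1]], pos[key[2]]])
        return np.array(vals, float)


def phi_matrix(spec: ModelSpec, params: Mapping) -> np.ndarray:
    m = len(spec.factors)
    phi = np.eye(m)
    fpos = {f.name: k for k, f in enumerate(spec.factors)}
    for a, b in spec.phi_free:
        v = _get(params, ("phi", a, b))
        phi[fpos[a], fpos[b]] = phi[fpos[b], fpos[a]] = v
    return phi


def loading_matrix(spec: ModelSpec, params: Mapping) -> np.ndarray:
    L = np.zeros((len(spec.items), len(spec.factors)))
    ipos = {it.name: i for i, it in enumerate(spec.items)}
    fpos = {f.name: k for k, f in enumerate(spec.factors)}
    for i, f in spec.loadings:
        L[ipos[i], fpos[f]] = _get(params, ("lambda", i, f))
    for i, f, v in spec.fixed_loadings:
        L[ipos[i], fpos[f]] = v
    return L


def _get(params: Mapping, key: tuple):
    if key in params:
        return params[key]
    if key[0] == "phi":
        alt = (key[0], key[2], key[1])
        if alt in params:
            return params[alt]
    if key[0] == "rtheta":
        alt = (key[0], key[2], key[1])
        if alt in params:
            return params[alt]
    raise KeyError(key)


def model_implied_moments(spec: ModelSpec, params: Mapping) -> ImpliedMoments:
    """Implied thresholds, means, variances and correlation matrix.

    Parameter keys: ``("lambda", item, factor)`` completely standardized
    loadings, ``("phi", f1, f2)`` factor correlations, ``("rtheta", a, b)``
    residual correlations, ``("tau", item, c)`` thresholds, ``("nu", item)``
    continuous means, ``("v", item)`` continuous total variances.

    The implied correlation of items i, j is ``lam_i' Phi lam_j + rtheta_ij``;
    ordinal items have unit total variance, so a communality at or above 1
    (non-positive residual variance) is a Heywood condition and an error.
    """
    L = loading_matrix(spec, params)
    phi = phi_matrix(spec, params)
    R = L @ phi @ L.T
    comm = np.diag(R).copy()
    for i, it in enumerate(spec.items):
        if comm[i] >= 1.0 and it.scale == ORDINAL3:
            raise ModelError(f"implied total variance of ordinal item {it.name!r} "
                             f"is non-positive (communality {comm[i]:.4f})")
    ipos = {it.name: i for i, it in enumerate(spec.items)}
    for a, b in spec.residual_pairs:
        v = _get(params, ("rtheta", a, b))
        R[ipos[a], ipos[b]] += v
        R[ipos[b], ipos[a]] += v
    np.fill_diagonal(R, 1.0)

    thresholds = {it.name: np.array([_get(params, ("tau", it.name, 1)),
                                     _get(params, ("tau", it.name, 2))])
                  for it in spec.ordinal_items}
    means = {it.name: float(_get(params, ("nu", it.name)))
             for it in spec.continuous_items}
    variances = {it.name: float(_get(params, ("v", it.name)))
                 for it in spec.continuous_items}
    return ImpliedMoments(thresholds, means, variances, R, spec.item_names)


def spec_stat_index(spec: ModelSpec) -> list[tuple]:
    return stat_index_for(spec.items)
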