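"""Item-response tables: the observed-data container for the whole pipeline.

A table holds one row per respondent: an id, a cluster (school) label, binary
covariates, and the item responses.  Items are either three-category ordinal
(coded 1-3) or continuous on a 0-10 scale; missing responses are NaN in
memory and empty cells on disk.  Item-level metadata (scale type, domain,
reverse-coding flag) travels in a YAML sidecar next to the CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

ORDINAL3 = "ordinal3"
CONTINUOUS = "continuous"

ID_COL = "respondent"
CLUSTER_COL = "cluster"
DEFAULT_COVARIATES = ("gender", "income")


class DataError(ValueError):
    """Raised when a table or config violates its invariants."""


@dataclass(frozen=True)
class ItemDef:
    """Definition of a single questionnaire item.

    Parameters
    ----------
    name : str
        Column name in the table.
    scale : {"ordinal3", "continuous"}
        Response scale: three ordered categories coded 1-3, or a continuous
        0-10 score.
    domain : str
        Substantive domain, e.g. ``internalising``/``externalising``/
        ``wellbeing``; used to build domain factors.
    reverse : bool
        True if the item was administered reverse-keyed.  Responses are
        stored already re-reversed, so loadings are positive; the flag is
        retained for sum-score bookkeeping and reporting.
    """

    name: str
    scale: str
    domain: str
    reverse: bool = False

    def __post_init__(self):
        if self.scale not in (ORDINAL3, CONTINUOUS):
            raise DataError(f"unknown scale type {self.scale!r} for item {self.name!r}")

    def to_dict(self) -> dict:
        return {"name": self.name, "scale": self.scale, "domain": self.domain,
                "reverse": self.reverse}

    @classmethod
    def from_dict(cls, d: dict) -> "ItemDef":
        return cls(name=d["name"], scale=d["scale"], domain=d["domain"],
                   reverse=bool(d.get("reverse", False)))


class ItemResponseTable:
    """Per-respondent item responses with covariates and cluster labels."""

    def __init__(self, data: pd.DataFrame, items: Sequence[ItemDef],
                 covariates: Sequence[str] = DEFAULT_COVARIATES,
                 validate: bool = True):
        self.items: list[ItemDef] = list(items)
        self.covariates = tuple(covariates)
        self.data = data.reset_index(drop=True)
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise DataError("duplicate item names")
        missing_cols = [c for c in names if c not in data.columns]
        if missing_cols:
            raise DataError(f"table is missing item columns: {missing_cols}")
        if validate:
            self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

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

    def domains(self) -> list[str]:
        seen: list[str] = []
        for it in self.items:
            if it.domain not in seen:
                seen.append(it.domain)
        return seen

    def items_in_domain(self, domain: str) -> list[ItemDef]:
        return [it for it in self.items if it.domain == domain]

    def responses(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def subset_rows(self, mask: np.ndarray) -> "ItemResponseTable":
        return ItemResponseTable(self.data.loc[np.asarray(mask, bool)],
                                 self.items, self.covariates, validate=False)

    def subset_items(self, names: Iterable[str]) -> "ItemResponseTable":
        names = list(names)
        items = [self.item(n) for n in names]
        keep = [c for c in self.data.columns if c not in self.item_names or c in names]
        return ItemResponseTable(self.data[keep], items, self.covariates, validate=False)

    def split_by(self, column: str) -> dict:
        """Split into subtables by the values of a covariate/grouping column."""
        if column not in self.data.columns:
            raise DataError(f"grouping column {column!r} not in table")
        out = {}
        col = self.data[column]
        for value in sorted(col.dropna().unique()):
            out[value] = self.subset_rows((col == value).to_numpy())
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for it in self.items:
            x = self.responses(it.name)
            obs = x[~np.isnan(x)]
            if it.scale == ORDINAL3:
                if obs.size and not np.isin(obs, [1.0, 2.0, 3.0]).all():
                    raise DataError(
                        f"ordinal item {it.name!r} has values outside {{1,2,3}}")
            else:
                if obs.size and ((obs < 0) | (obs > 10)).any():
                    raise DataError(
                        f"continuous item {it.name!r} has values outside [0, 10]")

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path, metadata_path: str | Path | None = None) -> None:
        path = Path(path)
        cols = [ID_COL, CLUSTER_COL, *self.covariates, *self.item_names]
        cols = [c for c in cols if c in self.data.columns]
        out = self.data[cols].copy()
        for it in self.ordinal_items:
            out[it.name] = out[it.name].astype("Int64")
        out.to_csv(path, index=False, na_rep="")
        meta = {"items": [it.to_dict() for it in self.items],
                "covariates": list(self.covariates)}
        mpath = Path(metadata_path) if metadata_path else path.with_suffix(".items.yaml")
        mpath.write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def read_csv(cls, path: str | Path,
                 metadata_path: str | Path | None = None) -> "ItemResponseTable":
        path = Path(path)
        mpath = Path(metadata_path) if metadata_path else path.with_suffix(".items.yaml")
        meta = yaml.safe_load(Path(mpath).read_text())
        items = [ItemDef.from_dict(d) for d in meta["items"]]
        data = pd.read_csv(path)
        return cls(data, items, covariates=tuple(meta.get("covariates", DEFAULT_COVARIATES)))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ItemResponseTable(n={self.n}, items={len(self.items)} "
                f"[{len(self.ordinal_items)} ordinal / {len(self.continuous_items)} continuous])")
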