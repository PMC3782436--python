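"""Exhaustive specification search over a saturated path-model framework.

Every subset of the framework's optional edges (mandatory edges always
present) is enumerated in lexicographic mask order, fitted by maximum
likelihood, and ranked by ascending BCC.  Ties break toward fewer free
parameters, then the lexicographically smaller inclusion mask, so the ranking
is a deterministic total order.  Non-converged and Heywood solutions are set
aside rather than ranked; unidentified candidates (df < 0) are skipped with a
logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CatalogEntry
from .sem import PathModel, SEMFit, fit_ml, sample_covariance

logger = logging.getLogger(__name__)

__all__ = ["ModelFramework", "SearchResult", "enumerate_candidates", "search"]

_MAX_OPTIONAL = 20


@dataclass(frozen=True)
class ModelFramework:
    """A structural skeleton: mandatory edges plus optional ("searchable") ones."""

    base: PathModel
    optional_edges: tuple[str, ...]  # edge names within base

    def __post_init__(self):
        names = {e.name for e in self.base.edges}
        unknown = set(self.optional_edges) - names
        if unknown:
            raise ValueError(f"optional edges not in framework: {sorted(unknown)}")
        if len(set(self.optional_edges)) != len(self.optional_edges):
            raise ValueError("duplicate optional edges")

    @classmethod
    def from_catalog(cls, entry: CatalogEntry, all_optional: bool = True) -> "ModelFramework":
        """Build from a saturated-framework catalog entry.

        ``all_optional=True`` lets the search drop any drawn edge (the
        specification-search convention); ``False`` keeps edges not marked
        optional in the file as mandatory.
        """
        optional = tuple(e.name for e in entry.model.edges) if all_optional else entry.optional_edges
        return cls(entry.model, tuple(optional))

    @property
    def k(self) -> int:
        return len(self.optional_edges)


def enumerate_candidates(framework: ModelFramework) -> list[tuple[int, PathModel]]:
    """All 2^k candidates as (mask, PathModel), lexicographic by mask.

    Bit i of the mask is edge i of ``optional_edges``; the full framework is
    acyclic, hence so is every edge subset.
    """
    if framework.k > _MAX_OPTIONAL:
        raise ValueError(f"{framework.k} optional edges exceeds the 2^{_MAX_OPTIONAL} guardrail")
    optional = set(framework.optional_edges)
    mandatory = [e for e in framework.base.edges if e.name not in optional]
    order = list(framework.optional_edges)
    base = framework.base
    out = []
    for mask in range(2 ** framework.k):
        included = [name for i, name in enumerate(order) if mask >> i & 1]
        keep = set(included)
        edges = mandatory + [e for e in base.edges if e.name in keep]
        model = PathModel(base.variables, edges, base.covariances, name=f"{base.name}|mask={mask}")
        out.append((mask, model))
    return out


@dataclass
class RankedModel:
    mask: int
    model: PathModel
    fit: SEMFit

    def row(self) -> dict:
        return {
            "mask": self.mask,
            "edges": " ".join(e.name for e in self.model.edges),
            "q": self.model.q,
            "df": self.fit.df,
            "chisq": self.fit.chisq,
            "pvalue": self.fit.pvalue,
            "bcc": self.fit.bcc,
            "aic": self.fit.aic,
            "converged": self.fit.converged,
            "heywood": self.fit.heywood,
        }


@dataclass
class SearchResult:
    ranked: list[RankedModel]
    excluded: list[RankedModel]
    skipped: list[tuple[int, str]]

    @property
    def best(self) -> RankedModel:
        return self.ranked[0]

    def rank_of_mask(self, mask: int) -> int | None:
        for i, r in enumerate(self.ranked):
            if r.mask == mask:
                return i
        return None

    def table(self, top: int | None = 10) -> pd.DataFrame:
        rows = [r.row() for r in (self.ranked if top is None else self.ranked[:top])]
        df = pd.DataFrame(rows)
        if len(df):
            df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df


def search(
    data: pd.DataFrame,
    framework: ModelFramework,
    n: int | None = None,
    exclude_heywood: bool = True,
    **fit_kwargs,
) -> SearchResult:
    """Fit every candidate and rank by ascending BCC.

    ``data`` is a complete table of the framework variables (rows = years);
    alternatively pass a precomputed covariance DataFrame plus ``n``.
    """
    variables = framework.base.variables
    missing = set(variables) - set(data.columns)
    if missing:
        raise ValueError(f"data lacks framework variables: {sorted(missing)}")
    if n is None:
        sub = data.loc[:, variables].dropna()
        n = len(sub)
        S = sample_covariance(sub)
    else:
        S = data.loc[variables, variables].to_numpy(float)

    # candidate fits skip the SE Hessian and extra multistarts (the warm start
    # is near-exact for these recursive candidates); winners are refit in full
    fit_kwargs.setdefault("compute_se", False)
    fit_kwargs.setdefault("n_starts", 2)
    ranked: list[RankedModel] = []
    excluded: list[RankedModel] = []
    skipped: list[tuple[int, str]] = []
    for mask, model in enumerate_candidates(framework):
        if model.df < 0:
            skipped.append((mask, f"unidentified (df={model.df})"))
            logger.info("skipping mask %d: df=%d < 0", mask, model.df)
            continue
        try:
            fit = fit_ml(S, model, n, **fit_kwargs)
        except Exception as exc:  # fit-level failure: exclude, keep searching
            skipped.append((mask, f"fit error: {exc}"))
            continue
        rm = RankedModel(mask, model, fit)
        if not fit.converged or (exclude_heywood and fit.heywood):
            excluded.append(rm)
        else:
            ranked.append(rm)
    if not ranked:
        raise RuntimeError("specification search: every candidate failed or was excluded")
    ranked.sort(key=lambda r: (r.fit.bcc, r.model.q, r.mask))
    # full refit (SEs, all multistarts) for the models anyone will inspect
    for rm in ranked[:10]:
        rm.fit = fit_ml(S, rm.model, n)
    return SearchResult(ranked, excluded, skipped)
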