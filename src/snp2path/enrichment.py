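"""Category over-representation with the OR > 1, -log10(p) > 1.33 rule.

Annotation schemes are data: a *functional* scheme places every universe gene
in exactly one category (a BIG-C-style library, 54 categories by default in
the synthetic world) while a *cell-type* scheme lets genes carry zero or more
labels (an I-Scope-style library). Enrichment of a query gene set against a
category is the one-sided (over-representation) exact hypergeometric test on
the 2x2 table over the library's own universe, with the sample odds ratio
ad/bc. A category is called enriched when OR > 1 and -log10(p) > 1.33
(p < 10^-1.33 ~ 0.0468); the threshold is read in base 10 because a natural
log would put it at p ~ 0.26, inconsistent with the p < 0.05 convention used
everywhere else in this analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import io as s2p_io

logger = logging.getLogger(__name__)

__all__ = [
    "ENRICHMENT_NEG_LOG10_P",
    "AnnotationLibrary",
    "enrich_categories",
    "top_enriched",
    "enrichment_heat_table",
]

ENRICHMENT_NEG_LOG10_P = 1.33


@dataclass
class AnnotationLibrary:
    """Gene -> category memberships over a declared universe."""

    scheme: str
    universe: set[str]
    memberships: dict[str, frozenset[str]]
    exclusive: bool = False
    categories: list[str] = field(init=False)

    def __post_init__(self):
        bad = sorted(set(self.memberships) - self.universe)
        if bad:
            raise ValueError(f"membership genes outside the universe: {bad[:10]}")
        if self.exclusive:
            multi = sorted(g for g, cats in self.memberships.items() if len(cats) != 1)
            if multi:
                raise ValueError(
                    f"exclusive scheme {self.scheme!r} requires exactly one category per gene; violated by {multi[:10]}"
                )
        cats: set[str] = set()
        for c in self.memberships.values():
            cats |= c
        self.categories = sorted(cats)

    @classmethod
    def from_table(cls, table: pd.DataFrame, scheme: str, exclusive: bool = False,
                   universe: set[str] | None = None) -> "AnnotationLibrary":
        """Build from a (gene, category) long table; universe defaults to the genes present."""
        memb: dict[str, set[str]] = {}
        for row in table.itertuples(index=False):
            memb.setdefault(row.gene, set()).add(row.category)
        uni = set(universe) if universe is not None else set(memb)
        return cls(scheme, uni, {g: frozenset(c) for g, c in memb.items()}, exclusive)

    @classmethod
    def from_gmt(cls, path: str | Path, scheme: str, exclusive: bool = False) -> "AnnotationLibrary":
        sets = s2p_io.read_gmt(path)
        memb: dict[str, set[str]] = {}
        for cat, genes in sets.items():
            for g in genes:
                memb.setdefault(g, set()).add(cat)
        return cls(scheme, set(memb), {g: frozenset(c) for g, c in memb.items()}, exclusive)

    def genes_in(self, category: str) -> set[str]:
        return {g for g, cats in self.memberships.items() if category in cats}


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    ad, bc = a * d, b * c
    if bc == 0:
        return float("inf") if ad > 0 else 0.0
    return ad / bc


def enrich_categories(query: set[str], library: AnnotationLibrary) -> pd.DataFrame:
    """Per-category 2x2 over-representation over the library universe.

    Genes outside the universe are dropped (count logged); an empty effective
    query is an error. p is the upper hypergeometric tail P(X >= a).
    """
    eff = set(query) & library.universe
    dropped = len(set(query)) - len(eff)
    if dropped:
        logger.info("dropped %d query genes outside the %s universe", dropped, library.scheme)
    if not eff:
        raise ValueError("query has no genes in the library universe")
    N = len(library.universe)
    n_query = len(eff)
    rows = []
    for cat in library.categories:
        members = library.genes_in(cat)
        K = len(members)
        a = len(eff & members)
        b = n_query - a
        c = K - a
        d = N - K - b
        p = float(stats.hypergeom.sf(a - 1, N, K, n_query))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        nlp = float(-np.log10(p))
        orr = _odds_ratio(a, b, c, d)
        rows.append(
            {
                "category": cat,
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": orr,
                "p": p,
                "neg_log10_p": nlp,
                "enriched": bool(orr > 1 and nlp > ENRICHMENT_NEG_LOG10_P),
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out.attrs["n_query_effective"] = n_query
    out.attrs["n_query_dropped"] = dropped
    return out


def top_enriched(result: pd.DataFrame, k: int | None = None) -> pd.DataFrame:
    """Enriched categories ranked by p ascending, ties by category label."""
    ranked = result.loc[result["enriched"]].sort_values(["p", "category"], kind="stable")
    return (ranked.head(k) if k is not None else ranked).reset_index(drop=True)


def enrichment_heat_table(queries: dict[str, set[str]], library: AnnotationLibrary) -> pd.DataFrame:
    """Categories x queries matrix of -log10 p, signed by the OR direction.

    Entries are positive where OR > 1 (over-representation) and negative
    otherwise, the usual heat-map convention for enrichment panels.
    """
    if not queries:
        raise ValueError("need at least one query")
    cols = {}
    for name in sorted(queries):
        res = enrich_categories(queries[name], library).set_index("category")
        sign = np.where(res["odds_ratio"] > 1, 1.0, -1.0)
        cols[name] = pd.Series(sign * res["neg_log10_p"], index=res.index)
    return pd.DataFrame(cols)
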