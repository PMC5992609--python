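"""Gene-set over-representation by 2x2 Fisher exact test with FDR control.

For a query gene set (e.g. genes with acquired deleterious mutations) and a
pathway collection, each pathway is tested with the contingency table

    a = |query ∩ pathway|     b = |query \\ pathway|
    c = |pathway \\ query|    d = |universe \\ (query ∪ pathway)|

restricted to the annotation universe, with a one-sided (over-representation)
Fisher exact p-value and Benjamini-Hochberg adjustment across all pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import fisher_exact

from .errors import ValidationError
from .resistance_classifier import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_FDR_LEVEL = 0.05


@dataclass(frozen=True)
class GeneSetCollection:
    """Pathway name -> member genes, plus the annotation universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"pathway {name!r} is empty")
            if not genes <= self.universe:
                raise ValidationError(f"pathway {name!r} contains genes outside the universe")

    @classmethod
    def from_sets(cls, sets: dict[str, set[str]], universe: set[str] | None = None) -> "GeneSetCollection":
        frozen = {name: frozenset(genes) for name, genes in sets.items()}
        if universe is None:
            universe = set().union(*frozen.values()) if frozen else set()
        return cls(sets=frozen, universe=frozenset(universe))

    @classmethod
    def from_gmt(cls, path: str | Path, universe: set[str] | None = None) -> "GeneSetCollection":
        """Load a GMT file (set name, description, member genes per line).

        By default the universe is the union of all annotated genes; pass an
        explicit ``universe`` (e.g. all exome-covered genes) to widen it.
        """
        from gseapy.parser import read_gmt  # deferred: gseapy import is heavy

        sets = {name: set(genes) for name, genes in read_gmt(str(path)).items()}
        return cls.from_sets(sets, universe)


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as handle:
        for name, genes in sets.items():
            handle.write("\t".join([name, description, *sorted(genes)]) + "\n")


def pathway_enrichment(
    query: set[str],
    collection: GeneSetCollection,
    fdr_level: float = DEFAULT_FDR_LEVEL,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every pathway of ``collection``.

    Query genes outside the universe are dropped (their count is logged).
    Returns a DataFrame with one row per pathway: the 2x2 counts, odds ratio,
    one-sided p, BH q and a significance flag (q < ``fdr_level``), sorted by p.
    """
    effective = set(query) & collection.universe
    n_dropped = len(set(query)) - len(effective)
    if n_dropped:
        logger.info("%d query genes outside the annotation universe were dropped", n_dropped)
    if not effective:
        raise ValidationError("query has no genes in the annotation universe")
    rows = []
    for name, genes in collection.sets.items():
        a = len(effective & genes)
        b = len(effective - genes)
        c = len(genes - effective)
        d = len(collection.universe) - a - b - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, b, c, d, float(odds), float(p)))
    result = pd.DataFrame(
        rows, columns=["pathway", "a", "b", "c", "d", "odds_ratio", "p"]
    )
    result["q"] = bh_fdr(result["p"].tolist())
    result["significant"] = result["q"] < fdr_level
    return result.sort_values("p", kind="stable").reset_index(drop=True)


__all__ = [
    "DEFAULT_FDR_LEVEL",
    "GeneSetCollection",
    "write_gmt",
    "pathway_enrichment",
]
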