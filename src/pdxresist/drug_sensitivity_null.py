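"""Expression-IC50 correlation screen with a random-gene-set null.

Given a gene x cell-line expression matrix and one drug's log-IC50 profile
over the same cell lines, every gene's Pearson correlation (PCC) with the
IC50 vector is computed over pairwise-complete cell lines.  A query gene set
(genes found mutated in resistance modeling) is then compared against the
PCCs of randomly chosen gene sets of equivalent size (1000 by default) with a
one-sided Mann-Whitney rank test: a small p means the query genes are
enriched in *negative* correlations — low expression tracks with high IC50,
i.e. with resistance.

Expression data is a pandas DataFrame (rows = genes, columns = cell lines);
the drug profile a pandas Series indexed by cell line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, t as t_dist

from .errors import ContractError, ValidationError
from .resistance_classifier import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_N_SETS = 1000
DEFAULT_FDR_LEVEL = 0.05
MIN_COMPLETE_PAIRS = 3
#: Largest group sizes for which the Mann-Whitney p is computed by exact
#: enumeration of rank arrangements (no ties); larger groups use the normal
#: approximation with tie correction.
EXACT_MW_MAX_N = 8


def _validate_inputs(expr: pd.DataFrame, drug: pd.Series) -> pd.DataFrame:
    if expr.index.duplicated().any():
        raise ValidationError("duplicate gene names in expression matrix")
    if expr.columns.duplicated().any():
        raise ValidationError("duplicate cell-line names in expression matrix")
    if drug.index.duplicated().any():
        raise ValidationError("duplicate cell-line names in drug response vector")
    shared = expr.columns.intersection(drug.index)
    if len(shared) < MIN_COMPLETE_PAIRS:
        raise ValidationError(
            f"only {len(shared)} shared cell lines between expression and drug response"
        )
    return shared


def per_gene_drug_pcc(
    expr: pd.DataFrame,
    drug: pd.Series,
    min_pairs: int = MIN_COMPLETE_PAIRS,
) -> pd.DataFrame:
    """Per-gene Pearson correlation with one drug's IC50 profile.

    Missing entries are handled pairwise-complete.  The two-sided p-value uses
    the exact t transform ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees
    of freedom; q is the BH adjustment across all reported genes.  Genes with
    fewer than ``min_pairs`` complete pairs are omitted (count logged).

    Returns a DataFrame indexed by gene with columns ``pcc, n_pairs, p, q``.
    """
    shared = _validate_inputs(expr, drug)
    x = expr[shared].to_numpy(dtype=float)
    y = drug[shared].to_numpy(dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(y)[None, :]
    xm = np.where(mask, x, 0.0)
    ym = np.where(mask, y[None, :], 0.0)
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xm.sum(axis=1) / n
        my = ym.sum(axis=1) / n
        xc = np.where(mask, x - mx[:, None], 0.0)
        yc = np.where(mask, y[None, :] - my[:, None], 0.0)
        cov = (xc * yc).sum(axis=1)
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        r = cov / denom
    ok = (n >= min_pairs) & np.isfinite(r)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%d genes omitted (<%d complete pairs or zero variance)", n_dropped, min_pairs)
    r_ok = np.clip(r[ok], -1.0, 1.0)
    n_ok = n[ok]
    with np.errstate(divide="ignore"):
        tstat = r_ok * np.sqrt((n_ok - 2) / np.maximum(1.0 - r_ok**2, np.finfo(float).tiny))
    p = 2.0 * t_dist.sf(np.abs(tstat), df=n_ok - 2)
    out = pd.DataFrame(
        {"pcc": r_ok, "n_pairs": n_ok, "p": p},
        index=expr.index[ok],
    )
    out["q"] = bh_fdr(out["p"].tolist())
    out.index.name = "gene"
    return out


def negative_fdr_threshold(
    results: pd.DataFrame, fdr_level: float = DEFAULT_FDR_LEVEL
) -> float | None:
    """Least-extreme PCC among significantly (q < level) negative correlations.

    This is the vertical dashed line of the correlation-distribution plot:
    any gene left of it is a significant negative correlate.  ``None`` when no
    gene qualifies.
    """
    negatives = results[(results["pcc"] < 0) & (results["q"] < fdr_level)]
    if negatives.empty:
        return None
    return float(negatives["pcc"].max())


@dataclass(frozen=True)
class NullDistribution:
    """PCCs of ``n_sets`` random gene sets of a fixed size.

    ``pccs`` has shape (n_sets, set_size); ``gene_indices`` records which row
    of the correlation table each draw took (for reproducibility audits).
    """

    pccs: np.ndarray
    gene_indices: np.ndarray
    set_size: int
    n_sets: int
    seed: int

    def pooled(self) -> np.ndarray:
        return self.pccs.ravel()

    def set_medians(self) -> np.ndarray:
        return np.median(self.pccs, axis=1)


def random_set_null(
    query_size: int,
    expr: pd.DataFrame,
    drug: pd.Series,
    n_sets: int = DEFAULT_N_SETS,
    seed: int = 0,
    correlations: pd.DataFrame | None = None,
) -> NullDistribution:
    """Null distribution of PCCs from uniformly drawn gene sets.

    Each of the ``n_sets`` sets draws ``query_size`` genes without replacement
    (within a set; sets may overlap each other and the query) from all genes
    with defined correlations.  Pass ``correlations`` to reuse an existing
    :func:`per_gene_drug_pcc` table.
    """
    if correlations is None:
        correlations = per_gene_drug_pcc(expr, drug)
    pcc = correlations["pcc"].to_numpy()
    if query_size < 1 or query_size > pcc.size:
        raise ValidationError(
            f"query_size {query_size} outside [1, {pcc.size}] genes with defined correlations"
        )
    rng = np.random.default_rng(seed)
    indices = np.stack(
        [rng.choice(pcc.size, size=query_size, replace=False) for _ in range(n_sets)]
    )
    return NullDistribution(
        pccs=pcc[indices], gene_indices=indices, set_size=query_size, n_sets=n_sets, seed=seed
    )


def mannwhitney_less(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided Mann-Whitney: alternative "x stochastically smaller than y".

    Exact enumeration when both groups have <= EXACT_MW_MAX_N values and no
    ties; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ContractError("Mann-Whitney requires non-empty groups")
    small = x.size <= EXACT_MW_MAX_N and y.size <= EXACT_MW_MAX_N
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (small and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="less", method=method)
    return float(res.statistic), float(res.pvalue)


def gene_set_negative_enrichment(
    query: set[str],
    expr: pd.DataFrame,
    drug: pd.Series,
    null: NullDistribution,
    correlations: pd.DataFrame | None = None,
    method: str = "pooled",
) -> tuple[float, float]:
    """Is the query set enriched in negative expression-IC50 correlations?

    ``method="pooled"`` (default) ranks the query genes' PCCs against the
    pooled PCCs of all random sets with a one-sided Mann-Whitney test.
    ``method="empirical"`` instead reports U as NaN and p as the fraction of
    random sets whose median PCC is <= the query median (add-one corrected).
    """
    if correlations is None:
        correlations = per_gene_drug_pcc(expr, drug)
    query_pcc = correlations.loc[correlations.index.intersection(sorted(query)), "pcc"].to_numpy()
    if query_pcc.size == 0:
        raise ValidationError("no query gene has a defined correlation")
    if method == "pooled":
        return mannwhitney_less(query_pcc, null.pooled())
    if method == "empirical":
        medians = null.set_medians()
        p = (1 + int((medians <= np.median(query_pcc)).sum())) / (1 + medians.size)
        return float("nan"), float(p)
    raise ValidationError(f"unknown enrichment method {method!r}")


__all__ = [
    "DEFAULT_N_SETS",
    "DEFAULT_FDR_LEVEL",
    "EXACT_MW_MAX_N",
    "NullDistribution",
    "per_gene_drug_pcc",
    "negative_fdr_threshold",
    "random_set_null",
    "mannwhitney_less",
    "gene_set_negative_enrichment",
]
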