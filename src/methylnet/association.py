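"""Candidate-gene vs clinical-phenotype correlation network.

Every candidate gene's methylation profile is correlated with every clinical
variable by both Pearson and Spearman correlation; pairs significant at raw
P < alpha (no multiple-testing correction by default, an optional
Benjamini-Hochberg switch is provided) form a bipartite gene-phenotype edge
list with signed coefficients.  Disease-specific phenotypes (duration, CAS,
TRAb) exist only for cases, so those pairs are correlated within cases.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConstantInputError",
    "pearson_corr",
    "spearman_corr",
    "build_association_network",
    "PHENOTYPE_COLUMNS",
    "CASE_ONLY_PHENOTYPES",
]

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("age", "SBP", "DBP", "BMI", "duration", "CAS", "TRAb")
CASE_ONLY_PHENOTYPES = ("duration", "CAS", "TRAb")


class ConstantInputError(ValueError):
    """Correlation undefined because one input vector is constant."""


def _check(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    return x, y


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided P value from the t transform
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    x, y = _check(x, y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson r of mid-ranks, average ranks for ties) with a
    two-sided P value from the same t transform."""
    x, y = _check(x, y)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def build_association_network(
    candidate_levels: pd.DataFrame,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Bipartite gene-phenotype edge list at significance level ``alpha``.

    Parameters
    ----------
    candidate_levels : DataFrame
        Genes x samples methylation levels (index: gene/node id).
    phenotypes : DataFrame
        Samples x variables; rows are matched to ``candidate_levels`` columns
        by sample id.  Missing phenotype values (case-only variables in
        controls) restrict that pair to the complete samples.
    alpha : float
        Per-test significance threshold on the (optionally BH-adjusted) P.
    bh_correct : bool
        Apply Benjamini-Hochberg across all tests of each method.

    Returns a DataFrame (gene, phenotype, method, coefficient, p_value) of
    the retained edges; pairs with fewer than three complete observations
    or constant input are skipped with a logged warning.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    shared = [s for s in candidate_levels.columns if s in phenotypes.index]
    if not shared:
        raise ValueError("no shared sample ids between methylation and phenotypes")
    records = []
    for gene, profile in candidate_levels[shared].iterrows():
        for pheno in PHENOTYPE_COLUMNS:
            if pheno not in phenotypes.columns:
                continue
            pv = pd.to_numeric(phenotypes.loc[shared, pheno], errors="coerce")
            mask = pv.notna() & profile.notna()
            if mask.sum() < 3:
                logger.warning("skipping %s~%s: <3 complete pairs", gene, pheno)
                continue
            x = profile[mask].to_numpy(dtype=float)
            y = pv[mask].to_numpy(dtype=float)
            for method, fn in (("pearson", pearson_corr), ("spearman", spearman_corr)):
                try:
                    coef, p = fn(x, y)
                except ConstantInputError:
                    logger.warning("skipping %s~%s (%s): constant input", gene, pheno, method)
                    continue
                records.append(
                    {"gene": gene, "phenotype": pheno, "method": method,
                     "coefficient": coef, "p_value": p}
                )
    edges = pd.DataFrame(records, columns=["gene", "phenotype", "method", "coefficient", "p_value"])
    if edges.empty:
        return edges
    if bh_correct:
        for method in ("pearson", "spearman"):
            sel = edges["method"] == method
            if sel.any():
                edges.loc[sel, "p_value"] = multipletests(
                    edges.loc[sel, "p_value"], method="fdr_bh"
                )[1]
    return edges[edges["p_value"] < alpha].reset_index(drop=True)
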