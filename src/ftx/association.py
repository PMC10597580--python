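"""Per-gene linear regression of expression against phenotypes.

Each differentially expressed gene's normalized log2 expression (the
independent variable) is regressed on a per-sample phenotype — the
composite function score, one of its determinants, or muscle mass — with
a t-test of the slope-zero null. Genes are then classified by correlation
strength (inclusive |R| thresholds at 0.50 and 0.70), association
direction (sign of R) and age regulation (sign of the DE log2 fold
change). Association p-values are deliberately not multiplicity-adjusted;
screening filters on |R|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

logger = logging.getLogger(__name__)

R_MODERATE = 0.50
R_STRONG = 0.70


@dataclass(frozen=True)
class AssociationResult:
    gene_id: str
    phenotype: str
    slope: float
    intercept: float
    r: float
    r2: float
    pval: float
    strength: str  # strong | moderate | weak
    direction: str  # positive | negative
    regulation: str  # up | down


def regress_gene(x, y) -> dict[str, float]:
    """OLS of phenotype y on expression x; returns slope/intercept/R/R2/p.

    The p-value is the two-sided t-test of zero slope, i.e.
    t = R * sqrt((n-2)/(1-R^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise DomainError(f"need >= 3 samples, got {x.size}")
    if np.ptp(x) == 0:
        raise DomainError("zero variance in expression; regression undefined")
    fit = stats.linregress(x, y)
    r = float(fit.rvalue)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": r,
        "r2": r * r,
        "pval": float(fit.pvalue),
    }


def coefficient_of_determination(r: float) -> float:
    """R squared from a correlation coefficient."""
    if not math.isfinite(r) or abs(r) > 1:
        raise DomainError(f"correlation must be finite with |R| <= 1, got {r}")
    return r * r


def classify_strength(r: float, r_moderate: float = R_MODERATE, r_strong: float = R_STRONG) -> str:
    if abs(r) >= r_strong:
        return "strong"
    if abs(r) >= r_moderate:
        return "moderate"
    return "weak"


def classify(
    core: dict[str, float],
    de_log2fc: float,
    *,
    gene_id: str = "",
    phenotype: str = "",
    r_moderate: float = R_MODERATE,
    r_strong: float = R_STRONG,
) -> AssociationResult:
    """Attach strength/direction/regulation labels to regression output."""
    r = core["r"]
    if not math.isfinite(r):
        raise DomainError(f"non-finite correlation for gene {gene_id!r}")
    return AssociationResult(
        gene_id=gene_id,
        phenotype=phenotype,
        slope=core["slope"],
        intercept=core["intercept"],
        r=r,
        r2=core["r2"],
        pval=core["pval"],
        strength=classify_strength(r, r_moderate, r_strong),
        direction="positive" if r >= 0 else "negative",
        regulation="up" if de_log2fc > 0 else "down",
    )


def screen(
    norm_deg: pd.DataFrame,
    phenotypes: pd.DataFrame,
    de_log2fc: pd.Series,
    *,
    r_moderate: float = R_MODERATE,
    r_strong: float = R_STRONG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regress every (DEG, phenotype) pair and cross-tabulate the labels.

    norm_deg: normalized log2 expression restricted to DEGs (genes x samples).
    phenotypes: samples x named phenotype columns, same sample set.
    de_log2fc: per-DEG log2 fold change used for the regulation label.

    Returns (results, crosstab). ``results`` has one row per pair, sorted
    by phenotype then |R| descending with gene-id tie-breaking.
    ``crosstab`` counts genes per (phenotype, strength, direction,
    regulation) cell.
    """
    if norm_deg.empty:
        raise DomainError("DEG expression matrix is empty")
    if list(phenotypes.index) != list(norm_deg.columns):
        raise DomainError("phenotype rows must align with expression sample columns")
    rows = []
    for gene_id in norm_deg.index:
        x = norm_deg.loc[gene_id].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("gene %s has zero expression variance; skipped", gene_id)
            continue
        lfc = float(de_log2fc.loc[gene_id])
        for name in phenotypes.columns:
            y = phenotypes[name].to_numpy(dtype=float)
            if np.any(~np.isfinite(y)):
                raise DomainError(f"phenotype {name!r} has missing values")
            res = classify(
                regress_gene(x, y),
                lfc,
                gene_id=str(gene_id),
                phenotype=str(name),
                r_moderate=r_moderate,
                r_strong=r_strong,
            )
            rows.append(res.__dict__ | {"log2fc": lfc})
    results = pd.DataFrame(rows)
    results["abs_r"] = results["r"].abs()
    results = (
        results.sort_values(["phenotype", "abs_r", "gene_id"], ascending=[True, False, True], kind="stable")
        .drop(columns="abs_r")
        .reset_index(drop=True)
    )
    crosstab = (
        results.groupby(["phenotype", "strength", "direction", "regulation"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return results, crosstab
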