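"""Negative-binomial differential expression between two groups.

The model mirrors the standard bulk RNA-seq NB workflow: median-of-ratios
size factors, per-gene NB dispersions shrunk toward a mean-dispersion
trend, then a per-gene NB GLM (intercept + group, log2 link) fit by IRLS,
with a Wald test on the group coefficient and Benjamini-Hochberg
adjustment. Dispersion is parameterized so that Var = mu + alpha * mu^2.

The dispersion scheme is deliberately simple: method-of-moments per gene,
a robust a0 + a1/mu trend across genes, and geometric interpolation
between the two. The regularized-log transform is replaced throughout by
log2(count / size_factor + 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

LN2 = math.log(2.0)

__all__ = [
    "CountMatrix",
    "DispersionEstimates",
    "size_factors",
    "estimate_dispersions",
    "wald_test",
    "bh_adjust",
    "normalized_log2",
    "pca_scores",
    "top_z_heatmap_data",
    "fold_change",
    "fold_change_percent",
    "truncate",
]


class CountMatrix:
    """Non-negative integer gene x sample count matrix.

    Thin wrapper over a pandas DataFrame that enforces the count-matrix
    invariants (unique ids, integral non-negative cells) at construction.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise DomainError(f"duplicate gene ids: {dupes[:5]}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise DomainError(f"duplicate sample ids: {dupes[:5]}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DomainError("counts must be numeric")
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise DomainError(
                f"negative count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
            )
        if not np.allclose(values, np.round(values)):
            g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise DomainError(
                f"non-integer count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
            )
        self.frame = counts.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.columns

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.frame.loc[:, list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.frame.shape
        return f"CountMatrix({g} genes x {s} samples)"


def _as_frame(counts) -> pd.DataFrame:
    return counts.frame if isinstance(counts, CountMatrix) else pd.DataFrame(counts)


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors.

    Per-gene geometric means are computed over genes with all-positive
    counts; each sample's factor is the median ratio of its counts to
    those geometric means.
    """
    frame = _as_frame(counts)
    values = frame.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise DomainError("no gene has positive counts in every sample; size factors undefined")
    logs = np.log(values[all_positive])
    log_geomeans = logs.mean(axis=1)
    log_sf = np.median(logs - log_geomeans[:, None], axis=0)
    return pd.Series(np.exp(log_sf), index=frame.columns, name="size_factor")


@dataclass(frozen=True)
class DispersionEstimates:
    """Per-gene dispersions with their trend fit.

    alpha: final (shrunk) dispersion per gene; NaN for untestable genes.
    alpha_mom: raw method-of-moments estimate.
    trend_a0, trend_a1: coefficients of the trend alpha(mu) = a0 + a1/mu.
    """

    alpha: pd.Series
    alpha_mom: pd.Series
    trend_a0: float
    trend_a1: float

    def trend(self, mu: np.ndarray) -> np.ndarray:
        return self.trend_a0 + self.trend_a1 / np.asarray(mu, dtype=float)


ALPHA_FLOOR = 1e-8


def estimate_dispersions(
    counts,
    factors: pd.Series,
    group_labels=None,
    *,
    alpha_floor: float = ALPHA_FLOOR,
    trend_weight: float = 0.5,
) -> DispersionEstimates:
    """Method-of-moments NB dispersions shrunk toward an a0 + a1/mu trend.

    Moments are taken on normalized counts; when ``group_labels`` is
    given, the variance pools within-group deviations so group mean
    differences do not inflate dispersion. The trend is fit by robust
    (Huber) regression of the per-gene estimates on 1/mu, and the final
    dispersion geometrically interpolates the gene estimate toward the
    trend with weight ``trend_weight``. All-zero genes get NaN.
    """
    frame = _as_frame(counts)
    norm = frame.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    mu = norm.mean(axis=1)

    if group_labels is None:
        centered = norm - norm.mean(axis=1, keepdims=True)
        df = norm.shape[1] - 1
    else:
        labels = np.asarray(group_labels)
        centered = np.empty_like(norm)
        n_groups = 0
        for lab in np.unique(labels):
            mask = labels == lab
            if mask.sum() < 2:
                raise DomainError(f"group {lab!r} has < 2 samples")
            centered[:, mask] = norm[:, mask] - norm[:, mask].mean(axis=1, keepdims=True)
            n_groups += 1
        df = norm.shape[1] - n_groups
    if df < 1:
        raise DomainError("not enough samples to estimate dispersion")
    var = (centered**2).sum(axis=1) / df

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var - mu) / mu**2
    alpha_mom = np.where(mu > 0, np.maximum(alpha_mom, alpha_floor), np.nan)

    a0, a1 = _fit_dispersion_trend(mu, alpha_mom, alpha_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_trend = np.maximum(a0 + a1 / mu, alpha_floor)
    # Gene estimates well below the trend are indistinguishable from
    # sampling noise at small n, and letting them pull alpha down inflates
    # the Wald test; floor them near the trend before interpolating.
    # The 0.7 factor centers null type-I error on the nominal level.
    log_final = trend_weight * np.log(alpha_trend) + (1 - trend_weight) * np.log(
        np.maximum(alpha_mom, 0.7 * alpha_trend)
    )
    alpha = np.where(np.isnan(alpha_mom), np.nan, np.maximum(np.exp(log_final), alpha_floor))

    index = frame.index
    return DispersionEstimates(
        alpha=pd.Series(alpha, index=index, name="alpha"),
        alpha_mom=pd.Series(alpha_mom, index=index, name="alpha_mom"),
        trend_a0=float(a0),
        trend_a1=float(a1),
    )


def _fit_dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray, floor: float) -> tuple[float, float]:
    """Robust fit of alpha = a0 + a1/mu over informative genes."""
    usable = np.isfinite(alpha_mom) & (mu > 0) & (alpha_mom > floor)
    if usable.sum() < 10:
        # too few overdispersed genes to fit a trend; flat fallback
        med = float(np.nanmedian(alpha_mom[np.isfinite(alpha_mom)])) if np.isfinite(alpha_mom).any() else floor
        return max(med, floor), 0.0
    x = 1.0 / mu[usable]
    y = alpha_mom[usable]
    try:
        import statsmodels.api as sm

        design = sm.add_constant(x)
        fit = sm.RLM(y, design, M=sm.robust.norms.HuberT()).fit()
        a0, a1 = float(fit.params[0]), float(fit.params[1])
    except Exception:  # pragma: no cover - numerical fallback
        a1, a0 = np.polyfit(x, y, 1)
    return max(a0, floor), max(a1, 0.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise DomainError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def wald_test(
    counts,
    factors: pd.Series,
    dispersions: DispersionEstimates,
    group_labels,
    *,
    reference: str | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene NB Wald test of the group effect.

    Fits an NB GLM with log2 link and design (intercept + group indicator)
    by IRLS, vectorized across genes. ``log2fc`` is the group coefficient
    (non-reference over reference), ``se`` comes from the Fisher
    information at the fit, ``wald = log2fc / se`` with a two-sided
    standard-normal p-value, BH adjustment over tested genes, and the DEG
    flag applies padj < ``alpha`` and \\|log2fc\\| >= ``lfc_threshold``.

    All-zero and non-converged genes get NaN p-values and are excluded
    from the BH family.
    """
    frame = _as_frame(counts)
    labels = np.asarray(group_labels)
    if labels.shape[0] != frame.shape[1]:
        raise DomainError("group_labels length must match number of samples")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise DomainError(f"exactly two groups required, got {uniq}")
    if reference is None:
        reference = uniq[0]
    elif reference not in uniq:
        raise DomainError(f"reference {reference!r} not among groups {uniq}")
    x = (labels != reference).astype(float)
    if min((x == 0).sum(), (x == 1).sum()) < 2:
        raise DomainError("each group needs >= 2 samples")

    y = frame.to_numpy(dtype=float)
    sf = factors.loc[frame.columns].to_numpy(dtype=float)
    alpha_disp = dispersions.alpha.loc[frame.index].to_numpy(dtype=float)
    norm = y / sf[None, :]
    base_mean = norm.mean(axis=1)

    testable = (y.sum(axis=1) > 0) & np.isfinite(alpha_disp)
    beta0, beta1, se, converged = _irls_two_group(
        y[testable], sf, alpha_disp[testable], x, max_iter=max_iter, tol=tol
    )

    n_genes = frame.shape[0]
    log2fc = np.full(n_genes, np.nan)
    se_full = np.full(n_genes, np.nan)
    conv_full = np.zeros(n_genes, dtype=bool)
    log2fc[testable] = beta1
    se_full[testable] = se
    conv_full[testable] = converged

    with np.errstate(invalid="ignore", divide="ignore"):
        wald = log2fc / se_full
    pval = np.where(conv_full, 2 * stats.norm.sf(np.abs(wald)), np.nan)
    pval = np.where(np.isfinite(wald), pval, np.nan)

    padj = np.full(n_genes, np.nan)
    tested = np.isfinite(pval)
    if tested.any():
        padj[tested] = bh_adjust(pval[tested])

    is_deg = tested & (padj < alpha) & (np.abs(log2fc) >= lfc_threshold)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "se": se_full,
            "wald": wald,
            "pval": pval,
            "padj": padj,
            "is_deg": is_deg,
            "converged": conv_full,
        },
        index=frame.index,
    )


_ETA_CAP = 64.0  # |log2 mean| cap keeps 2**eta finite through IRLS


def _irls_two_group(y, sf, alpha_disp, x, *, max_iter, tol):
    """Vectorized IRLS for the NB GLM log2(mu) = b0 + b1*x + log2(sf).

    Exploits the binary design: the weighted normal equations reduce to a
    closed-form 2x2 solve per gene. Returns (beta0, beta1, se_beta1,
    converged) arrays over genes.
    """
    eps = 1e-6
    mean_ref = (y[:, x == 0] / sf[x == 0]).mean(axis=1)
    mean_alt = (y[:, x == 1] / sf[x == 1]).mean(axis=1)
    beta0 = np.log2(mean_ref + eps)
    beta1 = np.log2(mean_alt + eps) - beta0
    offset = np.log2(sf)[None, :]
    alpha_col = alpha_disp[:, None]
    converged = np.zeros(y.shape[0], dtype=bool)

    for _ in range(max_iter):
        eta = np.clip(beta0[:, None] + beta1[:, None] * x[None, :], -_ETA_CAP, _ETA_CAP) + offset
        mu = np.exp2(eta)
        w = (LN2**2) * mu / (1.0 + alpha_col * mu)  # (dmu/deta)^2 / Var
        z = (eta - offset) + (y - mu) / (mu * LN2)  # working response less offset
        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x[None, :] * z).sum(axis=1)
        # [[sw, swx], [swx, swx]] beta = [swz, swxz]
        sw_ref = sw - swx
        with np.errstate(divide="ignore", invalid="ignore"):
            new_beta0 = (swz - swxz) / sw_ref
            new_beta1 = swxz / swx - new_beta0
        new_beta0 = np.where(np.isfinite(new_beta0), new_beta0, beta0)
        new_beta1 = np.where(np.isfinite(new_beta1), new_beta1, beta1)
        step = np.maximum(np.abs(new_beta0 - beta0), np.abs(new_beta1 - beta1))
        beta0, beta1 = new_beta0, new_beta1
        newly = ~converged & (step < tol)
        converged |= newly
        if converged.all():
            break

    eta = np.clip(beta0[:, None] + beta1[:, None] * x[None, :], -_ETA_CAP, _ETA_CAP) + offset
    mu = np.exp2(eta)
    w = (LN2**2) * mu / (1.0 + alpha_col * mu)
    sw = w.sum(axis=1)
    swx = (w * x[None, :]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / swx + 1.0 / (sw - swx))
    return beta0, beta1, se, converged


def normalized_log2(counts, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1) — the package's rlog stand-in."""
    frame = _as_frame(counts)
    sf = factors.loc[frame.columns].to_numpy(dtype=float)
    if np.any(sf <= 0):
        raise DomainError("size factors must be positive")
    return pd.DataFrame(
        np.log2(frame.to_numpy(dtype=float) / sf[None, :] + 1.0),
        index=frame.index,
        columns=frame.columns,
    )


def pca_scores(norm: pd.DataFrame, n_components: int = 2, n_top_genes: int = 500):
    """PCA of samples on the top-variance genes of a normalized matrix.

    Returns (scores, percent_variance): per-sample component scores and
    the percent of total (selected-gene) variance per component.
    """
    n_samples = norm.shape[1]
    if n_samples < 2:
        raise DomainError("need >= 2 samples for PCA")
    if n_components > n_samples:
        raise DomainError(f"cannot extract {n_components} components from {n_samples} samples")
    variances = norm.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top_genes]
    mat = norm.loc[top].to_numpy(dtype=float)
    centered = (mat - mat.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    total_var = (centered**2).sum()
    if total_var == 0:
        pct = np.zeros(n_components)
    else:
        pct = 100.0 * (s[:n_components] ** 2) / total_var
    score_frame = pd.DataFrame(
        scores, index=norm.columns, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    return score_frame, pct


def top_z_heatmap_data(
    norm: pd.DataFrame, de: pd.DataFrame, k: int = 50, clip: float = 3.0
) -> pd.DataFrame:
    """Row z-scores of the top-k DEGs (by padj), clipped to [-clip, clip]."""
    degs = de[de["is_deg"]].sort_index(kind="stable").sort_values("padj", kind="stable")
    if len(degs) < k:
        warnings.warn(f"only {len(degs)} DEGs available, requested {k}", stacklevel=2)
    chosen = degs.index[:k]
    mat = norm.loc[chosen]
    sds = mat.std(axis=1, ddof=1)
    keep = sds > 0
    mat = mat.loc[keep]
    z = mat.sub(mat.mean(axis=1), axis=0).div(sds[keep], axis=0)
    return z.clip(lower=-clip, upper=clip)


def fold_change(log2fc: float) -> float:
    """Linear fold change 2**log2fc."""
    return float(2.0**log2fc)


def fold_change_percent(log2fc: float) -> float:
    """Expression as a percent of baseline: 100 * 2**log2fc."""
    if not math.isfinite(log2fc):
        raise DomainError("log2fc must be finite")
    return 100.0 * 2.0**log2fc


def truncate(value: float, decimals: int = 0) -> float:
    """Truncate toward zero at the given number of decimal places."""
    factor = 10.0**decimals
    result = math.trunc(value * factor) / factor
    return int(result) if decimals == 0 else result
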