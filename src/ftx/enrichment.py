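"""Dual gene-set enrichment: hypergeometric over-representation and
preranked GSEA, plus the intersection of the genes each method flags.

The over-representation route tests a fixed target list (the DEGs)
against a background (all tested genes) per term: upper-tail
hypergeometric p, enrichment ratio E = (b/n)/(B/N), BH q-values. The
GSEA route walks a weighted running sum down a score-ranked gene list,
with a gene-label permutation null for p, NES and FDR. The final step
intersects the DEG list with the genes of the q < 0.05 enriched terms and
the leading edges of the FDR < 0.25 GSEA terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import DomainError


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with term descriptions (GMT-shaped)."""

    sets: Mapping[str, frozenset]
    descriptions: Mapping[str, str]

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if len(members) < 1:
                raise DomainError(f"gene set {term!r} is empty")
            if any(not g for g in members):
                raise DomainError(f"gene set {term!r} has an empty gene id")

    @classmethod
    def from_dict(cls, mapping: Mapping[str, tuple[str, Sequence[str]]]) -> "GeneSetCollection":
        return cls(
            sets={term: frozenset(genes) for term, (_, genes) in mapping.items()},
            descriptions={term: desc for term, (desc, _) in mapping.items()},
        )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def hypergeometric_enrichment(
    target: Iterable[str], background: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Per-term over-representation of ``target`` within ``background``.

    Sets are restricted to the background before counting. Terms with no
    background overlap (B = 0) are skipped. Returns a frame with columns
    term, description, N, B, n, b, E, pval, qval sorted by p.
    """
    target = set(target)
    background = set(background)
    if not background:
        raise DomainError("background is empty")
    if not target <= background:
        extra = sorted(target - background)[:5]
        raise DomainError(f"target genes missing from background, e.g. {extra}")
    n_total = len(background)
    n_target = len(target)
    rows = []
    for term in collection:
        members = collection.sets[term] & background
        big_b = len(members)
        if big_b == 0:
            continue
        b = len(members & target)
        expected = n_target * big_b / n_total
        e_ratio = (b / n_target) / (big_b / n_total) if n_target else 0.0
        pval = float(stats.hypergeom.sf(b - 1, n_total, big_b, n_target))
        rows.append(
            {
                "term": term,
                "description": collection.descriptions.get(term, ""),
                "N": n_total,
                "B": big_b,
                "n": n_target,
                "b": b,
                "E": e_ratio,
                "expected": expected,
                "pval": pval,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "description", "N", "B", "n", "b", "E", "expected", "pval", "qval"]
        )
    out = pd.DataFrame(rows)
    out["qval"] = bh_adjust(out["pval"].to_numpy())
    return out.sort_values(["pval", "term"], kind="stable").reset_index(drop=True)


def hypergeometric_pvalue_bruteforce(N: int, B: int, n: int, b: int) -> float:
    """Upper-tail hypergeometric P[X >= b] by direct enumeration (oracle)."""
    total = comb(N, n)
    return sum(comb(B, k) * comb(N - B, n - k) for k in range(b, min(n, B) + 1)) / total


def _running_sum_es(hit_mask: np.ndarray, weights: np.ndarray, miss_pen: float):
    """ES (signed max deviation) and extremum index of one running sum."""
    hit_total = weights[hit_mask].sum()
    steps = np.where(hit_mask, weights / hit_total, -miss_pen)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def gsea_preranked(
    scores: pd.Series,
    collection: GeneSetCollection,
    *,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
    fdr_threshold: float = 0.25,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    Genes are ranked by score descending (ties broken by gene id). For
    each term the running sum gains \\|score\\|^w / sum-over-hits at term
    members and loses 1/(L - \\|set\\|) elsewhere; ES is the signed maximum
    deviation. The null permutes set membership over ranked positions
    (``exhaustive=True`` enumerates all position subsets when feasible).
    NES divides ES by the mean same-sign null ES magnitude; p is the
    same-sign null tail fraction; FDR pools normalized null scores across
    terms in the standard GSEA fashion.

    Returns one row per scored term: ES, NES, pval, fdr, significant
    (fdr < ``fdr_threshold``), leading_edge (comma-joined gene ids).
    """
    if scores.index.has_duplicates:
        raise DomainError("ranked list has duplicate gene ids")
    if n_perm < 100 and not exhaustive:
        raise DomainError("n_perm must be >= 100")
    order = sorted(scores.index, key=lambda g: (-scores[g], str(g)))
    ranked_genes = np.array(order)
    ranked_scores = scores.loc[order].to_numpy(dtype=float)
    weights = np.abs(ranked_scores) ** weight_exponent
    L = len(ranked_genes)
    pos_of = {g: i for i, g in enumerate(ranked_genes)}
    rng = np.random.default_rng(seed)

    obs = {}
    null_es: dict[str, np.ndarray] = {}
    for term in collection:
        positions = np.array(sorted(pos_of[g] for g in collection.sets[term] if g in pos_of))
        k = positions.size
        if k == 0 or k == L:
            continue  # no overlap, or no misses: ES undefined
        miss_pen = 1.0 / (L - k)
        hit_mask = np.zeros(L, dtype=bool)
        hit_mask[positions] = True
        es, idx = _running_sum_es(hit_mask, weights, miss_pen)
        if es >= 0:
            leading = [g for g in ranked_genes[: idx + 1] if g in collection.sets[term]]
        else:
            leading = [g for g in ranked_genes[idx:] if g in collection.sets[term]]
        obs[term] = {"ES": es, "k": k, "leading_edge": leading}
        null_es[term] = _null_es(weights, k, miss_pen, L, n_perm, rng, exhaustive)

    if not obs:
        return pd.DataFrame(
            columns=["term", "description", "size", "ES", "NES", "pval", "fdr", "significant", "leading_edge"]
        )

    rows = []
    all_null_nes_pos: list[np.ndarray] = []
    all_null_nes_neg: list[np.ndarray] = []
    nes_by_term = {}
    for term, rec in obs.items():
        nulls = null_es[term]
        pos_nulls = nulls[nulls >= 0]
        neg_nulls = nulls[nulls < 0]
        es = rec["ES"]
        mean_pos = pos_nulls.mean() if pos_nulls.size else np.nan
        mean_neg = np.abs(neg_nulls).mean() if neg_nulls.size else np.nan
        if es >= 0:
            nes = es / mean_pos if pos_nulls.size else np.nan
            pval = float((pos_nulls >= es).sum() / pos_nulls.size) if pos_nulls.size else 1.0
        else:
            nes = es / mean_neg if neg_nulls.size else np.nan
            pval = float((neg_nulls <= es).sum() / neg_nulls.size) if neg_nulls.size else 1.0
        nes_by_term[term] = nes
        if pos_nulls.size:
            all_null_nes_pos.append(pos_nulls / mean_pos)
        if neg_nulls.size:
            all_null_nes_neg.append(neg_nulls / mean_neg)
        rows.append(
            {
                "term": term,
                "description": collection.descriptions.get(term, ""),
                "size": rec["k"],
                "ES": es,
                "NES": nes,
                "pval": pval,
                "leading_edge": ",".join(rec["leading_edge"]),
            }
        )

    pooled_pos = np.concatenate(all_null_nes_pos) if all_null_nes_pos else np.array([])
    pooled_neg = np.concatenate(all_null_nes_neg) if all_null_nes_neg else np.array([])
    obs_nes = np.array([nes_by_term[r["term"]] for r in rows])
    for row in rows:
        nes = nes_by_term[row["term"]]
        if not np.isfinite(nes):
            row["fdr"] = 1.0
            continue
        if nes >= 0:
            null_frac = (pooled_pos >= nes).mean() if pooled_pos.size else 1.0
            obs_frac = (obs_nes[np.isfinite(obs_nes) & (obs_nes >= 0)] >= nes).mean()
        else:
            null_frac = (pooled_neg <= nes).mean() if pooled_neg.size else 1.0
            obs_frac = (obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)] <= nes).mean()
        row["fdr"] = float(min(1.0, null_frac / obs_frac)) if obs_frac > 0 else 1.0

    out = pd.DataFrame(rows)
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values(["pval", "term"], kind="stable").reset_index(drop=True)[
        ["term", "description", "size", "ES", "NES", "pval", "fdr", "significant", "leading_edge"]
    ]


_EXHAUSTIVE_LIMIT = 200_000


def _null_es(weights, k, miss_pen, L, n_perm, rng, exhaustive) -> np.ndarray:
    if exhaustive:
        if comb(L, k) > _EXHAUSTIVE_LIMIT:
            raise DomainError(f"exhaustive enumeration infeasible: C({L},{k}) subsets")
        subsets = list(combinations(range(L), k))
        out = np.empty(len(subsets))
        for i, positions in enumerate(subsets):
            hit_mask = np.zeros(L, dtype=bool)
            hit_mask[list(positions)] = True
            out[i], _ = _running_sum_es(hit_mask, weights, miss_pen)
        return out
    # vectorized sampled permutations: rows = permutations
    idx = np.argsort(rng.random((n_perm, L)), axis=1)[:, :k]
    hit = np.zeros((n_perm, L), dtype=bool)
    hit[np.arange(n_perm)[:, None], idx] = True
    w = np.broadcast_to(weights, (n_perm, L))
    hit_totals = np.where(hit, w, 0.0).sum(axis=1)
    steps = np.where(hit, w / hit_totals[:, None], -miss_pen)
    running = np.cumsum(steps, axis=1)
    ext = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), ext]


def enriched_term_genes(
    enrich: pd.DataFrame, collection: GeneSetCollection, q_threshold: float = 0.05
) -> set[str]:
    """Union of member genes of terms enriched at q < ``q_threshold``."""
    hits = enrich.loc[enrich["qval"] < q_threshold, "term"]
    genes: set[str] = set()
    for term in hits:
        genes |= set(collection.sets[term])
    return genes


def gsea_leading_edge_genes(gsea: pd.DataFrame, fdr_threshold: float = 0.25) -> set[str]:
    """Union of leading-edge genes of terms at FDR < ``fdr_threshold``."""
    genes: set[str] = set()
    for edge in gsea.loc[gsea["fdr"] < fdr_threshold, "leading_edge"]:
        if edge:
            genes |= set(edge.split(","))
    return genes


def intersect_methods(
    overrep_genes: Iterable[str], gsea_genes: Iterable[str], degs: Iterable[str]
) -> list[str]:
    """Genes flagged by both enrichment routes, restricted to the DEG list."""
    return sorted(set(degs) & set(overrep_genes) & set(gsea_genes))
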