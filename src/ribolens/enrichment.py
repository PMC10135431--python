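"""Over-representation analysis and ranked-list gene-set enrichment.

ORA uses the upper-tail hypergeometric test (one-sided Fisher) against a
user-supplied universe, BH-corrected across the collection.  GSEA computes
the weighted Kolmogorov-Smirnov running-sum enrichment score over a ranked
list, with a gene-label permutation null, sign-matched normalization (NES),
and the standard positive/negative-pool FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_adjust, hypergeom_tail

__all__ = ["ora", "rank_genes", "enrichment_score", "gsea"]

AXES = ("totalRNA", "translated", "translation", "buffering")


def ora(selected, gene_sets: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each set.

    ``selected`` must be a subset of ``universe``; sets are intersected with
    the universe first.  Returns overlap, expected overlap, p, and BH FDR.
    """
    universe = set(universe)
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    rows = []
    for name, genes in gene_sets.items():
        in_universe = set(genes) & universe
        if not in_universe:
            raise ValueError(f"gene set {name!r} has no genes in the universe")
        overlap = len(in_universe & selected)
        p = hypergeom_tail(overlap, len(universe), len(in_universe), len(selected))
        rows.append(
            {
                "set": name,
                "set_size": len(in_universe),
                "overlap": overlap,
                "expected": len(in_universe) * len(selected) / len(universe),
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("set")
    table["fdr"] = bh_adjust(table["p"])
    return table


def rank_genes(
    de_total: pd.DataFrame,
    de_polysome: pd.DataFrame,
    calls: pd.DataFrame,
    axis: str,
) -> pd.Series:
    """Signed ranking scores for one regulatory axis of one contrast.

    totalRNA -> total log2FC; translated -> polysome log2FC; translation ->
    APV gamma; buffering -> APV gamma_b.  Sorted descending, ties broken by
    gene id (stable).
    """
    if axis == "totalRNA":
        scores = de_total["log2fc"]
    elif axis == "translated":
        scores = de_polysome["log2fc"]
    elif axis == "translation":
        scores = calls["gamma"]
    elif axis == "buffering":
        scores = calls["gamma_b"]
    else:
        raise KeyError(f"unknown axis {axis!r}; expected one of {AXES}")
    scores = scores.astype(float).rename("score")
    if scores.isna().any():
        raise ValueError("missing axis effects for some genes")
    # sort by gene id first, then stable-sort by score: ties end up in id order
    return scores.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )


def enrichment_score(ranked_scores: np.ndarray, member: np.ndarray, weight: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score for one membership vector.

    ``ranked_scores`` must already be in ranking order (best first).  Hit
    steps are proportional to |score|^weight, miss steps uniform; the ES is
    the running-sum value of largest magnitude.
    """
    n = ranked_scores.size
    n_hit = int(member.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0
    hit_w = np.abs(ranked_scores) ** weight
    hit_w = np.where(member, hit_w, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:  # all member scores exactly zero
        hit_w = member.astype(float)
        total_hit = hit_w.sum()
    steps = hit_w / total_hit - (~member).astype(float) / (n - n_hit)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    ranked: pd.Series,
    gene_sets: dict,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Permutation GSEA over a descending-ranked score Series.

    The null permutes gene labels (random membership of the same size).  NES
    is ES divided by the mean |null ES| of matching sign; p and FDR follow
    the standard positive/negative-pool normalization.  Sets outside
    [min_size, max_size] after intersection with the ranked list are skipped.
    """
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    n = genes.size
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(genes)}

    results = []
    null_nes_pos, null_nes_neg = [], []
    for name, members in sorted(gene_sets.items()):
        idx = [gene_pos[g] for g in members if g in gene_pos]
        size = len(idx)
        if size < min_size or size > max_size:
            continue
        member = np.zeros(n, dtype=bool)
        member[idx] = True
        es = enrichment_score(scores, member, weight)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=size, replace=False)] = True
            null[b] = enrichment_score(scores, perm, weight)
        pos, neg = null[null >= 0], null[null < 0]
        if es >= 0:
            denom = pos.mean() if pos.size else np.nan
            p = (1.0 + np.sum(pos >= es)) / (1.0 + pos.size)
        else:
            denom = np.abs(neg.mean()) if neg.size else np.nan
            p = (1.0 + np.sum(neg <= es)) / (1.0 + neg.size)
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes = np.concatenate(
                [
                    pos / (pos.mean() if pos.size else np.nan),
                    neg / (np.abs(neg.mean()) if neg.size else np.nan),
                ]
            )
        null_nes_pos.append(null_nes[null_nes >= 0])
        null_nes_neg.append(null_nes[null_nes < 0])
        results.append({"set": name, "size": size, "es": es, "nes": nes, "p": p})

    table = pd.DataFrame(results)
    if table.empty:
        return table.set_index(pd.Index([], name="set")) if "set" not in table else table
    pool_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.empty(0)
    pool_neg = np.concatenate(null_nes_neg) if null_nes_neg else np.empty(0)
    obs = table["nes"].to_numpy()
    fdr = np.full(len(table), np.nan)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            frac_null = np.mean(pool_pos >= nes) if pool_pos.size else 0.0
            frac_obs = np.mean(obs[np.isfinite(obs) & (obs >= 0)] >= nes)
        else:
            frac_null = np.mean(pool_neg <= nes) if pool_neg.size else 0.0
            frac_obs = np.mean(obs[np.isfinite(obs) & (obs < 0)] <= nes)
        fdr[i] = min(frac_null / frac_obs, 1.0) if frac_obs > 0 else np.nan
    table["fdr"] = fdr
    table["direction"] = np.where(table["es"] >= 0, "+", "-")
    return table.set_index("set")
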