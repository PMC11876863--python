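"""Gene-set enrichment: preranked weighted running-sum GSEA and
hypergeometric overrepresentation.

The GSEA statistic is the classical weighted Kolmogorov-Smirnov-like running
sum: walking the ranking, genes in the set add ``|stat|^weight`` normalized
over the set's hits and genes outside subtract ``1 / (n - K)``; the
enrichment score (ES) is the maximal-magnitude deviation.  Significance comes
from gene-label permutations (random subsets of size K from the ranked
universe); NES divides ES by the mean permutation |ES| of matching sign.

Overrepresentation uses the exact upper hypergeometric tail against a
user-supplied background, with set-size bounds applied after intersecting
each set with the background.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .normde import bh_adjust

__all__ = [
    "rank_genes",
    "enrichment_score",
    "preranked_gsea",
    "hypergeometric_ora",
]

logger = logging.getLogger(__name__)


def rank_genes(stat: pd.Series) -> pd.Series:
    """Order genes by statistic descending, ties broken by gene id ascending.

    Duplicate gene ids are rejected.
    """
    if stat.index.duplicated().any():
        dups = sorted(set(stat.index[stat.index.duplicated()]))
        raise ValueError(f"duplicate gene ids in ranking: {dups[:5]}")
    order = sorted(stat.index, key=lambda g: (-stat[g], g))
    return stat.loc[order]


def enrichment_score(
    stat: np.ndarray, hit_positions: np.ndarray, weight: float = 1.0
) -> tuple[float, int]:
    """ES of a set at the given 0-based ranking positions, plus peak index.

    Returns the signed maximal deviation of the running sum and the ranking
    position at which it is attained (used for the leading edge).
    """
    n = len(stat)
    k = len(hit_positions)
    if k == 0 or k >= n:
        raise ValueError("set must hit at least one and fewer than all ranked genes")
    pos = np.sort(np.asarray(hit_positions))
    w = np.abs(stat[pos]) ** weight
    total = w.sum()
    cum = np.cumsum(w) / total if total > 0 else np.arange(1, k + 1) / k
    i = np.arange(k)
    miss_before = (pos - i) / (n - k)
    after = cum - miss_before  # running sum just after each hit
    before = np.r_[0.0, cum[:-1]] - miss_before  # just before each hit
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    if after[i_max] >= -before[i_min]:
        return float(after[i_max]), int(pos[i_max])
    return float(before[i_min]), int(pos[i_min])


def _permutation_es(
    rng: np.random.Generator,
    stat_abs_w: np.ndarray,
    k: int,
    n_perm: int,
    chunk: int = 2000,
) -> np.ndarray:
    """ES values for random size-k subsets of the ranking (vectorized)."""
    n = len(stat_abs_w)
    out = np.empty(n_perm)
    done = 0
    i = np.arange(k)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        pos = np.argpartition(rng.random((m, n)), k - 1, axis=1)[:, :k]
        pos.sort(axis=1)
        w = stat_abs_w[pos]
        total = w.sum(axis=1, keepdims=True)
        safe = np.where(total == 0, 1.0, total)
        cum = np.where(total == 0, (i + 1) / k, np.cumsum(w, axis=1) / safe)
        miss = (pos - i) / (n - k)
        after = cum - miss
        before = np.concatenate([np.zeros((m, 1)), cum[:, :-1]], axis=1) - miss
        mx = after.max(axis=1)
        mn = before.min(axis=1)
        out[done : done + m] = np.where(mx >= -mn, mx, mn)
        done += m
    return out


def preranked_gsea(
    ranked: pd.Series,
    sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Parameters
    ----------
    ranked
        Ranking statistic per gene; re-sorted internally via
        :func:`rank_genes`.
    sets
        Mapping set name -> gene ids.  Sets with no overlap with the ranking,
        or covering the whole ranking, are excluded with a warning.
    n_perm
        Number of gene-label permutations (random subsets of matching size);
        fewer than 100 is refused.  The minimum reported p is
        ``1 / (n_perm + 1)``.
    seed, weight
        Permutation seed and hit-increment exponent.

    Returns
    -------
    pandas.DataFrame
        Indexed by set name with columns ``es``, ``nes``, ``p``, ``padj``,
        ``size``, ``leading_edge`` (comma-joined gene ids) and
        ``nes_undefined`` (no same-sign permutation ES existed).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    ranked = rank_genes(ranked)
    genes = np.array(ranked.index)
    index_of = {g: i for i, g in enumerate(genes)}
    stat = ranked.to_numpy(dtype=float)
    stat_abs_w = np.abs(stat) ** weight
    n = len(genes)
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in sets.items():
        pos = np.array(sorted(index_of[g] for g in set(members) if g in index_of), dtype=int)
        k = len(pos)
        if k == 0:
            logger.warning("set %s has no overlap with the ranking; excluded", name)
            continue
        if k >= n:
            logger.warning("set %s covers the entire ranking; excluded", name)
            continue
        es, peak = enrichment_score(stat, pos, weight)
        if es >= 0:
            leading = [genes[i] for i in pos if i <= peak]
        else:
            leading = [genes[i] for i in pos if i >= peak]
        perm = _permutation_es(rng, stat_abs_w, k, n_perm)
        same_sign = perm >= 0 if es >= 0 else perm < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            nes, p, undefined = np.nan, np.nan, True
        else:
            denom = np.abs(perm[same_sign]).mean()
            nes = es / denom if denom > 0 else np.nan
            undefined = not np.isfinite(nes)
            extreme = int((np.abs(perm[same_sign]) >= abs(es)).sum())
            p = max((1 + extreme) / (1 + n_same), 1.0 / (n_perm + 1))
        rows.append((name, es, nes, p, k, ",".join(leading), undefined))

    out = pd.DataFrame(
        rows, columns=["set", "es", "nes", "p", "size", "leading_edge", "nes_undefined"]
    ).set_index("set")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out[["es", "nes", "p", "padj", "size", "leading_edge", "nes_undefined"]]


def hypergeometric_ora(
    hits: Sequence[str],
    background: Sequence[str],
    sets: Mapping[str, Sequence[str]],
    min_size: int = 10,
    max_size: int = 500,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation test.

    ``hits`` must be a subset of ``background``; each set is intersected with
    the background before the size bounds ``[min_size, max_size]`` are
    applied.  Per surviving term, ``p = P(X >= k)`` for X hypergeometric with
    population N = len(background), K = set size, n = len(hits).  Terms are
    flagged significant when both p and BH q fall below ``threshold``.
    """
    background_set = set(background)
    hit_set = set(hits)
    offenders = sorted(hit_set - background_set)
    if offenders:
        raise ValueError(f"hits not in background: {offenders[:10]}")
    N, n = len(background_set), len(hit_set)

    rows = []
    for name, members in sets.items():
        in_bg = set(members) & background_set
        K = len(in_bg)
        if K < min_size or K > max_size:
            continue
        k = len(in_bg & hit_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"]).set_index("term")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["p"] < threshold) & (out["q"] < threshold)
    return out
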