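"""Gene-set enrichment: hypergeometric over-representation analysis and a
weighted running-sum rank enrichment with a gene-label permutation null.

The rank statistic is the classic weighted Kolmogorov–Smirnov-like running
sum over a descending score ranking (Wald t-scores here): member genes add
|score|^weight normalized over the set, non-members subtract 1/(N−K), and
the enrichment score (ES) is the running sum at its maximal deviation from
zero. Nominal p-values come from random same-size gene sets, compared
sign-matched; NES divides ES by the mean |permuted ES| of matching sign.
The leading edge is the set members at or before the extremum.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import ValidationError
from .dge import adjust_bh

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ranked lists

def make_ranked_list(scores: pd.Series) -> pd.Series:
    """Sort gene scores descending (score ties broken by gene id) and
    validate uniqueness/finiteness."""
    if scores.index.has_duplicates:
        dup = scores.index[scores.index.duplicated()][0]
        raise ValidationError(f"duplicate gene {dup!r} in ranked list")
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValidationError("ranked scores must be finite")
    df = scores.rename("score").rename_axis("gene").reset_index()
    df = df.sort_values(["score", "gene"], ascending=[False, True],
                        kind="mergesort")
    return pd.Series(df["score"].to_numpy(), index=df["gene"].to_numpy())


# ---------------------------------------------------------------------------
# over-representation

def ora(query: list[str], universe: list[str],
        collection: dict[str, tuple[str, list[str]]],
        min_size: int = 15) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    Sets are restricted to the universe; only sets with restricted size
    strictly greater than ``min_size`` are tested. Query genes outside the
    universe are dropped with a warning. BH adjustment across tested sets.
    """
    uni: dict[str, None] = {}
    for g in universe:
        uni.setdefault(g, None)
    if not uni:
        raise ValidationError("empty universe")
    uni_set = set(uni)
    q = [g for g in dict.fromkeys(query) if g in uni_set]
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.warning("ora: %d query genes outside the universe dropped",
                       dropped)
    qset = set(q)
    M, n_q = len(uni), len(q)
    rows = []
    for name, (_, members) in collection.items():
        in_uni = [g for g in dict.fromkeys(members) if g in uni_set]
        K = len(in_uni)
        if K <= min_size:
            continue
        overlap_genes = [g for g in in_uni if g in qset]
        k = len(overlap_genes)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, K, n_q))
        rows.append({"set": name, "size": K, "overlap": k, "pvalue": p,
                     "genes": ",".join(overlap_genes)})
    out = pd.DataFrame(rows, columns=["set", "size", "overlap", "pvalue",
                                      "genes"])
    out["padj"] = adjust_bh(out["pvalue"]) if len(out) else []
    return out[["set", "size", "overlap", "pvalue", "padj", "genes"]]


# ---------------------------------------------------------------------------
# running-sum enrichment

def _running_sum(abs_w: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Running sum over the ranking for one membership mask."""
    N = abs_w.size
    K = int(member.sum())
    inc = np.full(N, -1.0 / (N - K))
    denom = abs_w[member].sum()
    if denom <= 0:
        # all member scores zero: fall back to equal increments
        inc[member] = 1.0 / K
    else:
        inc[member] = abs_w[member] / denom
    return np.cumsum(inc)


def enrichment_score(ranked: pd.Series, members: set, weight: float = 1.0
                     ) -> tuple[float, int]:
    """ES and the 0-based extremum position for one gene set."""
    genes = ranked.index.to_numpy()
    member = np.isin(genes, list(members))
    K = int(member.sum())
    N = genes.size
    if K == 0 or K == N:
        raise ValidationError("set must partially intersect the ranking")
    abs_w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    rs = _running_sum(abs_w, member)
    pos = int(np.argmax(np.abs(rs)))
    return float(rs[pos]), pos


def leading_edge(ranked: pd.Series, members: set, weight: float = 1.0
                 ) -> list[str]:
    """Set members contributing up to and including the running-sum
    extremum, in rank order (positions after the extremum for negative ES)."""
    es, pos = enrichment_score(ranked, members, weight)
    genes = ranked.index.to_numpy()
    member = np.isin(genes, list(members))
    if es >= 0:
        take = member & (np.arange(genes.size) <= pos)
    else:
        take = member & (np.arange(genes.size) >= pos)
    return list(genes[take])


def gsea(ranked: pd.Series, collection: dict[str, tuple[str, list[str]]],
         min_size: int = 15, n_perm: int = 1000, weight: float = 1.0,
         seed: int = 0) -> pd.DataFrame:
    """Preranked enrichment over a collection with a permutation null.

    For each set (restricted size strictly > ``min_size``): ES as above,
    nominal p by gene-label permutation with sign-matched comparison,
    NES = ES / mean(|permuted ES| of matching sign), BH FDR across sets,
    and the leading-edge members. Sets with no member in the ranking are
    skipped with a warning.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if weight < 0:
        raise ValidationError("weight must be >= 0")
    ranked = make_ranked_list(ranked)
    genes = ranked.index.to_numpy()
    N = genes.size
    abs_w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    rng = np.random.default_rng([int(seed), 101])
    gene_set = set(genes)

    rows = []
    perm_cache: dict[int, np.ndarray] = {}
    for name, (_, members) in collection.items():
        present = set(members) & gene_set
        K = len(present)
        if K == 0:
            logger.warning("gsea: set %r has no member in the ranking; "
                           "skipped", name)
            continue
        if K <= min_size or K >= N:
            continue
        es, pos = enrichment_score(ranked, present, weight)
        if K not in perm_cache:
            # same-size random member masks shared across sets of a size
            u = rng.random((n_perm, N))
            sel = np.argpartition(u, K - 1, axis=1)[:, :K]
            masks = np.zeros((n_perm, N), dtype=bool)
            np.put_along_axis(masks, sel, True, axis=1)
            perm_cache[K] = masks
        masks = perm_cache[K]
        inc = np.full((n_perm, N), -1.0 / (N - K))
        w_members = np.where(masks, abs_w[None, :], 0.0)
        denom = w_members.sum(axis=1)
        safe = denom > 0
        norm = np.where(safe, denom, 1.0)
        inc = np.where(masks, w_members / norm[:, None], inc)
        if (~safe).any():
            inc[~safe] = np.where(masks[~safe], 1.0 / K, -1.0 / (N - K))
        rs = np.cumsum(inc, axis=1)
        extremum = np.take_along_axis(
            rs, np.argmax(np.abs(rs), axis=1)[:, None], axis=1).ravel()
        same_sign = extremum * np.sign(es) > 0 if es != 0 else \
            np.ones(n_perm, dtype=bool)
        n_same = int(same_sign.sum())
        if n_same:
            exceed = np.abs(extremum[same_sign]) >= abs(es)
            pval = (1 + int(exceed.sum())) / (1 + n_same)
            nes = es / np.mean(np.abs(extremum[same_sign]))
        else:
            pval = 1.0 / (1 + n_perm)
            nes = np.nan
        le = leading_edge(ranked, present, weight)
        rows.append({"set": name, "size": K, "ES": es, "NES": nes,
                     "pvalue": pval, "leading_edge": ",".join(le)})
    out = pd.DataFrame(rows, columns=["set", "size", "ES", "NES", "pvalue",
                                      "leading_edge"])
    out["padj"] = adjust_bh(out["pvalue"]) if len(out) else []
    return out[["set", "size", "ES", "NES", "pvalue", "padj", "leading_edge"]]
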