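"""Upstream-regulator activation scoring against signed target knowledge.

Given a knowledge base of signed regulator→target edges (+1: the regulator's
activity increases target expression, −1: decreases it) and a per-subset
differential-expression result, each regulator gets an activation z-score
z = (n_consistent − n_inconsistent) / √n_overlap over its targets that are
significant at the chosen FDR. A positive z means the observed fold-change
pattern matches the regulator being active; the mirrored reading calls
inhibition. Overlap enrichment is assessed with Fisher's exact upper tail
and BH-adjusted across regulators. The regulator×subset z matrix can be
ordered by complete-linkage hierarchical clustering on Euclidean distances.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from ._utils import ValidationError
from .dge import SubsetResult, adjust_bh
from .io import validate_kb

logger = logging.getLogger(__name__)


def activation_z(kb: pd.DataFrame, result: SubsetResult,
                 fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Per-regulator activation z-scores against one subset's DE result.

    Targets are restricted to genes significant at FDR ≤ threshold with a
    nonzero log2 fold change (zero fold changes have undefined sign and are
    excluded from both counts and the overlap). Regulators with no
    significant target are omitted with a logged count.
    """
    kb = validate_kb(kb)
    if kb.empty:
        raise ValidationError("knowledge base is empty")
    tab = result.table.set_index("gene")
    universe = set(tab.index)
    sig_mask = tab["padj"].notna() & (tab["padj"] <= fdr_threshold)
    sig = tab[sig_mask]
    sig_nonzero = sig[sig["log2FoldChange"] != 0]
    lfc_sign = np.sign(sig_nonzero["log2FoldChange"])

    rows = []
    omitted = 0
    for regulator, edges in kb.groupby("regulator", sort=True):
        targets = [t for t in edges["target"] if t in universe]
        overlap_idx = [t for t in targets if t in sig_nonzero.index]
        n_overlap = len(overlap_idx)
        if n_overlap == 0:
            omitted += 1
            continue
        edge_sign = edges.set_index("target")["sign"]
        n_consistent = int(sum(
            lfc_sign[t] == edge_sign[t] for t in overlap_idx))
        n_inconsistent = n_overlap - n_consistent
        z = (n_consistent - n_inconsistent) / np.sqrt(n_overlap)
        # Fisher upper tail: are KB targets enriched among significant genes?
        n_sig = int(len(sig))
        n_targets = len(targets)
        n_sig_targets = int(sum(t in sig.index for t in targets))
        table = [[n_sig_targets, n_sig - n_sig_targets],
                 [n_targets - n_sig_targets,
                  len(universe) - n_sig - (n_targets - n_sig_targets)]]
        _, p = scipy.stats.fisher_exact(table, alternative="greater")
        rows.append({"regulator": regulator, "subset_id": result.subset_id,
                     "n_overlap": n_overlap, "n_consistent": n_consistent,
                     "n_inconsistent": n_inconsistent, "z": float(z),
                     "pvalue": float(p)})
    if omitted:
        logger.info("activation_z[%s]: %d regulators with no significant "
                    "target omitted", result.subset_id, omitted)
    out = pd.DataFrame(rows, columns=["regulator", "subset_id", "n_overlap",
                                      "n_consistent", "n_inconsistent", "z",
                                      "pvalue"])
    out["padj"] = adjust_bh(out["pvalue"]) if len(out) else []
    return out


def classify_regulators(results: pd.DataFrame, z_threshold: float = 1.0,
                        adj_p_threshold: float = 0.05) -> pd.DataFrame:
    """Label each row activated (z > threshold), inhibited (z < −threshold)
    or ns; both calls additionally require adjusted p strictly below the p
    threshold."""
    out = results.copy()
    state = np.where(
        (out["z"] > z_threshold) & (out["padj"] < adj_p_threshold),
        "activated",
        np.where((out["z"] < -z_threshold) & (out["padj"] < adj_p_threshold),
                 "inhibited", "ns"))
    out["state"] = state
    return out


def cluster_zmatrix(z: pd.DataFrame) -> dict:
    """Complete-linkage ordering of a regulator×subset z matrix.

    Missing entries are imputed as 0 with a logged count. Returns row and
    column leaf orderings plus the scipy linkage matrices (None when a
    dimension has fewer than 2 entries, in which case the identity ordering
    is used). Ties in merge distances follow scipy's deterministic
    tie-breaking on input order.
    """
    n_missing = int(z.isna().to_numpy().sum())
    if n_missing:
        logger.info("cluster_zmatrix: %d missing entries imputed as 0",
                    n_missing)
    filled = z.fillna(0.0)

    def _order(mat: np.ndarray):
        if mat.shape[0] < 2:
            return list(range(mat.shape[0])), None
        link = sch.linkage(mat, method="complete", metric="euclidean")
        return list(sch.leaves_list(link)), link

    row_order, row_linkage = _order(filled.to_numpy())
    col_order, col_linkage = _order(filled.to_numpy().T)
    return {
        "row_order": [filled.index[i] for i in row_order],
        "col_order": [filled.columns[i] for i in col_order],
        "row_linkage": row_linkage,
        "col_linkage": col_linkage,
    }
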