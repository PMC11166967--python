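"""Cross-subset and cross-mission consensus calling over per-subset
differential-expression results.

All operations are plain set logic over the per-subset FDR columns: a gene
is significant in a subset when its adjusted p-value is at or below the
threshold (inclusive ≤). Genes absent from a subset's tested universe count
as not significant there. Direction is not required to agree across subsets.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from ._utils import ValidationError
from .dge import SubsetResult

logger = logging.getLogger(__name__)


class ResultCollection:
    """Maps subset_id → :class:`SubsetResult` with the mission partition."""

    def __init__(self, results: list[SubsetResult]):
        if not results:
            raise ValidationError("result collection is empty")
        ids = [r.subset_id for r in results]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subset ids in collection")
        self.results = {r.subset_id: r for r in results}
        self.missions = {r.subset_id: r.mission for r in results}

    @property
    def subset_ids(self) -> list[str]:
        return list(self.results)

    def significant_sets(self, fdr_threshold: float) -> dict[str, set]:
        return {sid: r.significant(fdr_threshold)
                for sid, r in self.results.items()}

    def gene_universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.results.values():
            for g in r.table["gene"]:
                seen.setdefault(g, None)
        return list(seen)


def multi_subset_degs(collection: ResultCollection, fdr_threshold: float = 0.1,
                      min_subsets: int = 2) -> pd.DataFrame:
    """Genes significant (FDR ≤ threshold) in at least ``min_subsets``
    subsets, with one boolean flag column per subset."""
    if min_subsets < 1:
        raise ValidationError("min_subsets must be >= 1")
    sig = collection.significant_sets(fdr_threshold)
    rows = []
    for gene in collection.gene_universe():
        flags = {sid: gene in s for sid, s in sig.items()}
        n = sum(flags.values())
        if n >= min_subsets:
            rows.append({"gene": gene, "n_significant": n, **flags})
    return pd.DataFrame(rows, columns=["gene", "n_significant",
                                       *collection.subset_ids])


def cross_mission_degs(collection: ResultCollection,
                       fdr_threshold: float = 0.1,
                       min_missions: int = 2) -> list[str]:
    """Genes significant in at least one subset of each of ≥ ``min_missions``
    distinct missions."""
    if min_missions < 2:
        raise ValidationError("min_missions must be >= 2")
    if len(set(collection.missions.values())) < 2:
        logger.warning("cross_mission_degs: all subsets belong to one "
                       "mission; returning an empty list")
        return []
    sig = collection.significant_sets(fdr_threshold)
    out = []
    for gene in collection.gene_universe():
        missions = {collection.missions[sid]
                    for sid, s in sig.items() if gene in s}
        if len(missions) >= min_missions:
            out.append(gene)
    return out


def upset_counts(collection: ResultCollection,
                 fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Counts of genes significant in exactly each subset combination.

    Every non-empty combination of subsets gets a row; the counts partition
    the genes significant in at least one subset.
    """
    sig = collection.significant_sets(fdr_threshold)
    ids = collection.subset_ids
    membership: dict[tuple, int] = {}
    for gene in collection.gene_universe():
        combo = tuple(sid for sid in ids if gene in sig[sid])
        if combo:
            membership[combo] = membership.get(combo, 0) + 1
    rows = []
    for r in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, r):
            rows.append({"combination": "&".join(combo),
                         "degree": r,
                         "count": membership.get(combo, 0)})
    return pd.DataFrame(rows, columns=["combination", "degree", "count"])


def effect_matrix(collection: ResultCollection, genes: list[str],
                  statistic: str = "log2FC", fdr_threshold: float = 0.1
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene×subset matrix of a chosen statistic plus a significance mask.

    Entries for genes absent from a subset's tested universe are NaN in the
    value matrix and False in the mask (absent, not zero).
    """
    if not genes:
        raise ValidationError("gene list is empty")
    column = {"log2FC": "log2FoldChange", "t": "stat"}.get(statistic)
    if column is None:
        raise ValidationError(f"unknown statistic {statistic!r}")
    ids = collection.subset_ids
    values = pd.DataFrame(np.nan, index=genes, columns=ids)
    mask = pd.DataFrame(False, index=genes, columns=ids)
    for sid, res in collection.results.items():
        tab = res.table.set_index("gene")
        present = [g for g in genes if g in tab.index]
        values.loc[present, sid] = tab.loc[present, column]
        padj = tab.loc[present, "padj"]
        mask.loc[present, sid] = (padj.notna() & (padj <= fdr_threshold))
    return values, mask
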