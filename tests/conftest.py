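import warnings

import numpy as np
import pandas as pd
import pytest

from spaceskin import simdata

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="umap")


@pytest.fixture
def tiny_design():
    """One mission, one subset, 6+6 replicates."""
    return simdata.make_design(
        None, missions=["m1"], subsets=[simdata.Subset("s1", "m1")],
        replicates_per_group=6)


@pytest.fixture
def small_counts():
    """A 4-gene × 4-sample counts fixture with an ERCC spike-in."""
    return pd.DataFrame(
        [[10, 20, 12, 18], [0, 0, 0, 0], [5, 5, 5, 5], [100, 90, 110, 95]],
        index=["GENE1", "GENE2", "ERCC-00130", "GENE3"],
        columns=["a", "b", "c", "d"])


@pytest.fixture
def small_samples():
    return pd.DataFrame({
        "sample_id": ["a", "b", "c", "d"],
        "mission": ["m1"] * 4,
        "subset_id": ["s1"] * 4,
        "condition": ["flight", "flight", "ground", "ground"],
    })


def make_subset_result(subset_id, mission, genes, padj, lfc=None):
    """Build a SubsetResult from explicit padj (and optional lfc) vectors."""
    from spaceskin.dge import SubsetResult

    padj = np.asarray(padj, dtype=float)
    lfc = np.asarray(lfc, dtype=float) if lfc is not None \
        else np.ones(len(genes))
    se = np.ones(len(genes))
    tab = pd.DataFrame({
        "gene": genes, "baseMean": 10.0, "log2FoldChange": lfc,
        "lfcSE": se, "stat": lfc / se, "pvalue": padj, "padj": padj,
    })
    return SubsetResult(subset_id=subset_id, mission=mission, table=tab)
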