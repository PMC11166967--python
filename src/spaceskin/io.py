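"""Readers and writers for counts, sample metadata, gene sets, regulator
knowledge bases and ortholog maps, with shared validation.

Counts TSV dialect: genes in rows, first column the gene identifier, header
row the sample identifiers. MatrixMarket counts are written as a trio
(``.mtx`` plus ``.mtx.rownames`` / ``.mtx.colnames`` text files). Gene sets
use GMT semantics (name, description, members, tab-separated).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._utils import ValidationError

logger = logging.getLogger(__name__)

ERCC_PREFIX = "ERCC-"
CONDITIONS = ("flight", "ground")


# ---------------------------------------------------------------------------
# counts

def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene×sample counts matrix (non-negative integers, unique
    ids) and return it with gene/sample indices as plain strings."""
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("counts must be numeric")
    bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValidationError(
            f"count for gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
            f" is {values[g, s]!r}: entries must be non-negative integers"
        )
    out = counts.astype(np.int64)
    out.index = counts.index.astype(str)
    out.columns = counts.columns.astype(str)
    out.index.name = "gene_id"
    return out


def read_counts(path, format: str | None = None) -> pd.DataFrame:
    """Read a gene×sample counts matrix from TSV, CSV or MatrixMarket."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix, "tsv"
        )
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(str(path) + ".rownames").read_text().split()
        samples = Path(str(path) + ".colnames").read_text().split()
        if mat.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"MTX shape {mat.shape} does not match name files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValidationError(f"unknown counts format {format!r}")
    return validate_counts(df)


def write_counts(counts: pd.DataFrame, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".mtx": "mtx"}.get(path.suffix, "tsv")
    counts = validate_counts(counts)
    if format in ("tsv", "csv"):
        counts.to_csv(path, sep="\t" if format == "tsv" else ",")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(counts.to_numpy()))
        Path(str(path) + ".rownames").write_text("\n".join(counts.index) + "\n")
        Path(str(path) + ".colnames").write_text("\n".join(counts.columns) + "\n")
    else:
        raise ValidationError(f"unknown counts format {format!r}")


# ---------------------------------------------------------------------------
# sample table

SAMPLE_COLUMNS = ("sample_id", "mission", "subset_id", "condition")


def validate_samples(samples: pd.DataFrame, counts: pd.DataFrame | None = None
                     ) -> pd.DataFrame:
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise ValidationError(f"sample table missing column {col!r}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    bad = ~samples["condition"].isin(CONDITIONS)
    if bad.any():
        raise ValidationError(
            f"condition must be one of {CONDITIONS}, got "
            f"{samples.loc[bad, 'condition'].iloc[0]!r}"
        )
    for subset_id, grp in samples.groupby("subset_id"):
        if set(grp["condition"]) != set(CONDITIONS):
            raise ValidationError(
                f"subset {subset_id!r} lacks one of the conditions {CONDITIONS}"
            )
    if counts is not None:
        if set(samples["sample_id"]) != set(counts.columns):
            raise ValidationError(
                "sample table ids do not match counts matrix columns"
            )
    return samples.reset_index(drop=True)


def read_samples(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_samples(df, counts)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file into ``{name: (description, members)}``.

    Duplicate members within a set are deduplicated with a logged warning;
    lines with fewer than three fields are a parse error naming the line.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    f"and at least one member (got {len(fields)} fields)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate set name {name!r}"
                )
            seen: dict[str, None] = {}
            for m in members:
                if m in seen:
                    logger.warning(
                        "set %r: duplicate member %r deduplicated", name, m
                    )
                seen[m] = None
            if not seen:
                raise ValidationError(
                    f"{path}: line {lineno}: set {name!r} has no members"
                )
            sets[name] = (desc, list(seen))
    return sets


def write_gmt(collection: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# regulator knowledge base

def read_kb(path) -> pd.DataFrame:
    """Read a signed regulator→target edge table (regulator, target, sign)."""
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    return validate_kb(df)


def validate_kb(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("regulator", "target", "sign"):
        if col not in df.columns:
            raise ValidationError(f"knowledge base missing column {col!r}")
    if not df["sign"].isin([1, -1]).all():
        bad = df.loc[~df["sign"].isin([1, -1]), "sign"].iloc[0]
        raise ValidationError(f"edge sign must be +1 or -1, got {bad!r}")
    if df.duplicated(subset=["regulator", "target"]).any():
        row = df[df.duplicated(subset=["regulator", "target"])].iloc[0]
        raise ValidationError(
            f"duplicate edge ({row['regulator']!r}, {row['target']!r})"
        )
    return df.reset_index(drop=True)


def write_kb(df: pd.DataFrame, path) -> None:
    validate_kb(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog map

def read_ortholog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source", "target"):
        if col not in df.columns:
            raise ValidationError(f"ortholog map missing column {col!r}")
    if df.duplicated().any():
        row = df[df.duplicated()].iloc[0]
        raise ValidationError(
            f"fully duplicated ortholog row ({row['source']!r}, {row['target']!r})"
        )
    return df.reset_index(drop=True)


def map_orthologs(genes: list[str], ortholog_map: pd.DataFrame) -> list[str]:
    """Map gene ids through a (possibly one-to-many) ortholog table.

    Returns the union of all targets of the input genes in first-seen order;
    unmapped genes are dropped with a logged count. Duplicate targets arising
    from several sources are emitted once.
    """
    lookup: dict[str, list[str]] = {}
    for src, tgt in zip(ortholog_map["source"], ortholog_map["target"]):
        lookup.setdefault(src, []).append(tgt)
    out: dict[str, None] = {}
    unmapped = 0
    for g in genes:
        if g in lookup:
            for t in lookup[g]:
                out.setdefault(t, None)
        else:
            unmapped += 1
    if unmapped:
        logger.info("map_orthologs: %d of %d genes unmapped and dropped",
                    unmapped, len(genes))
    return list(out)
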