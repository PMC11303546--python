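"""Readers and writers for the pipeline's plain-text tables.

Coverage and PAV matrices are TSV with genes as rows and accessions as
columns (header row of accession ids, first column of gene ids);
accession metadata is CSV with the columns accession_id, gene_pool,
status, subgroup, latitude, longitude.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_accessions",
    "write_accessions",
    "read_pav",
    "write_pav",
    "read_labels",
    "write_labels",
]

ACCESSION_COLUMNS = [
    "accession_id",
    "gene_pool",
    "status",
    "subgroup",
    "latitude",
    "longitude",
]


def read_matrix(path) -> pd.DataFrame:
    """Genes × accessions float table (coverage breadth) from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_pav(path) -> pd.DataFrame:
    """Genes × accessions 0/1 table from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise ValueError(f"{path}: PAV matrix entries must be 0/1")
    return df.astype("int8")


def write_pav(df: pd.DataFrame, path) -> None:
    df.astype(int).to_csv(path, sep="\t", index_label="gene_id")


def read_accessions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ACCESSION_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["accession_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate accession ids")
    return df


def write_accessions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("label")


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="gene_id")
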