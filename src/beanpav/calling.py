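"""Coverage-threshold PAV calling and gene frequency classification.

The presence/absence call uses an accession-specific *MIN threshold*:
for each accession, take the breadth of coverage of ~1000 always-present
single-copy calibration genes (BUSCO orthologs), discard the 10
least-covered to remove outliers, and use the minimum of the remainder as
that accession's presence cutoff. A gene is called present when its
breadth is at or above the cutoff (the cutoff is itself the observed
breadth of a present gene, so the boundary counts as present).

Genes are then classified by presence frequency across the analyzed
accessions: core (f = 1), soft-core (0.90 <= f < 1), accessory
(0.10 <= f < 0.90) and rare (f < 0.10).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_min_threshold",
    "compute_thresholds",
    "call_presence",
    "pav_frequency",
    "classify_genes",
    "CATEGORIES",
]

CATEGORIES = ("core", "soft-core", "accessory", "rare")


def _check_breadth(values: np.ndarray, what: str) -> None:
    if np.isnan(values).any():
        raise ValueError(f"{what} contains missing values")
    if (values < 0).any() or (values > 1).any():
        raise ValueError(f"{what} must lie in [0, 1]")


def compute_min_threshold(busco_breadths, n_discard: int = 10) -> float:
    """Accession-specific MIN threshold from calibration-gene breadths.

    Removes exactly the ``n_discard`` smallest values (ties broken by
    position in the sorted order) and returns the minimum of the rest,
    i.e. the ``(n_discard + 1)``-th smallest breadth.
    """
    values = np.asarray(busco_breadths, dtype=float)
    if values.ndim != 1:
        raise ValueError("busco_breadths must be one-dimensional")
    if len(values) <= n_discard:
        raise ValueError(
            f"need more than n_discard={n_discard} calibration genes, "
            f"got {len(values)}"
        )
    _check_breadth(values, "busco breadths")
    return float(np.sort(values)[n_discard])


def compute_thresholds(
    busco_coverage: pd.DataFrame,
    n_discard: int = 10,
    busco_n: int | None = 1000,
    seed: int | None = None,
) -> pd.Series:
    """Per-accession MIN thresholds from a calibration coverage table.

    ``busco_coverage`` is genes × accessions. If the table has more than
    ``busco_n`` genes, a seeded random subset of exactly ``busco_n`` is
    drawn once and used for every accession.
    """
    table = busco_coverage
    if busco_n is not None and len(table) > busco_n:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(table), size=busco_n, replace=False)
        table = table.iloc[np.sort(keep)]
    return pd.Series(
        {
            acc: compute_min_threshold(table[acc].to_numpy(), n_discard)
            for acc in table.columns
        },
        name="min_threshold",
    )


def call_presence(
    coverage: pd.DataFrame, thresholds: Mapping[str, float] | pd.Series
) -> pd.DataFrame:
    """Binary PAV matrix: present iff breadth >= the accession's threshold."""
    thresholds = pd.Series(thresholds)
    missing = coverage.columns.difference(thresholds.index)
    if len(missing):
        raise ValueError(f"no threshold for accessions: {list(missing)[:5]}")
    _check_breadth(coverage.to_numpy(dtype=float), "coverage")
    cut = thresholds.loc[coverage.columns].to_numpy(dtype=float)
    calls = (coverage.to_numpy(dtype=float) >= cut[None, :]).astype(np.int8)
    return pd.DataFrame(calls, index=coverage.index, columns=coverage.columns)


def pav_frequency(
    matrix: pd.DataFrame, accession_subset: Sequence[str] | None = None
) -> pd.Series:
    """Per-gene presence frequency over the analyzed accession set.

    The denominator is always the analyzed subset (the full matrix when
    ``accession_subset`` is None).
    """
    if accession_subset is not None:
        subset = list(accession_subset)
        if not subset:
            raise ValueError("accession subset is empty")
        unknown = set(subset) - set(matrix.columns)
        if unknown:
            raise ValueError(f"accessions not in matrix: {sorted(unknown)[:5]}")
        matrix = matrix[subset]
    if matrix.shape[1] == 0:
        raise ValueError("matrix has no accessions")
    freq = matrix.sum(axis=1) / matrix.shape[1]
    freq.name = "frequency"
    return freq.astype(float)


def classify_genes(frequencies: pd.Series) -> pd.DataFrame:
    """Frequency classification: core / soft-core / accessory / rare.

    core iff f = 1; soft-core iff 0.90 <= f < 1; accessory iff
    0.10 <= f < 0.90; rare iff f < 0.10. The classes partition the genes.
    """
    f = pd.Series(frequencies, dtype=float)
    if ((f < 0) | (f > 1)).any() or f.isna().any():
        raise ValueError("frequencies must lie in [0, 1]")
    category = pd.Series("accessory", index=f.index, dtype=object)
    category[f == 1.0] = "core"
    category[(f >= 0.90) & (f < 1.0)] = "soft-core"
    category[f < 0.10] = "rare"
    out = pd.DataFrame({"frequency": f, "category": category})
    out.index.name = "gene_id"
    return out
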