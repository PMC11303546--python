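"""Single-locus FST scans, absence enrichment, and diagnostic screening.

Each PAV is treated as a single biallelic locus scored 0/1 per accession,
with presence frequency ``p`` playing the role of an allele frequency and
heterozygosity ``H(p) = 2p(1 − p)``. Between two populations,

    FST = (H_total − H_within) / H_total,

where ``H_within`` is the unweighted mean of the two within-population
heterozygosities and ``H_total`` is the heterozygosity of the unweighted
mean frequency. Genes in the top 5% of the FST distribution over the
variable genome are candidates for selection; a bootstrap over random
gene sets tests whether candidates are enriched for complete absence in a
focal population, and a per-gene Fisher exact test with
Benjamini–Hochberg correction screens for pool-diagnostic loci
(frequency 1 in one pool, 0 in the other).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "single_locus_fst",
    "select_accessions",
    "fst_scan",
    "absence_enrichment",
    "diagnostic_screen",
    "frequency_change_summary",
    "EnrichmentResult",
    "FrequencyChangeSummary",
]


def single_locus_fst(p1, p2):
    """Heterozygosity-based FST for a binary presence/absence locus.

    Accepts scalars or arrays; returns ``(h_within, h_total, fst)``.
    FST is defined as 0 when the pooled locus is monomorphic
    (``h_total = 0``).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if ((p1 < 0) | (p1 > 1)).any() or ((p2 < 0) | (p2 > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")

    def h(p):
        return 2.0 * p * (1.0 - p)

    h_within = (h(p1) + h(p2)) / 2.0
    h_total = h((p1 + p2) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(h_total > 0, (h_total - h_within) / np.where(h_total > 0, h_total, 1.0), 0.0)
    fst = np.clip(fst, 0.0, 1.0)
    if fst.ndim == 0:
        return float(h_within), float(h_total), float(fst)
    return h_within, h_total, fst


def relative_decline(freq_wild: float, freq_dom: float) -> float:
    """Relative loss of presence from wild to domesticated populations.

    ``(freq_wild − freq_dom) / freq_wild``; e.g. a decline from 0.94 to
    0.25 is a ≈73% relative loss.
    """
    if freq_wild <= 0:
        raise ValueError("wild frequency must be positive")
    return (freq_wild - freq_dom) / freq_wild


def select_accessions(accessions: pd.DataFrame, selector) -> list[str]:
    """Resolve a population selector to a list of accession ids.

    ``selector`` may be an explicit list of ids, a dict of metadata
    column → value filters (e.g. ``{"gene_pool": "M", "status": "wild"}``),
    or a string of comma-separated ``column=value`` pairs.
    """
    if isinstance(selector, str):
        selector = dict(
            pair.split("=", 1) for pair in selector.split(",") if pair
        )
    if isinstance(selector, dict):
        mask = pd.Series(True, index=accessions.index)
        for col, value in selector.items():
            if col not in accessions.columns:
                raise ValueError(f"unknown metadata column {col!r}")
            mask &= accessions[col].astype(str) == str(value)
        return accessions.loc[mask, "accession_id"].tolist()
    return list(selector)


def _pop_ids(matrix, accessions, selector, name):
    ids = (
        select_accessions(accessions, selector)
        if accessions is not None
        else list(selector)
    )
    ids = [a for a in ids if a in matrix.columns]
    if not ids:
        raise ValueError(f"population {name!r} selects no accessions")
    return ids


def fst_scan(
    matrix: pd.DataFrame,
    accessions: pd.DataFrame,
    pop1,
    pop2,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-gene FST between two populations with top-fraction candidates.

    The scan covers the variable genome: genes not present in every
    analyzed accession, excluding genes absent from both populations
    (monomorphic total, FST undefined). The candidate threshold is the
    ``1 − top_fraction`` quantile of the FST values and every gene at or
    above it is flagged, so reported cutoffs read as ``FST >= x``.
    """
    ids1 = _pop_ids(matrix, accessions, pop1, "pop1")
    ids2 = _pop_ids(matrix, accessions, pop2, "pop2")
    if set(ids1) & set(ids2):
        raise ValueError("populations must be disjoint")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")

    sub = matrix[ids1 + ids2]
    p1 = matrix[ids1].mean(axis=1)
    p2 = matrix[ids2].mean(axis=1)
    combined = sub.mean(axis=1)
    variable = (combined < 1.0) & ~((p1 == 0.0) & (p2 == 0.0))
    if not variable.any():
        warnings.warn("no variable genes between the selected populations")
        return pd.DataFrame(
            columns=[
                "p_pop1", "p_pop2", "h_within", "h_total", "fst",
                "candidate", "threshold_used",
            ]
        )

    p1v, p2v = p1[variable], p2[variable]
    h_within, h_total, fst = single_locus_fst(
        p1v.to_numpy(), p2v.to_numpy()
    )
    threshold = float(np.quantile(fst, 1.0 - top_fraction))
    out = pd.DataFrame(
        {
            "p_pop1": p1v,
            "p_pop2": p2v,
            "h_within": h_within,
            "h_total": h_total,
            "fst": fst,
            "candidate": fst >= threshold,
            "threshold_used": threshold,
        }
    )
    out.index.name = "gene_id"
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    n_candidates: int
    observed_absent_fraction: float
    background_absent_fraction: float
    n_boot: int
    p_value: float
    seed: int | None


def absence_enrichment(
    fst_table: pd.DataFrame,
    matrix: pd.DataFrame,
    focal_pop,
    accessions: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
    candidate_ids=None,
) -> EnrichmentResult:
    """Bootstrap test for complete-absence enrichment among candidates.

    The observed statistic is the fraction of candidate genes with
    presence frequency exactly 0 in the focal population. The null draws
    ``n_boot`` random gene sets of the same size, with replacement, from
    the variable genome (all genes in ``fst_table``) and recomputes the
    fraction; the add-one empirical p-value is
    ``(1 + #{null >= observed}) / (n_boot + 1)``.

    ``candidate_ids`` overrides the table's candidate flags with an
    explicit gene list; repeated ids are kept (a multiset), mirroring the
    null's with-replacement draws.
    """
    ids = _pop_ids(matrix, accessions, focal_pop, "focal_pop")
    focal_freq = matrix.loc[fst_table.index, ids].mean(axis=1)
    absent = (focal_freq == 0.0).to_numpy()

    if candidate_ids is None:
        cand_mask = fst_table["candidate"].to_numpy(dtype=bool)
        if not cand_mask.any():
            raise ValueError("candidate set is empty")
        k = int(cand_mask.sum())
        observed_count = int(absent[cand_mask].sum())
    else:
        candidate_ids = list(candidate_ids)
        if not candidate_ids:
            raise ValueError("candidate set is empty")
        positions = fst_table.index.get_indexer(candidate_ids)
        if (positions < 0).any():
            raise ValueError("candidate ids missing from the variable genome")
        k = len(positions)
        observed_count = int(absent[positions].sum())

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(absent), size=(n_boot, k))
    null_counts = absent[draws].sum(axis=1)
    p = (1 + int((null_counts >= observed_count).sum())) / (n_boot + 1)
    return EnrichmentResult(
        n_candidates=k,
        observed_absent_fraction=observed_count / k,
        background_absent_fraction=float(absent.mean()),
        n_boot=n_boot,
        p_value=p,
        seed=seed,
    )


def diagnostic_screen(
    matrix: pd.DataFrame,
    accessions: pd.DataFrame,
    poolA,
    poolB,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher exact screen for frequency differentiation between pools.

    For every gene, a two-sided Fisher exact test on the 2×2
    presence/absence × pool table, Benjamini–Hochberg adjusted across all
    tested genes. A gene is *diagnostic* when its presence frequencies are
    exactly (1, 0) or (0, 1) across the two pools.
    """
    idsA = _pop_ids(matrix, accessions, poolA, "poolA")
    idsB = _pop_ids(matrix, accessions, poolB, "poolB")
    nA, nB = len(idsA), len(idsB)

    presA = matrix[idsA].sum(axis=1).to_numpy()
    presB = matrix[idsB].sum(axis=1).to_numpy()

    # Fisher p depends only on the count pair; cache unique tables
    pvals = np.empty(len(matrix))
    cache: dict[tuple[int, int], float] = {}
    for i, (a, b) in enumerate(zip(presA, presB)):
        key = (int(a), int(b))
        if key not in cache:
            table = [[a, nA - a], [b, nB - b]]
            cache[key] = stats.fisher_exact(table, alternative="two-sided")[1]
        pvals[i] = cache[key]

    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    pA = presA / nA
    pB = presB / nB
    out = pd.DataFrame(
        {
            "p_pool1": pA,
            "p_pool2": pB,
            "fisher_p": pvals,
            "fdr_q": qvals,
            "significant": reject,
            "diagnostic": ((pA == 1.0) & (pB == 0.0))
            | ((pA == 0.0) & (pB == 1.0)),
        },
        index=matrix.index,
    )
    out.index.name = "gene_id"
    return out


@dataclass(frozen=True)
class FrequencyChangeSummary:
    n_candidates: int
    n_variable: int
    candidate_lower_fraction: float
    background_lower_fraction: float
    p_value: float


def frequency_change_summary(
    matrix: pd.DataFrame,
    accessions: pd.DataFrame,
    wild,
    dom,
    candidate_ids,
) -> FrequencyChangeSummary:
    """Wild-vs-domesticated frequency-decline contrast.

    A gene is *lower in domesticated* when its domesticated presence
    frequency is strictly below its wild frequency. Reports that fraction
    among the candidate genes and among the whole variable genome, with a
    two-sided two-proportion z-test contrasting candidates against the
    remaining (non-candidate) variable genes.
    """
    candidate_ids = list(candidate_ids)
    if not candidate_ids:
        raise ValueError("candidate list is empty")
    unknown = set(candidate_ids) - set(matrix.index)
    if unknown:
        raise ValueError(f"candidates not in matrix: {sorted(unknown)[:5]}")
    ids_w = _pop_ids(matrix, accessions, wild, "wild")
    ids_d = _pop_ids(matrix, accessions, dom, "dom")

    sub = matrix[ids_w + ids_d]
    combined = sub.mean(axis=1)
    fw = matrix[ids_w].mean(axis=1)
    fd = matrix[ids_d].mean(axis=1)
    variable = (combined < 1.0) & (combined > 0.0)
    lower = (fd < fw) & variable

    is_cand = matrix.index.isin(candidate_ids)
    n_cand = int((variable & is_cand).sum())
    n_var = int(variable.sum())
    if n_cand == 0:
        raise ValueError("no candidate falls in the variable genome")
    cand_lower = int((lower & is_cand).sum())
    bg_lower = int(lower.sum())

    rest_n = n_var - n_cand
    rest_lower = bg_lower - cand_lower
    if rest_n > 0:
        _, p = proportions_ztest(
            [cand_lower, rest_lower], [n_cand, rest_n], alternative="two-sided"
        )
        p = float(p)
    else:
        p = float("nan")
    return FrequencyChangeSummary(
        n_candidates=n_cand,
        n_variable=n_var,
        candidate_lower_fraction=cand_lower / n_cand,
        background_lower_fraction=bg_lower / n_var,
        p_value=p,
    )
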