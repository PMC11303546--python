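"""NG86 Ka/Ks on gapless reference-vs-accession CDS pairs.

Implements the Nei–Gojobori (1986) counting method: synonymous and
non-synonymous *sites* are counted per codon as the fraction of possible
single-nucleotide changes that preserve the encoded amino acid
(changes producing stop codons excluded from the tally), averaged over
the two sequences; *differences* between codon pairs are averaged over
all mutational pathways with equal weights, excluding pathways that pass
through a stop codon. The proportions pN = Nd/N and pS = Sd/S receive
the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3).

NA semantics mirror the study's reporting: a pair with no differences
yields ``na_no_variants``; a zero synonymous distance yields
``na_zero_denominator``; sequences whose length is not a multiple of
three are ``skipped_not_triplet``; a proportion at or beyond the 3/4
Jukes–Cantor ceiling is ``na_saturated``. Codons containing ``N`` in
either sequence, or coinciding with a stop codon, are excluded from both
site and difference counts.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "KaKsRecord",
    "ng86_kaks",
    "codon_sites",
    "codon_pair_differences",
    "kaks_from_fasta",
    "records_to_frame",
    "category_comparison",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FWD = _TABLE.forward_table
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


@dataclass(frozen=True)
class KaKsRecord:
    """One Ka/Ks comparison (gene × accession)."""

    gene_id: str
    accession_id: str
    ka: float
    ks: float
    ratio: float
    status: str  # ok | na_no_variants | na_zero_denominator | na_saturated | skipped_not_triplet


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts for one sense codon.

    Each of the three positions contributes one site, split by the
    fraction of its non-stop single-nucleotide changes that are
    synonymous.
    """
    syn = 0.0
    for pos in range(3):
        n_valid = 0
        n_syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in _STOPS:
                continue
            n_valid += 1
            if _FWD[mutant] == _FWD[codon]:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two sense codons.

    Averaged over all orderings of the differing positions with equal
    weight; pathways whose intermediate codons are stops are excluded
    (if every pathway is blocked, all pathways are used as a fallback).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        steps = []
        current = c1
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            steps.append((current, nxt))
            current = nxt
        return steps, blocked

    pathways = [walk(order) for order in itertools.permutations(diff_pos)]
    open_paths = [steps for steps, blocked in pathways if not blocked]
    if not open_paths:
        open_paths = [steps for steps, _ in pathways]

    syn = nonsyn = 0.0
    for steps in open_paths:
        for a, b in steps:
            # a stop intermediate only occurs on the fallback branch;
            # classify such steps as non-synonymous
            if a in _STOPS or b in _STOPS or _FWD[a] != _FWD[b]:
                nonsyn += 1
            else:
                syn += 1
    n = len(open_paths)
    return syn / n, nonsyn / n


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_kaks(
    ref_cds: str,
    alt_cds: str,
    gene_id: str = "",
    accession_id: str = "",
) -> KaKsRecord:
    """Pathway-averaged NG86 Ka, Ks and their ratio for one CDS pair.

    Sequences must be over {A, C, G, T, N}, gapless and equal length;
    unequal lengths raise, while a length not divisible by three returns
    a ``skipped_not_triplet`` record rather than raising.
    """
    ref = str(ref_cds).upper()
    alt = str(alt_cds).upper()
    if len(ref) != len(alt):
        raise ValueError(
            f"sequence lengths differ ({len(ref)} vs {len(alt)}); "
            "only gapless same-length pairs are comparable"
        )
    bad = set(ref + alt) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")

    def record(ka, ks, ratio, status):
        return KaKsRecord(gene_id, accession_id, ka, ks, ratio, status)

    nan = math.nan
    if len(ref) % 3 != 0:
        return record(nan, nan, nan, "skipped_not_triplet")

    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    for i in range(0, len(ref), 3):
        c1, c2 = ref[i : i + 3], alt[i : i + 3]
        if "N" in c1 or "N" in c2 or c1 in _STOPS or c2 in _STOPS:
            continue
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        sd, nd = codon_pair_differences(c1, c2)
        s_diff += sd
        n_diff += nd

    if s_diff + n_diff == 0:
        return record(nan, nan, nan, "na_no_variants")
    if s_sites == 0 or n_sites == 0:
        return record(nan, nan, nan, "na_zero_denominator")

    ps = s_diff / s_sites
    pn = n_diff / n_sites
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    if math.isnan(ks) or math.isnan(ka):
        return record(ka, ks, nan, "na_saturated")
    if ks == 0.0:
        return record(ka, ks, nan, "na_zero_denominator")
    return record(ka, ks, ka / ks, "ok")


def kaks_from_fasta(ref_fasta, alt_fasta) -> list[KaKsRecord]:
    """Compare per-accession CDSs against reference CDSs.

    The reference FASTA is keyed by ``gene_id``; accession records are
    named ``gene_id|accession_id`` and matched to their reference.
    """
    refs = {rec.id: str(rec.seq) for rec in SeqIO.parse(ref_fasta, "fasta")}
    out = []
    for rec in SeqIO.parse(alt_fasta, "fasta"):
        gene_id, _, accession_id = rec.id.partition("|")
        if gene_id not in refs:
            raise ValueError(f"no reference CDS for gene {gene_id!r}")
        out.append(
            ng86_kaks(refs[gene_id], str(rec.seq), gene_id, accession_id)
        )
    return out


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def category_comparison(
    records, classification: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category Ka/Ks distribution summary with pairwise rank tests.

    The ratio is averaged per gene over its ``ok`` records, genes are
    grouped by frequency category, and every category pair is compared
    with a two-sided Wilcoxon rank-sum (Mann–Whitney U) test. Categories
    with no usable gene are dropped with a warning.

    Returns ``(summary, pairwise)``: per-category n/median/mean, and the
    pairwise p-value table.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    ok = frame[frame["status"] == "ok"]
    per_gene = ok.groupby("gene_id")["ratio"].mean()

    cats = classification["category"]
    joined = pd.DataFrame({"ratio": per_gene}).join(cats, how="inner")

    groups = {}
    for cat in ("core", "soft-core", "accessory", "rare"):
        vals = joined.loc[joined["category"] == cat, "ratio"].to_numpy()
        if len(vals) == 0:
            warnings.warn(f"category {cat!r} has no genes with Ka/Ks; omitted")
            continue
        groups[cat] = vals

    summary = pd.DataFrame(
        {
            "n": {c: len(v) for c, v in groups.items()},
            "median": {c: float(np.median(v)) for c, v in groups.items()},
            "mean": {c: float(np.mean(v)) for c, v in groups.items()},
        }
    )
    summary.index.name = "category"

    names = list(groups)
    pairwise = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        try:
            p = float(
                stats.mannwhitneyu(
                    groups[a], groups[b], alternative="two-sided"
                ).pvalue
            )
        except ValueError:  # degenerate (e.g. all-identical) samples
            p = math.nan
        pairwise.loc[a, b] = pairwise.loc[b, a] = p
    return summary, pairwise
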