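"""Synthetic cohorts for pan-genome PAV analysis.

Generates common-bean-like cohorts — two differentiated gene pools
(Mesoamerican-like ``M`` and Andean-like ``A``), each with wild and
domesticated subgroups — together with coverage-breadth observations and
paired coding sequences, so the whole calling/scanning pipeline can be
exercised without any sequencing data.

The generative model plants four gene classes:

* ``core`` — present in every accession;
* ``neutral`` — presence sampled per pool from a baseline frequency range;
* ``diagnostic`` — fixed (frequency 1) in one pool, absent (frequency 0)
  in the other, split 90/10 between the pools;
* ``fst_outlier`` — large between-pool frequency gap, a configurable
  fraction completely absent in the focal (Andean-like) pool.

Wild accessions carry latitudes; the expected per-individual gene count
changes linearly with signed latitude relative to an origin latitude,
emulating progressive gene loss along a range-expansion gradient.
Coverage breadth follows a saturating Lander–Waterman-style response to a
negative-binomial per-gene depth draw, with low uniform spurious breadth
on absent genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "SimulationConfig",
    "TrueCohort",
    "simulate_cohort",
    "simulate_coverage",
    "simulate_cds_pair",
]

GENE_POOLS = ("M", "A")
STATUSES = ("wild", "domesticated")

#: domesticated subgroups per pool, echoing the common-bean races
_SUBGROUPS = {"M": ("M1", "M2"), "A": ("A1", "A2", "A3")}

#: pool-specific wild latitude ranges (degrees; south negative)
_DEFAULT_LATITUDE_RANGES = {"M": (5.0, 30.0), "A": (-30.0, -5.0)}

#: pool-specific longitude centers (degrees west, negative)
_LONGITUDE_CENTER = {"M": -100.0, "A": -65.0}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_accessions_per_group:
        Accessions per (gene pool × status) cell; 4 cells total.
    n_genes:
        Total genes in the pan-genome, including always-present core genes.
    frac_core:
        Fraction of genes present in every accession.
    n_diagnostic:
        Loci fixed in one pool and absent in the other, split between the
        pools by ``diagnostic_pool_split``.
    n_fst_outliers:
        Loci with a large between-pool presence-frequency gap;
        ``outlier_absent_fraction`` of them are completely absent from the
        focal pool.
    baseline_freq_range:
        Interval from which neutral per-pool presence frequencies are drawn.
    background_absent_fraction:
        Fraction of neutral loci set to frequency 0 in the focal pool, so
        the variable genome has a realistic background absence rate.
    latitude_slope:
        Expected change in per-individual gene count per degree of signed
        latitude (relative to ``origin_latitude``), applied to wild
        accessions through their neutral loci. Positive values mean gene
        loss moving south of the origin.
    depth_mean, depth_dispersion:
        Negative-binomial sequencing-depth model (mean and size).
    busco_n:
        Number of always-present calibration genes.
    noise_max:
        Upper bound of the uniform spurious breadth on absent genes.
    breadth_jitter_sd:
        SD of the multiplicative jitter on present-gene breadth.
    """

    n_accessions_per_group: int = 25
    n_genes: int = 2000
    frac_core: float = 0.59
    n_diagnostic: int = 42
    n_fst_outliers: int = 50
    outlier_absent_fraction: float = 0.64
    background_absent_fraction: float = 0.25
    baseline_freq_range: tuple[float, float] = (0.10, 0.90)
    latitude_slope: float = 1.0
    origin_latitude: float = 25.0
    latitude_ranges: dict = field(
        default_factory=lambda: dict(_DEFAULT_LATITUDE_RANGES)
    )
    diagnostic_pool_split: float = 0.90
    focal_pool: str = "A"
    depth_mean: float = 10.0
    depth_dispersion: float = 5.0
    busco_n: int = 1000
    noise_max: float = 0.02
    breadth_jitter_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions_per_group < 1:
            raise ConfigurationError("need at least one accession per group")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        for name in (
            "frac_core",
            "outlier_absent_fraction",
            "background_absent_fraction",
            "diagnostic_pool_split",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.baseline_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("baseline_freq_range must be within [0, 1]")
        if self.depth_mean < 0 or self.depth_dispersion <= 0:
            raise ConfigurationError("depth parameters must be non-negative")
        if not 0.0 <= self.noise_max <= 1.0:
            raise ConfigurationError("noise_max must lie in [0, 1]")
        if self.focal_pool not in GENE_POOLS:
            raise ConfigurationError(f"unknown focal pool {self.focal_pool!r}")
        n_core = int(round(self.frac_core * self.n_genes))
        if n_core + self.n_diagnostic + self.n_fst_outliers > self.n_genes:
            raise ConfigurationError(
                "core + diagnostic + outlier loci exceed n_genes"
            )


@dataclass
class TrueCohort:
    """Ground truth of a simulated cohort.

    ``pav_truth`` is the genes × accessions 0/1 matrix; ``accessions`` the
    metadata table (accession_id, gene_pool, status, subgroup, latitude,
    longitude); ``locus_labels`` maps each gene to its generative role
    (core | neutral | diagnostic | fst_outlier); ``true_freqs`` holds the
    per-pool generating frequencies used for neutral/outlier sampling.
    """

    pav_truth: pd.DataFrame
    accessions: pd.DataFrame
    locus_labels: pd.Series
    true_freqs: pd.DataFrame


def _make_accessions(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for pool, status in itertools.product(GENE_POOLS, STATUSES):
        lat_lo, lat_hi = config.latitude_ranges.get(
            pool, _DEFAULT_LATITUDE_RANGES[pool]
        )
        subgroups = (
            (f"Wild_{pool}",) if status == "wild" else _SUBGROUPS[pool]
        )
        for i in range(config.n_accessions_per_group):
            if status == "wild":
                # evenly spread latitudes so the gradient spans the range
                frac = i / max(config.n_accessions_per_group - 1, 1)
                lat = lat_lo + frac * (lat_hi - lat_lo)
                lon = _LONGITUDE_CENTER[pool] + rng.normal(0, 3.0)
            else:
                lat = np.nan
                lon = np.nan
            rows.append(
                {
                    "accession_id": f"{pool}_{status[:3]}_{i:03d}",
                    "gene_pool": pool,
                    "status": status,
                    "subgroup": subgroups[i % len(subgroups)],
                    "latitude": lat,
                    "longitude": lon,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig) -> TrueCohort:
    """Draw a cohort's true presence/absence matrix and metadata.

    Presence is sampled per accession from pool-specific generating
    frequencies; wild accessions additionally receive a latitude-dependent
    shift on their neutral loci so that the expected per-individual gene
    count changes by ``latitude_slope`` genes per degree relative to
    ``origin_latitude``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    accessions = _make_accessions(config, rng)
    n_acc = len(accessions)
    pools = accessions["gene_pool"].to_numpy()
    is_wild = (accessions["status"] == "wild").to_numpy()
    latitudes = accessions["latitude"].to_numpy()

    n_core = int(round(config.frac_core * config.n_genes))
    n_diag = config.n_diagnostic
    n_out = config.n_fst_outliers
    n_neutral = config.n_genes - n_core - n_diag - n_out

    labels = np.array(
        ["core"] * n_core
        + ["diagnostic"] * n_diag
        + ["fst_outlier"] * n_out
        + ["neutral"] * n_neutral
    )
    gene_ids = np.array([f"gene{i:05d}" for i in range(config.n_genes)])
    # shuffle gene roles so classes are interleaved along the gene axis
    order = rng.permutation(config.n_genes)
    labels = labels[order]

    other_pool = "M" if config.focal_pool == "A" else "A"
    freq = pd.DataFrame(
        1.0, index=gene_ids, columns=list(GENE_POOLS), dtype=float
    )

    diag_idx = np.flatnonzero(labels == "diagnostic")
    n_diag_first = int(round(config.diagnostic_pool_split * n_diag))
    for j, g in enumerate(diag_idx):
        fixed_pool = other_pool if j < n_diag_first else config.focal_pool
        for pool in GENE_POOLS:
            freq.iloc[g, freq.columns.get_loc(pool)] = (
                1.0 if pool == fixed_pool else 0.0
            )

    out_idx = np.flatnonzero(labels == "fst_outlier")
    n_absent = int(round(config.outlier_absent_fraction * n_out))
    for j, g in enumerate(out_idx):
        high = rng.uniform(0.8, 1.0)
        low = 0.0 if j < n_absent else rng.uniform(0.05, 0.2)
        freq.iloc[g, freq.columns.get_loc(other_pool)] = high
        freq.iloc[g, freq.columns.get_loc(config.focal_pool)] = low

    neut_idx = np.flatnonzero(labels == "neutral")
    lo, hi = config.baseline_freq_range
    n_bg_absent = int(round(config.background_absent_fraction * len(neut_idx)))
    for j, g in enumerate(neut_idx):
        if j < n_bg_absent:
            freq.iloc[g, freq.columns.get_loc(other_pool)] = rng.uniform(lo, hi)
            freq.iloc[g, freq.columns.get_loc(config.focal_pool)] = 0.0
        else:
            for pool in GENE_POOLS:
                freq.iloc[g, freq.columns.get_loc(pool)] = rng.uniform(lo, hi)

    # per-accession presence probabilities: pool frequency, plus the
    # latitude shift spread across that accession's adjustable neutral loci
    prob = freq.loc[:, pools].to_numpy()  # genes × accessions
    if n_neutral > 0:
        shift_total = np.where(
            is_wild & ~np.isnan(latitudes),
            config.latitude_slope * (latitudes - config.origin_latitude),
            0.0,
        )
        per_locus = shift_total / n_neutral
        prob[neut_idx, :] = np.clip(prob[neut_idx, :] + per_locus[None, :], 0, 1)

    draws = rng.random(prob.shape)
    truth = (draws < prob).astype(np.int8)
    # fixed classes are deterministic regardless of the latitude shift
    truth[labels == "core", :] = 1
    for g in diag_idx:
        for k, pool in enumerate(GENE_POOLS):
            truth[g, pools == pool] = int(freq.iloc[g, k])

    # label soundness both ways: a locus is realized as pool-diagnostic
    # (frequency exactly 1 in one pool, 0 in the other) iff labelled so;
    # sampling can fix a neutral/outlier locus by chance, so flip one
    # presence in the fixed pool to keep the realized classes faithful
    pool_masks = {pool: pools == pool for pool in GENE_POOLS}
    for g in np.flatnonzero(np.isin(labels, ("neutral", "fst_outlier"))):
        f = {pool: truth[g, m].mean() for pool, m in pool_masks.items()}
        fixed = [p for p in GENE_POOLS if f[p] == 1.0]
        empty = [p for p in GENE_POOLS if f[p] == 0.0]
        if fixed and empty:
            cols = np.flatnonzero(pool_masks[fixed[0]])
            truth[g, rng.choice(cols)] = 0

    pav_truth = pd.DataFrame(
        truth, index=gene_ids, columns=accessions["accession_id"].to_numpy()
    )
    return TrueCohort(
        pav_truth=pav_truth,
        accessions=accessions,
        locus_labels=pd.Series(labels, index=gene_ids, name="label"),
        true_freqs=freq,
    )


def _breadth(depth: np.ndarray, rng: np.random.Generator, jitter_sd: float) -> np.ndarray:
    # Lander–Waterman expectation: fraction of bases covered >= 1x
    b = 1.0 - np.exp(-depth.astype(float))
    if jitter_sd > 0:
        b = b * (1.0 + rng.normal(0.0, jitter_sd, size=b.shape))
    return np.clip(b, 0.0, 1.0)


def simulate_coverage(
    truth: TrueCohort, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observe coverage breadth for the cohort and its calibration genes.

    Returns ``(coverage, busco_coverage)``; both are genes × accessions
    tables of breadth values in [0, 1]. Present genes draw a
    negative-binomial depth (mean ``depth_mean``, size ``depth_dispersion``)
    and convert it to breadth via ``1 − exp(−depth)`` with multiplicative
    jitter; absent genes get uniform spurious breadth on
    ``[0, noise_max]``, scaled down when overall depth is near zero. The
    ``busco_n`` calibration genes are always present and share the same
    observation model.
    """
    config.validate()
    if not truth.pav_truth.isin([0, 1]).all().all():
        raise ValueError("truth matrix must be binary")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    n_genes, n_acc = truth.pav_truth.shape
    m, r = config.depth_mean, config.depth_dispersion

    def nb_depth(shape):
        if m == 0:
            return np.zeros(shape)
        return rng.negative_binomial(r, r / (r + m), size=shape)

    present = truth.pav_truth.to_numpy(dtype=bool)
    depth = nb_depth((n_genes, n_acc))
    breadth = _breadth(depth, rng, config.breadth_jitter_sd)
    spurious = rng.uniform(0.0, config.noise_max, size=(n_genes, n_acc))
    spurious *= 1.0 - np.exp(-m)
    coverage = np.where(present, breadth, spurious)

    busco_depth = nb_depth((config.busco_n, n_acc))
    busco = _breadth(busco_depth, rng, config.breadth_jitter_sd)

    cols = truth.pav_truth.columns
    coverage_df = pd.DataFrame(coverage, index=truth.pav_truth.index, columns=cols)
    busco_df = pd.DataFrame(
        busco,
        index=[f"busco{i:04d}" for i in range(config.busco_n)],
        columns=cols,
    )
    return coverage_df, busco_df


# --- coding-sequence pair generator -------------------------------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_STANDARD_TABLE.stop_codons)
_CODONS = [c for c in _STANDARD_TABLE.forward_table]  # sense codons only
_BASES = "ACGT"


def _single_nt_variants(codon: str):
    for pos in range(3):
        for b in _BASES:
            if b != codon[pos]:
                yield codon[:pos] + b + codon[pos + 1 :]


class GenerationError(ValueError):
    """Raised when requested substitutions cannot be placed."""


def simulate_cds_pair(
    n_codons: int, n_syn: int, n_nonsyn: int, seed: int = 0
) -> tuple[str, str]:
    """Build a reference/variant CDS pair with exact substitution counts.

    The two in-frame sequences have length ``3 * n_codons`` and differ by
    exactly ``n_syn`` synonymous and ``n_nonsyn`` non-synonymous point
    substitutions, one per codon, never creating a stop codon. Verified by
    per-codon translation before returning.
    """
    if n_codons < 1:
        raise GenerationError("n_codons must be >= 1")
    if n_syn + n_nonsyn > n_codons:
        raise GenerationError(
            "requested substitutions exceed available codons "
            f"({n_syn}+{n_nonsyn} > {n_codons})"
        )
    rng = np.random.default_rng(seed)
    fwd = _STANDARD_TABLE.forward_table

    def variants(codon, synonymous):
        out = []
        for v in _single_nt_variants(codon):
            if v in _STOPS:
                continue
            if (fwd[v] == fwd[codon]) == synonymous:
                out.append(v)
        return out

    # codons that admit the needed change type
    syn_capable = [c for c in _CODONS if variants(c, True)]
    nonsyn_capable = [c for c in _CODONS if variants(c, False)]

    ref = [str(rng.choice(_CODONS)) for _ in range(n_codons)]
    positions = rng.permutation(n_codons)
    syn_pos = positions[:n_syn]
    nonsyn_pos = positions[n_syn : n_syn + n_nonsyn]
    # re-draw target codons so the requested change type is placeable
    for p in syn_pos:
        ref[p] = str(rng.choice(syn_capable))
    for p in nonsyn_pos:
        ref[p] = str(rng.choice(nonsyn_capable))

    alt = list(ref)
    for p in syn_pos:
        alt[p] = str(rng.choice(variants(ref[p], True)))
    for p in nonsyn_pos:
        alt[p] = str(rng.choice(variants(ref[p], False)))

    n_syn_obs = sum(
        r != a and fwd[r] == fwd[a] for r, a in zip(ref, alt)
    )
    n_nonsyn_obs = sum(
        r != a and fwd[r] != fwd[a] for r, a in zip(ref, alt)
    )
    assert (n_syn_obs, n_nonsyn_obs) == (n_syn, n_nonsyn)
    return "".join(ref), "".join(alt)
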