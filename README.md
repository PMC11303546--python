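# beanpav

Presence/absence variation (PAV) analysis for plant pan-genomes, built
around the population structure of common bean (*Phaseolus vulgaris*):
two differentiated gene pools (Mesoamerican, Andean), each containing
wild and domesticated accessions. The package is aimed at researchers
who have per-accession gene coverage tables from low-coverage WGS
mapping against a pan-genome and want to call gene presence/absence,
characterize pan-genome structure, and scan for selection on gene loss.

## What it computes

* **MIN-threshold PAV calling** — for each accession, the breadth of
  coverage of ~1000 always-present single-copy orthologs (BUSCO genes)
  is collected, the 10 least-covered are discarded, and the minimum of
  the remainder becomes that accession's presence cutoff. A gene is
  present iff its breadth ≥ the cutoff. This adapts the cutoff to each
  accession's sequencing depth instead of using one fixed coverage
  fraction.
* **Frequency classification** — core (f = 1), soft-core
  (0.90 ≤ f < 1), accessory (0.10 ≤ f < 0.90), rare (f < 0.10).
* **Accumulation curves** — pan-gene (union) and core-gene
  (intersection) counts as accessions are added in many random orders;
  mean ± SD per step and the n at which the pan curve reaches 99% of its
  final size.
* **Single-locus FST scans** — each PAV is a binary locus with presence
  frequency p and heterozygosity H(p) = 2p(1 − p);
  F<sub>ST</sub> = (H<sub>total</sub> − H<sub>within</sub>)/H<sub>total</sub>
  with unweighted population means. Genes in the top 5% of the FST
  distribution over the variable genome are candidates.
* **Bootstrap absence enrichment** — is complete absence from a focal
  population over-represented among candidates relative to random gene
  sets from the variable genome?
* **Diagnostic-PAV screen** — per-gene Fisher exact tests
  (Benjamini–Hochberg corrected) between gene pools, flagging loci fixed
  in one pool and absent in the other.
* **Frequency-change summaries** — the fraction of genes at lower
  frequency in domesticated than wild accessions, among candidates vs
  the whole variable genome, with a two-proportion test.
* **NG86 Ka/Ks** — pathway-averaged synonymous/non-synonymous counting
  with Jukes–Cantor correction on reference-vs-accession CDS pairs, with
  explicit NA statuses (no variants, zero denominator, non-triplet
  length, saturation), and per-frequency-category rank-sum comparisons.
* **Synthetic cohorts** — a generator that plants core, neutral,
  diagnostic and high-FST outlier loci in a two-pool wild/domesticated
  cohort with a latitudinal gradient and depth-dependent coverage noise,
  so every stage above can be exercised and benchmarked without data
  downloads.

## Worked example

```python
import beanpav as bp

cfg = bp.SimulationConfig(seed=42)            # 2 pools × 2 statuses × 25, 2000 genes, 10× depth
cohort = bp.simulate_cohort(cfg)
coverage, busco = bp.simulate_coverage(cohort, cfg)

thresholds = bp.compute_thresholds(busco)     # accession-specific MIN thresholds
pav = bp.call_presence(coverage, thresholds)

table = bp.classify_genes(bp.pav_frequency(pav))
curve = bp.accumulation_curves(pav, n_orders=100, seed=42)
scan = bp.fst_scan(pav, cohort.accessions,
                   {"gene_pool": "M", "status": "wild"},
                   {"gene_pool": "A", "status": "wild"})
enr = bp.absence_enrichment(scan, pav, {"gene_pool": "A", "status": "wild"},
                            accessions=cohort.accessions, n_boot=10_000, seed=42)
```

This prints (via the calls in the snippet's full version):

```
MIN thresholds: 0.624-0.852
per-cell error vs truth: 0.85%
classes: {'accessory': 799, 'soft-core': 781, 'core': 399, 'rare': 21}
pan(N) = 2000, core(N) = 399, 99% saturation at n = 13
68 candidates (FST >= 0.85) of 1283 variable genes
absence enrichment: 91% of candidates vs 20% background, p = 1.0e-04
diagnostic PAVs: 42 (planted: 42)
```

Reading the output: each accession's presence cutoff is the breadth of
its 11th least-covered calibration gene (0.62–0.85 here, tracking its
depth draw); calling recovers the planted truth matrix to within 0.85%
per cell; the pan curve saturates after ~13 accessions on this small
closed cohort; 68 of 1283 variable genes sit in the top 5% of the FST
distribution between the wild pools, and 91% of them are completely
absent from the focal (Andean-like) wild pool against a 20% background
rate — a strong, bootstrap-validated enrichment for gene loss. All 42
planted pool-diagnostic loci are recovered by the Fisher screen.

The same pipeline is scriptable from the shell via the `beanpav` CLI
(`simulate`, `call-pav`, `classify`, `curves`, `counts`,
`latitude-trend`, `fst-scan`, `enrich-absence`, `diagnostic`,
`freq-change`, `kaks`).

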