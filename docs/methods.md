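# Methods

## PAV calling with the MIN threshold

The caller consumes breadth-of-coverage tables: for each gene and
accession, the fraction of the gene's bases covered by at least one
read, a value in [0, 1]. Breadth (rather than mean depth) is used
because the accession-specific threshold is contrasted with the common
fixed "5% of the gene covered" convention, which is a breadth rule.

For each accession the breadths of ~1000 BUSCO single-copy orthologs —
genes assumed present in every accession — are sorted, the 10 smallest
are discarded as outliers (mis-annotation, collapsed repeats, dropout),
and the minimum of the remainder (the 11th-smallest breadth) becomes the
accession's presence cutoff. A gene is called present iff its breadth is
**at or above** the cutoff: the cutoff is itself the observed breadth of
a gene known to be present, so the boundary must call present. If more
than 1000 calibration genes are supplied, exactly 1000 are subsampled
once with the run seed.

Known failure mode: if an accession has more than 10 BUSCO genes with
zero breadth (very low or failed sequencing), the cutoff collapses to 0
and every gene is called present for that accession. The discard
parameter bounds the protection at 10 dropouts by construction; callers
should screen accessions for minimum depth first.

Frequencies are always computed over the analyzed accession subset,
stated per analysis; "core" means frequency exactly 1 over that subset.
The classification bins are core f = 1, soft-core 0.90 ≤ f < 1,
accessory 0.10 ≤ f < 0.90, rare f < 0.10; they partition the genes.
Missing coverage cells are an error, never imputed — a 0/1 matrix admits
no third state.

## Pan-genome structure

Accumulation curves add accessions in uniformly sampled random orders
(with replacement over permutation space; the reference analysis used
1000 orders). For each ordering, pan(n) is the union size and core(n)
the intersection size of the first n accessions' gene sets; means and
population SDs are reported per n. The saturation point is the smallest
n at which the mean pan curve reaches a stated fraction (default 99%) of
its final size — one crisp reading of "the curve flattens"; plateau-
slope rules are an alternative we do not implement.

The latitude trend is an ordinary least-squares regression of
per-individual gene counts on signed latitude (south negative), by
default over wild accessions only, matching the use of a wild panel
spanning the species' range; the two-sided p tests a zero slope.

## Selection scans on binary loci

Every PAV is treated as a single biallelic locus carried haploid:
presence frequency p plays the role of an allele frequency and
H(p) = 2p(1 − p) the heterozygosity. Between two populations,

    FST = (H_total − H_within) / H_total

with **unweighted** means: H_within = (H(p1) + H(p2))/2 and
H_total = H((p1 + p2)/2). Unweighted means reproduce the published
worked value for the wild/domesticated frequencies (0.94, 0.25) →
FST = 0.494 (reported as 0.50), whereas sample-size weighting gives
≈0.39. When the pooled locus is monomorphic (H_total = 0) FST is defined
as 0 and the gene is excluded from the ranked variable genome.

The scan covers the variable genome — genes not present in every
analyzed accession and not absent from both populations. The candidate
threshold is the 95th percentile (numpy linear interpolation) of the FST
values and every gene **at or above** it is flagged, so reported cutoffs
read "FST ≥ x"; ties can push the candidate count above 5%.

Absence enrichment: the observed statistic is the fraction of candidates
with presence frequency exactly 0 in the focal population. The null
resamples gene sets of the same size uniformly **with replacement** from
the variable genome, 10,000 draws by default, and the p-value is the
add-one empirical tail (1 + #{null ≥ observed})/(n_boot + 1), which
cannot be 0. Resample size, replacement and tail are our choices; the
reference analysis names bootstrap resampling without parameters.

Diagnostic screen: per gene, a two-sided Fisher exact test on the 2×2
presence × pool table, Benjamini–Hochberg adjusted across all tested
genes at α = 0.05 (the standard reading of "FDR corrected");
"diagnostic" means frequencies exactly (1, 0) or (0, 1) and is a
property of the frequencies, not of the test.

Frequency change: a gene is "lower in domesticated" iff its domesticated
frequency is strictly below its wild frequency. We report that fraction
among candidate genes and among the whole variable genome. The
accompanying two-proportion z-test contrasts candidates against the
**non-candidate** variable genes rather than against the full variable
genome: the candidate set is a subset of the latter, and a two-sample
test between overlapping samples misstates the variance, so its null
p-values would not be uniform. The two reported fractions are unchanged
by this choice.

## NG86 Ka/Ks

Synonymous/non-synonymous sites are counted per codon as the fraction of
possible single-nucleotide changes that preserve the amino acid, with
changes to stop codons excluded from the tally, averaged over the two
sequences. Differences between codon pairs are averaged over all
orderings of the differing positions with equal weights; pathways
passing through a stop codon are excluded (if every pathway is blocked,
all are used and stop-crossing steps count as non-synonymous). Codons
containing N in either sequence, or equal to a stop codon, are excluded
entirely. The proportions pN, pS receive the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3).

NA semantics: no differences → `na_no_variants`; synonymous distance
zero (or no countable sites) → `na_zero_denominator`; length not
divisible by three → `skipped_not_triplet` (returned, not raised);
p ≥ 3/4 → `na_saturated` (the JC ceiling — note that even a single
synonymous change in a short pair can saturate, e.g. pS = 0.75 on a
two-codon pair with S = 4/3 sites). Unequal lengths are an error; the
module deliberately consumes pre-built, gapless, equal-length CDS pairs
and does no alignment or consensus construction. NG86 with equal
pathway weights and JC correction is used in place of external
model-averaging calculators: it is the canonical, fully specified
baseline for this counting problem.

Category comparison averages the ratio per gene over its `ok` records,
groups genes by frequency category and compares every pair of categories
with a two-sided Wilcoxon rank-sum test; empty categories are dropped
with a warning and single-gene categories are reported but make the
corresponding tests uninformative rather than crashing.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not sequence data: no reads, reference or alignment are produced.

Cohort: two gene pools (Mesoamerican-like "M", Andean-like "A") × two
statuses (wild, domesticated), 25 accessions per cell by default (a
desk-scale stand-in for the reference panel's 339 accessions).
Domesticated accessions carry subgroup labels (M1–M2, A1–A3); wild
accessions carry latitudes spread evenly over pool-specific ranges
(M: 5–30°, A: −30 to −5°).

Gene classes (defaults chosen to mirror the reference proportions at
n_genes = 2000): 59% core (always present); 42 diagnostic loci fixed in
one pool and absent in the other, split 90/10 toward the M pool; 50
high-FST outlier loci with frequencies ~U(0.8, 1) in the M pool and
either exactly 0 (64% of them) or U(0.05, 0.2) in the focal A pool; the
remainder neutral with per-pool frequencies drawn from U(0.1, 0.9),
except that 25% of neutral loci are set to frequency 0 in the focal pool
so the variable genome has a realistic background absence rate. Presence
is sampled independently per accession from its pool's frequency.

Latitude gradient: wild accessions' neutral-locus presence probabilities
are shifted by slope × (latitude − 25°)/n_neutral, so the expected
per-individual gene count changes by the configured slope (genes per
degree) relative to the northern origin of the range; the realized
count–latitude regression additionally absorbs the between-pool
gene-content difference, so fitted slopes on full default cohorts exceed
the configured within-pool value. Clipping probabilities to [0, 1]
attenuates large shifts.

Label soundness is enforced in both directions: beyond planting the
labelled classes, any neutral/outlier locus whose sampled realization
lands on exactly (1, 0) pool frequencies gets one presence flipped, so
the realized diagnostic set equals the labelled one. Without this, a
locus at frequency 0.9 in a 50-accession pool realizes all-present with
probability ≈0.005 and the planted/recovered correspondence would fail
sporadically — recovery of the planted set would not be a testable
property of the screen.

Coverage observation model: per gene × accession, depth is drawn
negative-binomial with mean 10 (the study's low-coverage regime) and
dispersion (size) 5 — moderate extra-Poisson variation typical of WGS
libraries; breadth = 1 − e^(−depth), the Lander–Waterman expectation for
the fraction of bases covered ≥1×, times a small multiplicative jitter
(SD 1%), clipped to [0, 1]. Absent genes get spurious breadth uniform on
[0, 0.02] (mis-mapping; the true rate is unknown for real data — this is
a free parameter, not an estimate), scaled by 1 − e^(−mean depth) so a
zero-depth accession observes breadth 0 everywhere. BUSCO genes are
always-present genes under the same model. Under these defaults the MIN
threshold typically lands at the breadth of a depth-1 draw (~0.62) and
per-cell calling error is ≈0.9%, dominated by present genes that drew
depth 0 (0.4%) plus threshold-adjacent depth-1/2 draws.

CDS pairs for Ka/Ks testing are built codon-wise: a random stop-free
in-frame sequence in which the requested numbers of synonymous and
non-synonymous single-nucleotide substitutions are placed in distinct
codons and verified by translation.

What the generator does not emulate: linkage between loci, population
substructure within pools, shared ancestry between wild and domesticated
frequencies (they are drawn independently except for planted classes),
mapping bias, GC-dependent coverage, paralog collapse. Passing tests
therefore show that the statistics behave correctly under the stated
sampling model, not that the biological conclusions transfer to any real
cohort.

## Problem sizes and determinism

Default test cohorts use 100 accessions × 2000 genes × 1000 calibration
genes; recovery checks pool 20 seeded cohorts; resampling calibrations
use 500 replicates with 999-draw bootstraps (the add-one p then resolves
to 1/1000 granularity) and candidate sets of 200 genes, for which the
discrete null's attainable rejection rate at α = 0.05 is ≈0.04–0.045.
All randomness flows through `numpy.random.default_rng` seeds carried in
configs or arguments; identical config + seed reproduces every table
bit-for-bit.
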