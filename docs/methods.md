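# Methods

## Data model

All scans operate on a `GenotypePanel`: biallelic SNPs coded as
non-reference allele counts (0/1/2, −1 missing), 1-based positions strictly
increasing within chromosomes, a per-site ancestral-allele flag
(ref-ancestral / alt-ancestral / unknown), and a sample → population map.
Missing genotypes are never imputed: every statistic is computed from
called-allele counts only.  Coordinates are 1-based fully closed in memory;
BED output is converted to 0-based half-open on write.  The VCF loader
drops non-biallelic and non-SNP records and sites whose called fraction
falls below a threshold (default 0.9, matching common resequencing
filters), and reads the ancestral allele from the AA INFO tag or a
side-channel TSV.

Window grids are anchored at position 1 on each chromosome (not at the
first SNP) so grids are reproducible independently of the data; the last
window is truncated at the maximum observed position.  Windows below a
minimum SNP count are listed but flagged unusable.  The f_d preset is
100-kb windows with a 50-kb step and a 500-SNP minimum; both the step and
the minimum are plain parameters because both 50-kb and 20-kb steps are in
circulation for this scan, and desk-scale simulated data (≈ 4 SNPs/kb)
supports a lower minimum (tests use 100 SNPs per 100-kb window).

## Polarization

Two outgroup conventions are supported, because both are used in practice:
with `outgroup=ANCESTRAL` the panel's ancestral flag polarizes frequencies
(p₄ ≡ 0; sites with unknown ancestral state are excluded, and counted, not
silently zeroed), while with an outgroup population label the outgroup's
allele frequency p₄ enters the site-pattern formulas directly with no hard
polarization.

## D, f_d and significance

Site patterns are frequency-based (not pattern counts), so diploid
population samples of any size are handled naturally.  The jackknife uses
contiguous coordinate blocks (default 5 Mb, well beyond the LD scale of the
target systems; tests use 0.5 Mb on 10-Mb simulated chromosomes to keep
≥ 20 blocks) and the delete-one estimator
se² = (B−1)/B · Σ(D₍ⱼ₎ − D̄)².  The f_d denominator replaces both donor
slots with the dynamic donor P_D = argmax(p₂, p₃) per site — the defining
feature of the estimator, which keeps it bounded in low-diversity regions.
Clipping (window-D < 0, f_d < 0, or f_d > 1 → 0) discards values with no
meaning as P3 → P2 introgression fractions.

Window p-values use a per-scan z-transform of the clipped f_d values
(one-sided upper tail), BH-adjusted across the scan's usable windows, with
q < 0.05 by default.  Two caveats are documented deliberately.  First,
overlapping windows violate BH's independence assumptions; a
non-overlapping grid (step = size) is available for calibration.  Second,
the z-transform estimates its null location/scale from the scan itself, so
it can only flag windows when introgressed windows are a minority of the
scan (empirically, when true-tract windows are ≲ 25% of the scan); this is
the intended operating regime — genuinely introgressed genomes carry a few
percent donor material — and the synthetic recovery experiment is designed
to sit in it (see below).

Significant windows merge (overlapping or bookended) into tracts; the RIS
proportion is accumulated tract bp over scanned bp, and
PGI = Σ(f_dᵢ·Gᵢ)/G over all usable windows as listed (overlap included).

## Diversity, F_ST, ROD, PBS

π uses the per-site unbiased term 2p(1−p)·n/(n−1) summed over SNPs and
divided by the window span in bp, so monomorphic positions count as
invariant (no accessibility mask is applied by default, matching per-bp
conventions for the data the scans target).  d_xy uses
p_A(1−p_B) + p_B(1−p_A) over the same denominator.  Windowed F_ST is the
Weir–Cockerham (1984) ratio of sums Σa / Σ(a+b+c) — the weighted windowed
estimator of vcftools, invariant to duplicating sites — with a
mean-of-ratios mode for sensitivity checks; negative estimates are never
clipped in output, because clipping would bias the outlier tail.
ROD = 1 − π_improved/π_landrace is computed on a shared grid, with
π_landrace = 0 windows left undefined rather than ±∞.

PBS floors negative windowed F_ST at 0 before T = −ln(1−F_ST) (natural
log), since the transform is a branch length and negative estimates are
sampling noise; windows with any F_ST = 1 are +∞ and flagged.  Outlier
calling uses the type-7 empirical quantile with a strict inequality, so
ties at the threshold are excluded — documented rather than silent.

## ILS tract model

L = 1/(r·t) with t the TOTAL branch, 2 × divergence years / generation
years.  This interpretation is fixed by back-calculation: with
r = 1.5 cM/Mb (1.5 × 10⁻⁸ per bp per generation) and a 3-year generation
time it reproduces all four published tract-length anchors —
42.4 bp (2.36 Ma), 79.4 bp (1.26 Ma), 9,091 bp (11 ka) and 16.7–20 kb
(6–5 ka) — whereas a one-lineage branch does not.  The tail probability is
the Gamma(shape 2, rate 1/L) survival function (1 + m/L)e^(−m/L), which
agrees with the numeric Gamma CDF to 10⁻¹² over m/L ∈ [10⁻³, 50] and
underflows to exactly 0 at double precision for an 85.4-kb tract against
the 42-bp expectation.  A dedicated helper converts cM/Mb to per-bp rates
to avoid silent unit bugs.

## LD and N_e

r² is the composite genotypic estimate (squared Pearson correlation of
0/1/2 codes over samples called at both loci) because inputs are unphased;
note its null expectation is ≈ 1/n for n diploids, so half-decay estimates
from few individuals need either a large sample or the optional 1/n
subtraction (off by default).  The decay curve bins intra-chromosomal
pairs to 300 kb (MAF ≥ 0.05, with a deterministic per-chromosome SNP cap
for tractability); half-decay is the first bin at or below half the
curve's maximum, reported at the bin midpoint, undefined for flat curves.
N_e inverts E(r²) = 1/(1 + 4N_e·c) at t = 1/(2c) generations ago, mapping
distance to c with a constant cM/Mb rate (default 1.5).

## The synthetic scenario

The generator emulates a livestock-like four-taxon system on
((P1,P2),P3,O): splits at 1,000 / 10,000 / 60,000 generations; wild and
ancestral populations at N_e = 5,000; domestic breeds with a
breed-formation bottleneck (N_e = 40 for the most recent 300 generations,
matching linkage-based recent-N_e estimates of ~40–50 for sheep breeds)
out of a founder pool of N_e = 10,000; mutation rate 1.51 × 10⁻⁸ and
recombination 1.5 × 10⁻⁸ per bp per generation; a single mass-migration
pulse P3 → P2 (default f = 0.2 at 500 generations); 5 diploids per
population on 10-Mb chromosomes.  The outgroup split is scaled down from
the multi-million-year divergences of real wild relatives so that
simulations stay desk-scale; it remains deep enough (12 N_e generations)
that outgroup polarization is essentially perfect.

The breed bottleneck is a deliberate design choice, not a nuisance: it
coalesces the recipient sample before the pulse, so the sampled donor
tracts concentrate at a genome fraction close to f with near-unit dosage —
the localized regime in which the per-scan z-transform can flag windows at
all.  Without it, a sample of k haplotypes exposes a donor-tract union of
1 − (1−f)^k of the genome, the scan's empirical null absorbs the signal,
and no window is ever significant — matching the analytic saturation
argument above.  The diffuse (no-bottleneck) variant is retained for the
properties that hold only there, e.g. that window f_d in truth windows
estimates the local dosage ≈ f.

Truth tracts come from the simulator's migration records: every lineage
that takes the pulse contributes its genomic interval, mapped through the
trees to the sampled recipient haplotypes; the union across haplotypes
(merged, per chromosome) is the reference truth for window-level recovery.
Sweeps are emulated by post-hoc diversity scaling — inside a sweep region
a fraction 1 − s of sites have the focal population's genotypes set to its
major allele — which reduces that population's π by ≈ s and creates a
local F_ST/PBS excess without forward simulation.  Determinism: all
randomness derives from the scenario seed via per-chromosome seed
sequences; identical scenarios produce byte-identical VCFs.

## Validation experiments and problem sizes

* **Oracle agreement** — a hand-built 40-site toy fixture is evaluated by
  an independent loop-based implementation (explicit pairwise differences,
  the textbook Weir–Cockerham components, scalar site-pattern sums, hand
  BH); the vectorized pipeline matches to 10⁻¹⁰ (observed ≈ 10⁻¹⁶).
* **Null calibration** — 20 replicates of the default scenario with f = 0:
  |Z| < 3 in ≥ 18/20 and mean clipped f_d < 0.05 (observed ≈ 0.028).
* **Recovery** — five replicate scans of 3 × 10-Mb genomes at f = 0.2.
  Genome-wide D is pooled over the five genomes (jackknife across all
  blocks); truth-tract enrichment of significant windows is tested by a
  Fisher exact test on the 2 × 2 table pooled over the five scans, because
  a single scan at f = 0.2 sits near the z-transform's saturation point
  and its flag count is volatile, while pooling replicate scans is stable
  (design power ≈ 99.7% measured over 30 pilot scans).  PGI is computed
  across f ∈ {0, 0.05, 0.1, 0.2, 0.3} with shared seeds; the simulator
  couples the pulse draws across nested fractions, so realized donor
  content — and hence PGI up to estimation noise — is nondecreasing in f.
* **PBS** — a 0.1-scaling sweep in a calm (no-bottleneck) scenario lands
  in the PBS top 1%; the split-sample null (24 wild diploids split 8/8/8,
  500-kb windows) has |mean PBS| < 0.01.  The flooring of negative F_ST
  biases each branch term upward by ≈ 0.4·sd(F̂_ST)/2, which is why the
  null uses large groups and wide windows.
* **LD/N_e** — exact inversion identities, plus a directional check that
  larger ρ·N_e shortens the half-decay distance.

These sizes (10-Mb chromosomes, 5 diploids per population, 20–30
simulations per experiment) are the package's chosen desk-scale study
conditions; they exercise every code path in minutes on a single CPU.

## What passing tests do and do not show

The generator matches the target systems in mutation/recombination rates,
sampling depth and the qualitative demography (bottlenecked breeds, deeper
wild splits), but not in genome size, chromosome number, mutation-rate
heterogeneity, missing data, genotyping error, or selection at linked
sites.  Passing recovery tests demonstrates that the estimators and their
significance machinery behave as designed under the model they assume; on
real data the BH correction over overlapping, spatially correlated windows
remains anticonservative, headline quantities (global F_ST, half-decay
distance, RIS percentages) are data-set-specific, and per-scan thresholds
do not transfer between data sets.
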