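# Methods

This note documents the statistical models and estimators implemented in
`radpop`, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions used
throughout.

## Data model and filtering

All statistics operate on a samples-by-variants matrix of alt-allele
dosages (0/1/2, with −1 for missing) restricted to biallelic SNPs.
Variant positions are 1-based (VCF convention); genomic windows and BED
outputs are 0-based half-open. The conversion happens in exactly two
places: window overlap in the scan (`sweep.window_stats`) and gene/region
intersection (`sweep.annotate_regions`, where a 1-based inclusive gene
`[start, end]` is treated as `[start−1, end)`).

Genotype calls supported by fewer than `min_depth` reads (default 3×) are
masked to missing before variant filtering. Variants are then kept when
their pooled minor allele frequency is **strictly greater** than 0.05 and
their missing-genotype proportion **strictly less** than 0.20. MAF is
computed once on the pooled cohort, not per population, matching the usual
practice of filtering the combined call set before any per-population
statistic. Half-called genotypes (`./1`) have no defensible dosage and are
treated as missing. Filtering is idempotent and never increases the
variant count (property-tested).

Per-population SNP counts report *segregating* sites: sites at which both
alleles are observed among the population's non-missing genotypes. An
alternative reading — sites merely callable within the population — would
count nearly every variant; the segregating definition is the one that
varies informatively between populations.

## Diversity statistics

- **Per-site π** is the mean pairwise difference among the 2n sampled
  alleles, `ref·alt / C(n, 2)` — the unbiased estimator (equivalent to
  `2p̂q̂·n/(n−1)` on allele counts).
- **Population π** sums per-site π and divides by the total contig length
  (default) so values are per-bp and comparable across panels of different
  SNP density; a per-variant mode exists for windowed use. With 4–10
  diploids per population the `n/(n−1)` correction matters, hence the
  unbiased form everywhere.
- **Ho / He** are means over sites with at least two called genotypes; He
  uses the same unbiased correction. The included-site set is identical
  for both, so Ho and He are directly comparable.
- **F_IS** is computed per sample as `1 − O/E`, where O is the sample's
  observed heterozygote count over its non-missing sites that are
  polymorphic in its population and E is the summed unbiased expected
  heterozygosity at those sites, computed from the *population* allele
  frequencies; the population value is the arithmetic mean over samples.
  Using population rather than cohort frequencies keeps the statistic a
  within-breed quantity. Samples with E = 0 are excluded with a warning.
  Under the simulator's random-mating null this estimator is centred on 0
  and recovers a generating inbreeding level f to within Monte-Carlo error
  (tested at f = 0 and f = 0.3).

## Differentiation

The single F_ST estimator is Weir & Cockerham's (1984) θ for two
populations, assembled from the per-site variance components a (among
populations), b (among individuals within populations) and c (within
individuals). Estimates combine across sites — and across sites within a
window — as a **ratio of sums** Σa/Σ(a+b+c), which is far more stable for
small windows than averaging per-site ratios. Slightly negative estimates
are reported unclamped: the sweep scan ranks windows by empirical
quantile, and clamping at zero would pile mass at the quantile boundary.
Sites need at least two called genotypes in each population to
contribute. Breed-average F_ST is the arithmetic mean of that breed's
pairwise estimates against every other breed.

## LD decay

LD between two sites is the squared Pearson correlation of genotype
dosages over pairwise-complete samples (composite, Rogers–Huff style). No
phasing or haplotype EM is attempted: reduced-representation genotypes
are unphased, and the genotype correlation is the standard surrogate.
Decay curves consider all intra-chromosomal pairs within `max_dist`
(default 500 kb — configurable up to several Mb, but pair counts grow
quadratically and the informative decay happens well inside 500 kb at
these marker densities), binned by distance (default 5 kb). Bins over
`max_pairs_per_bin` (default 100,000) are subsampled with a seeded RNG,
reproducibly. Sites are pre-filtered to within-population MAF ≥ 0.05.
The expected r² between unlinked sites is ≈ 1/(n−1), which sets a noise
floor for small panels; the half-decay summary (first distance at which
the curve falls to half its first bin) is only meaningful when the first
bin sits well above that floor.

## Structure inference

PCA uses the standardized genetic relationship matrix: per usable site
(pooled 0 < p < 1), dosages are centred at 2p and scaled by
`sqrt(2p(1−p))`; missing dosages are mean-imputed (centred value 0);
entries average the per-site cross-products. Scores are eigenvectors
scaled by the square root of their (non-negative-truncated) eigenvalues,
and explained-variance percentages are taken over the positive spectrum.
Eigenvector sign is a gauge freedom; tests compare up to sign.

The tree is individual-level neighbour joining on allele-sharing
distances `mean |xᵢ − xⱼ|/2` over sites called in both samples (the
distance behind the tree is recorded in the tree metadata, since
distance choice is a genuine free parameter here). NJ uses the
Studier–Keppler Q criterion with ties broken on the smallest (row,
column) index pair, making the output deterministic; additive matrices
are recovered exactly (tested to 1e-9 and against an independent NJ
implementation). Negative branch lengths are clamped to zero for display
with a count recorded; the topology is untouched. Midpoint rooting is
applied only for display/monophyly checks.

## Sweep scan

Windows are 100 kb sliding by 10 kb; only full windows are emitted. Per
window and per contrast (control population vs target population) the
scan computes ratio-of-sums θ and per-bp π for both populations with the
window length as denominator (per-variant π would conflate SNP density
with diversity). A window is usable when both populations contribute at
least `min_snps` (default 10) sites. The π ratio is oriented
**control/target**, so diversity *loss* in the target ranks high;
`−log10 π_target` is reported alongside. Windows where the target has
zero π are floored at the smallest positive window π observed (value
logged) rather than producing infinities — they still rank at the top.

Candidates are the **intersection** of the top-5% windows by F_ST and the
top-5% by π ratio (a union mode is available behind a flag; intersection
is the default because requiring both signals is the usual composite-scan
practice and controls the selected fraction by construction). Quantiles
are nearest-rank with ties included, so selection is deterministic and
monotone in the fraction. Selected windows merge into regions when they
overlap (or sit within `max_gap`); genes overlap a region when the
intervals intersect by ≥ 1 bp after coordinate conversion.

Enrichment is database-agnostic: given a term→gene map, each term gets an
upper-tail hypergeometric p-value and Benjamini–Hochberg q-value, with
significance at q ≤ 0.05. Terms with no selected genes report p = 1.

## The synthetic-data generator

The generator follows the Balding–Nichols model: per site, an ancestral
alt frequency p ~ Uniform(0.05, 0.95) and per-population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), so F is an expected F_ST (the realized
per-population frequency variance matches F·p(1−p), property-tested).
Haplotypes are drawn either site-wise i.i.d. (independent sites: clean
conditions for estimator-recovery checks) or as recombination mosaics
over a pool of H founder haplotypes. The mosaic switch rate per bp is
`recomb_rate · H/2`: ancestral recombination accumulates with pool size,
so larger (more diverse) pools have shorter haplotype segments, lower r²
and faster LD decay — mirroring the population-genetic relationship
between LD range and effective size (r² ≈ 1/(1 + 4Nc)). With a
pool-independent switch rate, decay *rate* would not depend on pool size
at all and the diversity/LD ordering the analysis relies on would not
emerge.

Inbreeding acts per genotype: with probability f the second haplotype
copies the first at a site, giving each sample an expected F of f without
distorting allele frequencies. Sweeps reset the target population's alt
frequency to 1 − ε (default ε = 0.02) inside the swept interval before
haplotypes are drawn, jointly depressing target diversity and elevating
differentiation there. Missingness is uniform; read depths, when
requested, are negative-binomial.

The **standard scenario** fixes the study-shaped conditions used by the
acceptance checks: 8 populations of 10, 10, 8, 10, 10, 4, 9 and 10
diploids (71 total), two 2-Mb contigs with 5,000 SNP sites each (SNP
density comparable to a reduced-representation panel), F = 0.12,
30 founders with base recombination 1e-6/bp (haplotype segments of a few
tens of kb), per-breed inbreeding between 0.08 and 0.33, 5% missingness,
negative-binomial depths (mean 20, dispersion 5), and one 200-kb sweep
in the WZ population on contig 1. The documented default seed is
20210726. The toy annotation places three genes inside each sweep and 20
decoys per contig, enabling end-to-end annotation/enrichment tests
against known truth.

**What the generator does not emulate:** demographic history (bottlenecks,
growth, migration), realistic site-frequency spectra (no rare-allele
excess), linked selection outside the injected sweeps, genotyping error
that correlates with depth, or reference bias. Passing tests therefore
demonstrate estimator correctness and pipeline behaviour under the stated
model, not robustness to every artefact of real reduced-representation
data.

## Numerical conventions and edge cases

- Quantile thresholds: nearest-rank over usable windows, ties included.
- π denominator mode is recorded in output metadata.
- Contigs missing from the VCF header get `max observed position` as
  length, with a warning.
- Degenerate inputs raise typed errors naming the offending entity
  (samples missing from the population map, pairs with no shared sites,
  zero usable sites for a population pair, fewer than 20 usable windows
  for a quantile).
- Problem sizes in the test and acceptance runs (20,000 independent sites
  for estimator recovery, 5,000 sites per contig in the standard
  scenario, 10 generator seeds for sweep recall) were chosen so
  Monte-Carlo error is comfortably inside the asserted tolerances.
- All randomness flows from a single integer seed per run; reruns are
  bit-for-bit identical (VCF bytes and pipeline manifests are compared in
  tests).
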