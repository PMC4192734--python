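# Methods

This note documents the models and numerical choices behind `maizearray`:
what the synthetic-data generator emulates, how the genotype caller works,
how the selection machinery is specified, and where the open design
decisions were settled.

## Synthetic panel model

The generator exists so that every pipeline stage can be exercised against
planted truth. It emulates the statistical structure of a temperate maize
array-validation cohort, not any particular dataset.

**Genome.** Chromosomes carry a relative polymorphism-rate profile per
10 kb window. With the telomere gradient on (default strength 3), the rate
rises quadratically from the chromosome center towards the ends, giving the
telomere-enriched, centromere-depleted variant density typical of maize.
An optional masked interval per chromosome yields a variant-free region
like the nucleolus organizer region on chromosome 6S. Genes (default 120,
1.5–6 kb) are placed uniformly.

**Allele frequencies and pools.** Each variant draws a base frequency from
Beta(0.4, 0.4) — a U-shaped spectrum in which rare alleles are common, as
in an unascertained population sample. Pool divergence (default 0.3)
shifts the Dent and Flint frequencies symmetrically apart with a random
per-variant direction; admixed samples mix the two pool frequencies with a
per-sample weight in [0.25, 0.75]; outgroup accessions draw independent
frequencies.

**Genotypes.** A sample with inbreeding coefficient f draws genotypes with
heterozygote probability 2p(1−p)(1−f) and homozygote probabilities
inflated by f·p(1−p). Inbreds default to f = 0.95 (residual
heterozygosity), doubled haploids to f = 1. F1 hybrids are formed by one
gamete draw from each simulated parent, so trios are Mendelian-consistent
by construction; replicates copy their source genotypes exactly. Inbred
penalties follow the 0 / 12 / 14 convention (hybrids / unclear inbreds /
pure inbreds and DHs).

**Variant roles.** Disjoint seeded fractions of variants are planted as
monomorphic (5 %), het-only (5 %; the alt allele occurs only in
heterozygotes, producing the NoMinorHom geometry), and OTV (7.5 %). OTV
flanking-variant carriers are drawn per sample with a carrier frequency
from the same Beta(0.4, 0.4) as ordinary variants — flanking variants are
untouched by ascertainment, which is what makes their MAF spectrum richer
in rare alleles. Carrier status is treated as a dominant presence marker
(hybrids inherit it from either parent); OTV flags with fewer than two
carriers or fewer than two non-carriers are dropped, since no distinct
cluster can exist.

**Sequencing calls.** Per-line depths are Poisson around the line's mean
coverage (the deep/shallow split of 50x for four lines and 12x for the
rest is available through a per-sample depth map). A seeded fraction of
variants (default 10 %) is paralog-confounded: their calls flip to
heterozygous with probability 0.85 per line, their copy-number annotation
is drawn in [50, 200), and their MQ0 fraction in [0.06, 0.40) — the
signature the second-round filters remove, and the mechanism behind the
large het-versus-hom FDR gap. Caller-support flags disagree at rate 0.02;
2 % of sites receive a second alternate allele to exercise the bi-allelic
restriction.

**Intensities.** Two-channel signals are generated on the log2 scale
(lognormal noise on the raw channels, sd 0.15 in both contrast and size by
default): AA at contrast +1.5, AB at 0 (size raised by 0.3), BB at −1.5,
size baseline 10. Planted categories are derived consistently with the
genotype truth: genuinely monomorphic variants become MonoHighResolution,
variants whose minor allele occurs only in hets become NoMinorHom, OTV
carriers collapse to a cloud 3 size-units below baseline, a 5 % share of
three-class variants is shifted 2.7 contrast units off center
(misplaced clusters, HomRO failure → Other), and for another 5 % a quarter
of the samples smear uniformly along the contrast axis (→
CallRateBelowThreshold). The planted label is stored in the truth table
for recovery tests.

What the generator does **not** model: batch and plate effects,
chemistry-dependent channel bias, cluster-position drift across arrays,
segregating probe polymorphisms other than the binary OTV cloud,
genotyping-error correlation between replicates, and linkage (variant
genotypes are independent across loci, so LD analyses are validated
against injected curves and planted duplicated columns rather than against
a recombination model). Passing tests therefore demonstrate algorithmic
correctness and direction effects, not field performance on real arrays.

## Genotype caller

Per variant, points (x, y) = (log2 A − log2 B, (log2 A + log2 B)/2) (raw
signals floored at 1) are fitted with a diagonal-covariance Gaussian
mixture by EM. Three starts are tried:

1. generic a-priori centers AA (+1.5, y₀), AB (0, y₀+0.3), BB (−1.5, y₀)
   with y₀ the median size;
2. a contrast-quantile start (10th percentile, midpoint, 90th percentile)
   that rescues variants whose clusters sit far from the generic
   positions (misplaced clusters);
3. a low-size-aware start that seeds the middle component at the low
   cloud whenever the size range exceeds 1.5 (off-target geometry; the
   split point is the midpoint of the size range).

Each start is refined (components closer than 0.5 in (x, y) are merged
into the heavier one, followed by a short EM restart), and the refined fit
with the highest likelihood wins. Comparing *post-merge* fits matters:
raw three-component fits can win the likelihood race by overfitting a
single blob with coincident components.

A uniform background component with fixed density 1/bounding-box-area and
fixed weight 0.005 absorbs outliers; samples whose posterior is dominated
by it, or by a junk component (fitted variance above 0.25 in either
coordinate — no genotype cluster is that broad), become no-calls, as do
samples below the posterior-confidence threshold 0.95. Genotype labels
are assigned a posteriori by contrast order: the contrast-sorted
components get the ordered subsequence of (AA, AB, BB) minimizing total
distance to the a-priori centers, and the AA-above-BB ordering is
enforced. This keeps a lone cluster at +1.5 labeled AA, a pair at
(+1.5, 0) labeled (AA, AB), and a misplaced triplet labeled (AA, AB, BB)
regardless of the global shift.

**Inbred correction.** Sample penalty p multiplies the heterozygote prior
weight by 2^(−p/2) (p = 16 → ×2⁻⁸), renormalized per sample. Raising the
penalty can only reduce heterozygote posteriors, so het-call counts are
monotonically non-increasing in p (a tested contract). In this caller the
correction removes spurious het calls but cannot create calls, so the mean
call rate declines slightly under correction on synthetic data; on real
arrays the correction also repositions clusters learned from miscalled
hets, which is the mechanism behind call-rate gains there — that second
mechanism is not modeled.

**OTV re-calling.** Variants classified OTV (HetSO below −0.3), and
variants whose strongly negative HetSO was masked by a call-rate failure
or that left no-call samples more than one size-unit below every fitted
cluster, are refitted with four components: AA/BB seeded from the primary
fit, AB re-seeded at its generic position (the primary AB component is
often the one dragged onto the off-target cloud), and OO at the low-size
cloud. The lowest-size component becomes OO; its members get genotype OO.
The category is then settled from the recalled calls (OTV when a distinct
OO cluster exists and the call rate recovers, CallRateBelowThreshold when
it does not) — a pragmatic extension of the strict classification order,
without which OTVs with many true heterozygotes are misfiled as call-rate
failures. If the primary fit contains no homozygote cluster at all, the
variant is one low-size cloud: every sample is called OO and the variant
is flagged degenerate.

**Metrics.** FLD = |x̄_AB − x̄_hom*| / s with hom* the nearest homozygote
in contrast and s the count-weighted pooled within-cluster contrast sd;
homFLD is the analogue between AA and BB. HetSO is the size offset of the
AB center from the line through the AA and BB centers (from the single
homozygote's size when only one exists). HomRO = min(x̄_AA, −x̄_BB) over
present homozygotes. These geometric definitions are this package's own;
vendor formulas are unpublished, so only the qualitative behavior
(well-separated narrow clusters → high FLD; off-target clouds → negative
HetSO; misplaced clusters → negative HomRO) is matched.

**Classification** (defaults CR 90 %, FLD 3.6, HetSO −0.1, HetSO-OTV −0.3,
HomRO 0.3 with two clusters / −0.9 with three, minor-allele count 2):
one genotype cluster → MonoHighResolution (Other if call rate or HomRO
fail); call rate below cut → CallRateBelowThreshold; HetSO below the OTV
cut → OTV; HomRO/FLD/HetSO failures → Other; no minor-allele homozygote or
too few minor alleles → NoMinorHom; else PolyHighResolution. Two
homozygote clusters without heterozygotes count as polymorphic with both
homs present — the normal appearance of a good marker in fully inbred
material.

## Selection machinery

Filters, budgets and quotas follow the printed design constants: 100 kb
bins over 2.066 Gb → 20,660 bins; (1,230,000 − 150,394 − 2×48,324)/20,660
rounds to 48 per bin. Frequency class A is 0.2 ≤ f ≤ 0.8 (boundaries
inside), B otherwise; quota cells are keyed (Dent class, Flint class) with
(A,B) Flint-specific and (B,A) Dent-specific, exactly as printed even
though the naming reads inverted. Budget integerization uses
largest-remainder (Hamilton) apportionment; cells whose candidates run out
donate their shortfall to the remaining cells proportionally (re-applying
largest remainder), logged per bin. Undefined-frequency candidates never
enter quota cells. The 50 kb fill-up adds, per under-filled half-bin,
first up to six "recommended" candidates with ≥ 28 called lines and hom-ref
counts in [6, 22), then any remaining candidates, until eight are present.

The voting rank is 35w + 90c + 10s. w = 10 for OTV-stable and for
NoMinorHom→PHR promotions, 5 for any other promotion to PHR, 0 otherwise.
c is the fraction of matching, mutually non-missing calls across the
discovery lines (OO calls are not comparable; variants without comparable
pairs score 0 and are flagged). s compares a bin's count with the mean of
up to five bins on each side, truncated at chromosome ends. Duplicate
probes keep the higher rank; exact ties and top-k cutoff ties are broken
by a seeded draw so the design is reproducible. Forwarded variants are
never displaced by ranked ones.

Annotation uses interval trees over gene models; with feature-level models
(exon/CDS/UTR rows) variants are labeled coding/UTR/intron, with plain
intervals the three collapse to "genic" and the summary says so. Flank
labels are strand-aware at 5 kb. cM spacing interpolates a genetic map
linearly with constant extrapolation beyond the anchors.

## Panel analyses

Genotype matrices are samples × variants with codes 0/1/2/−1; indels are
treated as bi-allelic SNPs. Rogers' distance per bi-allelic locus,
sqrt(((Δp)² + (Δq)²)/2), reduces algebraically to |Δp| and is averaged
over pairwise-complete loci; with missing data the pairwise-complete
average can violate the triangle inequality (different locus sets per
pair), so the metric property holds on complete matrices only. PCoA is
classical metric scaling (via scikit-bio); mildly negative eigenvalues are
expected for non-Euclidean genetic distances and ignored. LD r² is the
squared Pearson correlation of 0/1/2 dosages over pairwise-complete
observations within 50 Mb windows; monomorphic variants are excluded.
Decay distance bins pairs on a log-distance grid (50 bins per decade),
makes bin means monotone non-increasing by isotonic regression, and
interpolates the 0.2 crossing linearly between bin centers; curves already
below threshold return 0, curves never crossing return undefined, as do
inputs with under 20 pairs. Pruning is the deterministic greedy
left-to-right scan at r² > 0.8 within windows. Missing data are imputed by
the per-variant modal genotype after dropping variants with ≥ 10 % missing
— a deterministic, dependency-free stand-in appropriate because imputation
only feeds the structure/LD analyses.

## Problem sizes and verification

The test suite validates each operation against hand-computed examples,
property tests (hypothesis, derandomized), and independent brute-force
oracles: the whole discovery cascade against a single-pass predicate
evaluation, bin assembly against quota arithmetic, final assembly against
a top-k sort, LD pruning against the greedy reference. Parameter-recovery
checks run a 285-sample panel at 2,000 variants (genotype recovery ≥ 99 %
and planted-category recovery ≥ 90 % on the default well-separated
geometry; planted OTV carrier sets recovered exactly at near-zero noise).
Planted-category recovery is evaluated on the uncorrected analysis, since
the planted labels describe cluster geometry and the inbred correction
deliberately suppresses heterozygote calls in penalty-14 samples. The
acceptance script uses 800 variants × 285 samples for the end-to-end stage
and 3,000 variants × 30 lines for the discovery stage — sizes chosen so
the whole run completes in a few minutes while keeping binomial noise on
the reported percentages around a tenth of a percent.

## Known limitations

* Cluster-position learning across variants (a-priori position updates
  from the panel, as vendor pipelines do) is not implemented; every
  variant is fitted independently.
* The inbred correction cannot increase call rates (see above).
* The misplaced-cluster ("Other") planted geometry is restricted to
  variants showing all three genotype classes; two-cluster misplacements
  are ambiguous under purely positional labeling and would be planted
  with an unrecoverable label.
* FLD/HetSO/HomRO are geometric stand-ins for unpublished vendor
  definitions; absolute values are comparable only within this package.
* The paper-style headline percentages that depend on real data (call
  rates, category-change shares, LD tables) are reported by the
  acceptance script as the synthetic panel's own values, not as
  reproductions.
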