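# Methods

## Association model

A cis candidate is any probe–SNP pair on one chromosome with
|snp_pos − probe_center| ≤ 250,000 bp, boundary included. The probe center
is `floor((start+end)/2)` of the alignment interval (the rounding rule is a
package choice; coordinates are 0-based half-open internally, SNP maps are
read as 1-based and converted). The association statistic is the midrank
Spearman correlation between dosage and intensity. P values use the
t approximation with n−2 df; for n < 10 the package switches to exhaustive
enumeration of expression permutations, which is exact under
exchangeability. P values are floored at 1e−300 so the signed normal
equivalent z stays finite.

Testability filters (applied once per scan): at least 30 shared samples
(configurable), sample MAF ≥ 0.05, at least 3 minor-allele carriers, at
least two distinct dosage values, non-constant expression. The
carrier-count reading of the minor-genotype rule was chosen deliberately:
requiring ≥3 samples in every observed genotype class would discard most
SNPs near the MAF floor at cohort sizes in the low hundreds, which no
array-era eQTL QC did. Missing dosages are handled by pairwise deletion on
a scalar fallback path; the vectorized path (standardized midranks + one
matrix product per scan) requires complete matrices, which the generator
produces.

## Permutation FDR

The null is built by shuffling the expression matrix's sample labels
relative to the genotypes — whole columns move together, so probe–probe
correlation survives and only the genotype–expression link is broken.
Because ranks are invariant under relabeling, each permutation costs one
matrix product over the pre-ranked data; 100 permutations of a
20,000-pair scan take about a second.

The counting unit defaults to the probe, whose statistic is its minimum P
over cis pairs (this min-P construction automatically accounts for the
varying number of SNPs per probe); a per-pair unit is available. Estimated
FDR at threshold t is the mean permuted count of units at or below t over
the observed count, evaluated only at observed unit P values (a step
function, no interpolation); the decision threshold is the largest
candidate with estimated FDR ≤ the nominal level, which makes the
threshold monotone in the level by construction. An empty significant set
yields threshold 0, not an error. Permutation seeds are spawned from the
master seed by counter and recorded in the result object.

Whether the null should pool all permuted unit P values or use per-unit
minima only is a genuinely open design point; this implementation pools
the per-unit statistics across permutations (each permutation contributes
one statistic per unit), which keeps observed and null counts on the same
scale.

## Replication and specificity

Replication restricts the scan to the cis pairs of discovery-significant
units and applies the same permutation FDR to that reduced universe.
Allele encodings are harmonized first: a SNP whose ref/alt are swapped
between cohorts has its dosage flipped (2−g), which flips z consistently.
Direction concordance is sign(z_discovery)·sign(z_replication) of the
discovery top pair. Transcript-class specificity labels each lincRNA top
eQTL SNP shared if any protein-coding probe passes the *same* P threshold
for that SNP, with the direction label taken against the strongest coding
association; the strongest-eQTL flag asks whether the SNP is also the top
SNP of some significant coding probe. Ties for "strongest" break by P,
then |rho|, then genomic position — fully deterministic.

## LD, GWAS intersection, enrichment

LD is composite (dosage-correlation) r²: the squared Pearson correlation
of unphased 0/1/2 vectors. This replaces haplotype r² from a phased
reference panel — the package's genotypes are unphased and the analysis
panel doubles as the reference, a documented divergence from reference-
panel practice. Proxy search scans SNPs within 500 kb (default; the
proxy-window size is a package choice) and keeps r² ≥ 0.8 (≥ vs > is
configurable; perfect proxies require r² = 1 within 1e−12). Proxy sets
are monotone in the threshold by construction.

Fold enrichment of an eQTL SNP set in an annotation track is
(fraction of query *sets* — a top SNP plus its perfect proxies, counted
once however many members overlap — hitting the track) / (fraction of
background SNPs in the track). The set-level counting avoids LD
double-counting; the background defaults to the analysis SNP panel (the
alternative, genome-wide SNPs, is not observable here). Significance
repeats the expression-label permutation: per permutation the eQTL scan is
re-run, the top-n probes re-selected, their top SNPs expanded by perfect
proxies, and the fold recomputed; a maximum-likelihood normal fit to the
log permuted folds gives the one-sided upper-tail P of the log observed
fold. Zero folds are replaced by half the smallest positive permuted fold
before the log (recorded in the result); if every permuted fold is zero
the P is reported as not estimable rather than guessed. The same fold
formula is applied to observed and permuted sets, so the comparison is
internally consistent even though the formula itself (set-hit fraction
over background fraction) is a package definition.

## Synthetic-data generator

The generator emulates, at desk scale, the statistical structure of a
blood microarray eQTL cohort with multiple tissues from the same
individuals:

- **Genotypes**: Hardy–Weinberg dosages; one MAF per LD block drawn
  uniformly from [0.05, 0.5]; block-copy LD (each SNP copies the previous
  block member's dosage per individual with probability `ld_decay`, else
  redraws), giving lag-k dosage correlation `ld_decay**k` within a block
  and independence across blocks — tunable r² without phased haplotypes.
  SNP positions are cumulative uniform spacings with a 5 kb mean, so a
  250 kb window holds ~100 SNPs.
- **Expression**: intensity = class baseline + β·dosage (planted pairs,
  if active in the tissue) + N(0, noise_sd). Protein-coding baseline 6.92
  and lincRNA shift 0.25 reproduce the printed class means of a blood
  cohort (6.92 vs 6.67). Noise SD 1.0 and effect sizes (0.8 for
  calibration runs) are tuning choices — no cohort-level effect-size or
  noise magnitudes exist to copy — picked so that planted effects at
  n = 200 are detectable but not trivial (Spearman ρ ≈ 0.4–0.5).
- **Class split**: `lincRNA_fraction` defaults to 0.5 so both classes stay
  testable with 200 probes; a real array's ~5% lincRNA share is reachable
  through the parameter.
- **Tissues**: every tissue is a seeded subset of the one genotyped sample
  universe with independent noise; effects can be restricted via
  `tissues_active`, mirroring multi-tissue designs where non-blood tissues
  come from the same individuals.
- **Fixtures**: the suite writer emits genotype/expression TSVs, a
  lincRNA exon catalog BED built over the lincRNA probes, a GWAS catalog
  with planted sub-threshold trait SNPs plus decoys, and enhancer BEDs
  (random tracks plus an optional track containing every planted causal
  SNP); a manifest records row counts, sha256 digests and the seed, and
  re-runs are byte-identical.

What the generator does **not** emulate: population structure and
relatedness, imputation uncertainty, probe cross-hybridization and other
array intensity artifacts, realistic MAF spectra or recombination maps,
and trans effects. Passing calibration tests on this generator therefore
shows that the procedures are statistically sound under their stated
assumptions (exchangeability under the null, additive cis effects,
independent noise), not that real-cohort counts would be reproduced.

## Normalization choices

Quantile normalization maps every sample column onto the across-sample
mean of order statistics; ties receive the mean of the target values their
sorted positions span, making the operation idempotent to 1e−12. PC
correction residualizes against the top-k singular components of the
*uncentred* matrix: k = 0 is then an exact identity and an exactly rank-k
matrix is annihilated, and the first uncentred component absorbs the mean
intensity pattern that expression pipelines remove anyway. The number of
components defaults to 0 for synthetic runs — the generator plants no
broad structure — and is configurable for real data. Probe matching for
abundance-matched control sets is greedy nearest-neighbour without
replacement in standardized (mean, SD) space, hardest-first so extreme
reference probes are not starved; the location statistic is the mean by
default with median available.

## Problem sizes and determinism

Default study sizes (200 samples × 2,000 SNPs × 200 probes, 100
permutations) run in ~1 s per cohort on one core; the calibration script's
20 replicates finish in well under a minute. All randomness flows from a
single master seed per generator or procedure through `numpy`
SeedSequence spawning, so every result object (including permutation
seeds, written into `FdrResult` and the fixture manifest) is reproducible
bit for bit.

## Known limitations

- The scalar missing-data path is O(pairs) and slow for large scans;
  complete matrices use the vectorized path.
- Composite r² understates haplotype r² when phase matters; proxy sets on
  real data should come from a phased reference panel.
- The enrichment normal fit assumes log permuted folds are roughly
  normal; with very sparse tracks the discreteness of set-hit counts makes
  the fitted tail approximate.
- `protect_genetic` in PC removal is an interface placeholder; protecting
  genetic components requires genotype-aware decomposition not implemented
  here.
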