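# Methods

## The problem being modeled

Designing a genotyping array for a breed without rich genomic resources
means reconciling variant calls from whatever sequencing exists. Here that
is three call sets over one composite reference genome: a low-to-mixed-depth
short-read set of individuals from three genetic groups plus two pooled-DNA
libraries (`S1`), a uniform high-depth short-read set of females from the
reference breed (`S2`), and a small long-read set of males (`L`). The
package reimplements the downstream analysis as a reusable, tested library:
QC per dataset, allele-aware intersection, group statistics, marker
selection, window densities, array budgeting and structure checks.

## Coordinate conventions

All coordinates are 1-based inclusive (VCF convention); windows are closed
intervals `[start, end]`. The final window of a chromosome is truncated, and
its density statistics use its actual covered width rather than the nominal
width — a deliberate choice to avoid edge-inflated densities (a raw-count
mode is provided for comparison with fixed-width summaries). Per-chromosome
density divides by assembly length from the layout table.

## Per-dataset QC

Genotype masking and site filtering are deliberately separable: masking sets
individual genotypes missing (keeping AD/DP evidence in place and never
changing the site count), site filters drop whole sites (never touching
genotypes). The two therefore compose in either order with identical output.

Dataset compositions:

- `S1`: mask genotypes with DP < 5 (pools exempt — their read evidence is
  used for frequencies, not genotypes), then drop sites with missing
  fraction > 0.1 among non-pool samples.
- `S2`: normalize MNPs into per-base SNPs (entries inherited verbatim,
  i.e. perfect linkage within the MNP), mask on GQ < 30 or DP < 10, same
  site-missingness rule.
- `L`: mask on GQ ≤ 20 or DP ≤ 5 (strict inequalities — "more than" —
  where the short-read sets use the vcftools-style inclusive minimum; both
  comparisons are configurable), keep biallelic SNPs, require the alternate
  allele in ≥ 2 genotyped samples. "Presence in at least 2" is read as alt
  *carriers*, the stricter interpretation; a `genotyped` mode is available.

Two documented ambiguities are exposed as switches. The site-missingness
threshold defaults to the plain-language reading (missing fraction ≤ 0.1,
`PROSE`); the vcftools `--max-missing` flag actually thresholds the *called*
fraction, available as the `VCFTOOLS` dialect. A genotype whose thresholded
field is absent is masked (conservative) and counted in the log — silently
passing it would inflate call rates.

## Intersection and merge rules

Variant identity is the full tuple (chrom, pos, ref, alt): call sets share
one reference, so alleles are comparable and no position-only or
strand-flipped matching is attempted. Multi-allelic records are classified
and excluded, not split — they are rare and their depth re-allocation is
undefined. The membership partition is exact set algebra; merge rules are a
table mapping chromosome class to the set of datasets that must contain a
key (autosomes and X: all three; Y: the male short-read set; MT: both
short-read sets — the all-female `S2` has no Y, the long-read set has no
MT). Alternative designs (e.g. short-read-only intersection) are a config
change, not a code change. No genotype reconciliation across datasets is
needed because each sample belongs to exactly one dataset.

## Group statistics

Call rate and allele frequency use different denominators by design:

- `CR = n_called / n_eligible` over non-pool group members. When a
  membership partition is supplied, samples whose dataset does not contain
  the variant are excluded from the denominator — they are missing by merge
  rule, not genotyping failure. Without a partition they count as missing.
- `AAF = Σ AD_alt / Σ DP` over all group members *including pools*, skipping
  samples with absent AD or DP (absence is never treated as zero). Zero
  total depth leaves AAF undefined (NaN), and undefined AAF never passes the
  polymorphism selection. Masked genotypes keep their AD/DP in the sums by
  default (the frequencies are read as reported); `aaf_respects_masking`
  excludes them.

Selection keeps markers with CR strictly > 0.9 and AAF in the closed band
[0.02, 0.98] in the reference group (all four numbers configurable). The
carry-over fraction of another group counts undefined-AAF markers in the
denominator only.

## Window statistics and array budgeting

Both spacing notions are reported: the empirical mean gap between successive
markers, and the density-implied gap `10⁶ / (markers per Mbp)` rounded to
the nearest bp, which is what headline per-chromosome figures quote. Window
counts satisfy a conservation invariant (they sum to the catalog size on the
windowed chromosomes) that the tests assert.

Array budgeting is two things. The availability report is pure counting —
candidates per 100-kbp window against a quota (≈3 per window for a 90K
design, ≈26 for a high-density one) — and reproduces the budget argument
with no scoring. The selection step is this package's own construction: a
composite score `w₁·CR + w₂·(1 − |2·AAF − 1|)` (weights default 0.5/0.5,
must sum to 1) with greedy picking under a minimum-spacing constraint, ties
broken by (position, ref, alt) so selection is total and deterministic.
Greedy is not optimal interval scheduling; tests compare it to exhaustive
search on small windows and the observed gap is small. Optimality is not
claimed.

## Population structure

Dosages (0/1/2) over individuals only; missing entries mean-imputed per
variant (the common default for genotype PCA), all-missing variants dropped.
PCA centers and variance-standardizes each variant (zero-variance columns
dropped; a flag disables scaling), decomposes by SVD, reports squared
singular values over their total, and fixes signs by making each
component's largest-magnitude loading positive. Clustering uses average
linkage on `1 − allele-sharing` distance (per-variant sharing
`1 − |aᵢ − aⱼ|/2`); the original study's exact metric is not recoverable, so
these defaults are declared rather than inferred. Dendrograms export to
Newick.

## Synthetic data generator

The generator emulates the study's statistical structure, not its reads:

- **Divergence**: Balding–Nichols — ancestral frequency `p ~ U(0.05, 0.95)`,
  group frequency `~ Beta` with mean `p` and variance `FST·p(1−p)` (exactly
  `p` at FST 0). Defaults FST(MED) = 0.05, FST(RIV) = 0.10, FST(SWA) = 0.35,
  fixed once as a realistic river/river/swamp divergence pattern.
- **Composition**: S1 = 11 MED + 5 RIV + 6 SWA males plus MED pools of 18
  and 3 (the published per-dataset roster); S2 = 24 MED females; L = 8 MED
  males.
- **Genotypes**: Hardy–Weinberg at the group frequency; haploid on Y, male X
  and MT (emitted as homozygous diploid calls, matching common caller
  output); females carry nothing on Y; MT is homoplasmic.
- **Reads**: `DP ~ Poisson(sample mean depth)` with per-sample means spread
  evenly across each dataset's printed coverage range (3–40× / 28–56× /
  25–63×; per-sample values are not published); `AD_alt ~ Binomial(DP,
  d/2·(1−e) + (1−d/2)·e)` at dosage `d` and base error `e` (0.005 for
  short reads, 0.02 for long reads). `DP = 0` ⇒ missing genotype.
- **Calls**: the emitted genotype is wrong with a small probability
  (0.02/0.01/0.03 per dataset); GQ is a monotone function of DP plus noise
  (≈3·DP ± 6, clipped to [0, 99]) — only its threshold behavior at 20/30
  matters downstream, so no likelihood calibration is attempted.
- **Pools**: haplotypes drawn from the group frequency (ploidy-aware count),
  AD/DP from the drawn alt fraction, genotype and GQ absent — pools inform
  frequencies only.
- **Dropouts**: each dataset misses a fixed fraction of true sites (10 % /
  8 % / 30 %), plus the structural absences (no Y in S2, no MT in L). S2
  additionally carries a few MNP records at positions clear of true sites,
  so normalization is exercised without perturbing the shared-site truth.
- **Determinism**: one seed fans out through `numpy` `SeedSequence.spawn`;
  identical seeds give byte-identical VCFs.

What the generator does *not* model: alignment artifacts (duplicates,
mapping quality), linkage disequilibrium between sites, indels and
multi-allelic sites beyond classification fixtures, batch effects within a
dataset, and reference bias. Passing tests therefore demonstrate that the
pipeline's logic is correct under its stated statistical assumptions — not
that those assumptions capture every failure mode of real resequencing data.

## Problem sizes and numerical choices

The default layout is a miniature genome (five autosomes of 2–6 Mbp, X, Y,
MT) and the default study 3000 variants, chosen so a full pipeline run takes
seconds while every chromosome class and merge rule is exercised; the real
assembly (24 autosomes + X + Y + MT) is expressible through the same layout
table. Recovery experiments use the sizes stated in the tests (2000 variants
× 20 samples at 30× for frequency recovery; 5000 × 60 for structure
recovery). Histogram bins are left-closed with the last bin closed;
selection tie-breaks are total orders; the lossless-limit configuration
(zero dropout/error rates, filters disabled) conserves the truth list
end-to-end exactly, which the tests assert.

## Known limitations

- Pool depth is a single mean (30×) rather than a per-pool profile.
- The carry-over and call-rate percentages produced at desk scale are
  qualitatively, not numerically, comparable to values computed on millions
  of real variants with herd-scale sample counts.
- Complex-allele normalization (vcfwave-style realignment) is out of scope;
  only plain MNP decomposition is implemented.
- BCF and indexed access are not supported; inputs/outputs are plain or
  bgzipped VCF text.
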