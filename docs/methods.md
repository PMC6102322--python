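# Methods

`rohfst` characterizes selection signatures and genomic inbreeding in
multi-breed SNP-array genotype panels. This note records the statistical
models, the conventions chosen where the literature leaves them open, and
what the synthetic-data experiments do and do not demonstrate.

## Data model and quality control

Genotypes are diploid autosomal biallelic calls, held as a samples x
markers matrix counting copies of one allele (0/1/2, -1 missing), with a
position-sorted marker map and a breed label per animal (PLINK PED/MAP or
BED/BIM/FAM; the FAM family-ID column carries the breed unless a
sample-to-breed table is supplied). Coordinates are 1-based inclusive
base pairs; BED interval output converts to 0-based half-open at the
boundary. Chromosome labels are opaque strings and the autosome set is
configurable (default `"1".."29"`, the goat karyotype), so the pipeline
is species-portable.

QC applies, in order: sample missing-call fraction >= 0.10 (inclusive
cutoff) removes the sample; then per marker — call rate < 0.95, minor
allele frequency < 0.05 (strict: MAF exactly 0.05 is kept), non-autosomal
placement, Hardy-Weinberg departure at p < 0.001, and unknown position
(chromosome "0" or position 0). Marker statistics are computed once on
the sample-filtered data with all breeds pooled; each removed marker is
attributed to the first filter that rejects it, so removal counts sum to
the total removed. The HWE test is the exact conditional test on the
heterozygote count (Wigginton, Cutler & Abecasis 2005), two-sided without
mid-p, computed by the stable ratio recurrence from the modal count —
the PLINK 1.9 default. Pooling breeds mixes populations, so Wahlund-style
departures can remove genuinely differentiated markers; a per-breed HWE
mode exists (`per_breed_hwe=True`) but is off by default to match
standard single-pass array QC.

## IBS similarity

For individuals i, j at marker k the four ordered allele pairings each
score 1 when identical by state, giving per-marker scores 1 (same
homozygote), 0 (opposite homozygotes) and 1/2 (any pairing with a
heterozygote); SIM_ij is the mean over markers called in both
individuals. The denominator is pairwise-complete by default so SIM stays
a proportion under missingness; `denominator="total"` reproduces the
textbook fixed-denominator formula (the two coincide as missingness
approaches zero). Within-breed means average all ordered pairs including
self-pairs — the convention under which, for complete data, the
within-breed mean equals the expected homozygosity
mean_k sum_a p_hat_{a,k}^2 exactly (asserted to 1e-12 in the tests).

## One-vs-rest F_ST scan

Each breed is contrasted against the pooled remaining breeds (optionally
with breeds excluded from the pool) using the two-population Weir &
Cockerham (1984) estimator theta-hat = a/(a+b+c), with per-marker
non-missing sample sizes, allele frequencies and observed heterozygote
proportions entering the a, b, c variance components (formulas in
`rohfst/fst.py`). Markers where either group has fewer than two called
samples, or where a+b+c = 0 (monomorphic across both groups), are
undefined and excluded from smoothing and thresholding. Negative
estimates mean no differentiation and are clamped to zero.

Two genome-wide summaries are reported and must not be conflated:

* `genome_mean_theta` — the mean of clamped per-SNP values, the
  conventional "average F_ST across all SNPs" report;
* `weighted_theta` — the multi-locus ratio of sums
  sum_k a_k / sum_k (a+b+c)_k, Weir & Cockerham's own combination over
  loci.

The per-SNP mean is not a consistent estimator of the underlying
differentiation parameter: markers with large frequency splits inflate
their own denominators, so the mean of ratios sits below the ratio of
sums (about 0.15 versus 0.20 under Balding-Nichols drift c = 0.2,
independent of sample size). Parameter-recovery experiments therefore
use `weighted_theta`, which recovers c within about 0.01 at 5,000
markers and 30 diploids per population.

Smoothing is an unweighted moving average of the clamped values over 5
adjacent SNPs (odd window, configurable), centred, restricted to one
chromosome; no value is produced within two markers of a chromosome end
(truncated edge windows would inflate variance exactly where coverage is
thinnest), and undefined markers inside a window are skipped. The
region-calling threshold is the empirical 95% quantile (linear
interpolation between order statistics, the numpy default) of the raw —
not smoothed — clamped per-SNP distribution; SNPs with smoothed value
strictly above it are signature candidates. Regions are maximal runs of
strictly consecutive above-threshold SNPs on one chromosome, with no
bridging of sub-threshold gaps; this is the most literal convention, and
published region counts obtained under undocumented merging rules will
differ from it. Region calling depends only on marker order within
chromosomes, so it is invariant under order-preserving position
rescaling.

## ROH detection and F_ROH

A run of homozygosity must satisfy four criteria (defaults): >= 20
consecutive SNPs, physical span >= 2 Mb, no inter-marker gap > 500 kb
inside the run, and at most 2 missing with zero heterozygous calls
inside. The 2 Mb floor corresponds to autozygosity no older than ~25
generations under the inverse-exponential IBD length model (mean
100/(2g) cM, ~1 cM/Mb), exposed as `expected_roh_length(g)`.

The caller's semantics are fully deterministic: per sample and
chromosome the marker sequence is split at heterozygous calls and
oversized gaps; within each remaining stretch, segments are committed
greedily left to right — at the leftmost homozygous call from which a
criterion-satisfying window can start, the longest such window (bounded
by the missing budget, trimmed so both endpoints are homozygous
non-missing) is taken, and scanning resumes beyond it. This
"leftmost-longest non-overlapping" rule is verified against an
exhaustive enumeration of all valid sub-intervals on 1,000 random
strings. Boundaries are SNP positions and length = end - start; missing
calls may not be terminal, preventing length inflation through missing
flanks. Note one non-obvious consequence of any such rule: enlarging the
missing budget can merge two runs separated by a missing cluster into
one, so the run *count* is not monotone in `max_missing` (total
coverage is, and is tested); counts are monotone in `min_snps` and
`min_length_bp`.

F_ROH for an individual is its summed ROH length divided by L_AUTO, the
SNP-covered autosome length — computed from the data as the summed
per-chromosome span of the post-QC marker map rather than hard-coded,
with an `--l-auto` override for replicating published denominators
(e.g. 2.463 Gb for the goat 50K panel). Runs are binned into 2-4, 4-8,
8-16 and >16 Mb classes, half-open on the right, so class-wise F_ROH
sums exactly to the total. Breed summaries report nROH (total count),
S_ROH (mean per-individual summed length in Mb, averaged over all
animals of the breed), mean segment length, and N_0 (animals with no
ROH); per-chromosome mean coverage fractions are also emitted.

## Synthetic data generator

The generator produces datasets in which every pipeline stage has a
known target, emulating a six-breed 50K-chip study in structure:

* **Drift** — Balding-Nichols: ancestral frequency
  p ~ Uniform(maf_floor, 1 - maf_floor) per marker (default floor 0.05,
  the post-QC MAF cutoff); breed frequency
  ~ Beta(p(1-c)/c, (1-p)(1-c)/c), so c is the breed's expected F_ST
  against the ancestral pool. Default fixture: one exotic-like breed of
  13 animals at c = 0.22 and five indigenous-like breeds (15-29
  animals) at c = 0.06, chosen via the closed-form one-vs-rest relation
  theta ~ (c_focal + c_rest/5)/2 to land the exotic scan near the
  0.10-0.12 differentiation of an intensively selected breed against
  pooled local breeds, and the indigenous scans below 0.05.
* **Autozygosity** — per individual and chromosome, a Poisson number of
  tracts with Exponential(100/(2g) Mb) lengths, started uniformly and
  truncated at the chromosome end; markers inside a tract are set
  homozygous for one haplotype drawn per tract from the breed
  frequencies. The Poisson intensity is calibrated in closed form for
  end truncation and tract overlap (raw coverage target -ln(1-f)), so
  the realized merged coverage averages the requested fraction f; the
  per-individual realized fraction is recorded as ground truth. Tracts
  carry no internal mutation, so detection error isolates
  marker-resolution effects.
* **Sweep** — inside a configured interval the focal breed's
  frequencies are set to a final value (1.0 = fixation) with a linear
  10-marker shoulder each side; the truth table records the full
  perturbed interval (core plus shoulders).
* **Missingness** — i.i.d. masking at rate mu (default 0.01, a
  realistic array no-call rate).

Default scale: 29 autosomes with lengths declining linearly from 130 to
40 Mb (2.46 Gb total, matching the goat autosome), 1,500 markers per
chromosome (~43.5k total, ~57 kb spacing). One seed drives a single
`numpy.random.default_rng`, so equal configurations give byte-identical
PLINK and truth files.

What the generator does **not** emulate: linkage disequilibrium outside
autozygous tracts (genotypes are independent across markers given
frequencies), realistic site-frequency spectra, genotyping error beyond
missingness, pedigree structure, or admixture. Passing recovery tests
therefore demonstrates correctness of the estimators under their
stated models at realistic marker density — not robustness to array
artifacts or complex demography.

## Verification problem sizes

Chosen to keep the default suite and the acceptance script at desk
scale: ROH oracle equivalence on 1,000 strings of 20-200 markers; theta
oracle on 300 random two-group configurations (exact rational
arithmetic); drift recovery at 5,000 markers, 2 x 30 samples, for
c in {0.05, 0.1, 0.2} (tolerance +/-0.02); autozygosity recovery on six
breeds of 12 at f = 0.15, g = 3, 3,000 markers per 100 Mb chromosome
(tolerance 15% relative; at this density boundary and sub-2 Mb losses
are ~1-2%); sweep localization over 100 seeded replicates (>= 95 must
place the genome-wide smoothed peak inside the perturbed interval).

## Known limitations

* Region counts depend on the unpublished merging conventions of any
  particular study; only the literal no-bridging convention is
  implemented.
* The ROH caller's tie resolution (leftmost-longest) is one defensible
  choice among several; alternatives can differ by a few segments on
  stretches with more than `max_missing` scattered missing calls.
* Pooled-breed HWE filtering can discard strongly differentiated
  markers (Wahlund effect); use the per-breed mode when that matters.
* hapFLK-style haplotype tests, ROH islands/consensus regions, and
  enrichment analyses are out of scope.
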