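# Methods

This note documents the models and procedures implemented in
`sgcohort`, the parameter defaults and why they were chosen, the
numerical decisions taken where the design was genuinely open, and the
limits of what the synthetic cohort can demonstrate.

## Variant refinement

Refinement operates on called somatic variants (SNVs, MNVs, indels)
with tumour/normal read support, after alignment and calling, which
are outside this package's scope.

**Common-SNP exclusion.** A call with a known population allele
frequency ≥ 0.01 (`common_af_threshold`) is treated as a germline
polymorphism and removed; an *absent* population frequency never
removes a call. The boundary is inclusive ("at least 0.01"), so
pop AF = 0.0099 is retained.

**MNV merging.** Maximal runs of SNVs at consecutive positions sharing
a sample, chromosome and phase set are merged into one MNV; runs longer
than `max_mnv_len = 3` bp are left as individual SNVs. The merged
record's depth and alt count are the minimum over constituents (the
conservative choice: the fully phased haplotype is supported by at
least that many reads). Phasing itself is represented by a `phase_set`
field supplied upstream (the synthetic generator sets it); read-backed
phasing is not re-implemented.

**Retention cascade.** With VAF = t_alt/t_depth (defined as 0 at zero
depth; such records are removed as malformed):

1. MNVs longer than 3 bp are removed (`long_mnv`).
2. VAF < 0.1 is removed (`low_vaf`).
3. An allele pair is *simple* if both alleles are ≤ 25 bp and **not**
   both > 10 bp; simple calls are retained.
4. Anything else (*complex*) is retained only with VAF > 0.25 and
   depth ≥ 20 in both tumour and normal (`complex_low_support`
   otherwise).

The simple/complex split is isolated in one predicate
(`refinery._is_simple_allele`) because the length rule admits more
than one reading; changing the interpretation is a one-line edit.

**Target proximity.** A call is kept if its reference span is within
100 bp (inclusive) of the flanked, merged target territory; 101 bp
away is removed.

**Hotspot rescue.** Recurrent hotspot sites suffer false-negative
filtering when tumour purity is low (low VAF) or the matched normal is
contaminated with tumour cells. Instead of manual alignment review,
rescue is automated with explicit evidence thresholds: a raw call at a
configured hotspot site that any filter removed is reinstated when it
has ≥ 3 tumour alt reads (`rescue_min_t_alt`) and normal VAF ≤ 0.01
(`rescue_max_n_vaf`), and is flagged `rescued:<rule>` with the
overridden rule's name. The audit log records every removal exactly
once, with the first rule that removed the record.

The full refinery is idempotent, order-invariant, and monotone in
`min_vaf`; these contracts are asserted in the test suite.

## Tumour mutation burden

TMB = (n_SNV + n_MNV + n_indel) / total_mb, where the denominator is
the merged coding target territory including a 2 bp splice flank
(overlaps counted once). A call counts if its reference span overlaps
the flanked territory at all — a variant touching only the 2 bp flank
is a splice-site variant and counts. An MNV counts as one mutation.
Burdens below 1 mutation/Mb carry a low-burden flag.

Cohorts are compared with the unpaired Wilcoxon rank-sum test using
the normal approximation: mid-ranks for ties, tie-corrected variance,
and a 0.5 continuity correction (delegated to
`scipy.stats.mannwhitneyu`; a degenerate pooled sample with zero
variance returns p = 1 with a warning). Complete enumeration over all
rank configurations at group sizes 3–6 shows the continuity-corrected
normal *tail* probability within 0.02 of the exact permutation tail;
the factor-two of a two-sided p doubles that error, and groups of one
or two are outside any sensible validity of the approximation (errors
up to ≈ 0.09), so the approximation should not be trusted below group
size 3. At the cohort sizes this package targets (tens of samples) the
approximation error is negligible.

## Copy-number analytics

Inputs are allele-specific segment profiles (sample, chromosome,
start, end, total CN, minor CN, ploidy, goodness of fit) in the shape
emitted by allele-specific CN callers. Profiles with goodness of fit
< 0.9 are flagged `low_fit` and excluded from every CN stage.

**Altered-genome fraction** is the length-weighted fraction of
autosomal segments with total CN ≠ 2. The diploid baseline is the
default because "amplified or deleted" does not define a baseline;
a ploidy-relative mode (`baseline="ploidy"`) is available.
X and Y do not contribute.

**Broad events.** An arm is lost (gained) when ≥ 50% of its length is
below (above) total CN 2; an exact tie between lost and gained halves
resolves to loss (documented tie-break; both cannot otherwise exceed
half simultaneously).

**Chromothripsis scoring.** A CN state switch is a breakpoint between
adjacent segments with different total CN. The score is the maximum
number of switches within a 50 Mb window; candidate windows are
anchored at every switch breakpoint, which is exact (any window's
count is achieved by the window starting at the first switch inside
it), rather than a fixed-step sliding approximation. Tiers: high ≥ 10,
intermediate 8–9, low 6–7 switches per 50 Mb. For chromosomes shorter
than the window the thresholds are scaled by `length/50 Mb` and
rounded to the nearest whole number, halves away from zero: a
46.709 Mb chromosome gives factor 0.934 and thresholds 9/7/6. Events
are canonical when the window holds 2–3 distinct CN states,
non-canonical above 3. Tier is monotone in switch count by
construction. Copy-number evidence alone cannot confirm chromothripsis
(that requires rearrangement-level data); calls are "chromothripsis-
like".

**Focal-event post-filters.** Candidate focal events (from an external
recurrence engine, or synthetic) receive exactly one status, in
cascade order: `removed_small` (size ≤ 100 kb, inclusive), then
`removed_difficult` (> 40% overlap with the difficult-region mask),
then `removed_discordant` (< 75% of supporting samples concordant —
exactly 75% is kept), else `kept`. A supporting sample concurs when at
least half the event length in its own profile has CN consistent with
the event direction.

**Two-hit calling.** Per gene: `two_variants` when ≥ 2 distinct
damaging variants (default damaging classes: stop-gained, frameshift,
splice-acceptor/donor, start-lost) overlap the gene; otherwise
`variant_plus_loh` when one damaging variant coincides with minor
CN = 0 over ≥ 50% of the gene body. The 50% LOH coverage is a
documented choice — the qualitative narratives this models ("LOH plus
point mutation") do not quantify it.

## Minimizer-proportion taxon test

Taxonomic classifier reports give, per taxon, `m` distinct database
minimizers observed of `M` available, from `n` assigned reads of `N`
evaluated. Under the null the taxon's minimizer discovery chance is
taken proportional to its read share: each of the `M` minimizers is
discovered independently with p₀ = n/N, so `m ~ Binomial(M, p₀)`. The
test is one-sided (upper tail): the screen is for presence/enrichment,
not depletion. p₀ is injectable for alternative null models.

P(X ≥ m) uses the continuity-corrected normal approximation
z = (m − M·p₀ − 0.5)/√(M·p₀·(1−p₀)) when the binomial variance is at
least `approx_validity_min`, the exact binomial tail otherwise. The
floor defaults to 25: a swept (M, p₀) grid shows a worst
normal-vs-exact discrepancy of 0.0094 above 25, while floors as low as
5 admit errors above 0.02; below the floor the exact tail is cheap, so
nothing is lost. Degenerate nulls: p₀ = 0 with m > 0 returns p = 0
with a warning; p₀ ≥ 1 is an error.

Benjamini-Hochberg correction is applied across the taxa of one sample
(the report is the natural family; the choice is documented, not
forced), and significance is adjusted p < 0.05, strict. On 12,000 null
taxa drawn from the test's own null the empirical type-I error at
p < 0.05 is 0.049.

## Cohort summaries

The binary alteration matrix holds one row per sample and one column
per gene with ≥ 1 non-silent call in ≥ 2 samples. Hotspot frequencies
report both nearest-integer and one-decimal percentages (half away
from zero); a `truncate` display mode reproduces the truncating style
occasionally seen in prose (93.75 → "93.7").

**Mutual exclusivity** is screened with a margin-preserving permutation
test: null matrices are generated by checkerboard swaps that conserve
every row and column sum, so the null conditions on both per-sample
alteration load and per-gene frequency. Swap chains run 10× the number
of 1-cells between snapshots, after an equal burn-in, seeded and
deterministic. Exclusivity p = (1 + #{null co-occurrence ≤ observed})
/ (n_permutations + 1); BH across tested pairs. The tested pairs can
be restricted to a curated driver panel (`test_genes`) while the null
still permutes the whole matrix — with few genes per sample, margins
alone force exclusivity and the test is powerless, so conditioning on
the full matrix (passengers included) is what gives the screen its
meaning. This permutation stand-in deliberately differs from published
model-based exclusivity methods; its q-values are not comparable
numerically to any external tool's. Under independent columns its
p-values are approximately uniform, with discrete atoms that shrink as
the cohort grows.

**Two-proportion comparison** is a Pearson chi-square on the 2×2 table
(df = 1), with an optional Yates correction that clamps |O−E| − 0.5 at
zero (so a table with all |O−E| < 0.5 gives exactly 0). It is computed
directly rather than through a library call because common
implementations do not clamp. A related published χ² value for a
5/32-vs-1/11 comparison (0.16) is not reproducible by either the
uncorrected (≈ 0.29) or corrected (≈ 0.001) statistic and is treated
as unverifiable; no acceptance value depends on it.

## Synthetic cohort generator

The generator emulates the *structure* of a two-cohort salivary-gland
tumour study on a synthetic genome of three chromosomes (60/50/47 Mb,
centromeres at 25/20/18 Mb) with 2 kb target tiles every 25 kb
(≈ 12.6 Mb of flanked territory — exome-like logic at 1/4 scale).
Study-condition defaults:

- 32 benign samples: 25 CTNNB1-hotspot carriers, 5 FBXW11-hotspot
  carriers (disjoint), 2 with neither; 11 malignant samples, one of
  them an FBXW11 carrier.
- Background mutation counts are Poisson with per-sample lognormal
  rates (benign median 0.32/Mb, σ = 0.35; malignant median 0.56/Mb,
  σ = 0.5), giving benign burdens ≈ 0.1–0.8/Mb and malignant
  ≈ 0.2–2.5/Mb. One malignant hypermutator has a fixed 7.5/Mb rate
  with an indel:SNV ratio of 1:3 (vs 1:9 elsewhere), the indel-rich
  spectrum characteristic of mismatch-repair deficiency.
- Planted events: MLH1 splice variant + copy loss in the hypermutator;
  two KMT2D-two-hit samples; one DICER1-two-hit sample; two CYLD
  variant+LOH samples inside the four 16q-analogue (chr3q) losses; two
  5q-analogue (chr2q) losses; HRAS/PIK3CA/IKBKB hotspot missense
  calls; one chromothripsis-like region (10 switches, 2 states) on the
  60 Mb chromosome; one 10-fold enriched taxon in one sample's
  minimizer report (null reports: M ∈ 10⁴–10⁵, n ∈ 10³–10⁴ reads of
  N = 10⁶, m drawn Binomial(M, n/N)).
- Noise exercising the refinery: per sample, 2 common SNPs
  (pop AF ≥ 0.01), 2 sub-threshold-VAF artefacts, ~1 off-target call,
  a phased in-cis SNV pair in three samples, and two low-purity
  hotspot carriers at VAF 0.06 that only hotspot rescue can recover.
- Background mutations are binned into 10 recurrent positional
  passenger-gene labels, so samples have realistic multi-gene rows in
  the alteration matrix (without which a margin-conditioned
  exclusivity null is degenerate), and are placed outside driver-gene
  intervals so planted prevalences are exact.

Randomness is a single seeded stream forked per sample by stable
hashing of the sample id: adding a sample never perturbs another
sample's data, and a fixed (config, seed) yields byte-identical
bundles. Infeasible prevalences fail before any file is written.

**What passing tests do and do not show.** The generator plants calls
and segments directly — it does not simulate reads, alignment error,
FFPE artefact spectra, trinucleotide signatures, subclonality or
caller-specific biases. Recovery of planted truths therefore validates
the *post-calling logic* (filter boundaries, scoring rules, test
calibration), not robustness to upstream noise. Real-data behaviour
additionally depends on the callers and QC outside this package's
scope.

## Problem sizes and determinism

The test suite and acceptance script use desk-scale problems chosen to
pin the statistics without waste: 200 random profiles for the
switch-count oracle, complete enumeration for the rank-sum oracle
(≤ 924 configurations per size pair), 12,000 null taxa for type-I
calibration, 400–2000 permutations for exclusivity screens, and 100
seeded cohorts for planted-truth recovery. Every stochastic step takes
an explicit seed; the swap kernel is JIT-compiled with numba, with a
pure-Python fallback.

## Known limitations

- The allele-length retention rule implements one reading of an
  ambiguous prose rule; the predicate is isolated so alternatives are
  one-line changes.
- The minimizer test's null (per-minimizer Bernoulli with p₀ = n/N)
  is a stated interpretation; classifiers do not document a formal
  null, and read-level alternatives would change the variance.
- Chromothripsis calls from CN oscillation alone are suggestive, not
  confirmatory.
- The exclusivity screen's q-values depend on the permutation null and
  the tested panel; they are not exchangeable with model-based tools.
- The generator's genome is synthetic; no conclusions about specific
  human loci follow from it.
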