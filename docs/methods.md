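# Methods

## Scope and model

`mosaicdn` analyses de novo variation in quad families and splits it into
germline de novo and post-zygotic (mosaic) components.  The underlying
biological model: a germline de novo variant is heterozygous in every cell,
so its alternate-allele read fraction (AARF) is ~0.5 (slightly less under
reference bias); a mosaic variant arose after fertilization on one parental
haplotype and is carried by a fraction *f* of cells, giving an expected AARF
of *f*/2.  Detection, classification, phasing confirmation, rate estimation
and the contribution model all follow from this picture.

## De novo calling

A call requires: the child's most likely diploid genotype contains the
alternate allele with the phred-scaled likelihood of hom-ref >= 20; both
parents' most likely genotype is hom-ref with a phred gap >= 20 to any
alt-bearing genotype; depth >= 20 in all three trio members; >= 3 alternate
reads in the child; and at most 2 individuals cohort-wide genotyped with the
allele.  Families in which any child accumulates more than 10 calls are
dropped entirely.  "Phred-scaled confidence" is operationalised as a
genotype-likelihood gap because the PL field is the only confidence the
input carries; this is a documented reading, not the only possible one.
Multi-allelic sites are represented as decomposed per-allele records before
filtering, and carrier counting includes parents and children of all
families.

## Mosaic classification

For each call, p = P(X <= alt_depth | n = total_depth, 0.5) from the exact
binomial lower tail; q-values from the Benjamini–Hochberg step-up computed
jointly over the whole callset (probands and siblings together — no
stratification); label mosaic iff q < 0.05 and AARF < 0.34.  The AARF
ceiling exists because deep sites with modest reference-capture bias can
clear the FDR line while not being mosaic; the ceiling is what lifts
classification precision in validation.  Ties in p are handled by the
standard cumulative-minimum step-up; AARF is computed from the same depth
fields the test uses.  One depth convention is used for SNVs and indels.

## Phasing

Reads spanning a de novo site and a linked inherited het (child het whose
alternate allele is attributable to exactly one parent, within 500 bp) are
tabulated into four configurations.  Let X be the inherited allele on which
the de novo allele is observed with >= `min_support` reads (default 2, the
minimal reading of "multiple reads"; exposed as a flag).  Observation of
(X, dn-ref) at >= `min_support` reads demonstrates three haplotypes and hence
mosaicism; perfect co-segregation is the germline pattern; de novo support
on both inherited alleles, or no configuration at support, is uninformative.
The cell-fraction estimate (X ∧ dn-alt)/((X ∧ dn-alt) + (X ∧ dn-ref))
assumes heterozygous mosaicism in a diploid region (no CNV correction).
Reads with base quality < Q20 at either site are dropped; the read-level QC
floor is a package choice.

## Mutation rates

Coverage is piecewise-constant; per-child joint regions are the four-way
intersection of the child's, father's and mother's >= 40x intervals with the
capture target (0-based half-open intervals, merged before measuring).
Counts inside the joint region are extrapolated linearly:
`count * capture_length / joint_length`.  Children with empty joint regions
are excluded with a warning.  Group means are compared with a one-sided
label-permutation test (10,000 permutations, add-one smoothing, exhaustive
enumeration when feasible); the source study does not name its test, so
permutation is a documented stand-in and printed p-values are not treated as
reproduction targets.

## Contribution model

With eps_c = fraction of class-c calls that are truly the other class
(measured separately per cohort and per classified class from phasing
validation), true rates are

    B_m = O^s_m (1 − eps^s_m) + O^s_g eps^s_g     B_g symmetrically
    T_m = O^p_m (1 − eps^p_m) + O^p_g eps^p_g     T_g symmetrically

and C = T − B.  Percent of cases is 100 × C (expected-count reading; a
Poisson P(>=1) variant, 100 × (1 − e^−C), is available and agrees to first
order).  The stacked-bar decomposition inverts the classified→true map
(O_c = A⁻¹C with A = [[1−eps_m, eps_g], [eps_m, 1−eps_g]], proband eps) and
splits each classified class by its own eps into correctly/incorrectly
classified portions — the unique reading that maps back to C exactly.
Negative contributory estimates are reported with a warning, never clipped.

Uncertainty: each eps is drawn from Beta(k + 1, n − k + 1) (uniform prior;
Jeffreys available) given its validation counts, the model re-solved per
draw, and 2.5/97.5 percentiles over 10,000 draws form the 95% credible
interval.  The observed rates are *not* resampled, so the interval reflects
classification-error uncertainty only; the calibration test therefore
replicates the validation experiment (binomial misclassification counts at
fixed true eps) rather than whole cohorts.

## Gene-length null and conservation

Under the null a mutation lands in a gene with probability proportional to
its capture-targeted coding length (overlapping coding intervals merged,
intersected with the capture target).  Recurrence: 10,000 draws with
replacement; a recurrent event is a gene drawn >= 2 times; the p-value uses
add-one smoothing (1 + #{sim >= obs})/(1 + n_sim) to avoid zero.  Gene-set
enrichment: expected = n_hits × set-length share; exact two-sided binomial p
by the minimum-likelihood convention; genes-harbouring-mutation counting by
default with a per-mutation flag.  Conservation comparisons use the
Wilcoxon rank-sum test (exact for small tie-free samples) with a
Hodges–Lehmann location-shift estimate.

## Synthetic cohort generator

The generator emulates the read-count structure of a large simplex exome
study at the level a joint caller would emit, with exact truth labels.

Parameters (defaults are the study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_families` | 2388 | quad families |
| `depth_mean` | 94.6 | mean depth at variant sites (reads) |
| `depth_dispersion` | 10 | negative-binomial size; capture depth is overdispersed |
| `germline_denovo_rate` | 0.877 | baseline germline de novo per child exome |
| `mosaic_rate` | 0.104 | baseline (detectable) mosaic per child exome |
| `contributory_germline_rate` | 0.056 | proband-only germline excess |
| `contributory_mosaic_rate` | 0.051 | proband-only mosaic excess |
| `cell_fraction_distribution` | U(0.25, 0.75) | mosaic cell fractions |
| `reference_bias` | 0.05 | fractional under-representation of alt reads |
| `sequencing_error` | 0.001 | symmetric per-read error |
| `capture_length` | 36 Mb | exome capture size |

Depth is negative-binomial; a carrier's alternate reads are binomial with
success probability (cell_fraction/2) × (1 − reference_bias), a
non-carrier's at the error rate; genotype likelihoods come from the
symmetric per-read error model over the three diploid genotypes, rescaled to
min 0.  The baseline/contributory rates are fixed once from the published
point estimates of the modelled quantities; the cell-fraction window is the
range detectable-and-relevant at ~95x under a diploid likelihood model
(AARF ~0.12–0.36, spanning the 0.34 classification ceiling so that both
misclassification directions occur).  Reference bias is a tunable guess:
the phenomenon is documented but unquantified in the source data.

Each planted de novo variant is guaranteed one origin-resolvable linked het
within the 500 bp phasing window (more at the configured density), so
phasing informativeness is much higher than in real data — synthetic
validation counts are correspondingly larger.  A few recurrent child-only
artifact sites are planted across unrelated families to exercise the
cohort-carrier filter; they carry no truth entry because they model
artifacts.  Coverage tracks are negative-binomial per 50 kb bin and drawn
independently of variant-site depth.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: alignment and capture artifacts (the dominant real
false-positive source), GC-dependent coverage, correlated depth between
family members, indel-specific error modes, mosaicism confined to single
tissues, and a caller with ploidy-aware genotype likelihoods.  The last
point matters quantitatively: with diploid PLs, mosaics below ~0.22 cell
fraction are not genotyped as carrying the allele at 95x, and measured
detection sensitivity for planted mosaics is ~0.95 versus ~1.00 for
germline variants.  End-to-end percent-of-cases estimates therefore sit a
few percent below the planted values (fraction-contributory is insensitive,
since detection sensitivity cancels in C/T).  No compensation is applied —
the package reports what the data support.

## Numerical and design choices

* Intervals: 0-based half-open everywhere internally; VCF positions 1-based.
  Interval arithmetic is a small numpy sweep (merge / two-pointer intersect),
  cross-checked against pyranges in tests; pyranges itself backs the
  gene-length BED preprocessing.
* Binomial tails and tests come from scipy (`binom.cdf`, `binomtest`), BH
  from statsmodels `multipletests`; tests verify both against from-scratch
  oracles.
* All simulation p-values use add-one smoothing; exact enumeration replaces
  Monte-Carlo when the assignment space is small enough.
* Determinism: every random stage takes a seed; the pipeline derives
  stage-salted substreams from one root seed, so config + seed pins all
  outputs (manifest hashes are compared in tests).
* Degenerate inputs: zero-depth precision denominators, empty joint regions,
  all-zero phase observations and zero-informative validation cells raise or
  warn explicitly rather than returning silent zeros.
* Problem sizes in the test-suite and acceptance script (50-quad oracle
  cohorts, 2,000-family recovery runs, 50,000-family acceptance cohort,
  200-replicate calibration loops) were chosen to keep Monte-Carlo error
  well below the asserted tolerances at interactive runtimes.

## Known limitations

* The caller consumes diploid genotype likelihoods; very low cell-fraction
  mosaics (< ~0.2) are invisible to it, as they are to any diploid caller.
* Classification error rates are estimated from phasing verdicts, which have
  their own small error; the model treats them as the truth.
* The credible interval ignores sampling noise in the observed rates by
  design (a bootstrap-over-children extension is off by default).
* BAM/CRAM input paths are out of scope; phasing and mixing consume the
  tabular read/count dialects documented in their modules.
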