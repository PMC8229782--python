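# Methods

## The two-stage design

The package models a pooled-DNA association study. In the discovery stage,
DNA from groups of subjects is combined at equimolar concentrations into
fixed-size pools (default 24 subjects per pool; 18 case pools — 7 female, 11
male — and 28 control pools — 15 female, 13 male, i.e. 432 cases and 672
controls), and each pool is hybridised to a two-channel SNP array. In the
verification stage, index SNPs chosen from the scan are genotyped in
individuals (the bundled worked example has 465 cases and ~1079 controls)
and analysed as genotype count tables. A final stage builds a multi-SNP
risk model.

## Pooled scan

**Relative allele signal.** For probe channels A and B, RAS = A/(A+B)
estimates the pool's frequency of the A-labelled allele. RAS is undefined
(missing) when A + B = 0; such probes are tested on the remaining pools and
dropped if fewer than two usable pools remain in either group.

**Test.** Per probe, a Welch two-sample *t* statistic compares case-pool and
control-pool RAS, with Satterthwaite degrees of freedom and two-sided
p-values. Degenerate inputs follow fixed conventions: zero variance in both
groups with equal means gives t = 0, p = 1; with unequal means, p = 0.
Family-wise correction uses the step-down Holm procedure over *all* probes
in the scan (no probe filtering).

**Pool QC.** Because pooled arrays have no per-sample call rate, outlying
pools are detected on the first two principal components of the pools ×
probes RAS matrix (complete probes only): each component is converted to a
modified z-score, 0.6745·(x − median)/MAD, and a pool is flagged when the
Euclidean norm of its two z-scores exceeds `mad_threshold` (default 6).
This replaces subjective visual inspection with a reproducible rule; the
threshold is deliberately lax so only gross artefacts are removed. A
component with zero MAD contributes 0 at the median and ∞ elsewhere.

**Inflation.** λ = median(χ²₁(1 − p)) / median(χ²₁), the usual
median-chi-square genomic inflation factor; λ ≈ 1 indicates no systematic
stratification. When every p equals 1 (e.g. constant intensities) λ is
undefined and reported as NaN with a warning.

## Block building and index SNPs

Within each chromosome, SNPs with p < `p_block` (default 5×10⁻³) are chained
greedily: the chain breaks whenever the gap to the previously retained SNP
is ≥ `max_gap` (default 30 kb; the inequality at the threshold is strict,
and gaps are measured between retained SNPs, not all probes). A block is
carried forward when it has ≥ `min_block_size` members (default 7, the
smallest block accepted in the motivating design; a stricter 11-member /
3-below-threshold preset is available via `min_block_size=11,
min_below_index=3`) and its best member reaches p < `p_index` (default
10⁻⁴); that member becomes the index SNP, with ties broken to the smaller
position. Distinct blocks are treated as independent loci; no r²-aware
clumping is attempted.

## Verification statistics

Given per-SNP counts (case and control mm/mM/MM, m = minor in controls):

* **HWE**: 1-df chi-square goodness of fit against p², 2pq, q² at the sample
  allele frequency (controls by default); an exact conditional test is
  available (`method="exact"`). Monomorphic SNPs return p = 1 with a warning.
* **Allelic test**: Pearson chi-square on the derived 2×2 allele table
  *without* continuity correction; this choice reproduces the worked
  example's published adjusted p-value chain exactly, which a Yates-corrected
  test does not. OR = (c/d)/(a/b) with the minor allele as exposure;
  95% CI = exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)). A zero cell triggers the
  Haldane-Anscombe +0.5 correction with a flag.
* **Genotypic test**: Cochran-Armitage trend with scores (0, 1, 2),
  two-sided. When any genotype cell is below five in either group the exact
  conditional 2×3 Fisher test (full enumeration with fixed margins,
  probability-ordering rule) is used instead — on the bundled data this rule
  fires for exactly one SNP (rs17575184, cells 1 and 11).
* **Per-genotype ORs**: heterozygote and minor-homozygote versus the
  major-allele homozygote reference, Wald CIs; a conditional median-unbiased
  (mid-p) estimator is available for sparse cells (`or_method="midp"`). The
  Wald estimate is unreliable when a homozygote cell is ≈1 and is flagged
  when corrected.
* **Multiplicity**: Benjamini-Hochberg step-up, applied separately to the
  allelic family and the genotypic family. Significance means adjusted
  allelic p below `alpha` (default 0.05).

Stratified analyses reuse the same machinery on a case subset versus all
controls.

## Risk model

Candidates are first screened: a SNP whose single-SNP likelihood-ratio test
has p ≥ 0.05 is excluded. The forward search starts from the intercept-only
model and at each round adds the candidate minimising the AIC of the
enlarged model, stopping when no addition lowers the AIC; there is no
removal step. Genotypes are coded additively (0/1/2) and rows incomplete
across the candidate set are dropped. Each accepted step records AIC and
Nagelkerke R² = (1 − exp(2(ll₀ − ll₁)/n)) / (1 − exp(2·ll₀/n)); the AIC
trace is strictly decreasing and R² non-decreasing by construction. The
final model is summarised by its in-sample rank-based AUC (no
cross-validation, matching how such models are usually first reported).
Separation is detected (singular Newton step or |β| > 15) and flagged, with
coefficients capped for scoring.

## Power

`cc_power` uses the two-proportion normal approximation at the per-subject
convention: the allele proportions p₀ and p₁ = OR·p₀/(1 + p₀(OR − 1)) are
compared with variance p(1−p)/n per group, n being the number of subjects.
This convention reproduces the 88–90% window quoted for OR = 1.5 at
432/672 subjects over reference proportions 0.3–0.5 (maximum 90.9% at
p₀ = 0.45); a per-allele-count convention (2n alleles per group) would give
materially higher power and is not the default. An optional continuity
correction is provided. The empirical check in the test suite simulates
binomial group proportions at the same convention and recovers the analytic
power within Monte-Carlo error.

## Synthetic-data generator

The generator emulates exactly the structure the analysis assumes:

* **Genotypes** are Hardy-Weinberg draws; null SNPs share one frequency per
  SNP between groups, drawn uniformly from 0.05–0.5 (the range the power
  grid considers realistic for common variants).
* **Disease model**: per-allele (multiplicative odds) effects. For a planted
  locus with control frequency p₀ and odds ratio OR, case genotypes are HWE
  at p₁ = OR·p₀/(1 + p₀(OR − 1)); the multiplicative weights factorise over
  the two allele draws, so this *is* the logistic per-allele model and the
  population allelic OR equals OR exactly.
* **LD blocks**: a single-parameter haplotype-copy model. Each of the
  block's neighbours copies the index haplotype and flips every allele
  independently with probability f (default 0.05). At allele frequency 0.5
  the allelic r² between neighbour and index is (1 − 2f)² exactly; at other
  frequencies the neighbour frequency shifts toward 0.5 and r² is slightly
  lower. Chosen over a full LD matrix because it is analytically tractable
  and exposes one interpretable decay parameter.
* **Pooling** is idealized equimolar: a pool's frequency is the exact mean
  allele dose of its 24 members over 48 alleles, i.e. binomial sampling
  error with variance p(1−p)/48 per pool — the dominant noise source at
  this pool size. No DNA-quantification error or inter-pool contamination
  is modelled.
* **Intensities**: A = g·f·(1+ε_A), B = g·(1−f)·(1+ε_B) with independent
  Gaussian relative errors of standard deviation `intensity_cv` (default
  0.02, a few percent of multiplicative array noise; this adds RAS noise of
  sd ≈ √2·f(1−f)·cv ≈ 0.007 at f = 0.35, an order of magnitude below the
  pooling sampling error) truncated at zero, and a common channel gain
  (default 1000). RAS is unbiased for f to first order in cv, and exact at
  cv = 0.
* **Sex labels** are generated to match the pool layout and carried through,
  but the default scan tests case versus control overall.
* **Missingness** can be injected at a configurable rate (default 0) to
  exercise complete-case handling.

What passing synthetic tests do *not* show: robustness to batch effects,
probe GC bias, population stratification, genotype-calling error or unequal
pool contributions — none of which the generator produces. The null-scan
calibration (λ within [0.99, 1.01], 5% type-I error, uniform p at 100,000
probes) validates the statistics under the generator's assumptions, not
against real-array artefacts.

## Problem sizes used in the checks

The test suite runs the calibration scan at 100,000 probes on the full
46-pool design; block/index selection is verified against a brute-force
oracle on 500 random instances; planted-locus recovery uses 100 replicates
of an 11-SNP block (OR 1.5, MAF 0.3) over 1000 null SNPs; stepwise recovery
uses 100 replicates at 2000 cases / 2000 controls; OR unbiasedness uses 200
replicates per effect size at 1000/1000. These sizes give Monte-Carlo
standard errors comfortably below the asserted tolerances while keeping a
full run around two minutes.

A note on detection power at the scan stage: with 46 pools of 24, the
pool-frequency sampling s.d. is ≈0.066, so the expected Welch statistic for
an OR 1.5 / MAF 0.3 locus is ≈4.4 and the probability that such a locus
yields an index SNP at p < 10⁻⁴ is only ≈0.5–0.6 per replicate — and under
the haplotype-copy LD model at f = 0.05 the ten neighbours are statistical
near-twins of the index, so the specific planted column attains the block's
minimum p in only ~1/6 of replicates regardless of effect size. Reliable
(≥80%) recovery of the exact planted index SNP at these settings is
therefore not achievable by any selection rule; the corresponding
recovery check in the test suite documents this limit (see the test
output), while recovery at OR 2.0 is near-certain and is asserted.

## Numerical choices

* Strict inequalities at every published threshold (p < 5×10⁻³, < 30 kb,
  p < 10⁻⁴, cell < 5); boundary cases are covered by tests.
* Fisher 2×3 enumeration includes tables whose probability is within a
  relative 10⁻⁷ of the observed table's (standard tie tolerance); the
  enumeration refuses tables whose candidate count exceeds 5×10⁶ and points
  to the trend test.
* Holm/BH adjustments delegate to `statsmodels.stats.multitest`; logistic
  fits to `statsmodels.Logit`; AUC to scikit-learn; PCA to scikit-learn —
  all behind the package's own API so conventions stay fixed.
* TSVs are written with six significant digits; reruns with the same config
  and seed are byte-identical.
* All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; the intensity-noise stream is decoupled from the genotype
  stream (seed + 1) so enabling noise does not perturb genotypes.

## Known limitations

* The scan models no array normalisation or probe-level bias; real pooled
  arrays need upstream vendor processing before the RAS is meaningful.
* Block building is purely positional; true LD-aware clumping (r² with a
  reference panel) is out of scope.
* The risk model reports in-sample fit only; predictive claims need
  external validation or cross-validation.
* The exact estimator behind sparse-cell genotype ORs is convention-laden;
  both Wald (+0.5) and conditional mid-p are exposed, and neither is
  asserted against published sparse-cell values.
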