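# poolgwas

Two-stage case-control association analysis for pooled-DNA genome-wide
scans, written for study designs where individual genotyping of every subject
is too expensive for the discovery stage: equimolar DNA pools are allelotyped
on SNP arrays, promising loci are verified by genotyping individuals, and the
verified SNPs are combined into a polygenic risk model.

The package covers the full workflow:

1. **Pooled scan** — the relative allele signal of each probe,
   RAS = A/(A+B) from the two channel intensities, proxies a pool's allele
   frequency; per probe, case pools are compared with control pools by an
   unequal-variance (Welch) *t*-test; p-values get a step-down Holm
   correction, pools are quality-controlled by a robust (median/MAD) distance
   rule on the first two principal components of the RAS matrix, and residual
   inflation is summarised by the genomic inflation factor
   λ = median(χ²₁(1−p)) / 0.4549.
2. **Index-SNP selection** — SNPs associated at p < 5×10⁻³ are chained into
   blocks while consecutive gaps stay under 30 kb; a block with at least 7
   members whose best p-value is below 10⁻⁴ contributes that SNP as the
   locus's *index SNP*.
3. **Verification** — per index SNP, a 2×3 genotype count table from
   individual genotyping is analysed: Hardy-Weinberg check, allelic Pearson
   χ² (no continuity correction) with Wald OR/95% CI (minor allele vs major),
   Cochran-Armitage trend test (exact 2×3 Fisher test when any genotype cell
   < 5), per-genotype ORs against the major-allele homozygote, and
   Benjamini-Hochberg adjustment separately for the allelic and genotypic
   families.
4. **Risk model** — forward stepwise logistic regression over the verified
   SNPs with AIC as entry criterion, Nagelkerke pseudo-R² per step and an
   in-sample AUC.
5. **Power** — two-proportion normal-approximation power for allelic odds
   ratios in an unmatched design, p₁ = OR·p₀ / (1 + p₀(OR−1)).

A first-class synthetic-data generator emulates the assumed data-generating
process (HWE genotypes, per-allele logistic disease model, haplotype-copy LD
blocks, binomial 24-sample pooling, multiplicative two-channel intensity
noise), so every stage is testable end to end without access to raw arrays.

## Worked example

The package bundles the genotype counts of seven candidate SNPs genotyped
individually in a Polish colorectal-cancer case-control cohort (465 cases,
~1079 controls):

```python
import poolgwas as pg
from poolgwas.datasets import load_crc_verification_counts

results = pg.VerificationStudy(load_crc_verification_counts()).fit()
print(results.summary())
```

```
Verification-stage association
  SNPs tested: 7   significant (allelic BH p < 0.05): 5
  snp          MA  MAF ctl  MAF case  OR (95% CI)          p_adj     geno test geno p_adj
 *rs17575184   A   0.108    0.065     0.57 (0.42-0.76)     0.000354  fisher    0.000791
 *rs10935945   T   0.422    0.515     1.46 (1.25-1.70)     1.26e-05  trend     1.29e-05
  rs10838094   A   0.414    0.455     1.18 (0.99-1.41)     0.0803    trend     0.0812
  rs12424924   A   0.205    0.179     0.85 (0.68-1.06)     0.147     trend     0.152
 *rs11060839   A   0.156    0.211     1.45 (1.19-1.76)     0.000392  trend     0.00057
 *rs9927668    C   0.391    0.309     0.70 (0.59-0.82)     5.04e-05  trend     8.25e-05
 *rs12935896   C   0.254    0.209     0.77 (0.64-0.93)     0.00885   trend     0.00887
```

Five SNPs remain significant after BH adjustment (starred). The odds ratios
are minor-allele-vs-major: rs10935945-T raises the odds of disease by ~46%
per copy, while rs17575184-A is protective (OR 0.57). rs17575184 is tested by
the exact 2×3 Fisher test because only 1 case and 11 controls carry the AA
genotype.

The same API drives a fully synthetic end-to-end run:

```python
from poolgwas.io import PipelineConfig, run_pipeline
from poolgwas.simulate import PlantedLocus, SimConfig

cfg = PipelineConfig(seed=3, sim=SimConfig(
    n_null_snps=800, seed=3,
    planted_loci=[PlantedLocus("chr3", 1_000_000, maf=0.3, odds_ratio=2.0,
                               name="plantA")]))
manifest = run_pipeline(cfg, "out/")
# manifest["lambda"] ~ 0.96, manifest["index_snps"] -> a member of plantA's block
```

or from the shell:

```sh
poolgwas simulate --out sim/ --seed 3
poolgwas scan --intensities sim/intensities.tsv --pools sim/pool_manifest.tsv --out scan/
poolgwas select --scan scan/scan.tsv --out blocks.tsv
poolgwas verify --counts counts.tsv --out report.tsv
poolgwas model --genotypes sim/genotypes.tsv --out trace.tsv
poolgwas power --n-cases 432 --n-controls 672 --out power.tsv
```

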