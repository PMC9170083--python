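# hlase

Allelic expression and cis-eQTL analysis of HLA class I, with a
haplotype-aware synthetic cohort generator.

## The problem

The HLA class I genes (HLA-A, -B, -C) are the most polymorphic loci in the
human genome; every individual carries two alleles per locus, and how much
each allele is *expressed* matters for transplantation outcomes, infection
control and tumor immune escape.  Bulk RNA-seq with allele-aware
quantification yields one tpm value per allele per sample, and two linked
questions follow:

1. **Is biallelic expression coordinated within individuals?**  The
   allele-specific expression ratio for one individual at one locus is

       ASE = tpm_low / (tpm_low + tpm_high)  ∈ (0, 0.5]

   where 0.5 means perfectly balanced expression of the two alleles.  A
   high cohort-median ASE could still arise from allele-intrinsic effects
   alone, so the package tests it against an **allele-constrained
   permutation null**: tpm values are shuffled among the carriers of each
   allele name (every individual keeps its own HLA typing), the per-locus
   median ASE is recomputed per replicate, and the one-sided empirical
   p-value is (b + 1)/(R + 1) with b the number of replicate medians ≥ the
   observed one.  A shared per-individual expression factor survives in
   the observed data but is destroyed by the shuffle, which is exactly
   what the test detects.

2. **Do non-coding variants regulate HLA expression?**  A compact cis-eQTL
   stage covers variant QC (MAF < 1%, missingness > 2.5%, HWE p < 1e-5),
   rank-based inverse-normal phenotype transformation, covariate
   residualization with expression/genotype PCs, a ±1 Mb per-variant
   linear scan, gene-level significance from phenotype permutations with
   a fitted Beta tail approximation, Benjamini–Hochberg eGene selection,
   genotype×stimulation interaction for paired designs, Storey's π1
   replication statistic, and LD r² against allele-tagging coding
   variants.

Because real donor cohorts of this kind are not publicly distributable,
the package ships a generative model of the data structure
(`hlase.simcohort`): ln tpm = μ_locus + α(allele) + g(individual) +
h(haplotype) + stimulation shift + Σ β_v·dosage_v + ε, with all effects on
the natural-log scale.  Every downstream stage is exercised against
cohorts drawn from this model with known ground truth.

## Worked example

```python
import numpy as np
from hlase import demo_config, sample_cohort, simulate_expression
from hlase.ase import permutation_test_median_ase
from hlase.summary import locus_summary, fold_upregulation

cfg = demo_config(seed=42)            # 63 donors, 3 loci, study-scale tpm
cohort = sample_cohort(cfg)
expr = simulate_expression(cohort, cfg, "unstim")

print(locus_summary(expr, "unstim"))
res = permutation_test_median_ase(expr, R=1000, rng=np.random.default_rng(42))
for locus, r in res.items():
    print(locus, round(r.observed_median_ase, 3), r.empirical_p)
```

prints

```
locus  mean_tpm  sd_tpm   n
    A     843.4   430.7 126
    B    1811.8   809.2 126
    C    1218.5   575.6 126
A 0.467 0.000999000999000999
B 0.473 0.000999000999000999
C 0.475 0.000999000999000999
```

The locus means land on the study-scale values (HLA-B highest, then
HLA-C, then HLA-A).  The observed median ASE sits near 0.47 at every
locus while the permutation null centers near 0.40, so no replicate
median reaches the observed one and each empirical p-value is at its
minimum 1/1001 — the signature of coordinated biallelic expression.
Adding the stimulated condition,

```python
stim = simulate_expression(cohort, cfg, "stim")
_, per_locus, _ = fold_upregulation(expr, stim)
```

reports mean fold upregulations of 2.49, 2.03 and 2.11 for A, B and C —
the ~2-fold multiplicative cytokine response the generator plants.

The same stages are available from the shell:

```bash
hlase run --config run.yaml --out results/       # full pipeline + manifest
hlase ase --expr expr.tsv --condition unstim --replicates 1000 --seed 7 --out report.json
hlase eqtl --vcf g.vcf --pheno pheno.tsv --tss tss.tsv --permutations 1000 --out eqtl.tsv
```

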