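# gpbench

Benchmarking machinery for genomic prediction on simulated plant-breeding
data: a genotype/phenotype simulator covering an 810-scenario architecture
grid, six prediction methods, a repeated cross-validation harness, and the
population-structure, SNP–QTN-LD and variance-decomposition experiments.
Everything runs on self-generated synthetic data; PLINK bed/bim/fam and
dosage-CSV adapters are provided for real panels.

## What is in the box

| module | contents |
| --- | --- |
| `gpbench.genosim` | binomial dosage simulation (fixed or per-locus MAF), MAF/LD statistics, sliding-window greedy LD pruning, PLINK `.bed`/`.bim`/`.fam` and dosage-CSV I/O |
| `gpbench.phenosim` | additive and additive×additive epistatic traits under three effect-size schemes (equal, one large effect, Gaussian), heritability-controlled residuals, the default 810-scenario grid |
| `gpbench.gpmodels` | VanRaden GRM, Gaussian kernels, Hadamard (epistatic) kinship; GBLUP via spectral REML; BayesA/BayesB Gibbs samplers (numba-accelerated); multi-kernel RKHS regression; Random Forest and gradient-boosted trees with inner-CV grid tuning |
| `gpbench.evalharness` | repeated k-fold CV planning, Pearson accuracy, Wilcoxon rank-sum (exact + asymptotic), SEM, benchmark orchestration |
| `gpbench.structld` | dosage PCA, population-structure correction experiment (Δμ), SNP–QTN LD experiment with low/high-LD pools and nearest-linked-SNP substitution (Δr) |
| `gpbench.vardecomp` | two-kinship (G, G∘G) variance decomposition by AI-REML or MCMC; additive-variance ratio |

## CLI

```bash
gpbench simulate-genotypes --n 500 --p 1000 --maf 0.4 --seed 1 --out geno.csv
gpbench grid --preset table1 --out grid.json
gpbench simulate-phenotypes --genotypes geno.csv --q 5 --h2 0.7 --seed 2 --out phen.tsv
gpbench fit --method gblup --genotypes geno.csv --phenotypes phen.tsv
gpbench run --grid grid.json --methods gblup,bayesB --max-scenarios 2 --seed 3 --out results/
gpbench ps-experiment --methods gblup,rf --seed 4 --out ps.json
gpbench ld-experiment --regime low --methods gblup,bayesB --seed 5 --out ld.json
gpbench decompose --genotypes geno.csv --phenotypes phen.tsv --engine reml --out vc.json
```

## Conventions

- Dosages are coded 0/1/2 (copies of the minor/A1 allele); missing
  genotypes are rejected, never imputed.
- All randomness flows through explicit seeds; simulated objects record
  the seed they were generated with.
- Accuracy is the Pearson correlation between observed phenotypes and
  predicted genomic values on held-out folds; 5 repeats × 5 folds by
  default.
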