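# peachgs

Multi-model genome-wide association (GWAS) and rrBLUP genomic prediction for
diversity panels of clonally propagated crops, built around the workflow used
to dissect fruit aroma and agronomic traits in peach germplasm: several
hundred accessions, 10⁴–10⁵ resequencing SNPs, a mix of quantitative volatile
traits and single-locus qualitative traits, and breeding decisions that need
genomic estimated breeding values (GEBVs) long before a seedling fruits.

The package is aimed at quantitative geneticists and breeders who want the
whole loop — simulate or load a panel, scan, select markers, cross-validate
prediction, interpret loci — as tested, scriptable Python.

## What it computes

**Association scans.** Four models over a dosage matrix, all using principal
components as fixed covariates and, where applicable, a genomic kinship
`K` (VanRaden `K = WWᵀ / 2Σpⱼ(1−pⱼ)`, optionally rescaled to unit mean
diagonal) as a random effect:

* **MLM** — single-locus mixed model `y = Xβ + zₘαₘ + u + e`,
  `u ~ N(0, σ²g K)`, with variance components fixed at the null REML estimates
  (P3D/EMMAX) and each marker tested by GLS in the eigenspace of `K`.
  Variance components come from EMMA: the restricted likelihood is profiled
  to one dimension in `log δ = log(σ²e/σ²g)` and maximized by grid search
  plus local refinement.
* **MLMM** — forward-stepwise MLM that moves the most significant marker into
  the fixed effects (a *pseudo-QTN*) and rescans.
* **FarmCPU** — alternates per-marker fixed-effect tests conditioned on
  pseudo-QTNs with a random-effect step that re-selects pseudo-QTNs by genome
  binning and REML model comparison.
* **BLINK** — FarmCPU-style iteration without kinship; pseudo-QTNs chosen by
  LD-pruned greedy selection and BIC.

Significance uses the Bonferroni cutoff `α / m` (for the 145,456-SNP peach
panel at α = 0.01 this is 6.87×10⁻⁸) or a fixed −log₁₀(p) > 7 calling rule.

**Genomic prediction.** rrBLUP: `y = 1μ + Zg + e` with `g ~ N(0, σ²g I)` over
the panel of GWAS-selected markers; shrinkage `λ = σ²e/σ²g` from EMMA REML.
Cross-validation follows the breeding protocol: 5 subpopulations, GWAS runs
on four folds only, GEBVs are predicted for the fifth, accuracy is the
Pearson `r` between observed phenotypes and pooled held-out GEBVs, averaged
over 30 replicates. *Multi-trait* mode augments the marker panel with
markers selected (in-fold) for genetically correlated traits — the mechanism
that lifts accuracy several-fold for trait families sharing QTNs, such as
biosynthetically related lactones.

**Post-GWAS.** Candidate genes within ±100 kb of significant SNPs,
multi-trait hotspot windows (≤300 kb gaps), genotype-combination phenotype
percentages, diagnostic-marker concordance, trait and expression–content
Pearson correlations.

**Synthetic panels.** A seeded generator emulating the statistical structure
of such a panel: haplotype-copying LD, Balding–Nichols subpopulation
structure, QTN-driven quantitative traits at target heritability, shared-QTN
trait families and single-major-locus qualitative traits. Every downstream
stage is testable without the original data.

## Worked example

```sh
peachgs simulate --preset tiny --out panel
peachgs gwas --vcf panel/genotypes.vcf --pheno panel/phenotypes.tsv \
    --schema panel/phenotypes.schema.json --trait aroma_a \
    --models mlm,blink --pcs 2 --out-prefix aroma_a
peachgs gp --vcf panel/genotypes.vcf --pheno panel/phenotypes.tsv \
    --schema panel/phenotypes.schema.json --trait aroma_a \
    --mode multi --related aroma_b --models mlm --reps 5 --seed 17 --out gp.json
```

prints

```
wrote 50 samples x 300 markers, 3 traits to panel
mlm: threshold p=3.333e-05, wrote aroma_a.mlm.tsv
blink: threshold p=3.333e-05, wrote aroma_a.blink.tsv
aroma_a [multi] accuracy=0.4013 h2=0.403 -> gp.json
```

The threshold is the Bonferroni cutoff 0.01/300; each scan TSV holds per-SNP
effect, SE, p and −log₁₀(p); the `gp` line reports the cross-validated
prediction accuracy (mean Pearson r over 5 replicates of 5-fold CV, here with
the correlated trait `aroma_b` contributing markers) and the REML estimate of
narrow-sense heritability. On this 50-accession toy panel the same command in
`--mode single` gives accuracy 0.4280 — the multi-trait gain needs the
low-power polygenic regime of the full-size panel (see
`docs/methods.md`), which the `paper_like` preset reproduces.

The same operations are available as a library:

```python
import peachgs as pg
g, pheno, arch, gff = pg.make_fixture_dataset("paper_like", "panel/")
res = pg.cv_gwas_gp(g, pheno, "lactone_c10", pg.CVScheme(seed=1),
                    mode="multi",
                    related_traits=["lactone_c6", "lactone_c8"],
                    gwas_config={"models": ("mlm",)})
print(res.final_accuracy, res.h2)
```

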