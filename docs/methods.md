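# Methods

## Mixed-model machinery

All variance-component estimation is EMMA-style REML for the single-kinship
model `y = Xβ + u + e`, `u ~ N(0, σ²g K)`, `e ~ N(0, σ²e I)`. The restricted
likelihood is expressed in the eigenbasis of `S K S` (with `S` the projection
off the column space of `X`), which profiles it to one dimension in
`log δ = log(σ²e/σ²g)`. The optimizer is a 100-point grid over
`log δ ∈ [−10, 10]` followed by bounded Brent refinement in the bracketing
interval; if refinement ever regresses below the grid optimum the grid value
is kept. δ is therefore bounded to roughly [4.5×10⁻⁵, 2.2×10⁴], i.e.
ĥ² ∈ [~5×10⁻⁵, ~0.99995]; a trait estimated at the boundary should be read as
"at the edge of the identifiable range", not as exactly 0 or 1. Heritability
is reported as `σ²g/(σ²g+σ²e) = 1/(1+δ)`, which assumes `K` is scaled to mean
diagonal ≈ 1 (the default kinship is rescaled that way).

The MLM scan uses the P3D/EMMAX approximation: variance components are
estimated once under the marker-free null and held fixed for every marker
test. Each marker is tested by GLS in the eigenspace of `K`; because the
rotated, variance-weighted problem is ordinary least squares, the scan is
fully vectorized (rank-one update formulas give effect, SE and residual sum
of squares per marker without per-marker solves). The per-marker test is a
two-sided t (Wald) test with `n − rank(X) − 1` degrees of freedom. Markers
collinear with the covariates (including constant markers) get `nan`
statistics and are flagged; they are never counted as significant. A
`MLMWorkspace` caches the kinship eigendecomposition and the rotated
genotype matrix so that scanning many traits on the same samples (the
cross-validation inner loop) costs one rotation, not one per trait.

## Kinship and structure covariates

VanRaden: `K = WWᵀ / (2 Σ pⱼ(1−pⱼ))` with `W` the dosage matrix centered by
twice the allele frequency. The default method rescales this matrix to unit
mean diagonal; that rescaling is an *approximation* of the GAPIT-style
relationship matrix, whose exact algorithm is not published in closed form —
the method flag records which variant produced a matrix. Structure
covariates are the top principal components of the column-standardized
dosage matrix (default 3, the conventional choice when the PC count is not
otherwise specified), computed from the n×n sample covariance because
markers far outnumber samples.

## Multi-locus scans

**MLMM** is forward stepwise selection: scan, promote the most significant
marker to a fixed-effect pseudo-QTN while its p-value beats the Bonferroni
threshold, rescan, up to 10 steps. Variance components are re-estimated at
every step. Final p-values come from the last conditional scan; each included
pseudo-QTN is re-tested leave-one-out against the final covariate set so it
has a finite p-value rather than a collinearity flag.

**FarmCPU** alternates (a) per-marker OLS t-tests conditioned on the current
pseudo-QTNs, where pseudo-QTNs themselves are tested by leave-self-out
substitution, and (b) a random-effect selection step: bin the genome at each
bin size in {0.5, 5, 50} Mb, take the best marker per bin, and choose the
(bin size, top-bin count ∈ {5, 10, …, 50}) combination that maximizes the
REML likelihood of the phenotype under a kinship built from just those
candidate markers; candidates mutually correlated at |r| > 0.7 are pruned
keeping the smaller-p member. Iteration stops when the pseudo-QTN set
repeats (oscillations are accepted at the first repeated state) or after 10
loops, which is flagged as non-converged.

**BLINK** replaces the binning step: markers are sorted by fixed-effect p,
greedily retained if their LD r² with every already-kept marker is below 0.7,
and the retained-set size is chosen by minimizing the BIC of the fixed model
`y ~ X + kept markers`. No kinship is used anywhere. Two bounded choices keep
the step linear: only markers with p < 0.01 enter the greedy pass (weaker
markers are always rejected by BIC) and at most 40 are retained before BIC
selection.

Both iterative scans apply an entry gate: if no marker passes the Bonferroni
threshold on the first scan, no pseudo-QTNs are selected at all and the
reported p-values are the plain conditioned-on-nothing scan. Both original
methods include this control; without it, conditioning on the best markers
of a pure-noise trait produces occasional genome-wide false positives
(measured ~16% of null replicates instead of ~2%).

Ties in minimum p are broken by (chromosome, position) order. Significance
calling uses strict inequality, −log₁₀(p) > cutoff, so p = 10⁻⁷ is *not*
called at cutoff 7. Qualitative traits are scanned as their numeric codings
({0,1} and {−1,0,1}).

## Genomic prediction

rrBLUP fits `y = 1μ + Zg + e`, `g ~ N(0, σ²g I)` over the selected marker
panel. The shrinkage parameter comes from EMMA REML on the training samples
with the panel relationship matrix `K = ZZᵀ/m`, so the per-marker ridge
parameter is `λ = m·δ`. μ is the training-sample phenotype mean; effects
solve `(ZᵀZ + λI)ĝ = Zᵀ(y − μ)`. This marker-effect form is algebraically
identical to GBLUP (`Zᵀ(ZZᵀ + λI)⁻¹ = (ZᵀZ + λI)⁻¹Zᵀ`), which the test suite
verifies numerically. Selected markers enter as the random-effect design
matrix, not as fixed covariates.

Cross-validation: per replicate, a fresh seeded permutation splits the panel
into 5 folds. Per fold, the configured GWAS models run on the 4 training
folds only; the prediction panel is the union of Bonferroni-significant
markers for the focal trait (single mode) or for the focal trait plus the
caller-specified related traits (multi mode); rrBLUP is fitted on the
training folds and GEBVs predicted for the held-out fold. Replicate accuracy
is the Pearson r between observed values and the pooled held-out GEBVs of
all 5 folds; the final accuracy averages 30 replicates (default). Held-out
samples never reach marker selection or fitting — an assertion enforces the
empty intersection on every fold. When a training fold yields no significant
marker, the panel falls back to the top-k markers by p-value (k = 10,
logged); something must enter the ridge model, and the top of the scan is
the least-bad choice. Trait normalization happens once on the full table
before CV; the z-scoring constants therefore see all samples. This mirrors
the original protocol but is a (mild, monotone-transform-only) leakage the
user should be aware of.

"Related traits" are caller-specified; `select_related_traits` offers an
|r| ≥ threshold helper over the trait correlation matrix. Multi-trait mode
is marker-panel augmentation, *not* a multivariate mixed model — no
genetic-covariance parameters are estimated.

## Synthetic panels

The generator emulates a resequenced diversity panel of a perennial fruit
crop (defaults: 242 accessions, 8 chromosomes × 2500 SNPs, two
subpopulations at Fst 0.1, MAF floor 0.05):

* **LD** by first-order haplotype copying: along a chromosome, each allele is
  copied from the previous marker with probability `ld_rho` (default 0.8),
  else redrawn from the subpopulation frequency. Adjacent-marker correlation
  is ≈ `ld_rho` per step and decays geometrically with marker lag — a
  deterministic, closed-form stand-in for recombination-map realism.
* **Structure** by Balding–Nichols: subpopulation frequencies are
  Beta-distributed around an ancestral frequency with variance
  `Fst·p(1−p)`, so Hudson's estimator recovers `fst_target`.
* **MAF floor**: markers drifting below the floor are repaired by flipping a
  minimal number of alleles; the perturbation affects only near-monomorphic
  markers and slightly weakens their LD with neighbors.
* **Quantitative traits**: `y = Σ effectⱼ·dosageⱼ + e`, effects standard
  normal, noise scaled so the realized genetic-variance fraction equals the
  h² target. Trait families share a common core of QTNs (fraction `overlap`
  of each member's QTN list, identical core effects scaled per trait), giving
  pairwise Jaccard `overlap/(2−overlap)` between QTN sets.
* **Qualitative traits**: single fully penetrant major locus — carrier
  threshold (dosage ≥ 1) for binomial traits, the three dosage classes for
  trinomial traits — with an optional penetrance < 1 that flips a sample to
  another class, emulating diagnostic-marker discordance.
* Genotype and per-trait noise streams are separately seeded; identical
  configuration and seed give byte-identical serialized files.

The `paper_like` preset sets the 6-trait correlated family to 8
equal-magnitude QTNs per trait at h² = 0.6 and 60% QTN sharing. That choice
is deliberate and matters for the single- vs multi-trait contrast. Real
lactone-family traits show low single-trait prediction accuracy despite
moderate heritability, i.e. single-trait GWAS power is marginal; the
multi-trait gain arises because a QTN shared by six traits gets six chances
to be detected. At n ≈ 194 training samples and a Bonferroni bar of
p < 5×10⁻⁷ (|t| ≈ 5), per-QTN variance h²/8 ≈ 7.5% gives |t| ≈ 4: each scan
detects a given QTN rarely, but at least one of the six relatives usually
does. Standard-normal effects break this regime unpredictably — one heavy
tail draw makes the trait effectively oligogenic, single-trait power high,
and panel union a pure dilution; equal magnitudes pin every QTN to the
boundary. The multi-trait advantage is therefore a property of the power
regime, not of the estimator: passing tests show the method behaves
correctly *given* this architecture, not that any particular real trait has
it.

Not emulated: recombination-map heterogeneity, sequencing/genotyping error,
imputation uncertainty, dominance/epistasis, shared environmental covariance
between traits (trait correlations here are purely genetic).

## Problem sizes in tests and acceptance

The acceptance checks run at: 200 pooled null simulations (n = 300,
m = 1000) for type-I error and genomic-control λ; 20 seeds of (n = 400,
m = 2000, 50 QTNs) for h² recovery; a 100×50 panel for the rrBLUP/GBLUP
identity; and the full 242 × 20,000 scale with 5 CV replicates for the
single- vs multi-trait contrast. Unit tests use smaller panels (50–500
samples, 300–2000 markers) with seeded generators throughout; Monte-Carlo
assertions state the tolerance implied by their replicate counts.

## Known limitations

* P3D only — no exact per-marker REML, no compression/SUPER variants.
* The rescaled-VanRaden "zhang" kinship approximates, not reproduces, the
  GAPIT matrix; numerical results can differ from GAPIT runs.
* FarmCPU/BLINK internals are re-derived from their published descriptions;
  bin ladder, candidate counts, pruning and BIC bounds are fixed defaults
  exposed in the API, and exact agreement with the R implementations is not
  expected marker-by-marker.
* rrBLUP centers by the sample mean rather than a GLS intercept; for
  strongly structured panels the two differ slightly.
* Missing genotypes are mean-imputed per marker; no genotype-likelihood
  handling, no indels, no BCF/PLINK binary formats.
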