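# Methods

## The model

`tensoromics` integrates three omics layers measured on the same cohort —
gene expression (GE), promoter methylation (ME) and miRNA expression
(MI) — by encoding each layer as a gene × sample matrix, stacking the
matrices into a non-negative third-order tensor

    T ∈ [0,1]^(N genes × M samples × K omics),

and fitting a rank-R non-negative CP (PARAFAC) model

    x_ijk ≈ Σ_{f=1..R} g_if · p_jf · o_kf,

i.e. T ≈ Σ_f g_f ⊗ p_f ⊗ o_f with factor matrices C_g (N×R, genes),
C_p (M×R, samples/patients) and C_o (K×R, omics), all entrywise
non-negative. Each of the R columns — a *rank feature* — is a latent
multi-omics program: its gene loadings say which genes participate, its
omics loadings say through which molecular layer it acts, and its
patient loadings say how active it is in each sample.

Non-negativity is what makes the features readable: components
accumulate rather than cancel, so a large loading always means "more of
this program". The objective is the sum of squared residuals under the
non-negativity constraint.

Phenotype-specific features are then found on the patient component
alone. For each class label a one-vs-rest lasso

    min_w Σ_i (y_i − Σ_f z_if w_f)² + α Σ_f |w_f|

is fitted, with y_i = 1 for samples carrying the label and 0 otherwise
and z the rows of C_p. The objective is used exactly as written: no
1/M normalization and no intercept by default (an intercept flag
exists), so the coordinate-descent soft threshold sits at α/2 and a
feature is extinguished once α ≥ 2|z_f·y| in the single-feature case.
Surviving (nonzero-weight) features are ranked by |w| and the top 20 %
kept (ceiling, minimum one, ties to the lower index). Genes attach to
features by the argmax of their C_g row; each feature attaches to the
omics layer with the largest C_o loading. A label's gene set is every
gene whose feature lies in that label's selected set; sets may overlap
across labels.

The information content of a selection is scored by stratified 10-fold
cross-validation of a small MLP (one hidden layer, 100 ReLU units,
≤500 epochs, seeded) with macro-averaged F1, optionally restricted to a
subset of omics layers (the ablation protocol).

## Preprocessing

Each layer is made gene-centric before stacking:

* **Expression** — log2(x+1), then quantile normalization across sample
  columns (every column receives the across-column means of the order
  statistics; ties get the mean of the tied reference values).
* **Methylation** — array probes are assigned to a gene when they fall
  in its strand-aware promoter window: the 2 kb upstream of the TSS
  plus the TSS itself ([TSS−2000, TSS] on '+', [TSS, TSS+2000] on '−';
  coordinates 1-based inclusive on disk, half-open internally). Probes
  missing in every sample are dropped first; the gene value is the mean
  of non-missing betas in the window; genes with no window probe are
  dropped. Gene-level betas are quantile normalized without a log.
* **miRNA** — miRNAs with zero expression everywhere are removed, the
  remaining ones are bundled per target gene, and the bundle value is
  the geometric mean exp(mean(ln(x+1)))−1 (arithmetic mean available as
  an option). Untargeted genes get 0 — sparsity in the MI slice is
  tolerated rather than dropping the genes. Bundle values are then
  log2-quantile normalized.

The common gene axis keeps genes that are protein-coding, present in
every layer, and have promoter methylation missing in at most 80 % of
samples. Residual missing values are imputed by the gene's mean within
its slice; each slice is then min-max scaled **globally** into [0,1].
Per-gene scaling would erase exactly the cross-gene magnitude structure
the factorization is meant to explain; the global scaling only equalizes
the layers against one another.

## Fitting: HALS with norm-matched starts

The CP model is fitted by hierarchical alternating least squares: each
factor column is updated in closed form with the others fixed, clipping
at zero, which keeps the objective monotonically non-increasing (the
suite asserts this to 1e-9 per sweep). Several random starts
(default 5, uniform(0.1,1) entries, seeds derived from the user seed
and the start index) are run and the best by relative error kept;
identical seeds give bit-identical factors.

One numerical choice matters in practice: each start is rescaled so its
initial reconstruction has the tensor's Frobenius norm. Omics tensors
are sparse — most entries sit near zero — and an unscaled dense start
overshoots so badly that the first sweep clips most columns to zero,
after which HALS cannot revive them; on the default synthetic cohort
this stalls at 0.73 relative error where the noise floor is 0.14. With
norm-matched starts the same fits recover all planted components
(matched cosines ≥ 0.97).

Scale indeterminacy is fixed by normalizing C_g and C_o columns to unit
L2 norm and pushing magnitude into C_p, since the patient loadings are
what the lasso consumes. Convergence: relative objective change < 1e-7
(default) or 500 sweeps. These defaults suit pipeline use; for
exact-recovery demonstrations (noise-free tensors driven to ≤1e-4
relative error) the exposed knobs are tightened to `max_iter=2000,
tol=1e-9`, which the rank-8 300×80×3 case reaches in ~15 s on one CPU.
The relative error of an all-zero tensor is defined as 0.

Held-out samples are mapped into feature space by non-negative least
squares: under the model a sample's N×K slice satisfies
vec(X) ≈ D p with D[(i,k),f] = g_if·o_kf, solved per sample with the
fixed C_g, C_o.

## Rank estimation

Candidate ranks are scored by NMF consensus clustering on a gene ×
sample slice: 20 seeded NMF runs (multiplicative updates, Frobenius
loss) per rank, each sample assigned to its maximum-coefficient basis,
the M×M consensus matrix C holding the fraction of runs co-clustering
each pair, and the dispersion

    ρ = (1/M²) Σ_ij 4 (C_ij − ½)²  ∈ [0,1]

(1 = perfectly stable, 0 = maximally ambiguous). The elbow is the
interior candidate with the largest downward curvature
2ρ_i − ρ_{i−1} − ρ_{i+1} — the last rank at which dispersion is still
high before its sharpest drop — with ties to the smaller rank and a
flat curve falling back to the smallest candidate with a warning. The
default rank for real cohorts is 120 with a scan grid of {20,…,200}
exposed.

## Evaluation modes

* **transductive** — decompose and select once on the full cohort, then
  cross-validate only the classifier. Fast; mirrors a
  decompose-once-describe-later analysis, but the selection has seen
  every sample.
* **strict** (default) — inside each fold, quantile references, min-max
  bounds, the decomposition and the lasso selection are refitted on
  training samples only; test samples are normalized with the training
  statistics and projected by NNLS. An instrumentation test asserts the
  fitting stages never receive test-fold samples.

The classifier input is either the scaled omics values of the selected
feature genes concatenated over the chosen omics subset (`gene_values`,
default — this is what the ablation varies) or the sample's C_p values
at the selected features (`patient_features`). Classes smaller than the
fold count reduce the fold count with a warning. Macro F1 is used
because subtype cohorts are imbalanced and every class should weigh
equally.

## The synthetic generator

`tensoromics.synthetic.generate` plants a known CP structure:
N=300 genes, M=80 samples, K=3 omics, R*=8 components, 4 balanced
labels by default. Component f is owned by label f mod 4; samples of
the owner load signal=1.0 plus half-normal jitter (sd 0.25), others a
uniform baseline in [0, 0.05]. Gene factors put uniform(0.5, 1.5)
weight on a random 5 % of genes per component. Omics routing is
uniform(0.5, 1.0) by default; "ge_me" alternates components between a
dominant GE or ME loading (1.0 vs 0.05 elsewhere) to emulate a
phenotype driven by two layers, "round_robin" cycles all layers.
Truncated-at-zero Gaussian noise (sd 0.05) is added before per-slice
min-max scaling, keeping non-negativity.

`make_fixture_files` writes the cohort as the on-disk formats the
readers expect: expression and miRNA matrices are the scaled slices
inverted through 2^(10·v)−1 (a ~3-decade dynamic range; the log2 step
of the pipeline inverts this exactly), methylation as two probes per
promoter carrying the gene beta with sd-0.01 jitter, plus annotation,
manifest, one-miRNA-per-gene target map and labels.

What the generator does *not* emulate: library-size effects, beta-value
bimodality, probe density variation, unmatched samples, batch effects,
and — importantly — sample columns with identical value distributions.
That last gap has a visible consequence: quantile normalization, by
design, forces all sample columns onto one distribution, so the tensor
rebuilt from fixture files differs from the generated tensor by a
systematic monotone remap of the column tails (relative Frobenius gap
0.47 at defaults, measured once and frozen in the suite) while
preserving structure (per-slice Pearson r ≥ 0.97, planted-factor
recovery cosines ≥ 0.97, selection precision/recall 1.0 through the
file path). Passing tests therefore demonstrate correctness of the
mechanics and recoverability of planted structure, not performance on
real TCGA-scale data.

## Problem sizes and defaults

| Parameter | Default | Why |
|---|---|---|
| rank R (real cohorts) | 120 | consensus-dispersion elbow scale for ~300–600-sample cohorts |
| rank R (synthetic demos) | 8 | matches the planted R* |
| α (lasso) | 0.01 | downstream classification accuracy peaks there; grid {0, 0.001, 0.005, 0.01, 0.05, 0.1} exposed |
| top fraction | 0.2 | keep the strongest fifth of surviving features |
| promoter window | 2000 bp | standard promoter-proximal definition |
| n_starts | 5 | multi-start guard against local minima |
| max_iter / tol | 500 / 1e-7 | pipeline fits; 2000 / 1e-9 for exact-recovery demos |
| folds | 10 | standard; reduced automatically for small classes |
| MLP | 1×100 ReLU, ≤500 epochs | deterministic, desk-scale |
| dispersion runs | 20 per rank | consensus stability |

Demonstrations and the acceptance script run at 300×80×3 with R*=8;
these sizes make every planted component identifiable while keeping a
full strict-mode 10-fold evaluation around 20 s.

## Known limitations

* HALS converges linearly near the optimum; very tight error targets
  need the tightened convergence knobs above.
* The L1 step treats C_p columns on their natural (unnormalized) scale,
  exactly as the objective is written; columns with larger norms are
  penalized relatively less.
* Rank estimation clusters samples from a single slice at a time; it
  does not use the tensor structure itself.
* `choose_rank` needs at least three candidates to find an elbow.
* Strict-mode evaluation refits the decomposition per fold, so its cost
  is folds × the transductive cost.
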