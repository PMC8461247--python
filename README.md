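# tensoromics

Gene-centric integration of matched multi-omics cohorts by non-negative
tensor decomposition, with phenotype-specific feature selection.

## The problem

A cohort of patients measured on several omics layers — gene
expression, promoter methylation, miRNA expression — carries more
information about a phenotype (say, a cancer subtype) than any single
layer, but the layers live on different scales and different feature
spaces. `tensoromics` encodes every layer *per gene*, so that all
layers share one gene × sample grid, stacks them into a non-negative
third-order tensor

T ∈ [0,1]^(N×M×K)  (genes × samples × omics),

and fits a rank-R non-negative CP/PARAFAC model

x<sub>ijk</sub> ≈ Σ<sub>f=1..R</sub> g<sub>if</sub> · p<sub>jf</sub> · o<sub>kf</sub>,

giving three factor matrices: C_g (gene loadings), C_p (patient
loadings), C_o (omics loadings). Each of the R latent *features* is a
multi-omics program shared across all three views.

Label-specific features are then selected from the patient component by
a one-vs-rest lasso per class,

min<sub>w</sub> Σ<sub>i</sub> (y<sub>i</sub> − Σ<sub>f</sub> z<sub>if</sub> w<sub>f</sub>)² + α Σ<sub>f</sub> |w<sub>f</sub>|,

keeping the top 20 % of surviving features by |w|. Genes map onto
features by the argmax of their C_g row, features onto omics layers by
the argmax of their C_o column, and the resulting gene sets are scored
by stratified 10-fold cross-validated macro F1 of an MLP classifier —
including ablations over omics subsets to ask *which layers carry the
signal*.

It is aimed at anyone with matched per-sample omics tables (TCGA-style
exports or similar) and a categorical sample attribute worth
explaining. Full model details, defaults and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

Everything runs from synthetic data with planted ground truth, so the
example is fully reproducible. Generate a cohort of 80 samples × 300
genes × 3 omics with 8 planted components owned by 4 labels, routing
the signal through expression and methylation, then run the whole
pipeline:

```
$ tensoromics simulate --out cohort --seed 5 --routing ge_me
wrote 8 files to cohort

$ tensoromics run --data cohort --out results --rank 8 --alpha 0.01 \
      --seed 5 --mode strict
mean macro F1 = 1.0000
```

`results/` now holds the tensor slices, the factor matrices
(`C_g.tsv`, `C_p.tsv`, `C_o.tsv`), per-label lasso weights, the gene
assignment table and the evaluation report. The decomposition metadata
(`results/decomposition/decomposition.json`):

```
{"rank": 8, "relative_error": 0.6444, "seed": 5, "n_iter": 434, "converged": true}
```

The relative error looks high because it is honest: this cohort routes
its signal through GE and ME only, so the miRNA slice (and the
quantile-normalized background of the others) is largely unstructured
noise that no low-rank model should fit. The structure that matters is
recovered, which the selection summary
(`results/selection/selection.json`) shows — every label keeps
2 = ceil(0.2·8) features and collects its block of marker genes:

```
L1: 8 nonzero -> 2 selected -> 50 genes
L2: 8 nonzero -> 2 selected -> 89 genes
L3: 8 nonzero -> 2 selected -> 84 genes
L4: 8 nonzero -> 2 selected -> 83 genes
```

and the strict 10-fold evaluation (`results/evaluation/eval.json`) —
normalization, decomposition and selection refitted per fold on
training samples only, held-out samples projected by non-negative least
squares — classifies all four labels perfectly:

```
mean_f1 = 1.0   (per-class precision/recall all 1.0)
```

Asking which layers carry the signal:

```
$ tensoromics classify --data cohort --rank 8 --alpha 0.01 --seed 5 \
      --mode strict --omics GE --out ge_only
mean macro F1 = 0.9733
```

Expression alone misclassifies the samples whose labels ride on the
methylation-routed components; the all-omics run recovers them.
`omics_ablation` tabulates this comparison over all seven non-empty
subsets of {GE, ME, MI}.

Other subcommands: `build-tensor`, `estimate-rank` (NMF
consensus-dispersion scan with elbow choice), `decompose`, `select`,
`alpha-sweep`. All take `--seed`; identical configuration and seed
give checksum-identical artifacts.

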