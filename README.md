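# bgcmf

Bipartite-graph collaborative matrix factorization for predicting
miRNA–disease associations.

## The problem

Dysregulated microRNAs (miRNAs) are implicated in many human diseases, but
experimentally confirming each miRNA–disease association (MDA) is slow and
expensive. Given a curated binary association matrix **Y** ∈ {0,1}ⁿˣᵐ
(rows: *n* miRNAs, columns: *m* diseases), a miRNA functional similarity
matrix **Sₘ** and a disease semantic similarity matrix **S_d**, the task is
to score every unobserved pair so that true-but-unrecorded associations
rank highly. This package is for computational biologists who want a
tested, scriptable implementation of that prediction pipeline, including a
leakage-free cross-validation harness and a synthetic-data generator for
method development.

## The method

1. **Similarity fusion.** Gaussian interaction-profile (GIP) kernels are
   computed from the rows and columns of Y,
   GIP(i,j) = exp(−γ‖Y(i)−Y(j)‖²) with γ = γ′ normalized by the mean
   squared profile norm, and fused with the input similarities:
   **Kₘ** = α **Sₘ** + (1−α) **GIP**ₘ, and likewise **K_d** (default α = 0.5).
   Disease semantic similarity can alternatively be computed from a
   disease-ontology DAG, where each ancestor term's contribution decays by
   Δ per level and two diseases score by the contributions of shared terms.
2. **WKNKN imputation.** Unknown entries of Y are pre-filled from the K
   most similar neighbours that have at least one known association,
   weighted by similarity and a rank decay p (defaults K = 7, p = 0.6);
   known 1-entries are never decreased.
3. **Bipartite-graph score Y₁.** Each entity's profile is predicted from
   its single nearest neighbour (similarity-weighted), and the miRNA-side
   and disease-side predictions are averaged.
4. **Matrix-factorization score Y₂ = A Bᵀ**, minimizing

   ‖Y − A Bᵀ‖²_F + λ_l(‖A‖²_F + ‖B‖²_F) + λ_d‖Kₘ − A Aᵀ‖²_F + λ_t‖K_d − B Bᵀ‖²_F

   by alternating least squares from a truncated-SVD initialization.
5. **Fusion.** Y_predict = w·Y₁ + (1−w)·Y₂ (default w = 0.5).

Evaluation is repeated five-fold cross-validation over the known
associations, with GIP kernels and WKNKN recomputed inside every training
fold so no held-out information leaks, scored by the midrank (Mann–Whitney)
AUC. A grid search over (λ_l, λ_d, λ_t) is included.

## Worked example

All matrices are plain labeled TSV (rows miRNAs, columns diseases). The
`simulate` command writes a synthetic dataset with a planted low-rank
association pattern and similarity matrices consistent with it:

```sh
$ bgcmf simulate --n 100 --m 80 --rank 5 --density 0.05 --seed 7 --out-dir demo
wrote synthetic dataset (100x80, 400 positives) to demo

$ bgcmf cv --associations demo/associations.tsv \
           --mirna-sim demo/mirna_similarity.tsv \
           --disease-sim demo/disease_similarity.tsv --repeats 1 --seed 42
mean AUC 0.9781 (std 0.0035, 5 folds)

$ bgcmf rank --associations demo/associations.tsv \
             --mirna-sim demo/mirna_similarity.tsv \
             --disease-sim demo/disease_similarity.tsv \
             --disease disease_0004 --top 8
1	mirna_0089	0.905241	known
2	mirna_0095	0.877366	known
3	mirna_0076	0.604706	known
4	mirna_0019	0.408529
5	mirna_0086	0.398593	known
6	mirna_0036	0.173546
7	mirna_0099	0.167657
8	mirna_0094	0.167141
```

The CV line is the cross-validated AUC: 0.9781 means that a held-out true
association outranks a random unknown pair ~98% of the time on this
planted dataset. The ranking lists each candidate miRNA's fused score for
one disease; rows flagged `known` are already in Y (their high ranks are a
sanity check), and unflagged high scorers such as `mirna_0019` are the
novel predictions. `bgcmf predict` writes the full score matrix, and
`bgcmf tune` grid-searches the regularization weights. Real data in the
same TSV layout (e.g. an HMDD-derived matrix plus the published miRNA
functional similarity) drops in unchanged; identifiers are treated as
opaque strings.

The same functionality is available as a library:

```python
from bgcmf import SyntheticSpec, generate_dataset, PipelineConfig, five_fold_cv
Y, Sm, Sd, truth = generate_dataset(SyntheticSpec(seed=7))
print(five_fold_cv(Y, Sm, Sd, PipelineConfig(), n_repeats=1, seed=42).mean_auc)
```

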