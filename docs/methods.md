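# Methods

This note documents the model, the defaults and the numerical choices the
package makes, and what the synthetic benchmark does and does not show.

## Model and assumptions

The method treats MDA prediction as link prediction on a bipartite graph
with side information. Its working assumptions are (a) functionally
similar miRNAs associate with semantically similar diseases, so similarity
matrices carry signal about missing links; and (b) the association matrix
is approximately low-rank, so a factorization Y ≈ A Bᵀ generalizes beyond
observed entries. Two predictors embody these assumptions — the
bipartite-graph nearest-profile/weighted-profile score Y₁ (pure
neighbour transfer) and the similarity-regularized factorization Y₂ — and
their average is the final score. Neither predictor models causality; the
scores are ranking evidence only.

### Disease semantic similarity

Each disease is an ancestor-closure DAG in a term hierarchy. The disease's
own term contributes 1 and every other term t contributes
Δ·max over t's children inside the DAG, evaluated in topological
(child-before-parent) order, so a term reached by several paths takes the
maximum over paths. Similarity between two diseases is the sum of both
contributions over shared terms divided by the sum of the two total
semantic values; the diagonal is exactly 1 by construction.

### GIP kernel

GIP(i,j) = exp(−γ‖Y(i)−Y(j)‖²) over rows (miRNAs) or columns (diseases).
γ is an adjustable bandwidth; the default follows the standard GIP
convention of normalizing a raw bandwidth γ′ by the mean squared profile
norm, γ = γ′ / ((1/q)Σᵢ‖Y(i)‖²), with γ′ = 1, so the kernel scale adapts
to the dataset's density. The `normalize` flag turns this off and uses γ′
raw. Two all-zero profiles have distance zero and hence similarity 1; this
is the formula's own behaviour for cold-start entities and is kept as-is
(the profile-norm fallback only guards the γ division).

### WKNKN

For each miRNA, the K most similar miRNAs *with at least one known
association* (self excluded, ties broken by input order) are averaged with
weights pʳ⁻¹·similarity, r the neighbour rank; likewise per disease. The
output is max(Y, (row estimate + column estimate)/2), so the imputation is
conservative: known entries never decrease and all values stay in [0,1].
Defaults K = 7, p = 0.6 — the values at which cross-validated performance
plateaus on the curated benchmark this pipeline targets. When fewer than K
eligible neighbours exist all of them are used (with a warning); a zero
weight sum contributes a zero estimate.

### Bipartite score

Nearest-profile first removes self-similarity and keeps, per row of the
fused similarity, only the single largest off-diagonal entry (ties: lowest
index; an identity similarity yields an all-zero neighbour matrix and thus
a zero score). Weighted-profile then averages neighbour profiles with
those weights; with the one-nonzero-per-row matrix this transfers the
nearest neighbour's profile, but the operation is implemented as a general
weighted average so a dense weight matrix can reuse it. Both sides consume
the WKNKN-processed matrix and are averaged into Y₁. Zero-denominator
rows return zeros, which is neutral in the final averaging.

### Collaborative matrix factorization

Objective:

    J(A,B) = ‖Y − ABᵀ‖²_F + λ_l(‖A‖²_F + ‖B‖²_F)
             + λ_d‖Kₘ − AAᵀ‖²_F + λ_t‖K_d − BBᵀ‖²_F.

Initialization is the truncated SVD, A = U_k S_k^½, B = V_k S_k^½, with
each left singular vector's largest-magnitude element made positive so the
initialization (and therefore the whole fit) is deterministic. The updates
are derived by setting ∂J/∂A = 0 and ∂J/∂B = 0:

    A ← (Y B + 2λ_d Kₘ A)(BᵀB + λ_l I + 2λ_d AᵀA)⁻¹
    B ← (Yᵀ A + 2λ_t K_d B)(AᵀA + λ_l I + 2λ_t BᵀB)⁻¹

Note the factor 2 on the similarity terms: it is what differentiation of
the quartic ‖K − AAᵀ‖²_F terms produces, and with it the fixed point of
the iteration is exactly a stationary point of J (verified in the tests by
a finite-difference gradient check). Published presentations of this
update family often drop the 2, which silently halves the effective
λ_d/λ_t; since these weights are grid-searched, either convention reaches
the same models under a rescaled grid, but the consistent form keeps the
objective, the update and the gradient check in agreement. The k×k systems
(symmetric positive definite for λ_l > 0) are solved with LAPACK solves,
never explicit inverses. Updates are Gauss–Seidel: the B step uses the
fresh A.

The scheme is a fixed-point iteration, not an exact block minimizer (the
AᵀA term makes each block subproblem non-quadratic), so the objective
trace is not guaranteed monotone; empirically it decreases on essentially
all random instances, and the test suite asserts descent on ≥95%.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| α | 0.5 | fusion weight on the precomputed similarity vs the GIP kernel; 0.5 is the performance optimum on the curated benchmark |
| γ′ | 1.0 | raw GIP bandwidth before profile-norm normalization |
| K, p | 7, 0.6 | WKNKN neighbour count and decay |
| k | 50 | latent dimension; clipped to min(n,m) by the pipeline so one config serves CV folds and small problems |
| λ_l | 1.0 | Tikhonov weight; midpoint of the 2⁻²…2² search grid |
| λ_d, λ_t | 0.25 | similarity-reconstruction weights; midpoint of the 2⁻⁶…2² grid, coupled by default in the grid search (`lambda_dt`), independently searchable |
| max_iter, tol | 100, 1e-6 | ALS stopping: relative objective change |
| w | 0.5 | Y₁/Y₂ combination weight; the unweighted average mirrors the two-sided averaging used inside the bipartite score |

The λ defaults are a neutral choice for running the pipeline without
tuning; `grid_search` reproduces the intended selection procedure
(five-fold CV over the grid above, first-in-grid tie-break).

## Evaluation protocol

Known 1-entries are shuffled with a seeded generator and split into five
folds. Per fold the test positives are zeroed in the training matrix and
*everything downstream is recomputed on the training matrix* — GIP
kernels, WKNKN, both predictors. This is stricter than protocols that
compute kernels once on the full matrix: interaction profiles contain the
test labels, so kernels computed outside the fold leak. Scoring ranks the
fold's positives against all pairs that are 0 in the original matrix
(training positives excluded) with the midrank AUC; a harness self-test
confirms that feeding the training matrix itself as the prediction yields
AUC exactly 0.5, i.e. the held-out positives are truly invisible. Mean and
std are reported over all folds of all repeats (std over folds and over
repeat means are both available from `fold_aucs`).

## Synthetic data

`generate_dataset` plants non-negative gamma-distributed factors A*
(n×rank) and B*, thresholds the planted scores A*B*ᵀ at the quantile
matching the target density to get Y, and builds similarities as the
row-cosine matrices of A* and B* plus clipped symmetric Gaussian noise —
so the "similar entities share partners" assumption holds by construction
and its strength is controlled by `similarity_noise`. The desk-scale
default is 100×80, rank 5, density 0.05; `hmdd_shaped_spec()` provides a
495×383 preset with 5430 positives matching the scale of the curated
human MDA benchmark, used for runtime checks.

What the synthetic world does *not* emulate: the heavy-tailed degree
distribution of curated databases (literature bias concentrates
annotations on a few famous miRNAs), block structure from disease
ontologies, and annotation noise in the similarities' construction.
Passing the planted-recovery test therefore shows the pipeline recovers
signal *of the kind it assumes*, not that it attains any particular AUC on
real curated data. The shuffled-label null (positives rethrown uniformly)
checks the complementary failure: with all structure destroyed, CV AUC
stays near 0.5, so the harness does not manufacture signal.

`generate_dags` builds a shared rooted hierarchy (configurable depth and
branching) and attaches each disease as its own leaf term under a random
internal node; depth 1 degenerates to singleton DAGs and an identity
semantic similarity.

## Numerical choices and degenerate inputs

- Similarity TSVs with asymmetry ≤ 1e-8 are symmetrized by averaging;
  larger asymmetry is rejected (the tolerance covers float TSV
  round-trips, not data errors).
- All ranking/neighbour ties break by input order, making every code path
  deterministic; consequently exact permutation equivariance holds only on
  tie-free inputs.
- λ_l = 0 with a singular system raises a clear error advising λ_l > 0
  rather than silently regularizing.
- A non-finite ALS objective raises immediately with the iteration and λ
  values (divergence is possible for extreme λ since the update is not a
  descent method by construction).
- Problem sizes in the test suite and acceptance script (8×6 to 10×8
  oracle instances, 100×80 CV with 10 recovery / 20 null seeds in the
  suite and 3/5 in the script, one 495×383 fold) were chosen to exercise
  every path at desk scale; all are generated programmatically from seeds.

## Known limitations

- Cold-start entities (all-zero profiles) get GIP similarity 1 to each
  other, which can cluster unrelated new entities; supplying informative
  Sₘ/S_d mitigates this (α > 0).
- The WKNKN construction follows the standard decay-weighted formulation;
  no alternative imputations are provided.
- Only AUC is implemented; precision-at-k or AUPR would need the scores
  matrix, which `bgcmf predict` exposes for external computation.
- The Y₁/Y₂ combination is a fixed weight, not learned.
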