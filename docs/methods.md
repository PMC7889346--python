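# Methods

## Problem and model

The package predicts drug–target interactions (DTIs) per cell line by
learning to rank. Each drug `d_i` and each target or nontarget `t_j`
carries an expression profile (978 features, the dimensionality of
L1000-style landmark-gene signatures); known interactions form a sparse
binary matrix `Y`. A *nontarget* is a protein with no recorded interaction
with any drug in the cell line; drug × nontarget cells are the candidate
negative pool, and negatives are sampled from it uniformly without
replacement, one per positive, so positives and negatives are balanced.

The model is a matrix factorization: drug factors `F^D ∈ R^{m×f}` and
target factors `F^T ∈ R^{n×f}`, with pair score `r_ij = F_i^D · F_j^T`.
Training consumes partial-order triples `(d_i, t_j, t_k)` with
`y_ij = 1, y_ik = 0`, asserting `r_ij > r_ik` (Bayesian personalized
ranking, BPR). The per-triple objective minimized by SGD is

    L = −ln σ(r_ij − r_ik) + λ_θ (‖F_i^D‖² + ‖F_j^T‖² + ‖F_k^T‖²)
      + λ_adv · [−ln σ(r̃_ij − r̃_ik)]
      + λ_sim · [SimGaus(S^D, F^D, i) + SimGaus(S^T, F^T, j) + SimGaus(S^T, F^T, k)]

with `σ(x) = 1/(1+e^{−x})`. The three ingredients:

* **Adversarial term.** `r̃` is the score after adding a fast-gradient
  perturbation `Δ_adv = ε Γ/‖Γ‖` to each of the triple's three factor rows,
  where `Γ` is the gradient of the unregularized ranking loss with respect
  to that row. The perturbation is the first-order worst case within an L2
  ball of radius ε, recomputed per update and then treated as a constant
  (no second-order term). Training is thus a minimax game: the factors must
  rank correctly even under the worst bounded distortion, which emulates
  measurement error in the expression profiles.
* **Dual similarity regularization.**
  `SimGaus(S, F, a) = Σ_b (S[a,b] − e^{−‖F_a − F_b‖²})²` matches
  profile-derived similarity to the Gaussian kernel of latent distances, on
  both the drug side (`S^D`) and the target side (`S^T`). Because
  `e^{−d²} ∈ (0,1]`, similarity matrices are clamped to `[0,1]` by default
  (negative cosine/Spearman/Tanimoto values become 0); unclamped values
  would be unmatchable by the kernel.
* **L2 term** `λ_θ‖θ‖²`, applied once at the unperturbed parameters.
  Applying it again inside the adversarial term would double-count the
  regularizer, so the perturbed term contains only the ranking loss.

### Similarity kernels

Four kernels on raw profiles: Tanimoto `x·y/(‖x‖²+‖y‖²−x·y)` (undefined
when the denominator is ≤ 0, a pathological anti-parallel case treated as
an error), cosine, a *global* SSIM
`(2μ_xμ_y+c₁)(2σ_xy+c₂)/((μ_x²+μ_y²+c₁)(σ_x²+σ_y²+c₂))` with
`c₁ = c₂ = 0.001` computed from whole-vector population moments (no
sliding windows — mean, variance and covariance are read as
expression-change statistics), and Spearman
`1 − 6Σg_i²/(n(n²−1))` with average ranks on ties. Matrices are
symmetrized, the diagonal is set to exactly 1, and assembly is vectorized
but verified against the naive pairwise loop in the tests.

## Numerical choices

* `−ln σ(x)` is computed as `softplus(−x) = ln(1+e^{−x})` via
  `logaddexp`, stable for score gaps beyond ±500.
* Factors are initialized from `N(0, 0.01²)` with a seeded generator; all
  randomness (init, per-epoch shuffle, sampling) descends from one integer
  seed, so runs are bit-reproducible.
* Each SGD step accumulates all gradient contributions for the three
  touched rows and applies them *simultaneously* (not Gauss–Seidel); with
  `λ_adv = λ_sim = 0` the trajectory is bit-identical to plain BPR, which
  the tests assert against an independent reference loop.
* The similarity gradient applied to a row is the own-term block
  `∂SimGaus(S, F, a)/∂F_a = Σ_b 4(S[a,b] − e^{−d²}) e^{−d²} (F_a − F_b)`;
  the cross term of `SimGaus(·, j)` with respect to `F_k` is dropped, the
  usual stochastic-gradient simplification. Each similarity update touches
  all m (or n) entities, O(m·f) per triple — acceptable at desk scale.
* Zero-gradient blocks yield zero perturbation; nonzero blocks have norm
  exactly ε (the budget is enforced per block, since a joint normalization
  of the concatenated gradient is ambiguous between rows).
* Training runs a fixed number of epochs (no early stopping) and records
  the mean per-triple objective per epoch; non-finite loss aborts with the
  epoch and triple index.
* Ranking ties break by ascending target index, making predictions
  deterministic. The metrics are nevertheless pessimistic about ties by
  construction (below).

## Defaults and why

| parameter | default | note |
|---|---|---|
| latent dimension `f` | 25 | performance plateaus beyond ~25 on both real-scale reports and the synthetic sweep |
| `λ_θ` | 0.1 | L2 weight |
| `λ_sim` | 0.3 | small-to-moderate; the best value is dataset-dependent (larger helps sparser data) |
| `λ_adv` | 0.3 | best-performing adversarial strength |
| `ε` | 0.1 | perturbation radius |
| learning rate | 0.03 | SGD step |
| epochs | 100 | fixed budget |

## Evaluation

All metrics are per-drug (macro) averages. AUC is the fraction of test
triples with `r_ij > r_ik` (ties count 0). `Top_k` counts a test positive
when at most `k−1` other candidates score ≥ it (a tied competitor therefore
pushes it down), divided by the drug's positive count; `prec_k` divides the
same count by `k`, so `prec_k·k = Top_k·#positives` holds exactly. AUPR
integrates the per-drug (recall, precision) curve over `k = 1..#candidates`
by trapezoid, anchored at recall 0 with the precision of the top-ranked
candidate. NDCG uses binary gains with `1/log₂(rank+1)` discounts,
normalized by the ideal ordering. By default the candidate pool excludes
the drug's training positives (filtered ranking, switchable to the full
pool).

Enrichment of a predicted edge list against a reference edge set (both
restricted to the in-scope drug × target universe) uses the fold
enrichment `ES = (k/n)/(m/N)`, the hypergeometric upper tail
`P(X ≥ k)` (scipy, log-space internally), and Benjamini–Hochberg FDR
across reference sets. Overlap curves count reference hits in consecutive
bins of the ranked predictions (stride = bin size by default; an
overlapping stride is available). Note that BH adjustment is *not*
idempotent — re-adjusting adjusted values inflates them — so the tests
assert monotonicity and a hand-computed example instead.

## Synthetic data and what it shows

The generator plants rank-`f_true` Gaussian factors `G_D, G_T`, thresholds
the top `interaction_rate` fraction of `G_D G_T'` (true-target columns
only) into positives, and embeds the factors into profile space through a
shared orthonormal map plus `N(0, signal_noise²)` feature noise. With zero
noise, profile cosine similarity equals planted-factor cosine similarity
exactly; noise degrades that agreement monotonically. A Bernoulli/logistic
positive rule is available as an option. Defaults — 60 drugs, 40 targets,
300 nontargets, `f_true = 5`, 978 features, `interaction_rate = 0.05`
(~2 positives per drug), `signal_noise = 0.02` (noise norm ≈ 0.63 against
signal norm ≈ √5) — are a scaled-down cell-line dataset that keeps the
full pipeline in seconds.

What passing synthetic tests do **not** show: real transcriptomic
covariance, batch effects, or identifier noise are absent; profiles here
are exactly low-rank plus isotropic noise, so the similarity regularizer
is better-specified than on real data, and absolute metric values should
not be read across.

### Leakage and the negative control

Triples are the cross product of a drug's positives and sampled negatives,
so a fold split at the triple level places the same positive pair — and
the same trained-down negative cells — on both sides of the split; even a
label-permuted control then scores AUC ≈ 0.7–0.9 by memorization. The
recovery experiment (`advbpr.experiments.recovery_experiment`) therefore
(a) splits folds by positive *pair* (`split_cv(..., unit="pair")`) and
(b) scores held-out positives against freshly sampled nontarget negatives
never used in training. Under that protocol the planted-signal run reaches
held-out AUC ≥ 0.9 while the permuted control sits at chance. The default
pipeline split remains triple-level (matching the usual protocol and kept
for the standard CV workflow), with the strict mode one flag away.

## Known limitations

* Per-drug macro metrics are noisy at desk scale (a drug may hold a single
  test positive); the control AUC correspondingly has visible seed-to-seed
  variance.
* Nested cross-validation is supported structurally (outer folds plus an
  inner 4:1 split helper) but the CLI's `run-all` evaluates at fixed
  hyperparameters rather than grid-searching the inner loop.
* The trainer is plain single-threaded SGD over triples; no mini-batching,
  no alternative optimizers, no neighbor subsampling of the similarity sums
  (adequate for hundreds of entities, not for 10⁵).
* Identifier handling is plain strings; no cross-database mapping.
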