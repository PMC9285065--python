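# Methods

This note documents the models, numerical choices and design decisions
behind `moca`, in the spirit of the methods documentation of packages like
statsmodels or msprime. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Preprocessing

Columns are mean-centered and, by default, scaled to unit variance (UV
scaling). Means and standard deviations are estimated over **observed
cells only**; the standard deviation uses the n−1 denominator, the
chemometrics convention. Constant columns (observed-cell variance ≤ 1e−12)
must be removed before UV scaling; `remove_constant_columns` does this and
reports the removals. Missing cells are never imputed — the NIPALS engines
below handle them natively — and preprocessing never alters the missing
mask. Endpoint tables in toxicology are conventionally transformed to
negative log molar units before modelling; `neg_log_molar` provides the
−log10 (potencies) and log10 (partition-type quantities such as
bioconcentration factors) variants.

## NIPALS PCA with missing values

Components are extracted sequentially by alternating least-squares updates
of a score vector t and a unit-norm loading vector p, followed by
deflation X ← X − t p′ at observed cells. All inner products skip missing
cells, with per-row and per-column denominators restricted to observed
entries; consequently the returned residual is exactly zero at missing
cells and a missing value has no leverage on the fit.

Numerical choices:

* **Convergence**: relative change of the score vector ≤ `tol`
  (default 1e−9), `max_iter` 500. Non-convergence returns the component
  flagged `converged=False` with a warning rather than failing.
* **Initialization**: the observed column of largest sum of squares —
  deterministic, no RNG anywhere in fitting.
* **Explained variance**: R² per component is the drop in observed-cell
  residual sum of squares divided by the total observed sum of squares of
  the centered block. This makes cumulative R² monotone and consistent
  with the missing-value contract.
* **Sign convention**: the loading element of largest absolute value is
  positive, applied to every component of every engine.
* **Component count**: the caller passes `n_components` or a cumulative-R²
  stop (default 0.95). No automatic significance testing is attempted.

On complete data the fixed point of the iteration is the dominant
singular pair, so NIPALS agrees with a dense SVD; the test suite asserts
this to 1e−6 over 50 random matrices and cross-checks against
scikit-learn's PCA.

Jackknife loading intervals are leave-one-observation-out: each refit
re-centers (and re-scales) the remaining rows, is sign-aligned to the
full-model loadings, and the interval is loading ± t-quantile × jackknife
standard error with m−1 degrees of freedom (m = successful refits).
Refits that fail to converge are excluded and counted.

## PLS2 and single-y OPLS

`fit_pls` is NIPALS PLS2 with the same masked inner products and the
standard deflation (X by t p′, Y by t c′). Q² is estimated by K-fold
cross-validation (default 7 contiguous folds by observation order — the
data have no meaningful order in our use cases, and contiguous folds keep
the procedure deterministic); left-out rows are predicted through the
weight/loading sequence and Q²_a = 1 − PRESS_a / SS(Y). The refits reuse
the full-data preprocessing, a common and slightly optimistic shortcut
that matters little at n ≥ 100.

`fit_opls` implements the single-y orthogonal PLS decomposition
X = t_p p_p′ + T_o P_o′ + E, y = t_p q_p + f. Each orthogonal round
computes the y-predictive weight w, the candidate loading p, and splits
off w_o ∝ p − (w′p)w; the final predictive component is computed on the
deflated X. With a single y there is exactly one predictive component;
with `n_ortho=0` the model coincides with one-component PLS. Multi-Y OPLS
is deliberately not implemented; PLS2 covers the multi-response case.

## The multiblock decomposition

Step 1 — pairwise joint ranks. For every block pair the blocks are
divided by the square root of their total observed sum of squares (equal
weight independent of block size) and the SVD of the cross-product
`X_a'X_b` is taken. A component is retained while all three hold:

1. its singular value exceeds 2 % of the nuclear norm (`sv_fraction_threshold`);
2. it exceeds 1.3 × the analytic Gaussian-noise edge
   (√p_a + √p_b)/√(n·p_a·p_b) — the expected top singular value of the
   cross-product of two *independent* noise blocks after norm
   equalization (`noise_sv_multiplier`). Without this gate the fraction
   rule alone admits the top noise component, whose singular-value
   fraction is ≈ 10 % at n = 200, p = 20;
3. the paired score correlation is at least 0.35 (`min_score_correlation`),
   a weak sanity floor.

Pairwise score vectors are computed by per-row least-squares projection
over observed cells (the same zero-residual contract as NIPALS); plain
zero-filled products measurably degrade scores once a block has tens of
percent missing cells.

Step 2 — compression. Per block, all its pairwise score vectors are
collected and compressed by PCA; components are kept until cumulative R²
reaches 0.98 (`compression_r2`), yielding an orthonormal joint score
basis per block (possibly empty).

Step 3 — split. Each block is regressed column-wise (observed cells
only) on its accepted basis directions *sequentially*, so per-direction
explained sums of squares add exactly; the residual block retains zeros
at missing cells.

Step 4 — unique components. NIPALS PCA on the residual, keeping a
component while (a) it explains ≥ 2 % of the *original* block's observed
sum of squares (`unique_r2_threshold`) and (b) its explained sum of
squares exceeds 1.3² × the Gaussian-noise expectation sd²(√n + √p)² with
sd² estimated from the current residual (`unique_edge_multiplier`). Gate
(b) is what keeps pure-noise residuals component-free: the first PC of an
n = 200 × p = 20 noise matrix explains ≈ 8.6 % all by itself, so an R²
floor alone cannot distinguish noise from structure. Under missing data
the gate is conservative (the true noise edge shrinks with the observed
fraction).

Step 5 — classification. Iteratively, the first principal direction
across all remaining basis vectors proposes a consensus score. Each block
answers with its best-matching direction — the normalized projection of
the consensus onto the block's remaining basis span, which makes matching
invariant to how compression happened to rotate the basis. A block
becomes a member if |corr(matched direction, consensus)| ≥ 1 +
strictness, and members are pruned (weakest first) until every *pair* of
member scores also satisfies the bound — so the strictness genuinely
bounds inter-block score agreement, not merely agreement with the
average. A component is emitted with ≥ 2 members (global if all blocks
joined, local otherwise). Every block aligned with the candidate above a
fixed structural floor (`consensus_align_floor` = 0.35) has its matched
direction deflated from its basis whether or not it joined; non-member
variance is thereby routed back to that block's unique pool. Because the
candidate sequence and the deflations depend only on the floor and never
on the strictness, memberships are nested across strictness values and
each block's joint explained variance is non-decreasing as the strictness
relaxes — the behavior the strictness-sweep meta-analysis relies on.
Deflation removes at least one direction per round, guaranteeing
termination.

Component numbering is model-wide and deterministic: global components
first (descending mean per-block R²), then local, then unique per block
in input block order. Per-block component scores are scaled so that the
squared norm equals the explained sum of squares; loadings are unit-norm.
The consensus score of a joint component is the mean of the member scores
after unit-variance scaling and sign alignment to the first member, and
the per-observation disagreement is the RMS deviation of member scores
from the consensus — observations where the blocks tell different stories
get large disagreement values.

### Strictness: interpretation and recommended ranges

Strictness maps to a correlation threshold 1 + strictness on block-score
agreement. Near 0 the demand is extreme: a threshold of 0.99 exceeds what
a block can deliver even in principle once its own measurement noise is
accounted for. For a block with p variables each carrying a fraction f of
signal variance, the correlation between the block's best score estimate
and the true latent is bounded by √(fp/(fp + 1 − f)); at p = 30 and
f ≈ 1/3 this ceiling is ≈ 0.97, and for a 7-variable endpoint block with
30 % missing cells it is ≈ 0.85–0.91. Settings of −0.05 to −0.2 are
therefore recommended for exploratory decomposition of small or noisy
blocks, and the package's own structure-recovery validation runs at −0.1.
This matches the practical experience that the strictest settings abruptly
shrink the joint fraction, while results stabilize once strictness is
relaxed moderately.

## Block metrics

Redundancy and predictivity are weighted sums over the joint components
in which the target block participates, with the target's per-component
explained variance as weight and absolute score correlations as factors.
Correlations enter in absolute value because score signs are fixed only
by convention; using signed correlations can only lower both metrics
(asserted as a test invariant). Components in which the target is the
sole member (impossible for emitted joint components, but kept for
robustness) contribute zero. P(T, T) = R²Xj(T) exactly.

## Synthetic data generator

The generator emulates blocked descriptor/endpoint tables: orthonormal
latent factor scores (centered, Gram–Schmidt, unit variance), per-factor
per-block Gaussian loading vectors drawn once and scaled to an exact norm
(strength × √p), i.i.d. Gaussian noise, and optional uniform
missing-at-random masking (per block). The design R² of a factor in a
block is strength²/(Σ strengths² + noise_sd²); realized fractions are
reported in the returned truth object and converge to the design values
as n grows. Everything is deterministic given the seed.

What it does **not** emulate: count-valued and binary fingerprint
descriptors (the linear Gaussian model is a poor description of sparse
bit vectors, which in practice yield many tiny components), structured
missingness (real endpoint panels are missing by study, not at random),
inter-column noise correlation, and heavy-tailed descriptor
distributions. Passing tests therefore demonstrate correct recovery of
linear latent structure under Gaussian noise, not performance on raw
fingerprint blocks.

The bundled `pesticide_like_fixture` mimics a five-descriptor-block +
7-endpoint-block study: one dominant size-like global factor, one local
factor among the descriptor blocks only, and two smaller factors joining
the endpoint block with subsets of descriptor blocks, with 30 % of the
endpoint block masked. Factor strengths were chosen from the correlation
ceiling above so that the global and the mid-sized endpoint-joint factors
sit clearly above the −0.2 classification threshold while the smallest is
deliberately marginal — it is rejected increasingly often as strictness
tightens, which is the qualitative behavior the strictness sweep is meant
to expose. A rejected ("demoted") joint factor reappears, correctly, as
unique variance of the blocks that carried it.

## Serialization and CLI

A fitted model is saved as `model.json` (options, block metadata,
component kinds/members/per-block R²) plus TSV tables: `scores.tsv`
(observations × components, including consensus and disagreement columns)
and `loadings_<block>.tsv`. All TSV floats use the %.6g format, and CLI
output is byte-identical to the corresponding library calls. Exit codes:
0 success, 1 data/model error, 2 usage error.

## Validation problem sizes

The automated validation uses n = 200 observations with 3 blocks of
30/50/80 variables (structure recovery, conservation, monotonicity), 3 ×
20-variable noise blocks over 20 seeds (null behavior), the 6-block
fixture above (target-block recovery, metrics), and 50 random matrices up
to 40 × 12 (SVD oracle equivalence). These sizes give stable pass/fail
behavior for the planted effect sizes while keeping the full suite fast.

## Known limitations

* Joint-rank selection is threshold-based (deterministic), not
  cross-validated; the thresholds are exposed in `MocaOptions` because no
  canonical values exist.
* The classification's consensus extraction is greedy; pathological bases
  with many equally strong cross-block directions may split or merge
  components differently than an exhaustive search would.
* Q² folds are contiguous by default; use seeded random folds for data
  with meaningful observation order.
* With very small blocks (few variables) the unique-component noise gate
  is strict — genuine unique structure explaining less than roughly
  (√n + √p)²/N of the block cannot be distinguished from noise and is
  left in the residual.
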