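# Methods

## Model

All predictors act on the univariate mixed linear model

    y = W alpha + Z g + e,        g ~ N(0, K sigma_g^2),

where `y` (length n) holds phenotypes, `W` an optional full-rank
fixed-effect design, `Z` the random-effect incidence (the identity when
every individual is phenotyped once), and `K` an r x r relationship matrix
— genomic `G` built from marker dosages, pedigree `A` from the tabular
recursion, or any user-supplied positive (semi-)definite similarity
matrix.  Record `i` carries a replication count `n_i` (daughters of a
bull, field plots of a line, clones), so its residual variance is
`sigma_e^2 / n_i` whatever the residual family.

Three residual families are supported, and each yields a posterior-mode
predictor computed by (re-)solving Henderson's mixed-model equations:

| method | residual law            | weights            | penalty on K^-1 |
|--------|-------------------------|--------------------|-----------------|
| GBLUP  | Gaussian                | `n_i` (fixed)      | `lambda = sigma_e^2 / sigma_g^2` |
| TMAP   | scaled Student t(nu)    | `d_i = n_i / (1 + n_i r_i^2 / (tau_e^2 nu))` | `lambda'' = lambda (nu-2)/(nu+1)` |
| LMAP   | Laplace                 | `m_i = n_i / |r_i|` (floored) | `omega = sigma_e^2 / (2 sqrt(2) sigma_g^2)` |

Here `r_i = y_i - mu_i` is the current residual and
`tau_e^2 = (nu-2)/nu * sigma_e^2` is the t scale that makes Var(e_i) =
`sigma_e^2 / n_i` exact, so heritability means the same thing across
families.  The t weights attenuate records smoothly as their residual
grows; the Laplace weights are the classical IRLS majorization of the
absolute loss.  GBLUP solves one linear system; the robust methods
iterate weight updates and solves until a fixed point.

The TMAP functional iteration is the EM algorithm for the
normal/chi-square scale-mixture representation of the t distribution, so
its log-posterior objective ascends monotonically; a Newton–Raphson
variant (`fit_tmap_newton`) uses the curvature matrix built from
`Q = D - 2 D S D`, `s_i = r_i^2/(tau_e^2 nu)`, with step-halving, and
falls back to one functional step whenever `Q` makes the curvature
indefinite (the t log-density is non-concave in the tails).  The LMAP
iteration is a majorize–minimize scheme for

    J(g) = sum_i n_i |y_i - mu_i| + (omega/2) g' K^-1 g,

so `J` descends monotonically.

Approximate posterior covariances come from the inverse curvature at the
mode: exact for the Gaussian case (`sigma_e^2` times the inverted MME
blocks), the standard Gaussian approximation scaled by
`tau_e^2 nu/(nu+1)` for TMAP (reported with a PSD flag, never repaired),
and `sigma_e^2/(2 sqrt 2)` times the M-weighted blocks for LMAP.  The
absolute scale of the LMAP covariance inherits a parameterization
ambiguity of the Laplace density (the operational definitions of `m_i`
and `omega` above are authoritative; the penalty implied by the written
log-posterior differs from the one implied by the iteration by a factor
of two, and the iteration's convention is used throughout); `scale_note`
flags this.

## Variance components and regularizers

MINQUE estimates `(sigma_g^2, sigma_e^2)` non-iteratively from a guessed
heritability: with `lambda_guess = (1-h2)/h2` and
`V* = K/lambda_guess + I`, a 2 x 2 system of traces of products of `K`
and `V*^-1` is solved for the two components.  The estimator is unbiased
at any guess; wrong guesses only inflate its sampling variance.
Everything is evaluated in the eigenbasis of `K`, computed once per
matrix and cached, so a 19-point heritability grid costs one
eigendecomposition.  `K` proportional to the identity makes the two
components non-identifiable and is rejected.

Spectral maximum likelihood (`ml_estimate`) profiles the overall scale
out of the Gaussian likelihood of the zero-means model and optimizes a
1-D criterion over heritability (bounded Brent, `xatol 1e-10`); boundary
solutions are flagged.  Iterating MINQUE (guess <- estimate) converges to
the same interior optimum, which the tests verify.  Negative MINQUE
components are replaced, by default, with the full-data ML estimate of
the offending component (a clamp-to-`1e-6 var(y)` policy is selectable).

Fixed effects are handled by pre-correction: phenotypes are centered (or
residualized on `W`) before variance-component estimation, which keeps
the zero-means machinery exact.

## Predictive evaluation

* **GCV** for the Gaussian smoother `H(lambda) = (I + lambda K^-1)^-1`:
  `GCV = (1/n) y'(I-H)^2 y / (1 - mean diag H)^2`, evaluated for a whole
  lambda grid from one eigendecomposition.
* **LOO shortcut**: all three predictors have the form `C^-1 y` with
  `C = I + sP` (GBLUP: `s = lambda, P = K^-1`; TMAP: `s = lambda'',
  P = (KD)^-1`; LMAP: `s = omega, P = (KM)^-1`, weights frozen at the
  full-data fixed point).  Then `g_loo,i = (g_i - c_ii y_i)/(1 - c_ii)`
  with `c_ii` from `C^-1`.  For GBLUP at fixed lambda this is exactly
  leave-one-out; for the robust methods it is an approximation because a
  refit would adapt the weights.
* **Brute-force LOO** refits n times, optionally re-running MINQUE per
  fold (guess = full-data ML), and predicts the held-out individual from
  the kinship cross-covariances, `g_out = K_out,in K_in,in^-1 g_in`.
* **Metrics**: predictive MSE, Pearson correlation, and the intercept and
  slope of the regression of observed value on prediction ((0, 1) =
  empirically unbiased).  MNDCG@k ranks individuals by prediction, scores
  gains = positivity-shifted targets discounted by `log2(position+1)`,
  normalizes by the ideal ordering, and averages NDCG over positions
  1..k.  The shift applied to the gains depends only on the targets, so
  the criterion is invariant to monotone transforms of the predictions;
  prediction ties break by original index.  (The combination of
  log2 discount, shifted-target gains, ideal normalization and
  mean-over-positions is a declared convention — several variants
  circulate under the same name.)
* **Paired bootstrap**: rows of (target, prediction-per-method) are
  resampled with replacement; all methods share the index draws, so win
  fractions (strict wins; ties counted separately) are paired.
* **Train/test replication**: random splits, MINQUE per grid entry on the
  training set, fits per method, cross-covariance prediction of the test
  set, metric tables in tidy form plus winner frequencies (max PCOR, min
  PMSE; exact ties break by method order).  Replicate r draws its RNG
  stream from (seed, r), so the replicate set is order-independent.

## Synthetic data

The generator emulates exactly the structure the methods assume:
binomial(2, p) marker dosages at frequencies drawn from (0.05, 0.95)
(monomorphic columns redrawn), VanRaden G with a 1e-6 diagonal ridge so
`K^-1` exists, `g ~ N(0, K sigma_g^2)` via the eigen square root with
negative eigenvalues clipped, and residuals from the normal, scaled-t or
Laplace family, all variance-matched to `sigma_e^2 / n_i`.  Outlier
contamination adds a sign-balanced mean shift (in units of `sigma_e`) to
a random fraction of records — the "undeclared preferential treatment"
scenario — and flags exactly those records.  Optional sparse major-gene
effects are added to `g` before phenotypes are formed.

Defaults are n = 200 individuals, p = 500 markers, `sigma_g^2 = 0.3`,
`sigma_e^2 = 0.7` (heritability 0.3, a typical complex-trait value),
Gaussian residuals, no replication structure, no contamination.

What the generator does **not** emulate: linkage disequilibrium, family
or population structure in the genotypes, selection, multi-trait
covariance, or heterogeneous residual classes beyond `n_i`.  Passing
tests therefore demonstrate correctness of the algorithms and the
direction of the robustness effect under idealized sampling, not
performance on structured real populations.

## Numerical choices

* Linear solves by Cholesky of the assembled symmetric system; `K^-1` is
  obtained by factor solves and cached per matrix.
* Convergence: `max|dg| / (1 + max|g|) < 1e-8`, with budgets of 100
  iterations (TMAP functional and Newton) and 500 (LMAP).  Because the
  L1 solution interpolates a few records, the LMAP iteration contracts
  sublinearly at those kinks and the step criterion alone can be
  unattainable; convergence is therefore also declared when the relative
  decrease of `J` per round falls below 1e-9, at which point further
  movement of `g` is below the resolution induced by the residual floor.
  Non-convergence returns a flagged result with a warning, not an
  exception.
* LMAP residual floor: `|r_i|` is floored at `1e-8 * SD(y)` inside the
  weights, since `m_i` is unbounded at a zero residual.
* Kinship regularization: if the Cholesky of `K` fails, `1e-8 *
  mean(diag K) * I` is added and recorded in metadata; already-definite
  matrices pass through unchanged.
* Genomic G: VanRaden's first method with observed-frequency centering by
  default; user-supplied frequencies are honored, and {0,1}
  presence/absence codings use centering by `p` and denominator
  `sum p(1-p)` (no diploid factor).  Missing dosages are mean-imputed per
  marker; monomorphic markers are dropped with a logged count.
* Winner ties, degenerate leverage (`c_ii = 1`), constant predictions and
  negative variance estimates all have explicit, tested contracts rather
  than silent behavior.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` regenerates every quantity from scratch at sizes
chosen to make Monte-Carlo noise small relative to the tolerances it
reports: n = 100 for the Gaussian-limit check, n = 50 for the LOO
shortcut/brute-force identity, 10 random n = 6 instances for the
MME/closed-form identity, 500 replicates at n = 200 for MINQUE
unbiasedness, and 50 seeds at n = 300 with 10% 5-SD contamination for the
robustness direction.

## Known limitations

* The LMAP posterior-covariance scale is a convention (see above), and
  its LOO shortcut freezes weights; both are flagged in the results they
  affect.
* MINQUE requires a kinship matrix distinguishable from the identity.
* The brute-force LOO is O(n) refits and intended for n up to a few
  hundred.
* No sparse or iterative solvers: dense Cholesky limits the practical
  size to a few thousand individuals.
* The directional robustness advantage of LMAP depends on the evaluation
  route: it holds for the frozen-weight LOO comparison, while
  brute-force refits with cross-covariance prediction can favor GBLUP at
  small n even under contamination.
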