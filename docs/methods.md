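# Methods

## Model

`irtstream` estimates two-parameter logistic item response models from a
stream of binary response vectors. Item `j` has a loading (discrimination)
vector `a_j` over `Q` latent dimensions and a scalar intercept `d_j`; an
examinee with latent trait `theta ~ N(0, I_Q)` answers correctly with
probability

    P_j(theta) = sigma(a_j' theta + d_j),      sigma(x) = 1 / (1 + e^{-x}).

Everything is stored and updated in this slope–intercept form. The
unidimensional 2PL with discrimination `a` and difficulty `b` (predictor
`a (theta - b)`) is the `Q = 1` case with `d = -a b`; reports convert back
with `b = -d / a`. One parameterization means one update code path for both
models.

The marginal likelihood of a response vector integrates the trait against
its standard normal prior. The integral is approximated on a fixed
tensor-product grid of `K` nodes per dimension (see *Quadrature* below),
giving a discrete prior `w_k` over nodes `x_k`. An examinee's discrete
ability posterior is `w_k * L(y | x_k)` renormalized, computed in log space
throughout; response probabilities are clipped to `[1e-12, 1 - 1e-12]` so
log terms stay finite (far below any estimation precision of interest).

## Streaming estimator

The engine maintains, per item: the current iterate `beta_j`, the averaged
iterate `beta_bar_j` (the reported estimate), and an accumulated curvature
matrix `S_j` seeded with a positive-definite prior term `S0_j`. When
examinee `n` arrives:

1. **Gradient.** The examinee's ability posterior is computed at the
   current iterates, and the per-item score
   `g_j = -sum_k post_k (y_j - P_jk) (x_k, 1)` is evaluated. Because the
   posterior's own parameter dependence cancels in the score of the
   marginal likelihood, this is the exact gradient of the examinee's
   negative log marginal likelihood (finite-difference agreement ~1e-7).
2. **Curvature.** The posterior is recomputed at the *averaged* iterates
   and the truncated per-examinee information
   `Phi_j = sum_k post_k max(P_jk (1 - P_jk), lambda_n) (x_k,1)(x_k,1)'`
   is formed. The floor `lambda_n = c_lambda (n+1)^{-alpha_lambda}` keeps
   the accumulated curvature bounded away from singularity while decaying
   to zero; `c_lambda <= 1/4` because the Bernoulli variance
   `P(1-P) = 1/(2 + 2 cosh(eta))` never exceeds 1/4.
3. **Newton step.** `beta_j <- beta_j - nu_n (S_j / n)^{-1} g_j` with
   `nu_n = c_nu (n + n0)^{-gamma}`, using `S_j` from *before* this
   examinee's curvature is added. The delay constant `n0` damps the
   earliest steps, when both the iterate and the curvature estimate are
   poor.
4. **Accumulate.** `S_j <- S_j + Phi_j`.
5. **Average.** `beta_bar_j <- (1 - tau_n) beta_bar_j + tau_n beta_j` with
   `tau_n = omega_n / sum_{i<=n} omega_i`. The default is the log-weighted
   sequence `omega_i = ln(1+i)^2`, which gives later (better) iterates more
   weight while still averaging out noise; `omega_i = 1` gives the plain
   arithmetic mean, and `tau_n = 1` (mode `"none"`) disables averaging,
   recovering the non-averaged truncated recursion. The two variants share
   one code path (verified bitwise).

The examinee is then EAP-scored (posterior mean of `theta`) with the
just-updated averaged item parameters, so every record in the stream yields
both refreshed item estimates and an ability estimate — one pass, constant
memory in the number of examinees.

Anchored entries (see *Identification*) never move: their gradient entries
are zeroed and the corresponding rows/columns of `S_j` are held at the
identity pattern, which makes the embedded full-dimension solve equal to
the free-restricted solve exactly.

### Defaults and what they mean

| parameter | default | role |
|---|---|---|
| `gamma` | 0.65 (averaged) / 0.75 (non-averaged) | step-size exponent in `(1/2, 1]`; smaller = more aggressive steps, viable only with averaging |
| `c_nu` | 1.0 | step-size scale |
| `n0` | 20 | step delay; damps the first ~dozens of updates roughly 7x at n=1 |
| `c_lambda`, `alpha_lambda` | 0.2, 0.49 | curvature-floor scale/exponent; floor must decay slower than 1/sqrt(n) |
| `avg_w` | 2.0 | exponent of the log-weighted averaging sequence |
| `K` | 11 | quadrature nodes per dimension for estimation |
| `hessian_init` | expected | `S0` = prior-weighted expected item information at the start values (+ ridge 1e-3), so the first Newton steps are on the right scale; identity is available |
| start values | a = 1, d = 0 | neutral item of unit discrimination |

`gamma = 1` is admissible but accumulates variance noticeably faster than
0.65 under averaging; the recovery experiments in the test suite check the
ordering. The step exponent, delay, and floor constants interact: the
n=2,500 accuracy of the averaged estimate is dominated by how quickly the
early transient is forgotten, and is therefore quite sensitive to `n0`
(see *Limitations*).

### Standard errors

`SE_j = sqrt(diag(S_j^{-1}))` at the final sample size. Because `S_j` is
the *unnormalized* accumulated curvature (roughly `n` times the average
per-examinee information), the `1/sqrt(n)` asymptotic scale is built in.
Note that the accumulated matrix is the posterior-weighted complete-data
(cross) information, which is an upper bound on the marginal Fisher
information by the missing-information principle; these SEs are therefore
somewhat optimistic, and Wald intervals built from them undercover in the
package's own calibration experiment (~0.82–0.85 empirical coverage at
nominal 0.95, n = 10,000). They are reported because they are the
estimator's natural, cheaply available uncertainty summary; treat them as
lower bounds on uncertainty.

## Quadrature

Two node conventions are provided:

- **Gauss–Hermite** (default): physicists' abscissae scaled by `sqrt(2)`,
  weights renormalized to a probability vector, tensorized over dimensions
  and renormalized again so the discrete prior is exactly proper. This is
  the estimation workhorse: at `K = 11` it integrates the wide marginal
  integrands accurately and keeps per-examinee cost low. A guard rejects
  grids beyond `10^6` nodes (`K = 31` at `Q = 4` would exceed it).
- **Equally spaced, density-weighted** (`rule="rectangle"`, `[-4, 4]` by
  default): the classic fixed-grid convention with weights proportional to
  the normal density at each node. After ~20 items an examinee's posterior
  has sd ≈ 0.3, and Gauss–Hermite node *placement* quantizes the posterior
  mean at the 1e-3–1e-2 level for `K = 21`, while the uniform 0.4 spacing
  of the scoring grid agrees with a dense reference to ~1e-5. Use this
  grid for precision EAP scoring; use Gauss–Hermite for fitting.

## EM baseline

A fixed-quadrature Bock–Aitkin marginal-maximum-likelihood EM serves as the
offline reference: the E-step aggregates every examinee's discrete
posterior into expected node counts `nbar_k` and expected correct counts
`rbar_jk`; the M-step solves each item's weighted logistic score equation
by damped Newton (step-halving on any decrease of the item's expected
log-likelihood, information matrix shared with the online curvature at
floor 0). The observed-data log-likelihood is asserted non-decreasing every
cycle; convergence is declared when it improves by less than 1e-6 (at most
500 cycles). EM standard errors are out of scope — the streaming SEs are
the point of the package.

## Synthetic data and identification

The generator draws, per replication: discriminations `a_jq ~ U(0.5, 2)`
(bounds config-exposed; the default covers typical operational slopes),
difficulties (2PL) or intercepts (M2PL) from `N(0, 1)`, abilities from
`N(0, I_Q)`, and Bernoulli responses from the model. For `Q >= 2` the first
`Q` items are anchored to intercept 0 and an identity loading pattern
*before* responses are generated, so the anchors are part of the
data-generating truth; for `Q = 1` the standard-normal prior fixes the
scale and nothing is anchored. RNG order (items, then abilities, then
response uniforms) makes a seed fully reproducible; replication `r` uses
`base_seed + r`, and estimator comparisons within a replication share the
dataset (paired design).

What the generator does *not* emulate: missing responses (the reader's
masked mode exists, but the experiments use complete data), polytomous
items, correlated latent dimensions, item-parameter drift over the stream,
and nonstationary arrival processes. Passing recovery tests therefore
demonstrate correctness of the estimator under the model, not robustness
to real-data violations of it.

## Evaluation conventions

Recovery is summarized by bias and RMSE per parameter across replications;
for the unidimensional model errors are taken on the `(a, b)` scale
(`b = -d/a`, the scale practitioners read), for `Q >= 2` on the
slope–intercept scale over free parameters only. "Pooled RMSE" pools
discrimination and difficulty errors within a replication and averages the
result over replications. Ability recovery compares streaming EAP scores
against batch EAP computed with reference item parameters.

The standard experiment sizes (chosen to keep a full run on one CPU in the
tens of seconds to minutes): J = 20 items, streams of 2,500–20,000
examinees, 10–20 replications; the real-time trajectory is checkpointed at
500, 1,000, 2,000, 2,500, 5,000, 7,500, 10,000, 15,000, 20,000. Since the
estimator is one-pass, the state at an intermediate checkpoint *is* the
fit a shorter stream would produce, so one long stream serves every
checkpoint.

## Numerical choices

- Posteriors via log-sum-exp; invariant to constant shifts of the
  conditional log-likelihood (property-tested).
- Per-item systems are `(Q+1) x (Q+1)`; they are solved directly (batched
  `solve`), not by rank-one inverse updates — at these sizes the explicit
  solve is both faster and simpler, and the contract is the solution, not
  the factorization.
- Items whose free set is empty are skipped in the update loop but still
  contribute to every likelihood and posterior.
- JSON trajectory output serializes floats at 17 significant digits so
  round-trips are bit-exact; arrival order is file order, never shuffled.

## Known limitations

- The n=2,500 accuracy of the averaged estimate depends strongly on the
  early-transient constants (`n0`, `c_nu`): with the defaults the pooled
  RMSE at 2,500 is ≈ 0.115 (20 replications), reaching ≈ 0.08 at 5,000 and
  ≈ 0.034 at 20,000. Streams shorter than ~1,000 examinees give estimates
  that are still dominated by the start values.
- Inverse-Hessian SEs undercover (see *Standard errors*).
- Cross-item curvature is ignored (block-diagonal by item), which is exact
  for the per-item update scheme but means no joint covariance across
  items is available.
- `K^Q` node growth makes `Q >= 4` expensive; the guard refuses grids past
  `10^6` nodes. Adaptive quadrature is out of scope.
- MLE/MAP ability scoring, polytomous models, non-logistic links, and
  correlated latent priors are out of scope.
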