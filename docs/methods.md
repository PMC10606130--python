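# Methods

## The model

`countssm` models a scalar daily event-count series `y_t` (t = 1..T) as a
nonlinear observation of a linear Gaussian latent process driven by known
external inputs — in the motivating application, the daily dosages of
several drugs and the daily number of epileptic seizures:

    x_t = A x_{t-1} + B_u u_t + eta_t,   eta_t ~ N(0, Q)
    y_t = f(C x_t) + eps_t,              eps_t ~ N(0, r)

The state is partitioned into independent blocks, and `A`, `Q` are
block-diagonal with identical partitions:

* **Drug blocks** (one per control input): a deterministic AR(1) response
  `x_t = a x_{t-1} + b u_t` with carry-over coefficient `a ∈ [0, 0.99)` and
  control gain `b`. The block's row of `Q` is zero — the response to a
  known dosage is deterministic. The sign of `b` is the clinical verdict:
  negative means the drug reduces the event rate.
* **One ARMA(2,1) block** for temporally correlated fluctuations unrelated
  to the inputs. It is realized in the two-state innovations form
  `A_blk = [[a1, 1], [a2, 0]]` with noise gain `g = [1, b1]^T` and
  `Q_blk = sigma^2 g g^T`, so that with the fixed unit observation weight
  the block's first state is exactly the ARMA(2,1) process
  `x_t = a1 x_{t-1} + a2 x_{t-2} + eta_t + b1 eta_{t-1}` (verified in the
  test suite by driving the block and the scalar recursion with the same
  noise stream). Other internal 2-state realizations of the same process
  exist; this one was chosen because it honors the fixed-weight convention.

`C` is not estimated: it holds weight 1.0 on the first state of each block
and 0 elsewhere, and the ARMA block's control-gain rows are zero, to avoid
redundancy with `B_u`.

Counts are non-negative, so `f` must keep the model output non-negative.
Three nonlinear choices are provided besides the identity:

* `exponential`: `f(z) = exp(z)` — natural but divergent for large
  positive arguments, which is exactly what breaks EKF-type filters;
* `adh` (affinely distorted hyperbolic): `f(z) = z/2 + sqrt(z^2/4 + k)`,
  `k > 0` — vanishes like `k/|z|` for very negative `z` and approaches the
  line `z` for positive `z`, so it never explodes;
* `softplus`: `f(z) = k log(1 + exp(z/k))` — qualitatively the same shape
  as adh (both vanish on the left and become linear on the right), though
  the left tails differ in decay law (power law vs exponential), so the
  two functions agree closely only for arguments above ≈ 2.

Integer counts are interpreted as rounded observations of the continuous
model output ("quantization noise"); the simulator below makes this
explicit.

## State estimation

**Iterated EKF.** At each time point, after the linear prediction step
(`x_pred = A x + B_u u_t`, `P_pred = A P A^T + Q`), a Gauss–Newton inner
iteration relinearizes the observation around successive filtered-state
iterates `x^(i)` (initialized at `x_pred`): with `H = f'(C x^(i)) C`,

    nu      = y_t - f(C x^(i))
    nu_lin  = nu - H (x_pred - x^(i))      # relinearized prediction error
    V       = H P_pred H^T + r
    K       = P_pred H^T / V
    x^(i+1) = x_pred + K nu_lin

The iteration stops when the norm of the relative state change
`||x^(i+1) - x^(i)|| / max(||x^(i)||, 1e-30)` falls below `iter_tol`
(default 1e-10) or after `iter_max` iterations (default 100). The filtered
covariance uses the final-iteration `K`, `H`: `P = (I - K H) P_pred`,
symmetrized. The relinearized error `nu_lin`, not the raw residual, is the
innovation entering the likelihood: for the identity observation it
collapses to `y_t - C x_pred`, which makes the linear Kalman filter, the
IEKF and the SVD-IEKF produce identical log-likelihoods on linear models —
an equivalence the test suite asserts to 1e-6.

**SVD square-root IEKF.** The dense update `(I - K H) P_pred` can lose
positive definiteness in unlucky parameter regions, which derails both the
likelihood and the inner iteration. The square-root variant therefore
propagates every covariance as an SVD factor `M = W diag(sigma^2) W^T`:
`Q`, `R` and `P_0` are factorized once before the recursion, and each
update is a singular value decomposition of a stacked pre-array —

* time update: SVD of `[diag(sigma_P) W_P^T A^T ; diag(sigma_Q) W_Q^T]`
  (the structurally zero dynamical-noise rows are dropped: `Q` has rank 1
  for a single ARMA block, so the pre-array is `(m+1) x m`, not `2m x m`);
* innovation variance: squared column norm of `[s_R ; diag(sigma_P) W_P^T H^T]`
  (scalar data, so this SVD is a vector norm);
* measurement update: SVD of `[diag(sigma_P) W_P^T (I - K H)^T ; s_R K^T]`.

No subtraction of positive matrices ever occurs, so every covariance is
positive semi-definite by construction; the left factors of the SVDs are
discarded. Divergence is still possible for the exponential observation —
a non-finite prediction or a state norm beyond `state_norm_guard`
(default 1e50, far above plausible states but below overflow) aborts the
recursion with status `diverged` rather than raising.

Initial conditions: `x_0 = 0`, `P_0 = I` for all blocks (including the
deterministic ones, whose variance then contracts toward zero as data
arrive). The likelihood ignores the initial state's contribution, so this
proper, moderately diffuse choice has vanishing influence on a 500-day
series.

The three recursions are compiled with numba; iteration traces (one
relative-change norm per inner iteration per time point) are recorded and
exportable as CSV for convergence plots.

## Parameter estimation

The innovation likelihood is the Gaussian prediction-error decomposition

    logL = -1/2 sum_t (log V_t + nu_t^2 / V_t) - T/2 log 2 pi

with `nu_t`, `V_t` taken from the final inner iteration at each time
point. Models are compared by the corrected AIC,
`AICc = -2 logL + 2 Npar T / (T - Npar - 1)`, where `Npar` counts the
data-adaptive parameters (per drug: `a`, `b`; ARMA: `a1`, `a2`, `b1`,
`sigma`; plus `r`, and `k` when it is estimated — 11 for the default
three-drug model with `k` fixed at 1).

Optimization works in unconstrained coordinates: the drug AR coefficient
through a logistic map onto `[0, 0.99)`, the AR(2) pair through the
partial-autocorrelation (tanh) parameterization of the stationarity
triangle, `sigma` through `log`, and the observation noise through
`r = 1/12 + exp(phi)`.

**Why the observation-noise floor.** The observed counts are rounded model
outputs, so the effective observation error contains a quantization
component of variance 1/12. Without the floor the Gaussian innovation
likelihood is *unbounded*: a model can push all drug-phase states deep into
the flat region of `f`, predict the long zero-count stretches essentially
exactly, and then send `r -> 0`, gaining `-log r` per zero-count day. In
experiments this degenerate spike inflated the third drug's gain estimate
by a factor of about three while the likelihood grew without limit. The
floor removes the spike at its root and is the physically correct
statement that a rounded observation is never noise-free. Fitted `r`
values near `1/12 + true r` are therefore expected and correct.

A filter failure during optimization is penalized with `+inf`, never
raised, so the optimizer backs away from pathological regions. The default
optimizer is a Nelder–Mead exploration (150 iterations, objective
tolerance 1e-8) followed by a BFGS polish (15 iterations, numerical
gradients); both algorithms are available individually.

**Ensembles.** On a few hundred observations the likelihood surface has
many local optima, so a single fit is unreliable. `fit_ensemble` draws
`size` random starting points from documented ranges — drug `a ~ U(0.1, 0.9)`,
gains `~ U(-1, 1)`, `(a1, a2)` uniform on the 0.9-shrunk stationarity
triangle (rejection sampling), `b1 ~ U(-0.5, 0.5)`, `sigma` and `r - 1/12`
log-uniform on `[0.05, 1]` — optimizes each, and retains the minimum-AICc
member. All randomness flows from one seed; identical calls are
bit-identical. Members are classified by the worst behavior they
exhibited: covariance indefiniteness at any likelihood evaluation,
divergence at the optimum, or an inner iteration hitting its cap (checked
both for the randomly initialized model and at the optimum). Failures are
counted, never raised.

**Error bars.** Standard errors come from the central-difference Hessian
(step 1e-4 per coordinate, in each parameter's reporting scale) of the
negative log-likelihood at the optimum. Because the per-time inner
iteration makes the likelihood surface locally rough, these errors can be
far too optimistic; a non-positive-definite or singular Hessian is
surfaced as a reliability flag rather than silently inverted.

## Baselines

Two non-dynamic regressions provide the comparison floor, both without an
intercept (an `intercept` flag adds one) and both reporting AICc by the
same formula as the state space fits:

* Gaussian: OLS through the origin, residual variance with the
  maximum-likelihood divisor `T`, `logL = -(T/2)(log Sigma_n + log 2pi + 1)`;
  coefficient errors from the OLS covariance.
* Poisson: log-linear model fitted by Newton's method on the concave
  log-likelihood `sum_t [y_t eta_t - exp(eta_t) - log y_t!]`; errors from
  the inverse Fisher information. Boundary MLEs (for instance all-zero
  counts in a dosage phase) are capped at coefficient magnitude 30 and
  flagged. `Npar` counts the regression coefficients.

## The simulator

The generator emulates a 500-day diary of a simulated patient on three
drugs: AED1 (gain −0.40) and AED3 (−0.70) reduce the daily count, AED2
(+0.95) increases it. Dynamics and noise defaults are recorded constants:
drug carry-over 0.7 per drug (a visible multi-day delay), ARMA(2,1)
`(a1, a2, b1, sigma) = (1.2, -0.35, 0.2, 0.08)` (characteristic roots 0.7
and 0.5 — smooth, stationary background fluctuation), adh observation with
`C = 1`, `k = 1`, observation noise variance 0.04. The output is
`round(f(C x_t) + eps_t)` clamped at zero (rounding half away from zero);
everything is driven by one seeded generator, and the noise draws are
consumed even when a noise amplitude is zero, so switching a noise source
off does not shift the remaining stream.

The default dosage schedule is piecewise constant with three to four
titration steps per drug, staggered so that every drug has on, overlap and
withdrawal phases *and* so that each drug's dose changes while the
predicted count sits in the responsive range of the observation function.
The second point is essential for identifiability: a dose step taken where
`f` is flat (predicted counts pinned near zero) reveals only the
steady-state ratio `b/(1-a)`, not the gain and the carry-over separately —
an earlier two-step-per-drug schedule left the third drug's gain
identified only up to that ratio. The dose levels were calibrated once so
that the generated counts span 0–6 (checked over 30 probe seeds), a
realistic range for daily seizure counts; the calibrated schedule is a
recorded constant, not a runtime fit.

What the simulator does *not* emulate: missing diary days, misclassified
or missed events, dose–concentration pharmacokinetics, drug interactions,
over-dispersed count noise, and regime changes unrelated to dosage.
Passing the validation study therefore demonstrates that the estimation
machinery recovers the generating mechanism it assumes, not that the model
family is adequate for any particular real diary.

## Diagnostics

A well-specified model leaves innovations that are white. The whiteness
report compares the mean-removed sample ACF of the innovations (lags 1–30)
with the ACF of the raw counts. `AcfResult` carries the classical
one-standard-deviation reference band `1/sqrt(T)`; the pass rule, however,
evaluates coverage at two standard deviations, because a truly white
series leaves only ≈68% of sample-ACF lags inside the one-sd band but
≈95% inside two — a ≥90%-inside requirement is only meaningful at the
wider band. The report passes when at least 90% of innovation lags lie
inside `2/sqrt(T)` while the raw counts violate the same band at one or
more lags (the dosage phases persist for months, so raw counts are
strongly autocorrelated by construction).

## Validation study and problem sizes

The acceptance script (`scripts/acceptance.py`) regenerates the default
scenario, fits a 100-member SVD-IEKF ensemble, and reports the best
member's three control gains, its maximum inner-iteration count across the
500 time points, and the maximum generated count. The package's own
validation (the acceptance test suite) additionally contrasts the
square-root filter's zero indefiniteness failures with the plain IEKF's
non-zero failure count on ensembles of the same size, compares the best
model's AICc against both baselines, and checks innovation whiteness. The
ensemble size of 100 restarts was chosen as the smallest ensemble that
reliably reproduces the study's qualitative conclusions; a single
100-member fit of the default scenario takes a few minutes on one core.

## Known limitations

* Scalar data path only; the formulas are written so a vector-observation
  extension changes dimension checks and the innovation-variance
  factorization, not the architecture.
* ARMA order fixed at (2,1); no smoothing (filtered estimates only); no
  missing-data handling — gaps in the diary are rejected at read time.
* Gain/carry-over separation is only as good as the dosage schedule's
  excitation; near-constant dosing identifies only `b/(1-a)`.
* Hessian-based error bars on iterated-filter likelihoods are frequently
  optimistic; treat the ensemble scatter as the more honest uncertainty
  summary.
* No global-optimization guarantee: the ensemble raises the probability of
  finding the global AICc minimum but does not certify it.
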