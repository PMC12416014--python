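# Methods

## Model

Longitudinal measurements y_i (length p_i, subject i = 1..n, N = Σ p_i
total measurements) follow a K-component mixture of normal linear
regressions with subject-level membership:

    f(y_i | X_i) = Σ_k π_k N(y_i; X_i θ_k, σ_k² I_{p_i}).

The conditional-independence, homoscedastic within-group covariance
σ_k² I is the classical trajectory-analysis assumption; unstructured or
autocorrelated Σ_ik, random effects (GMM) and non-normal component
families are out of scope. Design matrices are built from time only:
polynomial bases [1, t, …, t^d] or a broken stick [1, t, (t−κ₁)₊]. Times
are used as given, in raw units, with no centering; within-subject row
order is preserved from the input file and never re-sorted.

## Scaled Box-Cox transformation

For strictly positive responses the Box-Cox transform is
y(λ) = (y^λ−1)/λ (λ≠0), log y (λ=0). Likelihoods of differently
transformed data are not directly comparable: the change of variables
contributes a Jacobian Π y_ij^{λ−1} = ỹ^{N(λ−1)}, with ỹ the geometric
mean. The scaled transform divides by ỹ^{λ−1},

    w(λ) = (y^λ − 1) / (λ ỹ^{λ−1}),   w(0) = ỹ log y,

which makes the log-Jacobian identically zero — equivalently,
Σ_ij (λ−1)(log y_ij − log ỹ) = 0 — so maximized log-likelihoods on the
w-scale are commensurate across λ and satisfy

    l_w(λ) = l_BC(λ) + N(λ−1) log ỹ,

where l_BC is the maximized likelihood of the plain Box-Cox data. The
implementation uses the ỹ^{N(λ−1)} Jacobian orientation, which is the one
under which this equivalence holds (tests verify it numerically against
closed-form single-component fits and against the textbook Box-Cox profile
likelihood for intercept-only models).

Numerical choices: powers are evaluated as exp(λ log y) and the geometric
mean in log space, so large N and extreme λ do not overflow; |λ| < 1e-10
is routed to the log branch (continuity makes the cutoff immaterial at
double precision). Nonpositive responses are a hard error; for
semicontinuous data (point mass at zero) an explicit additive shift c may
be supplied and is recorded in all outputs — no default shift is assumed.

For balanced designs (all p_i equal) estimates transfer to the Box-Cox
scale via θ*_k = ỹ^{λ−1} θ_wk, σ*_k = ỹ^{λ−1} σ_wk, π unchanged. The
conversion carries a slight bias and is refused for ragged p_i.

## EM fitting

Membership is subject-level: responsibilities form an n × K matrix.

* E-step: r_ik ∝ π_k f_k(y_i | X_i), computed via log-sum-exp.
* M-step: θ_k solves least squares with subject weight r_ik applied to all
  of subject i's rows; σ_k² = Σ_i r_ik ‖y_i − X_i θ_k‖² / Σ_i r_ik p_i;
  π_k is the mean responsibility.
* Initialization: a random crisp partition of subjects into K non-empty
  groups followed by an M-step. `fit_multistart` runs the EM from
  `n_restarts` seeded partitions (restart r uses seed + r) and keeps the
  highest likelihood; a single start suffices for K = 1, whose fit is
  start-independent.
* Convergence: relative log-likelihood change below tol = 1e-6, cap 200
  iterations. The returned log-likelihood is always re-scored against the
  returned parameters.
* Degeneracy: a fit is flagged when any π_k < 0.05 (`min_prior`) or any
  σ_k² falls below 1e-10 × var(y). Degenerate fits are never preferred
  over non-degenerate ones and are excluded from model selection; a K
  whose every restart degenerates is skipped (and reported), which is the
  expected behaviour when K exceeds the number of separable groups.
* Label switching: components are reported sorted by fitted mean at the
  earliest observed time point, ascending, making all outputs invariant to
  the internal component numbering. MAP classification breaks ties toward
  the smaller component index.

The EM inner loop is compiled with numba for speed; the package also
contains plain-numpy `e_step` / `m_step` implementations which are the
reference the compiled kernel is tested against.

## Model selection

h = Kq + K + (K−1) free parameters, plus 1 when λ is estimated. Then

    AIC = −2l + 2h,   BIC = −2l + h log N,   ICL = −2l_ICL + h log N,

with N the total number of measurements (not the number of subjects) and
l_ICL the classification likelihood under MAP assignment, computable as
l + Σ_i log max_k r_ik — hence ICL ≥ BIC with equality exactly at crisp
posteriors. Whether λ counts toward h is configurable
(`count_lambda_in_h`): published analyses exist under both conventions,
and the two differ by a constant 2 (AIC) or log N (BIC) per row, which can
matter in close calls. Counting λ is the default.

λ is estimated per K by maximizing the scaled likelihood — not by
minimizing the criterion jointly over (K, λ) — either on a user grid
(default [−2, 2] step 0.05) or by a three-stage successive refinement: 11
points over [−5, 5] (step 1.0), 11 over best ± 1 (step 0.2), 11 over
best ± 0.2 (step 0.04): exactly 33 likelihood evaluations, final
resolution 0.04, exact on unimodal profiles. Stage centers are clipped so
refinement grids never leave the search range. K then minimizes the chosen
criterion across the per-K optima; ties within 1e-6 go to the smaller K
(parsimony).

## Synthetic data

Two study designs are built in; both are first-class, tested generators.

* Lognormal mixtures (M1/M2/M3): y_ij = exp(η_k(x_j) + ε_ij),
  ε ~ N(0, 0.5²), x_j = (j−1)/9, j = 1..10, n = 200. Means: M1 {1+0.2x};
  M2 {1, 1+x} with π = (0.6, 0.4); M3 {1, 1+x, 1+x+x²} with
  π = (0.5, 0.3, 0.2). The error sits inside the exponent, so log y is
  exactly a normal mixture and the nominal transformation is λ = 0.
* Gamma-error mixtures (S1–S4): y_ij = η_k(x_j) + ε_ij with means
  {1, 1+2x}, x_j = (j−1)/5, j = 1..6, ε ~ Gamma(shape 2, scale 1) (mean 2,
  variance 2, right-skewed). Setups: S1 (n=200, π=.5/.5), S2 (200, .8/.2),
  S3 (500, .5/.5), S4 (500, .8/.2).

Labels are drawn first, then the full error matrix, from numpy's PCG64
generator; a (scenario, seed) pair is reproducible across platforms.
`simulate_custom` generalizes both (arbitrary mean functions, normal/gamma
/noise-free errors, identity or exp link).

What these generators emulate — and what they do not: mixture structure,
skewness and the transformation's role in recovering K. They have a shared
time grid, no missing visits, no dropout, no covariates beyond time, no
within-subject autocorrelation, and i.i.d. errors. Passing tests therefore
demonstrate correct recovery under the model's own assumptions, not
robustness to the violations real cohort data exhibit.

## Evaluation tools

Adjusted Rand index (Hubert–Arabie, via scikit-learn, validated in tests
against a brute-force pair-count), cluster purity, and a Shapiro–Wilk test
on pooled standardized within-component residuals (MAP assignment;
samples above 5000 are randomly subsampled, seeded, to stay in the test's
validity range).

The study harnesses (`run_study1`, `run_study2`) replay the full
simulate → profile-λ → select-K pipeline over replicates and tabulate
selected-K counts per criterion (study 1: grid λ, AIC/BIC/ICL,
transformed and untransformed arms; study 2: optimized λ search, BIC,
k ≤ 4, plus adjusted Rand indices of the selected classification).
Replicate r of model/setup m uses seed = base + m·replicates + r, so any
table cell can be re-derived in isolation and results are independent of
execution order.

## Problem sizes used in the shipped checks

The package's own verification runs use desk-scale replications chosen to
keep a full check of both studies comfortable on one CPU: study 1 with 20
replicates per model (λ grid step 0.2 in the test harness, step 0.05 in
`scripts/acceptance.py`) and 5 EM restarts; study 2 with 25 replicates per
setup and 5 restarts. Full-scale runs (100 replicates, 10 restarts, grid
step 0.05) are a flag away via `trajmix reproduce` and tighten the
binomial error bands but do not change the qualitative results.

## Known limitations

* The equal-variance, independence-within-group covariance can itself
  drive group composition; alternatives are not implemented.
* Estimate conversion to the Box-Cox scale requires balanced p_i and is
  slightly biased.
* The λ profile is assumed well-behaved for the refinement search;
  multimodal profiles can pin λ̂ to a local basin (the brute-force grid is
  the safe fallback).
* Zero responses must be handled explicitly via the shift option; the
  package deliberately takes no default.
* ICL's hard assignment uses MAP responsibilities; soft-assignment
  variants of ICL are not offered.
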