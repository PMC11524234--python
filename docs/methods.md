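# Methods

## The trial model

The unit of analysis is a randomized-complete-block provenance trial:
`p` provenances × `b` blocks, `n` trees planted per plot. For a trait
`y` measured on living trees the observation model is

    y = Xβ + Zu + ε,

where `β` holds the intercept and block effects (fixed; blocks absorb
site heterogeneity), `u` stacks provenance effects `~ N(0, V_P I)` and
provenance×block interaction effects `~ N(0, V_PB I)`, and
`ε ~ N(0, V_e I)`. Mortality makes surviving plot counts `n_ij`
unequal, so the design is unbalanced and the components are estimated by
restricted maximum likelihood rather than ANOVA moments.

Wood properties are measured on a few cored trees per provenance with no
block replication, so the wood-trait model is intercept + provenance +
residual only: the interaction term is structurally absent
(`model="wood"` in `fit_lmm_reml`).

### REML algorithm

`MixedModelREML` iterates EM-REML with an average-information (AI)
acceleration: each iteration forms both the EM update and an AI/Newton
candidate and keeps whichever has the higher restricted log-likelihood.
Because the EM candidate can never decrease it, the likelihood path is
non-decreasing by construction (asserted in tests), while the AI step
supplies the fast terminal convergence plain EM lacks. All per-iteration
quantities — BLUPs, traces, scores, the AI matrix and the restricted
log-likelihood — derive from a single Cholesky factorization of the
mixed-model-equation matrix `C = [[X'X, X'Z], [Z'X, Z'Z + D_λ]]` with
`λ_k = V_e/V_k`, via the identities `Pw = (w − T C⁻¹T'w)/V_e` and
`−2ℓ_R = (n − rank X)·log V_e + Σ_k q_k log(V_k/V_e) + log|C| + y'Py + c`.

Numerical choices:

- convergence when the relative parameter change is below `1e-8` or the
  log-likelihood change below `1e-10`; `max_iter = 500`; exceeding it
  raises with the last iterate and score norm;
- components are constrained to `[0, ∞)`: candidates are floored at
  `1e-10·var(y)`, and a component below `1e-7·var(y)` for 5 consecutive
  accepted iterations is dropped and flagged NE ("not estimated, assumed
  zero"), after which the reduced model continues to convergence;
- standard errors are square roots of the diagonal of the inverse AI
  matrix at the optimum (pseudo-inverse if singular); for NE components
  the AI matrix is evaluated with the component held at numerical zero.
  Asymptotic SEs at a boundary are indicative only;
- the implementation is cross-checked in the tests against the balanced
  one-way closed form (`V_e = MS_within`, `V_P = (MS_b − MS_w)/n`) to
  1e-6 and against an independent mixed-model REML implementation (lme4)
  on unbalanced data.

### Covariance components and correlations

Trait-pair provenance and error covariances use the variance-of-sum
identity `Cov(a,b) = [Var(a+b) − Var(a) − Var(b)]/2` on three univariate
REML fits, then are clipped to the geometric-mean bound so implied
correlations lie in `[−1, 1]`. If either marginal provenance variance is
NE the provenance covariance (and `r_g`) is NE. The phenotypic
correlation uses provenance plus error components only — the
interaction component is excluded by the formula's definition, which is
followed as printed even though one could argue for absorbing it.
Correlation SEs use the delta method with a diagonal (independence)
approximation to the covariance of the three fits' components; this is
an approximation, adequate for flagging which correlations are
resolvable at all (with 10 provenance levels, most are barely so).

### Heritability and gain

Provenance heritability `h² = V_P/(V_e/(n_h b) + V_PB/b + V_P)` uses the
harmonic-mean surviving plot size `n_h = (#non-empty plots)/ΣΣ(1/n_ij)`;
empty plots are excluded with the numerator reduced, since the harmonic
mean is undefined at zero. Balanced data give `n_h = n` exactly. When
reproducing the published heritability table from its printed
components, `n_h = 4.0` is used — the value consistent with the
published figures under 10 blocks, 5-tree plots and ~80 % survival
(`provtrial.reproduce.DEFAULT_N_H`).

Superior-provenance selection takes the overall (mean of provenance
means) value of two traits as thresholds; a provenance is selected when
it strictly exceeds both. Realized gain uses the unweighted mean of the
selected provenances' means. The library computes gains exactly; the
`reproduce` helpers additionally round means to two decimals first,
because the published gain table is a function of its display-rounded
means (e.g. volume 0.09 vs 0.08 → 12.50 %, where the unrounded means
would give 5.4 %).

### Duncan's multiple range test

One-way (provenance) ANOVA supplies `MS_e` and `df_e`; unequal group
sizes enter through the harmonic-mean group size (the standard
field-trial convention). The span of `k` adjacent ranked means is tested
against `q*(α_k, k, df_e)·√(MS_e/n_h)` with protection level
`α_k = 1 − (1−α)^(k−1)`, step-down (sub-spans of a homogeneous span are
not re-tested), and the usual contiguous letter display. At `k = 2` the
procedure reduces exactly to a pooled two-sample t-test
(`q(α,2,df) = √2·t(α/2,df)`), and under a zero-provenance-variance null
the probability of a single letter group is `(1−α)^(p−1)` — both are
asserted in the tests (0.95 for p = 2, ≈0.81 for p = 5 at α = 0.05).
Ties in means are broken by provenance code for determinism.

### Trend surfaces

Ordinary least squares on the raw-coordinate quadratic basis, matching
how such surfaces are conventionally fitted and reported: no centering
or scaling (a condition-number warning is emitted above 1e10),
observations are individual trees tagged with their provenance's
coordinates — which is why the fits have tiny R² yet strong
significance: hundreds of residual degrees of freedom against only a
handful of distinct locations. The F test uses (5, n−6) df. Grid
evaluation pads the data hull by 0.5° and writes a long-format lattice,
leaving contouring to any plotting layer.

## The synthetic generator

`simulate_trial` draws, from one seeded generator in a fixed order
(blocks, provenance effects, interaction effects, residuals, survival):
block effects (drawn once per trial, then treated as fixed — matching
the analysis model's fixed-block assumption), provenance effects from a
multivariate normal `G_P` across traits, interaction effects
independently per trait, residuals from `R` across traits, and i.i.d.
Bernoulli survival (the trial reports no mortality mechanism, so
independence is the neutral choice). Defaults are the study conditions:
10×10×5, survival 0.8, DBH/height-like traits with components
(0.47, 0.08, 8.97) and (0.23, 0.26, 5.46), genetic correlation 0.97,
grand means 12.52 cm and 11.98 m, block SD 1.0 (chosen once as a
realistic level of site heterogeneity). Phenotypes are floored at a
small positive value because living trees must have positive
measurements; at realistic parameters the floor is never hit.

What the generator does **not** emulate: spatial autocorrelation within
blocks, competition between neighbours, non-normal trait distributions,
measurement rounding, or any structured mortality. Passing
parameter-recovery tests therefore demonstrates correctness of the
estimation machinery under the assumed model, not robustness to field
realities outside it.

## Small-sample limits of the design (known limitations)

With only `p = 10` provenance levels the provenance variance carries a
sampling SD of roughly `√(2/(p−1))·(V_P + V_e/(n_h b) + V_PB/b) ≈ 0.34`
for the DBH-like trait — comparable to the component itself. Three
consequences, all visible in the 200-replicate recovery study the test
suite runs and worth stating plainly:

- the interaction component `V_PB = 0.08` is essentially unidentifiable
  at this design (its moment-estimator SD is ≈0.3), so the boundary
  constraint inflates its mean estimate to ≈0.19; no constrained
  estimator can avoid this;
- per-replicate `h²` is a concave function of the noisy `V_P`, so its
  mean (≈0.54) sits below `h²` at the true components (≈0.65) by Jensen's
  inequality, even though the component estimates themselves are nearly
  unbiased;
- genetic correlations estimated from 10 provenance effects are
  extremely noisy (SD ≈ 0.46 around a true 0.8, with clipping at ±1),
  so single-trial `r_g` values should be read as order-of-magnitude
  statements only.

The corresponding acceptance-level recovery test asserts the idealized
targets and documents these gaps rather than hiding them; the
well-identified quantities (`V_P`, `V_e`, their reported SEs, selection,
all closed-form results) recover cleanly.

## Problem sizes used in the test suite

Recovery studies use 200 replicates of the 10×10×5 study design (the
conditions above), the Duncan null calibration 1000 two-group trials,
and the remaining oracle tests small deterministic fixtures; the full
suite runs in well under a minute on one CPU, excluding the two shared
200-replicate fixtures (~20 s).
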