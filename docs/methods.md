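# Methods

## Data model and preprocessing

A *flock-week record* summarizes one flock's intake and reproductive
output for one week of hen age: age (weeks), daily feed intake
(g/bird/d), either precomputed daily nutrient intakes (ME in kcal/bird/d;
dLys/dMet/dThr in g/bird/d) or the dietary composition they derive from,
and the response — chicks produced per hen per week, a composite of egg
production, fertility and hatchability. Intakes are recalculated from
composition as

    dAA intake = feed [g/d] × concentration [g/100 g] / 100 × digestibility
    ME intake  = feed [kg/d] × ME concentration [kcal/kg]

Amino acid concentrations are g per 100 g feed; this unit convention is
fixed in the CSV schema to avoid ambiguity. Records are stratified into
early (26–32 wk), mid (33–50 wk) and late (51–62 wk) production.

Quality control is deliberately mechanical rather than graphical:
records are rejected against configurable physiological bounds
(`range:<field>` reasons) and missing required fields; an optional
per-phase Tukey fence (1.5×IQR beyond the linearly interpolated
quartiles) flags outliers, and only rejects them when explicitly enabled.
Fitting uses complete cases for (intake, response); there is no
imputation. The default bounds are exposed configuration, not claims
about any particular dataset.

## Dose–response model

Mean response: `y = A·tanh(c·x + b) + B`. `A` and `B` are in response
units (chicks/hen/week), `c` is per nutrient unit, `b` dimensionless.
The curve is monotone increasing when `A·c > 0`; its asymptote is
`A + B`. The sign symmetry `(A, b, c, B) ↔ (−A, −b, −c, B)` is resolved
by always reporting the `A > 0` representative.

### Estimation

Both axes are min-max scaled to [−1, 1] before fitting — this conditions
the tanh and makes the weight penalty scale-free; it also makes the fit
exactly equivariant under affine changes of nutrient units (kcal vs
Mcal), since the scaled problem is identical. The objective is

    F = β·E_D + α·E_W,  E_D = ½ Σ r_i²,  E_W = ½ (A_s² + b_s² + c_s² + B_s²)

minimized in scaled space by Levenberg–Marquardt on penalty-augmented
residuals (`scipy.optimize.least_squares`, analytic Jacobian). After each
converged inner solve the hyperparameters are re-estimated by the
evidence approximation with the Gauss–Newton Hessian `H = β·JᵀJ + α·I`:

    γ = 4 − α·tr(H⁻¹),  α ← γ/(2·E_W),  β ← (n − γ)/(2·E_D)

iterated until the objective changes by < 1e−9 (relative) and both
hyperparameters by < 1e−6, capped at 300 outer iterations. `γ ∈ [0, 4]`
is the effective number of parameters. `β` is capped at 1e12 so that
noiseless data (E_D → 0) degrade gracefully to an essentially
unregularized least-squares fit (α/β ≲ 1e−12); for constant responses
the penalty shrinks `A` to zero and the requirement is reported invalid
downstream rather than extrapolated.

Ten restarts are drawn uniformly from [−1, 1]⁴ under a seeded generator;
the best converged restart by final objective (ties by RMSE) wins.
Parameters are back-transformed to original units analytically
(`A = A_s/g_y`, `c = c_s·g_x`, `b = c_s·h_x + b_s`, `B = (B_s − h_y)/g_y`
for the affine maps `x_s = g_x·x + h_x`, `y_s = g_y·y + h_y`); tests
verify this path agrees with evaluating the scaled model through the
scaler to 1e−9.

RMSE is reported as `sqrt(SSE/n)` — not the df-corrected variant — and
the same convention is applied to the OLS benchmarks, so linear,
quadratic and tanh fits are compared on an identical scale.

### Requirements

`Req_p = (arctanh((p·(A+B) − B)/A) − b)/c`, valid iff `c > 0` and the
arctanh argument lies strictly inside (−1, 1); otherwise the estimate is
flagged `non-increasing curve` or `target outside response range`. The
default fraction p = 0.95 balances output against oversupply; 0.90 or
0.97 are configurable alternatives. A bracketing-bisection oracle that
solves the level equation with forward tanh evaluations only is kept in
the package for independent verification; tests require agreement to
1e−8 over randomized valid parameter sets.

## Uncertainty and phase comparison

Nonparametric case-resampling bootstrap (default 100 replicates):
each replicate resamples records with replacement, refits, and
recomputes Req_p. Replicate refits warm-start from the full-data
solution (one start by default) — with n in the hundreds-to-thousands the
replicate likelihood is a small perturbation of the original, so cold
multi-starts would add cost without changing the optimum; the restart
count is configurable for harder data. Replicates whose refit fails or
whose requirement is invalid are dropped and counted, with their
sub-seeds logged for replay; a run fails above 50% failures. CIs are
percentile intervals (linear-interpolated quantiles); BCa is deliberately
not implemented. Replicate r derives its resample indices and fit seed
from the r-th child of `SeedSequence(seed)`, making every run
deterministic and the point estimate independent of the replicate count.

Phases are compared by pairing replicate i of one phase with replicate i
of the other (phases use disjoint data, so any pairing is valid; index
pairing keeps determinism) and computing the two-sided resampling
p-value `min(1, 2·min(P(d≤0), P(d≥0)))` with the (count+1)/(R+1)
correction — p is floored at 2/(R+1), i.e. ≈0.02 at 100 replicates. No
multiplicity adjustment is applied across the three pairwise tests by
default. Results are summarized as a compact letter display
(insert-and-absorb), letters assigned in descending order of point
estimate.

Notched boxplot summaries of replicate distributions use quartiles by
linear interpolation, whiskers at the most extreme values within
1.5×IQR, notch = median ± 1.57·IQR/√n, and a seeded 1,000-replicate
percentile bootstrap CI for the mean.

## Synthetic scenarios

The generator draws intakes uniformly over a design range, evaluates the
true tanh curve, adds homoscedastic Gaussian noise, and clips responses
at zero (chick output cannot be negative; with the default scenario
floors the clip affects ≲0.1% of draws except the noisiest early-phase
presets, where it touches ~2% of the lowest-intake tail). Ages are
uniform within the phase. Each of the twelve presets fixes:

- **published conditions** — phase sample sizes 515/1,471/699; true
  Req95% equal to the published point estimates (e.g. 1.03 g/d dLys at
  mid); noise SD equal to the published model RMSEs per nutrient and
  phase (dLys reuses the dMet values, whose fit quality was reported as
  nearly identical);
- **assumed geometry** (`scenario_defaults.yaml`, versioned) — response
  ceilings 4.2/5.6/4.6 and floors 0.8/2.0/1.2 chicks/hen/week for
  early/mid/late, curve midpoint at 0.95×Req95%, and a uniform intake
  design range of 0.85–1.05×Req95%, reflecting commercial flocks fed
  near guideline levels. These are not published values. The geometry
  was calibrated once against the precision the published bootstrap CIs
  imply (e.g. the early-phase ME CI of 449.0–458.4 kcal/d): with the
  design concentrated on the curve bend, the early-phase requirement has
  a sampling SE of ≈1.7 kcal/d, comparable to the study's, and the
  early-vs-mid ME difference is detectable as reported. The defaults
  file records the values; they are not tuned per analysis.

What the generator does **not** emulate: flock identity and repeated
measures (records are i.i.d., while real flock-weeks are autocorrelated
within flock), heteroscedasticity across the intake range, covariates
(season, house, health), non-uniform intake distributions, and any
between-nutrient correlation (each scenario varies one nutrient at a
time). Passing tests therefore demonstrate that the estimation machinery
recovers known truths under the stated statistical structure — not that
the model is correct for any particular commercial dataset.

## Problem sizes

The validation suite uses the preset sample sizes directly (n up to
1,471). Stochastic recovery is assessed over 50 simulated datasets at
the mid-phase preset; bootstrap CI coverage over 100 simulated datasets
with 50 bootstrap replicates each — replicate counts chosen as the
smallest giving stable pass/fail behaviour for these checks. The
acceptance script fits all twelve scenarios at full size and bootstraps
the ME early/mid phases at 100 replicates.

## Known limitations

- Homoscedastic Gaussian noise is assumed throughout; a single RMSE per
  fit is reported accordingly.
- Percentile CIs from small replicate counts (≤100) are mildly
  anticonservative; measured coverage at nominal 95% is ≈92% over
  repeated simulations.
- The evidence-framework updates use the Gauss–Newton approximation to
  the Hessian; for severely misspecified curves γ can be optimistic.
- The population-level treatment ignores flock random effects; standard
  errors on real field data will be understated to the extent flocks are
  autocorrelated.
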