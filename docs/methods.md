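# Methods

## Model and assumptions

The package models the fast plasma dynamics of glucose (G), insulin (I)
and glucagon (A) during a 240-min isoglycemic intravenous glucose
infusion (IIGI) with three coupled delay differential equations (see the
README for the equations).  The modelling assumptions are:

* Glucose clearance has a glucose-dependent first-order term (rate
  `SG`) and an insulin-dependent bilinear term (`a1·I·G`); hepatic
  glucose production is first order in glucagon (`a2·A`), treating other
  substrates (glycogen) as in excess.  Insulin-dependent suppression of
  hepatic glucose production is *not* modelled, nor are somatostatin or
  incretin states or hepatic insulin extraction — the experiment is
  designed to exclude gut-mediated effects, and the remaining couplings
  are not identifiable from these data.
* Insulin and glucagon are cleared first order (`n1`, `n2`) and secreted
  under glucose control through dose-response functions ψ and φ.
  ψ is sigmoidal (Hill) with half-max `K` = 17 mM fixed from human-islet
  dose-response data; φ declines exponentially in glucose.
* Both dose-response functions may switch behavior at the **hysteresis
  anchor** — the maximum of the glucose curve, `(G_hyst, t_hyst)`.
  Insulin secretion may follow different Hill steepnesses while glucose
  rises (`h1`) and falls (`h2`, model 2); glucagon suppression (`e^{-k1 G}`)
  gives way to a slower recovery (`e^{-k2 G} + yshift`,
  `yshift = e^{-k1 G_hyst}`) that stays depressed through the end of the
  experiment, a phenomenological stand-in for glucose-driven paracrine
  regulation.
* Subjects enter at an overnight-fast steady state: the history for
  t ≤ 0 is the constant initial state.
* A single secretion phase is assumed; first-phase insulin bursts
  (triggered in some subjects by infusion overshoot) are outside the
  model, which is why such subjects were excluded from the original
  cohort and are not emulated by the generator.

### Units

`G` is carried internally in mg/dL (matching `a2`'s units and the
infusion term `R/V` with `V` in dL/kg), while ψ and φ take glucose in mM
(matching `K`, `k1`, `k2`); the conversion constant is 18.016 mg/dL per
mM.  Insulin is carried in units of 10 pM so that `a1` (in
(10 pM·min)⁻¹) and `gamma1` (10 pM/min) keep their conventional table
scales; data files carry pM and are divided by 10 at ingestion.  Only
this mixed convention reproduces the magnitudes of the published
parameter tables.  All unit conversions happen at the I/O boundary.

### The yshift discontinuity

As written, φ jumps by `e^{-k2·G_hyst}` at the switch (the falling
branch at `G_hyst` is `e^{-k2 G_hyst} + e^{-k1 G_hyst}`, the rising
branch `e^{-k1 G_hyst}`).  The formula is implemented exactly as
printed; a continuity-corrected mode
(`yshift = e^{-k1 G_hyst} − e^{-k2 G_hyst}`) is available behind the
`continuity_corrected` flag, default off.  Branch selection for both ψ
and φ uses undelayed time `t` relative to `t_hyst`.

## Parameters

| symbol | meaning | units | default / treatment |
|---|---|---|---|
| SG | glucose-dependent clearance | min⁻¹ | fixed 0.014 |
| a1 | insulin sensitivity | (10 pM·min)⁻¹ | estimated |
| a2 | glucagon action | mg/dL·(pM·min)⁻¹ | estimated |
| n1 | insulin degradation | min⁻¹ | fixed 0.14 |
| n2 | glucagon degradation | min⁻¹ | fixed 0.08 |
| γ1 | insulin secretion scale | 10 pM·min⁻¹ | estimated |
| γ2 | glucagon secretion scale | pM·min⁻¹ | estimated |
| k1 | glucagon suppression | mM⁻¹ | estimated |
| k2 | glucagon recovery | mM⁻¹ | manual |
| h, h1, h2 | Hill coefficients | — | estimated, bounded [0.5, 4] |
| K | Hill half-max | mM | fixed 17 |
| ψ prefactor | dose-response scale | — | fixed 1.5 |
| τ, τ1, τ2 | delays: infusion arrival, insulin secretion, glucagon suppression | min | manual, ≥ 0 |
| V | glucose distribution volume | dL/kg | fixed 1.35 |

"Manual" parameters are held at supplied values during least squares
(the infusion profile's lack of smoothness makes the delays poorly
suited to gradient-based estimation); `grid_adjust_manual` systematizes
their selection by refitting over finite grids and keeping the lowest
weighted SSE, breaking ties toward smaller delays, then smaller k2.

## Estimation

Weighted residuals are `(y_data − y_model)/(CV·y_data)` with assay CVs
2% (glucose), 3% (insulin), 5.5% (glucagon), concatenated over analytes
(glucose, insulin, glucagon) and time; an assay floor (0.5 mM, 5 pM,
1 pM) caps the weight of points near the detection limit.  CV weighting
is the default; raw residuals are available as `weighting="unweighted"`
(the original analysis weighted only some subjects, which subjects being
unrecorded — a flag reproduces both behaviors).

Minimization uses scipy `least_squares` with the trust-region-reflective
algorithm — a Levenberg-Marquardt-style damped Gauss-Newton that, unlike
the classical LM implementation, honors bounds (all free parameters
positive; Hill coefficients in [0.5, 4], spanning all published
estimates with margin).  Because some fits are sensitive to starting
values, seeded multi-start is built in (default 5 starts: the group's
published mid-range values plus log-uniform jitter; best SSE kept).
The hysteresis anchor is detected from the measured glucose samples
(raw-sample argmax over t ≥ 0, ties to the earliest time); the initial
state is the mean of the baseline (t ≤ 0) samples.

Standard errors come from the Gauss-Newton covariance
`(JᵀJ)⁻¹·RSS/(n−p)`; p-values are two-sided Student-t with n−p degrees
of freedom (the reference distribution of the original software is
unrecorded; t is the standard choice).  Adjusted R² is computed on the
weighted scale, with the weighted total sum of squares about the
weighted-data mean — the definition under weighted regression is not
standardized, so this choice is documented rather than assumed.  AICc
uses the Gaussian RSS-profile likelihood with additive constants
dropped, `AICc = n ln(RSS/n) + 2p + 2p(p+1)/(n−p−1)`; only AICc
*differences* on a shared dataset are meaningful, so the dropped
constant is irrelevant and absolute values are not comparable across
packages.

Exact Mann-Whitney p-values are computed by full enumeration of group
labelings (two-sided `2·min(P(U≤u), P(U≥u))`, capped at 1, midranks for
ties) whenever the labeling count is at most 125 000 — which covers the
7-vs-7 group comparisons of interest — and by a tie-corrected normal
approximation with continuity correction beyond that.  Spearman rank
correlation is the Pearson correlation of midranks, with exact
permutation p for n ≤ 8 and the t-approximation otherwise.

## Simulation

The delay system is integrated by the **method of steps**, restarting
the integrator at every discontinuity image: infusion-block edges
shifted by τ, the hysteresis switch `t_hyst` (and its images under τ1,
τ2), and the ends of the constant history.  Two backends:

* `adaptive` (default for forward simulation): scipy RK45 per segment,
  rtol 1e-8 / atol 1e-10, with segments capped at the smallest positive
  state delay so delayed-glucose lookups always hit completed dense
  output.
* `rk4` (default inside the fitting loop): a numba-compiled fixed-step
  classical RK4 on the same restart grid, cubic-Hermite interpolation of
  the delayed glucose history, default step 0.1 min.  A fixed step makes
  the objective smooth in the parameters (no adaptive-step noise in
  finite-difference Jacobians) and is ~100× faster; against a
  Δt = 0.01 min reference the adaptive and fixed-step solutions agree to
  ~3×10⁻⁴ sup-norm relative, far inside the accuracy the data support.

Negative concentrations are never reflected; values in [−1e-8, 0)
(roundoff) are clamped to zero at sampling, anything more negative is an
integration error.  The integrator and tolerances of the original
analysis are unrecorded; the defaults above are this package's choice.

**Forward-mode anchor detection.**  In fitting mode the anchor comes
from data, but a pure-forward simulation needs the glucose maximum of
the very solution being computed.  The simulator first runs the
rising-branch-only model and takes the dense argmax
(`detect_anchor_forward`), then re-simulates with the anchor fixed.  The
generator goes one step further (`simulate_sampled`): it iterates the
anchor to the fixed point of *simulate → sample → raw-sample argmax*, so
the anchor embedded in a generated series is exactly the one the fitter
will detect, making generator and fitter mutually consistent (noiseless
refits recover free parameters to ~1e-12).  Rare draws whose glucose
maximum alternates between two near-equal peaks have no such fixed point
and are rejected and redrawn.

## Synthetic subjects

The generator emulates the study conditions:

* **Sampling** at the experimental blood-draw schedule: −15, −10, 0, 5,
  10, 15, 20, 25, 30, 35, 40, 45, 50, 60, 70, 90, 120, 150, 180,
  240 min (20 points).
* **Infusion profiles** discretized to 15-min blocks, total ≤ 75 g (the
  OGTT-matched ceiling): controls get a two-bump mixture (peaks near
  ~20 and ~65 min, finished within ~2 h), patients a single broad bump
  extending to ~180 min — the group shapes seen in the experimental
  arrival profiles.  Totals are drawn U(25, 45) g for controls and
  U(45, 75) g for patients: the infused total is the oral load minus the
  incretin-mediated saving, which is large in controls and small in
  diabetes.  Body weight U(75, 95) kg (a BMI-29-matched cohort).
* **Parameters** drawn uniformly within the published per-group ranges
  (`range_uniform`), or verbatim published rows (`table_resample`).
* **Baselines** from equilibrium algebra: fasting glucose drawn
  U(4.8, 6.0) mM (controls) / U(7.0, 10.0) mM (patients) — physiological
  conventions, as the cohort's fasting distributions are not published —
  then `I0 = γ1ψ(G0)/n1`, `A0 = γ2 e^{−k1 G0}/n2`, and `a2` derived to
  close the glucose balance, so pre-infusion trajectories are exactly
  flat as in the data.  In the alternative `a2_drawn` mode a2 is kept as
  drawn and fasting glucose is solved for instead.
* **Noise**: independent multiplicative Gaussian per analyte at the
  assay CVs (2/3/5.5%), truncated at zero.  Gaussian is chosen to match
  the weighted-least-squares likelihood; only the CVs themselves are
  experimental facts.

What passing the synthetic validation shows — and does not.  Recovery
and model-selection results demonstrate that the pipeline is correct and
well-conditioned *under the model*: data generated by the very equations
being fit, with independent multiplicative noise.  Real IIGI data add
model misspecification (5-min infusion adjustments averaged into 15-min
blocks, assay drift, correlated errors, baseline mismatch between OGTT
and IIGI days, first-phase secretion), so real-data errors will be
larger than the synthetic medians; the synthetic study is a lower bound
on attainable error, not a claim about clinical accuracy.

## Validation studies (problem sizes)

* **Recovery**: 20 synthetic control subjects at assay CVs; each fit
  with the true manual parameters held, single start from mid-range
  values.  Median relative errors: a few percent for all free
  parameters.  Noiseless refits (same 20 subjects, noise off, tolerances
  1e-14) recover free parameters to ~1e-12 — the generator/fitter
  consistency check.
* **Model selection**: 20 replicates per truth variant.  Hysteresis
  truth uses (h1, h2) = (1.0, 2.5) at one quarter of the assay CVs
  ("low noise"); single-Hill truth draws h within the control range at
  the same noise.  AICc prefers the hysteresis model in 20/20 replicates
  under hysteresis truth; under single-Hill truth the median |ΔAICc| is
  ~2 — the two extra-parameter penalty — consistent with AICc being
  unable to separate the models when there is no hysteresis to find.
* **Solver oracle**: 10 random per-group parameter draws, adaptive vs
  Δt = 0.01 min fixed step, sup-norm relative error < 0.1%; the jitted
  integrator is additionally cross-checked against an independent
  pure-Python method-of-steps implementation in the test suite.

These sizes keep the whole suite under a minute on one CPU while leaving
the Monte-Carlo margins (thresholds 15%/25%, majority preference) far
from their bounds.

## Known limitations

* The delays and k2 are selected, not estimated; their uncertainty is
  not propagated into the reported standard errors.
* `a2` trades off against `γ2` through the baseline glucagon level; its
  recovery is intrinsically wider than the other parameters'.
* The glucagon recovery branch never returns to baseline within 240 min
  by construction; extrapolation beyond the experiment window is not
  meaningful.
* Published summary SEMs were evidently computed from unrounded
  per-subject estimates: recomputing from the printed (2 s.f.) values
  reproduces 35 of 36 mean/SEM cells exactly and two SEM cells to one
  unit in the last printed digit.
* Group summary tables require ≥ 2 subjects per group; Mann-Whitney
  falls back to a normal approximation beyond ~125 000 labelings.
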