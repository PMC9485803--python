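# iigidyn

Coupled glucose–insulin–glucagon modelling of **isoglycemic intravenous
glucose infusion (IIGI)** experiments.

In an IIGI experiment an intravenous glucose infusion is manually
adjusted to replicate the plasma glucose profile of a prior 75-g oral
glucose tolerance test (OGTT), so the hormonal response is measured in
the normal physiological range without incretin and other gut-mediated
effects.  `iigidyn` implements a minimal delay-differential-equation
model of the resulting glucose (G), insulin (I) and glucagon (A)
dynamics, fits it per subject to three-analyte time series, and
quantifies insulin sensitivity, glucose-stimulated insulin response, and
— its distinguishing feature — glucagon action, secretion and
suppression, all in a single estimation step.

## The model

$$\frac{dG}{dt} = -(S_G + a_1 I)\,G + a_2 A + R_{\mathrm{IIGI}}(t-\tau)/V$$
$$\frac{dI}{dt} = -n_1 I + \gamma_1\, \psi\big(G(t-\tau_1)\big)$$
$$\frac{dA}{dt} = -n_2 A + \gamma_2\, \phi\big(G(t-\tau_2)\big)$$

* $R_{\mathrm{IIGI}}$ is the exogenous glucose arrival rate,
  reconstructed from the grams infused per 15-min block:
  $R = \mathrm{grams}/15 \times 1000 / \mathrm{weight}$ in mg/(kg·min).
* $\psi$ is the glucose-dependent insulin secretion drive.  Two variants
  are provided: **model 1**, a single Hill function
  $\psi = 1.5\,G^h/(K^h + G^h)$ with $K$ = 17 mM fixed from islet
  dose-response data; and **model 2**, a *hysteretic* pair of Hill
  curves — coefficient $h_1$ while glucose rises, and
  $C_1 G^{h_2}/(K^{h_2}+G^{h_2})$ after the glucose maximum
  $(G_{\mathrm{hyst}}, t_{\mathrm{hyst}})$, with $C_1$ chosen so the
  branches meet at the switch.
* $\phi$ is the glucagon secretion drive: $e^{-k_1 G}$ while glucose
  rises (suppression), and $e^{-k_2 G} + y_{\mathrm{shift}}$ with
  $y_{\mathrm{shift}} = e^{-k_1 G_{\mathrm{hyst}}}$ afterwards — a slower,
  persistently depressed recovery, as observed in IIGI glucagon data.

$S_G$ = 0.014 min⁻¹, $n_1$ = 0.14 min⁻¹, $n_2$ = 0.08 min⁻¹ and
$V$ = 1.35 dL/kg are fixed at literature values.  The free parameters
($a_1$, $a_2$, $\gamma_1$, $\gamma_2$, $k_1$, and $h$ or $h_1,h_2$) are
estimated by CV-weighted nonlinear least squares (assay CVs 2%, 3%, 5.5%
for glucose, insulin, glucagon); the delays $\tau,\tau_1,\tau_2$ and the
recovery constant $k_2$ are "manual" parameters, held fixed or selected
on a grid.  Model variants are compared per subject by small-sample-
corrected Akaike information criterion (AICc); groups (type-2-diabetes
patients vs weight-matched controls) are compared with exact
Mann–Whitney U and Spearman rank tests.

Because the original per-subject time series are not public, the package
ships the published per-subject fitted-parameter tables as fixtures and
includes a first-class synthetic-subject generator (group-shaped
infusion profiles, equilibrium-consistent baselines, assay-level noise)
so the entire pipeline is testable end to end without any download.

## Worked example

Generate one synthetic control subject, fit it, and compare with truth:

```bash
iigidyn generate --n-cs 1 --n-t2d 0 --seed 42 --out cohort
iigidyn fit --series cohort/CS01_series.csv --infusion cohort/CS01_infusion.csv \
    --weight 89.82 --tau 2.52 --tau1 5.87 --k2 0.4976 --out CS01_fit.json
```

The fit log reports `adj R^2 = 0.9951, AICc = -3.3`, and the report
contains

```
estimates: a1 8.38e-4  a2 0.246  gamma1 15.2  gamma2 5.37  k1 0.284  h 2.13
se:        a1 2.2e-5   a2 0.008  gamma1 0.43  gamma2 0.40  k1 0.011  h 0.037
```

against generator truth `a1 7.84e-4, a2 0.229, gamma1 15.1, gamma2 5.87,
k1 0.297, h 2.08` — every free parameter is recovered within a few
percent at assay noise.  Here `a1` is insulin sensitivity in
(10 pM·min)⁻¹, `a2` glucagon action in mg/dL·(pM·min)⁻¹, `gamma1`/`gamma2`
the insulin/glucagon secretion scales, `k1` the glucagon suppression
constant in mM⁻¹ and `h` the Hill coefficient of the insulin
dose-response.

The shipped cohort tables reproduce the published group summary:

```bash
iigidyn summarize --fixtures model1
```

```
parameter,CS_mean,CS_sem,...,T2D_mean,T2D_sem,...
a1,0.00052,0.00015,...,8.4e-05,7.5e-06,...
k1,0.26,0.048,...,0.16,0.015,...
h,1.9,0.14,...,1.4,0.15,...
```

— e.g. glucose-dependent glucagon suppression `k1` is 0.26 mM⁻¹ in
controls but 0.16 mM⁻¹ in type-2 diabetes, and the insulin-sensitivity
ratio between groups is ~6×.

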