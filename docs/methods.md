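# Methods

This note records the model, the estimation choices and their rationale,
what the synthetic data do and do not emulate, and the package's known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The Stress Addition Model (SAM) rests on three assumptions:

1. **Beta-distributed stress capacity.** Each individual tolerates a
   total general stress up to its capacity, distributed Beta(p, q) on
   [0, 1]. Survival under stress S is the beta survival function
   `N(S) = 1 - I(S; p, q)`, with the boundary conventions `N(0) = 1`
   and `N(S) = 0` for `S >= 1`. Symmetry (p = q) is imposed in
   calibration; the library accepts p ≠ q because the distribution
   family is general, but no asymmetric use case is established.
2. **Mortality as the common currency.** A stressor causing
   stand-alone mortality m exerts general stress `F⁻¹(m)` (the beta
   quantile). The transfer is agnostic to the stressor's physical units.
3. **Additivity of general stress.** Stress levels of *independent*
   stressors add; the sum is kept uncapped and the `S >= 1` rule is
   applied only when survival is evaluated. Independence means distinct
   modes of action (e.g. a neurotoxicant plus food limitation); two
   stressors hitting the same receptor belong in a concentration-
   addition framework instead.

Default shape: `p = q = 3.2`, the value recovered by the calibration
machinery on shift data (see below). All mortalities inside the library
are fractions; percent appears only at interface boundaries.

### Exact versus tabulated transfer

`mortality_to_stress` is the exact continuous beta quantile by default —
required for the quantile/CDF round-trip invariant (tested to 1e-9).
Spreadsheet-calculator workflows instead tabulate the stress axis in
steps of 0.01 and map a mortality to the first tabulated level whose CDF
reaches it, i.e. the quantile rounded *up* to the grid. The
`resolution=0.01` option reproduces that convention and with it the
classic worked example: 10% mortality → stress 0.26 (exact: 0.254),
15% → 0.30 (exact: 0.296), sum 0.56 → 61.5% combined mortality (exact
path: 59.7%). The tabulated transfer is never used in fitting or
calibration, only for reporting worked-example values in the tabulated
convention.

## Dose-response pipeline

Curves are five-parameter log-logistic (LL.5), allowing asymmetric fits.
Pre-processing before fitting, in this order:

1. **Williams transformation** — weighted pool-adjacent-violators
   averaging in the non-increasing direction (survival must not rise
   with concentration). It is mean-preserving and the identity on
   already-monotone data. Implemented via `scipy.optimize.
   isotonic_regression`; the pooled-weighted-means variant is used, the
   common reading of the classic procedure.
2. **Log-scale interpolation** — resampling to k = 10 points
   equidistant in log concentration, linear interpolation of survival
   between neighbours in log space. This is a smoothing device for
   sparse curves (digitised literature studies frequently have at most
   three partial-response concentrations); it is configurable and can
   be disabled for dense designs. The control (C = 0) never enters the
   interpolation (log 0 undefined) and contributes only through the
   fixed upper limit.

Fitting: nonlinear least squares on the survival scale
(`scipy.optimize.least_squares`, trf, tolerances 1e-10), parameters
b, e, f optimised in log space with bounds [1e-6, 1e6], `c` fixed to 0
and `d` to the control response by default. Multi-start initialisation:
e at the observed concentration nearest 50% effect, b ∈ {0.5, 1, 2, 4},
f ∈ {0.5, 1, 2}; the best residual sum of squares wins. Plain
(unweighted) least squares is used deliberately: it is the classic
workflow for these fits, and inverse-variance weighting was found to
degrade downstream shape recovery by over-weighting the response tails.
A flat response (all survivals within 1e-8 of the control) raises a
degenerate-data error rather than returning an arbitrary curve.

Lethal concentrations invert the curve in closed form; `lc(params, x)`
is defined for `x/100 < 1 - c/d` and errors otherwise.

## Effect scale and shift conventions

Every curve's LCx is taken at x% mortality **relative to its own fitted
control** (Abbott-corrected): the combined arm's upper limit is its
environmentally stressed control. Consequences:

- effect addition predicts *exactly* no shift (its combined curve is
  the toxicant curve scaled by the env survival), matching its
  definition;
- LCx* exists for every environmental mortality in [0, 1), so shift
  curves extend across the full 1–90% environmental-stress range;
- SAM's LCx* has the closed form `lc(curve, 100·F(F⁻¹(m_total) −
  F⁻¹(m_env)))` with `m_total = m_env + (1 − m_env)·x/100`, and the
  adapted CA's is `lc(m_total) − lc(m_env)` on the common curve.

The alternative convention (x% of the *unstressed* control) breaks the
"EA never shifts" identity and makes LC10 undefined whenever the
environmental stress alone exceeds 10%; it is not used.

## Calibration of the capacity shape

`calibrate_shape` minimises the sum of squared differences between
log10 observed and log10 SAM-predicted LCx shifts (x ∈ {10, 50}) over
all studies with environmental mortality > 0 — studies without a
measurable environmental effect carry no information about the
transfer. Shifts span orders of magnitude, hence the log scale;
`model_r2` reports goodness of fit on the same scale (raw-scale R² is
available via `log_scale=False`). The optimiser is a deterministic
two-stage grid (steps 0.5 then 0.1 on p ∈ [1, 20]) with bounded scalar
refinement — the objective is cheap and this avoids any dependence on
starting points.

**Predicted-shift readout.** A SAM-combined curve is not itself
log-logistic. Reading the observed shift off an LL.5 fit but the
predicted shift off the exact closed form therefore compares two
different approximations and biases the calibration (the discrepancy is
largest for LC10 on shallow low-effect regions). The calibration's
default `predicted="refit"` readout instead applies SAM to the fitted
toxicant curve at the study's own design concentrations, passes the
predicted response through the same fitting pipeline as the data, and
inverts the fitted curve — observed and predicted shifts then share the
readout, the approximation cancels, and on noise-free data the
calibration recovers the generating shape exactly (tested to 0.05).
`predicted="exact"` retains the closed form for comparison. The closed
form remains the model's exact prediction and is what
`overall_prediction` uses on the average curve.

## Average curve and overall prediction

Each fitted toxicant-alone curve is normalised by mapping
log LC1 → 0 and log LC99 → 1 (an affine map of the log-concentration
axis; the "normalised concentration" is therefore linear in log dose,
and adding normalised concentrations multiplies raw doses). The re-expressed curve is logistic in the normalised
coordinate, so it is carried exactly as a `NormalizedCurve` object
rather than forced into LL.5 parameters. Averaging evaluates all
normalised curves at 10 equidistant levels (endpoints included),
takes the pointwise median and standard error, and refits LL.5 to the
median and to median ± SE — the level-0 value anchors each fit's upper
limit. `overall_prediction` then tabulates LC10/LC50 shifts for SAM,
adapted CA and EA at environmental mortalities from 1% to 90%, with the
SE-band curves providing a sensitivity envelope (the band curves are
independent fits, so the envelope is indicative, not a pointwise bound).

## Synthetic data generator

`generate_meta_dataset` emulates the paired-design literature a
meta-analysis consumes. Defaults are the study conditions of interest:
23 study pairs, 1000 organisms per concentration (binomial sampling),
capacity shape 3.2, environmental mortalities uniform on (0.02, 0.5),
8 concentrations per study. The drawn LL.5 curves have
b ~ U(0.8, 3), d ~ U(0.85, 1), log10 e ~ U(−1, 2) and asymmetry
f ~ U(0.1, 0.5): acute-toxicity curves are right-skewed in log
concentration (effect onset well before the LC50, long tail to complete
kill), and on the normalised axis this places 10% mortality near
position 0.1, the documented geometry of averaged literature curves.
Only f controls the normalised shape, so it is the parameter that
matters. Draws whose LC1–LC99 range exceeds 5 decades are rejected and
redrawn (capped retries): no real bioassay spans ten orders of
magnitude, and the cap couples strong right-skew to steep slopes as in
fitted literature curves. The concentration grid covers the union of
the toxicant arm's 1–99% effect range and the combined arm's own-scale
transition, so both arms satisfy the usual inclusion criteria (control,
partial response, near-complete kill).

The generator does **not** emulate hormesis (out of scope by design),
digitisation error, inter-replicate overdispersion beyond binomial, or
correlated tolerances between stressors. Passing tests on synthetic
data therefore demonstrate internal consistency and estimator behaviour
under the stated conditions, not robustness to those real-data
pathologies.

Determinism: one `numpy` Generator seeded from the config, threaded
explicitly; no global random state. Fixed seed ⇒ identical output.

## Problem sizes used in the checks

The acceptance-style checks run at desk scale: the worked example is
closed-form; the Monte-Carlo agreement uses 10⁶ simulated individuals;
the stochastic parameter recovery uses the full 23 pairs × 1000
organisms; the model-ordering and self-consistency checks use 4–10
study pairs. The binomial-noise scaling check uses 200 replicates per
organism count with warm-started single-start fits.

## Known limitations

- **Interpolation bias under noise.** Resampling noisy points by
  piecewise-linear log interpolation distorts curve shape; with
  binomial noise at n = 1000 it biases the calibrated shape downward by
  roughly 0.3. The recovery analyses therefore calibrate with the
  Williams step on and interpolation off; interpolation remains
  default-on for its intended use, sparse literature-style curves.
- **LL.5 approximation of combined curves.** Observed shifts read off
  LL.5 fits of SAM-generated data differ from the closed-form model
  shifts (up to tens of percent at LC10 for strongly right-skewed
  curves). This is inherent to summarising a non-log-logistic curve
  with a log-logistic fit; the refit readout (above) is the consistent
  way to compare.
- **SAM ≥ CA ordering is empirical, not a theorem.** It holds on
  right-skewed average curves; as the environmental stress tends to 0
  both models converge to shift 1 and hairline crossings (< 1%) can
  occur at the 1% level on some synthetic ensembles.
- **Identifiability of f.** LL.5 fits of sigmoid data can drift to
  large-f/large-e parameterisations that represent essentially the same
  curve (a Gompertz-like limit); downstream quantities (LCx, shifts)
  are unaffected, but the raw parameter values of average-curve fits
  should not be over-interpreted.
- Calibration assumes the two stressors are genuinely independent; the
  package does not test that assumption.
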