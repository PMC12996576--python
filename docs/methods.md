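# Methods

This note documents the models, numerical choices and known limitations
behind `petinput`. It is the package's own account of its science; every
number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Data model

Time is expressed in seconds from the start of injection. PET frames are
half-open intervals `[start, end)` so that adjacent frames tile the scan
without double-counting; frame values represent the mean of the
underlying dense curve over the frame (trapezoidal integral divided by
duration). Continuous detector traces are stored on a fixed 1 s grid.
The default small-animal frame schedule is 30×2 s, 14×5 s, 10×10 s,
10×30 s, 22×100 s = 2730 s (45.5 min); only the total scan length is a
protocol constant, the framing itself is this package's choice.
Concentrations are carried either as kBq/ml or as SUV (g/ml,
`value × weight / dose`); all simulator output is in SUV. Curves are
assumed decay-corrected (the standard output of PET reconstruction); the
`ExperimentConfig.decay_corrected` flag records the assumption.

## Parametric bolus model

The arterial bolus is modelled with the Feng input-function family

    cp(τ) = (A1·τ − A2 − A3) e^{−λ1 τ} + A2 e^{−λ2 τ} + A3 e^{−λ3 τ},  τ = t − t0 ≥ 0,

which rises linearly from exactly zero at onset and decays through
three ordered eigenvalues λ1 > λ2 > λ3 > 0. Fitting enforces the
ordering by parameterising positive gaps (λ2 = λ3 + δ2, λ1 = λ2 + δ1)
and uses five deterministic heuristic starting points (onset guesses at
the 1/5/10% peak crossings, tail decay from a log-linear fit of the
last third); the best sum of squares wins. On noiseless in-family data
the fit recovers all seven parameters to well below 0.1%.

Two refinements matter in practice:

- **Measurement-operator fitting.** The detector does not see the
  bolus; it sees the bolus convolved with a unit-area boxcar of the
  injection duration, convolved with the tubing dispersion kernel
  `(1/τ)e^{−t/τ}` and shifted by the catheter transit delay. When these
  acquisition parameters are known (they are part of the experiment
  configuration), `fit_feng(..., forward=measurement_operator(...))`
  fits the underlying bolus *through* this operator. This removes the
  structural mismatch that a plain Feng fit suffers on slow-injection
  data and makes tail extrapolation (needed for triple-injection
  correction) exact in the noise-free limit.
- **Count-noise weighting.** Detector noise variance is proportional to
  the count rate, so residuals can be weighted by
  `1/sqrt(max(v, 2% of peak))` (`weights="counts"`). This is the
  statistically efficient weighting under the generator's noise model
  and reduces noise-induced bias of downstream fast-kinetics fits.

## Dispersion and delay

Dispersion is modelled as convolution with a mono-exponential kernel of
time constant τ; the correction is the exact inverse
`c(t) + τ·dc/dt`, with the derivative taken by central differences on
the dense grid, so it must be applied to a smooth curve (a parametric
fit), never to raw noisy data. Round-tripping
`correct_dispersion(apply_dispersion(c, τ), τ)` on the reference bolus
stays below 0.4% of the peak for τ up to 30 s.

The withdrawal-rate link is τ = κ / rate with κ = 600 µl·s/min,
calibrated so the reference 120 µl/min withdrawal gives τ = 5 s; a
PET/MR-style long-tubing setup adds 10 s of dispersion and 30 s of
delay. These links are this package's quantification of effects that
are only described qualitatively in the literature (slower withdrawal
and longer tubing lower and widen the measured peak); the constants are
configuration, not physics. The catheter delay itself (default 30.4 s)
is treated as measured per setup and removed by shifting the fitted
onset.

## Two-tissue compartment model

The reversible 2TCM

    dC1/dt = K1·cp − (k2+k3)·C1 + k4·C2
    dC2/dt = k3·C1 − k4·C2
    PET(t) = (1−vB)(C1+C2) + vB·cb

is solved analytically: the impulse response is a sum of two
exponentials with rates `α± = ((k2+k3+k4) ± sqrt((k2+k3+k4)² − 4k2k4))/2`,
and the convolution with a piecewise-linear input uses an exact
per-interval exponential update (an IIR recursion on uniform grids).
Against a stiff `solve_ivp` oracle the forward model agrees to better
than 1e-8 relative; a generic ODE stepper would be both slower and
rougher for the optimizer. Rates are handled internally in minutes (the
conventional reporting unit); public time axes stay in seconds.

Fitting minimises frame-duration-weighted least squares with bounds
K1, k2, k3, k4 ∈ [0, 5] and vB ∈ [0, 1], from five deterministic starts.
Noiseless self-consistency recovers all five parameters to machine
precision; with 1% multiplicative noise the median K1 error over 20
replicates is below 1%. Near the non-identifiable corner k3 ≈ k4 ≈ 0
the micro-parameters trade off; the macro-parameter Ki = K1·k3/(k2+k3)
remains well determined.

Patlak analysis regresses `C_T(t)/cp(t)` on `∫cp/cp(t)` (in minutes)
over frames past t* (default 600 s). For irreversible uptake (k4 = 0,
vB = 0) the slope matches Ki to ~0.1%. Note the asymptotic Patlak slope
on PET data is `(1−vB)·Ki` under this package's vB convention, so a 5%
blood volume depresses the slope by exactly 5%; the diagnostic
comparison against the closed form is therefore run at vB = 0.

## IDIF construction

The left-ventricle TAC is corrected for partial volume by inverting the
two-compartment spill model `measured = RC·blood + (1−RC)·myocardium`
(RC = 0.42 for the PET/CT geometry, 0.44 for PET/MR). The LV/liver
hand-over time is found objectively as the maximum of the smoothed
(3-frame moving average by default) second derivative of the LV curve
after its peak — where the fast ventricular washout flattens into the
tail — with ties broken to the earlier frame. The liver curve is scaled
to a late manual blood sample and supplies all frames after the
junction; no interpolation bridges the junction, but a QC warning fires
if the two sources disagree by more than 15% at the hand-over frame.
On a noise-free simulated subject the IDIF reproduces the true framed
blood curve to better than 0.4% per frame, confirming the construction
is the exact inverse of the simulator's spill/scale forward model.

## Curve features and the break point

Features are computed on a dense smooth curve (a parametric fit, or
smoothed data): SUVmax; time to peak relative to injection (argmax,
earliest on ties); FWHM from linearly interpolated half-maximum
crossings; and the peak/tail AUC split at the break point. The break
point uses derivative landmarks: the minimum of the first derivative
after the peak (steepest descent), the inflection where the curve turns
convex again (the second positive local maximum of the second
derivative — input functions have an earlier one at bolus onset; if
fewer than two exist, the only positive maximum after the peak is
used), and `break = inflection + (inflection − minslope)/2`. Positive
maxima below 1e-6 of the largest curvature are ignored to keep
floating-point ripple from registering as candidates. On
`c(t) = t·e^{−t}` the landmarks are exactly 2, 3 and 3.5, and the tail
area is `4.5·e^{−3.5}`; both are verified numerically. The AUC split is
computed by interpolating the curve value at the break point, so
`auc_peak + auc_tail` equals the total trapezoidal AUC identically.

## Triple-injection correction

Three repeated small boluses on one arterial line are separated
sequentially: fit the parametric model to segment one, subtract its
measured-domain extrapolation from segment two, fit, subtract both
extrapolations from segment three, fit, and realign curves two and
three to the first injection time. Segments run from each injection to
the next on the trace clock. When the injection duration and dispersion
are supplied, fits and extrapolations go through the measurement
operator; in the noise-free limit the corrected curves then equal their
ground-truth components exactly, and with realistic noise all six curve
features of each corrected curve stay within ~1.5% of its component.
The repeatability check is deliberately run in the noise-free limit as
an algebraic identity of the correction; the noisy, statistical
analogue (no significant feature differences across injections) is
covered by the group-comparison machinery.

## Statistics

Groups are compared per quantity with the two-sided Mann-Whitney U-test
at α = 0.05 without multiplicity correction, reporting
U = min(U_a, U_b) with midrank ties. The p-value is exact (full null
enumeration) when the combined sample size is ≤ 16 and the pooled data
are tie-free — which covers the small cohorts this design targets — and
otherwise uses the normal approximation with tie and continuity
correction. The exact branch is validated against an independent
permutation-enumeration oracle for all sample sizes up to 8 + 8; the
empirical type-I error at n = 8 per group over 1000 null replicates is
within two percentage points of 5%. Summaries are mean ± t-based 95%
confidence half-width (undefined at n = 1 and reported missing).

## Synthetic-data generator

`simulate_subject` composes the forward chain: Feng bolus → injection
boxcar → (ground-truth AIF) → dispersion + delay + gain + noise
(detector trace) → 2TCM tissue responses (brain, myocardium) → LV with
partial-volume spill (`RC·blood + (1−RC)·myocardium`, the same RC the
correction inverts) → frame averaging → duration-weighted Gaussian
noise (SD = scale·sqrt(value/duration), approximating Poisson counting
after decay correction) → three late-scan blood samples with
multiplicative error. Every stochastic step is a pure function of its
inputs and a seed; cohort subject seeds derive deterministically from
the cohort seed.

Default conditions emulate the reference protocol: 15 MBq over 30 s in
100 µl, 120 µl/min withdrawal, PET/CT, 45.5 min scan. The default bolus
shape (A1 = 3.65 SUV/s, A2 = 0.7, A3 = 1.3 SUV, λ = 0.115, 0.014,
0.00019 s⁻¹, t0 = 4 s) was calibrated once so the measured reference
AIF lands on typical healthy-mouse values — peak ≈ 8.7 g/ml,
FWHM ≈ 38 s, peak/tail AUC ratio ≈ 0.12. Default tissue parameters are
FDG-like: brain K1 = 0.24 ml/min/ml, k2 = 0.42, k3 = 0.06, k4 = 0.012
min⁻¹, vB = 0.05; myocardium K1 = 1.1, k2 = 2.6, k3 = 0.45, k4 = 0.04,
vB = 0.25. Within-cohort biological variability is lognormal with 15%
CV by default — a placeholder for unknown true population spread, and
configurable. The liver is modelled as a constant fraction (0.6) of
whole blood; real liver kinetics include parenchymal uptake, but the
blood-pool-dominated model makes the IDIF construction exactly
invertible, which is what the validation needs.

What the generator does **not** emulate: image-space effects
(reconstruction noise correlations, motion, spill-over beyond the
single LV↔myocardium term), metabolite build-up (plasma-to-whole-blood
ratio defaults to 1.0, configurable as a constant or function of time),
radioactive decay (curves are decay-corrected by assumption), and
physiological drift within a scan. Passing tests therefore demonstrate
the correctness and self-consistency of the analysis chain under the
stated acquisition model, not its accuracy on any particular real
dataset.

## Condition studies and problem sizes

`run_variability_study` simulates one cohort per condition, runs the
full per-subject pipeline (calibrate → bolus fit → dispersion/delay
handling → IDIF → features → kinetics) and compares each group to the
reference. The `matched_cohorts` option reuses the same biological
draws in every group, a paired design that isolates a condition's
systematic effect from between-animal sampling noise; it is the right
tool for convergence checks (e.g. "injection duration reshapes the peak
but leaves kinetic parameters unchanged"), while independent cohorts
emulate a real multi-group experiment. The injection-duration
diagnostic uses three matched groups of 20 subjects — larger than a
typical physical cohort, chosen to beat estimator noise on a ~5%
stability question — and confirms: peak monotonically decreasing and
FWHM increasing in duration, total AUC constant to <0.5%, and all
2TCM parameter group means stable to <5%, with the noise-free limit
exactly invariant.

## Known limitations

- The break-point rule assumes a single-pass bolus; recirculation
  humps or multi-peak inputs are out of scope.
- `correct_dispersion` amplifies noise through the derivative; it is
  only meaningful on fitted or strongly smoothed curves.
- Feng fits on data that truly lack a peak (flat or monotone curves)
  fail by design with a `FitError`.
- The exact U-test branch requires tie-free data; heavily tied small
  samples silently fall back to the corrected normal approximation.
- Fast-exchange parameters (myocardial k2) remain noise-sensitive even
  with efficient weighting; group-level conclusions should rest on
  means/medians over subjects, not single fits.
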