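# Methods

This note documents the models and procedures implemented in `ppgglu`, the
assumptions behind the synthetic data, the numerical choices, and the known
limitations.

## The estimation problem

A fingertip PPG sensor records transmitted light intensity; each cardiac
cycle produces one beat with four landmark (fiducial) points — the systolic
peak (SP), the dicrotic notch (DN) caused by aortic valve closure, the
diastolic peak (DP), and the inter-beat bottom (Bot). Glucose contributes to
near-infrared absorption in the pulsatile blood volume, so beat amplitudes
relative to Bot carry a glucose signal. The pipeline maps per-recording
summaries of beat morphology (X-features), plus subject covariates
(P-features), to the reference blood glucose in mmol/L (y-label) with a
regression model, and evaluates the result with the metrics standard for
glucose monitors.

## Synthetic PPG generator

Real fingertip recordings with reference glucose are not publicly
deposited, so the package ships a first-class simulator whose ground truth
is exact by construction.

**Beat model.** One beat of period `T` is a sum of two Gaussian pulses minus
a narrow Gaussian notch. The systolic pulse (centre 0.17 T) is two-sided —
rising width 0.4× its decay width 0.10 T — so the upstroke is steep and both
window endpoints decay to near the beat minimum. The diastolic pulse
(centre 0.46 T, width 0.18 T) is wide enough to ride the systolic decay as a
shoulder: with the notch removed the beat is a single hump with no interior
minimum after SP, and it is the notch (width 0.05 T, centred between the
pulses) that carves DN and thereby separates DP. A damped fixed-point
iteration (14 rounds on a 8192-point grid) adjusts component amplitudes and
centres until the waveform's measured SP−Bot, DP−Bot, DN−Bot amplitudes and
SP/DP times hit their targets, to well under 1%; the generator's recorded
ground truth is measured from this continuous model, not assumed from the
parameters.

**Glucose link.** The three anchored amplitudes are affine in glucose:
baselines (1.0, 0.52, 0.30) a.u. at 5.0 mmol/L with slopes (0.10, 0.06,
0.035) a.u. per mmol/L. Additive white Gaussian noise has standard
deviation `max(0.004, 0.06 − 0.008·g)` a.u. — decreasing in glucose,
reflecting that low-glucose recordings show weaker absorption contrast and
noisier waveforms. A mild per-subject gain `1 − 0.005·(BMI − 25)` (clipped
to [0.7, 1.3]) stands in for thicker tissue transmitting less pulsatile
light, and gives the P-features predictive value in multi-subject cohorts.

**Recordings and cohorts.** Each recording draws a beat rate uniformly in
60–100 bpm (inside the 1–3 Hz human band), a random start phase, and spans
8 s at 500 Hz by default (the acquisition hardware's rate and duration are
not published; these are module choices giving 8–13 beats per recording).
Scenario presets fix the cohort shapes: `nir_single` (292 records, one
subject, 4.4–6.4 mmol/L), `nir_single_88` (an 88-record variant),
`solar_single` (237 records, same range, 3× noise — sunlight illumination
is weaker and less stable than the laser), and `multi_patient` (626
records, 49 subjects, 3.9–15.0 mmol/L to span diabetic excursions, 2×
noise for the less controlled clinical setting). Labels are uniform over
the closed range with both endpoints inserted deterministically (records 0
and 1), so the label extremes are reproducible. Ground truth lists exactly
the beats whose two delimiting troughs lie at least 50 ms inside the
record — the set that trough-to-trough segmentation can ever recover.

**What the simulator does not emulate.** No motion artifacts, baseline
wander, optical path or tissue physiology, beat-to-beat period or amplitude
variability within a recording, nor nonlinear glucose–morphology coupling.
Passing tests on this generator demonstrate that the pipeline recovers a
known signal under realistic sampling and noise — not that the same
accuracy holds on human data, where the published figures from comparable
hardware are MARD of a few percent rather than the sub-percent values the
clean synthetic link yields.

## Signal conditioning and segmentation

Conditioning is a zero-phase band-pass implemented as an ideal mask on the
real FFT, keeping 0.5–8 Hz inclusive: DC and drift are removed, mains
interference rejected, and the heart-rate fundamental and notch-shaping
harmonics retained. The binary mask makes conditioning exactly idempotent,
at the cost of some ringing near the sharp inter-beat troughs; amplitudes
extracted from conditioned signals carry a few-percent filter bias that is
consistent across records and therefore harmless to the regression.
Conditioning is optional (`condition=False`) and the zero-noise
recoverability tests bypass it.

Beat boundaries are local minima of the conditioned signal found with
minimum separation 1/(3 Hz) (the upper heart-rate bound) and prominence at
least 30% of the robust signal span — the prominence floor keeps
dicrotic-notch dips from being taken as boundaries. Segmentation starts at
the trough preceding the first beat containing at least two local maxima
with prominence ≥ 10% of the beat span (the double-peak test), and beats
run trough to trough in half-open 0-based index ranges.

## Fiducial location and the 11 features

Within a beat: Bot is the minimum up to the systolic peak, SP the global
maximum, DN the deepest interior local minimum after SP, and DP the highest
local maximum after DN. Because the beat ends in the inter-beat trough —
the global low region, where noise or ringing creates spurious minima — the
DN search is restricted to the first 70% of the post-systolic span and the
DP search to the first 90%. When no interior minimum exists (a notch-free
beat), DN and DP fall back to the first up and down zero crossings of a
Savitzky–Golay-smoothed first derivative (50 ms window, order 3); if the
derivative never crosses zero, DN is taken at the flattest point of the
decay — the limit of the notch position as its depth goes to zero — and DP
50 ms beyond it, with `notch_fallback_used` flagged either way. Flat,
monotone, or boundary-peaked beats raise a degenerate-beat error;
aggregation skips and counts such beats rather than failing the recording.

The 11 features, in fixed order: (1–3) SP−Bot, DP−Bot, DN−Bot amplitudes;
(4–6) SP, DN, DP times from beat start; (7) beat period; (8–9) DP/SP and
DN/SP amplitude ratios (Bot-anchored, hence offset-invariant); (10)
systolic rise slope (SP−Bot)/t_SP; (11) spectral ratio — the power at the
beat fundamental (the first DFT bin of the mean-removed beat, since one
segment spans one cycle) over total AC power, the one spectral feature.
The source text for this analysis names only the three anchored amplitudes;
the remaining eight realize its "temporal and spectral" description
anchored to the four named fiducials, and the set is isolated behind
`FEATURE_NAMES` so alternates can be swapped in. P-features are encoded as
age, sex (F=0/M=1), height and weight, with cohort-median imputation for
missing values (flagged, never silent).

## Regression models

**CART.** Greedy variance-reduction splits over all (feature,
midpoint-of-consecutive-unique-values) candidates; ties broken by lowest
feature index, then lowest threshold, with reductions within a relative
1e-10 treated as ties so floating-point jitter cannot upset the documented
order. Leaves store training means; growth stops at the depth limit,
below twice the minimum leaf size, or at zero-variance nodes.

**GBDT.** `F₀ = mean(y)`; for k = 1…N, tree `Tₖ` fits the residuals
`rₖ = y − F_{k−1}(X)` and `Fₖ = F_{k−1} + ν·Tₖ`. Per-round residual vectors
and training MSE are retained; for ν ∈ (0, 1] the training MSE is provably
non-increasing. Defaults N = 200, ν = 0.1, depth 3, min-leaf 2 — the source
work states no hyperparameters, and these standard values interpolate the
clean synthetic link without overfitting the noisy one. Predictions can
optionally be clipped to the physiological 2–30 mmol/L.

**Baselines.** Linear and ridge regression by normal equations (intercept
unpenalised), k-nearest-neighbours (Euclidean, distance ties broken by
training-row order), a single tree, bagged trees, and a random forest
(bootstrap resamples plus √d feature subsampling per split), all seeded.
SVM, AdaBoost, extra-trees and CNN variants from the published comparison
are not implemented — no kernel or architecture details are available —
and are deliberately absent from the benchmark table.

**Personal calibration.** A population model is adapted to an individual
from k initial (PPG, glucose) pairs either by fitting additional boosting
rounds on the personal residuals with the population trees frozen
(default: 25 rounds of depth-1 trees), or by an affine output correction
`a·y′ + b` (k = 1 fixes a = 1 and fits only the offset).

## Evaluation

Metrics follow the glucose-monitoring conventions: MARD =
mean(|y′−y|/y)·100%, with per-point signed relative differences reported in
percent; R² = 1 − SS_res/SS_tot (NaN for zero-variance references, error
for n < 2). The Clarke Error Grid converts mmol/L to mg/dL with 18.016 and
applies the canonical 1987 piecewise inequalities in the conventional
decision order A, E, C, D, else B, with inclusive boundaries (documented
inequality by inequality in `evaluation.py`); a point-for-point sweep
against an independently transcribed scalar oracle is part of the test
suite. Monte Carlo cross-validation repeats seeded random train/test
splits (default 50 repeats, 20% test — the source states neither) and
summarises each metric as mean/min/max. Uncertainty is decomposed as:
epistemic — the mean over points of the prediction standard deviation
across an ensemble trained on bootstrap resamples; aleatoric — the mean ±
sd over points of each point's held-out prediction spread across MC-CV
repeats. These operational definitions pin down what the underlying
methodology leaves loose.

## Problem sizes and determinism

The acceptance script runs each scenario at its full preset size (292, 237
and 626 records) with 5-fold cross-validation, 50 MC-CV repeats and a
20-model bootstrap ensemble, completing in about a minute on one CPU; the
test suite uses 30–88-record cohorts for the same checks. Every stochastic
step takes an explicit seed (NumPy `SeedSequence` spawning for per-record
and per-repeat children), reports embed the seed and a SHA-256 hash of
their configuration, and repeated runs are byte-identical.

## Known limitations

- The feature set is a documented package assumption, not a published
  specification; alternate registries can be swapped in but are not
  provided.
- The ideal-mask band-pass trades passband ripple for ringing at sharp
  troughs; heavily filtered amplitudes are biased a few percent low or
  high depending on beat rate. Disable conditioning for bias-sensitive
  analyses of clean signals.
- Clarke zone boundaries follow the canonical decision chain; on the
  measure-zero overlap line between the D and E regions (reference ≥ 240
  mg/dL with prediction exactly 70 mg/dL) the chain assigns E.
- The multi-patient scenario models between-subject variation only through
  a BMI-linked gain; it cannot probe covariate shift, medication effects,
  or device placement variability.
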