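# Methods

## Problem and scope

`blvest` estimates cumulative blood-loss volume (BLV, mL) during
controlled hemorrhage from two continuously monitored waveforms: the
photoplethysmogram (PPG, arbitrary units) and the invasive arterial
blood pressure (ABP, mmHg), both sampled at 250 Hz. The reference BLV
is the pump record — rate × elapsed active-bleed time — so labels are
exact by construction. Only the pre-resuscitation phase is modeled;
resuscitation, ventilator interaction and device drivers are out of
scope.

## Synthetic cohort model

No waveform dataset is distributed with this protocol, so the package
includes a generative model of the experiment. It is phenomenological:
it reproduces the statistical structure the estimator relies on, not
cardiovascular mechanics.

**Protocol.** Subject weight ~ N(31.82, 3.52²) kg; estimated blood
volume EBV = 67.9 mL/kg (the coefficient that reconciles the cohort
mean weight with a mean blood volume of 2160 mL; configurable).
Baseline duration ~ U(18, 31) min. Bleeding is a sequence of 3–6 active
pump segments at 20 mL/min separated by rest pauses, sized so the
bleeding period lands in roughly 106–185 min; the final segment is cut
at the 1-s simulation step where the effective volume deficit reaches
the subject's shock fraction, at which point MAP equals 30 mmHg by
construction.

**Effective deficit and refill.** The cumulative fractional deficit
f(t) = BLV(t)/EBV is relieved by transcapillary refill r(t), which
relaxes toward ρ·f with time constant τ = 20 min (ρ = 0.2). All
hemodynamic responses are driven by f_eff = f − r, so vital signs
partially recover during rest pauses while the label (cumulative pumped
volume) does not — an intentional, physiologic source of irreducible
estimation error, and the mechanism behind the model's underestimation
of large losses.

**Responses.** Pulse rate rises logistically from its baseline
(~85 bpm) by up to ~55 bpm, centered at 25 % deficit; PPG pulse
amplitude falls as exp(−2·f_eff); MAP is near-flat (3 % sag) below a
compensation knee at 15 % deficit and declines linearly to 30 mmHg at
the subject's shock fraction (N(0.40, 0.10²), clipped to [0.25, 0.60],
chosen so cumulative terminal loss lands near 48 % of EBV after
refill); pulse pressure narrows as exp(−0.8·f_eff). All response curves
are exact at f_eff = 0 (baseline identity) and monotone.

**Beats.** Each beat is a two-lobe Gaussian template (dominant systolic
wave plus a delayed reflected wave), which guarantees a single systolic
peak, a detectable dicrotic notch, and zero-valued endpoints so
concatenated beats are continuous. PPG beats are scaled by a
per-subject device gain (U(0.5, 2)) and offset (U(1, 3)); ABP beats
span [DBP, SBP] exactly. Per-beat jitter (2 % rate and amplitude,
~1 mmHg pressure) plus small additive measurement noise make the
"variation" features non-degenerate at baseline.

**Artifacts.** Segments of 60 s aligned to the 30-s window grid are
replaced by flatline/saturation/noise; the segment count uses
stochastic rounding so the expected share of windows touching an
artifact equals the configured 3.3 %.

**Hematocrit.** Baseline HCT ~ N(30.8, 6.0²) %. Draws follow
hct(t) = hct₀ · exp(−V_d(t)/EBV) where the diluting volume V_d lags the
pumped volume through a first-order filter (τ = 40 min), plus 0.5 %
measurement noise. With the lag and noise disabled the model is pure
exponential dilution and Ward's formula EBV·ln(Hct_i/Hct_f) inverts it
exactly — this is the module's self-consistency oracle. With the lag
on, the fractional HCT drop is strictly smaller than the fractional
blood loss, so all three HCT formulas underestimate, matching clinical
experience.

**What the generator does not emulate.** Real waveform morphology
variation (arrhythmias, respiratory modulation, probe repositioning),
inter-individual differences in compensatory dynamics beyond the
sampled parameters, measurement devices' transfer functions, and any
resuscitation physiology. Tests passing on this cohort demonstrate that
the pipeline's mechanics are correct and that it recovers the planted
monotone volume–feature relationships; they do not certify accuracy on
real animals or patients.

## Windowing and labels

Windows are 60 s with a 30-s hop, tiling [0, T−60]; the count is
⌊(T−60)/30⌋+1. The BLV label is read at the window's **end** time (the
estimate means "blood lost so far when the window completes"); start-
and center-aligned labeling are available via `label_at`. Windows
ending at or before bleed onset are baseline with label 0; windows
straddling the onset belong to the bleeding phase with the end-time
label. A window is dropped if any sample overlaps the artifact mask
(strict rule; a laxer sample-fraction threshold is configurable).

## Features

Beat delineation finds pulse feet as local minima preceding
first-derivative maxima, peaks as maxima between consecutive feet, and
the dicrotic notch as the first local minimum after the peak (fallback:
second-derivative zero crossing). Beats violating the
foot < peak < notch < end ordering are excluded; a window needs 20
valid beats (≈ one third of the expected count at 60 bpm) or it is
unusable.

Fourteen of the 18 PPG features follow the published feature tables
(peak and peak−foot amplitudes with their variations, slope transit
time, systolic/diastolic times, systolic/notch/diastolic areas and
ratios, PIR). The remaining four are **reconstructions** — foot
amplitude, foot amplitude variation, pulse width at half amplitude, and
total pulse area — standard amplitude/time-domain PPG metrics chosen
because the original appendix cataloguing them is not available; they
should not be read as the original authors' exact choices. Conventions:
areas integrate above the beat's foot value (so PPG DC offset cancels),
each "ratio" divides by total pulse area (the three sub-areas partition
it exactly), "variation" is (max−min)/mean across the window's beats
(the classic pulse-pressure-variation form; SD/mean would be the main
alternative), per-window aggregation is the mean over valid beats, and
slope transit time is amplitude divided by the maximal upstroke slope.
Pulse-rate features (mean/min/max/SD/median rate, RMSSD of the
inter-beat intervals in ms) are computed from inter-foot intervals; in
the combined modality the pulse-rate block comes from the PPG channel
so the combined vector's PPG sub-vector equals the PPG-only vector.

## Normalization

Centers are per-feature means over baseline windows — the subject's own
(person scope) or a set of other subjects' (group scope), averaged per
window rather than per subject, so longer baselines weigh more (an
interpretive choice; per-subject weighting would differ when baseline
lengths differ). Centers must be strictly positive; a zero baseline
mean raises an error naming the feature rather than silently flipping
signs. During cross-validation, group centers are fit on the training
fold only and applied unchanged to the held-out subject. Raw
(non-normalized) features are available as `normalization="none"` for
ablation only.

## Models and validation

LASSO (α = 0.05) and random forests with per-modality defaults
(PPG: 34 trees, depth 12; ABP: 15, 8; combined: 43, 19) are trained on
baseline plus bleeding windows. Validation is leave-one-animal-out:
subject-level folds prevent within-subject leakage, verified by
hashing each fold's training matrix and showing it is invariant to
arbitrary mutation of the held-out subject's rows. One master seed
spawns per-fold estimator seeds. Negative predictions are reported as-is by
default so biases stay visible (an opt-in `clip_zero` clamp exists); importance rankings average
|coefficient| (LASSO) or impurity importance (RF) across folds, with
per-fold zero-coefficient counts reported for LASSO. The grid-search
helper evaluates an exhaustive (n_estimators, max_depth) grid with an
inner leave-one-subject-out split and RMSE objective, breaking ties
toward the smaller model; the published hyperparameters are the
defaults, so the pipeline does not re-search them.

## Evaluation

Error is predicted − reference (positive = overestimate) by default;
the opposite convention is a flag, and the HCT comparison reports both.
Severity classes partition loss fraction at 15/30/45 % of EBV with
baseline windows as a separate no-bleeding class; the overall mean
error equals the window-weighted mean of class means by construction.
The HCT comparison pairs each bleeding-stage draw with the model
prediction of the window ending nearest before the draw and with the
three formula estimates (the baseline draw supplies Hct_i; noisy draws
above baseline are clamped to zero implied loss). Bourke's formula
converts percent HCT to fractions internally, since its (3 − Hct_mean)
factor is only dimensionally sensible on the fraction scale; Ward and
Gross are scale-invariant.

## Numerical and design notes

- Signals are stored float32 (memory; serialized losslessly at 9
  significant digits); all feature math is float64.
- The effective-deficit ODE uses 1-s exponential-Euler steps; beat
  lengths are quantized to whole samples, so a "72 bpm" window's
  measured rate is 60/round(250·60/72)·250 ≈ 72.1 bpm — tests compare
  against the quantized value.
- Reported problem sizes: the default cohort is 40 subjects (~14,000
  windows); examples and unit fixtures use 2–10 subjects, and a
  compressed-timeline configuration (identical physiology, higher pump
  rate, minutes-long records) backs the fast unit tests.
- Determinism: identical (config, seed) pairs give byte-identical
  cohorts, feature CSVs and report tables; per-subject seeds are
  spawned from the master seed and recorded on each record.

## Known limitations

The generator's monotone response curves make the estimation task
easier than real physiology, where compensation saturates at deep shock
and varies across subjects and time; absolute error numbers on
synthetic cohorts are therefore optimistic. At small cohort sizes
out-of-fold shrinkage reproduces the clinically observed
underestimation of extreme losses (at 6 subjects the >45 %-loss class
shows a −168 mL mean error, printed by `examples/04`), but on the full
40-subject synthetic cohort the homogeneous physiology gives the forest
dense coverage of the deep-loss range and the deep-loss bias largely
vanishes — real heterogeneous animals should not be expected to behave
this well. HCT-formula underestimation under refill, near-zero early
bias, and the model-vs-formula spread advantage are robust across
cohort sizes. Group normalization inherits the cohort's homogeneity;
with heterogeneous real populations its bias would be larger. Record
I/O is plain CSV + JSON; binary waveform container formats are not
supported.
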