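# Methods

This note documents the models, defaults and numerical choices behind
`pinglab`, in the package's own terms: what each stage assumes, which
parameters matter, and what the synthetic data do and do not emulate.

## Synthetic EEG trials (`pinglab.synth`)

Each trial is a Gamma-shaped evoked waveform

f(t | a, b) = e^{a−1} · [b(a−1)]^{−(a−1)} · t^{a−1} · e^{−t/b},

normalised so that f peaks at exactly 1 at the mode t = (a−1)b. The
peak-normalised form is the only reading under which fixed amplitude
scalings give interpretable microvolt-scale peaks; the raw kernel
t^{a−1}e^{−t/b} is available via `normalized=False`.

Defaults (per condition, drawn independently per trial):

| parameter | condition 1 | condition 2 | unit |
|---|---|---|---|
| μ_a (shape mean) | 2.0 | 3.0 | — |
| μ_b (time-constant mean) | 0.130 | 0.080 | s |
| σ_a | 0.2 | 0.2 | — |
| σ_b | 0.0005 | 0.0005 | s |
| amplitude scale | 0.5 | 0.25 | a.u. |
| onset | 0.1 | 0.1 | s |

Draws with a ≤ 1 or b ≤ 0 are rejected and redrawn (clipping would
distort the shape distribution; at the default σ's rejections are
vanishingly rare). Sensor noise is i.i.d. gaussian per channel and
sample, σ = 0.75, reduced by 30% (to σ = 0.525) inside the impulse
window 1.3–1.5 s. "Variability reduction" is interpreted on the s.d.
scale, matching 0.75 × 0.7 = 0.525.

The forward model is a deliberately synthetic lead field: two sources
with smooth gaussian gain profiles across a posterior channel row
(`two-dipole-default`), or random orthonormal rows. Decoding properties
depend only on a stable full-rank source-to-channel mixing, not on head
geometry, so no BEM/FEM modelling is attempted. Both sources carry the
condition waveform; the K-orientation generator modulates the two source
amplitudes by 1 + g·cos(2θ) and 1 + g·sin(2θ) — a doubled-angle circular
code, since orientation is π-periodic. The generator emulates evoked
waveform variability, sensor noise and its impulse-window quench; it does
not emulate oscillatory backgrounds, artifacts (blinks, line noise),
channel covariance structure beyond the source mixing, or drifts — so
passing tests speak to the statistical machinery, not to robustness
against real-world EEG contamination.

## Preprocessing (`pinglab.preprocess`)

Baselining subtracts, per trial and channel, the mean over a window;
`debaseline_stitch` reverts per-epoch baselining by measuring each
trial's voltage offset between consecutive epochs over their overlap (or
junction samples when they merely abut) and adding it back — recovering
the continuous trace up to one global constant. Temporal smoothing is a
unit-area gaussian (reflection padding, kernel truncated at 8σ so a
delta reproduces the sampled gaussian to ~1e−7). Band-limited power uses
a zero-phase FIR band-pass (firwin + filtfilt, ~2 cycles of the low edge)
followed by the analytic signal; squared magnitude gives total power.
Filter edge transients extend about half the filter length into each
epoch edge; assertions exclude them. Detrending is a per-series
least-squares line (`scipy.signal.detrend`).

## Decoding (`pinglab.decoding`)

Stratified 8-fold cross-validation; per fold, class means and the
covariance of training residuals, shrunk toward a scaled identity either
by a fixed coefficient or the analytic Ledoit–Wolf value (default).
Held-out Mahalanobis distances are re-indexed by doubled-angle label
difference and mean-centred per trial; the vector strength −mean(cosΔ ·
p(Δ)) makes "distance grows with angular difference" positive. With
exactly two conditions the profile degenerates to own/cross bins and the
strength reduces to (cross − within) distance. With shrinkage exactly 0
the decoder is affine-invariant; a singular covariance then raises an
error advising shrinkage > 0. `MahalanobisRDFDecoder` exposes the same
mathematics as a scikit-learn estimator (fit/transform/score) for use
with sklearn model selection; the pipeline functions use the vectorised
multi-timepoint path.

The posterior-channel subset of real recordings is configuration-driven
(`channels=`): the printed catalogue of such channel lists is unreliable
(duplicates/omissions are common), so no fixed list is hard-coded.

## Inference (`pinglab.inference`)

One-sided tests throughout, since negative decoding strengths are not
expected and one-sided testing is conservative when arguing a *lack* of
decoding. The subsampling grid draws sessions, then trials per session,
without replacement (5,000 resamples by default) and records mean
strength and mean one-sided p per cell; the full-data corner reproduces
the pooled test exactly. Randomization p-values use the add-one rule
(1 + #{null ≥ obs}) / (1 + n) so p is never 0. The cross-validated
median split halves each session's trials (stratified by orientation, so
both half-decoders stay balanced), ranks sessions on half 1 in the
0.25–0.45 s window, and evaluates held-out strength on half 2; with an
odd session count the high group receives the extra session. The shuffle
predictor re-runs the identical procedure on label-shuffled decoders
(1,000 shuffles × 200 split-folds at full scale) and the 95%-of-folds
criterion declares significance. Bootstrap CIs resample sessions with
replacement (percentile interval; SEM = s.d. of bootstrap means).

## Variability (`pinglab.variability`)

Across-trial variance is computed per session, per-sensor detrended,
sensor-averaged, then session-averaged — the ordering matters because
pooled variance absorbs between-session mean offsets. Detrending can
push variance slightly negative; Δvar therefore raises a diagnostic on a
non-positive baseline and the raw (undetrended) variant is available.
Two baseline conventions exist in practice (a long ~2 s pre-impulse
baseline and a short 0.2 s one); the window is a parameter everywhere.
Outlier-session screening excludes sessions whose variance at the
impulse exceeds median + 5×MAD across sessions — a robust screen for
"extremely high variance at the impulse" that needs no tuning to data.
The decoding split (low vs high single-trial strength at the time of
maximal decodability) is a median split by default, with the quantile
exposed, tested two-sided per timepoint with a p < 0.005 flag.

## Spiking ring networks (`pinglab.spiking`)

Current-based LIF neurons on a ring (default 2,048 E / 512 I; reduced
voltage convention: rest 0, threshold 20 mV, reset 10 mV; τ_m = 20/10 ms
E/I; 2 ms refractory). E→E connections are all-to-all with a gaussian
footprint over angular distance (nearby preferred angles couple more
strongly); all connections involving inhibition are all-to-all and
untuned, so inhibition mediates global competition. Weights scale as 1/N,
making regimes transfer across network sizes. Integration is fixed-step
Euler at dt = 0.1 ms with per-step gaussian membrane noise; every trial
is reproducible from its seed. STP follows the standard presynaptic
(u, x) scheme on E→E synapses only, normalised so the resting efficacy
u·x/U equals the nominal weight.

Three calibrated regimes (parameters in the shipped dataclasses):

- **silent** (`SILENT_SPEC`): *fast* recurrent excitation (τ_ee = 20 ms,
  peak 260, footprint 15°) with facilitation-dominated STP (U = 0.2,
  τ_f = 3 s, τ_d = 0.3 s) and a quiet background (~0.1–0.3 Hz). The cue
  drives u high at cue-adjacent synapses; spiking then collapses and the
  delay is effectively silent while u·x stays elevated. A weak
  nonspecific drive (1.5, near the ignition threshold) triggers an
  explosive, depression-terminated population event at the cued location
  in a seed-dependent subset of trials. The fast synapse is essential:
  with slow (NMMA-like, 100 ms) recurrence reignition is graded and
  regular, and the across-trial variance it adds is cancelled by
  sub-Poisson within-trial firing, leaving ΔFF ≤ 0.
- **bump** (`BUMP_SPEC`): slow recurrence (τ_ee = 100 ms, peak 40), no
  STP; the cued bump persists ≥ 2 s with diffusive angular drift. The
  matched-window drive (amplitude 4) boosts the attractor and quenches
  across-trial count variability (ΔFF < 0).
- **boost** (`BOOST_SPEC`): the same architecture with peak 36 — a soft
  bump whose amplitude sags through the delay, leaving headroom so a
  weak sustained drive (2.0) visibly sharpens population-vector tuning
  without any silent trace.

Drive *windows* are matched across regimes (1.6–1.85 s after a 0.2–0.45 s
cue in a 2.3 s trial); drive *amplitudes* are per-regime defaults, since
each regime's qualitative phenomenon lives at a different point of its
drive response. Fano factors use 100-ms sliding windows, per-neuron
FF = var/mean of counts across trials, averaged over neurons with
non-zero mean; ΔFF references each neuron to its own pre-drive baseline,
and regime tests use the per-neuron ΔFF distribution (the pooled curve is
additionally exposed, but its neuron composition changes between windows
when silent neurons activate, which biases pooled comparisons). The
default Fano population is all excitatory neurons; a cue-adjacent subset
can be selected by slicing the returned per-neuron matrix. One genuine
bump-regime caveat: angular drift accumulates variance across the delay,
so even the no-drive control shows a small positive ΔFF trend (~+0.05);
the regime contrast is therefore asserted against both zero and the
no-drive control.

## The baselining-artifact study (`pinglab.demos.run_s3_demo`)

Two-condition trials (n = 200 each) contain evoked waveforms early in the
trial and a 30% noise-s.d. drop in the impulse window — no impulse-locked
signal. An *early* baseline (0–0.1 s, pre-onset) subtracts pure noise; a
*late* baseline (0.55–0.75 s, inside the delay) additionally folds each
trial's residual evoked activity into every sample of the trial. That
injected, condition-specific offset becomes *more decodable* exactly
where the noise variance drops, producing a spurious impulse-locked
decoding increase. The reactivation index is the decoding strength in
the impulse window minus the average of flanking reference windows
(1.2–1.3 and 1.65–1.75 s); bracketing cancels, to first order, the slow
decay of the residual evoked signal, so that without the variance drop
the paired late-vs-early difference is statistically indistinguishable
from zero while with the drop it is large (paired t ≈ 30 at 100 seeds).

## Problem sizes and numerical choices

The test-suite and acceptance runs use deliberately reduced sizes chosen
as the package's own desktop defaults: ring networks at 512E/128I (the
1/N weight scaling preserves all qualitative contrasts, re-verified at
full size), 100 trials per spiking condition, null calibrations at
4-orientation / few-channel geometry with 19-shuffle exact randomization
tests (level exactly 1/20), and 2,000-trial noise-only datasets for the
variance predictions. Ties in the median split are broken by stable sort
order; permutation p-values use the add-one rule; covariance inversion
falls back to an informative error rather than a silent pseudo-inverse.

## Known limitations

- The synthetic EEG generator is phenomenological; it validates the
  analysis chain, not physiological realism.
- Network parameters realise the intended dynamical regimes but are not
  a fit to any published parameter table; quantitative ΔFF magnitudes
  are regime-dependent and should be read qualitatively.
- Real-recording analyses (posterior-channel lists, session structure,
  TMS artifacts) are out of scope; the interfaces accept such data but
  ship no loaders for specific public datasets.
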