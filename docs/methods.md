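# Methods

This note documents the models, conventions and numerical choices behind
`reflexkit`. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Scope and conventions

The package quantifies the airway-closure (gasping) reflex from four kinds
of recordings: respiratory traces (tracheal/oesophageal pressure in cmH₂O or
pneumotachograph flow in ml s⁻¹), two-channel GCaMP/tdTomato fluorescence
from vagal ganglia, multiunit vagal nerve or respiratory-muscle EMG signals,
and stimulus-epoch annotations. Throughout:

- all time windows are half-open `[start, end)`; breath membership in a
  window is decided by the inspiratory onset;
- sample indexing is 0-based; traces are uniformly sampled;
- cohort percentages use half-up rounding (one decimal by default), the
  convention under which every published count→percentage pair reproduces
  exactly (e.g. 25/495 → 5.1%);
- a stimulus epoch carries both a delivery window and an observation window;
  nebulized stimuli are observed for 5 min after delivery, compression,
  suction and inflation for the epoch plus 30 s (a package convention —
  gasping after these challenges is acute).

## Breath segmentation

The acquisition software used for the original recordings is proprietary,
so segmentation is a deliberately parameter-sparse reimplementation:

1. smooth with a moving average (default 0.02 s);
2. find inspiratory peaks by prominence ≥ max(3·σ̂, 5% of the robust
   2.5–97.5% range), where σ̂ is the noise s.d. estimated from the median
   absolute first difference of the smoothed trace. A first-difference
   noise estimate is insensitive to the breathing oscillation itself, so
   clean periodic traces are segmented with essentially zero threshold
   while noisy traces are protected at 3 noise s.d.; the relative-range
   floor suppresses residual smoothed-noise bumps. (A threshold set from
   the MAD of the trace *values* would scale with breathing amplitude —
   for a pure sinusoid it exceeds the peak prominence — so it cannot serve
   as a detection floor.)
3. place the inspiratory onset at the last baseline crossing before each
   peak, the expiratory onset at the first crossing after it, and the
   expiratory end at the next onset (trace end for the last breath).

The baseline is the midpoint between the median peak height and the median
inter-peak trough. For symmetric waveforms this is the mean; for the
asymmetric pressure morphology of a tracheostomized mouse (brief inspiratory
deflection, decaying expiration, long near-baseline plateau) the plain
median sits well below the plateau and biases onsets by tens of
milliseconds, which the midpoint estimator avoids.

Amplitudes are magnitudes relative to the baseline. Segmentation is
amplitude-scale invariant and time-shift equivariant; constant or too-short
traces yield an empty table with a warning rather than an exception.
Tidal volume (flow traces only) is the trapezoidal integral of the positive
flow over the inspiratory phase; peak inspiratory flow is its maximum.
Pressure traces get no tidal volume (no calibration exists); pressure
amplitude serves as the volume proxy.

## Gasp/sigh classification

A breath *i* is an augmented breath under the anaesthetized rule when its
expiratory amplitude strictly exceeds 1.5× both neighbours; the
plethysmography rule additionally requires the same of the inspiratory
amplitude. The threshold is strict: a ratio of exactly 1.5 is not a call,
and the first/last breaths are never callable. No suppression logic for
adjacent calls is needed — two neighbours cannot both exceed each other by
50%. Events inside a stimulus observation window are typed *gasp*, outside
*sigh*; the amplitude rule is identical and context is the only separator.

Reflex metrics: gasps/min over either the observation or the stimulus
window (1 gasp in a 10-s illumination → 6.0 min⁻¹); latency from stimulus
onset to the first gasp; per-breath features normalized to the mean over
the 10 s immediately before stimulus onset. The Hering–Breuer reflex is
quantified as breath-count rate during the 10-s inflation divided by the
10-s pre-inflation baseline rate, so complete apnoea gives exactly 0. The
10-s baseline window is reused here as a convention (none is stated for
this quantification). Trial aggregation is figure-style: per-animal trial
means, then group mean ± s.e.m. (sample s.d./√n animals).

## Ratiometric calcium analysis

The ratio R(t) = GCaMP/tdTomato cancels photobleaching, motion and
expression level, which both channels share. Each epoch's F₀ is the mean of
R over the 20 s preceding that epoch (per-epoch F₀ tolerates slow drift
between stimuli); the session-wide ΔF/F₀ trace used for the responsiveness
threshold is referenced to the first epoch's F₀. A cell is responsive to an
epoch when its peak ΔF/F₀ over `[start, end + 5 s)` — the 5-s lag captures
offset-peaking transients and is configurable — is positive and at least
`session mean + 3 session s.d.` of its ΔF/F₀ trace. Requiring a strictly
positive magnitude prevents a degenerate zero-variance trace from being
"responsive" at a threshold of 0. Session statistics include stimulus
periods (the criterion is stated over the entire session).

Responsive cells are classified by Rc/Ri (compression/inflation peak
ΔF/F₀): > 2 compression-selective, < 0.5 inflation-selective, interior
polymodal. Exact boundary values fall to polymodal, the class whose
interval bounds they sit on; Rc > 0 with Ri = 0 is compression-selective.

Unhealthy cells (distinctively strong, unvarying GCaMP) are flagged when
the coefficient of variation of their *ratio* trace is below 0.01 and their
mean ratio exceeds the 90th percentile of ROI means. The ratio, not the raw
channel, is tested because a realistic shared bleaching envelope gives even
a perfectly unvarying cell a large raw-channel CV; the ratio is the
bleach-corrected signal the rest of the pipeline analyses.

Population tallies partition a cohort into compression-only,
inflation-only, both and neither; derived percentages (including pooled
any-compression/any-inflation and conditional fractions among compression
responders) are computed from counts only and rounded half-up.

## Nerve/EMG integration

Signals are rectified about their median — robust to amplifier offset and
spike asymmetry; a mean-centred variant would differ on skewed spike
distributions — then filtered with a first-order leaky integrator,
discretized exactly (`alpha = 1 − exp(−dt/τ)`), default τ = 0.02 s (the
only integration constant stated for this preparation; the hardware nerve
integrator's constant is unstated, so the EMG value is adopted for both and
exposed in config). The step response reaches 1 − 1/e of its asymptote at
t = τ. Responses are `100·(mean(stim) − mean(baseline))/mean(baseline)` of
the integrated signal (default 60-s baseline, a package convention) and are
normalized to the serotonin response over the 100 s after administration; a
nonpositive serotonin response marks the reference trial unusable.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
tested, since no raw signals are publicly deposited.

**Respiration** — 150 breaths/min, unit amplitude, 1 kHz sampling (pressure
acquisition rates are unstated; EMG/ECG hardware samples at 1–2 kHz, and
the rate is a parameter). Each cycle is a half-sine inspiration (35% duty)
followed by an alpha-function expiration that decays to ~4% of its peak by
cycle end — enough asymmetric-pressure realism to exercise segmentation
without a lung-mechanics model. Gasps and sighs scale one whole cycle by
`gasp_gain` (default 2.0; must exceed 1.5 so injected events satisfy the
detection rule by construction — detector sensitivity on clean data is
therefore 1.0 by design, and that is what the zero-noise round trip shows).
Events closer than one breath period are rejected with the colliding times
named. Compression epochs multiply cyclic amplitude by (1 − attenuation),
attenuation ∈ [0.4, 0.6] (default 0.5). Noise is additive white Gaussian —
the simplest model that exercises thresholds; no coloured noise, no
breath-to-breath variability, no baseline drift, so passing round trips
demonstrate correctness of the rules, not field robustness on real traces.

**Calcium** — 100 ROIs, 240-s session at 2 Hz (volume rates are 1.5–3 Hz)
with a 10-s compression epoch at 60 s and a 10-s inflation epoch at 160 s.
Responder ROIs carry a saturating-rise (τ 1 s), exponentially decaying
(τ 2 s) transient of peak ΔF/F₀ 1.0 on the GCaMP channel only; both
channels share one exponential bleach envelope (default τ 600 s), which the
ratiometric pipeline cancels to < 10⁻¹⁰. Channel noise is Gaussian
(s.d. 0.05 of a unit baseline). Unhealthy ROIs are constant at 5× baseline
GCaMP with zero variance.

**Nerve** — Poisson spike train (200 s⁻¹) of random-sign exponential spikes
(τ 2 ms) on Gaussian background, at 2 kHz. Epoch gains multiply the whole
process, so the rectified-integrated mean scales exactly with gain: suction
gain 1.5 → +50%, serotonin gain 3.0 → +200%, normalized response 0.25.

All generation is a pure function of (parameters, seed); one integer seed
feeds named substreams per generator, and regeneration is bit-identical.

## Problem sizes and determinism

Detector performance is estimated over 100 seeded 30-s replicates at 10%
amplitude noise (sensitivity and precision ≥ 0.95 observed at 1.0); nerve
recovery averages 20 seeded 300-s trials. `scripts/acceptance.py` derives
all replicate seeds from its `--seed` argument, so repeated runs with the
same seed are identical.

## Known limitations

- Segmentation assumes a dominant positive inspiratory deflection; inverted
  or biphasic transducer polarities must be flipped upstream.
- The eupneic tidal-volume bounds only apply where tidal volumes exist
  (flow traces); pressure-trace filtering uses the rate bound alone.
- The synthetic generator does not model rate modulation (apnoea, CNO
  time courses); Hering–Breuer quantification is tested on constructed
  breath tables instead.
- No motion correction, ROI detection, spike sorting or inferential
  statistics; epochs are inputs, never inferred from the trace.
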