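# Methods

This note documents the models, defaults and numerical choices behind
`avbind`, and what the synthetic test-bed does and does not establish.

## Stimuli

Two competing auditory streams are artificial vowels with distinct pitch
and timbre: A1 = [u] (F1–F4 = 460, 1105, 2857, 4205 Hz, F0 = 195 Hz) and
A2 = [a] (936, 1551, 2975, 4263 Hz, F0 = 175 Hz). Each stream is amplitude
modulated by an independent *noisy low-pass envelope*: Gaussian white noise
passed through a zero-phase FFT-domain low-pass (flat to 0.9× the 7-Hz
cut-off, raised-cosine roll-off reaching zero at the cut-off) and min-max
normalized to [0, 1]. Implementing the cut-off as a true band edge makes
the envelope's above-cut-off power identically zero before normalization,
which is the property the envelope is supposed to have (the visual stream
must carry no information above the modulation band). The visual stimulus
is a luminance envelope sample-identical to the AM envelope of the stream
named in the condition (V1 ↔ A1's envelope, V2 ↔ A2's).

Vowels are rendered additively: a cosine harmonic comb at F0 weighted by
the cascade gain of four two-pole resonators (default bandwidths 80, 120,
160, 200 Hz — standard vowel-synthesis values; configurable), plus a
−30 dB formant-shaped Gaussian noise floor (aspiration). The mixed
excitation matters: a strictly harmonic source at F0 = 195 Hz has no
spectral line near F1 = 460 Hz, whereas the aspiration floor puts genuine
local spectral maxima at the resonance frequencies between the harmonics,
so formant positions are verifiable from the rendered audio. The summed
source is peak-normalized before the envelope is applied. Default audio
rate 24 414 Hz; trials are 3 s (longer renderings are supported but all
analyses window to the first 3 s).

Timbre deviants are 200-ms epochs in which F1/F2 follow a raised-cosine
trajectory to another vowel's values ([u]→[ε] 730/2058 Hz; [a]→[i]
437/2761 Hz), reaching the target exactly at the epoch midpoint. During
the morph the per-harmonic gain vector is rescaled to constant total power,
so the deviant is amplitude-neutral (verified at < 5% RMS change in 50-ms
windows); outside the epoch the waveform is sample-identical to the
no-deviant rendering. Deviant onsets are free parameters (defaults: 0.8
and 2.1 s in A1; 1.3 and 2.5 s in A2), two per stream.

A conflicting F0 assignment exists between two descriptions of the
stimuli; we follow the detailed methods table (A1 = [u] at 195 Hz,
A2 = [a] at 175 Hz). Both assignments are configurable.

## Synthetic spiking units

Spikes are an inhomogeneous Poisson process (1-ms steps, uniform jitter
within a step):

```
λ(t) = baseline + Σ_s g_s·w_s·gain_auditory·env_s(t−latency)·d_s(t)
       + g_v·gain_visual·env_V(t−latency)
```

- Per-trial multiplicative gains `g ~ N(1, sd)` with
  `sd = trial_noise_sd / (1 + κ·coherent(s))`: audio-visual temporal
  coherence enters as *reliability*, not rate — mean evoked rates are
  identical across coherence conditions by construction, matching the
  negative rate control.
- Stream envelopes are rescaled to a common RMS inside the simulator;
  otherwise the random energy difference between two 3-s envelopes biases
  dual-stream decoding toward one template regardless of the visual
  stream.
- In sound mixtures accompanied by a visual stream, the coherent stream's
  drive is weighted by `1+δ` and the other stream's by `1−δ`, with
  `δ = κ/(1+κ)`. This rate-neutral representation bias is required for a
  first-order visual-preference effect: a reliability-only mechanism
  cannot move the VPI because the nearest-template decision statistic is
  linear in the response, so gain-variance changes shift label proportions
  only at second order. With the weighting, the fraction of units with
  significant VPI recovers monotonically in κ (measured ≈ 0.05 / 0.50 /
  0.92 / 0.97 at κ = 0 / 0.5 / 1 / 2).
- Deviant epochs scale the deviant stream's drive by
  `1 + deviant_gain·(1+κ·coherent)`: the deviant-evoked perturbation is
  larger in the visually bound stream, which is the binding signature the
  deviant analysis detects. Deviants occupy ≤ 0.4 s of a 3-s trial, so
  mean rates stay matched.
- Negative intensities after composition are clipped at zero.

Defaults: baseline 2–8 spikes/s, auditory gain 20–40 spikes/s per unit
envelope, latency 20 ms, trial_noise_sd 0.6, 20 trials per condition
(the recording sessions this emulates collected 14–34 repetitions,
typically 20).

## Synthetic LFP sites

Each trace (600 Hz default) is the sum of 1/f background noise, an
envelope-following evoked component, and a band-limited oscillation
implementing a *power-neutral phase reset*:

- Per trial, a carrier frequency is drawn from a clipped normal centred on
  the reset band (default 8–15 Hz, sd = band/6).
- The oscillation is a constant-amplitude FM sinusoid whose total phase is
  anchored to a fixed target (plus von Mises jitter whose resultant length
  equals `reset_strength`) at every luminance rising edge (envelope
  crossing 0.5 upward, edges closer than 0.35 s to the previous anchor
  skipped to bound the FM excursion); between anchors the phase offset
  follows a raised-cosine interpolation, so there are no transients.
- A trial-private slow (< 2 Hz) amplitude modulation (sd 0.6) decorrelates
  the residual stimulus-locked FM fine structure of single-trial power
  time courses.

Across trials this yields a decaying phase-locked transient after every
luminance edge — concentrated in the reset band, power-matched across
visual conditions — which is exactly the dissociation the phase/power
dissimilarity analysis must recover. A `power_modulation_gain` option
multiplies the oscillation amplitude by the luminance envelope, providing
a deliberately non-power-neutral control mode.

## Decoding

Responses are binned 0–3 s in 20-ms bins (half-open bins; a spike exactly
at the window end is excluded). The classifier assigns each trial to the
class with the nearest mean template (Euclidean distance), excluding the
held-out trial from its own template (LOOCV); distance ties are broken
uniformly at random under the operation seed. Dual-stream trials are
decoded against full single-stream condition templates without LOOCV,
since template and test conditions are disjoint.

Significance uses a 1000-iteration resampling null with random class
assignment; a response is informative when the observed score exceeds the
95th percentile of the null. Two schemes are implemented: class-size-
preserving label permutation (default) and bootstrap resampling with
replacement. The bootstrap null is conservatively biased — a duplicated
trial can appear in its own leave-one-out template, inflating null scores
— so the calibrated permutation scheme is the default (measured
false-positive rate 3–5% at α = 0.05, uniform p-values; the bootstrap
flags ~2%).

The VPI is reported with percentages truncated toward zero to whole
percents before subtraction (19/23 → 82); population percentages round
half-away to one decimal (91/271 → 33.6). The VPI permutation test
shuffles which single-stream trials form the two templates (1000
iterations, class sizes preserved) and compares |VPI| two-sidedly against
the null; internally the null and observed VPI use raw (untruncated)
percentages.

Unit classification decodes the auditory axis ({A1V1 ∪ A1V2} vs
{A2V1 ∪ A2V2}) and the visual axis ({A1V1 ∪ A2V1} vs {A1V2 ∪ A2V2});
simple-stimulus classification (noise bursts × light flashes) uses a
balanced two-factor ANOVA by the closed-form sums-of-squares
decomposition, with labels: sound main effect only → auditory, light main
effect only → visual, both main effects or interaction → auditory-visual
(α = 0.05 per test).

## Deviant analysis

Deviant and control (no-deviant, otherwise identical stimulus) trials are
compared over the 200-ms deviant window in 10-ms bins (20 bins) with the
same LOOCV classifier and permutation criterion; unequal trial counts are
subsampled (seeded) to the minimum. Per unit the four deviants (two per
stream) are decoded separately and grouped by coherency (deviant stream
matches the visual stream or not); the mean score is taken across all of
a group's deviants for units detecting at least one.

## LFP phase/power dissimilarity

Morlet wavelets: Gaussian-windowed complex exponentials,
σ_t = cycles/(2πf) with 7 cycles, unit energy, FFT convolution with
zero-padding; samples within 2σ_t of either trace end are flagged per
frequency and excluded from time averages. The grid is 2.5–45 Hz in
0.5-Hz steps (86 points).

Within-stimulus ITPC is the resultant length of per-trial phases, averaged
over valid times; the across term recomputes it on trial subsets drawn
without replacement across the two conditions sharing the auditory
stimulus (default 100 shuffle draws, averaged; pipeline runs use 30–50).
The PDI is within minus across, averaged over the two stimuli of a
coherency grouping (single-stream) or over the two mixtures (dual-stream).
Population significance per frequency: paired one-sided t test (within >
across) across sites, Bonferroni-corrected over frequencies (0.05/86 by
default; 0.05/43 = 0.0012 reproduces the coarser correction reported for
43 frequencies), with at least two adjacent significant bins required; the
PDI magnitude sums the site-mean PDI over retained frequencies.

The power dissimilarity control substitutes z-scored single-trial power
time courses for unit phasors: within-condition consistency is the mean
pairwise Pearson correlation of power courses (computed from summed
z-courses), the across term recomputes it on shuffled mixtures. The exact
construction of a "power analogue" is not canonical; per-trial z-scoring
was chosen so the statistic, like the phase version, discards absolute
amplitude and is sensitive only to condition-specific power *dynamics*.

Band-localization statements are resolution-limited: a 7-cycle wavelet at
frequency f has spectral sd f/7, so a band-limited oscillation legitimately
drives significance at frequencies whose 2σ passband reaches the band. The
parameter-recovery tests therefore require the significant run to include
at least two adjacent bins inside the configured band and every
significant frequency to lie within that reach.

A "driven unit" criterion is provided (`pipeline.is_driven`): a unit is
driven when in some condition the trial-mean evoked rate exceeds 1.5x the
pre-stimulus baseline rate and the excess beats a seeded sign-flip
permutation null (α = 0.05). The factor, windows and α are configurable.
Synthetic trials start at stimulus onset and contain no pre-stimulus
interval, so pipeline runs include all units unless a baseline window is
supplied with suitable data.

## Problem sizes and determinism

Every stochastic step takes an explicit seed; identical configurations
reproduce bit-identical reports (the pipeline hashes all tables). The
test-suite recovery runs use 20 seeded replicates of a 100-unit
(all-auditory, κ = 1, deviant gain 0.6) population for the spiking
directions and 6-site populations (20 trials, 30 shuffle draws) for the
LFP directions; null calibration uses 500 baseline-only units. These sizes
were chosen as the smallest populations at which the tested effects are
stable across replicates.

## What the synthetic data do and do not show

The generator encodes exactly the effects the analyses test — envelope
following, coherence-dependent reliability and representation bias,
deviant-gain enhancement, band-limited power-neutral phase resets — with
independent Poisson units and a phenomenological LFP. Passing tests
demonstrate that the pipeline recovers each effect when present, stays
null when absent, and is correctly calibrated; they say nothing about
whether real auditory cortex behaves this way (no cross-unit correlations,
no laminar structure, no biophysics, no behavioural state), and the
generator's effect sizes were set for detectability at desk scale, not
fitted to recordings.

## Known limitations

- The vowel synthesizer is additive with analog-prototype resonance gains,
  not a time-domain filter cascade; waveform details differ from
  filter-based synthesizers although spectra match at the resolution the
  tests verify.
- The bootstrap permutation variant is conservative (see above) and is
  retained only as an option.
- The LFP phase reset is implemented at luminance rising edges only;
  falling-edge or graded-luminance reset models are not implemented.
- `classify_simple_unit` requires a balanced design; unbalanced cell
  counts are rejected rather than approximated.
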