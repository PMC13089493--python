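# Methods

This note documents the models and procedures implemented in `napscape`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Pre-processing

EEG is band-passed 0.2–40 Hz with a first-order Butterworth filter applied
forward–backward (`sosfiltfilt`), so the effective magnitude response is the
squared one-pass response and event peak latencies are not phase-shifted.
Zero-phase application is our choice; it matters because K-complex
*latencies* are an outcome. Notch filters at 50/100/150/200 Hz are kept in
the interface for fidelity to the acquisition chain but are no-ops after the
40 Hz low-pass (frequencies at or above Nyquist are skipped with a log
note).

Analyses use the linked-mastoid reference (mean of TP9/TP10 subtracted from
every channel); contralateral referencing (left channels minus right
mastoid and vice versa, midline channels minus the linked average) is
available for staging-style derivations. A nap whose mastoid channels are
flagged bad is excluded rather than re-referenced differently — reference
choice changes spindle amplitudes, so consistency is prioritized over
sample size. Bad-channel flags are input metadata, not auto-detected.

Artifact masking works on 1-s windows: per-channel RMS, log-transformed,
averaged across channels, z-scored within each sleep stage; a window is
flagged at z > 3 (default). This is a covariance-free stand-in with matched
granularity for the library artifact detector used in the original
pre-processing chain, whose parameters are unpublished; the single
interpretable knob is the z threshold. Under stationary Gaussian noise the
false-flag rate is ≈ 0.1–0.5 %, and a 10× amplitude burst in one window is
flagged reliably.

## Band powers

Welch PSDs use 4-s periodic Hann segments at 50 % overlap with *median*
combining across segments. Artifact/arousal seconds are excised before
segmentation and segments never span an excision boundary, so a single bad
second cannot leak into any periodogram. We deliberately do not apply the
small-sample median-bias correction some implementations use: the raw
median keeps deterministic signals exact (a unit tone integrates to its
variance 0.5 µV²) at the cost of a uniform ≈ ln 2 downward bias on Gaussian
background power, which cancels in every between-nap and between-condition
contrast the pipeline reports. Band powers are trapezoidal integrals of the
PSD over 0.5–2 Hz (SWA, stages N2+N3 pooled) and 9–16 Hz (sigma, N2 only),
aggregated as the median across the ROI channels (SWA: F3, Fz, F4, FC1,
FC2, C3, Cz, C4, O1, Oz; sigma: the same without O1/Oz).

## Slow-wave detection

The 0.5–2 Hz signal (zero-phase Butterworth, order 3) is scanned for zero
crossings; a candidate is a maximal negative half-wave followed by a
positive half-wave. Acceptance requires: negative half-wave duration
0.3–1.5 s, positive 0.1–1 s, |negative peak| > 40 µV, positive peak
> 10 µV, peak-to-peak > 75 µV. Infant slow waves exceed adult amplitudes,
so there are no upper amplitude limits. Conventions (needed for the
stimulus-locked counts and fixed here because they were open): event onset
is the down-going zero crossing, offset the end of the positive half-wave,
the negative peak time is the arg-min within the negative half-wave;
amplitudes are measured on the band-passed signal; candidates touching an
ineligible sample are discarded, not clipped; a sample is "negative" when
strictly below zero. The detector is verified event-for-event against a
brute-force half-wave enumerator on hundreds of synthetic signals.

SW density = events per artifact-free N2+N3 minute per channel, median over
the 10-channel ROI.

## Sleep spindle detection

Three per-sample features over a common grid:

1. **moving RMS** of the 9–16 Hz (4th-order Butterworth, zero-phase)
   signal, 0.3-s window;
2. **moving correlation** between the broadband (0.2–40 Hz preprocessed)
   and sigma-filtered signals, 0.3-s window;
3. **relative sigma power**, sigma/total power per 2-s Hann STFT frame
   (0.2-s step), linearly interpolated to the sample grid.

Each feature votes where it exceeds its threshold. The RMS threshold is
soft — mean + 1.275 SD of the moving-RMS series over eligible sleep — and
the correlation and relative-power thresholds are absolute (0.52 and 0.13).
These are the infant-adjusted values, 85 %/80 %/65 % of the adult defaults
(1.5 σ, 0.65, 0.2): infant spindles are lower-amplitude, longer, and lack
the adult waxing–waning envelope. The vote count is smoothed over 0.1 s;
maximal runs with ≥ 2 of 3 votes are candidates; candidates closer than
750 ms merge; events outside 0.5–4 s are discarded, as are events not fully
inside eligible runs. Spindle density = events per artifact-free N2 minute,
aggregated across the 8-channel ROI by the median (consistent with the
slow-wave measures; a mean aggregate is available since the density
definition said only "averaged").

The broadband band for the moving correlation (0.2–40 Hz) follows the
preprocessed band; it was unstated.

## Detector tuning

Detected and annotated events match greedily 1–1 by overlap amount, any
overlap counting by default (minimum-overlap configurable); performance is
event-level F1. The grid search maximizes *pooled* (micro-averaged) F1 over
(RMS, correlation, relative-power) threshold cells on training naps — the
per-nap mean F1 is also reported — with ties broken toward higher precision
and then higher thresholds, and persists the full surface. Validation uses
a held-out split of exchangeable naps. Comparing the manual-vs-detector
density correlations of two detector variants uses Steiger's (1980) test
for dependent correlations sharing one variable, with the back-transformed
average correlation in the covariance term.

## Stimulus-locked statistics

Tone pairs: two 1-s tones 700 ms apart, 12–18 s (uniform) between pairs.
Only S1 responses are scored (evoked K-complexes have a refractory period).
Windows, all half-open `[low, high)` in S1-relative time:

| window | span | rationale |
|---|---|---|
| K-complex ON | 0.45–0.70 s | negative-peak latency of evoked K-complexes |
| K-complex OFF | −1.25 to −1.00 s | matched 250-ms pre-stimulus control |
| spindle ON | 0–3.4 s | S1 + gap + S2 + an equal post-S2 interval |
| spindle OFF | −3.4–0 s | matched control |
| spindle segment | −4.4 to +4.4 s | ON+OFF plus 1-s edge buffers |
| K-complex segment | −4.15 to +12.35 s | detector minimum-length requirement |

The K-complex segment endpoints are implemented as stated even though their
span (16.5 s) disagrees with their "16-second" label in the source
description. A stimulus is *eligible* when every second its segment
overlaps is artifact/arousal-free N2 (evaluated on the 1-s grid). K-complex
likelihood = detected slow waves on Cz with a negative peak in the window,
divided by the number of eligible S1; spindle likelihood is the same with
membership decided by event *start* time. Evoked averages are time-locked
means across stimuli then central channels, baseline-corrected by the
pre-S1 window mean.

## Macroarchitecture and arousals

Sleep onset = first epoch of any sleep stage after lights-off (first-N2
optional); offset = end of the last sleep epoch. SOL = onset − lights-off;
WASO = wake between onset and offset; nap duration = total sleep time.
Efficiency defaults to TST over the sleep period (onset→offset): reported
nap efficiencies of ~97 % alongside ~10-min onset latencies are only
consistent with that denominator; a lights-off→offset variant is available.
Arousal density = non-external arousals / ((sleep period − total arousal
time)/60); arousals attributed to known external causes are excluded from
the count and their duration from the denominator (the source specifies the
numerator; removing the time as well keeps the denominator meaning "time in
which arousals could occur").

## Sensory reactivity

Composite = mean of reverse-scored (6 − raw) non-NA items over the 13
sensitivity + 11 avoidance items; nobody is excluded by NA count.
Classification labels ("more reactive" > 1.9, "much more reactive" > 2.5)
are optional output. Cronbach's alpha uses listwise deletion.

## Mixed models

Outcomes are modelled as
`y ~ stimulation + reactivity + sex + age + (1|subject)` (base) and with
`+ stimulation:reactivity` (interaction); sensitivity variants add autism
likelihood; the arousal-density model adds sleep arrangement; the
likelihood outcomes replace nap condition with the stimulus window (OFF=0,
ON=1) within stimulation naps. Estimation is maximum likelihood via
statsmodels `MixedLM` (with internal column scaling for optimizer
conditioning). Satterthwaite degrees of freedom are computed analytically
for the random-intercept model: with per-group covariance
V = σ²I + τ²J, df_j = 2·C_jj² / (gᵀ A g), where C = (XᵀV⁻¹X)⁻¹, g is the
gradient of C_jj in (σ², τ²) and A the inverse expected information. On
reference data the estimates, SEs, dfs and p-values agree with R's
`lmerTest` (ML) to at least four decimals. Main effects are reported from
the base model and the interaction from the interaction model.
Standardized coefficients come from refitting with the z-scored outcome and
continuous predictors (binary predictors stay 0/1); note that in an
interaction model this evaluates the condition effect at the mean
reactivity, which is the standard consequence of centring.

Winsorization replaces values with |z| > 4 (z from the full sample) by the
highest non-outlier value plus one declared unit (sign-respecting for low
outliers); the unit defaults to 1.0 and is exposed because the variable's
natural granularity is context-dependent.

Stage proportions are modelled with a zero-inflated beta GLMM —
`prop ~ stage * condition * reactivity + (1|subject)`, logit link,
intercept-only zero-inflation, N1 reference — delegated to R `glmmTMB`
(exact ones are nudged to 1−10⁻⁶, zeros are handled by the inflation
component). The contract pins family, link, reference coding and
random-effects structure, not the backend's internals.

## Synthetic data generator

The generator defines the conditions under which the pipeline is tested.

**Background**: spectrally shaped Gaussian noise with power ∝ f^−1.8
(flat below 0.3 Hz), scaled per stage to broadband RMS
W 25 / N1 30 / REM 30 / N2 40 / N3 60 µV — the calibration is qualitative
(N3 > N2 > N1/REM ordering), with no claim of matching infant spectra
beyond band-power ordering. The exponent matters: it sets the background
sigma-band share (≈ 13 % of RMS at 1.8), hence both the detector's false
vote rate and the absolute size of an "SNR 3" spindle. Channels are
independent draws sharing planted events; mastoids carry 0.5× background
and no events.

**Hypnograms**: semi-Markov stage bouts (geometric lengths around
N1 3 / N2 8 / N3 10 / REM 5 minutes, scaled down proportionally for short
test naps so stage mixture is preserved), rare brief wake bouts
(efficiency ≥ 95 %), lognormal-free fixed-target durations (the nap
duration is a parameter; study-scale defaults 60 min with 10-min onset
latency). Arousals: Poisson, 5.4 per 60-min nap, 3–15 s, 10 % flagged
external. Artifacts: 3.6 % of seconds, as 1-s 6× amplitude bursts.

**Spindles**: Poisson rates 3/min in N2 and 0.5/min in N3; duration
U(0.5, 2) s, frequency U(10, 14) Hz, Tukey(α = 0.2) envelope — mostly flat
with raised-cosine ramps, reflecting the absent waxing–waning shape of
infant spindles. SNR is defined as the burst's sigma-band RMS at envelope
peak over the background sigma-band RMS (peak amplitude = √2·SNR·σ_bg).

**Slow waves / K-complexes**: biphasic half-sine pairs drawn to satisfy the
detection criteria by construction (spontaneous: negative half 0.4–1.0 s at
60–120 µV, rates 3/min N2 and 6/min N3; evoked: negative half 0.5–0.7 s at
150–220 µV with positive peaks 40–70 µV, reflecting the large, sharp
evoked K-complexes of infant sleep). Evoked K-complexes occur after each S1
falling in N2/N3 with probability `p_evoked` (default 0.35, consistent with
an ON−OFF likelihood contrast near 0.38), at a latency drawn from a
truncated normal (0.55 ± 0.04 s on [0.45, 0.70]), positioned so the
waveform's negative peak sits at S1 + latency. Events keep a 2.5-s minimum
separation so ground truth stays unambiguous; near-threshold spontaneous
waves (60–90 µV) may legitimately fall below criteria after band-pass
attenuation — they are background, and being time-uniform they cancel in
every ON−OFF contrast.

**Cohort layer**: per-subject latent reactivity ~ truncated normal
(1.7 ± 0.35 on [1.14, 2.78]); questionnaire items = rounded/clipped latent
+ N(0, 0.5) noise with NA probability 2 % (20 % for five designated
age-inappropriate items, giving a median of ~1 NA and a long tail); item
noise calibrated to Cronbach's alpha ≈ 0.85. Outcome rows are drawn from a
planted linear mixed model (per-outcome intercept, condition, reactivity
and interaction effects defaulting to the reported unstandardized
magnitudes, e.g. −1.279 for the spindle-density interaction; random
intercept and residual SDs chosen to give study-like effect sizes), with
reactivity entered as the *scored* composite so recovery is exact with
respect to the model actually fitted. Condition order is counterbalanced.

**What passing tests show — and don't.** Recovery results demonstrate that
the chain is internally correct under a generator whose events are
criteria-true, time-locked exactly, and embedded in stationary 1/f
background. Real infant EEG has non-stationary spectra, topographic
structure, movement artifacts correlated with arousals, spindle/slow-wave
morphology variation, and annotation noise; detector scores on real data
(event-level F1 ≈ 0.55–0.59 in the source study) are far below the
synthetic recoveries here, and nothing in this test suite certifies
real-data performance.

## Problem sizes

Default test/acceptance scales: 8–15-minute naps with 1–4 channels for
detector studies (20 naps for SNR-3 recovery, 10 × (5+5) naps for tuning,
50 naps for likelihood recovery), 200 cohorts of 35 subjects for
interaction recovery and 1000 for type-I error, chosen as the package's own
test scale; study-scale parameters (60-minute naps, 12 channels, 35
subjects) remain the generator defaults.

## Known limitations

- The artifact detector is a standardized log-RMS stand-in, not a
  reimplementation of the original library function (whose parameters are
  unpublished).
- Channels in the generator are independent; topography (and hence
  cross-channel aggregation behaviour under correlated noise) is untested.
- The Satterthwaite machinery covers the random-intercept structure used
  here, not general random-effects designs.
- The stage-proportion GLMM requires `Rscript` with `glmmTMB` on PATH.
- Spindle detection near eligibility boundaries is conservative (events
  must lie fully inside eligible runs), which can drop boundary events that
  a human scorer would keep.
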