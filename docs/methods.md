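# Methods

`fearephys` quantifies single-unit and intracellular electrophysiology
recorded during discriminative fear conditioning, and ships a synthetic-data
generator with known ground truth so every stage of the quantification can be
exercised and validated offline.

## Protocol model

A conditioning session is represented as an ordered timeline of half-open
epochs `[onset, onset + duration)` in seconds from session start. The default
session is a 10 min baseline followed by 20 randomly interleaved trials — 10
CS+ (a 10 s constant light cue whose final 0.5 s is a co-terminating
footshock, the US) and 10 CS− (a light flashing 5 × 200 ms at 2 s intervals,
no shock) — each followed by a 110 s inter-trial interval (ITI). Total
default session length is therefore 600 + 20 × 120 = 3000 s. A 2 min
baseline preset exists for behavior-style sessions; the recording default is
10 min.

Two conventions are our own choices rather than protocol facts:

* **CS− window length.** The CS− cue functionally ends with its last flash
  (8.2 s), but we give CS− analysis windows the same 10 s nominal duration as
  CS+ so the two PSTHs are directly comparable; flash onsets are carried as
  epoch metadata.
* **Interleaving constraint.** "Randomly interleaved" is implemented as a
  uniformly random order rejected until no more than 3 consecutive trials
  share a type, a common constraint in conditioning designs.

## Unit quantification

Firing is binned (rate = count / bin width on half-open bins) and normalized
to the session baseline with a Z-score

```
Z_i = (R_i − R_m) / S.D.
```

where `R_i` is the rate in bin `i`, and `R_m` and `S.D.` are the mean and
sample standard deviation (ddof = 1) of the baseline bin rates. A unit is
**activated** by a stimulus if the trial-averaged stimulus-aligned Z exceeds
+1 in any bin within the first 500 ms after onset, and **inhibited** if it is
not activated and Z falls below −0.5 in that window. Units whose baseline
variance is zero (e.g. silent units) are **unclassifiable**; we do not floor
the standard deviation.

Bin widths are configurable and default to 100 ms for classification (five
bins tile the 500 ms decision window), 20 ms for latency, and 50 ms for
display curves. Classification operates on the trial-averaged Z curve. Note
that at fine (20 ms) bins the trial-averaged baseline Z fluctuates at about
0.7 of the 100 ms-bin S.D. (the S.D. is estimated at the coarser width), so
a latency threshold of +1 will occasionally trip on noise; latency analyses
that need to be noise-robust should raise the threshold, as the latency-shift
recovery test does.

Derived readouts:

* **Response curve / AUC** — trial-averaged Z against time from stimulus
  onset, with the area under the mean curve over a declared post-onset window
  (default [0, 1] s, trapezoidal rule, units Z·s). This is the plasticity
  readout compared across conditioning days.
* **Concatenated percent change** — 100 × (rate over all trial+ITI spans of
  one stimulus, concatenated, minus `R_m`) / `R_m`; undefined when the
  baseline rate is zero. Averaging is per-unit first, then group mean ± sem.
* **Latency** — left edge of the first fine bin crossing the threshold,
  censored if no crossing within the window; population latencies are
  summarized as right-continuous ECDFs with censored counts reported.
* **Discrimination contrast** — per matched unit, mean response-window Z for
  CS+ minus CS−; the group p-value comes from shuffling trial labels within
  each unit (10 000 seeded permutations by default). Permutation tests stand
  in for repeated-measures ANOVA throughout the tested core; classical ANOVA
  can be run on the tidy output tables with any standard statistics package.

The baseline for stimulus-aligned Z is the session baseline; a per-trial
pre-stimulus baseline can be configured. Both conventions appear in the
literature, so the choice is a declared default rather than a field standard.

## Synthetic spike trains

Units are inhomogeneous Poisson processes: a constant baseline rate
(log-uniform on 1–20 Hz across a cohort, a declared assumption since real
baseline distributions are only available graphically) modulated by
stimulus-locked difference-of-exponentials kernels

```
k(t) = (e^{−t/τ_d} − e^{−t/τ_r}) / k_peak ,   τ_r < τ_d ,
```

peak-normalized so a response "gain" is the peak fractional rate change.
Excitation is additive, `rate = b(1 + Σ g·m·k)`; inhibition is
multiplicative, `rate = b·Π(1 − g·m·k)`, with `g·m ≤ 1` enforced at profile
validation and the rate clipped at zero. Sampling is by thinning against a
piecewise-constant envelope (baseline outside kernel support, elevated
inside), which the time-rescaling test validates against Exp(1) rescaled
intervals.

Cohorts are mixtures over five profile classes — US-activated, US-inhibited,
CS-activated, CS-inhibited, non-responsive (default weights 0.30 / 0.10 /
0.25 / 0.20 / 0.15) — with class counts drawn once from a multinomial. The
per-stimulus gain is multiplied by a day trajectory, the only thing the two
presets differ in:

| class | stimulus | gain | control-like trajectory (d1→d3) | ko-like |
|---|---|---|---|---|
| us_activated | US | 6.0 | 1.0 → 1.8 → 1.0 (transient) | flat |
| us_inhibited | US | 0.8 | flat | flat |
| cs_activated | CS+ | 2.5 | 1.0 → 1.6 → 2.2 (growing) | flat |
| cs_activated | CS− | 2.0 | flat | flat |
| cs_inhibited | CS+ | 0.6 | flat | flat |
| cs_inhibited | CS− | 0.7 | 1.0 → 0.65 → 0.35 (shrinking) | flat |

Kinetics: US responses use latency 20 ms, rise 10 ms, decay 150 ms; CS
responses latency 50 ms, rise 20 ms, decay 300 ms. These magnitudes are free
parameters — the phenomena they emulate are reported only graphically — and
were chosen once for physiological plausibility (shock responses are strong
and fast; cue responses moderate and slower). They are documented here
precisely because no quantitative published value constrains them.

What the generator does **not** emulate: bursting and refractoriness,
rate drift and electrode instability across a session, correlated noise
across simultaneously recorded units, units responsive to several stimulus
classes at once, and day-to-day unit identity loss (real recordings sample
different units each day; the simulator keeps unit identity). Passing
recovery tests therefore shows the quantification recovers what it assumes —
Poisson firing with transient kernels — not that it is robust to every
failure mode of real tetrode data.

## Slice quantification

Evoked compound PSPs (current clamp, mV) are averaged pointwise over 15–30
sweeps per cell; the pharmacologically isolated EPSP average is digitally
subtracted from the compound average to give the IPSP, with no filtering, so
`EPSP + IPSP = compound` holds by construction. Amplitudes are
baseline-to-peak — baseline mean over a 50 ms pre-stimulus window, extremum
over a 200 ms post-stimulus search window (both configurable) — and the E/I
ratio is the EPSP:IPSP amplitude ratio, a scale-free index of
excitatory/inhibitory balance. E/I ratios are sometimes computed on peak
amplitudes and sometimes on areas; peak amplitude is the default here and
area integration can be layered on the same decomposition.

Miniature events (voltage clamp at −60 mV; inward, i.e. negative-going for
both mEPSCs and, with a high-chloride internal, mIPSCs) are detected by
threshold crossing: the trace is detrended with a 50 ms moving-median
baseline, noise is estimated as a Gaussian-consistent MAD on the detrended
trace, and peaks are searched on a 1 ms moving-average smoothed copy with an
amplitude criterion of 3 × the raw noise sd (so single-sample noise spikes,
which sit many smoothed-noise sd below the threshold, cannot trigger).
Candidates closer than 5 ms merge into the larger one and candidates with a
10%-to-peak rise slower than 5 ms are rejected. This detector replaces the
manual-inspection step of interactive mini-analysis software with an
automatic, seeded, testable rule. Frequency is count/duration; amplitude and
inter-event-interval distributions are reported as ECDFs; group comparisons
(naive vs shocked, per cell) use a seeded label-permutation test on the
difference of group means.

## Numerical choices

* Time is float seconds; all windows half-open; ties at bin edges go to the
  right bin (the final `numpy.histogram` bin is re-opened to keep this).
* AUC uses the trapezoidal rule on bin centers within the declared window.
* ECDFs step at every distinct value with jump = multiplicity/n and are
  right-continuous; censored observations are excluded from the CDF and
  counted separately.
* Permutation p-values use the add-one correction `(hits + 1)/(B + 1)`.
* Degenerate inputs fail loudly: zero-variance baselines raise (or map to
  the UNCLASSIFIABLE label in the cohort pipeline), zero IPSP amplitude
  raises on ratio computation, all-censored latency sets refuse an ECDF.
* Exact spike-timestamp duplicates after thinning (a measure-zero event) are
  dropped to preserve the strictly-sorted invariant.

## Problem sizes used in validation

The shipped validation runs use cohorts of 60 units × 3 days × 10 seeds per
preset for plasticity recovery, 10 000 homogeneous-Poisson units for
classifier false-positive calibration, 14 cells per group × 20 replicates
(60 s sweeps at 5 kHz) for the mini-frequency power study, and 300 s sweeps
for detector recall/precision. These sizes were chosen to give stable
Monte-Carlo estimates at desk scale; all are configurable.

## Known limitations

* The Poisson assumption ignores refractoriness; at very high gains the
  thinning sampler remains correct but real neurons would saturate.
* Classification at the fixed (+1, −0.5) threshold pair is asymmetrically
  sensitive: weak inhibition is harder to detect than weak activation at
  equal |gain| because rates are bounded below by zero.
* The mini detector is tuned for well-separated events; at rates above a few
  Hz refractory merging biases frequency downward.
* Group inference is permutation-based; no repeated-measures structure is
  modeled within the tested core.
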