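# Methods

`wtea` implements wave-train electrical-activity analysis: EEG fragments are
transformed into complex-Morlet wavelet spectrograms, local spectrogram
maxima ("wave trains") are extracted and described by six characteristics,
and two groups of fragments are compared through the per-fragment *rate* of
wave trains falling inside a constraint subspace and a frequency band.  The
comparison statistic is the ROC AUC of the two groups' rates, mapped over
every frequency band (an *AUC diagram*), and constraint subspaces are found
by a genetic search.  This note records the model, the conventions the
package fixes where the method leaves them open, and what the synthetic
generator does and does not emulate.

## Wavelet transform and power calibration

The analyzing wavelet is

    psi(x) = (pi * Fb)^(-1/2) * exp(2*pi*i*Fc*x) * exp(-x^2 / Fb),

with bandwidth and center parameters `Fb = Fc = 1` by default.  The
coefficient at analyzed frequency `f` and time `t` is the cross-correlation
of the signal with `psi(f (tau - t))`; with `Fc = 1` this assigns scale
`1/f` to frequency `f`.  The default analysis grid is 0.1–50 Hz in 0.1 Hz
steps (500 rows).  Two interchangeable implementations exist — frequency-
domain multiplication with the wavelet's analytic Gaussian response, and
direct time-domain convolution with a sampled kernel (truncated where the
envelope falls below ~1e-16) — and they agree to better than 1e-10
relative; the FFT route is the default, the direct route serves as an
independent oracle in the tests.

**Power convention.** Coefficients are amplitude-normalized ("1/a"
convention): a sinusoid of amplitude A produces a flat ridge whose argmax
over frequency lies exactly at the tone frequency.  The squared modulus is
scaled to a one-sided PSD in uV²/Hz anchored at a calibration frequency
`cal_freq` (default 8 Hz, the center of the spike–wave/spindle band): the
ridge peak equals `(A²/2) / ENBW(cal_freq)` with
`ENBW(f) = f / sqrt(2 pi Fb)` the wavelet filter's equivalent noise
bandwidth.  At 8 Hz this matches the Welch PSD peak obtained with a
Gaussian window whose time standard deviation equals the wavelet envelope's
(`calibrate_power` verifies the closed form numerically to < 0.1%).

The alternative — dividing each row by its *own* ENBW — yields a strictly
per-frequency density but tilts every ridge: the argmax of a tone's column
moves down by the factor `1 + 1/(4 pi² Fb)` (~2.5%), biasing central
frequencies.  Since the method's criteria bound central frequency directly
(e.g. "no more than 8.5 Hz"), unbiased ridge positions matter more than a
frequency-uniform absolute scale; the anchored convention is exact at 8 Hz
and drifts linearly with frequency elsewhere.  Absolute PSD thresholds (the
50,000 uV²/Hz red criterion) therefore refer to this convention and remain
configuration values.

**Cone of influence.** Values within `sqrt(Fb)/(pi f)` seconds of either
fragment edge, and whole rows whose wavelet e-folding time `sqrt(Fb)/f`
exceeds half the fragment, are masked; candidate maxima there are
discarded.  This costs sensitivity below ~0.5 Hz on 5–10 s fragments, which
is acceptable because all criteria act above 2 Hz.

## Wave trains

A wave train is a spectrogram cell strictly greater than its 8 neighbours,
at or above a power floor, outside the cone of influence.  Its six
characteristics: central frequency (grid frequency of the peak), maximum
PSD, duration in seconds and in periods (half-height run along the peak's
frequency row; periods = seconds x central frequency by construction),
bandwidth (half-height run along the peak's time column), and instantaneous
phase (argument of the complex coefficient at the peak, in (-pi, pi], no
unwrapping).  Half-height extents are one-dimensional runs, not 2-D
contours, which keeps them unambiguous for tilted ridges; a run reaching
the matrix border is measured one-sided and the train flagged truncated
(truncated trains are excluded from subspace searches by default).  When
two maxima's half-height boxes overlap by at least 50% (intersection over
the smaller box), only the higher-power one is kept.

**Power floor.** For a single fragment the default floor is 5x the median
of its spectrogram.  For *group comparisons* the pipeline instead pools the
median over all fragments of the dataset (same 5x factor).  The
distinction matters: a per-fragment floor renormalizes away genuine
between-group differences in absolute power — during a discharge the
broadband background is suppressed, the fragment's median power drops, a
per-fragment floor drops with it, and the suppression becomes invisible in
the counts.  The pooled floor preserves it.  Both strategies, the factor,
and an absolute floor are configuration knobs.

## AUC diagrams

For a band [lo, hi] (inclusive on both ends) and a constraint box, each
fragment contributes one rate: the number of its wave trains inside box and
band divided by the annotated fragment duration.  The cell's AUC is the
Mann–Whitney statistic of the two groups' rates with half credit for ties
(AUC = U/(nm)); the first group is the positive class, so 1 means "more
wave trains in the first group" (red) and 0 fewer (blue).  The full
diagram over all (lower, upper) pairs of the 0.1 Hz grid is computed from
per-fragment cumulative counts: for a fragment pair the band comparison
reduces to the sign of `d_b * C_a - d_a * C_b` evaluated at the band's two
endpoints, so each pair contributes an outer comparison of two prefix
vectors and every cell is exact (integer counts, no accumulation error).
Characteristic diagrams use the same machinery over a grid of bounds on one
characteristic (default: 100 uniform bins spanning the pooled observed
range).

Group-swap maps every cell AUC to 1 - AUC exactly at the level of pair
counts; after the final division the two can differ by one ulp.

## Genetic subspace search

A chromosome is 12 reals — lower/upper bound per characteristic, with
bounds at the observed data-range endpoints decoded as "unbounded".
Fitness is the best cell of the frequency diagram under the box, evaluated
on a coarsened 0.5 Hz grid: `max (AUC - 0.5)` for a red search,
`max (0.5 - AUC)` for blue; boxes keeping fewer than `min_support` (default
1.0) trains per fragment on average score -inf, which blocks degenerate
one-train boxes from reaching AUC 1.  Operators: tournament selection
(size 3), uniform crossover (rate 0.7), Gaussian mutation (sigma = 10% of
each characteristic's range, clipped), elitism of one; population 64,
100 generations by default; fully deterministic under the config seed.
The winner is re-evaluated on the full 0.1 Hz grid, and bounds within 2%
of a characteristic's data range are reported as unbounded, mirroring how
discovered criteria are quoted with most cells open.  Fitness uses the
single best cell rather than the area of the red/blue region, matching how
one refined diagram is reported per constraint set.

## Statistics

Mann–Whitney p-values are two-sided: exact enumeration when n+m <= 20 with
no ties, otherwise the normal approximation with tie and continuity
corrections.  Spearman's rho is the Pearson correlation of mid-ranks; for
n <= 9 the p-value is an exact permutation probability over all n!
orderings (valid under ties), above that the t approximation.  No
multiple-testing correction is applied across diagram cells; note that box
selection and significance testing reuse the same fragments unless the
caller splits them — the reported p-values describe the selected cells, not
a confirmatory test on held-out data.  Histograms use Freedman–Diaconis
bins on the pooled rates (minimum 10); the separation statistic is the
overlap coefficient of the two normalized histograms.

## Synthetic EEG generator

Recorded rat EEG underlying the published criteria is not deposited, so the
generator emulates the four documented signal classes and defines the
conditions under which the pipeline's claims are tested:

* **Background**: Gaussian noise spectrally shaped to 1/f (exponent
  configurable), band-limited 0.1–120 Hz, exact-RMS normalized.  Default
  RMS 200 uV: with the power convention above, this places
  immature-discharge ridge PSDs (~1.3e5 uV²/Hz) above the 50,000 uV²/Hz
  criterion and background noise maxima (~6e3) well below it, i.e. the
  published threshold is meaningful on the synthetic scale.  Chosen from
  this closed-form calibration argument, once.
* **Mature SWD** (> 2 s by definition): phase-accumulated spike–wave
  cycles — slow sine fundamental plus a sharp derivative-of-Gaussian spike
  at a fixed cycle phase, spike/wave amplitude ratio 1.8 — with cycle
  frequency decaying exponentially from 11.5 Hz to a stable 7.5 Hz within
  0.5 s.  The periodic spike train produces the documented harmonic
  Fourier structure.
* **Immature discharge**: the same cycle construction but nearly symmetric
  (ratio 0.7), blunter spikes (12% of the cycle vs 4.5% for mature), 30%
  of cycles lacking their spike, and per-cycle frequency following a
  reflected random walk in 5.5–8.5 Hz — no stable fundamental, hence no
  harmonic peaks.
* **Sleep spindle**: a Hann-envelope (waxing–waning) packet whose carrier
  random-walks inside 7–14 Hz, with occasional small sharp waves.

Events are scaled so their peak-to-peak amplitude equals `ratio x 2 x 3.5 x
background_rms` (3.5 ~ the peak/RMS excursion of Gaussian noise over a few
seconds), translating amplitude ratios stated "as seen on the trace"
(mature 3x, spindle 2x, immature 2.2x) into waveform scalings; this also
yields the RMS ordering background < spindle ~ immature < mature.  During
any event the added background is attenuated by 0.5 (amplitude), emulating
the event-locked suppression of broadband noise-type activity; this is the
mechanism behind the blue (bandwidth >= 2 Hz) criterion and can be turned
off.  Per-fragment seeds derive from the master seed through a counter
scheme, so a dataset is a pure function of (config, seed) and is stable
under fragment reordering.

What the generator does *not* emulate: multi-channel/spatial structure,
sleep staging and state transitions, artifacts (EMG, movement, line noise),
inter-animal variability, and events embedded in longer recordings (each
fragment is one annotated event or background stretch).  Passing the
simulation-based acceptance checks therefore shows the pipeline recovers
the documented class differences when the morphology assumptions hold; it
is not evidence about recorded EEG.

## Problem sizes and numerics

The reference comparison runs 9 immature vs 9 background fragments of
5–10 s at 500 Hz (and 6 vs 6 for the spindle contrast in the test suite) —
the full pipeline takes ~15 s on one core, dominated by the 500-row
spectrograms.  GA-based tests use population 24 / 20 generations on
synthetic feature tables, which recover planted thresholds in seconds.
Degenerate inputs are rejected loudly: empty signals, frequencies at or
above Nyquist, bands with lo >= hi, empty groups, fragments shorter than
the zero-phase filter transient.  Ties in AUC and rank statistics use the
half-credit / mid-rank conventions throughout, so the AUC–U identity holds
exactly including ties.
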