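# Methods

This note records the models, parameter choices and numerical decisions
behind `ripplesync`, and what the synthetic-data validation does and does
not establish.

## Detection model

The detector is the classical envelope-threshold scheme. The trace is
band-passed with a 4th-order Butterworth filter applied forward–backward
(`sosfiltfilt`), so the filter is zero-phase: event peak times are not
skewed by group delay, which matters downstream when peak times enter the
cross-correlogram at 5 ms resolution. The envelope is the magnitude of the
analytic signal from the Hilbert transform. We use |analytic| rather than
|analytic|²; the squared-envelope variant is available
(`ripple_envelope_z(..., squared=True)`) and changes only the effective
threshold, not event ordering.

The envelope is z-scored against its mean and SD over the whole session
(default) or immobile samples only; the first and last 0.5 s are excluded
from the estimate because `filtfilt` edge transients inflate the SD.
Whole-session normalization is the default because the detection threshold
is then a property of the recording, not of the behavioral schedule.

Events are maximal runs of samples with z > 5. Two pragmatic parameters
shape run segmentation, both recorded in output metadata and configurable:

- `merge_gap_ms = 10`: supra-threshold runs separated by less than this
  are one event. Envelope ripple at the carrier frequency (~5 ms period)
  otherwise fragments single physiological events.
- `min_duration_ms = 5`: shorter runs are discarded; a 150–250 Hz
  oscillation needs ≥1 cycle (≥4–7 ms) to be a ripple at all.

Duration is the merged supra-threshold extent itself — no secondary
lower-threshold edge extension is applied, so reported durations are
systematically shorter than full-envelope widths; comparisons between
groups are unaffected because the rule is identical everywhere. An event
is kept iff the sample at its z-peak is immobile (speed < 2 cm/s, strict
inequality): peak-based gating is the least destructive reading of
"restricted to immobility" and avoids discarding events that merely
straddle a movement-onset boundary.

Spectral metrics use a Hann-window periodogram of the *raw* (unfiltered)
snippet, padded symmetrically to at least 64 ms so the 150–250 Hz band
contains ~7 frequency bins. Mean power is the mean of 10·log10(PSD) over
in-band bins; the frequency peak is the in-band argmax.

Sharp waves are detected with the same machinery on the 1–50 Hz band
(5σ, no immobility gate), and a ripple is flagged as co-occurring when
any sharp-wave peak lies within ±30 ms of the ripple peak
(peak-to-peak anchoring).

## Motion gating

Running speed comes from central differences on boxcar-smoothed
(0.4 s default) head positions; two-LED tracking is reduced to the LED
midpoint. Speed is resampled to the LFP clock by previous-value hold, so
the immobility mask is piecewise constant between 50 Hz camera fixes, and
samples outside the tracked range count as mobile. No hysteresis is
applied around the 2 cm/s threshold.

## Cross-correlogram

For each CA1 ripple peak t, MEC peaks u with |u − t| ≤ 100 ms increment
the 5 ms bin nearest to u − t; counts are divided by total immobile
duration so sessions of different lengths are comparable. 5 ms bins
resolve the ~15 ms separation between the two coordination regimes of
interest while keeping per-bin counts stable at realistic event rates.
The peak lag is the center of the argmax bin after a 3-bin boxcar smooth;
exact ties break toward the smallest |lag|, then toward the negative
(MEC-leads) side. An all-zero correlogram has no defined lag and returns
`None` rather than a number.

## Granger causality

Both regions' envelope z-series are sparsified — z kept where z > 5,
zero elsewhere, with **no** velocity mask (the series would otherwise be
almost entirely empty) — and modelled as a bivariate VAR fitted by
conditional least squares. Direction x→y is tested with the nested-model
F-statistic

    F = ((RSS_r − RSS_f) / p) / (RSS_f / (n − 2p − 1)),

where the restricted model regresses y on its own p lags and the full
model adds x's p lags. The order p minimizes AIC (default) or BIC over
1–50, all candidates fitted on the common sample so criteria are
comparable; ties go to the smallest order. All four nested regressions of
a pair are solved on subblocks of one Gram matrix, which makes the
50-order search cheap even on long series; each series is pre-scaled by
its SD (the criteria and F are invariant to per-series scale) to condition
the normal equations.

**Sampling rate.** The default pipeline decimates the envelope z-series
to 100 Hz (zero-phase FIR anti-aliasing, factor 20 from a 2 kHz
recording) before sparsification, via `decimate_envelope`. The envelope
of a 150–250 Hz band carries at most ~100 Hz of bandwidth, so the native
rate oversamples it ~20-fold; at 2 kHz the VAR residuals are so strongly
autocorrelated that the F-test — whose null assumes independent
residuals — treats every sample as fresh evidence and drives *both*
directions to p ≈ 0 on any coupled pair, erasing the direction contrast
the analysis exists to measure. At 100 Hz the series is approximately
critically sampled and one 10 ms step covers the relevant coordination
lags, with order 50 spanning 500 ms of history. Analysis at the native
rate remains available (`decimate_factor = 1`).

Significance is binary at α = 0.05 after Benjamini–Hochberg FDR across
the family of all tests within one session (all pairs × 2 directions);
BH rather than BY because nothing suggests the tests' dependence requires
the more conservative bound. Binary outcomes are averaged over sessions
within each electrode pair, then over pairs per direction; pairs whose
sparsified series are empty or rank-deficient are excluded and logged
rather than contributing a spurious 0 or 1.

## Group statistics

Electrodes are the unit of analysis; per-session values are averaged
within electrode first. The rank-sum test uses the exact null when the
pooled sample is ≤ 20 and tie-free, and the tie- and continuity-corrected
normal approximation otherwise (`scipy.stats.mannwhitneyu` under the
hood; tests pin it against full enumeration for all group sizes ≤ 8).
The two-sample KS test uses the asymptotic null. Group means are
reported ± SD/√n over electrodes. A sex-pooling helper implements the
compare-then-pool design (pool when the between-sex rank-sum is
non-significant).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with exact ground truth:

- **Background**: seeded 1/f^α Gaussian noise per channel (α = 1,
  SD 30 μV), independent between regions. This reproduces the broadband
  spectral tilt of cortical LFP; it does not contain theta, gamma, or
  movement artifacts.
- **Ripples**: sinusoidal carriers (200 Hz) under an alpha-like envelope
  with a 6 ms rise constant and an exponentially decaying tail whose
  time constant is the per-event "width" (lognormal, median 8 ms,
  σ = 0.35, floor 7 ms). Peak amplitude defaults to 8× the background SD
  with 10% lognormal jitter. The asymmetric fast-rise/exponential-decay
  window was chosen over a symmetric Gaussian for two reasons: real SWR
  envelopes ramp up quickly and decay, and — decisive for the
  directed-influence validation — an exponential tail is (near-)exactly
  representable by a linear autoregression. With symmetric smooth
  envelopes each region's series linearly predicts the other *regardless
  of lead direction* (a fractional-delay interpolation effect), so
  reverse-direction Granger causality is always "significant" and the
  generator cannot produce a ground-truth unidirectional regime at all.
  The width floor and rise constant jointly keep ≥ 90% of every burst's
  energy inside 150–250 Hz. A Gaussian window and a stochastic
  within-burst amplitude modulation remain available as options.
- **Sharp waves**: derivative-of-Gaussian biphasic transients (40 ms
  FWHM, 8× background SD) co-added at the ripple peak. Co-injection uses
  a stratified draw — exactly round(p·n) of the n events are flagged —
  so the generator's realized co-occurrence equals its configured
  probability up to rounding instead of fluctuating binomially; measured
  co-occurrence then isolates detector fidelity.
- **Coupling**: ripple *propagation*. The sign of the configured lag
  picks the leading region (negative = MEC leads); a coupled fraction of
  leader events is copied into the follower at lag mean + per-event
  Gaussian jitter (5 ms SD), with the same envelope trajectory, rescaled
  amplitude and independent carrier phase; the remainder of the
  follower's events are independent. Copying the waveform (rather than
  drawing an independent one at a coupled time) is what makes the leader
  a genuine Granger cause: with independent waveforms the shared event
  *time* is a latent common cause and bivariate GC correctly reports
  bidirectional dependence. Timing-only coupling remains available
  (`coupling_waveform="independent"`).
- **Behavior**: alternating 20 s mobile / 20 s immobile blocks; during
  mobile blocks the animal shuttles at 15 cm/s on a 100 cm track, frozen
  otherwise; events are placed only in immobile epochs (0.15 s margin,
  250 ms minimum separation).
- **Presets**: `wt` — lag −8.9 ms, coupled fraction 0.8; `ad` — lag
  +23.2 ms, coupled fraction 0.5, both with 5 ms jitter.

Identical seeds give bit-identical sessions (one `SeedSequence` per
session, deterministic sub-streams per channel).

What passing on this generator shows: the detector recovers events and
their duration ordering at realistic SNR and rates, density normalization
is exact, the correlogram recovers injected lags to one bin, and the GC
chain distinguishes the propagation direction while staying calibrated on
white noise. What it does not show: robustness to non-stationary
background (state changes, theta during mislabelled movement), electrode
artifacts, overlapping/merged physiological events, or real ripple
waveform diversity — conclusions about recorded data still require visual
QC of detected events.

## Validation problem sizes

The acceptance suite (tests/test_acceptance.py, scripts/acceptance.py)
uses: two 1800 s sessions for detector fidelity and two for null
calibration; one 5200 s session (~250 events, widths uniform 9–35 ms) for
the duration–width rank correlation; 50 runs per preset of 400 s sessions
at 0.4 events/s for lag recovery; 20 pairs × 4 sessions of 300 s for GC
directionality (300 s matches a typical linear-track session, four
sessions per pair matches the averaging design) plus 1000 white-noise
pairs (n = 2000, order 5) for type-I calibration; and one 2000 s session
at 0.2 events/s with 90% co-injection for sharp-wave recovery. On one CPU
the whole script runs in about a minute.

## Known limitations

- Electrodes are treated as independent units; electrode-within-animal
  nesting is not modelled (no mixed-effects machinery).
- The F-test's independence assumption is only approximately restored by
  envelope-rate sampling; on strongly coupled pairs reverse-direction
  significance rates remain above nominal, and the group-level contrast
  (forward vs reverse rates across pairs) is the meaningful readout, not
  any single pair's binary outcome.
- Event boundaries at the 5σ crossing underestimate physiological event
  extent by construction; no sub-bin (interpolated) lag estimation is
  attempted beyond the 5 ms correlogram bin.
- The generator's coupling is event-level propagation; filtered
  common-input drive is out of scope.
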