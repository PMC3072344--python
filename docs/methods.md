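# Methods

## Study design emulated by the simulator

The pipeline targets a two-color spotted-array circadian experiment:
each array carries 45,220 features — 43,803 probe spots (20,692 probes
spotted twice, 793 thrice, 10 four times) plus 1,417 spike-in control
spots — hybridized with a timepoint sample (channel 1) against a common
24 h reference RNA pool (channel 2). Heads are collected at 10
timepoints (the 24 h reference plus 72–104 h every 4 h) in two
biological replicate cages. Because the two replicates cover the same
circadian day, the first six timepoints of each are concatenated into
one continuous 12-point, 48 h series (timestamps 0–44 h, 4 h step,
nominally starting 9 am at lights-on of a 12:12 LD cycle).

The simulator plants truth per probe: a rhythmic flag, one of four
discrete phase classes (peak at 0/6/12/18 h into the series), an
amplitude and a baseline on the log₂-ratio scale, and a spot-noise sd.
The expected M-value at time t is

    M(t) = baseline + amplitude · cos(2π(t − 6·phase)/24).

Signal-to-noise ratio throughout this package means amplitude /
noise_sd (so SNR 2 = amplitude 1.0, sd 0.5; in power terms
(A²/2)/sd² = 2).

Modeling choices:

* **Noise** is multiplicative log-normal on foreground intensities
  (i.i.d. per spot on the log₂ scale), the standard model for two-color
  array intensities. Foreground is simulated as background + signal, so
  subtracting the *recorded* background recovers the signal component
  exactly; with zero noise the pipeline round-trips the planted cosine
  to machine precision (tested).
* **Reference channel** carries the probe's abundance without the
  oscillation or baseline term, mirroring its role as a fixed
  denominator: the expected log-ratio is then exactly the model above.
* **Phases** are planted only at the four discrete classes a 12-point
  series can resolve; no continuous acrophases.
* Not simulated: dye bias, print-tip/spatial effects, scanner
  saturation. Passing tests therefore demonstrate correctness of the
  statistical machinery under the stated noise model, not robustness to
  array artifacts a real scan would add.

Defaults (`RunConfig`): 1,000 duplicate probes, 50 spikes, 50 %
rhythmic, amplitude 1.0, noise sd 0.5. These are the package's standard
demonstration conditions: a moderate-SNR mixture where the direct vs
continuum contrast is clearly visible.

## Preprocessing

Spike spots are removed (1,417 per array at the study layout); median
background is subtracted per channel with a floor of 1 intensity unit
(keeps log₂ defined when fg ≤ bg; floored spots are counted in the run
log); M = log₂(sample/reference), so positive M means expression above
the 24 h reference. The sign convention is fixed and documented here —
the direction is chosen so the heatmap's red corresponds to
above-reference expression. Technical replicate spots are processed as
separate profiles, never averaged (an averaged mode exists but is off
by default). Spots missing any timepoint in either replicate are
excluded, not imputed, and listed in the log; the log reconciles
rows_in = spikes + floored + excluded + emitted so no record silently
disappears.

## Conditioning

Smoothing is a single pass of a 7-point degree-3 Savitzky–Golay filter
applied circularly (indices mod N), so the series' end informs its
start — appropriate for a closed two-cycle series. The 7-point cubic
center weights are (−2, 3, 6, 7, 6, 3, −2)/21 (verified in tests
against a direct least-squares solve). "Median subtraction" is applied
as a separate sequential step after smoothing (SG itself contains no
median operation). Z-scores use the population (1/N) sd — material at
N = 12 — and are applied on top of smoothing and median subtraction
where the continuum requires them.

**Calibration caveat, and a deliberate design choice:** smoothing
colors white noise. Measured on 12-point white-noise profiles, circular
SG smoothing inflates the Fisher-g rejection rate at α = 0.05 from
~0.053 to ~0.56 and the autocorrelation rate from ~0.05 to ~0.14.
Nominal calibration of the direct tests is therefore a property of
*unsmoothed* profiles; the pipeline defaults to `smooth_for_tests:
false` and `smooth_for_continuum: true`, keeping smoothing in the
signal-enhancement path where calibration is not the contract.

## The test panel

* **Periodogram:** mean removed, I(ω_k) = (1/N)|Σ x_t e^(−iω_k t)|²,
  k = 1..⌊N/2⌋. Pinned by the Parseval identity Σ c_k I(ω_k) =
  (N/2)·var(Y) with the even-N Nyquist term weighted ½, and by a
  brute-force O(N²) DFT-sum oracle (1e−10, tested).
* **Fisher's g:** exact null sum as in the README. For even N the
  Nyquist ordinate is χ²₁-scaled, not exponential, which makes the
  "exact" test anticonservative if included (measured 0.074 vs 0.053
  rejection at α = 0.05 over 5,000 null series); the g-test therefore
  drops the Nyquist ordinate by default (n = 5 at N = 12), with
  `include_nyquist=True` available.
* **Autocorrelation:** wrap-around Pearson R at lag = period/Δt
  (6 samples). The verdict compares R (positive side) to the tabulated
  two-sided α cutoff from the t-distribution with N−2 df; using the
  two-sided cutoff one-sidedly gives a measured null positive rate of
  ~0.044 at N = 12 — the wrap-around reuse of points widens the null
  just about as much as the one-sided use narrows it. The maximum
  positive R over all lags is reported alongside.
* **Pt-test:** permutations are one sweep of N random transpositions,
  each redrawn until |n−m| ∉ {0, p}, so no single swap exchanges points
  one period apart; 2 series × min(N!, 100) permutations; the stored
  statistic is the permuted periodogram's intensity at the circadian
  bin (the test targets that period specifically; a global-max mode
  exists). p is the fraction of stored peaks ≥ observed ("same or
  higher peak"), with no add-one correction; significance is strictly
  p < α. Per-profile permutation seeds are derived from the profile id,
  so panel results are independent of input row order (tested).

Measured null rejection rates at α = 0.05 over 2,000 flat-noise
profiles: Fisher g ≈ 0.054, Pt ≈ 0.053, autocorrelation ≈ 0.053 (seed
dependent, all within 0.02–0.08; recomputed by the acceptance script).

## Phase continuum

Phases are assigned by maximal correlation to four discretized cosine
templates anchored to the series start (phase = peak at 0/6/12/18 h
into the series, not wall-clock phase). Within a phase, z-scored
profiles are sorted by descending R_c (ties broken by profile id for
determinism) and concatenated; the stream is filtered and scanned.

**Filter.** The published procedure names only "a low-pass frequency
filter and polynomial smoothing" chosen not to propagate oscillation
along the stream, so the binding contract here is spectral, not a
named kernel: near-unit gain at the circadian frequency and no
amplification anywhere. The implementation subtracts a zero-phase
centered moving average spanning one circadian cycle (the 2×6 seasonal
filter, frequency response exactly zero at the circadian frequency, so
the residual passes it with unit gain) and then applies a circular
7-point degree-5 SG pass (gain ≈ 0.978 at the circadian frequency;
total measured attenuation ≈ 2.2 % < 5 %, and circadian-bin power of
pure-noise streams is not amplified — both asserted in tests). The
common degree-3 SG pass was rejected for this stage: its gain at the
circadian frequency is 14/21 ≈ 0.67, a 33 % attenuation of the very
signal being enhanced.

**Scan.** The window spans whole profiles (5 for the g-test = 60
timepoints, its minimal useful length; 3 for Pt and autocorrelation)
and steps one profile at a time, so profiles are atomically in or out.
Deterioration is the *first* window with p ≥ α — streams are sorted so
signal decays monotonically in expectation, and no look-ahead is
performed. Profiles wholly before the deterioration window count as
rhythmic; if no window fails, all do. Window p-values: exact Fisher p;
one-sided t-test p for the window's circadian-lag R; Pt permutation p.

**Known limitation — the continuum overcounts.** Sorting by R_c is a
selection step: the top of an all-noise stream genuinely contains
profiles that look circadian and are phase-aligned by construction, so
windows there pass honestly. Measured on 200 flat-noise profiles, the
full pipeline reports 0.6–0.9 "rhythmic" fractions while the direct
tests stay at ~0.05. This mirrors the method's observed behavior on
real data (continuum counts far above direct counts) and is the price
of its sensitivity; continuum output should be read as an upper
estimate, direct testing as a lower one. The scan itself is
well-calibrated absent selection: on unsorted noise streams the
rhythmic count stays ≤ the frame size in ≥ 90 % of runs (tested).

## Heatmap

Rows are grouped into the four phase blocks and sorted within block by
decreasing circadian-lag autocorrelation; cells use a symmetric
red–black–green ramp (red = positive M) clipped at the 98th percentile
of |M| by default (the ramp stays informative against outliers);
colorize(−v) is the channel-swapped mirror of colorize(v). The PNG
carries block separators and a 12:12 LD bar. Rendering is a pure
function of (matrix, scale).

## Determinism and problem sizes

Every stochastic routine takes a mandatory seed; identical seeds give
byte-identical outputs (tested end-to-end through the CLI). The test
suite and the acceptance script run the simulator at 200–1,000 probes
(400–2,000 technical profiles) — sizes at which the measured rates
(null calibration, phase recovery ≥ 0.98 at SNR 2, fraction recovery
within [f, f + 0.05] at high SNR, continuum ≥ direct at SNR 1) are
stable across seeds while the whole suite stays fast; the statistical
machinery is size-agnostic and handles the full 45,220-feature layout
(exercised for the layout/filter arithmetic).
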