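# Methods

## Signal model

An FMCW radar transmits linear chirps of bandwidth `B` from carrier `fc`
(defaults: 3.99 GHz from 77 GHz, so `lambda = c/fc ≈ 3.893 mm` and range
resolution `c/2B ≈ 3.76 cm`); one frame is emitted every 0.5 ms, giving a
slow-time sampling rate (PRF) of 2000 Hz and an unambiguous Doppler band of
±1000 Hz.  A chest at radial displacement `r(t)` contributes slow-time
phase `phi(t) = 4 pi r(t) / lambda`; its derivative is the instantaneous
Doppler frequency `f = 2 v / lambda`.  Sign convention: motion *away* from
the radar (the chest being compressed, radar above the chest) is positive
Doppler, matching an `e^{-j 2 pi f t}` analysis kernel acting on
`exp(+j 4 pi r / lambda)`.

Two synthesis paths exist and are tested against each other:

* **Phase level** (fast path): write the slow-time sequence directly.
* **Chirp level**: synthesise every chirp's de-chirped IF signal
  `A cos(2 pi (Sw tau t + fc tau - Sw tau^2/2))` with
  `tau = 2 (R + r)/c`, then range-FFT each frame (Hann window) and track
  the peak bin.  The phase of a range-compressed peak advances at the
  *sweep-centre* frequency, not the carrier: with a symmetric fast-time
  window the fixed-bin DFT phase is `2 pi tau (fc + Sw (N-1)/(2 fs))`, a
  2.6 % wavelength difference at these parameters.  `range_process`
  therefore attaches the centre-frequency wavelength to its output, and
  the two paths agree to well below 1e-2 rad RMS noise-free.

## Synthetic campaign

The generator emulates a guided mannequin study: 8 subjects × 3 radar
positions × target depths {3, 4, 5, 6} cm × rates {90, 100, 110} CPM,
30 s per condition.  Each cycle is a raised sine
`d(t) = D sin^2(pi t / T_c)` — smooth, zero velocity at the endpoints, one
downstroke and one upstroke lobe per compression, consistent with the
alternating-lobe spectrograms such motion produces.  Subject variability:
depth bias ~ N(0, 0.2 cm) drawn once per subject, per-cycle depth jitter
~ N(0, 0.15 cm), per-cycle rate jitter ~ N(0, 2 CPM).  These values are a
design choice calibrated to produce between-subject RMSE spreads of the
order seen in mannequin studies; they are configurable.  Noise is complex
white Gaussian at a stated SNR (default 20 dB) relative to the
unit-modulus signal.  Radar positions beyond the frontal one are modelled
purely as an aspect angle (defaults: 0°, 30°, 45° for cases 1–3; the
oblique angles are conventions, not measured values).

What the generator does **not** model: respiration and heartbeat
superposition, rescuer body motion and multipath, amplitude modulation
from the moving hands, range migration of clutter, or hardware
imperfections.  Passing tests therefore demonstrate correctness of the
algorithms under the stated motion model, not field performance on human
data.

## Time–frequency representations

* **STFT**: Hamming window, 75 % overlap, `fft_length = max(256, L)`;
  squared magnitude; only full windows (no edge padding).  Physical
  resolutions are `df = PRF/L` and `dt = L/PRF` regardless of FFT
  zero-padding.
* **WVD**: lag FFT of `x(t + tau/2) x*(t - tau/2)`.  Computed on a
  two-fold FFT-interpolated copy so the frequency axis covers the full
  ±PRF/2 (the bilinear product would otherwise halve the band), with
  zero padding outside the signal support and Riemann-sum normalisation,
  so the time marginal equals `|x(t)|^2` exactly.  Real input is first
  made analytic.
* **SPWVD**: separable Hamming smoothing, 256 points (on the original
  slow-time grid) in both time and lag by default; the time window is
  normalised to unit sum and the lag window to unit centre value so a
  stationary ridge keeps its scale.

## Doppler-integration estimator

Per time slice the linear-power profile is smoothed (3-bin moving
average); on the dominant-power side of zero frequency, the envelope is
the frequency of maximal energy-derivative magnitude beyond the spectral
peak.  Slices within 3 dB of the map's median power are zeroed.  Defaults
for this pipeline: window length 64 (tracking the fast Doppler sweep
matters more than frequency resolution here), FFT length 512.

The detected boundary sits a fixed distance *outside* the instantaneous
frequency — the steepest-descent point of the window's spectral response.
That offset depends only on the analysis window, grid and smoothing, so it
is measured once on a synthetic stationary tone (`edge_offset_hz`, cached)
and subtracted before integration.  With this correction, noise-free
recovery of 3–6 cm compressions is accurate to well under 1 %.

Cycle segmentation: lobe peaks of the rectified envelope
(`scipy.signal.find_peaks`, prominence 25 % of the global peak, minimum
separation of half a minimal cycle, `min_cycle_s = 0.25 s`), boundaries at
the minimum between consecutive peaks, and a positive lobe followed by a
negative lobe forms one compression.  Each lobe is integrated separately
(trapezoidal rule on the map's own time grid, rectified) and the two lobe
displacements averaged — both strokes traverse the same distance, and
averaging halves the noise.  Oblique geometry is compensated by
`d = r / cos(theta)`; theta is assumed known from the setup.

## Regression and CNN estimators

The regression model is a second-order polynomial of the cycle's maximum
Doppler frequency, solved by least squares (equivalent to the
normal-equation closed form; the feature is z-scored before expansion for
conditioning, and coefficients are available in both bases).

The CNN input is a 64×64 grayscale crop of one compression: 0.8 s centred
on the segmented cycle, ±400 Hz, dB-scaled over 60 dB, anti-aliased and
bilinearly resampled, min–max normalised.  The network is the fixed
sequence conv(3×3, 8)/BN/ReLU/avg-pool, conv(3×3, 32)/BN/ReLU/avg-pool,
two more conv(3×3, 32)/BN/ReLU stages, then fully connected 32 and 1
(283,329 parameters).  Training: SGD with momentum 0.9, MSE loss,
batch 32, validation split 1/7, early stopping with patience 10 (best
validation epoch restored).  The learning rate default is 3e-4, chosen by
the usual heuristic adjustment — 1e-2 diverges for this parameterisation.
All randomness (init, split, shuffling) fans out from one seed.

Evaluation is leave-one-subject-out: fit on all other subjects' cycles
(pooled over conditions by default; per-condition training is available by
filtering the manifest), score RMSE per (held-out subject, radar position),
summarise per case with mean, sample std (n−1) and Student-t 95 %
half-width `t_{0.975, n-1} * std / sqrt(n)`.

## Reference tables

The packaged CSVs transcribe the per-subject RMSE tables of the four
published estimators.  Recomputing the summary rows requires two
conventions: the sample std (a normal quantile or an n-denominator std
fails to reproduce the printed intervals), and computing the CI from the
std *rounded to 3 decimals* (e.g. case 1 of the integration table:
`t * 0.17879 / sqrt(8) = 0.1495 -> 0.149`, while the printed ±0.150
follows from the rounded 0.179).  Five printed cells do not reproduce from
their own column values and are flagged as expected failures: the STFT-CNN
table's case-2/case-3 std and CI values (which duplicate the regression
table's columns) and the WVD-CNN table's case-3 mean (0.489 printed,
0.487 recomputed).  The prose grand mean 0.909 cm for the integration
method also differs from the 24-value mean 0.890 cm; the recomputed value
is used.

## Numerical and design notes

* SI units internally; centimetres only at reporting boundaries.
* Flat envelope minima break ties at the first index; envelopes are zeroed,
  not interpolated, in no-signal slices.
* The WVD of multi-component signals is signed; images clip negatives at
  the dB floor.
* Chirp duration is not constrained by any result; default 50 µs.
  Only chirp 0 of each 3-chirp frame is used for phase extraction.
* Determinism: identical (scenario, seed) produce bit-identical signals;
  campaign record seeds derive from one master seed via `SeedSequence`.
* Problem sizes in the shipped acceptance run: 8 subjects × 12
  frontal-geometry conditions × 30 s for the integration/regression
  campaign, and 5 subjects × 4 depths × 10 s (~300 crops, ≤30 epochs) for
  the CNN fold — sizes chosen to exercise every pipeline stage at desk
  scale.

## Known limitations

* The aspect angle must be supplied; no angle estimation or motion
  compensation is attempted, and a mis-specified angle biases depth by the
  cosine ratio.
* The envelope edge-offset calibration assumes the analysis window used at
  calibration matches the one used at estimation (enforced by parameter
  keying) and a single dominant point scatterer.
* SPWVD-based Doppler integration is biased upward by the long time
  smoothing window and is not the default for integration; SPWVD is
  intended as CNN input.
* The NumPy CNN is single-threaded and deliberately small; it is not a
  general deep-learning facility.
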