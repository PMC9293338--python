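# Methods

`ucachar` implements the acoustic characterization workflow for ultrasound
contrast agents (UCAs): harmonic side-scatter spectroscopy, insertion-loss
attenuation estimation, linear backscatter fractions, and contrast-specific
(PI+AM) dynamic contrast-enhanced ultrasound (DCE-US) bolus analysis. A
synthetic acquisition generator supplies inputs with known ground truth for
every estimator; real recordings in the same container format are analyzed
by the identical code path.

## Side-scatter spectroscopy

Each acquisition is a train of 92–95 tone bursts (10–20 cycles at the
transmit frequency f0 of 1.0, 2.25 or 3.5 MHz), sampled at 25 MHz with
250 µs silence between pulses. The analysis cuts one 9 µs segment per
pulse, tapers it with a periodic Hanning window to limit leakage, and
averages the *amplitude* spectra (not power spectra) over the pulses of
the acquisition. Harmonic amplitudes A(k·f0), including the subharmonic
k = 0.5, are read off as the local maximum within ± f0/n_cycles of k·f0 —
half the −6 dB bandwidth of an n_cycles burst — which is robust to sub-bin
frequency offsets.

Two dB statistics quantify nonlinear scatter:

* versus the saline (noise) reference:  S_nonl(f) = 10·log10(A_CA(f)/A_sal(f));
* versus the fundamental:               S_nonl(f) = 10·log10(A_CA(f)/A_CA(f0)).

Both deliberately use 10·log10 on amplitude ratios — the form in which
these statistics are defined for this workflow — and every function takes
`db_factor=20` for the conventional amplitude-dB scale. The
fundamental-normalized statistic is exactly 0 at f0 by construction; its
purpose is to mitigate concentration and bubble-size differences between
agents, since in the low-concentration regime all harmonic amplitudes
scale with concentration.

Replicates (15 acquisitions per agent, each a fresh dispersion injected
into the cuvette) are summarized as mean ± sample standard deviation
(ddof = 1). Agents are compared per harmonic with a two-tailed two-sample
Student t-test (pooled variance by default, Welch by flag) at the 0.05
level, with no multiple-testing correction — one decision per harmonic,
matching the per-harmonic reporting convention. Two identical
zero-variance groups return p = 1.

### Numerical choices

The spectrum object exposes the native grid fs/len(segment); the
harmonic-extraction pipeline zero-pads the FFT by a factor of 8 so that
Hanning scalloping contributes < 0.03 dB to any amplitude ratio. The
analysis-window start defaults to the acoustic travel time stored in the
record metadata (zero for synthetic records), a deterministic stand-in
for the manual window placement used with physical recordings.

## Attenuation

Through-transmission (insertion loss): with saline and then the agent
dispersion in a cuvette of inner path d = 1 cm,

    α(f) = (20/d) · log10(T · A_sal(f)/A_CA(f))   [dB/cm],

where the fundamental amplitudes come from the averaged amplitude spectrum
at f0 (not the time-domain peak) and the transmit coefficient T defaults
to 1, neglecting reflection losses (configurable). The estimate is
aggregated over 15 replicate pairs as mean ± SD. A QC hook warns when a
record's second harmonic exceeds 5% of its fundamental, flagging departure
from the linear-oscillation regime the method assumes.

Echo mode: the same formula with effective path 2d (forward and backward
pass), applied to the mean gray level of a reflector plate behind the
cuvette, averaged over the frames of an envelope-mode clip (no log
compression, so gray levels are signal envelopes).

The linear backscatter fraction is S_lin = 100·A_backsc/A_transmit, where
A_transmit is the plate gray level without the cuvette divided by the
water–aluminum pressure reflection coefficient, computed from configurable
impedances (defaults 1.48 and 17.3 MRayl, giving r = 0.842).

A sound-speed sanity check converts an arrival-time delay over the cuvette
path into a percent speed difference versus a reference speed (default
1480 m/s, configurable); a 0.6 µs delay over 1 cm maps to 8%.

## DCE-US bolus analysis

The contrast-specific transmit scheme combines pulse inversion and
amplitude modulation: three pulses with relative amplitudes [1, −0.5,
−0.5] (three cycles at 3.5 MHz, MI 0.2). The combined nonlinear image is
the plain sum P1+P2+P3 computed on the RF-like signed responses, so any
response linear in transmit amplitude cancels exactly (1 − 0.5 − 0.5 = 0);
the envelope is taken after summation. RF-domain summation is a design
choice made for exact linear cancellation; envelope-domain combination
would leave a residual set by speckle statistics rather than by the
scheme.

TICs are the ROI mean of the squared envelope per frame ("linearized":
the linear-energy scale given envelope gray levels), extracted from the
middle of the phantom. Peaks are compared as 100·(peak_a − peak_b)/peak_b.
An optional moving-average smoother (window = one pulsation period)
suppresses the periodic pulsatile-flow fluctuation; smoothing a skewed
triangle shifts its apex slightly, so peak-time readings use the raw TIC.

The triangular indicator-dilution model assumes only conservation, not an
isoceles shape: ∫C dt = dose/flow forces C_peak = 2·dose/(Q·T_b) for base
duration T_b and flow Q (mL/s), and the mixing volume is dose/C_peak.

The maximum-intensity projection is the per-pixel maximum over frames.

## Synthetic data generator

The generator prescribes rather than derives the physics: no
bubble-oscillation ODE and no field modelling. What it emulates:

* **Scatter acquisitions** — the protocol's pulse-train structure; harmonic
  content at k·f0 with configured linear amplitude ratios (+ optional
  subharmonic); rectangular tone-burst envelope by default, Gaussian by
  flag (the echo-mode experiment used Gaussian pulses); additive white
  Gaussian noise as the stationary hydrophone-chain floor (`noise_rms` =
  0.01 by default, i.e. 40 dB SNR against the unit fundamental; the true
  noise statistics of a hydrophone chain are not modelled). Harmonic
  phases are zero by default and randomizable — amplitude spectra are
  phase-blind.
* **Replicate variability** — lognormal multiplicative scatter per
  harmonic with CV 0.1 (≈0.4 dB on the 10·log10 scale), keeping amplitudes
  positive and dB values approximately Gaussian, as the t-test assumes.
  Transmission replicates get a common-mode source-amplitude factor, which
  cancels in α exactly as in the physical measurement.
* **Transmission pairs** — the medium record is the reference scaled by
  10^(−α_true·d/20), independent noise realizations.
* **DCE-US clips** — envelope-level images directly (no beamforming): a
  static linear speckle field over the image plus a nonlinear speckle
  field confined to a lumen band, scaled by a response curve applied to a
  triangular concentration curve modulated by pulsatile-flow fluctuation
  (default 10% at 1 Hz, the peristaltic-pump signature). The nonlinear
  channel carries the transmit sign with quadratic magnitude
  (r(a·s) = a·|a|·s-like), so it survives the PI+AM sum with weight 1/2.
  The default response is √C, making squared-envelope intensity — hence
  the TIC — proportional to concentration, the physically expected
  energy–concentration linearity at low concentration.
* **Bolus shape** — triangle base 25 s arriving at 5 s within a 40 s clip
  (covering complete wash-in and wash-out), apex at 35% of the base
  (wash-in faster than wash-out, typical of indicator-dilution curves);
  frame rate 10 Hz, a realistic contrast-mode rate. Conservation fixes the
  peak; pulsatility modulates the *signal*, leaving the underlying
  concentration curve conservative.

What the generator does **not** reproduce — and therefore what passing
tests do not show about real data: emergent harmonic content and its
pressure dependence, resonance behavior, attenuation of the scattered
signal inside the dispersion (the masking effect), bubble rise/destruction
over time, probe/phantom reverberation, and frequency-dependent
attenuation across the burst bandwidth. Ground-truth recovery validates
the estimators, not the acoustics.

## Calibration arithmetic

MI = PNP[MPa]/√(f[MHz]), no derating; reported pressures round to the
nearest 10 kPa (374 → 370 at MI 0.2, 3.5 MHz). Dilution:
(stock_mass/stock_volume)·aliquot/(aliquot+diluent); the protocol's
10 mg/12 mL stock with 0.35 mL into 3.35 mL gives 0.0788 → 0.08 mg/mL.
Bubbles-per-mg conversion factors are user-supplied; the package asserts
no invented physical constants.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` run everything at the protocol
scale it emulates: 93-pulse records at 25 MHz (~600 k samples each), 15
replicates, 100 seeded transmission pairs per attenuation level
α_true ∈ {0.3, 4.4, 9.7} dB/cm (recovery within 0.1 dB/cm bias and SD at
40 dB SNR, matching the ±0.1 dB/cm verification scale of the corn-oil
control), 10 000 null trials for the t-test calibration (rejection rate
inside the binomial 99% interval around 0.05), 20 seeded clip pairs for
TIC linearity (peak ratio within 5%), and noise-free harmonic recovery
within 0.1 dB. DCE-US clips are 400 frames of 32×48 px — small images,
since only ROI statistics enter the analysis.

## Known limitations

* Harmonic amplitudes are prescribed; the generator cannot probe whether
  an estimator would misbehave on physically coupled harmonics (e.g.
  fundamental depletion at high pressure).
* The echo-mode simulator shares the transmission simulator's amplitude
  model, so the echo-vs-transmission agreement it demonstrates is by
  construction; the systematic offset seen between the two measurements on
  physical data (different pulse shapes) is out of reach.
* Measured agent-specific values (e.g. attenuation 8.7/9.7/4.4 dB/cm for
  the antibubble agent) require the original recordings; here they serve
  as simulator ground truths that the pipeline must recover, not as
  quantities the package derives from first principles.
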