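# Methods

`toipulse` implements contactless heart-rate and heart-rate-variability
(HRV) measurement from ordinary RGB facial video by transdermal optical
imaging (TOI), together with the ECG reference branch and the
method-agreement statistics used to validate it.  This note records the
models, the parameters that matter, and the design choices made where the
problem was genuinely open.

## The measurement model

Light re-emitted from facial skin is modulated by sub-epidermal hemoglobin
concentration (HC), which pulses with the cardiac cycle.  The signal is
faint and does not live uniformly across the 8-bit dynamic range of a
camera: it is sought in *bitplanes* — the 24 one-bit images formed by one
bit position of one RGB channel.  The HC signal is a signed, unscaled
combination of bitplanes (pixel-wise additions and subtractions),
spatially averaged over facial regions of interest (ROIs) to raise SNR.
Nine fixed ROIs are used (forehead, nose regions, cheeks, lips, chin);
masks are supplied by configuration, not detected — participants are
assumed seated and still, so masks do not track the face.

### Bitplane selection

Which planes carry blood-volume information is learned per recording.  The
original procedure trained against contact instruments (laser Doppler,
cuff blood pressure); lacking those, the objective here is the
cardiac-band spectral SNR of the composed ROI signal:

    SNR = 10 log10( P[f_lo, f_hi] / P[0.05 Hz, Nyquist] \ band )   (dB)

computed from a mean-removed Welch periodogram (Hann, 2048-sample
segments, 50 % overlap).  The cardiac band defaults to 0.7–4 Hz
(42–240 BPM).  Selection is greedy coordinate ascent over weights in
{−1, 0, +1}²⁴: starting from all zeros, the single (channel, bit, sign)
change that most increases mean training-split SNR across ROIs is applied
until no move gains `snr_tolerance` dB.  The recording is split 80/20
along the time axis; the report carries the training objective and the
held-out SNR of the best single ROI (the signal the pulse stage will
actually consume).  Enumeration order (R→G→B, bit 7→0, +1 before −1)
breaks exact ties, making the search deterministic.

Two numerical choices deserve note.  A constant (degenerate) ROI
composition is scored at the chance level a flat spectrum would get,
`10 log10(bandwidth / complement)`, rather than vetoing a move.  And
`snr_tolerance` defaults to 1 dB: the Welch SNR of a noise plane
fluctuates by a few tenths of a dB, and the best of ~48 candidate moves
beats the chance baseline by roughly that spread, so a smaller tolerance
would let pure noise "converge".  With 1 dB, a noise-only recording is
reported `converged=False` with all-zero weights.

### Pulse extraction (Hilbert-Huang)

The composed ROI signal is band-passed (4th-order Butterworth,
forward-backward for zero phase, 0.7–4 Hz), then decomposed by empirical
mode decomposition: cubic-spline envelopes through mirror-extended
extrema, Rilling two-threshold sifting (θ₁ = 0.05, θ₂ = 0.5, α = 0.05),
at most 10 IMFs.  Completeness (Σ IMFs + residue = input) holds by
construction.

The cardiac component is chosen by the Hilbert stage: for each IMF the
analytic signal gives an amplitude-weighted mean instantaneous frequency;
the in-band IMF with greatest cardiac-band power anchors the selection.
Because sifting splits an oscillation lying near a dyadic boundary across
two neighboring IMFs (mode mixing), IMFs whose mean frequency lies within
a factor 1.5 of the anchor's and whose in-band power is at least 5 % of
the anchor's are summed back into the component; the window is narrower
than an octave, so pulse-waveform harmonics stay excluded.  The merge
window is allowed to reach slightly past the band edge, since mixing can
drag a pulse-carrying IMF's average frequency just outside it.

Beat times are the local maxima of the component, refined to sub-sample
precision by a parabola through the three samples around each maximum.
The first and last second are excluded (filter and EMD edge effects).
Maxima closer together than the implied rate allows are merged, keeping
the larger amplitude: the refractory is one period of the band's upper
edge, or 0.7 of the principal period when known — this absorbs the
half-beat double maxima that amplitude beating between mode-mixed IMFs
produces, while true beats (which can come no closer than ~0.85 of the
mean period under respiratory modulation) are never touched.

R-R intervals follow as successive differences; the analysis ROI is the
one with the highest cardiac-band SNR (config-overridable).

### ECG reference branch

A Pan-Tompkins-style energy detector: band-pass 5–35 Hz, squared
derivative, 150 ms moving-window integration, adaptive threshold,
refractory 250 ms, refinement to the filtered waveform's maximum within
±50 ms.  The threshold sits a tenth of the way from the quiet-baseline
energy (25th percentile of the integrated energy) up to the
QRS-population energy (99.5th percentile) — the static analog of the
Pan-Tompkins quarter-way rule.  A median + k·MAD threshold was tried
first and abandoned after measurement: at low heart rates it sits below
the T-wave energy (false positives), and at high heart rates the median
itself is contaminated by QRS energy so that no k both detects QRS and
rejects T-waves.  The quantile rule separates the two populations across
40–180 BPM because QRS energy exceeds T-wave energy by roughly 20 dB
regardless of rate.  A guard rejects records whose energy distribution has
no QRS population at all (signal/noise quantile ratio below 8; pure noise
scores ≈ 4, real ECG ≥ 35).

### HRV summary

From an R-R series RR₁…RRₙ (ms), with sample (n−1) standard deviations
and dₙ = RRₙ − RRₙ₊₁:

    SD1 = (√2/2)·SD(d)
    SD2 = √( 2·SD(RR)² − ½·SD(d)² )
    heart rate = 60000 / mean(RR)   (beats per elapsed time)

SD1 is the Poincare-plot dispersion perpendicular to the identity line
(short-term, respiration-driven variability), SD2 the dispersion along it;
SD1/SD2 is the stress index (lower = more basal stress).  The SD2 radicand
is snapped to zero within a 1e−10 relative tolerance (it rounds either way
in floats when exactly zero) and clamped with a flag when genuinely
negative (short anti-correlated series); the ratio is then undefined, not
an error.  Intervals outside 250–2500 ms set a validity flag rather than
raising.

A geometric cross-check rotates the lag cloud (RRₙ, RRₙ₊₁) by 45° and
takes axis SDs.  The perpendicular SD equals SD1 *exactly*.  The
along-identity SD equals the SD2 formula only when the SD(RR)² term is
read as the mean of the lag cloud's two marginal variances; with the
full-series SD (the convention used here, and standard in the HRV
literature) the two agree to O(1/n).  Tests assert the exact identity in
its exact form and the convergence of the full-series formula.

### Agreement statistics

Differences are TOI − ECG, so negative bias means the contactless branch
reads low.  Limits of agreement are bias ± 1.96·SD(differences), sample
SD, no small-sample t correction.  Pearson correlation is the standard
product-moment coefficient and is undefined (error) for constant series.

## The synthetic world

Because no recordings are distributed, every claim is validated on a
generator whose defaults state the acquisition world: 120 s of 60 fps RGB
video and a 1000 Hz ECG driven by one ground-truth beat process.

* **Beats**: RRIₙ = 60000/HR + A·sin(2π·f_resp·tₙ) + N(0, σ²), evaluated
  at each beat time — a genuine frequency modulation emulating respiratory
  sinus arrhythmia.  Defaults: HR 72 BPM, RSA depth A = 40 ms (60 ms in
  the recovery tests), f_resp = 0.25 Hz, jitter σ = 5 ms — mid-range
  resting values for healthy adults.
* **ECG**: Gaussian P-QRS-T bumps (amplitudes 0.15/1.0/0.3, SDs
  25/10/40 ms, offsets −180/0/+250 ms) plus white noise (default SD 0.1,
  i.e. 20 dB below the unit R amplitude).
* **Video**: a static skin-toned 64×64 base image with smooth gradients.
  Inside three embedded ROIs (forehead and both cheeks) each target bit of
  the green channel (bits 5–7) is forced to 1 with probability
  p(t)·amplitude, where p(t) is a raised-cosine bump peaking exactly at
  each beat (width 0.6 of the local R-R interval) and amplitude defaults
  to 0.6.  The remaining six ROIs receive no pulse, exercising ROI
  selection.  Gaussian sensor noise (default SD 2 intensity units; the
  recovery tests use 10^(10/20) ≈ 3.16, reading "10 dB intensity noise" as
  power re 1 LSB) and a slow illumination drift (2 units at 0.03 Hz) are
  added in intensity space before re-quantization, so low-order bitplanes
  are genuinely noisy while the embedded planes stay pulse-locked.

Everything is bit-reproducible from the seed.  What the generator does
*not* emulate — and what a green test therefore does not establish —
includes head motion, facial expression, lighting changes, codec
compression (which perturbs exactly the low-order bitplanes the method
reads), melanin/hemoglobin radiative transfer, and realistic PPG pulse
morphology; the raised cosine carries timing only, which is all the
downstream analysis uses.

## Known limitations

* The SNR objective is a stand-in for the original instrument-supervised
  "signal differentiation" criterion, which is not defined mathematically
  in the source method; one global weight set is produced and applied to
  all ROIs.
* The train/validation split is within a single recording (time axis), not
  across subjects.
* Mode mixing is handled by frequency-windowed IMF merging rather than
  ensemble EMD (out of scope); signals whose harmonic falls inside the
  merge window of the fundamental (impossible with the 1.5× window) would
  defeat it.
* Beats in the first/last second of video, and ECG beats truncated by the
  record boundary, are not reported; statistics are over interior beats.
* MP4/AVI decoding requires an imageio backend with codec support; the
  `.npz` frame archive is the only bit-exact, always-available format.
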