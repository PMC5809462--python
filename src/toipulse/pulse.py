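"""Heartbeat timing from hemoglobin-concentration series via Hilbert-Huang.

The ROI-averaged HC series is band-passed to the cardiac band, decomposed
into intrinsic mode functions (IMFs) by empirical mode decomposition, and
the IMF carrying the principal cardiac frequency is selected with the
Hilbert spectral stage (analytic-signal instantaneous frequency).  Beat
times are the refined local maxima of that IMF; successive differences
give the R-R interval series of the contactless branch.

Numerical choices: 4th-order Butterworth applied forward-backward (zero
phase); Rilling-style two-threshold sifting criterion with cubic-spline
envelopes on mirror-extended extrema, at most 10 IMFs; peak times refined
by quadratic interpolation of the three samples around each maximum; the
first and last second are excluded from peak detection because both the
filter and EMD distort the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

CARDIAC_BAND = (0.7, 4.0)  # Hz; 42-240 BPM


@dataclass
class HCSignal:
    """Per-ROI hemoglobin-concentration time series at the video frame rate."""

    values: np.ndarray
    fps: float
    roi_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("HCSignal requires a 1-D series of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HCSignal values must be finite")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fps


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the monotone residue.

    Completeness: ``sum(imfs) + residue`` reconstructs the input to within
    floating-point accumulation error.
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    fps: float

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass
class PeakTrain:
    """Strictly increasing beat times in seconds with a source tag."""

    peak_times_s: np.ndarray
    source: str = "TOI"
    duration_s: float | None = None

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.peak_times_s.ndim != 1:
            raise ValueError("peak times must be 1-D")
        if self.peak_times_s.size and np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.peak_times_s.size


def bandpass(signal: HCSignal, band: tuple[float, float] = CARDIAC_BAND) -> HCSignal:
    """Zero-phase Butterworth band-pass; removes the mean as well.

    Raises if the upper band edge is at or above Nyquist.
    """
    f_lo, f_hi = band
    if signal.fps <= 2 * f_hi:
        raise ValueError(
            f"fps {signal.fps} too low for band up to {f_hi} Hz (need > {2 * f_hi})"
        )
    sos = sps.butter(4, [f_lo, f_hi], btype="bandpass", fs=signal.fps, output="sos")
    x = signal.values - signal.values.mean()
    y = sps.sosfiltfilt(sos, x)
    return HCSignal(values=y, fps=signal.fps, roi_name=signal.roi_name)


# ---------------------------------------------------------------------------
# empirical mode decomposition
# ---------------------------------------------------------------------------

def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints)."""
    d = np.sign(np.diff(x))
    # collapse zero slopes onto the previous nonzero slope so flat tops count once
    for i in range(1, d.size):
        if d[i] == 0:
            d[i] = d[i - 1]
    dd = np.diff(d)
    maxima = np.flatnonzero(dd < 0) + 1
    minima = np.flatnonzero(dd > 0) + 1
    return maxima, minima


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema mirrored past both ends."""
    t = idx.astype(float)
    v = x[idx]
    # mirror up to two extrema about each endpoint to anchor the spline
    k = min(2, t.size)
    t_left = -t[:k][::-1]  # reflect about sample 0
    v_left = v[:k][::-1]
    t_right = 2 * (n - 1) - t[-k:][::-1]
    v_right = v[-k:][::-1]
    tt = np.concatenate([t_left, t, t_right])
    vv = np.concatenate([v_left, v, v_right])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    tt, vv = tt[keep], vv[keep]
    if tt.size < 4:
        # too few knots for a cubic: fall back to linear interpolation
        return np.interp(np.arange(n, dtype=float), tt, vv)
    return CubicSpline(tt, vv)(np.arange(n, dtype=float))


def _sift(x: np.ndarray, theta1: float = 0.05, theta2: float = 0.5,
          alpha: float = 0.05, max_sift: int = 100) -> np.ndarray | None:
    """Extract one IMF from ``x``; None if ``x`` has too few extrema."""
    h = x.copy()
    n = x.size
    for it in range(max_sift):
        maxima, minima = _local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            return None if it == 0 else h
        upper = _mirrored_envelope(h, maxima, n)
        lower = _mirrored_envelope(h, minima, n)
        mean = 0.5 * (upper + lower)
        amp = 0.5 * (upper - lower)
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma = np.abs(mean) / np.where(amp > 0, amp, np.inf)
        if (np.mean(sigma < theta1) >= 1 - alpha) and np.all(sigma < theta2):
            return h - mean
        h = h - mean
    return h


def emd(signal: HCSignal | np.ndarray, fps: float | None = None,
        max_imfs: int = 10) -> IMFSet:
    """Empirical mode decomposition by standard sifting.

    Iterates envelope-mean subtraction until the two-threshold IMF
    criterion holds, peels off at most ``max_imfs`` modes, and stops when
    the residue has fewer than two maxima or minima.
    """
    if isinstance(signal, HCSignal):
        x, fps = signal.values, signal.fps
    else:
        x = np.asarray(signal, dtype=float)
        if fps is None:
            raise ValueError("fps is required with a bare array")
    if x.size < 16:
        raise ValueError("EMD requires at least 16 samples")
    if np.ptp(x) == 0:
        raise ValueError("EMD of a constant signal is undefined")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        imf = _sift(residue)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
        maxima, minima = _local_extrema(residue)
        if maxima.size < 2 or minima.size < 2:
            break
    return IMFSet(imfs=imfs, residue=residue, fps=float(fps))


# ---------------------------------------------------------------------------
# Hilbert spectral stage
# ---------------------------------------------------------------------------

def _instantaneous_frequency(imf: np.ndarray, fps: float) -> tuple[float, np.ndarray]:
    """Amplitude-weighted mean instantaneous frequency of one IMF (Hz)."""
    analytic = sps.hilbert(imf)
    amp = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    f_inst = np.diff(phase) * fps / (2 * np.pi)
    w = 0.5 * (amp[:-1] + amp[1:])
    # trim half a second each side: the analytic signal rings at the edges
    k = max(1, int(round(0.5 * fps)))
    if f_inst.size > 4 * k:
        f_inst, w = f_inst[k:-k], w[k:-k]
    if w.sum() == 0:
        return float("nan"), f_inst
    return float(np.sum(w * f_inst) / np.sum(w)), f_inst


def _band_power(x: np.ndarray, fps: float, band: tuple[float, float]) -> float:
    nperseg = min(x.size, 2048)
    freqs, psd = sps.welch(x, fs=fps, nperseg=nperseg, noverlap=nperseg // 2,
                           detrend="constant")
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(psd[sel].sum())


def principal_frequency(
    imfset: IMFSet, band: tuple[float, float] = CARDIAC_BAND,
    power_fraction: float = 0.05,
    freq_window: float = 1.5,
) -> tuple[np.ndarray, float]:
    """Select the cardiac component and its principal frequency.

    Candidates are IMFs whose amplitude-weighted mean instantaneous
    frequency falls inside the cardiac band; the one with the greatest
    in-band spectral power anchors the selection.  Sifting splits an
    oscillation whose frequency sits near a dyadic boundary across two
    neighboring IMFs (mode mixing), so candidates within a factor
    ``freq_window`` of the anchor's frequency that carry at least
    ``power_fraction`` of its in-band power are summed back together; the
    window is narrower than an octave, so harmonics of the pulse waveform
    stay excluded.  For a clean tone this reduces to picking the single
    dominant IMF.  Raises when no IMF is in band.
    """
    fps = imfset.fps
    scored: list[tuple[float, float, np.ndarray]] = []
    for imf in imfset.imfs:
        if np.ptp(imf) == 0:
            continue
        f_mean, _ = _instantaneous_frequency(imf, fps)
        if not np.isfinite(f_mean):
            continue
        scored.append((_band_power(imf, fps, band), f_mean, imf))
    in_band = [c for c in scored if band[0] <= c[1] <= band[1]]
    if not in_band:
        raise ValueError("no cardiac component: no IMF has in-band mean frequency")
    p_max, f_anchor, _ = max(in_band, key=lambda c: c[0])
    # the merge window may reach slightly past the band edge: mode mixing can
    # drag a pulse-carrying IMF's average frequency just outside the band
    component = np.sum(
        [imf for p, f, imf in scored
         if p >= power_fraction * p_max
         and f_anchor / freq_window <= f <= f_anchor * freq_window],
        axis=0,
    )
    f_principal, _ = _instantaneous_frequency(component, fps)
    return component, float(f_principal)


def reconstruct_peaks(
    imf: np.ndarray,
    fps: float,
    band: tuple[float, float] = CARDIAC_BAND,
    edge_exclude_s: float = 1.0,
    source: str = "TOI",
    f_principal: float | None = None,
) -> PeakTrain:
    """Beat times from the cardiac component.

    Local maxima, refined to sub-sample precision by fitting a parabola
    through the three samples around each maximum; the first/last
    ``edge_exclude_s`` seconds are ignored.  Maxima closer together than
    the implied rate allows are merged keeping the larger amplitude: the
    refractory is one period of the band's upper edge, or — when the
    principal frequency is known — 0.7 of the principal period, which
    absorbs the half-beat double maxima that amplitude beating between
    mode-mixed IMFs produces while never touching genuine beats.
    """
    imf = np.asarray(imf, dtype=float)
    n = imf.size
    if np.ptp(imf) == 0:
        raise ValueError("insufficient beats: constant signal has no peaks")
    idx, _ = sps.find_peaks(imf)
    lo = edge_exclude_s * fps
    hi = (n - 1) - edge_exclude_s * fps
    idx = idx[(idx >= lo) & (idx <= hi)]
    times, amps = [], []
    for i in idx:
        if i == 0 or i == n - 1:
            continue
        y0, y1, y2 = imf[i - 1], imf[i], imf[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        times.append((i + delta) / fps)
        amps.append(y1 - 0.25 * (y0 - y2) * delta)
    # merge peaks violating the implied-rate refractory
    min_gap = 1.0 / band[1]
    if f_principal is not None and f_principal > 0:
        min_gap = max(min_gap, 0.7 / f_principal)
    kept_t: list[float] = []
    kept_a: list[float] = []
    for t, a in zip(times, amps):
        if kept_t and t - kept_t[-1] < min_gap:
            if a > kept_a[-1]:
                kept_t[-1], kept_a[-1] = t, a
        else:
            kept_t.append(t)
            kept_a.append(a)
    if len(kept_t) < 3:
        raise ValueError(f"insufficient beats: found {len(kept_t)} peaks")
    return PeakTrain(peak_times_s=np.asarray(kept_t), source=source,
                     duration_s=n / fps)


def extract_peaks(signal: HCSignal,
                  band: tuple[float, float] = CARDIAC_BAND) -> PeakTrain:
    """Full pulse stage: band-pass -> EMD -> cardiac IMF -> peak train."""
    filtered = bandpass(signal, band)
    imfset = emd(filtered)
    component, f_principal = principal_frequency(imfset, band)
    return reconstruct_peaks(component, signal.fps, band,
                             f_principal=f_principal)
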