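"""Reference branch: R-wave detection in an ECG waveform.

A Pan-Tompkins-style energy detector: band-pass 5-35 Hz to isolate QRS
energy, squared derivative, 150 ms moving-window integration, an adaptive
quantile threshold placed a tenth of the way from the quiet-baseline
energy to the QRS-population energy, a 250 ms refractory period, and final
refinement to the local maximum of the band-passed signal within +/-50 ms
of each detection.  All constants are exposed on :class:`RPeakConfig`.

The detector is scale-invariant: every stage is homogeneous in the input
amplitude and the threshold is derived from robust statistics of the
energy itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .pulse import PeakTrain


@dataclass
class ECGRecord:
    """Uniformly sampled ECG voltage trace.

    ``fs`` defaults to 1000 Hz; when loading from disk it is taken from a
    JSON sidecar or inferred from the time stamps.
    """

    t_s: np.ndarray
    voltage: np.ndarray
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.t_s.shape != self.voltage.shape or self.t_s.ndim != 1:
            raise ValueError("t_s and voltage must be equal-length 1-D arrays")
        if self.t_s.size < 2 * self.fs:
            raise ValueError("ECG record must cover at least 2 s")
        dt = np.diff(self.t_s)
        if dt.size and abs(dt.mean() * self.fs - 1.0) > 1e-6:
            raise ValueError("time stamps disagree with fs beyond 1 ppm")
        if np.ptp(dt) > dt.mean() * 1e-6 + 1e-9:
            raise ValueError("sampling is not uniform within 1 ppm")

    @property
    def duration_s(self) -> float:
        return self.t_s[-1] - self.t_s[0]


@dataclass
class RPeakConfig:
    """Detector constants.  The threshold sits a fraction of the way from
    the quiet-baseline energy (``noise_quantile``) up to the QRS-population
    energy (``signal_quantile``) — the static analog of Pan-Tompkins'
    quarter-way rule.  ``min_signal_noise_ratio`` guards against running on
    a record with no QRS population at all (pure noise scores ~4)."""

    band_hz: tuple[float, float] = (5.0, 35.0)
    integration_window_s: float = 0.150
    noise_quantile: float = 25.0
    signal_quantile: float = 99.5
    threshold_frac: float = 0.1
    min_signal_noise_ratio: float = 8.0
    refractory_s: float = 0.250
    refine_window_s: float = 0.050


def detect_r_peaks(record: ECGRecord, config: RPeakConfig | None = None) -> PeakTrain:
    """Detect R-wave peak times; raises if no beat clears the threshold."""
    config = config or RPeakConfig()
    x = record.voltage
    if np.ptp(x) == 0:
        raise ValueError("no beats detected: constant signal")
    fs = record.fs
    sos = sps.butter(3, config.band_hz, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x - x.mean())
    energy = np.gradient(filt) ** 2
    win = max(1, int(round(config.integration_window_s * fs)))
    integ = uniform_filter1d(energy, size=win, mode="nearest")

    noise_level = np.percentile(integ, config.noise_quantile)
    signal_level = np.percentile(integ, config.signal_quantile)
    if signal_level < config.min_signal_noise_ratio * max(noise_level, 1e-300):
        raise ValueError("no beats detected: no QRS energy population")
    thr = noise_level + config.threshold_frac * (signal_level - noise_level)
    distance = max(1, int(round(config.refractory_s * fs)))
    idx, _ = sps.find_peaks(integ, height=thr, distance=distance)
    if idx.size == 0:
        raise ValueError("no beats detected: nothing above adaptive threshold")

    # refine each detection to the band-passed waveform's local maximum
    half = max(1, int(round(config.refine_window_s * fs)))
    refined = []
    for i in idx:
        lo, hi = max(0, i - half), min(filt.size, i + half + 1)
        refined.append(lo + int(np.argmax(filt[lo:hi])))
    refined = np.unique(refined)
    # re-apply the refractory period after refinement
    kept: list[int] = []
    for i in refined:
        if kept and i - kept[-1] < distance:
            if filt[i] > filt[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    times = record.t_s[np.asarray(kept, dtype=int)]
    return PeakTrain(peak_times_s=times, source="ECG",
                     duration_s=float(record.duration_s))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_ecg_csv(path: str | Path, fs: float | None = None) -> ECGRecord:
    """Read a two-column ``t_s,voltage`` CSV, honoring a ``.json`` sidecar
    with ``{"fs": ...}`` when present."""
    path = Path(path)
    df = pd.read_csv(path)
    if fs is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            fs = float(json.loads(sidecar.read_text()).get("fs", 0)) or None
    if fs is None:
        dt = np.diff(df["t_s"].to_numpy())
        fs = 1.0 / dt.mean()
    return ECGRecord(t_s=df["t_s"].to_numpy(), voltage=df["voltage"].to_numpy(),
                     fs=float(fs))


def write_ecg_csv(path: str | Path, record: ECGRecord) -> None:
    pd.DataFrame({"t_s": record.t_s, "voltage": record.voltage}).to_csv(
        path, index=False
    )
    Path(path).with_suffix(".json").write_text(json.dumps({"fs": record.fs}))
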