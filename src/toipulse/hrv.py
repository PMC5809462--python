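"""R-R intervals, heart rate, and Poincare SD1/SD2.

The Poincare plot scatters each R-R interval RR(n) against the next,
RR(n+1).  SD1 is the dispersion perpendicular to the identity line
(short-term, respiration-driven variability); SD2 is the dispersion along
it (long-term variability).  Their ratio SD1/SD2 is the stress index:
lower values indicate higher basal stress.  Closed formulas, with sample
(n-1) standard deviations and d_n = RR_n - RR_{n+1}:

    SD1 = (sqrt(2)/2) * SD(d)
    SD2 = sqrt(2 * SD(RR)^2 - (1/2) * SD(d)^2)

The SD2 radicand can round below zero for short anti-correlated series; it
is clamped at zero and flagged rather than raised.  Heart rate is
60000 / mean(RR), i.e. beats per elapsed time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .pulse import PeakTrain

#: Physiologically plausible R-R interval range (ms); violations flag, not raise.
RRI_PLAUSIBLE_MS = (250.0, 2500.0)


@dataclass
class RRISeries:
    """Ordered R-R intervals in milliseconds with a source tag."""

    rri_ms: np.ndarray
    source: str = "TOI"
    t_s: np.ndarray | None = None  #: time of each interval's closing beat
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rri_ms = np.asarray(self.rri_ms, dtype=float)
        if self.rri_ms.ndim != 1:
            raise ValueError("rri_ms must be 1-D")
        if self.rri_ms.size and np.any(self.rri_ms <= 0):
            raise ValueError("R-R intervals must be positive")
        lo, hi = RRI_PLAUSIBLE_MS
        if self.rri_ms.size and (
            self.rri_ms.min() < lo or self.rri_ms.max() > hi
        ):
            if "implausible_rri" not in self.flags:
                self.flags.append("implausible_rri")
        if self.t_s is not None:
            self.t_s = np.asarray(self.t_s, dtype=float)
            if self.t_s.shape != self.rri_ms.shape:
                raise ValueError("t_s must align with rri_ms")

    def __len__(self) -> int:
        return self.rri_ms.size


@dataclass
class PoincareSummary:
    sd1_ms: float
    sd2_ms: float
    sd_ratio: float | None  #: None when SD2 = 0 (undefined)
    heart_rate_bpm: float
    n_intervals: int
    source: str = "TOI"
    flags: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "heart_rate_bpm": self.heart_rate_bpm,
                "sd1_ms": self.sd1_ms,
                "sd2_ms": self.sd2_ms,
                "sd_ratio": self.sd_ratio,
                "n_intervals": self.n_intervals,
                "flags": self.flags,
            },
            sort_keys=True,
        )


def rri_from_peaks(peaks: PeakTrain) -> RRISeries:
    """Successive beat-time differences in milliseconds."""
    t = peaks.peak_times_s
    if t.size < 2:
        raise ValueError("need at least 2 peaks to form an interval")
    return RRISeries(rri_ms=1000.0 * np.diff(t), source=peaks.source, t_s=t[1:])


def heart_rate(rri: RRISeries | np.ndarray) -> float:
    """Mean heart rate in BPM: 60000 / mean(RRI)."""
    values = rri.rri_ms if isinstance(rri, RRISeries) else np.asarray(rri, float)
    if values.size == 0:
        raise ValueError("empty R-R interval series")
    return 60000.0 / values.mean()


def poincare(rri: RRISeries | np.ndarray, source: str | None = None) -> PoincareSummary:
    """SD1, SD2, SD1/SD2 and heart rate from an R-R interval series."""
    if isinstance(rri, RRISeries):
        values, src = rri.rri_ms, rri.source
        flags = list(rri.flags)
    else:
        values, src, flags = np.asarray(rri, dtype=float), "TOI", []
    if source is not None:
        src = source
    if values.size < 3:
        raise ValueError("Poincare analysis needs at least 3 intervals")
    d = values[:-1] - values[1:]
    sd_d = d.std(ddof=1)
    sd1 = float(np.sqrt(0.5) * sd_d)
    radicand = 2.0 * values.std(ddof=1) ** 2 - 0.5 * sd_d**2
    # an exactly-zero radicand rounds either way in floats; snap to 0
    tol = 1e-10 * max(2.0 * values.std(ddof=1) ** 2, 1.0)
    if radicand < tol:
        if radicand < -tol:
            flags.append("sd2_radicand_clamped")
        radicand = 0.0
    sd2 = float(np.sqrt(radicand))
    if sd2 > 0:
        ratio: float | None = sd1 / sd2
    else:
        ratio = None
        flags.append("sd_ratio_undefined")
    return PoincareSummary(
        sd1_ms=sd1,
        sd2_ms=sd2,
        sd_ratio=ratio,
        heart_rate_bpm=heart_rate(values),
        n_intervals=int(values.size),
        source=src,
        flags=flags,
    )


def poincare_projection_oracle(values: np.ndarray) -> tuple[float, float]:
    """Geometric cross-check: axis SDs of the 45-degree-rotated lag cloud.

    Rotates the points (RR_n, RR_{n+1}) by 45 degrees and returns the
    sample SDs perpendicular to and along the identity line.  The
    perpendicular SD equals SD1 exactly; the along-identity SD equals the
    SD2 formula written with the lag cloud's marginal variances (and the
    full-series formula asymptotically).
    """
    values = np.asarray(values, dtype=float)
    x, y = values[:-1], values[1:]
    perp = (x - y) / np.sqrt(2.0)
    along = (x + y) / np.sqrt(2.0)
    return float(perp.std(ddof=1)), float(along.std(ddof=1))


def tachogram_correlation(a: RRISeries, b: RRISeries, grid_hz: float = 4.0) -> float:
    """Pearson correlation of two R-R tachograms on a common time grid.

    Both series must carry beat times (``t_s``).  Each tachogram RRI(t) is
    linearly interpolated onto a ``grid_hz`` grid over the overlapping time
    span; used to compare a recovered series against ground truth when the
    two branches detect different beat counts.
    """
    if a.t_s is None or b.t_s is None:
        raise ValueError("both series need beat times for alignment")
    t0 = max(a.t_s[0], b.t_s[0])
    t1 = min(a.t_s[-1], b.t_s[-1])
    if t1 - t0 < 2.0 / grid_hz:
        raise ValueError("series do not overlap in time")
    grid = np.arange(t0, t1, 1.0 / grid_hz)
    ya = np.interp(grid, a.t_s, a.rri_ms)
    yb = np.interp(grid, b.t_s, b.rri_ms)
    if ya.std() == 0 or yb.std() == 0:
        raise ValueError("constant tachogram: correlation undefined")
    return float(np.corrcoef(ya, yb)[0, 1])
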