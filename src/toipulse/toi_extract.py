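"""Bitplane selection: composing the hemoglobin-concentration signal.

The hemoglobin-concentration (HC) signal is a signed, unscaled sum of
bitplanes — pixel-wise additions and subtractions of 1-bit images — whose
ROI average pulses with the cardiac cycle.  Which of the 24 planes carry
blood-volume information is not known a priori; it is learned by greedy
coordinate ascent on a cardiac-band spectral signal-to-noise objective,
with an in-recording train/validation split along the time axis.

The SNR objective stands in for training against contact instruments
(laser Doppler, cuff blood pressure): it scores how much of a composed ROI
signal's power falls in the cardiac frequency band (default 0.7-4 Hz,
42-240 BPM) relative to everything else above 0.05 Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .videoio import CHANNELS, FrameStack, ROIMap, plane_index, roi_bitplane_means

PLANE_KEYS: tuple[tuple[str, int], ...] = tuple(
    (c, b) for c in CHANNELS for b in range(8)
)


class DegenerateSignalError(ValueError):
    """Raised when an operation receives a constant (zero-power) series."""


@dataclass
class BitplaneWeights:
    """Signed coefficient in {-1, 0, +1} for each of the 24 bitplanes."""

    w: dict[tuple[str, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {k: 0 for k in PLANE_KEYS}
        for k, v in self.w.items():
            if k not in full:
                raise ValueError(f"unknown bitplane {k!r}")
            if v not in (-1, 0, 1):
                raise ValueError(f"weight for {k!r} must be in {{-1, 0, +1}}")
            full[k] = int(v)
        self.w = full

    def as_vector(self) -> np.ndarray:
        """Length-24 int vector in channel-major (R0..R7, G0..G7, B0..B7) order."""
        return np.array([self.w[k] for k in PLANE_KEYS], dtype=int)

    def nonzero(self) -> dict[tuple[str, int], int]:
        return {k: v for k, v in self.w.items() if v != 0}

    def is_zero(self) -> bool:
        return all(v == 0 for v in self.w.values())

    def to_json(self, band: Sequence[float] = (0.7, 4.0)) -> str:
        keys = {f"{c}{b}": v for (c, b), v in sorted(self.nonzero().items())}
        return json.dumps({"weights": keys, "band": list(band)}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str | Path) -> "BitplaneWeights":
        if isinstance(text, Path) or (isinstance(text, str) and "\n" not in text
                                      and Path(text).is_file()):
            text = Path(text).read_text()
        obj = json.loads(text)
        w = {(k[0], int(k[1:])): int(v) for k, v in obj["weights"].items()}
        return cls(w=w)


@dataclass
class SelectionConfig:
    """Knobs of the greedy bitplane search.

    ``train_fraction`` splits the recording along the time axis; the
    selector optimizes mean training SNR across ROIs and reports held-out
    validation SNR.  ``snr_tolerance`` is the asymptote threshold: ascent
    stops when no single-coordinate move gains at least this many dB.
    """

    cardiac_band: tuple[float, float] = (0.7, 4.0)
    train_fraction: float = 0.8
    max_iterations: int = 48
    snr_tolerance: float = 1.0
    seed: int = 0
    candidate_planes: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cardiac_band[0] < self.cardiac_band[1]:
            raise ValueError("cardiac_band must satisfy 0 < f_lo < f_hi")
        if self.train_fraction not in (0.7, 0.8, 0.9):
            raise ValueError("train_fraction must be one of 0.7, 0.8, 0.9")


@dataclass
class SelectionReport:
    weights: BitplaneWeights
    snr_train_db: float
    snr_validation_db: float
    iterations: int
    converged: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": {f"{c}{b}": v for (c, b), v in
                            sorted(self.weights.nonzero().items())},
                "snr_train_db": self.snr_train_db,
                "snr_validation_db": self.snr_validation_db,
                "iterations": self.iterations,
                "converged": self.converged,
            },
            sort_keys=True,
        )


def compose_signal(
    stack_or_planes: FrameStack | np.ndarray,
    weights: BitplaneWeights,
    roi: np.ndarray | None = None,
) -> np.ndarray:
    """ROI-averaged signed bitplane combination, one value per frame.

    Accepts either a :class:`~toipulse.videoio.FrameStack` plus an ROI mask,
    or a precomputed ``(24, T)`` matrix of per-ROI bitplane means (see
    :func:`~toipulse.videoio.roi_bitplane_means`); the two routes agree
    because ROI averaging is linear.  All-zero weights yield the zero
    series (flagged degenerate downstream, not an error here).
    """
    wvec = weights.as_vector()
    if isinstance(stack_or_planes, FrameStack):
        if roi is None:
            raise ValueError("an ROI mask is required with a FrameStack")
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            raise ValueError("ROI mask is empty")
        pix = stack_or_planes.frames[:, roi, :]  # (T, npix, 3)
        out = np.zeros(pix.shape[0])
        for i, (c, b) in enumerate(PLANE_KEYS):
            if wvec[i] == 0:
                continue
            chan = pix[..., CHANNELS.index(c)]
            out += wvec[i] * ((chan >> b) & 1).mean(axis=1)
        return out
    planes = np.asarray(stack_or_planes, dtype=float)
    if planes.shape[0] != 24:
        raise ValueError("plane-mean matrix must have 24 rows")
    return wvec @ planes


def snr_objective(
    series: np.ndarray, fps: float, band: Sequence[float] = (0.7, 4.0)
) -> float:
    """Cardiac-band SNR of a time series, in dB.

    ``10 log10(P_in / P_out)`` with ``P_in`` the averaged-periodogram
    (Welch, Hann, 50% overlap) power inside ``band`` and ``P_out`` the
    power in ``[0.05 Hz, Nyquist]`` outside it.  The mean is removed, so
    DC never counts as noise.
    """
    series = np.asarray(series, dtype=float)
    f_lo, f_hi = band
    n_min = int(np.ceil(10 * fps / f_lo))
    if series.size < n_min:
        raise ValueError(
            f"series too short for SNR in band >= {f_lo} Hz: "
            f"need {n_min} samples, got {series.size}"
        )
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    if np.ptp(series) == 0:
        raise DegenerateSignalError("constant series has zero total power")
    nperseg = min(series.size, 2048)
    freqs, psd = sps.welch(
        series, fs=fps, nperseg=nperseg, noverlap=nperseg // 2, detrend="constant"
    )
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    out_band = (freqs >= 0.05) & ~in_band
    p_in = psd[in_band].sum()
    p_out = psd[out_band].sum()
    if p_out == 0:
        return np.inf
    if p_in == 0:
        return -np.inf
    return 10.0 * np.log10(p_in / p_out)


def chance_snr_db(fps: float, band: Sequence[float]) -> float:
    """SNR a flat (uninformative) spectrum scores: the band-width ratio."""
    bw = band[1] - band[0]
    return 10.0 * np.log10(bw / ((fps / 2.0 - 0.05) - bw))


def _mean_snr(planes_train: Sequence[np.ndarray], wvec: np.ndarray,
              fps: float, band: Sequence[float]) -> float:
    """Mean SNR across ROIs; a degenerate (constant) composition carries no
    information and scores at chance level rather than vetoing the move."""
    floor = chance_snr_db(fps, band)
    vals = []
    for rows in planes_train:
        series = wvec @ rows
        if np.ptp(series) == 0:
            vals.append(floor)
        else:
            vals.append(snr_objective(series, fps, band))
    return float(np.mean(vals))


def select_bitplane_weights(
    stack: FrameStack,
    roi_map: ROIMap,
    config: SelectionConfig | None = None,
    plane_means: Mapping[str, np.ndarray] | None = None,
) -> SelectionReport:
    """Greedy coordinate ascent over signed bitplane weights.

    Starting from all-zero weights, the single (channel, bit, sign) change
    that most increases the mean training-split SNR across ROIs is applied
    each iteration, until no move gains ``snr_tolerance`` dB or
    ``max_iterations`` is hit.  Deterministic: exact ties are broken by the
    fixed enumeration order R->G->B, bit 7->0, +1 before -1.  When no move
    ever clears the tolerance the report has ``converged=False`` and
    all-zero weights.
    """
    config = config or SelectionConfig()
    if plane_means is None:
        plane_means = roi_bitplane_means(stack, roi_map)
    fps, band = stack.fps, config.cardiac_band
    n = next(iter(plane_means.values())).shape[1]
    n_train = int(round(config.train_fraction * n))
    train = [np.asarray(plane_means[r])[:, :n_train] for r in roi_map.names()]
    valid = [np.asarray(plane_means[r])[:, n_train:] for r in roi_map.names()]

    if config.candidate_planes is None:
        candidates = [plane_index(c, b) for c in CHANNELS for b in range(7, -1, -1)]
    else:
        candidates = [plane_index(c, b) for c, b in config.candidate_planes]

    wvec = np.zeros(24, dtype=int)
    # The all-zero composition has no spectrum; its stand-in baseline is the
    # chance-level SNR of a flat spectrum, so the first accepted plane must
    # carry more cardiac-band power than white noise would.
    best_snr = chance_snr_db(fps, band)
    iterations = 0
    accepted_any = False
    for _ in range(config.max_iterations):
        move_best: tuple[int, int] | None = None
        move_snr = -np.inf
        for idx in candidates:
            # candidate new values in fixed tie-break order: +1, -1, then clear
            for new in (1, -1, 0):
                if new == wvec[idx]:
                    continue
                trial = wvec.copy()
                trial[idx] = new
                snr = _mean_snr(train, trial, fps, band)
                if snr > move_snr:
                    move_snr = snr
                    move_best = (idx, new)
        gain = move_snr - best_snr
        if move_best is None or not np.isfinite(move_snr) or gain < config.snr_tolerance:
            break
        wvec[move_best[0]] = move_best[1]
        best_snr = move_snr
        accepted_any = True
        iterations += 1

    weights = BitplaneWeights(w={PLANE_KEYS[i]: int(wvec[i]) for i in range(24)})
    if not accepted_any:
        return SelectionReport(
            weights=weights, snr_train_db=float("nan"),
            snr_validation_db=float("nan"), iterations=0, converged=False,
        )
    # Report the held-out SNR of the best ROI: downstream pulse extraction
    # uses the single highest-SNR ROI, so that is the quantity that predicts
    # whether the selected weights generalize.
    try:
        per_roi = []
        for rows in valid:
            series = wvec @ rows
            if np.ptp(series) == 0:
                continue
            per_roi.append(snr_objective(series, fps, band))
        snr_val = float(max(per_roi)) if per_roi else float("-inf")
    except ValueError:
        snr_val = float("nan")  # validation split too short for the band
    return SelectionReport(
        weights=weights,
        snr_train_db=float(best_snr),
        snr_validation_db=float(snr_val),
        iterations=iterations,
        converged=True,
    )


def exhaustive_weights(
    stack: FrameStack,
    roi_map: ROIMap,
    planes: Iterable[tuple[str, int]],
    config: SelectionConfig | None = None,
    plane_means: Mapping[str, np.ndarray] | None = None,
) -> tuple[BitplaneWeights, float]:
    """Brute-force search over all sign assignments of the given planes.

    Exponential in the number of planes — a cross-check oracle for the
    greedy selector on toy problems, not a production path.
    """
    config = config or SelectionConfig()
    if plane_means is None:
        plane_means = roi_bitplane_means(stack, roi_map)
    n = next(iter(plane_means.values())).shape[1]
    n_train = int(round(config.train_fraction * n))
    train = [np.asarray(plane_means[r])[:, :n_train] for r in roi_map.names()]
    idxs = [plane_index(c, b) for c, b in planes]
    best: tuple[float, np.ndarray] = (-np.inf, np.zeros(24, dtype=int))
    for code in range(3 ** len(idxs)):
        wvec = np.zeros(24, dtype=int)
        rem = code
        for idx in idxs:
            wvec[idx] = (-1, 0, 1)[rem % 3]
            rem //= 3
        snr = _mean_snr(train, wvec, stack.fps, config.cardiac_band)
        if snr > best[0]:
            best = (snr, wvec)
    weights = BitplaneWeights(w={PLANE_KEYS[i]: int(best[1][i]) for i in range(24)})
    return weights, float(best[0])
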