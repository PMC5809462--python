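"""Ground-truthed synthetic physiology: RRI series, ECG, and facial video.

The generator states the acquisition world the pipeline is validated in:
120 s of 60 fps RGB video of a still face, with the pulse embedded as a
probabilistic bit-flip signal in chosen bitplanes of chosen facial ROIs,
and a matched ECG driven by the same ground-truth beat times.

The beat model is respiratory sinus arrhythmia over a fixed mean rate:

    RRI_n = base + rsa_amp * sin(2 pi f_resp t_n) + N(0, rri_noise^2)

with base = 60000 / hr_bpm.  The video pulse waveform is a raised cosine
centered on each beat (width tied to the local RRI), carrying beat timing
without modelling PPG morphology.  Sensor noise and a slow illumination
drift are added in intensity space before re-quantization, so low-order
bitplanes are genuinely noisy while the embedded planes stay pulse-locked.

Everything is bit-reproducible given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .ecg import ECGRecord
from .hrv import RRISeries
from .pulse import PeakTrain
from .videoio import FrameStack, ROIMap, ROI_NAMES, roi_map_to_config, roi_map_from_config


@dataclass
class EmbedSpec:
    """Where and how strongly the pulse is written into the video."""

    channel: str = "G"
    bits: tuple[int, ...] = (5, 6, 7)
    rois: tuple[str, ...] = ("Forehead Small", "Right Cheek Narrow",
                             "Left Cheek Narrow")
    amplitude: float = 0.6  #: peak bit-set probability, in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("embed amplitude must lie in [0, 1]")
        if self.channel not in "RGB":
            raise ValueError("embed channel must be one of R, G, B")
        if any(not 0 <= b <= 7 for b in self.bits):
            raise ValueError("embed bits must lie in 0..7")


@dataclass
class DriftSpec:
    """Slow multiplexed illumination trend, additive in intensity units."""

    amplitude: float = 2.0
    freq_hz: float = 0.03


@dataclass
class SyntheticConfig:
    seed: int
    hr_bpm: float = 72.0
    rsa_amp_ms: float = 40.0
    resp_freq_hz: float = 0.25
    rri_noise_ms: float = 5.0
    duration_s: float = 120.0
    fps: float = 60.0
    ecg_fs: float = 1000.0
    ecg_noise_sd: float = 0.1  #: 20 dB below the unit R amplitude
    embed: EmbedSpec = field(default_factory=EmbedSpec)
    video_noise_sd: float = 2.0  #: intensity units (LSB)
    drift: DriftSpec = field(default_factory=DriftSpec)
    frame_shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if not 40.0 <= self.hr_bpm <= 180.0:
            raise ValueError("hr_bpm must lie in [40, 180]")
        if self.resp_freq_hz >= self.hr_bpm / 60.0 / 2.0:
            raise ValueError("resp_freq must be below half the beat frequency")
        base_ms = 60000.0 / self.hr_bpm
        if base_ms - self.rsa_amp_ms - 6.0 * self.rri_noise_ms <= 0:
            raise ValueError("parameters imply non-positive R-R intervals")


@dataclass
class TruthBundle:
    """Ground truth emitted alongside every synthetic recording."""

    true_rri_ms: np.ndarray
    true_peak_times_s: np.ndarray
    roi_map: ROIMap
    embed: EmbedSpec
    config: SyntheticConfig

    def __post_init__(self) -> None:
        t = np.asarray(self.true_peak_times_s, dtype=float)
        r = np.asarray(self.true_rri_ms, dtype=float)
        recon = t[0] + np.cumsum(r) / 1000.0
        if not np.allclose(recon, t[1:], atol=1e-9):
            raise ValueError("cumulative RRI does not match peak times")

    def rri_series(self) -> RRISeries:
        return RRISeries(rri_ms=self.true_rri_ms, source="TRUTH",
                         t_s=self.true_peak_times_s[1:])

    def peak_train(self) -> PeakTrain:
        return PeakTrain(peak_times_s=self.true_peak_times_s, source="TRUTH",
                         duration_s=self.config.duration_s)

    def to_json(self) -> str:
        cfg = asdict(self.config)
        cfg["embed"]["bits"] = list(cfg["embed"]["bits"])
        cfg["embed"]["rois"] = list(cfg["embed"]["rois"])
        cfg["frame_shape"] = list(cfg["frame_shape"])
        return json.dumps(
            {
                "true_rri_ms": self.true_rri_ms.tolist(),
                "true_peaks_s": self.true_peak_times_s.tolist(),
                "roi_config": roi_map_to_config(self.roi_map),
                "config": cfg,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str | Path) -> "TruthBundle":
        if isinstance(text, Path):
            text = text.read_text()
        obj = json.loads(text)
        cfg = obj["config"]
        cfg["embed"] = EmbedSpec(
            channel=cfg["embed"]["channel"],
            bits=tuple(cfg["embed"]["bits"]),
            rois=tuple(cfg["embed"]["rois"]),
            amplitude=cfg["embed"]["amplitude"],
        )
        cfg["drift"] = DriftSpec(**cfg["drift"])
        cfg["frame_shape"] = tuple(cfg["frame_shape"])
        config = SyntheticConfig(**cfg)
        return cls(
            true_rri_ms=np.asarray(obj["true_rri_ms"]),
            true_peak_times_s=np.asarray(obj["true_peaks_s"]),
            roi_map=roi_map_from_config(obj["roi_config"]),
            embed=config.embed,
            config=config,
        )


# ---------------------------------------------------------------------------
# beat-interval and ECG generators
# ---------------------------------------------------------------------------

def gen_rri(config: SyntheticConfig) -> tuple[RRISeries, PeakTrain]:
    """RSA-modulated beat times over the recording duration.

    Iterative: the n-th interval is evaluated at the n-th beat time, so the
    modulation is a genuine frequency modulation of the beat process.
    """
    rng = np.random.default_rng(config.seed)
    base_ms = 60000.0 / config.hr_bpm
    t = 0.0
    times = [0.0]
    rri: list[float] = []
    while True:
        interval = (
            base_ms
            + config.rsa_amp_ms * np.sin(2 * np.pi * config.resp_freq_hz * t)
            + rng.normal(0.0, config.rri_noise_ms)
        )
        if interval <= 0:
            raise ValueError("generated a non-positive R-R interval")
        t_next = t + interval / 1000.0
        if t_next > config.duration_s:
            break
        times.append(t_next)
        rri.append(interval)
        t = t_next
    peaks = PeakTrain(peak_times_s=np.asarray(times), source="TRUTH",
                      duration_s=config.duration_s)
    series = RRISeries(rri_ms=np.asarray(rri), source="TRUTH",
                       t_s=np.asarray(times[1:]))
    return series, peaks


def gen_ecg(
    peaks: PeakTrain,
    ecg_fs: float = 1000.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    duration_s: float | None = None,
) -> ECGRecord:
    """Template ECG: P-QRS-T Gaussian bumps at the given beat times.

    Unit-amplitude R wave (SD 10 ms) at each beat, a P bump (0.15, SD
    25 ms) 180 ms before it and a T bump (0.3, SD 40 ms) 250 ms after,
    plus white Gaussian noise.
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 beats to synthesize an ECG")
    rng = np.random.default_rng(seed)
    dur = duration_s if duration_s is not None else (
        peaks.duration_s or peaks.peak_times_s[-1] + 1.0
    )
    n = int(round(dur * ecg_fs))
    t = np.arange(n) / ecg_fs
    v = np.zeros(n)
    for amp, offset_s, sd_s in ((1.0, 0.0, 0.010), (0.15, -0.180, 0.025),
                                (0.3, 0.250, 0.040)):
        for tk in peaks.peak_times_s:
            c = tk + offset_s
            lo = max(0, int((c - 5 * sd_s) * ecg_fs))
            hi = min(n, int((c + 5 * sd_s) * ecg_fs) + 1)
            if lo < hi:
                v[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / sd_s) ** 2)
    if noise_sd > 0:
        v += rng.normal(0.0, noise_sd, size=n)
    return ECGRecord(t_s=t, voltage=v, fs=ecg_fs)


# ---------------------------------------------------------------------------
# face video generator
# ---------------------------------------------------------------------------

def default_roi_map(frame_shape: tuple[int, int] = (64, 64)) -> ROIMap:
    """The nine facial ROIs laid out schematically on the frame.

    Rectangles are placed where the named regions sit on a centered face;
    positions scale with the frame shape.
    """
    h, w = frame_shape
    # fractional (y0, y1, x0, x1) boxes on a 64x64 reference face
    boxes = {
        "Forehead Small": (4, 14, 20, 44),
        "Nose Between Eyes": (16, 22, 28, 36),
        "Nose Bridge Full": (22, 34, 29, 35),
        "Nose Tip Small": (34, 40, 28, 36),
        "Right Cheek Narrow": (26, 40, 10, 20),
        "Left Cheek Narrow": (26, 40, 44, 54),
        "Upper Lip": (42, 46, 26, 38),
        "Lower Lip": (48, 52, 26, 38),
        "Chin Small": (54, 60, 28, 36),
    }
    rois = {}
    for name in ROI_NAMES:
        y0, y1, x0, x1 = boxes[name]
        y0, y1 = int(y0 * h / 64), int(y1 * h / 64)
        x0, x1 = int(x0 * w / 64), int(x1 * w / 64)
        mask = np.zeros((h, w), dtype=bool)
        mask[max(y0, 0):max(y1, y0 + 1), max(x0, 0):max(x1, x0 + 1)] = True
        rois[name] = mask
    return ROIMap(rois=rois, frame_shape=(h, w))


def default_face(frame_shape: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Static skin-toned base image with smooth spatial gradients."""
    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    shade = 10.0 * np.sin(2 * np.pi * yy / h) + 8.0 * np.cos(2 * np.pi * xx / w)
    base = np.empty((h, w, 3))
    base[..., 0] = 165.0 + shade  # R
    base[..., 1] = 120.0 + shade  # G
    base[..., 2] = 98.0 + shade   # B
    return np.clip(np.round(base), 0, 255).astype(np.uint8)


def pulse_waveform(t: np.ndarray, peaks: np.ndarray,
                   width_frac: float = 0.3) -> np.ndarray:
    """Raised-cosine bump train in [0, 1], maxima exactly at beat times."""
    t = np.asarray(t, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    idx = np.searchsorted(peaks, t)
    prev_i = np.clip(idx - 1, 0, peaks.size - 1)
    next_i = np.clip(idx, 0, peaks.size - 1)
    prev, nxt = peaks[prev_i], peaks[next_i]
    nearest = np.where(np.abs(t - prev) <= np.abs(nxt - t), prev, nxt)
    gaps = np.diff(peaks)
    med_gap = float(np.median(gaps)) if gaps.size else 1.0
    # bump width follows the bracketing interval; endpoints use the median
    local = np.where(next_i > prev_i, nxt - prev, med_gap)
    local = np.where(local > 0, local, med_gap)
    hw = width_frac * local
    dt = np.abs(t - nearest)
    p = 0.5 * (1.0 + np.cos(np.pi * dt / hw))
    return np.where(dt < hw, p, 0.0)


def gen_face_video(
    peaks: PeakTrain, config: SyntheticConfig,
    roi_map: ROIMap | None = None,
) -> tuple[FrameStack, TruthBundle]:
    """Render the synthetic recording and its truth bundle.

    Inside the embed ROIs, each target bit of the target channel is forced
    to 1 with probability ``p(t) * amplitude`` (otherwise the base pixel's
    own bit), giving a pulse-locked signal that lives in those bitplanes
    and nowhere else.  Sensor noise and drift then perturb all channels in
    intensity space before re-quantization.
    """
    if roi_map is None:
        roi_map = default_roi_map(config.frame_shape)
    embed = config.embed
    for roi in embed.rois:
        if roi not in roi_map.rois:
            raise ValueError(f"embed ROI {roi!r} not in ROI map")
    rng = np.random.default_rng(config.seed + 1)  # independent of gen_rri stream
    h, w = config.frame_shape
    n_frames = int(round(config.fps * config.duration_s))
    t = np.arange(n_frames) / config.fps
    p = pulse_waveform(t, peaks.peak_times_s) * embed.amplitude

    base = default_face((h, w))
    embed_mask = np.zeros((h, w), dtype=bool)
    for roi in embed.rois:
        embed_mask |= roi_map[roi]
    npix = int(embed_mask.sum())
    ci = "RGB".index(embed.channel)
    bits = np.asarray(embed.bits, dtype=np.uint8)
    bit_or = np.bitwise_or.reduce((1 << bits).astype(np.uint8)) if bits.size else 0

    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    drift = config.drift.amplitude * np.sin(2 * np.pi * config.drift.freq_hz * t)
    chunk = 512
    for s in range(0, n_frames, chunk):
        e = min(s + chunk, n_frames)
        m = e - s
        block = np.broadcast_to(base, (m, h, w, 3)).astype(np.float32).copy()
        if npix and bits.size:
            chan = base[embed_mask, ci]  # (npix,)
            u = rng.random((m, npix, bits.size))
            flip = u < p[s:e, None, None]
            vals = np.broadcast_to(chan, (m, npix)).copy()
            for j, b in enumerate(bits):
                vals = np.where(flip[..., j], vals | np.uint8(1 << b), vals)
            block[:, embed_mask, ci] = vals
            del u, flip, vals
        if config.video_noise_sd > 0:
            block += rng.normal(0.0, config.video_noise_sd,
                                size=block.shape).astype(np.float32)
        block += drift[s:e, None, None, None].astype(np.float32)
        frames[s:e] = np.clip(np.round(block), 0, 255).astype(np.uint8)
    stack = FrameStack(frames=frames, fps=config.fps)
    truth = TruthBundle(
        true_rri_ms=1000.0 * np.diff(peaks.peak_times_s),
        true_peak_times_s=peaks.peak_times_s,
        roi_map=roi_map,
        embed=embed,
        config=config,
    )
    return stack, truth


def generate_subject(config: SyntheticConfig) -> dict:
    """One complete synthetic subject: video, ROI map, ECG, truth."""
    rri, peaks = gen_rri(config)
    stack, truth = gen_face_video(peaks, config)
    record = gen_ecg(peaks, ecg_fs=config.ecg_fs, noise_sd=config.ecg_noise_sd,
                     seed=config.seed + 2, duration_s=config.duration_s)
    return {"video": stack, "roi_map": truth.roi_map, "ecg": record,
            "truth": truth, "rri": rri, "peaks": peaks}
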