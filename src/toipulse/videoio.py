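"""Frame-stack I/O, bitplane decomposition and ROI averaging.

A *bitplane* is the binary image formed by one bit position of one color
channel across all pixels: an 8-bit RGB frame decomposes into 24 binary
planes.  The pulse-bearing hemoglobin signal lives in specific bitplanes of
specific facial regions, so everything downstream operates on per-ROI mean
time series of these planes.

Conventions: frames are ``H x W x 3`` uint8 arrays, channels ordered
R, G, B; pixel indices are row-major and 0-based; ROI masks are boolean
images of frame shape.  Rectangles in ROI config files are half-open,
``[x0, x1) x [y0, y1)`` with ``x`` the column and ``y`` the row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

CHANNELS = ("R", "G", "B")

#: The nine facial regions used for pulse extraction.
ROI_NAMES = (
    "Forehead Small",
    "Nose Between Eyes",
    "Nose Bridge Full",
    "Nose Tip Small",
    "Right Cheek Narrow",
    "Left Cheek Narrow",
    "Upper Lip",
    "Lower Lip",
    "Chin Small",
)


class VideoFormatError(ValueError):
    """Raised for inputs that are not 8-bit, 3-channel video frames."""


@dataclass
class FrameStack:
    """Ordered RGB frames with a fixed frame rate.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W, 3), dtype uint8
        The video, channels ordered R, G, B.
    fps : float
        Frames per second (acquisition default 60).
    """

    frames: np.ndarray
    fps: float = 60.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise VideoFormatError(
                f"expected (T, H, W, 3) frames, got shape {self.frames.shape}"
            )
        if self.frames.dtype != np.uint8:
            raise VideoFormatError(f"expected uint8 frames, got {self.frames.dtype}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class ROIMap:
    """Named boolean pixel masks over a fixed frame shape."""

    rois: dict[str, np.ndarray]
    frame_shape: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("ROIMap requires at least one ROI")
        shapes = {m.shape for m in self.rois.values()}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent mask shapes: {shapes}")
        if self.frame_shape is None:
            self.frame_shape = next(iter(shapes))
        elif tuple(self.frame_shape) != next(iter(shapes)):
            raise ValueError("masks do not match frame_shape")
        for name, mask in self.rois.items():
            if mask.dtype != bool:
                self.rois[name] = mask.astype(bool)
            if not self.rois[name].any():
                raise ValueError(f"ROI {name!r} has an empty mask")

    def names(self) -> list[str]:
        return list(self.rois)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.rois[name]


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise VideoFormatError(f"expected (H, W, 3) frame, got shape {frame.shape}")
    if frame.dtype != np.uint8:
        if not np.issubdtype(frame.dtype, np.integer):
            raise VideoFormatError("frame must contain integer pixel values")
        if frame.min() < 0 or frame.max() > 255:
            raise VideoFormatError("pixel values must lie in [0, 255]")
        frame = frame.astype(np.uint8)
    return frame


def decompose_bitplanes(frame: np.ndarray) -> dict[tuple[str, int], np.ndarray]:
    """Split an 8-bit RGB frame into its 24 binary bitplanes.

    Returns a mapping ``(channel, bit) -> H x W uint8 array`` of zeros and
    ones, where bit 0 is the least significant.
    """
    frame = _check_frame(frame)
    planes: dict[tuple[str, int], np.ndarray] = {}
    for ci, c in enumerate(CHANNELS):
        chan = frame[..., ci]
        for b in range(8):
            planes[(c, b)] = (chan >> b) & 1
    return planes


def reconstruct_channel(planes: Sequence[np.ndarray]) -> np.ndarray:
    """Reassemble one 8-bit channel from its 8 bitplanes (bit 0 first).

    Inverse of :func:`decompose_bitplanes` restricted to one channel:
    ``sum_b 2**b * plane[b]`` exactly recovers the original image.
    """
    if len(planes) != 8:
        raise ValueError(f"expected 8 bitplanes, got {len(planes)}")
    out = np.zeros(np.asarray(planes[0]).shape, dtype=np.uint8)
    for b, p in enumerate(planes):
        p = np.asarray(p)
        if p.shape != out.shape:
            raise ValueError("bitplanes must share one shape")
        out |= (p.astype(np.uint8) & 1) << b
    return out


def average_roi(signal_video: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Mean over the masked pixels of each frame of a per-pixel signal.

    ``signal_video`` is ``(T, H, W)``; the result has one value per frame.
    Spatial averaging over an ROI is the first SNR-raising step of the
    pipeline.
    """
    signal_video = np.asarray(signal_video)
    roi = np.asarray(roi, dtype=bool)
    if signal_video.ndim != 3:
        raise ValueError("signal_video must be (T, H, W)")
    if roi.shape != signal_video.shape[1:]:
        raise ValueError("ROI mask shape does not match frames")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    return signal_video[:, roi].mean(axis=1)


def roi_bitplane_means(stack: FrameStack, roi_map: ROIMap) -> dict[str, np.ndarray]:
    """Per-ROI mean time series of every bitplane.

    Returns ``{roi_name: array of shape (24, T)}`` with rows ordered
    channel-major (R bits 0..7, G bits 0..7, B bits 0..7).  Because ROI
    averaging is linear, any signed bitplane combination restricted to an
    ROI is a weighted sum of these rows; the selector works on this compact
    representation instead of materializing T full bitplane stacks.
    """
    if roi_map.frame_shape != stack.frame_shape:
        raise ValueError("ROI map does not match video frame shape")
    out: dict[str, np.ndarray] = {}
    for name, mask in roi_map.rois.items():
        pix = stack.frames[:, mask, :]  # (T, npix, 3)
        rows = np.empty((24, stack.n_frames))
        for ci in range(3):
            chan = pix[..., ci]
            for b in range(8):
                rows[ci * 8 + b] = ((chan >> b) & 1).mean(axis=1)
        out[name] = rows
    return out


def plane_index(channel: str, bit: int) -> int:
    """Row index of (channel, bit) in :func:`roi_bitplane_means` output."""
    if channel not in CHANNELS or not 0 <= bit <= 7:
        raise ValueError(f"invalid bitplane ({channel!r}, {bit})")
    return CHANNELS.index(channel) * 8 + bit


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_video(path: str | Path, fps: float | None = None) -> FrameStack:
    """Load a video as a :class:`FrameStack`.

    ``.npz`` archives (keys ``frames`` uint8 ``(T,H,W,3)`` and ``fps``) are
    read bit-exactly and are the recommended interchange format: lossy
    codecs perturb the low-order bitplanes the method depends on.  Other
    extensions are handed to :mod:`imageio` when it can decode them.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            frames = z["frames"]
            fps_in = float(z["fps"]) if "fps" in z else fps
        if fps_in is None:
            raise ValueError("archive lacks fps; pass fps explicitly")
        return FrameStack(frames=frames, fps=fps_in)
    try:
        import imageio.v3 as iio

        frames = np.stack([_check_frame(f) for f in iio.imiter(path)])
        meta = iio.immeta(path)
        fps_in = fps if fps is not None else float(meta.get("fps", 0)) or None
    except Exception as exc:  # pragma: no cover - backend-dependent
        raise VideoFormatError(f"cannot decode {path}: {exc}") from exc
    if fps_in is None:  # pragma: no cover
        raise ValueError("container lacks fps metadata; pass fps explicitly")
    return FrameStack(frames=frames, fps=fps_in)


def write_video(path: str | Path, stack: FrameStack) -> None:
    """Write a frame stack to an uncompressed-content ``.npz`` archive."""
    np.savez_compressed(path, frames=stack.frames, fps=np.float64(stack.fps))


def roi_map_from_config(config: Mapping | str | Path) -> ROIMap:
    """Build an :class:`ROIMap` from a JSON config (path, str or mapping).

    Schema::

        { "frame_shape": [H, W],
          "rois": { "<name>": {"type": "rect",
                               "x0": ..., "y0": ..., "x1": ..., "y1": ...} } }

    Rectangles are half-open in both axes.  A ``"poly"`` type with a
    ``"vertices"`` list of ``[x, y]`` pairs is also accepted.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    h, w = (int(v) for v in config["frame_shape"])
    rois: dict[str, np.ndarray] = {}
    for name, spec in config["rois"].items():
        kind = spec.get("type", "rect")
        mask = np.zeros((h, w), dtype=bool)
        if kind == "rect":
            x0, y0, x1, y1 = (int(spec[k]) for k in ("x0", "y0", "x1", "y1"))
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(f"ROI {name!r} rectangle outside frame bounds")
            mask[y0:y1, x0:x1] = True
        elif kind == "poly":
            from matplotlib.path import Path as MplPath  # lazy; rarely used

            verts = np.asarray(spec["vertices"], dtype=float)
            yy, xx = np.mgrid[0:h, 0:w]
            pts = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
            mask = MplPath(verts).contains_points(pts).reshape(h, w)
        else:
            raise ValueError(f"unknown ROI type {kind!r}")
        rois[name] = mask
    return ROIMap(rois=rois, frame_shape=(h, w))


def roi_map_to_config(roi_map: ROIMap) -> dict:
    """Serialize rectangular ROIs back to the JSON schema.

    Only works when every mask is an axis-aligned rectangle.
    """
    out = {"frame_shape": list(roi_map.frame_shape), "rois": {}}
    for name, mask in roi_map.rois.items():
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        y0, y1 = int(rows[0]), int(rows[-1]) + 1
        x0, x1 = int(cols[0]), int(cols[-1]) + 1
        if not mask[y0:y1, x0:x1].all() or int(mask.sum()) != (y1 - y0) * (x1 - x0):
            raise ValueError(f"ROI {name!r} is not rectangular")
        out["rois"][name] = {"type": "rect", "x0": x0, "y0": y0, "x1": x1, "y1": y1}
    return out
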