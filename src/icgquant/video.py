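"""Reduce a fluorescence frame sequence plus ROI to a time-intensity curve.

This plays the role the external video-tracking tool plays in the
operating room: frames in, one mean-intensity trace out.  The ROI is a
boolean mask (or a rectangle) fixed for the whole sequence; multi-segment
comparisons are done by repeated runs with different ROIs.  No motion
correction, distance normalization or illumination compensation is
attempted -- imaging conditions are acknowledged as uncontrolled, which
is precisely why downstream analysis leans on affine-invariant time
factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .curves import PerfusionCurve
from .exceptions import CurveFormatError, InvalidRoiError, InvalidSpecificationError

__all__ = ["RoiMask", "read_frames", "extract_curve"]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}
_FRAME_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class RoiMask:
    """Boolean region-of-interest mask matching the frame geometry."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise InvalidRoiError("ROI mask must be a 2-D boolean image")
        if not mask.any():
            raise InvalidRoiError("ROI mask needs at least one true pixel")
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def rectangle(
        cls, shape: tuple[int, int], x0: int, y0: int, x1: int, y1: int,
        label: str = "",
    ) -> "RoiMask":
        """Rectangular ROI in pixel coordinates, half-open upper bounds."""
        h, w = shape
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise InvalidRoiError(
                f"rectangle ({x0},{y0},{x1},{y1}) out of bounds for {shape}"
            )
        mask = np.zeros(shape, dtype=bool)
        mask[y0:y1, x0:x1] = True
        return cls(mask=mask, label=label or f"rect({x0},{y0},{x1},{y1})")

    @classmethod
    def from_image(cls, path, label: str = "") -> "RoiMask":
        """Load a mask image; any nonzero pixel is inside the ROI."""
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path))
        if img.ndim == 3:
            img = img.max(axis=-1)
        return cls(mask=img > 0, label=label or str(path))


def _reduce_channel(frames: np.ndarray, channel: str) -> np.ndarray:
    """Reduce trailing RGB(A) channels to a single intensity plane."""
    if frames.ndim == 3:
        return frames
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        if channel == "mean":
            return frames[..., :3].mean(axis=-1)
        if channel not in _CHANNELS:
            raise InvalidSpecificationError(
                f"unknown channel {channel!r}; use red/green/blue/mean"
            )
        return frames[..., _CHANNELS[channel]]
    raise CurveFormatError(f"unsupported frame array shape {frames.shape}")


def _sidecar_frame_rate(candidates) -> float | None:
    for c in candidates:
        c = Path(c)
        if c.is_file():
            try:
                with open(c) as fh:
                    meta = json.load(fh)
                rate = meta.get("frame_rate_fps")
                if rate is not None:
                    return float(rate)
            except (json.JSONDecodeError, OSError):
                continue
    return None


def read_frames(
    path,
    frame_rate: float | None = None,
    channel: str = "green",
) -> tuple[np.ndarray, float]:
    """Load a frame sequence from a multi-page TIFF or a frame directory.

    Frames are returned as a float (n, h, w) array in acquisition order
    (directory entries sorted by name); multi-channel input is reduced by
    `channel` (default green, matching the fluorescence emission display).
    The frame rate comes from an explicit argument or from a sidecar JSON
    (`<stack>.json` next to a TIFF, `metadata.json` inside a directory);
    neither present is a configuration error.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if len(files) < 2:
            raise CurveFormatError(
                f"frame directory {path} holds {len(files)} frame(s); "
                "need at least 2"
            )
        import imageio.v3 as iio

        imgs = [np.asarray(iio.imread(f)) for f in files]
        shapes = {im.shape for im in imgs}
        if len(shapes) > 1:
            raise CurveFormatError(f"mixed frame dimensions in {path}: {shapes}")
        frames = np.stack(imgs).astype(float)
        sidecar = [path / "metadata.json"]
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = np.asarray(tifffile.imread(path)).astype(float)
        if frames.ndim == 2:
            raise CurveFormatError(
                f"{path} holds a single frame; need a multi-page stack"
            )
        sidecar = [path.with_suffix(".json")]
    else:
        raise CurveFormatError(
            f"cannot read frames from {path}: expected a .tif/.tiff stack "
            "or a directory of frames"
        )
    frames = _reduce_channel(frames, channel)
    if frame_rate is None:
        frame_rate = _sidecar_frame_rate(sidecar)
    if frame_rate is None:
        raise InvalidSpecificationError(
            "frame_rate not given and no sidecar metadata found"
        )
    if frame_rate <= 0:
        raise InvalidSpecificationError("frame_rate must be positive")
    return frames, float(frame_rate)


def extract_curve(
    frames: np.ndarray, roi: RoiMask, frame_rate: float
) -> PerfusionCurve:
    """Mean ROI intensity per frame as a perfusion curve.

    The intensity at frame i is the arithmetic mean of the pixel values
    inside the ROI; sample times are i / frame_rate (0-based, start of
    frame).  Linear in pixel intensities and permutation-invariant over
    the masked pixels.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise CurveFormatError("frames must be a (n, h, w) array")
    if roi.mask.shape != frames.shape[1:]:
        raise InvalidRoiError(
            f"ROI shape {roi.mask.shape} does not match frames {frames.shape[1:]}"
        )
    if frame_rate <= 0:
        raise InvalidSpecificationError("frame_rate must be positive")
    intensities = frames[:, roi.mask].mean(axis=1)
    times = np.arange(frames.shape[0]) / frame_rate
    return PerfusionCurve(
        times=times, intensities=intensities, frame_rate=frame_rate,
        label=roi.label,
    )
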