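"""Core containers: acquisition metadata, movies, rectangular ROIs, nucleus masks.

Conventions
-----------
* Pixel coordinates are 0-based; rectangles are half-open,
  ``[x0, x0 + width) × [y0, y0 + height)``.
* Frames are indexed 0-based.  ``damage_frame`` is the index of the first
  frame acquired *after* damage induction, so frames
  ``0 .. damage_frame - 1`` are pre-damage and ``n_predamage ==
  damage_frame``.
* The time axis is ``time_s = (frame - damage_frame) * frame_interval``:
  the first post-damage frame sits at t = 0 and pre-damage frames have
  negative times, which makes t50 (measured from damage) unambiguous.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np


@dataclasses.dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata for one time-lapse channel.

    Parameters
    ----------
    frame_interval : float
        Seconds between consecutive frames (> 0).  0.5 s in the standard
        recruitment regime, 0.1 s in the fast-imaging regime.
    pixel_size : float
        Micrometres per pixel (> 0).  Never inferred from image content;
        must come from the acquisition configuration.
    damage_frame : int
        Index (0-based, >= 1) of the first post-damage frame; equals the
        number of pre-damage frames.
    """

    frame_interval: float
    pixel_size: float
    damage_frame: int

    def __post_init__(self) -> None:
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        if int(self.damage_frame) != self.damage_frame or self.damage_frame < 1:
            raise ValueError("damage_frame must be an integer >= 1")
        object.__setattr__(self, "damage_frame", int(self.damage_frame))

    @property
    def n_predamage(self) -> int:
        """Number of frames acquired before damage induction."""
        return self.damage_frame

    def times(self, n_frames: int) -> np.ndarray:
        """Time axis in seconds from damage for ``n_frames`` frames."""
        return (np.arange(n_frames) - self.damage_frame) * self.frame_interval


@dataclasses.dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle, 0-based, half-open on both axes."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "width", "height"):
            v = getattr(self, name)
            if int(v) != v:
                raise ValueError(f"{name} must be an integer")
            object.__setattr__(self, name, int(v))
        if self.width * self.height < 1 or self.width < 1 or self.height < 1:
            raise ValueError("ROI must contain at least one pixel")

    @property
    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices selecting the ROI from an H×W frame."""
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )

    def validate_in(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x0 < 0 or self.y0 < 0 or self.x0 + self.width > w or self.y0 + self.height > h:
            raise ValueError(f"ROI {self} does not fit inside frame of shape {shape}")

    def shifted(self, dx: int, dy: int) -> "RectROI":
        return RectROI(self.x0 + dx, self.y0 + dy, self.width, self.height)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean H×W mask of the rectangle (clipped to the frame)."""
        m = np.zeros(shape, dtype=bool)
        sy = slice(max(self.y0, 0), min(self.y0 + self.height, shape[0]))
        sx = slice(max(self.x0, 0), min(self.x0 + self.width, shape[1]))
        m[sy, sx] = True
        return m


class NucleusMask:
    """Boolean nucleus mask used for bleaching correction and size analysis."""

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask)
        if mask.ndim != 2 or mask.dtype != bool:
            mask = mask.astype(bool)
        if mask.ndim != 2:
            raise ValueError("nucleus mask must be 2-D")
        if int(mask.sum()) < 1:
            raise ValueError("nucleus mask must contain at least one pixel")
        self.mask = mask

    @property
    def area(self) -> int:
        """Nucleus area in pixels."""
        return int(self.mask.sum())

    def area_um2(self, pixel_size: float) -> float:
        return self.area * pixel_size**2

    def check_contains(self, roi: RectROI) -> bool:
        """Warn (do not fail) if the damage ROI is not fully inside the mask."""
        inside = bool(self.mask[roi.slices].all())
        if not inside:
            warnings.warn(
                "damage ROI is not fully contained in the nucleus mask",
                stacklevel=2,
            )
        return inside

    @classmethod
    def from_rect(cls, roi: RectROI, shape: tuple[int, int]) -> "NucleusMask":
        roi.validate_in(shape)
        return cls(roi.mask(shape))

    @classmethod
    def from_ellipse(
        cls,
        shape: tuple[int, int],
        center: tuple[float, float],
        semi_axes: tuple[float, float],
    ) -> "NucleusMask":
        """Elliptical mask; ``center`` and ``semi_axes`` are (x, y) in pixels."""
        cx, cy = center
        ax, ay = semi_axes
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return cls(((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0)


class TimeLapseMovie:
    """A T×H×W stack of non-negative intensities for a single channel."""

    def __init__(self, frames: np.ndarray, meta: AcquisitionMeta, channel_label: str = ""):
        frames = np.asarray(frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a T×H×W array")
        if frames.shape[0] < 2:
            raise ValueError("too few frames: a time lapse needs at least 2")
        if not np.isfinite(frames).all():
            raise ValueError("frames contain non-finite intensities")
        if frames.min() < 0:
            raise ValueError("frames contain negative intensities")
        if meta.damage_frame >= frames.shape[0]:
            raise ValueError(
                f"damage_frame {meta.damage_frame} not before last frame "
                f"(T={frames.shape[0]})"
            )
        self.frames = frames
        self.meta = meta
        self.channel_label = channel_label

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def times(self) -> np.ndarray:
        return self.meta.times(self.n_frames)

    def with_frames(self, frames: np.ndarray, channel_label: str | None = None) -> "TimeLapseMovie":
        return TimeLapseMovie(
            frames,
            self.meta,
            self.channel_label if channel_label is None else channel_label,
        )
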