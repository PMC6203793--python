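"""Image containers: single frames and z/time stacks with physical metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageFrame", "ImageStack"]


@dataclass
class ImageFrame:
    """A single grayscale microscope frame in detector units.

    Pixels are non-negative and, after camera quantization, bounded by
    ``2**bit_depth - 1``.  ``pixel_size_nm`` is the physical size of one
    pixel in the sample plane.
    """

    pixels: np.ndarray
    pixel_size_nm: float = 160.0
    time_s: float = 0.0
    z_index: int = 0
    channel_id: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageStack:
    """An ordered sequence of frames along the z or time axis.

    ``axis`` is ``"z"`` (spacing ``z_step_um``, default 0.22 um) or
    ``"time"`` (spacing ``frame_interval_s``).  All frames must share the
    same shape and bit depth.
    """

    frames: list[ImageFrame] = field(default_factory=list)
    axis: str = "z"
    z_step_um: float = 0.22
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if self.axis not in ("z", "time"):
            raise ValueError(f"axis must be 'z' or 'time', got {self.axis!r}")
        if self.axis == "z" and not self.z_step_um > 0:
            raise ValueError("z_step_um must be > 0")
        if self.frames:
            shape = self.frames[0].shape
            depth = self.frames[0].bit_depth
            for f in self.frames:
                if f.shape != shape or f.bit_depth != depth:
                    raise ValueError("all frames in a stack must share shape and bit depth")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> ImageFrame:
        return self.frames[i]

    def as_array(self) -> np.ndarray:
        """Stack pixel data into a (n_frames, H, W) array."""
        return np.stack([f.pixels for f in self.frames])
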