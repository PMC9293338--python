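"""Rectangular regions of interest on envelope images.

Pixel coordinates are 0-based with half-open intervals, matching numpy
slicing: a pixel (row, col) belongs to the ROI iff y0 <= row < y1 and
x0 <= col < x1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Rect"]


@dataclass(frozen=True)
class Rect:
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("ROI must have positive extent (x0<x1, y0<y1)")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI coordinates must be non-negative")

    def validate_within(self, shape: tuple[int, int]) -> None:
        ny, nx = shape
        if self.y1 > ny or self.x1 > nx:
            raise ValueError(f"ROI {self} exceeds image shape {shape}")

    def slice(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def extract(self, image: np.ndarray) -> np.ndarray:
        self.validate_within(image.shape[-2:])
        return image[..., self.y0 : self.y1, self.x0 : self.x1]

    @classmethod
    def parse(cls, text: str) -> "Rect":
        """Parse ``"x0,y0,x1,y1"``."""
        parts = [int(p) for p in text.split(",")]
        if len(parts) != 4:
            raise ValueError("ROI must be 'x0,y0,x1,y1'")
        return cls(*parts)
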