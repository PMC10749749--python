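"""Core image containers: a single optical section and an ordered Z-stack.

Intensities are held as double-precision floats regardless of the on-disk
sample format, since all downstream arithmetic (Fourier transforms, Gaussian
fits) is real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ImagePlane:
    """One 2D intensity raster with a physical lateral pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D array of intensities, converted to float64. Must be finite.
    pixel_size : float
        Physical width of one pixel in micrometres (> 0).
    z_index : int
        0-based slice index within the parent stack.
    """

    pixels: np.ndarray
    pixel_size: float
    z_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values (NaN/Inf)")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (height, width)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def crop(self, x: int, y: int, w: int, h: int) -> "ImagePlane":
        """Crop a w×h window with top-left corner (x, y), in pixel coordinates."""
        if x < 0 or y < 0 or x + w > self.width or y + h > self.height:
            raise ValueError(f"crop ({x},{y},{w},{h}) exceeds image bounds {self.shape}")
        return ImagePlane(self.pixels[y : y + h, x : x + w], self.pixel_size, self.z_index)


@dataclass
class ZStack:
    """Ordered sequence of image planes separated by a fixed axial step.

    Parameters
    ----------
    planes : list of ImagePlane
        All planes must share shape and pixel_size; z_index runs 0, 1, 2, ...
    z_step : float
        Distance between consecutive planes (µm, > 0).
    depth_origin : float
        Physical depth of plane 0 (µm). Defaults to 0 (stack starts at the surface).
    """

    planes: list[ImagePlane]
    z_step: float
    depth_origin: float = 0.0

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("ZStack must contain at least one plane")
        if self.z_step <= 0:
            raise ValueError(f"z_step must be > 0, got {self.z_step}")
        first = self.planes[0]
        for i, p in enumerate(self.planes):
            if p.shape != first.shape:
                raise ValueError("all planes must share the same shape")
            if p.pixel_size != first.pixel_size:
                raise ValueError("all planes must share the same pixel_size")
            if p.z_index != i:
                raise ValueError("plane z_index must increase 0, 1, 2, ...")

    def __len__(self) -> int:
        return len(self.planes)

    def __getitem__(self, i: int) -> ImagePlane:
        return self.planes[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape

    @property
    def pixel_size(self) -> float:
        return self.planes[0].pixel_size

    def depth_of(self, z_index: int) -> float:
        """Physical depth (µm) of a slice: depth_origin + z_index * z_step."""
        return self.depth_origin + z_index * self.z_step

    def as_array(self) -> np.ndarray:
        """Stack intensities into a (z, y, x) float64 array."""
        return np.stack([p.pixels for p in self.planes])
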