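"""Regions of interest: per-slice closed polygons and their rasterisation.

Coordinate convention: pixel coordinates are 0-based with x increasing to the
right and y downward. A pixel (x, y) belongs to a polygon iff its centre
(x + 0.5, y + 0.5) is inside under the even-odd rule, with a half-open
crossing test so that pixels on shared edges are assigned to exactly one side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Polygon = np.ndarray  # (n, 2) array of (x, y) vertices


def _as_polygon(vertices) -> Polygon:
    pts = np.asarray(vertices, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError(f"polygon needs >= 3 (x, y) vertices, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("polygon vertices must be finite")
    return pts


@dataclass
class RoiSet:
    """Mapping from z_index to a list of closed polygons (pixel coordinates).

    Slices without an entry contribute no tiles (empty ROI). Vertices may lie
    slightly outside the image; they are clamped to the bounds at rasterisation.
    """

    polygons: dict[int, list[Polygon]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, list[Polygon]] = {}
        for z, polys in self.polygons.items():
            if z < 0:
                raise ValueError(f"negative z_index {z}")
            clean[int(z)] = [_as_polygon(p) for p in polys]
        self.polygons = clean

    def add(self, z_index: int, vertices) -> None:
        self.polygons.setdefault(int(z_index), []).append(_as_polygon(vertices))

    def get(self, z_index: int) -> list[Polygon]:
        return self.polygons.get(z_index, [])

    def slices(self) -> list[int]:
        return sorted(self.polygons)

    def is_empty(self) -> bool:
        return not any(self.polygons.values())

    def mask(self, z_index: int, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of the union of this slice's polygons."""
        return polygons_mask(shape, self.get(z_index))

    @classmethod
    def full_frame(cls, shape: tuple[int, int], z_indices) -> "RoiSet":
        """ROI covering the whole image on the given slices."""
        h, w = shape
        rect = [(0.0, 0.0), (w, 0.0), (w, h), (0.0, h)]
        return cls({int(z): [np.asarray(rect)] for z in z_indices})


def polygon_mask(shape: tuple[int, int], vertices) -> np.ndarray:
    """Rasterise one polygon: even-odd rule, pixel-centre test, half-open edges."""
    poly = _as_polygon(vertices)
    h, w = shape
    # clamp vertices to the image bounds; ROIs drawn slightly outside snap in
    poly = np.column_stack([np.clip(poly[:, 0], 0, w), np.clip(poly[:, 1], 0, h)])
    xc = np.arange(w, dtype=np.float64) + 0.5
    yc = np.arange(h, dtype=np.float64) + 0.5
    inside = np.zeros((h, w), dtype=bool)
    x0, y0 = poly[-1]
    for x1, y1 in poly:
        if y0 != y1:
            # rows whose centre lies in the half-open vertical span of the edge
            crosses = (y0 <= yc) != (y1 <= yc)
            x_at = x0 + (yc - y0) * (x1 - x0) / (y1 - y0)
            inside ^= crosses[:, None] & (xc[None, :] < x_at[:, None])
        x0, y0 = x1, y1
    return inside


def polygons_mask(shape: tuple[int, int], polygons) -> np.ndarray:
    """Union of several polygons rasterised independently."""
    mask = np.zeros(shape, dtype=bool)
    for poly in polygons:
        mask |= polygon_mask(shape, poly)
    return mask
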