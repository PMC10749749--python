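"""Tiled FRC over a region of interest and the mtFRC depth profile.

Each optical section's ROI is covered with non-overlapping square tiles on a
grid anchored at the image origin. FRC is evaluated per tile (single-image or
two-image mode) and the mean resolution over the tiles that contain
correlating spatial frequencies — the mean tiled FRC, mtFRC — is reported per
depth. A depth is flagged as reportable when at least a threshold fraction
(default 95%) of its tiles are valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frc import (
    DEFAULT_CUTOFF,
    FRCResult,
    FRCStatus,
    frc_resolution,
    compute_frc_curve,
    nyquist_bound,
    single_image_frc,
)
from .roi import RoiSet, polygons_mask
from .stack import ImagePlane, ZStack


@dataclass(frozen=True)
class TileResult:
    """FRC outcome for one tile."""

    origin: tuple[int, int]  # (x, y) of the tile's top-left corner, pixels
    size: int
    result: FRCResult

    @property
    def valid(self) -> bool:
        """Whether the tile contains correlating spatial frequencies."""
        return self.result.status is not FRCStatus.NO_CORRELATION

    @property
    def resolution(self) -> float | None:
        return self.result.resolution


@dataclass(frozen=True)
class PlaneSummary:
    """Aggregate of the tiles of one optical section."""

    mtfrc: float | None  # mean resolution over valid tiles (µm); None if no valid tile
    n_tiles: int
    n_valid: int

    @property
    def fraction_valid(self) -> float:
        return self.n_valid / self.n_tiles if self.n_tiles else 0.0


@dataclass
class DepthProfile:
    """mtFRC as a function of depth for one stack."""

    depths: list[float] = field(default_factory=list)        # µm
    mtfrc: list[float | None] = field(default_factory=list)  # µm; None when no valid tile
    n_tiles: list[int] = field(default_factory=list)
    n_valid: list[int] = field(default_factory=list)
    reported: list[bool] = field(default_factory=list)

    def append(self, depth: float, summary: PlaneSummary, validity_threshold: float) -> None:
        self.depths.append(depth)
        self.mtfrc.append(summary.mtfrc)
        self.n_tiles.append(summary.n_tiles)
        self.n_valid.append(summary.n_valid)
        self.reported.append(
            summary.n_tiles > 0 and summary.fraction_valid >= validity_threshold
        )

    def fraction_valid(self) -> list[float]:
        return [nv / nt if nt else 0.0 for nv, nt in zip(self.n_valid, self.n_tiles)]

    def __len__(self) -> int:
        return len(self.depths)


def enumerate_tiles(
    plane_shape: tuple[int, int],
    roi_polygons,
    tile_size: int,
    containment_fraction: float = 1.0,
) -> list[tuple[int, int]]:
    """Origins of the grid tiles selected by the ROI.

    Tiles lie on a regular grid anchored at (0, 0) with stride equal to
    ``tile_size`` (non-overlapping); tiles straddling the image border are
    never generated. A tile is selected iff at least ``containment_fraction``
    of its pixel centres lie inside the ROI (1.0 = fully contained, the
    default, per the rule of selecting only tiles contained within the
    feature).

    Returns origins as (x, y) pairs sorted row-major.
    """
    h, w = plane_shape
    if tile_size < 8 or tile_size % 2:
        raise ValueError(f"tile_size must be even and >= 8, got {tile_size}")
    if tile_size > min(h, w):
        raise ValueError(f"tile_size {tile_size} exceeds image {plane_shape}")
    if not 0 < containment_fraction <= 1.0:
        raise ValueError("containment_fraction must be in (0, 1]")
    mask = polygons_mask(plane_shape, roi_polygons)
    need = containment_fraction * tile_size * tile_size
    origins = []
    for y in range(0, h - tile_size + 1, tile_size):
        for x in range(0, w - tile_size + 1, tile_size):
            if mask[y : y + tile_size, x : x + tile_size].sum() >= need:
                origins.append((x, y))
    return origins


def _tile_resolution(result: FRCResult, pixel_size: float) -> float | None:
    """Resolution contributed by one tile to the mean; bounds non-crossing curves.

    A pair-mode tile whose curve never drops below the cut-off correlates out
    to Nyquist, so its resolution is bounded by 2 × pixel_size; that bound is
    used so the mean stays defined. NO_CORRELATION tiles contribute nothing.
    """
    if result.status is FRCStatus.NO_CORRELATION:
        return None
    if result.resolution is not None:
        return result.resolution
    return nyquist_bound(pixel_size)


def mtfrc_plane(
    plane: ImagePlane,
    roi_polygons,
    tile_size: int = 64,
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "single",
    partner_plane: ImagePlane | None = None,
    containment_fraction: float = 1.0,
    **frc_kwargs,
) -> tuple[list[TileResult], PlaneSummary]:
    """Per-tile FRC over one optical section's ROI, plus the plane summary.

    mode="single" runs single-image FRC on each tile crop; mode="pair" runs
    two-image FRC between the tile and the same tile of ``partner_plane``
    (which must be registered and of identical shape). The summary mean is
    taken over valid tiles only, in sorted origin order (bit-reproducible).
    """
    if mode not in ("single", "pair"):
        raise ValueError(f"mode must be 'single' or 'pair', got {mode!r}")
    if mode == "pair":
        if partner_plane is None:
            raise ValueError("pair mode requires a partner plane")
        if partner_plane.shape != plane.shape:
            raise ValueError("partner plane shape mismatch")

    origins = enumerate_tiles(plane.shape, roi_polygons, tile_size, containment_fraction)
    tiles: list[TileResult] = []
    for x, y in origins:
        crop = plane.crop(x, y, tile_size, tile_size)
        if mode == "single":
            res = single_image_frc(crop, cutoff, **frc_kwargs)
        else:
            partner = partner_plane.crop(x, y, tile_size, tile_size)
            curve = compute_frc_curve(crop, partner, **frc_kwargs)
            res = frc_resolution(curve, cutoff)
        tiles.append(TileResult((x, y), tile_size, res))

    values = [
        r for t in tiles if (r := _tile_resolution(t.result, plane.pixel_size)) is not None
    ]
    n_valid = sum(t.valid for t in tiles)
    mean = float(np.mean(values)) if values else None
    return tiles, PlaneSummary(mean, len(tiles), n_valid)


def mtfrc_stack(
    stack: ZStack,
    rois: RoiSet,
    tile_size: int = 64,
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "single",
    partner_stack: ZStack | None = None,
    validity_threshold: float = 0.95,
    containment_fraction: float = 1.0,
    **frc_kwargs,
) -> DepthProfile:
    """mtFRC depth profile: one row per slice that carries an ROI.

    Every slice with ROI polygons produces a row; a row is marked ``reported``
    when its fraction of valid tiles meets ``validity_threshold`` (the rule
    used to decide which depths are drawn in plots — all rows stay in the
    table regardless).
    """
    if rois.is_empty():
        raise ValueError("RoiSet is empty")
    if mode == "pair" and partner_stack is None:
        raise ValueError("pair mode requires a partner stack")
    profile = DepthProfile()
    for z in rois.slices():
        if z >= len(stack):
            raise ValueError(f"ROI slice {z} outside stack of {len(stack)} planes")
        polys = rois.get(z)
        if not polys:
            continue
        partner = partner_stack[z] if mode == "pair" else None
        _, summary = mtfrc_plane(
            stack[z], polys, tile_size, cutoff, mode,
            partner_plane=partner, containment_fraction=containment_fraction,
            **frc_kwargs,
        )
        profile.append(stack.depth_of(z), summary, validity_threshold)
    return profile
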