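"""Rolling-block FRC resolution colourmaps.

Instead of tiling the ROI, a block (default 64×64) centred on every ROI pixel
is evaluated and the resulting resolution is written to that pixel, giving a
per-pixel map of local resolution. The map is typically smoothed with a
disc-shaped median filter (radius 10) and rendered on a fixed physical scale
(0 to 7+ µm by default) so maps from different stacks are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from skimage.morphology import disk

from .frc import DEFAULT_CUTOFF, FRCStatus, single_image_frc, two_image_frc
from .roi import polygons_mask
from .stack import ImagePlane
from .tiling import _tile_resolution


@dataclass
class ResolutionMap:
    """Per-pixel resolution raster aligned to the source plane.

    ``values`` holds resolution in µm; NaN marks pixels outside the ROI or
    where the block showed no correlating frequencies.
    """

    values: np.ndarray
    block_size: int
    pixel_size: float
    scale: tuple[float, float] = (0.0, 7.0)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise ValueError("values must be 2D")
        defined = vals[np.isfinite(vals)]
        if defined.size and (defined <= 0).any():
            raise ValueError("defined resolutions must be positive")
        self.values = vals

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined_mask]


def _clamped_origin(centre: int, block: int, extent: int) -> int:
    """Top-left of a block centred on ``centre``, shifted inward at the edges."""
    return min(max(centre - block // 2, 0), extent - block)


def rolling_frc_map(
    plane: ImagePlane,
    roi_polygons,
    block_size: int = 64,
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "single",
    partner_plane: ImagePlane | None = None,
    stride: int = 1,
    scale: tuple[float, float] = (0.0, 7.0),
    frc_fn=None,
    **frc_kwargs,
) -> ResolutionMap:
    """Evaluate FRC on a block centred on every ROI pixel.

    Blocks near the image edge are clamped inward (the centre pixel is kept,
    the block shifts). With ``stride`` > 1 only every stride-th pixel in each
    axis is evaluated and the gaps are filled by nearest-neighbour assignment,
    trading fidelity for speed; stride 1 evaluates every ROI pixel.

    ``frc_fn``, if given, replaces the per-block FRC evaluation; it receives
    the block ImagePlane (and the partner block in pair mode) and must return
    an FRCResult. Intended for instrumentation and cost accounting.
    """
    h, w = plane.shape
    if block_size > min(h, w):
        raise ValueError(f"block_size {block_size} exceeds image {plane.shape}")
    if mode == "pair" and partner_plane is None:
        raise ValueError("pair mode requires a partner plane")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    mask = polygons_mask(plane.shape, roi_polygons)
    values = np.full((h, w), np.nan)

    def evaluate(x: int, y: int) -> float | None:
        ox = _clamped_origin(x, block_size, w)
        oy = _clamped_origin(y, block_size, h)
        crop = plane.crop(ox, oy, block_size, block_size)
        if frc_fn is not None:
            if mode == "pair":
                res = frc_fn(crop, partner_plane.crop(ox, oy, block_size, block_size))
            else:
                res = frc_fn(crop)
        elif mode == "pair":
            res = two_image_frc(
                crop, partner_plane.crop(ox, oy, block_size, block_size),
                cutoff, **frc_kwargs,
            )
        else:
            res = single_image_frc(crop, cutoff, **frc_kwargs)
        return _tile_resolution(res, plane.pixel_size)

    ys, xs = np.nonzero(mask)
    if stride == 1:
        for y, x in zip(ys, xs):
            r = evaluate(int(x), int(y))
            values[y, x] = np.nan if r is None else r
    else:
        sampled = {}
        for y, x in zip(ys, xs):
            sy, sx = (y // stride) * stride, (x // stride) * stride
            key = (min(sy, h - 1), min(sx, w - 1))
            if key not in sampled:
                sampled[key] = evaluate(int(key[1]), int(key[0]))
            r = sampled[key]
            values[y, x] = np.nan if r is None else r

    return ResolutionMap(values, block_size, plane.pixel_size, scale)


def smooth_map(res_map: ResolutionMap, radius: int = 10) -> ResolutionMap:
    """Median-filter the map over a disc neighbourhood of the given radius.

    The median is taken over defined pixels only; undefined pixels remain
    undefined. Radius 0 is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return ResolutionMap(res_map.values.copy(), res_map.block_size,
                             res_map.pixel_size, res_map.scale)
    foot = disk(radius).astype(bool)
    offsets = np.argwhere(foot) - radius  # (dy, dx) pairs within the disc
    h, w = res_map.values.shape
    padded = np.full((h + 2 * radius, w + 2 * radius), np.nan)
    padded[radius : radius + h, radius : radius + w] = res_map.values
    stack = np.empty((len(offsets), h, w))
    for i, (dy, dx) in enumerate(offsets):
        stack[i] = padded[radius + dy : radius + dy + h, radius + dx : radius + dx + w]
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighbourhoods
            med = np.nanmedian(stack, axis=0)
    med[~res_map.defined_mask] = np.nan
    return ResolutionMap(med, res_map.block_size, res_map.pixel_size, res_map.scale)


def render_map(
    res_map: ResolutionMap,
    path=None,
    scale: tuple[float, float] | None = None,
    palette: str = "viridis",
    background: str = "0.35",
    colorbar: bool = True,
):
    """Render the map with a fixed physical scale and an embedded colour bar.

    Values are clipped to [scale min, scale max]; anything above the maximum
    renders at the top colour (the "max+" convention). Undefined pixels are
    drawn in the background colour. Returns the matplotlib Figure; if ``path``
    is given the figure is also saved there and closed.
    """
    lo, hi = scale if scale is not None else res_map.scale
    if not lo < hi:
        raise ValueError(f"invalid scale ({lo}, {hi})")
    cmap = plt.get_cmap(palette).copy()
    cmap.set_bad(background)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(np.clip(res_map.values, lo, hi), cmap=cmap, vmin=lo, vmax=hi,
                   interpolation="nearest")
    ax.set_axis_off()
    if colorbar:
        cbar = fig.colorbar(im, ax=ax, fraction=0.046)
        cbar.set_label("minimum resolvable distance (µm)")
        ticks = cbar.get_ticks()
        labels = [f"{t:g}+" if np.isclose(t, hi) else f"{t:g}" for t in ticks]
        cbar.set_ticks(ticks)
        cbar.set_ticklabels(labels)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def map_colors(res_map: ResolutionMap, scale=None, palette: str = "viridis") -> np.ndarray:
    """RGBA array (uint8) of the map under the clipping scale; NaN → grey."""
    lo, hi = scale if scale is not None else res_map.scale
    if not lo < hi:
        raise ValueError(f"invalid scale ({lo}, {hi})")
    cmap = plt.get_cmap(palette).copy()
    cmap.set_bad("0.35")
    norm = matplotlib.colors.Normalize(vmin=lo, vmax=hi, clip=True)
    masked = np.ma.masked_invalid(res_map.values)
    return (cmap(norm(masked)) * 255).astype(np.uint8)
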