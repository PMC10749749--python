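"""Reading stacks and ROIs; writing tables, plots, and colourmap images.

Stacks are single-channel multi-page TIFFs (8/16-bit integer or 32-bit
float); intensities are promoted to float64 on load. ROIs come either from
ImageJ .roi/.zip files or from a plain-text polygon format with one line per
slice::

    z_index: x1,y1 x2,y2 x3,y3 ...

Lines starting with '#' and blank lines are ignored. An untagged single .roi
applies to every slice of the stack.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile

from . import imagej_roi
from .colormap import ResolutionMap, render_map
from .roi import RoiSet
from .stack import ImagePlane, ZStack
from .tiling import DepthProfile

_ALLOWED_DTYPES = ("u", "i", "f")


def read_stack(path, pixel_size: float, z_step: float, depth_origin: float = 0.0) -> ZStack:
    """Load a single-channel multi-page TIFF as a ZStack.

    Pages appear in file order as slices 0, 1, 2, ... Multi-channel or RGB
    data is rejected; acquisition metadata (pixel size, z step) is supplied
    by the caller, not parsed from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        if not tf.pages:
            raise ValueError(f"{path}: TIFF has zero pages")
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(
                f"{path}: unsupported sample format "
                f"({page.samplesperpixel} samples per pixel; expected grayscale)"
            )
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: unsupported sample format (expected single-channel pages, "
            f"got array of shape {arr.shape})"
        )
    if arr.dtype.kind not in _ALLOWED_DTYPES:
        raise ValueError(f"{path}: unsupported sample format (dtype {arr.dtype})")
    planes = [ImagePlane(arr[z], pixel_size, z) for z in range(arr.shape[0])]
    return ZStack(planes, z_step, depth_origin)


def write_stack(stack: ZStack, path, dtype=np.float32) -> None:
    """Write a ZStack as a multi-page grayscale TIFF."""
    data = stack.as_array().astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")


def _parse_roi_text(text: str) -> list[tuple[np.ndarray, int]]:
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            z_part, coords = line.split(":", 1)
            z = int(z_part)
            pts = [tuple(float(v) for v in pair.split(",")) for pair in coords.split()]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: cannot parse ROI line {line!r}") from exc
        if len(pts) < 3:
            raise ValueError(f"line {lineno}: polygon needs >= 3 vertices, got {len(pts)}")
        out.append((np.asarray(pts, dtype=float), z))
    if not out:
        raise ValueError("ROI text file contains no polygons")
    return out


def read_rois(path, stack: ZStack) -> RoiSet:
    """Read per-slice ROI polygons from .roi, .zip, or the text format.

    A single untagged .roi (no slice position) is broadcast to every slice of
    the stack. Slice indices outside the stack are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".roi":
        entries = [imagej_roi.read_roi_file(path)]
    elif suffix == ".zip":
        entries = imagej_roi.read_roi_zip(path)
    else:
        entries = _parse_roi_text(path.read_text())

    rois = RoiSet()
    for verts, z in entries:
        if z is None:
            for zi in range(len(stack)):
                rois.add(zi, verts)
        else:
            if not 0 <= z < len(stack):
                raise ValueError(
                    f"{path}: ROI slice {z} outside stack of {len(stack)} planes"
                )
            rois.add(z, verts)
    return rois


def write_rois_text(rois: RoiSet, path) -> None:
    """Write an RoiSet in the one-line-per-polygon text format."""
    lines = []
    for z in rois.slices():
        for poly in rois.get(z):
            pts = " ".join(f"{x:g},{y:g}" for x, y in poly)
            lines.append(f"{z}: {pts}")
    Path(path).write_text("\n".join(lines) + "\n")


def profile_frame(profile: DepthProfile) -> pd.DataFrame:
    """DepthProfile as a tidy DataFrame (one row per depth)."""
    return pd.DataFrame(
        {
            "depth_um": profile.depths,
            "mtfrc_um": [np.nan if v is None else v for v in profile.mtfrc],
            "n_tiles": profile.n_tiles,
            "n_valid": profile.n_valid,
            "fraction_valid": profile.fraction_valid(),
            "reported": profile.reported,
        }
    )


def write_profile_csv(profile: DepthProfile, path) -> None:
    """Write the full depth profile (all rows, reported or not) as CSV."""
    if len(profile) == 0:
        raise ValueError("cannot write an empty depth profile")
    profile_frame(profile).to_csv(path, index=False)


def write_profile_plot(profile: DepthProfile, path, title: str | None = None) -> None:
    """Plot mtFRC vs depth, drawing only the depths that pass the validity rule."""
    if len(profile) == 0:
        raise ValueError("cannot plot an empty depth profile")
    frame = profile_frame(profile)
    shown = frame[frame.reported & frame.mtfrc_um.notna()]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(shown.depth_um, shown.mtfrc_um, "o-", color="tab:blue")
    ax.set_xlabel("depth (µm)")
    ax.set_ylabel("mtFRC (µm)")
    if title:
        ax.set_title(title)
    ax.grid(alpha=0.3)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def write_colormap_png(res_map: ResolutionMap, path, scale=None, palette="viridis") -> None:
    """Render a resolution map to PNG with its colour bar and physical scale."""
    render_map(res_map, path, scale=scale, palette=palette)
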