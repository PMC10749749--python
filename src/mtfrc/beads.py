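"""Bead-based resolution validation.

Sub-diffraction fluorescent beads sample the point-spread function directly:
the full width at half maximum (FWHM) of a Gaussian fit through each bead is
the classical resolution measure, against which FRC estimates can be
validated. The pipeline extracts a substack around every bead, finds the
centre as the maximum-intensity pixel (MIP) of the median-filtered substack,
fits 1D Gaussians to the horizontal and vertical profiles through it
(FWHM = 2·sqrt(2·ln 2)·σ), runs single-image FRC on a tile centred on the
MIP, and tracks normalized peak intensity against depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit
from scipy.stats import linregress
from skimage.feature import peak_local_max

from .frc import DEFAULT_CUTOFF, FRCResult, FRCStatus, single_image_frc
from .stack import ImagePlane, ZStack

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM / sigma for a Gaussian

# radius-1 disc (4-connected cross), the footprint of the rank filter used
# for centre finding
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class BeadRecord:
    """Per-bead measurements; all physical quantities in µm."""

    x: int
    y: int
    z: int
    depth: float
    sigma_x: float | None
    sigma_y: float | None
    fwhm_x: float | None
    fwhm_y: float | None
    fwhm: float | None
    frc_resolution: float | None
    frc_status: FRCStatus
    peak_raw: float
    peak_norm: float = np.nan
    fit_ok: bool = True

    def __post_init__(self) -> None:
        if self.fit_ok:
            for f, s in ((self.fwhm_x, self.sigma_x), (self.fwhm_y, self.sigma_y)):
                if abs(f - FWHM_FACTOR * s) > 1e-9 * max(abs(f), 1.0):
                    raise ValueError("FWHM and sigma are inconsistent")
            expected = 0.5 * (self.fwhm_x + self.fwhm_y)
            if abs(self.fwhm - expected) > 1e-9 * max(abs(expected), 1.0):
                raise ValueError("fwhm must be the mean of fwhm_x and fwhm_y")


def _median_filtered(volume: np.ndarray) -> np.ndarray:
    """Radius-1 disc median filter applied per plane (2D, not 3D)."""
    return np.stack([median_filter(p, footprint=_CROSS, mode="nearest") for p in volume])


def extract_bead_substacks(
    stack: ZStack,
    min_separation: int | None = None,
    box_size: int = 64,
    threshold: float = 0.2,
) -> list[tuple[ZStack, tuple[int, int, int]]]:
    """Find candidate beads and cut a box around each.

    Candidates are lateral local maxima of the maximum-intensity z-projection
    above ``threshold`` × the global maximum, separated by at least
    ``min_separation`` pixels (default: the box size); of two candidates
    closer than that, the brighter survives. Each substack is a box_size-wide
    lateral crop over the full z extent (clamped to the image bounds), so a
    bead near an edge still yields a full-size box.

    Returns (substack, (x0, y0, z_peak)) pairs where (x0, y0) is the crop
    origin in the parent plane and z_peak the slice of the projection maximum.
    """
    if min_separation is None:
        min_separation = box_size
    volume = stack.as_array()
    vmax = volume.max()
    if vmax <= 0:
        return []
    projection = volume.max(axis=0)
    peaks = peak_local_max(
        projection,
        min_distance=min_separation,
        threshold_abs=threshold * vmax,
        exclude_border=False,
    )
    h, w = stack.shape
    out = []
    for y, x in peaks:
        x0 = min(max(x - box_size // 2, 0), max(w - box_size, 0))
        y0 = min(max(y - box_size // 2, 0), max(h - box_size, 0))
        z_peak = int(np.argmax(volume[:, y, x]))
        sub = ZStack(
            [
                ImagePlane(
                    volume[z, y0 : y0 + min(box_size, h), x0 : x0 + min(box_size, w)],
                    stack.pixel_size,
                    z,
                )
                for z in range(len(stack))
            ],
            stack.z_step,
            stack.depth_origin,
        )
        out.append((sub, (int(x0), int(y0), z_peak)))
    return out


def locate_centre(substack: ZStack) -> tuple[int, int, int]:
    """Centre of a bead: argmax of the per-plane median-filtered substack.

    The radius-1 median filter suppresses single-pixel hot noise before the
    argmax. Ties resolve to the lexicographically smallest (z, y, x).
    """
    filtered = _median_filtered(substack.as_array())
    z, y, x = np.unravel_index(int(np.argmax(filtered)), filtered.shape)
    return int(x), int(y), int(z)


def _gaussian(u, a, mu, sigma, c):
    return a * np.exp(-((u - mu) ** 2) / (2.0 * sigma**2)) + c


def fit_profile_sigma(profile: np.ndarray, centre: int) -> float | None:
    """Fit a·exp(−(u−µ)²/(2σ²)) + c to a 1D profile; return σ in px, or None
    when the fit fails or degenerates (flat input, non-positive width)."""
    u = np.arange(profile.size, dtype=np.float64)
    lo, hi = profile.min(), profile.max()
    if hi - lo <= 0:
        return None
    p0 = [hi - lo, float(centre), max(profile.size / 10.0, 1.0), lo]
    try:
        popt, _ = curve_fit(
            _gaussian, u, profile, p0=p0,
            bounds=([0.0, -1.0, 1e-3, -np.inf], [np.inf, profile.size, profile.size, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return None
    sigma = float(popt[2])
    if not np.isfinite(sigma) or sigma <= 0:
        return None
    return sigma


def fit_fwhm(
    substack: ZStack, centre: tuple[int, int, int]
) -> tuple[float, float, float, float, float] | None:
    """FWHM from Gaussian fits to the row and column through the bead centre.

    Profiles are taken from the median-filtered plane of the centre's slice.
    Returns (fwhm_x, fwhm_y, fwhm, sigma_x, sigma_y) in µm — the final FWHM
    is the mean of the two axes — or None if either fit fails.
    """
    x, y, z = centre
    plane = median_filter(substack[z].pixels, footprint=_CROSS, mode="nearest")
    row = plane[y, :]
    col = plane[:, x]
    if row.size < 7 or col.size < 7:
        raise ValueError("profile lines need at least 7 samples")
    sx = fit_profile_sigma(row, x)
    sy = fit_profile_sigma(col, y)
    if sx is None or sy is None:
        return None
    ps = substack.pixel_size
    fwhm_x = FWHM_FACTOR * sx * ps
    fwhm_y = FWHM_FACTOR * sy * ps
    return fwhm_x, fwhm_y, 0.5 * (fwhm_x + fwhm_y), sx * ps, sy * ps


def bead_frc(
    substack: ZStack,
    centre: tuple[int, int, int],
    tile: int = 64,
    cutoff: float = DEFAULT_CUTOFF,
) -> FRCResult:
    """Single-image FRC on a tile centred on the bead, raw (unfiltered) pixels.

    The tile is clamped inward near edges so it stays full size; a 64 px tile
    means 32×32 sub-images after decimation.
    """
    x, y, z = centre
    plane = substack[z]
    h, w = plane.shape
    t = min(tile, h, w)
    x0 = min(max(x - t // 2, 0), w - t)
    y0 = min(max(y - t // 2, 0), h - t)
    return single_image_frc(plane.crop(x0, y0, t, t), cutoff)


def analyse_beads(
    stack: ZStack,
    box_size: int = 64,
    tile: int = 64,
    threshold: float = 0.2,
    min_separation: int | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[BeadRecord]:
    """Full bead pipeline: extract, centre, fit, FRC, normalize peaks."""
    records: list[BeadRecord] = []
    for sub, (x0, y0, _) in extract_bead_substacks(
        stack, min_separation=min_separation, box_size=box_size, threshold=threshold
    ):
        cx, cy, cz = locate_centre(sub)
        filtered_plane = median_filter(sub[cz].pixels, footprint=_CROSS, mode="nearest")
        peak_raw = float(filtered_plane[cy, cx])
        depth = stack.depth_of(cz)
        fit = fit_fwhm(sub, (cx, cy, cz))
        frc_res = bead_frc(sub, (cx, cy, cz), tile=tile, cutoff=cutoff)
        if fit is None:
            records.append(BeadRecord(
                x0 + cx, y0 + cy, cz, depth, None, None, None, None, None,
                frc_res.resolution, frc_res.status, peak_raw, fit_ok=False,
            ))
        else:
            fwhm_x, fwhm_y, fwhm, sigma_x, sigma_y = fit
            records.append(BeadRecord(
                x0 + cx, y0 + cy, cz, depth, sigma_x, sigma_y,
                fwhm_x, fwhm_y, fwhm, frc_res.resolution, frc_res.status,
                peak_raw,
            ))
    if records:
        top = max(r.peak_raw for r in records)
        for r in records:
            r.peak_norm = r.peak_raw / top if top > 0 else np.nan
    return records


def records_table(records: list[BeadRecord]) -> pd.DataFrame:
    """Per-bead table (one row per bead, physical units)."""
    return pd.DataFrame(
        {
            "x": [r.x for r in records],
            "y": [r.y for r in records],
            "z": [r.z for r in records],
            "depth_um": [r.depth for r in records],
            "fwhm_x_um": [r.fwhm_x for r in records],
            "fwhm_y_um": [r.fwhm_y for r in records],
            "fwhm_um": [r.fwhm for r in records],
            "frc_um": [r.frc_resolution for r in records],
            "peak_raw": [r.peak_raw for r in records],
            "peak_norm": [r.peak_norm for r in records],
            "fit_ok": [r.fit_ok for r in records],
        }
    )


def _linfit(x: np.ndarray, y: np.ndarray) -> dict:
    res = linregress(x, y)
    return {"slope": res.slope, "intercept": res.intercept, "r": res.rvalue,
            "stderr": res.stderr}


def bead_summary(records: list[BeadRecord]) -> dict:
    """Summary statistics and regressions over a bead population.

    Returns a dict with the per-bead table, linear fits of FWHM vs depth,
    FRC vs depth and FRC vs FWHM, an exponential decay fit
    I(z) = A·exp(−z/ℓ) to normalized peak intensity vs depth, and paired
    percentage-difference statistics (FRC − FWHM)/FWHM × 100 per bead.
    """
    table = records_table(records)
    ok = table[table.fit_ok & table.frc_um.notna()]
    if len(ok) < 2:
        raise ValueError("need at least 2 beads with successful fits")
    out: dict = {"table": table, "n_beads": len(table), "n_used": len(ok)}
    depth = ok.depth_um.to_numpy(float)
    fwhm = ok.fwhm_um.to_numpy(float)
    frc = ok.frc_um.to_numpy(float)
    out["fwhm_vs_depth"] = _linfit(depth, fwhm)
    out["frc_vs_depth"] = _linfit(depth, frc)
    out["frc_vs_fwhm"] = _linfit(fwhm, frc)

    pct = (frc - fwhm) / fwhm * 100.0
    out["pct_difference_mean"] = float(pct.mean())
    out["pct_difference_sd"] = float(pct.std(ddof=1)) if len(pct) > 1 else 0.0

    peaks = table[table.peak_norm.notna()]
    d = peaks.depth_um.to_numpy(float)
    i = peaks.peak_norm.to_numpy(float)
    try:
        popt, _ = curve_fit(
            lambda z, a, ell: a * np.exp(-z / ell), d, i,
            p0=[1.0, max(d.max(), 1.0)],
            bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=5000,
        )
        out["intensity_decay"] = {"amplitude": float(popt[0]), "length_um": float(popt[1])}
    except (RuntimeError, ValueError):
        out["intensity_decay"] = None
    return out
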