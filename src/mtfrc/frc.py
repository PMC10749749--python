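"""Fourier ring correlation (FRC) and resolution estimation.

FRC measures, ring by ring in frequency space, the Pearson-type correlation
between the Fourier transforms of two independent images of the same scene:

    FRC(r) = Re( sum_{k in ring r} F1(k) · F2(k)* )
             / sqrt( sum |F1(k)|^2 · sum |F2(k)|^2 )

The minimum resolvable distance is the inverse of the first spatial frequency
at which the curve drops below a fixed cut-off (1/7 by convention). A
"single image" variant splits one image into four decimated sub-images and
correlates the two diagonal pairs, at the cost of doubling the effective
pixel size.

Ring binning uses unit-width integer rings by rounded Euclidean radius in
index units; the DC term is excluded and rings beyond the Nyquist index
floor(N/2) are discarded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal.windows import tukey

from .stack import ImagePlane

#: the conventional fixed FRC threshold
DEFAULT_CUTOFF = 1.0 / 7.0


class FRCStatus(enum.Enum):
    OK = "ok"                         # curve crosses the cut-off at some ring
    NO_CROSSING = "no_crossing"       # never drops below the cut-off before Nyquist
    NO_CORRELATION = "no_correlation"  # below the cut-off from the first ring


@dataclass(frozen=True)
class FRCCurve:
    """Per-ring correlation curve for one image pair.

    ring_radii are integer ring indices 1..floor(N/2); the physical spatial
    frequency of ring r is r / (N · pixel_size) cycles/µm.
    """

    ring_radii: np.ndarray
    correlations: np.ndarray
    n_pixels_per_ring: np.ndarray
    image_side: int
    pixel_size: float

    def frequencies(self) -> np.ndarray:
        """Spatial frequency of each ring in cycles/µm."""
        return self.ring_radii / (self.image_side * self.pixel_size)

    def __len__(self) -> int:
        return len(self.ring_radii)


@dataclass(frozen=True)
class FRCResult:
    """Resolution estimate derived from an FRC curve.

    resolution is in µm when status is OK (or when a Nyquist bound was
    substituted for a non-crossing curve, in which case ``bounded`` is True);
    it is None for NO_CORRELATION and for plain NO_CROSSING results.
    """

    status: FRCStatus
    resolution: float | None
    crossing_frequency: float | None  # cycles/µm
    curve: FRCCurve | None
    bounded: bool = False
    pair_results: tuple["FRCResult", "FRCResult"] | None = None


@lru_cache(maxsize=64)
def _ring_bins(n: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Flattened ring label per Fourier sample, sample counts, Nyquist index.

    Samples outside 1..floor(n/2) (the DC term and corner frequencies beyond
    Nyquist) are labelled 0 and ignored.
    """
    k = np.fft.fftfreq(n) * n
    radius = np.hypot(k[:, None], k[None, :])
    labels = np.rint(radius).astype(np.intp)
    r_max = n // 2
    labels[(labels < 1) | (labels > r_max)] = 0
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=r_max + 1)
    return flat, counts, r_max


def _prepare_tile(img: ImagePlane, subtract_mean: bool, window: bool) -> np.ndarray:
    """Mean-subtract, optionally apodise, and zero-pad to the enclosing square."""
    px = img.pixels
    if subtract_mean:
        px = px - px.mean()
    if window:
        wy = tukey(px.shape[0], alpha=0.25)
        wx = tukey(px.shape[1], alpha=0.25)
        px = px * wy[:, None] * wx[None, :]
    h, w = px.shape
    n = max(h, w)
    if h != w:
        padded = np.zeros((n, n), dtype=np.float64)
        padded[:h, :w] = px
        px = padded
    return px


def compute_frc_curve(
    img1: ImagePlane,
    img2: ImagePlane,
    *,
    subtract_mean: bool = True,
    window: bool = False,
) -> FRCCurve:
    """Fourier ring correlation curve between two registered images.

    The images must share shape and pixel size. Non-square inputs are
    mean-subtracted then zero-padded to the enclosing square. Rings with zero
    energy in either image get correlation 0.

    Parameters
    ----------
    subtract_mean : bool
        Remove each image's mean before transforming (default). Prevents DC
        leakage into the first ring; the DC term itself is always excluded.
    window : bool
        Apply a Tukey (α = 0.25) apodisation window before transforming.
        Off by default.
    """
    if img1.shape != img2.shape:
        raise ValueError(f"image shapes differ: {img1.shape} vs {img2.shape}")
    if img1.pixel_size != img2.pixel_size:
        raise ValueError("pixel sizes differ")
    a = _prepare_tile(img1, subtract_mean, window)
    b = _prepare_tile(img2, subtract_mean, window)
    n = a.shape[0]
    if n < 2:
        raise ValueError("image too small for FRC")

    f1 = np.fft.fft2(a)
    f2 = np.fft.fft2(b)
    labels, counts, r_max = _ring_bins(n)

    num = np.bincount(labels, weights=(f1 * np.conj(f2)).real.ravel(), minlength=r_max + 1)
    p1 = np.bincount(labels, weights=(f1.real**2 + f1.imag**2).ravel(), minlength=r_max + 1)
    p2 = np.bincount(labels, weights=(f2.real**2 + f2.imag**2).ravel(), minlength=r_max + 1)

    denom = np.sqrt(p1[1:] * p2[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num[1:] / denom, 0.0)
    radii = np.arange(1, r_max + 1)
    keep = counts[1:] > 0
    return FRCCurve(
        ring_radii=radii[keep],
        correlations=corr[keep],
        n_pixels_per_ring=counts[1:][keep],
        image_side=n,
        pixel_size=img1.pixel_size,
    )


def frc_resolution(curve: FRCCurve, cutoff: float = DEFAULT_CUTOFF) -> FRCResult:
    """Threshold an FRC curve at the cut-off and convert to a physical resolution.

    Rings are scanned in increasing radius; the first ring whose correlation
    falls strictly below ``cutoff`` sets the crossing frequency
    r / (N · pixel_size) and the resolution is its inverse. A curve that never
    crosses yields NO_CROSSING; one already below the cut-off at the first
    ring yields NO_CORRELATION (the tile contains no correlating spatial
    frequencies).
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    if len(curve) == 0:
        raise ValueError("empty FRC curve")
    below = curve.correlations < cutoff
    if not below.any():
        return FRCResult(FRCStatus.NO_CROSSING, None, None, curve)
    first = int(np.argmax(below))
    if first == 0:
        return FRCResult(FRCStatus.NO_CORRELATION, None, None, curve)
    r = curve.ring_radii[first]
    freq = r / (curve.image_side * curve.pixel_size)
    return FRCResult(FRCStatus.OK, 1.0 / freq, freq, curve)


def two_image_frc(
    img1: ImagePlane,
    img2: ImagePlane,
    cutoff: float = DEFAULT_CUTOFF,
    **kwargs,
) -> FRCResult:
    """Convenience wrapper: curve plus threshold in one call."""
    return frc_resolution(compute_frc_curve(img1, img2, **kwargs), cutoff)


def split_single_image(img: ImagePlane) -> tuple[ImagePlane, ImagePlane, ImagePlane, ImagePlane]:
    """Split an image into four sub-images by two-fold decimation.

    Sub-image (a, b) takes pixels at rows 2i+a, columns 2j+b; each sub-image's
    pixel size is doubled. Odd trailing rows/columns are trimmed. The four
    sub-images together contain every (untrimmed) pixel exactly once.

    Returns sub-images in order (0,0), (0,1), (1,0), (1,1).
    """
    h, w = img.shape
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2×2 to split")
    h -= h % 2
    w -= w % 2
    px = img.pixels[:h, :w]
    ps = img.pixel_size * 2
    return tuple(
        ImagePlane(px[a::2, b::2], ps, img.z_index) for a in (0, 1) for b in (0, 1)
    )


def nyquist_bound(pixel_size: float) -> float:
    """Best resolution representable at a given pixel size: 2 × pixel_size (µm)."""
    return 2.0 * pixel_size


def single_image_frc(
    img: ImagePlane,
    cutoff: float = DEFAULT_CUTOFF,
    *,
    average_curves: bool = False,
    **kwargs,
) -> FRCResult:
    """FRC resolution from a single image via four-way sub-image splitting.

    The image is decimated into four sub-images (pixel size doubled) and FRC
    is computed for the two diagonal pairs, (0,0)/(1,1) and (1,0)/(0,1). The
    final resolution is the arithmetic mean of the two pair resolutions. If
    either pair shows no correlation at all the result is NO_CORRELATION; if a
    pair never crosses the cut-off its sub-image Nyquist bound is used and the
    result is flagged ``bounded``.

    With ``average_curves=True`` the two pair curves are averaged ring-wise
    and thresholded once instead.
    """
    if img.height < 4 or img.width < 4:
        raise ValueError("image must be at least 4×4 for single-image FRC")
    s00, s01, s10, s11 = split_single_image(img)

    if average_curves:
        c1 = compute_frc_curve(s00, s11, **kwargs)
        c2 = compute_frc_curve(s10, s01, **kwargs)
        mean_curve = FRCCurve(
            ring_radii=c1.ring_radii,
            correlations=(c1.correlations + c2.correlations) / 2.0,
            n_pixels_per_ring=c1.n_pixels_per_ring,
            image_side=c1.image_side,
            pixel_size=c1.pixel_size,
        )
        return frc_resolution(mean_curve, cutoff)

    r1 = two_image_frc(s00, s11, cutoff, **kwargs)
    r2 = two_image_frc(s10, s01, cutoff, **kwargs)
    pair = (r1, r2)
    if FRCStatus.NO_CORRELATION in (r1.status, r2.status):
        return FRCResult(FRCStatus.NO_CORRELATION, None, None, None, pair_results=pair)

    bounded = False
    resolutions = []
    for r in pair:
        if r.status is FRCStatus.NO_CROSSING:
            resolutions.append(nyquist_bound(s00.pixel_size))
            bounded = True
        else:
            resolutions.append(r.resolution)
    mean_res = float(np.mean(resolutions))
    if bounded and r1.status is FRCStatus.NO_CROSSING and r2.status is FRCStatus.NO_CROSSING:
        return FRCResult(FRCStatus.NO_CROSSING, mean_res, None, None, bounded=True,
                         pair_results=pair)
    freq = 1.0 / mean_res
    return FRCResult(FRCStatus.OK, mean_res, freq, None, bounded=bounded, pair_results=pair)


def abbe_resolution(wavelength_nm: float, numerical_aperture: float) -> float:
    """Abbe diffraction limit d = λ / (2·NA), in the units of ``wavelength_nm``."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    if not 0 < numerical_aperture <= 1.7:
        raise ValueError("numerical aperture must be in (0, 1.7]")
    return wavelength_nm / (2.0 * numerical_aperture)


def nyquist_pixel_size(d: float) -> float:
    """Pixel size satisfying Shannon–Nyquist sampling for resolution ``d``: d/2."""
    if d <= 0:
        raise ValueError("resolution must be positive")
    return d / 2.0
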