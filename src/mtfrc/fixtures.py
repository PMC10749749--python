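"""Synthetic microscopy data with known ground truth.

Generates everything the test-suite and worked examples need in place of
acquired stacks: image pairs sharing a ground-truth scene with independent
noise, depth stacks whose blur grows and intensity decays with z, and bead
stacks of Gaussian-approximated sub-diffraction spots with a recorded layout.

All generators are fully determined by their seed (bit-reproducible). Bead
spots use a Gaussian approximation of the Airy point-spread function: a bead
of intrinsic Gaussian width σ_bead imaged through a PSF of width σ_psf
appears with width sqrt(σ_psf² + σ_bead²), which keeps full-width-at-half-
maximum recovery tests exact. Poisson noise is applied after depth-dependent
intensity scaling, so signal-to-noise falls with simulated depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stack import ImagePlane, ZStack

_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class SceneSpec:
    """Recipe for a synthetic ground-truth scene.

    Parameters
    ----------
    size : int
        Side of the square scene in pixels.
    seed : int
        Seed for all randomness; identical specs produce identical output.
    texture : str
        'white_noise' (flat spectrum), 'filtered_noise' (1/f-weighted noise,
        a crude stand-in for tissue texture) or 'sparse_spots' (scattered
        bright points on a dark background).
    blur_sigma : float
        Gaussian blur applied to the scene, px. Emulates the PSF plus
        scattering; larger values mean worse resolution.
    band_limit : float or None
        Hard isotropic low-pass of the scene at this spatial frequency
        (cycles/px, <= 0.5). None disables it.
    noise_sd : float
        Standard deviation of additive Gaussian read noise (intensity units).
    poisson_scale : float or None
        If set, shot noise is simulated by drawing Poisson counts at
        ``intensity × poisson_scale`` and rescaling back. None disables it.
    pixel_size : float
        Physical pixel size, µm.
    """

    size: int = 256
    seed: int = 0
    texture: str = "filtered_noise"
    blur_sigma: float = 0.0
    band_limit: float | None = None
    noise_sd: float = 0.1
    poisson_scale: float | None = None
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        if self.size < 4:
            raise ValueError("size must be >= 4")
        if self.texture not in ("white_noise", "filtered_noise", "sparse_spots"):
            raise ValueError(f"unknown texture {self.texture!r}")
        if self.band_limit is not None and not 0 < self.band_limit <= 0.5:
            raise ValueError("band_limit must be in (0, 0.5] cycles/px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def band_limit_image(img: np.ndarray, limit: float) -> np.ndarray:
    """Zero all spatial frequencies above ``limit`` cycles/px (hard low-pass)."""
    n0, n1 = img.shape
    fy = np.fft.fftfreq(n0)
    fx = np.fft.fftfreq(n1)
    radius = np.hypot(fy[:, None], fx[None, :])
    spectrum = np.fft.fft2(img)
    spectrum[radius > limit] = 0.0
    return np.fft.ifft2(spectrum).real


def make_scene(spec: SceneSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Ground-truth scene: texture, then optional band-limit, then blur."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.size
    if spec.texture == "white_noise":
        scene = rng.standard_normal((n, n))
    elif spec.texture == "filtered_noise":
        white = rng.standard_normal((n, n))
        fy = np.fft.fftfreq(n)
        radius = np.hypot(fy[:, None], fy[None, :])
        weight = 1.0 / np.maximum(radius, 1.0 / n)  # ~1/f amplitude spectrum
        scene = np.fft.ifft2(np.fft.fft2(white) * weight).real
        scene /= scene.std()
    else:  # sparse_spots
        scene = np.zeros((n, n))
        n_spots = max(4, n * n // 256)
        ys = rng.integers(0, n, n_spots)
        xs = rng.integers(0, n, n_spots)
        scene[ys, xs] = rng.uniform(0.5, 1.0, n_spots) * 10.0
    if spec.band_limit is not None:
        scene = band_limit_image(scene, spec.band_limit)
    if spec.blur_sigma > 0:
        scene = gaussian_filter(scene, spec.blur_sigma, mode="wrap")
    return scene


def _add_noise(scene: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    img = scene
    if spec.poisson_scale is not None:
        shifted = img - img.min()  # Poisson rates must be non-negative
        img = rng.poisson(shifted * spec.poisson_scale) / spec.poisson_scale + img.min()
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return img


def make_pair(spec: SceneSpec) -> tuple[ImagePlane, ImagePlane]:
    """Two images sharing one ground-truth scene with independent noise.

    Emulates the two independent acquisitions that conventional FRC needs:
    the pair shares signal, not noise. With all noise off the two images are
    identical.
    """
    rng = np.random.default_rng(spec.seed)
    scene = make_scene(spec, rng)
    img1 = _add_noise(scene, spec, rng)
    img2 = _add_noise(scene, spec, rng)
    return (
        ImagePlane(img1, spec.pixel_size, 0),
        ImagePlane(img2, spec.pixel_size, 0),
    )


def make_single(spec: SceneSpec) -> ImagePlane:
    """One noisy realisation of the scene (for single-image FRC)."""
    rng = np.random.default_rng(spec.seed)
    scene = make_scene(spec, rng)
    return ImagePlane(_add_noise(scene, spec, rng), spec.pixel_size, 0)


def make_heterogeneous_plane(
    spec: SceneSpec, sigma_left: float, sigma_right: float
) -> ImagePlane:
    """Plane whose left and right halves are blurred with different sigmas.

    Mirrors the within-plane resolution heterogeneity seen in thick tissue,
    where path length through scattering material varies across the field.
    """
    rng = np.random.default_rng(spec.seed)
    base = SceneSpec(**{**spec.__dict__, "blur_sigma": 0.0})
    scene = make_scene(base, rng)
    n = spec.size
    out = np.empty_like(scene)
    out[:, : n // 2] = gaussian_filter(scene, sigma_left, mode="wrap")[:, : n // 2]
    out[:, n // 2 :] = gaussian_filter(scene, sigma_right, mode="wrap")[:, n // 2 :]
    return ImagePlane(_add_noise(out, spec, rng), spec.pixel_size, 0)


def make_depth_stack(
    spec: SceneSpec,
    n_slices: int,
    sigma_of_z: Callable[[int], float] | list[float],
    z_step: float = 10.0,
    intensity_decay_length: float | None = None,
    partner: bool = False,
) -> ZStack | tuple[ZStack, ZStack]:
    """Z-stack whose blur grows and intensity decays with depth.

    One shared ground-truth scene is blurred with ``sigma_of_z(z)`` px per
    slice and scaled by exp(−depth/decay_length); noise is drawn after
    scaling so deeper slices are also noisier relative to signal — the
    qualitative signature of imaging into scattering tissue. With
    ``partner=True`` a second stack sharing the scenes but with independent
    noise is returned (for two-image FRC).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    sig = sigma_of_z if callable(sigma_of_z) else (lambda z: sigma_of_z[z])
    rng = np.random.default_rng(spec.seed)
    base = make_scene(SceneSpec(**{**spec.__dict__, "blur_sigma": 0.0}), rng)
    planes, partner_planes = [], []
    for z in range(n_slices):
        s = float(sig(z))
        scene = gaussian_filter(base, s, mode="wrap") if s > 0 else base
        if intensity_decay_length is not None:
            scene = scene * math.exp(-(z * z_step) / intensity_decay_length)
        planes.append(ImagePlane(_add_noise(scene, spec, rng), spec.pixel_size, z))
        if partner:
            partner_planes.append(
                ImagePlane(_add_noise(scene, spec, rng), spec.pixel_size, z)
            )
    stack = ZStack(planes, z_step)
    if partner:
        return stack, ZStack(partner_planes, z_step)
    return stack


def make_bead_stack(
    n_beads: int,
    bead_diameter_nm: float = 210.0,
    psf_sigma_um: float = 0.15,
    *,
    shape: tuple[int, int] = (256, 256),
    n_slices: int = 12,
    pixel_size: float = 0.0931,
    z_step: float = 0.5,
    z_sigma_um: float = 0.6,
    peak_intensity: float = 1000.0,
    intensity_decay_length: float | None = None,
    poisson_noise: bool = True,
    background: float = 10.0,
    min_separation: int = 64,
    seed: int = 0,
) -> tuple[ZStack, pd.DataFrame]:
    """Simulated bead field plus its ground-truth table.

    Beads are Gaussian spots of lateral width sqrt(σ_psf² + σ_bead²) — the
    analytic width of a Gaussian bead imaged through a Gaussian PSF — placed
    at integer pixel positions on a grid jittered under a minimum-separation
    constraint, each centred on a (possibly different) z plane with Gaussian
    axial extent. Peak amplitude decays as exp(−depth/decay_length) when a
    decay length is given. Poisson shot noise on top of a constant background.

    Returns the stack and a table with columns x, y, z, depth_um, sigma_px,
    sigma_um, fwhm_um, amplitude.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    sigma_bead_um = (bead_diameter_nm / 1000.0) / _FWHM_FACTOR  # FWHM ≈ diameter
    sigma_um = math.hypot(psf_sigma_um, sigma_bead_um)
    sigma_px = sigma_um / pixel_size

    # grid pitch leaves room for jitter so pairwise separation stays > min_separation
    jitter = min_separation // 8
    pitch = min_separation + 2 * jitter + 2
    margin = pitch // 2
    nx = max(1, (w - 2 * margin) // pitch + 1)
    ny = max(1, (h - 2 * margin) // pitch + 1)
    if n_beads > nx * ny:
        raise ValueError(
            f"cannot place {n_beads} beads with separation {min_separation} in {shape}"
        )
    cells = [(margin + i * pitch, margin + j * pitch) for j in range(ny) for i in range(nx)]
    chosen = rng.choice(len(cells), size=n_beads, replace=False)
    records = []
    for idx in sorted(chosen):
        cx, cy = cells[idx]
        x = int(np.clip(cx + rng.integers(-jitter, jitter + 1), 8, w - 9))
        y = int(np.clip(cy + rng.integers(-jitter, jitter + 1), 8, h - 9))
        z = int(rng.integers(0, n_slices))
        depth = z * z_step
        amp = peak_intensity
        if intensity_decay_length is not None:
            amp *= math.exp(-depth / intensity_decay_length)
        records.append((x, y, z, depth, amp))

    z_sigma_planes = z_sigma_um / z_step
    volume = np.full((n_slices, h, w), background, dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    for x, y, z, _, amp in records:
        lateral = np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma_px**2)))
        for zi in range(n_slices):
            axial = math.exp(-((zi - z) ** 2) / (2.0 * z_sigma_planes**2))
            if axial > 1e-4:
                volume[zi] += amp * axial * lateral
    if poisson_noise:
        volume = rng.poisson(volume).astype(np.float64)

    planes = [ImagePlane(volume[z], pixel_size, z) for z in range(n_slices)]
    truth = pd.DataFrame(
        records, columns=["x", "y", "z", "depth_um", "amplitude"]
    )
    truth["sigma_px"] = sigma_px
    truth["sigma_um"] = sigma_um
    truth["fwhm_um"] = _FWHM_FACTOR * sigma_um
    return ZStack(planes, z_step), truth
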