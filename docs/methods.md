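# Methods

## Fourier ring correlation

For two registered images of the same scene with independent noise, the FRC
at integer ring index *r* is the normalised real part of the cross-power
summed over all Fourier samples whose Euclidean distance from DC rounds to
*r*. Rings are unit-width; the DC term is excluded; rings beyond the Nyquist
index ⌊N/2⌋ are discarded (corner frequencies above Nyquist exist only along
the diagonals and are not isotropic). The physical frequency of ring *r* is
r/(N·pixel_size) cycles/µm.

Numerical choices:

- **Mean subtraction.** Each tile is mean-subtracted before the transform so
  the excluded DC term cannot leak into ring 1 through the tile's offset.
  For exact integer binning this leaves all retained rings unchanged; it is
  on by default and exposed as a flag.
- **No apodisation by default.** A Tukey window (α = 0.25) is available
  behind `window=True` for edge-artefact suppression but is off by default;
  windowing changes the effective support and is not part of the standard
  procedure this package implements.
- **Zero-variance rings.** If either image has zero energy on a ring, that
  ring's correlation is defined as 0.
- **Non-square tiles** are mean-subtracted and zero-padded to the enclosing
  square.

### Threshold and resolution

The resolution is 1/f of the first ring *strictly below* the fixed 1/7
cut-off, scanned in increasing radius, with no interpolation between rings
and no curve smoothing. Two sentinel outcomes matter downstream:

- `NO_CORRELATION`: already below the cut-off at ring 1 — the patch contains
  no correlating spatial frequencies. Such tiles are excluded from means and
  counted against the validity fraction.
- `NO_CROSSING`: never drops below the cut-off before Nyquist. The curve is
  censored from below; where a mean must stay defined the Nyquist bound
  2·pixel_size is substituted and the result flagged `bounded`, rather than
  silently dropping the tile.

Ring quantisation limits precision: on an N-px tile the resolution can only
take the values N·pixel_size/r, so small tiles trade localisation for a
coarser (and noisier) resolution scale. This is the reason 64 px is the
default tile size.

### Single-image FRC

The image is decimated into four sub-images taking pixels (2i+a, 2j+b),
a,b ∈ {0,1}; each sub-image has double the pixel size. FRC is computed for
the two diagonal pairs (0,0)/(1,1) and (1,0)/(0,1) — diagonal pairs have the
same geometric half-pixel offset along both axes — and the final resolution
is the arithmetic mean of the two pair resolutions. Averaging the two pair
*curves* before thresholding is available behind `average_curves=True`; the
default averages resolutions because the two pair estimates are the natural
unit of replication. If either pair shows no correlation the tile is
`NO_CORRELATION`; a non-crossing pair contributes its sub-image Nyquist
bound and flags the result `bounded`.

The null distribution of a ring correlation between independent images is
centred on 0 with standard deviation ≈ 1/√n_ring (each ring holds n_ring/2
independent complex samples; their Hermitian conjugates double the counted
samples without adding information). Ring 1 of a 32×32 sub-image has ~8
samples, so even pure noise clears the 1/7 cut-off at ring 1 in a
predictable minority of pairs — single tiles of noise are *usually*, not
always, classified `NO_CORRELATION`, which is why validity is assessed as a
fraction over many tiles.

## Tiling and the depth profile

Tiles lie on a grid anchored at the image origin with stride equal to the
tile size; border-straddling tiles are never generated. A tile is selected
when at least `containment_fraction` (default 1.0 — full containment) of its
pixel centres fall inside the ROI; thin features can relax this to 0.5.
Pixel membership uses the even-odd rule on pixel centres (x+0.5, y+0.5) with
a half-open crossing test, so shared polygon edges assign each pixel exactly
once. Tiles are evaluated and averaged in sorted-origin order, making the
mean bit-reproducible.

Per depth, the mtFRC is the mean resolution over valid tiles only; the depth
coordinate is geometric stage depth, depth_origin + z·z_step, with no
refractive-index correction. Every slice with an ROI produces a table row;
a row is `reported` (drawn in plots) only when its valid-tile fraction meets
the validity threshold (default 0.95). Multi-specimen aggregation is out of
scope: profiles are per stack, and cohort overlays should filter
pre-computed profiles externally.

## Rolling-block colourmaps

A block (default 64 px) centred on each ROI pixel is evaluated and its
resolution written to that pixel. Blocks near the border are clamped inward
— the centre pixel keeps its value but the block shifts — rather than
zero-padded, because padding would inject artificial sharp edges that bias
FRC towards optimistic values. `NO_CORRELATION` pixels are undefined (NaN).
Smoothing is a median over a *disc* neighbourhood (radius 10 by default,
matching the "radius" semantics of the standard rank filters), computed over
defined pixels only, applied to physical values before rendering. Rendering
clips to a fixed physical scale (0–7 µm by default; values above the top
render at the top colour, the "7+" convention) on a perceptually uniform
palette with undefined pixels in neutral grey. A `stride` option evaluates
every k-th pixel and fills neighbours by nearest assignment for tractability;
the default stride of 1 evaluates every ROI pixel.

## Bead workflow

Candidate beads are local maxima of the maximum-intensity z-projection above
a threshold fraction (default 0.2) of the global maximum, with a minimum
lateral separation (default: the box size); the brighter of two close
candidates survives. Each bead gets a box-size lateral crop over the full z
range, clamped inside the image. The centre is the maximum-intensity pixel
of the per-plane median-filtered (radius-1 cross footprint) substack, ties
broken lexicographically in (z, y, x).

FWHM comes from least-squares fits of a·exp(−(u−µ)²/(2σ²))+c to the row and
column through the centre of the *median-filtered* centre plane —
filtering stabilises the fit — converted per axis by FWHM = 2√(2 ln 2)·σ and
averaged; the FWHM/σ relation is enforced as an invariant on every record.
Per-bead FRC runs on the *raw* pixels of a tile (default 64 px → 32 px
sub-images) centred on the same point, because filtering would bias the
correlation. Fit failures (flat profiles, non-convergence, σ ≤ 0) are
flagged and excluded from summaries. The summary reports linear fits (FWHM
vs depth, FRC vs depth, FRC vs FWHM), the paired percentage difference
(FRC−FWHM)/FWHM·100 per bead, and an exponential decay regression
I(z) = A·exp(−z/ℓ) of normalized peak intensity.

## Synthetic data

The generators stand in for acquired stacks and define the conditions under
which the tests and the acceptance script run:

- **Scenes**: white noise, 1/f-weighted noise (a crude tissue-texture proxy),
  or sparse bright spots; optional hard isotropic band-limit (which fixes the
  ground-truth resolution exactly: a limit of 0.2 cycles/px means 5 px);
  Gaussian blur; Gaussian read noise and optional Poisson shot noise. Image
  pairs share the scene, never the noise. Everything is bit-reproducible
  from the seed.
- **Depth stacks**: one shared scene per stack, blurred per slice with
  σ(z) and attenuated by exp(−depth/ℓ) before noise, so SNR falls with depth
  as it does in scattering tissue. The depth-degradation condition used
  throughout the tests is σ(z) = 1 + 0.5 z px with ℓ = 50 µm over 10 slices
  at 10 µm steps and read-noise sd 0.15 — a regime of strong but realistic
  attenuation under which resolution roughly triples across the stack.
- **Bead stacks**: Gaussian-approximated spots of lateral width
  √(σ_psf² + σ_bead²) — the analytic width of a Gaussian bead under a
  Gaussian PSF, which makes FWHM-recovery tests exact — placed at integer
  positions on a jittered grid that guarantees the advertised minimum
  separation, with Gaussian axial extent, optional depth decay, Poisson
  noise on a constant background, and a returned ground-truth table.

What the generators do **not** emulate: anisotropic or depth-varying PSF
shape, spherical aberration, refractive-index mismatch, sample motion,
detector artefacts, photobleaching, or structured biological texture.
Passing tests therefore demonstrate correctness of the estimator pipeline on
controlled ground truth, not robustness to every artefact of real
acquisitions — on real data the usual cautions about high-frequency
artefacts inflating FRC apply.

## Problem sizes

The test-suite and acceptance runs use 128–256 px planes, 10-slice stacks,
and bead fields of 50–100 beads on 720–900 px frames; rolling-map checks run
stride 1 on a 128×128-px ROI within a 256-px plane. These sizes give
estimator noise small enough for the stated tolerances (e.g. band-limit
recovery within 10 %, FWHM recovery within 5 %) while keeping runs fast.

## Known limitations

- Resolution is quantised to the ring grid; no sub-ring interpolation.
- Single-image FRC assumes noise independence between decimated sub-images;
  detector noise correlated across neighbouring pixels breaks this and
  biases results optimistic.
- The 1/7 cut-off is the conventional fixed threshold; σ-factor or
  bit-based criteria are not implemented.
- ROI parsing covers polygon, rectangle, oval, and freehand ImageJ ROIs;
  traced/composite ROIs are rejected.
- Axial (Z) FWHM and 2D elliptical Gaussian bead fits are out of scope.
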