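# mtfrc

Depth-resolved lateral resolution measurement for 3D fluorescence microscopy,
based on the **mean tiled Fourier ring correlation (mtFRC)**.

In thick specimens — a fly brain, an organoid, beads in agarose — image
quality is not uniform: scattering and attenuation degrade resolution with
depth, and often differently in different parts of the same optical section.
A single whole-image resolution number is then meaningless. This package
quantifies resolution *inside a user-drawn feature of arbitrary shape*, slice
by slice, producing resolution-versus-depth curves, per-pixel resolution
colourmaps, and a bead-based validation workflow. It is aimed at microscopists
comparing sample preparations, imaging modalities (e.g. confocal vs
two-photon), or instrument settings such as laser power.

## Method

Fourier ring correlation (FRC) measures, for each spatial frequency ring *r*
in Fourier space, the correlation between two independent images of the same
scene:

```
            Re Σ_{k∈r} F₁(k) · F₂*(k)
FRC(r) = ─────────────────────────────────
         √( Σ_{k∈r} |F₁(k)|² · Σ_{k∈r} |F₂(k)|² )
```

Signal correlates across the two images; noise does not. The minimum
resolvable distance is the inverse of the first frequency at which the curve
drops below the conventional fixed cut-off of **1/7**. A *single-image*
variant decimates one image into four sub-images (pixel size doubled) and
correlates the two diagonal pairs, removing the need for a registered second
acquisition.

Because FRC needs a square patch, arbitrary feature shapes are handled by
**tiling**: each slice's region of interest (ROI) is covered with small
(default 64 × 64 px) tiles, FRC is run per tile, and the mean over tiles with
correlating content is the mtFRC for that depth. A depth is only plotted when
at least 95 % of its tiles contain correlating spatial frequencies. For
fine-grained maps, a **rolling-block** mode evaluates a 64 × 64 block centred
on every ROI pixel (at ~4000× the cost of tiling for a megapixel ROI) and
renders the result on a fixed 0–7+ µm scale after disc median filtering
(radius 10).

The **bead workflow** validates FRC against the classical measure: for
sub-diffraction beads the full width at half maximum, FWHM = 2√(2 ln 2) σ,
of Gaussian fits through each bead centre is compared with per-bead
single-image FRC, and peak-intensity decay with depth is fit with
I(z) = A·exp(−z/ℓ).

## Worked example

Generate a synthetic Z-stack whose blur and attenuation grow with depth, then
profile it:

```sh
mtfrc fixtures --recipe depth_stack --seed 7 --size 256 --out fx
mtfrc profile --stack fx/stack.tif --rois fx/rois.txt \
      --pixel-size 0.1 --z-step 10 --tile-size 64 --out out
cat out/profile.csv
```

```
depth_um,mtfrc_um,n_tiles,n_valid,fraction_valid,reported
0.0,0.4085714285714286,16,16,1.0,True
10.0,0.41157509157509153,16,16,1.0,True
20.0,0.48286380286380287,16,16,1.0,True
30.0,0.5491200466200465,16,16,1.0,True
40.0,0.6547288822288824,16,16,1.0,True
50.0,0.7712251637251637,16,16,1.0,True
60.0,0.8862265512265511,16,16,1.0,True
70.0,1.0038888888888888,16,16,1.0,True
80.0,1.1615079365079364,16,16,1.0,True
90.0,1.401904761904762,16,16,1.0,True
```

Each row is one optical section: its depth, the mean tiled FRC resolution in
µm (larger = worse), how many 64-px tiles the ROI contained, how many of them
held correlating frequencies, and whether the slice passes the 95 % validity
rule used for plotting (`out/profile.png` draws only reported rows). Here
resolution degrades smoothly from 0.41 µm at the surface to 1.40 µm at 90 µm
depth, tracking the simulated blur and signal loss.

Other entry points: `mtfrc colormap` renders a rolling-block resolution map of
one slice; `mtfrc beads` runs the bead pipeline and regression summaries. The
same functionality is available as a library (`mtfrc.mtfrc_stack`,
`mtfrc.rolling_frc_map`, `mtfrc.analyse_beads`, ...). ROIs can be ImageJ
`.roi`/`.zip` files or a plain-text format (`z: x1,y1 x2,y2 ...`).

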