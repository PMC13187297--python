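# Methods

This document describes the physics and algorithms implemented in
`clxm`, in pipeline order. All defaults reproduce the study conditions:
Cu-Kα radiation (λ = 1.5406 Å), propagation distance R = 5 mm, pixel /
voxel size 0.271 µm (0.275 µm for the drift study), 200 projections
over 180°, incident intensity I₀ = 10⁴ counts.

## 1. Synthetic phantom (`clxm.phantom`)

The specimen is a paraffin-embedded kidney-biopsy block digitized on a
(z, y, x) voxel grid, default 192 × 128 × 128 at 0.271 µm:

- a paraffin cylinder (radius 0.47 × FOV) inset axially so clean air
  rows exist above and below the block in every projection — these are
  the reference for the transmission statistic;
- a tissue core (radius 0.28 × FOV) with flat caps;
- one glomerulus, painted to exact voxel counts from a target volume
  and the published volume ratios: GM/GB = 0.574, PL/GB = 0.267,
  BS/GB = 0.159, HDR/GM = 0.293. Region painting is *count-exact*:
  the voxel count equals `round(volume / voxel³)` by construction, so
  volumetry oracles are exact, not approximate;
- three mesangial lesions grown voxel-by-voxel inside the HDR
  compartment to exact target volumes (defaults 4.7, 7.9, 4.8 µm³);
- cell nuclei (default 30, diameter 2–3 µm) confined to the central
  60 % of the tissue column, leaving nucleus-free tissue bands for the
  CNR windows;
- one dense contrast marker in the paraffin annulus, the fiducial for
  drift tracking.

Attenuation is assigned per label as a multiple of the paraffin
coefficient (tissue 1.15, PL 1.25, BS 1.05, GM 1.35, HDR and lesions
1.50, nuclei 1.60, marker 8.0). Infeasible geometries (glomerulus too
large for the tissue core, no annulus left for the marker, block
exceeding the field of view under rotation) raise `ParameterError`.

`extract_section` renders a pseudo light-microscopy section: an oblique
slab at a rigid pose, with the contained nuclei recorded as paired
(2-D section pixel, 3-D voxel) landmarks.

## 2. Beam simulation (`clxm.beam`)

Parallel-beam projection integrates the attenuation grid along rays
(rotation + sum) and applies Beer–Lambert: `I = I₀ exp(−∫µ dl)`.
Material leaving the field of view under rotation raises
`GeometryError`.

Free-space propagation uses the angular-spectrum Fresnel propagator at
distance R on the complex field implied by the intensity and the
homogeneous-object phase (δ/β coupling), producing the edge fringes
that phase retrieval later inverts. Propagation after detector noise
has been applied is a physics ordering violation and raises
`StageOrderError`.

Stage drift is a smooth random walk (smoothed Gaussian increments)
rescaled to an exact peak-to-peak width in µm per axis; frames are
shifted by Fourier phase ramps (sub-pixel exact). Detector effects are
fixed per-column gain stripes (flat-field removable) and Poisson
counting noise, all seeded.

## 3. Projection preprocessing (`clxm.preprocess`)

In the published processing order:

1. **Flat-field correction** — `(raw − dark) / (flat − dark)`.
2. **Ring reduction** — iterated smoothed-column-mean equalization: for
   each detector row, the across-angle mean column profile is smoothed
   (boxcar, 11 px); the zero-mean deviation is subtracted from every
   frame; four fixed-point iterations make the corrected profile
   invariant under the smoother. The correction is mass-preserving per
   row and exactly zero for data with no column structure.
3. **Brightness normalization** — each frame is scaled so the 256-bin
   histogram peak of an air region is constant across angles.
4. **Marker tracking and drift compensation** — the marker is found per
   frame by a band-pass difference-of-Gaussians (σ = 1 and 5 px) within
   a search window, refined by center-of-mass over the darkest 20 % of
   pixels; a lost marker raises `TrackingError` with the frame index.
   The horizontal track is fit to `A sin(θ + φ) + c` (the physical
   rotation orbit) and the vertical track to a constant; the residuals
   are the drift estimate, reported as peak-to-peak widths in µm, and
   their negation is applied as the compensation table.
5. **Paganin phase retrieval** — single-distance homogeneous-object
   retrieval: Fourier division by `1 + π λ R (δ/β) |f|²` (δ/β = 100)
   followed by −log. As δ/β → 0 this reduces to the plain line
   integral.
6. **Median filter** — 3 × 3 per frame.

`run_preset_pipeline` applies the chain with the published "disease"
parameters and records every step in the series provenance list.

## 4. Reconstruction (`clxm.recon`)

Slice-by-slice filtered back-projection (`skimage.transform.iradon`,
Hann-apodized ramp by default) of the line integrals divided by the
pixel size, giving attenuation per µm; coverage below 180° raises
`GeometryError`. Volumes are stored as 16-bit opacities with an affine
slope/intercept over the robust (0.01–99.99 percentile) value range, so
`stored × slope + intercept` recovers attenuation to half a
quantization step.

## 5. Image quality (`clxm.quality`)

- **Transmission**: ratio of the 256-bin histogram-peak intensity of
  the tissue shadow to that of the air rows in the raw projections.
- **CNR**: `|mean A − mean B| / √(var A + var B)` over paired 15 × 15
  windows, five repeats, mean ± 95 % CI, with Welch t, F and
  Kolmogorov–Smirnov tests. Windows are placed automatically:
  material masks eroded by a 4-px standoff (first Fresnel fringe
  ≈ √(λR) ≈ 0.88 µm), and slices within `axial_exclusion_margin` of a
  specimen cap are excluded. That margin is *derived, not tuned*: the
  raw (uncompensated) reconstruction smears each flat cap over the full
  peak-to-peak drift excursion plus about three Fresnel fringe orders —
  `ceil(drift_pp/px) + ceil(3√(λR)/px)` = 24 slices at the defaults.
- **SBE** (size of blurring at edges): a Gaussian-CDF step is fit to a
  line opacity profile across the paraffin–tissue boundary; the 10–90 %
  width of the fitted step (2.5631 σ) is reported in µm.

## 6. Segmentation and volumetry (`clxm.segment`)

GB/GM/PL/BS masks are ingested (manual segmentation in the study; truth
masks in simulation). High-density mesangial regions (HDR) are
extracted by a relative threshold at fraction f of the GM opacity
range — `min + f (max − min)`, f = 0.469 published — followed by one
binary opening and closing. A threshold search scans f and scores each
candidate by largest-connected-component fraction minus a volume
penalty, returning the full table for manual override. Lesions are
connected components seeded at user-marked points, clipped by per-seed
bounding masks (the stand-in for manual delineation). Volumes are
voxel counts × voxel³ exactly; ratios follow the published table
nesting (GM/PL/BS vs GB, HDR vs GM, lesions vs HDR). `group_z_project`
reduces 15-slice groups (4 µm at 0.271 µm) to match section thickness.

## 7. Registration (`clxm.register`)

Nuclei are detected in the volume by scale-space Laplacian-of-Gaussian
blob detection over the 2–3 µm diameter band with center-of-mass
subpixel refinement; detections outside the tissue core are discarded
(the paraffin edge fringes produce spurious blobs). Matched 3-D/2-D
landmark pairs (section depth = thickness/2) are aligned by weighted
Kabsch (SVD with reflection correction, no scaling); degenerate
configurations raise `GeometryError`. The orientation residual is the
axis-angle magnitude of `R_est R_ref⁻¹`. `resample_slab` renders the
matched virtual section (oblique slab, reduced along its normal, 15
samples for 4 µm).

## 8. Workflow (`clxm.pipeline`, `clxm.cli`)

Stages `simulate → preprocess → reconstruct → qc → segment → volumetry
→ register` run as any contiguous subset; missing upstream artifacts
raise `DependencyError` naming the stage. Every run writes its fully
resolved config as YAML beside the outputs. All randomness derives
from the single master seed via
`SeedSequence([seed, stage_index]) mod 2³¹`; identical config + seed
reproduces every numeric report bit-for-bit. Artifacts are multipage
TIFF with JSON sidecars; reports are plain CSV.
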