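# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic experiments do and do not demonstrate.

## Coordinate and acquisition model

The world frame is right-handed with units of µm: x along stage travel, y
along the illumination beam (camera columns), z decreasing into the tissue.
Pixel indices are 0-based and ranges half-open. The oblique frame mapping is

    x = ox + frame·Δx + row·p·cos θ
    y = oy + col·p
    z = oz − row·p·sin θ

with frame step Δx = stage speed / scan rate, in-plane pixel p = sensor
pitch / effective magnification, and tilt θ (default 45°). Effective
magnification is nominal magnification × tube focal length / reference tube
length; the 180 mm reference follows the Olympus convention because the
objective is specified only by its nominal magnification. The sensor pitch
defaults to 6.5 µm (typical sCMOS). The tilt is a parameter rather than a
hard-coded 45° so the geometry can be exercised at analytic angles (90°
reduces the deskew to a pure restack).

Phantom volumes are indexed (z, y, x) with z the *depth* below the slice
surface; the sign flip relative to the acquisition world frame is confined
to `simulate_acquisition`.

## Synthetic data

Somata/nuclei are additive anisotropic Gaussians truncated at 3σ with
σ = radius/2 — a profile whose DoG response peaks at the centre, which is
the property detection relies on. Dendrites are Gaussian-profile tubes
stamped along polylines. Noise is Poisson shot noise followed by Gaussian
read noise (default σ = 2 counts, sCMOS-like). All randomness flows from a
single integer seed; identical seeds give bit-identical volumes.

The dual-channel presets place somata by random sequential adsorption with
a 14 µm minimum centre separation inside the region box, with class counts
fixed to a stimulated animal's profile: the PVN-like preset has 834 red
somata (r = 6 µm), 430 of them carrying a co-centred green nucleus
(r = 5 µm) plus 25 green-only cells; the MEA-like preset has 1018 red,
569 green, 104 double-positive. Box sizes (380³×140 and 460²×160 µm) keep
the packing fraction below ~10% so rejection sampling terminates and cells
remain individually resolvable. What these phantoms do *not* emulate:
spatial clustering beyond density, intensity heterogeneity within a cell,
vasculature/fiber background, optical scattering and depth-dependent
attenuation. Recovery numbers on them therefore bound algorithmic error,
not biological segmentation difficulty.

Slice cutting splits the volume along z and gives each slice an independent
in-plane displacement field — a sum of up to five random-phase sinusoids
band-limited to 0.2–0.8 cycles per slice extent (section deformation is
dominated by low-order bending/stretch modes) — plus an optional surface
tilt. Resampling uses the exact fixed-point inverse of the recorded forward
field, so the stored parameters are exact ground truth for alignment
metrics. Tissue expansion after clearing is exposed as a scale parameter
and defaults to 1.0 (no expansion).

The cohort generator emits 8 + 8 animals × 14 subcortical regions with
region-specific baseline counts (250–1200 cells, control CV 0.30), a
+3-control-SD mean shift in BMA/MEA/VMH for the stressed group, CV inflated
×1.8 in most regions, and *reduced* CV in VMH (a ceiling effect under
strong activation). The baselines are fixed study conditions, not
seed-dependent.

## Stitching

Deskew resamples each column onto an axis-aligned grid (trilinear) at the
native anisotropic spacing (pixel, pixel, axial step) — downstream counting
is voxel-scale, so we keep the native 3.5 µm axial spacing rather than
isotropize. Pair offsets are integer-voxel: FFT phase correlation proposes
a correction inside the nominal overlap, background-subtracted NCC scores
it, and the nominal stage offset wins ties or incoherent matches
(NCC < 0.1) and overlaps thinner than 16 voxels. Global positions solve a
score-weighted linear least squares with the first column anchored;
disconnected components fall back to stage coordinates with a warning.
Fusion feathers linearly across the full overlap, so every output voxel is
a convex combination of inputs.

## Serial-section alignment

1. **Flatten** — per-(x, y) surface heights are the first/last crossing of
   an Otsu threshold, refined to subvoxel by linear interpolation and
   median-filtered (3×3); planes are least-squares fits over unmasked
   points (masks exclude ventricle-like openings). Resampling maps the
   fitted faces to their mean levels and interpolates linearly between, so
   already-flat slices pass through unchanged.
2. **Correspond** — the dense-flow stage is pluggable; the default is NCC
   block matching (25 px blocks on a 10 px grid, ±10 px search) on
   gradient-magnitude images, with a downsampled coarse pass contributing
   only a robust global (median) prior — per-point coarse matches on face
   images are too unreliable to steer the fine search. Peaks are refined to
   subpixel by parabola fitting; matches inconsistent with their 8-neighbor
   median flow by >2 µm are dropped; the surviving flow is lightly
   Gaussian-smoothed. Faces default to the single plane nearest the cut:
   averaging several planes doubles the apparent content drift between
   opposing faces.
3. **Adjust** — displacements d are jointly regularized over the whole
   stack by minimizing ‖d − d̂‖² + λ_s·Σ_neighbors‖d_i − d_j‖²
   + λ_0·‖d‖², a sparse SPD solve. Neighbor terms are averaged (1/k per
   edge) so λ_s is independent of neighborhood size. Defaults
   λ_s = 0.25, λ_0 = 0.01: large enough to suppress matcher noise and pull
   outliers toward their neighborhood, small enough not to attenuate
   genuine smooth deformation (a ridge penalty shrinks the correction
   itself, so heavier settings directly cap how much mismatch the warp can
   remove).
4. **Warp** — similarity-variant moving least squares, which reproduces
   global similarity transforms exactly and hence morphs minimally. The
   `mls_warp` primitive defaults to the textbook α = 1 weights
   (w = 1/|p − v|^2α); the composed reconstruction uses α = 2 because the
   slowly decaying α = 1 weights average over a spatially varying
   correction field and attenuate it. Slices are warped sequentially, each
   toward the already-warped slice above; interfaces whose median adjusted
   displacement is below 0.25 µm (matcher noise) are left untouched, which
   also makes the zero-deformation pipeline an exact identity.

The headline alignment metric — median cross-interface mismatch of the
known deformation fields before vs after — improves ≥5× on the textured
block phantom at 5 µm deformation amplitude. The floor is matcher noise
(~0.5 µm), set by how similar the two faces' content actually is.

## Tone mapping

Processing happens on log(1 + I). The bilateral base/detail split is exact
by construction (detail := log − base). The range sigma defaults to
0.4 × (p95 − p5) of the gradient-magnitude distribution, making the
edge/texture split adapt to content. Base compression is a global affine
range scaling about the mid-level, applied in `n_steps` steps of factor
`compression_factor` (defaults 3 × 0.6); the stepwise form is exactly
scale-composable (range × f^k). Recombination adds the untouched detail,
exponentiates, and rescales globally — per-volume rather than per-image, so
brightness is comparable across a brain.

## Cell detection

2D-then-link by design: axial sampling (≈3.5 µm nominal) is much coarser
than in-plane, so per-plane detection followed by 3D linking respects the
anisotropy where a 3D blob detector would mix scales. Per plane: 4×
block-mean downsample; DoG with σ1 = cell_size/(4√2)/4, σ2 = 2σ1 (the
paper-style scheme names the DoG but no scales); strict 8-neighbor maxima
above median + 3·MAD of the DoG; per-peak patches of side 3 × cell size
thresholded at (peak + border-ring mean)/2 — a local rule that is exactly
invariant to global gain; seeded watershed only where several peaks share a
component. Linking is greedy across adjacent planes (centroid < 6 µm, IoU
> 0.25; conflicts resolved by max IoU then min distance). Chains whose
axial intensity profile is bimodal (an interior valley below 0.75 of both
flanking maxima) are split — two cells stacked along z but overlapping
in-plane otherwise merge into one elongated record.

Features: volume = Σ area × axial spacing; centroid intensity-weighted;
eccentricity = √(1 − λ_min/λ_max) of the intensity-weighted second-moment
ellipsoid (intensity weighting keeps a ball-like soma's chain from reading
as elongated merely because its detectable extent in z spans ±3σ).
Validation ranges default to volume 100–4000 µm³, eccentricity ≤ 0.95,
intensity above background + 5 robust σ, ≥2 sections. Colocalization is
mutual-nearest-neighbor pairing within one cell radius (6 µm).

## Statistics

Welch's unequal-variance t-test is used for group comparisons (the safer
default when inter-animal variance differs between groups, which the
cohort generator makes explicit). FDR is Benjamini–Hochberg by default
with a Storey fixed-λ option. SDs use ddof = 1 throughout. Degenerate
zero-variance regions fall back to an exact permutation p-value. Counts
are used as-is; per-volume density normalization is available as an option
since region-volume normalization conventions vary.

## Problem sizes

The default test and acceptance workloads are sized for a laptop-class
single core: phantoms ≤ 460 × 460 × 80 voxels, three-slice alignment
blocks of 200 × 200 × 48, 60–220 simulated cohorts per calibration check.
The full suite runs in about a minute; the acceptance script in under half
a minute.

## Known limitations

- Integer-voxel stitching offsets; subvoxel registration is out of scope
  because counting is voxel-scale.
- The alignment correspondence stage assumes the opposing faces share
  trackable texture; content-free interfaces fall back to stage coordinates
  (an empty correspondence set leaves the slice unwarped).
- No optical PSF beyond the Gaussian beam-width blur implicit in phantom
  smoothness; no scattering, aberration or attenuation modelling.
- Atlas registration itself is external: the package only downscales to
  25 µm isotropic and applies a supplied affine to cell coordinates.
- Deformations are in-plane per slice; through-thickness shear within a
  single slice is not modelled.
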