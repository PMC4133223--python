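# Methods

## Model and assumptions

The detector assumes the pupil is, photometrically, the most radially
symmetric dark structure in a periocular patch. Two per-pixel evidence maps
formalize this:

**Radial self-similarity.** A neighborhood is radially self-similar when its
intensities are preserved (up to a linear relationship) under reflections
about mirror lines through its center. The per-orientation score is the
Pearson correlation between the vector of intensities sampled on a polar grid
over a disk of radius r and the vector sampled at the reflected locations.
Both vectors are centered on one shared mean — the average intensity of the
untransformed sample set — and each is normalized by its own sum of squares.
The final map averages the coefficient over M mirror orientations φ_m = kπ/M
and over a set of radii. Averaged this way, the reflection family and the
rotation family (angles 2φ_m) yield the *same* map: on a sample grid closed
under the dihedral group the two coefficient sums differ only by a coset
reindexing, and the denominators coincide because each transform permutes the
sample set. The individual per-orientation coefficients are *not* pairwise
equal — only the averages are — which is why the package tests the averaged
identity (it holds to ~1e-16) and not a per-orientation one.

**Isophote curvature voting.** Isophotes are level curves of intensity; their
curvature κ is the reciprocal of the osculating-circle radius and is computed
from Gaussian image derivatives,

    κ = −(Ly²Lxx − 2LxLyLxy + Lx²Lyy) / (Lx² + Ly²)^(3/2).

Scaling the gradient by 1/κ gives the displacement to the circle's center,

    D = −(Lx, Ly)(Lx² + Ly²) / (Ly²Lxx − 2LxLyLxy + Lx²Lyy),

so boundary pixels of a disk all vote at its center. Both κ and D are
invariant under positive rescaling of intensities. Votes are accumulated by
bilinear splatting and weighted by the curvedness √(Lxx² + 2Lxy² + Lyy²);
unit weights are available (`curvedness_weight=False`), as is restricting
votes to centers darker than their surround (`dark_only`, off by default).
Voting runs on every level of a difference-of-Gaussians pyramid (levels
normalized to zero mean and unit max-abs), and per-level accumulators are
upsampled to base resolution and summed, covering a range of pupil sizes.

**Fusion.** Each map is min–max normalized to [0, 1] (a constant map becomes
zeros, the neutral element of the sum), the maps are summed pointwise over the
margin-trimmed region, smoothed with a Gaussian (reflect borders), and the
argmax — ties broken row-major — is the estimate. Equal weighting is the
default; per-map weights exist for ablation.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_orientations` (M) | 8 | mirror orientations π/8 apart; with `n_angular = 16` the polar grid is closed under all of them |
| `radii` | 2…8 px | spans plausible pupil radii in a ~25 %-of-face-width patch |
| `n_radial` | one ring per pixel of radius | keeps ring spacing ≈ 1 px at every scale |
| `margin` | 10 px | border discarded by the self-similarity map; must cover the largest radius |
| `base_sigma` | 1.6 px | first pyramid blur, standard DoG constant |
| `n_octaves`, `n_intervals` | 3, 2 | six DoG levels on a 64×48 patch (octaves stop early below 16 px) |
| `deriv_sigma` | 1.0 px | scale of the derivative filters applied to each level |
| `gradient_floor`, `numerator_floor` | 1e-4, 1e-6 | mask numerically meaningless curvature/displacement pixels |
| `max_displacement` | half patch diagonal | discards votes that would leave the patch neighborhood |
| `smoothing_sigma` | 3 px | joint-space smoothing; broad coherent hills beat isolated spikes |

## Numerical choices

- **Off-grid sampling is cubic B-spline** (`scipy.ndimage.map_coordinates`,
  order 3, mirror boundaries). Bilinear lookup is anisotropic at the ρ = 1
  sampling ring: on analytic radially symmetric fields it erodes the center
  score by ~2e-3, an order of magnitude more than the fidelity budget of the
  self-similarity tests; cubic sampling brings the deviation to ~3e-8.
- **Derivative kernels are sampled Gaussians with corrected discrete
  moments** (zero sum, unit response to the matching monomial). Raw sampled
  second-derivative kernels respond ~1e-5 to constants, which leaks the local
  mean into the curvature numerator on nearly flat regions.
- **Octave upsampling is grid-aligned**: decimation keeps every 2^o-th pixel,
  so level pixel i sits at base coordinate i·2^o and accumulators are
  upsampled on exactly that grid (a corner-aligned resize would shift all
  coarse-octave votes by half a pixel).
- **Degenerate pixels** (zero-variance sample vectors) score 0, not 1: a flat
  region is no evidence of radial structure, and 0 keeps saturated sclera
  from competing with the pupil. Degenerate normalization (constant map) gives
  all-zeros. An all-zero joint space yields the first map pixel with a
  low-confidence flag, never an exception.
- **Ties** in the peak search are broken by smallest row, then smallest
  column, for bit-reproducible output.
- The anthropometric crop applies the percentages (left 20 %/30 %, right
  60 %/30 %, size 25 %×20 %) to the face box before rounding half-up. The
  24×24 minimum patch size is enforced only when border clipping shrank the
  patch: the canonical 100×100 worked example legitimately yields 25×20, and
  each processing stage checks its own margin precondition anyway.

## Synthetic scenes: what they emulate, what they do not

`synthetic_fixtures` renders the gross photometry of an eye region: bright
sclera (0.75–0.95), mid-gray iris, dark pupil as anti-aliased concentric
disks (4×4 subpixel area sampling, so boundaries have smooth gradients), an
eyelid as a horizontal skin-level cap (sclera − 0.1) occluding up to 40 % of
the iris height from above, an optional specular highlight clipped to the
iris, a linear illumination gradient up to ±0.002 intensity/px, and Gaussian
pixel noise up to σ = 0.05. Scene parameters are drawn by a seeded PCG64
generator; identical parameters and seeds reproduce images bit-for-bit.

Eye centers are drawn at least 16 px from every border of the default 64×48
patch: the anthropometric crop exists precisely to center the eye in the
patch, so truth centers hugging the margin-trimmed map boundary are not
scenes the cropping stage produces.

Not modeled: eyelash/skin texture, glasses and their reflections, motion
blur and defocus, pose-dependent iris ellipticity, and sensor artifacts.
Passing the synthetic benchmark therefore demonstrates the geometric
correctness and noise/occlusion robustness of the pipeline — not performance
on any real face dataset, which additionally stresses the face-detector
stage and the texture nuisances above.

For shell-level end-to-end runs, `render_face_scene` pastes a left and right
patch onto a skin-level canvas sized so that a face box covering the canvas
crops back exactly the rendered patches; ground truth is written in canvas
coordinates. When standalone patches are paired for the worst-eye protocol, a
nominal right-patch offset of 96 px defines the pseudo-face frame (the offset
cancels in the per-eye distances and only sets the interocular scale).

## Benchmark sizes

The localization benchmark uses 200 patches (pupil radius 3–8 px, eyelid
coverage 0–0.4, noise σ 0–0.05, gradients up to 0.002/px) and 40 patches per
level of the noise ladder {0, 0.05, 0.1, 0.2}; the brute-force oracle
comparisons run on 21×21 patches with a reduced configuration (M = 4, radii
{2, 3}, margin 5), where the double-loop oracle is exact and fast.

## Known limitations

- The peak is reported at integer pixel resolution (no sub-pixel refinement);
  on the 2-px benchmark this leaves up to ~0.7 px of quantization error.
- Heavy eyelid occlusion (≥ 0.4 of the iris) genuinely shifts the visible
  structure's symmetry center downward; both evidence maps follow it.
- The self-similarity stage scales with patches × radii × orientations ×
  samples; the vectorized implementation handles ~0.5 s per 64×48 patch on
  one CPU, which is fine for evaluation but not real-time.
- Voting runs on DoG levels directly (the literal reading of a band-pass
  pyramid analysis); voting on Gaussian levels selected by DoG extrema is a
  plausible alternative that was not adopted.
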