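# Methods

## Optical model

The imaging geometry is the standard on-chip in-line layout: a quasi-plane
wave illuminates a thin, semi-transparent object at distance `z2 < 1 mm`
from the sensor. The object is modelled purely by its complex transmittance
`t = 1 + Δt` sampled on the sensor grid; thickness, refraction inside the
object, and multiple scattering are ignored (thin-object approximation).
Illumination is a unit-amplitude, normally incident, fully coherent plane
wave. The physical device derives its partial coherence from a pinhole at
`z1 ≈ 5 cm`; `z1` and the pinhole are carried as geometry metadata but not
modelled — coherence-induced blur is therefore absent from all simulations,
which makes the simulated holograms *sharper* than a real recording at the
same geometry.

Propagation uses the angular spectrum method, which is exact for scalar
fields: multiply the field's DFT by
`exp(j·z·(2π/λ)·√(1 − (λfx)² − (λfy)²))` and invert. Choices that matter:

- **Frequency grid**: cycles per metre on the plain DFT grid, spacing
  `1/(N·pitch)`, DC at the corner.
- **Evanescent band**: hard-zeroed (`(λfx)² + (λfy)² ≥ 1`), no apodization.
  A geometry whose propagating band collapses to the DC bin alone is
  rejected as a configuration error.
- **No padding by default.** Zero-padding changes results, so the plain
  (circular) transform is the default and an explicit power-of-two
  `pad_factor` is available for large-distance wrap-around suppression.
  At the reference optics (z2 = 0.5 mm, 1.12 µm pixels, grids ≥ 256²) the
  diffraction spread is a small fraction of the field of view and the
  unpadded transform is accurate, as the brute-force DFT oracle tests
  confirm.
- **Double-precision complex throughout**: the recovery loop feeds fields
  back through FFTs up to 15 times and float32 round-off is visible at the
  1e-3 convergence tolerance.

## Synthetic data

The simulator is the package's data source; every quantitative claim in the
tests is made against its ground truth.

- **Disc phantoms** emulate the mixed sample the device targets: cells
  (default radius 9 µm, amplitude transmittance 0.7) and polystyrene beads
  (radius 7.5 µm — 15 µm diameter — transmittance 0.3). The transmittance
  split encodes the observation that low-refractive-index cells reconstruct
  brighter than high-index beads; 0.3/0.7 give a comfortable three-level
  histogram. Phase shifts default to zero (pure absorbers); non-zero phase
  is supported but not the tested regime. Centres are rejection-sampled
  with a minimum edge separation (default 5 µm); discs are hard-edged so
  object masks are exact.
- **USAF-1951 phantoms** render three-bar elements (bar length 5× width,
  one-width gaps) for requested groups, with per-element pixel layout
  recorded for contrast probing. Elements whose rounded bar or gap would
  fall below one pixel are skipped and logged; at 1.12 µm pixels this
  first bites in group 8.
- **Recording**: intensity of the propagated field, optionally with Poisson
  shot noise (default 1e4 photons per unit intensity when enabled) or
  additive Gaussian read noise, clipped at zero. The default is noiseless
  so oracles stay exact; quantization to 8/16 bits is opt-in.

What the generator does *not* emulate: partial coherence, sensor Bayer
patterns/PRNU/dark current, LED spectral bandwidth, out-of-focus debris,
and cell-shape irregularity. Passing tests therefore demonstrate algorithmic
correctness under the stated optical model, not end-to-end performance on
real smears.

## Phase recovery

The loop implements the support-constraint scheme for in-line holograms:

1. `U¹ = P[−z2]{√I_norm}` with zero sensor phase; this is also the naive
   reconstruction kept for comparison.
2. Outside the support S: replace with `m·D`, where `D = P[−z2]{√B_norm}`
   and `m = mean|Uⁱ| / mean|D|` over the outside-S region (`m_region`
   switches to whole-field averaging; the outside-S ratio-of-means reading
   is the default because it makes `m` a dimensionless level match).
3. Forward to the sensor, keep the phase, reset the modulus to `√I_norm`,
   backpropagate. Repeat 2–3.

Numerical choices:

- **Normalisation** defaults to division by the background (flattens
  illumination), flooring the divisor at 1e-6 of its peak. Subtractive and
  pass-through modes exist. Without a background frame the raw hologram is
  used and `D` falls back to the backpropagation of a uniform field at the
  hologram's mean level (warned).
- **Support**: Otsu threshold on the modulus of `U¹` (objects darker than
  background), closed with a radius-2 disc, dilated by 2 px so edges are
  covered. The support is frozen after iteration 1 by default — the frozen
  mask is deterministic and testable; periodic re-estimation is available
  (`support_update_every`).
- **Convergence**: relative L2 change of the object-plane modulus,
  tolerance 1e-3, cap 15 iterations. Residuals are recorded per iteration;
  monotonicity is not guaranteed by the algorithm and not asserted — only
  that a converged run ends below its first residual. On reference
  simulations the loop converges in 6–8 iterations.
- **Degenerate input**: an empty scene yields a constant modulus, an empty
  support, and an immediate return of the naive field flagged as converged
  in one iteration.

The loop contains no randomness: identical inputs and config give
bit-identical results.

## Metrics

- **Oblique edge energy** uses the fixed 3×3 kernel
  `[[-1,0,-1],[0,2,0],[0,0,0]]` (two diagonal first differences summed),
  id `oblique-diff-3x3-v1`, applied as a correlation with 'valid' support.
  The kernel is a declared convention: any consistent oblique-difference
  kernel rescales S for reference and test alike, leaving Kblur's ordering
  unchanged, but the id is versioned so reported values are comparable.
- **Kblur** may legitimately exceed 1: noise and reconstruction ringing add
  edge energy, so values above 1 indicate spurious high-frequency content
  rather than super-sharpness. The implementation does not clamp.
- **Q** is computed globally (one number per image pair), with n−1
  normalisation applied identically to variances and covariance so that
  Q(x, x) = 1 holds exactly. Constant-vs-constant input is undefined and
  raises.
- **Resolution**: an element is resolved when, in both orientations, the
  across-bar mean profile (central 60% of the bar length) separates all
  three bar troughs from the gap peaks with Michelson contrast ≥ 0.1. The
  0.1 default is a conventional just-resolvable contrast; the threshold is
  exposed. No-reference (learned) quality scores are out of scope.

## Counting

Deterministic re-implementation of the usual interactive workflow:

1. **Two-threshold classification** into background / cell / particle
   (multi-level Otsu by default). This replaces an interactive, trained
   pixel classifier; the gray-level separation between cell and bead
   reconstructions is what makes intensity alone sufficient here. Passing
   the thresholds in swapped order swaps the class labels — the rule is
   symmetric by construction.
2. **Cleaning**: border-touching components removed (objects with
   incomplete edges cannot be counted reliably), components under
   `min_area_px` (default 30 px ≈ a 3.5 µm-radius disc at 1.12 µm pixels —
   well below any real cell) removed, interior holes filled. Both removal
   counts are reported separately.
3. **Watershed splitting** on the Euclidean distance transform, seeded at
   local maxima with a minimum separation defaulting to the typical object
   radius (estimated from the median component area). Every component
   keeps at least one seed, so isolated convex objects are never split.
4. **Counting**: per-class totals and per-object records; labels are
   assigned in raster order of centroids so output is deterministic.

## Problem sizes and verification

Reference simulations use 512×512 grids at the documented optics (587 nm,
z2 = 0.5 mm, 1.12 µm pixels); counting sweeps use 256×256 grids over 20
placement seeds, sizes at which a full simulate–recover–count cycle takes
a fraction of a second and the whole suite a few seconds. Brute-force
oracles (entrywise transfer-function evaluation, O(N⁴) DFT propagation)
run on grids up to 16×16.

## Known limitations

- Fully coherent plane-wave model: no partial coherence, no magnification
  (unit fringe magnification assumed, valid for z1 >> z2).
- `z2` is a required input — no autofocus search.
- Single wavelength, single height: no multi-height or multi-wavelength
  phase retrieval.
- The intensity-threshold classifier assumes the two object classes
  separate in gray level; overlapping distributions (e.g. debris) would
  need a richer feature set.
- The watershed bound (≤ 5% count error at 20% touching objects) is
  established for convex, near-circular objects; elongated or heavily
  clumped cells will do worse.
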