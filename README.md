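# holochip

Computational core of a lensless on-chip microscope based on in-line
(Gabor) holography. A semi-transparent sample sits a fraction of a
millimetre above a bare CMOS sensor; the sensor records the interference of
the illumination with the light scattered by the sample — the hologram —
and everything else is numerics. This package provides that numerics end to
end: a forward hologram simulator, angular-spectrum reconstruction with
iterative twin-image suppression, reference image-quality metrics,
USAF-1951 resolution scoring, and a watershed-based cell/particle counting
pipeline. It is aimed at people building or evaluating lensless holographic
imagers for point-of-care cell counting.

## The model

A weakly absorbing object is a transmittance `t(x0, y0) = 1 + Δt` with
`|Δt| << 1`. Under plane-wave illumination `A`, the sensor at distance `z2`
records

    I(x, y) = |P[z2]{A·t}|² = |A′|² + A′*·a + A′·a* + |a|²,

where `P[z]` is the angular-spectrum propagator with transfer function

    H(fx, fy) = exp(j·z·(2π/λ)·√(1 − (λfx)² − (λfy)²)),   (λfx)² + (λfy)² < 1,

and zero on the evanescent band. Backpropagating `√I` over `−z2` recovers
the object superimposed with its defocused conjugate — the twin image. The
iterative recovery loop suppresses it with an object-support constraint:
outside the segmented support the field is replaced by `m·D`, the scaled
backpropagation of the sample-free background (`m` matches the mean levels);
at the sensor plane the modulus is reset to `√I` while the recovered phase
is kept. The loop converges in well under 15 iterations on simulated scenes.

Image quality is scored by the blur coefficient `Kblur = S_test / S_ref`
(ratio of oblique-differential edge energies, 1 = equally sharp) and the
quality index

    Q = 4·σxy·x̄·ȳ / ((σx² + σy²)·(x̄² + ȳ²)) ∈ [−1, 1],

which is exactly 1 for identical images. Resolution is read off a USAF-1951
three-bar target: element (g, e) has frequency `2^(g + (e−1)/6)` lp/mm, and
an element is resolved when all three bars separate at a Michelson-contrast
threshold in both orientations.

## Worked example

```python
import numpy as np
from holochip import (OpticalGeometry, RecoveryConfig, make_disc_phantom,
                      record_hologram, record_background, iterate_phase_recovery,
                      count_amplitude_image, quality_index, kblur, usaf_frequency)

geometry = OpticalGeometry(wavelength=587e-9, z2=0.5e-3, pixel_pitch=1.12e-6,
                           grid_rows=512, grid_cols=512)
phantom = make_disc_phantom(geometry, n_cells=20, n_particles=10, seed=42)
hologram = record_hologram(phantom)
background = record_background(geometry)

result = iterate_phase_recovery(hologram, background, geometry, RecoveryConfig())
print(f"converged in {result.iterations_run} iterations "
      f"(last residual {result.residual_history[-1]:.2e})")

truth = np.abs(phantom.transmittance)
rmse_rec = np.sqrt(np.mean((result.object_field.modulus - truth) ** 2))
rmse_naive = np.sqrt(np.mean((result.naive_field.modulus - truth) ** 2))
print(f"RMSE vs ground truth: recovered {rmse_rec:.4f}, naive {rmse_naive:.4f}")

_, report = count_amplitude_image(result.object_field.modulus)
print(f"counted {report.n_cells} cells and {report.n_particles} particles "
      f"(ground truth: 20 cells, 10 particles)")

print(f"Kblur(truth, recovered) = {kblur(truth, result.object_field.modulus):.4f}")
print(f"Q(truth, recovered)     = {quality_index(truth, result.object_field.modulus):.4f}")
print(f"group 6 element 4: {usaf_frequency(6, 4):.1f} lp/mm")
```

prints

```
converged in 7 iterations (last residual 9.67e-04)
RMSE vs ground truth: recovered 0.0039, naive 0.0370
counted 20 cells and 10 particles (ground truth: 20 cells, 10 particles)
Kblur(truth, recovered) = 1.2726
Q(truth, recovered)     = 0.9980
group 6 element 4: 90.5 lp/mm
```

The iterative loop cuts the reconstruction error roughly tenfold relative
to single-pass backpropagation (the twin image dominates the naive RMSE),
the counting pipeline reproduces the simulated ground truth exactly, and
`Q ≈ 1` says the recovered amplitude is a near-perfect match to the
phantom. A `Kblur` slightly above 1 is the documented signature of residual
reconstruction ringing adding edge energy.

The same workflow is scriptable from the shell:

```sh
holochip simulate --out sim/               # phantom + hologram + background
holochip recover sim/hologram.tiff sim/background.tiff --out rec/
holochip count rec/recovered_modulus.tiff --out counts/
holochip assess reference.tiff test.tiff --out metrics.json
holochip demo --out demo/                  # USAF + disc end-to-end run
```

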