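"""Shared fixtures: optical geometries and seeded band-limited fields."""

import numpy as np
import pytest

from holochip import OpticalGeometry


@pytest.fixture
def geometry_16():
    """Tiny grid for brute-force oracles."""
    return OpticalGeometry(
        wavelength=587e-9, z2=0.5e-3, pixel_pitch=1.12e-6, grid_rows=16, grid_cols=16
    )


@pytest.fixture
def geometry_32():
    return OpticalGeometry(
        wavelength=587e-9, z2=0.5e-3, pixel_pitch=1.12e-6, grid_rows=32, grid_cols=32
    )


@pytest.fixture
def geometry_256():
    """Working grid for recovery/counting simulations."""
    return OpticalGeometry(
        wavelength=587e-9, z2=0.5e-3, pixel_pitch=1.12e-6, grid_rows=256, grid_cols=256
    )


@pytest.fixture
def geometry_512():
    """Full study grid (587 nm LED, z2 = 0.5 mm, 1.12 um pixels)."""
    return OpticalGeometry(
        wavelength=587e-9, z2=0.5e-3, pixel_pitch=1.12e-6, grid_rows=512, grid_cols=512
    )


def band_limited_values(geometry, seed, keep_fraction=0.5):
    """Random complex field with zero energy outside the propagating band.

    Spectral support is restricted to ``keep_fraction`` of the evanescent
    cutoff so round trips are exact to floating point.
    """
    rng = np.random.default_rng(seed)
    rows, cols = geometry.shape
    spectrum = rng.normal(size=(rows, cols)) + 1j * rng.normal(size=(rows, cols))
    fy = np.fft.fftfreq(rows, d=geometry.pixel_pitch)[:, None]
    fx = np.fft.fftfreq(cols, d=geometry.pixel_pitch)[None, :]
    lam = geometry.wavelength
    inside = (lam * fx) ** 2 + (lam * fy) ** 2 < keep_fraction
    spectrum = np.where(inside, spectrum, 0.0)
    return np.fft.ifft2(spectrum)
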