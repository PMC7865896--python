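"""Free-space scalar propagation by the angular spectrum method.

The angular spectrum method propagates a monochromatic complex field over a
distance ``z`` by multiplying its 2-D spatial-frequency spectrum with the
transfer function

    H(fx, fy) = exp(j * z * (2*pi/lambda) * sqrt(1 - (lambda*fx)^2 - (lambda*fy)^2))

on the propagating band ``(lambda*fx)^2 + (lambda*fy)^2 < 1`` and zero on the
evanescent band.  It is an exact solution of the scalar Helmholtz equation
(no paraxial approximation), which is why it is the standard choice for the
sub-millimetre sample-to-sensor distances of on-chip holography.

Conventions
-----------
* Frequencies ``fx, fy`` are cycles per metre on the standard DFT grid with
  spacing ``1/(N * pixel_pitch)``; the DC bin sits at the array corner
  (``numpy.fft`` layout) and is shifted only for display.
* Grids are row-major with the origin at the top-left pixel.
* All arithmetic is double-precision complex: the iterative phase-recovery
  loop downstream accumulates round-off, so float32 is not used.
* A positive distance propagates away from the source (object -> sensor);
  a negative distance backpropagates.  On the propagating band the
  negative-distance mask is the complex conjugate of the positive one.
* No zero-padding by default; an optional power-of-two pad factor is exposed
  for large-distance wrap-around suppression and must be requested
  explicitly (padding changes results, so the plain transform is the
  default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "Plane",
    "OpticalGeometry",
    "ComplexField",
    "angular_spectrum_transfer",
    "propagate",
]


class Plane(str, Enum):
    """Which plane a field is sampled on."""

    OBJECT = "object"
    SENSOR = "sensor"

    def flipped(self) -> "Plane":
        return Plane.SENSOR if self is Plane.OBJECT else Plane.OBJECT


@dataclass(frozen=True)
class OpticalGeometry:
    """Optical layout of the in-line holographic microscope.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in metres (e.g. 587e-9 for a yellow LED).
    z2 : float
        Sample-to-sensor distance in metres; must be positive.  Propagation
        over ``-z2`` is requested through :func:`propagate`'s signed
        distance, never by negating this field.
    pixel_pitch : float
        Sensor pixel pitch in metres (e.g. 1.12e-6).
    grid_rows, grid_cols : int
        Sensor grid dimensions; at least 2 each.
    z1 : float
        Source-to-sample distance in metres.  Informational only: the
        illumination is modelled as a unit plane wave, so ``z1`` never
        enters the math.
    """

    wavelength: float
    z2: float
    pixel_pitch: float
    grid_rows: int
    grid_cols: int
    z1: float = 0.05

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        if not (self.pixel_pitch > 0):
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")
        if not (self.z2 > 0):
            raise ValueError(f"z2 must be positive, got {self.z2}")
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError(
                f"grid must be at least 2x2, got {self.grid_rows}x{self.grid_cols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid_rows, self.grid_cols)

    def with_shape(self, rows: int, cols: int) -> "OpticalGeometry":
        return replace(self, grid_rows=rows, grid_cols=cols)

    def frequency_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (fy, fx) broadcastable DFT frequency grids in cycles/m."""
        fy = np.fft.fftfreq(self.grid_rows, d=self.pixel_pitch)[:, None]
        fx = np.fft.fftfreq(self.grid_cols, d=self.pixel_pitch)[None, :]
        return fy, fx


@dataclass
class ComplexField:
    """A 2-D complex amplitude sampled on the sensor/object grid."""

    values: np.ndarray
    geometry: OpticalGeometry
    plane: Plane = Plane.OBJECT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values.view(np.float64))):
            raise ValueError("field contains non-finite entries")

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def energy(self) -> float:
        """Total energy: sum of squared moduli."""
        return float(np.sum(np.abs(self.values) ** 2))


def angular_spectrum_transfer(
    geometry: OpticalGeometry, distance: float
) -> np.ndarray:
    """Angular-spectrum transfer function for a signed propagation distance.

    Entries are ``exp(j * distance * (2*pi/lambda) * sqrt(1 - (lambda*fx)^2
    - (lambda*fy)^2))`` where the radicand is positive, and exactly zero on
    the evanescent band (hard cutoff, no apodization).

    Raises
    ------
    ValueError
        If the geometry is so badly sampled that every non-DC frequency is
        evanescent (a configuration error: the pixel pitch is far below the
        half-wavelength sampling bound).
    """
    if not np.isfinite(distance):
        raise ValueError("distance must be finite")
    lam = geometry.wavelength
    fy, fx = geometry.frequency_grids()
    radicand = 1.0 - (lam * fx) ** 2 - (lam * fy) ** 2
    propagating = radicand > 0.0
    if np.count_nonzero(propagating) <= 1 and propagating.size > 1:
        raise ValueError(
            "degenerate geometry: every non-DC spatial frequency is "
            "evanescent (pixel pitch grossly under half a wavelength of "
            "usable bandwidth)"
        )
    mask = np.zeros(np.broadcast_shapes(fy.shape, fx.shape), dtype=np.complex128)
    k = 2.0 * np.pi / lam
    mask[...] = np.where(
        propagating,
        np.exp(1j * distance * k * np.sqrt(np.where(propagating, radicand, 0.0))),
        0.0,
    )
    return mask


def propagate(
    field: ComplexField, distance: float, pad_factor: int = 1
) -> ComplexField:
    """Propagate a complex field by a signed distance.

    Computes ``ifft2(fft2(field) * H)`` with ``H`` from
    :func:`angular_spectrum_transfer`.  Energy is conserved on the
    propagating band (unit-modulus transfer); evanescent truncation can only
    remove energy, never add it.

    Parameters
    ----------
    field : ComplexField
        Input field; its geometry defines the sampling.
    distance : float
        Signed propagation distance in metres (negative = backpropagation).
    pad_factor : int
        Optional power-of-two zero-padding factor to suppress circular
        wrap-around for large distances.  Default 1 (no padding).

    The output plane tag flips when ``|distance|`` equals the geometry's
    ``z2`` (the sample-to-sensor hop); other distances keep the tag.
    """
    geom = field.geometry
    if field.values.shape != geom.shape:
        raise ValueError("field/geometry shape mismatch")
    if pad_factor < 1 or (pad_factor & (pad_factor - 1)) != 0:
        raise ValueError(f"pad_factor must be a power of two >= 1, got {pad_factor}")

    values = field.values
    if pad_factor > 1:
        rows, cols = geom.shape
        prow = rows * (pad_factor - 1) // 2
        pcol = cols * (pad_factor - 1) // 2
        values = np.pad(values, ((prow, prow), (pcol, pcol)))
        work_geom = geom.with_shape(*values.shape)
    else:
        work_geom = geom

    mask = angular_spectrum_transfer(work_geom, distance)
    out = np.fft.ifft2(np.fft.fft2(values) * mask)

    if pad_factor > 1:
        out = out[prow : prow + geom.grid_rows, pcol : pcol + geom.grid_cols]

    plane = field.plane
    if np.isclose(abs(distance), geom.z2, rtol=1e-12, atol=0.0):
        plane = plane.flipped()
    return ComplexField(out, geom, plane)
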