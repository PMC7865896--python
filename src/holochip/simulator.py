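"""Synthetic phantoms and hologram recording for the on-chip microscope.

A semi-transparent object is modelled by its complex transmittance
``t(x0, y0) = 1 + dt(x0, y0)`` with ``|dt| << 1`` in the weak-object regime.
Illumination is a unit-amplitude, normally incident plane wave (the pinhole
and the source distance z1 are carried as geometry metadata but not
modelled: partial coherence is outside this package's scope).  The sensor
records the intensity of the field propagated over z2,

    I(x, y) = |P[z2]{A * t}|^2 = |A' + a|^2
            = |A'|^2 + A'* a + A' a* + |a|^2,

i.e. a background term, the two interference (image + twin image) terms and
an object self-interference term.

Two phantom families cover the study's samples: discs emulating ~15 um
polystyrene beads and mouse ascites tumour cells (cells are assigned a
higher amplitude transmittance than beads, mirroring the lower refractive
index of cells against the mounting medium), and a USAF-1951 three-bar
resolution target.  Disc edges are hard by default so the ground-truth
masks used by the counting tests are crisp.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path

import numpy as np

from .propagation import ComplexField, OpticalGeometry, Plane, propagate

log = logging.getLogger(__name__)

__all__ = [
    "ObjectClass",
    "DiscObject",
    "UsafElement",
    "Phantom",
    "SensorImage",
    "NoiseModel",
    "PoissonNoise",
    "GaussianNoise",
    "PackingError",
    "make_disc_phantom",
    "phantom_from_discs",
    "make_usaf_phantom",
    "record_hologram",
    "record_background",
    "quantize",
]


class ObjectClass(str, Enum):
    CELL = "cell"
    PARTICLE = "particle"
    BAR = "bar"


@dataclass(frozen=True)
class DiscObject:
    """Ground-truth record of one disc: centre in pixels, radius in metres."""

    center_row: float
    center_col: float
    radius_m: float
    object_class: ObjectClass
    amplitude_transmittance: float
    phase_shift: float = 0.0


@dataclass(frozen=True)
class UsafElement:
    """Ground-truth record of one rendered USAF three-bar element.

    ``bar_spans``/``gap_spans`` are half-open pixel index ranges across the
    bars (columns for vertical bars, rows for horizontal bars);
    ``length_span`` is the range along the bars.  ``bbox`` is
    (row0, row1, col0, col1), half-open.
    """

    group: int
    element: int
    orientation: str  # "vertical" | "horizontal"
    lp_per_mm: float
    bar_width_px: float
    bbox: tuple[int, int, int, int]
    bar_spans: tuple[tuple[int, int], ...]
    gap_spans: tuple[tuple[int, int], ...]
    length_span: tuple[int, int]


@dataclass
class Phantom:
    """Ground-truth transmittance map plus object metadata."""

    transmittance: np.ndarray
    objects: list
    geometry: OpticalGeometry
    seed: int = 0

    def __post_init__(self) -> None:
        self.transmittance = np.asarray(self.transmittance, dtype=np.complex128)
        if self.transmittance.shape != self.geometry.shape:
            raise ValueError("transmittance shape does not match geometry")

    @property
    def max_delta_t(self) -> float:
        """max |t - 1|, the weak-object scale of the phantom."""
        return float(np.max(np.abs(self.transmittance - 1.0)))

    def object_mask(self) -> np.ndarray:
        """Boolean mask of every non-unity region of t."""
        return np.abs(self.transmittance - 1.0) > 1e-12

    def class_mask(self, object_class: ObjectClass) -> np.ndarray:
        mask = np.zeros(self.geometry.shape, dtype=bool)
        rr, cc = np.mgrid[0 : self.geometry.grid_rows, 0 : self.geometry.grid_cols]
        pitch = self.geometry.pixel_pitch
        for obj in self.objects:
            if isinstance(obj, DiscObject) and obj.object_class is object_class:
                r_px = obj.radius_m / pitch
                mask |= (rr - obj.center_row) ** 2 + (
                    cc - obj.center_col
                ) ** 2 <= r_px**2
        return mask

    def to_json(self) -> str:
        pitch_um = self.geometry.pixel_pitch * 1e6
        records = []
        for obj in self.objects:
            d = asdict(obj)
            if isinstance(obj, DiscObject):
                d["object_class"] = obj.object_class.value
                d["radius_um"] = obj.radius_m * 1e6
            records.append(d)
        return json.dumps(
            {
                "seed": self.seed,
                "pixel_pitch_um": pitch_um,
                "max_delta_t": self.max_delta_t,
                "objects": records,
            },
            indent=2,
        )


@dataclass
class SensorImage:
    """A real, non-negative intensity map as recorded by the sensor."""

    intensity: np.ndarray
    geometry: OpticalGeometry
    kind: str = "hologram"  # "hologram" | "background"
    bit_depth: int | str = "float"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.shape != self.geometry.shape:
            raise ValueError("intensity shape does not match geometry")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.kind not in ("hologram", "background"):
            raise ValueError(f"unknown kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Noise models


class NoiseModel:
    def apply(self, intensity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class PoissonNoise(NoiseModel):
    """Shot noise: photon_scale photons per unit intensity."""

    photon_scale: float = 1e4

    def apply(self, intensity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        counts = rng.poisson(np.clip(intensity, 0, None) * self.photon_scale)
        return counts.astype(np.float64) / self.photon_scale


@dataclass(frozen=True)
class GaussianNoise(NoiseModel):
    """Additive read noise with standard deviation sigma (intensity units)."""

    sigma: float = 0.01

    def apply(self, intensity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return intensity + rng.normal(0.0, self.sigma, size=intensity.shape)


class PackingError(RuntimeError):
    """Raised when the requested discs cannot be packed into the field."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could not pack {requested} discs (placed {placed}); "
            "reduce the count, radii or separation"
        )


# ---------------------------------------------------------------------------
# Disc phantoms


def phantom_from_discs(
    geometry: OpticalGeometry, discs: list[DiscObject], seed: int = 0
) -> Phantom:
    """Build a phantom from an explicit list of disc records.

    Discs are hard-edged: a pixel belongs to a disc when its centre falls
    within the disc radius.  Discs may extend past the border (pixels
    outside the grid are simply not rendered), which is how the counting
    tests construct edge-straddling objects.
    """
    t = np.ones(geometry.shape, dtype=np.complex128)
    rows, cols = geometry.shape
    pitch = geometry.pixel_pitch
    for obj in discs:
        r_px = obj.radius_m / pitch
        r0 = max(0, int(math.floor(obj.center_row - r_px)) - 1)
        r1 = min(rows, int(math.ceil(obj.center_row + r_px)) + 2)
        c0 = max(0, int(math.floor(obj.center_col - r_px)) - 1)
        c1 = min(cols, int(math.ceil(obj.center_col + r_px)) + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        inside = (rr - obj.center_row) ** 2 + (cc - obj.center_col) ** 2 <= r_px**2
        value = obj.amplitude_transmittance * np.exp(1j * obj.phase_shift)
        patch = t[r0:r1, c0:c1]
        patch[inside] = value
    return Phantom(t, list(discs), geometry, seed)


def make_disc_phantom(
    geometry: OpticalGeometry,
    n_cells: int,
    n_particles: int,
    cell_radius_m: float = 9e-6,
    particle_radius_m: float = 7.5e-6,
    cell_transmittance: float = 0.7,
    particle_transmittance: float = 0.3,
    cell_phase: float = 0.0,
    particle_phase: float = 0.0,
    min_separation_m: float = 5e-6,
    seed: int = 0,
    margin_px: int = 3,
    max_attempts: int = 20000,
) -> Phantom:
    """Scatter non-overlapping cell and particle discs over the field.

    Cells default to a 9 um radius and amplitude transmittance 0.7;
    polystyrene particles to 7.5 um (15 um diameter) and transmittance 0.3,
    so particles image darker than cells.  Centres are rejection-sampled
    with the given minimum edge-to-edge separation (a negative separation
    permits deliberate overlap, used to construct touching pairs).

    Raises :class:`PackingError` when placement fails after ``max_attempts``
    draws, reporting how many discs were placed.
    """
    rng = np.random.default_rng(seed)
    pitch = geometry.pixel_pitch
    rows, cols = geometry.shape

    specs = [
        (ObjectClass.CELL, cell_radius_m, cell_transmittance, cell_phase)
    ] * n_cells + [
        (
            ObjectClass.PARTICLE,
            particle_radius_m,
            particle_transmittance,
            particle_phase,
        )
    ] * n_particles

    placed: list[DiscObject] = []
    attempts = 0
    for object_class, radius_m, trans, phase in specs:
        r_px = radius_m / pitch
        lo_r, hi_r = r_px + margin_px, rows - 1 - r_px - margin_px
        lo_c, hi_c = r_px + margin_px, cols - 1 - r_px - margin_px
        if lo_r >= hi_r or lo_c >= hi_c:
            raise PackingError(len(placed), len(specs))
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PackingError(len(placed), len(specs))
            cr = rng.uniform(lo_r, hi_r)
            cc = rng.uniform(lo_c, hi_c)
            ok = True
            for other in placed:
                min_d = (radius_m + other.radius_m + min_separation_m) / pitch
                if (cr - other.center_row) ** 2 + (
                    cc - other.center_col
                ) ** 2 < min_d**2:
                    ok = False
                    break
            if ok:
                placed.append(
                    DiscObject(cr, cc, radius_m, object_class, trans, phase)
                )
                break

    return phantom_from_discs(geometry, placed, seed=seed)


# ---------------------------------------------------------------------------
# USAF-1951 bar targets


def usaf_bar_width_m(group: int, element: int) -> float:
    """Bar width in metres for a USAF-1951 (group, element)."""
    lp_per_mm = 2.0 ** (group + (element - 1) / 6.0)
    lp_per_m = lp_per_mm * 1e3
    return 0.5 / lp_per_m


def make_usaf_phantom(
    geometry: OpticalGeometry,
    groups: list[int],
    dark_transmittance: float = 0.1,
    elements: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    padding_px: int = 6,
) -> Phantom:
    """Render a USAF-1951 style three-bar target phantom.

    For each (group, element) the line-pair frequency is
    ``f = 2^(group + (element - 1)/6)`` lp/mm and the bar width is
    ``0.5 / f``.  Each element is drawn twice: three vertical bars and,
    beside them, three horizontal bars, each bar 5x as long as wide with
    one bar-width gaps (the standard three-bar convention).  Elements whose
    bar or gap would fall below one pixel, or that do not fit on the grid,
    are skipped.  Every rendered element's pixel layout is recorded as a
    :class:`UsafElement` for contrast probing.
    """
    t = np.ones(geometry.shape, dtype=np.complex128)
    pitch = geometry.pixel_pitch
    rows, cols = geometry.shape
    records: list[UsafElement] = []
    cursor_row = padding_px

    for group in groups:
        row_height = 0
        cursor_col = padding_px
        for element in elements:
            lp_per_mm = 2.0 ** (group + (element - 1) / 6.0)
            w_px = usaf_bar_width_m(group, element) / pitch
            length_px = int(round(5 * w_px))
            block = int(round(5 * w_px))  # 3 bars + 2 gaps across
            if w_px < 1.0:
                log.warning(
                    "USAF group %d element %d unrenderable at this pitch "
                    "(bar width %.2f px); skipped",
                    group,
                    element,
                    w_px,
                )
                continue
            # spans across the bars, from float layout rounded per edge
            edges = [int(round(k * w_px)) for k in range(6)]
            bar_spans = tuple((edges[2 * k], edges[2 * k + 1]) for k in range(3))
            gap_spans = tuple((edges[2 * k + 1], edges[2 * k + 2]) for k in range(2))
            if any(b1 - b0 < 1 for b0, b1 in bar_spans) or any(
                g1 - g0 < 1 for g0, g1 in gap_spans
            ):
                log.warning(
                    "USAF group %d element %d: rounded bar/gap below one "
                    "pixel; skipped",
                    group,
                    element,
                )
                continue
            tile_h = max(length_px, block)
            tile_w = block + padding_px + length_px  # vertical block + horizontal block
            if cursor_col + tile_w + padding_px > cols:
                continue
            if cursor_row + tile_h + padding_px > rows:
                continue

            value = dark_transmittance
            # vertical bars: columns vary across bars, rows along length
            v_r0, v_c0 = cursor_row, cursor_col
            for b0, b1 in bar_spans:
                t[v_r0 : v_r0 + length_px, v_c0 + b0 : v_c0 + b1] = value
            records.append(
                UsafElement(
                    group=group,
                    element=element,
                    orientation="vertical",
                    lp_per_mm=lp_per_mm,
                    bar_width_px=w_px,
                    bbox=(v_r0, v_r0 + length_px, v_c0, v_c0 + edges[5]),
                    bar_spans=bar_spans,
                    gap_spans=gap_spans,
                    length_span=(v_r0, v_r0 + length_px),
                )
            )
            # horizontal bars: rows vary across bars, cols along length
            h_r0 = cursor_row
            h_c0 = cursor_col + block + padding_px
            for b0, b1 in bar_spans:
                t[h_r0 + b0 : h_r0 + b1, h_c0 : h_c0 + length_px] = value
            records.append(
                UsafElement(
                    group=group,
                    element=element,
                    orientation="horizontal",
                    lp_per_mm=lp_per_mm,
                    bar_width_px=w_px,
                    bbox=(h_r0, h_r0 + edges[5], h_c0, h_c0 + length_px),
                    bar_spans=bar_spans,
                    gap_spans=gap_spans,
                    length_span=(h_c0, h_c0 + length_px),
                )
            )
            cursor_col += tile_w + 2 * padding_px
            row_height = max(row_height, tile_h)
        cursor_row += row_height + 2 * padding_px

    return Phantom(t, records, geometry, seed=0)


# ---------------------------------------------------------------------------
# Recording


def record_hologram(
    phantom: Phantom,
    illumination_amplitude: float = 1.0,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
) -> SensorImage:
    """Simulate the sensor recording of the phantom's in-line hologram.

    The object-plane field ``A * t`` is propagated over z2 and its squared
    modulus recorded.  Optional shot/read noise is applied and the result
    clipped at zero.  With no noise and an empty phantom the image is
    exactly ``A^2`` everywhere.
    """
    if illumination_amplitude < 0:
        raise ValueError("illumination amplitude must be non-negative")
    geom = phantom.geometry
    field = ComplexField(
        illumination_amplitude * phantom.transmittance, geom, Plane.OBJECT
    )
    at_sensor = propagate(field, geom.z2)
    intensity = np.abs(at_sensor.values) ** 2
    if noise_model is not None:
        rng = np.random.default_rng(seed)
        intensity = noise_model.apply(intensity, rng)
    intensity = np.clip(intensity, 0.0, None)
    return SensorImage(intensity, geom, kind="hologram")


def record_background(
    geometry: OpticalGeometry,
    illumination_amplitude: float = 1.0,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
) -> SensorImage:
    """Record a sample-free background frame (phantom with t = 1)."""
    empty = Phantom(
        np.ones(geometry.shape, dtype=np.complex128), [], geometry, seed=seed
    )
    img = record_hologram(empty, illumination_amplitude, noise_model, seed)
    return SensorImage(img.intensity, geometry, kind="background")


def quantize(image: SensorImage, bit_depth: int) -> SensorImage:
    """Quantize a float image to 8 or 16 bits (full range at the max)."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    peak = float(image.intensity.max())
    scale = (2**bit_depth - 1) / peak if peak > 0 else 1.0
    q = np.round(image.intensity * scale)
    return SensorImage(q, image.geometry, kind=image.kind, bit_depth=bit_depth)


def write_phantom_json(phantom: Phantom, path: str | Path) -> None:
    Path(path).write_text(phantom.to_json())
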