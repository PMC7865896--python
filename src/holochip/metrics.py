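"""Reference image-quality metrics and USAF-1951 resolution scoring.

Two full-reference metrics compare a test image against a reference frame
(in the study's workflow, a 10x bright-field micrograph of the same scene):

* the blur coefficient ``Kblur = S_out / S_in``, the ratio of oblique-edge
  energies, where ``S = sum |y_f|`` sums the absolute responses of an
  oblique (diagonal) spatial differential filter.  Equal sharpness gives 1;
  blur pushes the value below 1, while noise or ringing can push it above 1
  because spurious high-frequency structure adds edge energy.
* the quality index
  ``Q = 4 * sigma_xy * xbar * ybar / ((sigma_x^2 + sigma_y^2) * (xbar^2 + ybar^2))``
  in [-1, 1], a product of correlation, luminance and contrast agreement;
  identical images give exactly 1.  ``sigma_xy`` is the sample covariance
  (the only reading under which Q(x, x) = 1); variances and covariance share
  the same n-1 normalisation.

Resolution is scored on three-bar USAF-1951 targets: the element frequency
is ``2^(group + (element - 1)/6)`` lp/mm, and an element counts as resolved
when all three bars separate from the gaps with at least the requested
Michelson contrast in both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate2d

from .simulator import UsafElement

__all__ = [
    "OBLIQUE_KERNEL",
    "OBLIQUE_KERNEL_ID",
    "MetricReport",
    "oblique_edge_energy",
    "kblur",
    "quality_index",
    "metric_report",
    "usaf_frequency",
    "resolve_limit",
]

# Two diagonal first differences (centre minus NE, centre minus NW) summed;
# coefficients sum to zero so a constant image has zero edge energy.  The
# kernel choice only scales S; Kblur is a ratio, so any fixed oblique kernel
# gives the same ordering — but it must stay fixed and versioned.
OBLIQUE_KERNEL = np.array(
    [
        [-1.0, 0.0, -1.0],
        [0.0, 2.0, 0.0],
        [0.0, 0.0, 0.0],
    ]
)
OBLIQUE_KERNEL_ID = "oblique-diff-3x3-v1"


@dataclass
class MetricReport:
    """One row of a reference-quality comparison (Kblur and Q)."""

    kblur: float
    q_index: float
    reference_id: str = "reference"
    test_id: str = "test"
    filter_kernel_id: str = OBLIQUE_KERNEL_ID

    def __post_init__(self) -> None:
        if self.kblur < 0:
            raise ValueError("kblur must be non-negative")
        if not (-1.0 - 1e-9 <= self.q_index <= 1.0 + 1e-9):
            raise ValueError(f"q_index {self.q_index} outside [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "reference": self.reference_id,
            "test": self.test_id,
            "kblur": self.kblur,
            "q": self.q_index,
            "filter_kernel": self.filter_kernel_id,
        }


def oblique_edge_energy(image: np.ndarray) -> float:
    """Oblique-edge energy S: sum of absolute oblique-differential responses.

    The kernel is applied in correlation orientation (as written) with
    'valid' support, so border pixels never contribute phantom edges.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single-frame 2-D grayscale image")
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image smaller than the 3x3 differential kernel")
    response = correlate2d(image, OBLIQUE_KERNEL, mode="valid")
    return float(np.sum(np.abs(response)))


def kblur(reference_image: np.ndarray, test_image: np.ndarray) -> float:
    """Blur coefficient: test edge energy over reference edge energy.

    1 means the test image is as sharp as the reference; blur gives < 1;
    added noise or reconstruction ringing can give > 1.
    """
    reference_image = np.asarray(reference_image, dtype=np.float64)
    test_image = np.asarray(test_image, dtype=np.float64)
    if reference_image.shape != test_image.shape:
        raise ValueError("reference and test images must have equal shapes")
    s_in = oblique_edge_energy(reference_image)
    if s_in == 0.0:
        raise ValueError("reference image has zero edge energy")
    return oblique_edge_energy(test_image) / s_in


def quality_index(reference_image: np.ndarray, test_image: np.ndarray) -> float:
    """Global quality index Q in [-1, 1]; 1 iff the images are identical.

    Computed over the whole frame with sample (n-1) variance/covariance so
    that Q(x, x) is exactly 1 for any non-constant image.
    """
    x = np.asarray(reference_image, dtype=np.float64).ravel()
    y = np.asarray(test_image, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("reference and test images must have equal shapes")
    x_mean = x.mean()
    y_mean = y.mean()
    var_x = x.var(ddof=1)
    var_y = y.var(ddof=1)
    if var_x == 0.0 and var_y == 0.0:
        raise ValueError("quality index undefined: both images are constant")
    cov = float(np.dot(x - x_mean, y - y_mean) / (x.size - 1))
    denom = (var_x + var_y) * (x_mean**2 + y_mean**2)
    if denom == 0.0:
        raise ValueError("quality index undefined: zero denominator")
    return float(4.0 * cov * x_mean * y_mean / denom)


def metric_report(
    reference_image: np.ndarray,
    test_image: np.ndarray,
    reference_id: str = "reference",
    test_id: str = "test",
) -> MetricReport:
    """Evaluate both reference metrics and bundle them in a report."""
    return MetricReport(
        kblur=kblur(reference_image, test_image),
        q_index=quality_index(reference_image, test_image),
        reference_id=reference_id,
        test_id=test_id,
    )


def usaf_frequency(group: int, element: int) -> float:
    """USAF-1951 element frequency in line pairs per mm: 2^(g + (e-1)/6)."""
    if not 1 <= element <= 6:
        raise ValueError(f"element must be in 1..6, got {element}")
    return float(2.0 ** (group + (element - 1) / 6.0))


def _element_contrast(image: np.ndarray, el: UsafElement) -> float:
    """Michelson contrast between bar troughs and gap peaks of one element."""
    r0, r1, c0, c1 = el.bbox
    patch = image[r0:r1, c0:c1]
    if patch.size == 0:
        return 0.0
    # Average along the bar length (central 60% to dodge end effects), keep
    # the profile across the bars.
    if el.orientation == "vertical":
        n = patch.shape[0]
        lo, hi = int(0.2 * n), max(int(0.8 * n), int(0.2 * n) + 1)
        profile = patch[lo:hi, :].mean(axis=0)
    else:
        n = patch.shape[1]
        lo, hi = int(0.2 * n), max(int(0.8 * n), int(0.2 * n) + 1)
        profile = patch[:, lo:hi].mean(axis=1)
    bar_levels = []
    for b0, b1 in el.bar_spans:
        seg = profile[b0:b1]
        if seg.size == 0:
            return 0.0
        bar_levels.append(float(seg.min()))
    gap_levels = []
    for g0, g1 in el.gap_spans:
        seg = profile[g0:g1]
        if seg.size == 0:
            return 0.0
        gap_levels.append(float(seg.max()))
    bright = min(gap_levels)
    dark = max(bar_levels)
    if bright <= dark:
        return 0.0
    total = bright + dark
    if total <= 0:
        return 0.0
    return (bright - dark) / total


def resolve_limit(
    image: np.ndarray,
    layout: list[UsafElement],
    contrast_threshold: float = 0.1,
) -> tuple[int, int, float] | None:
    """Finest USAF element resolved in an image of a known bar-target layout.

    An element is resolved when the across-bar profile separates all three
    bars from the gaps with Michelson contrast >= ``contrast_threshold`` in
    both rendered orientations.  Returns (group, element, lp_per_mm) of the
    finest resolved element, or None when nothing resolves.
    """
    if not layout:
        raise ValueError("missing USAF layout metadata")
    image = np.asarray(image, dtype=np.float64)
    by_key: dict[tuple[int, int], list[UsafElement]] = {}
    for el in layout:
        by_key.setdefault((el.group, el.element), []).append(el)
    best: tuple[int, int, float] | None = None
    for (group, element), els in by_key.items():
        if len(els) < 2:
            continue  # need both orientations
        if all(_element_contrast(image, el) >= contrast_threshold for el in els):
            freq = usaf_frequency(group, element)
            if best is None or freq > best[2]:
                best = (group, element, freq)
    return best
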