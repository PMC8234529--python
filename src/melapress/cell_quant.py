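"""Image-derived cell metrics: progression, viability, and F-actin length.

Three bulk measurements taken on multi-cell fields where single-cell
segmentation is infeasible:

* colony progression — the cell-occupied area ``a_t`` is reduced to an
  equivalent-circle radius, and the progression distance
  ``l_t = sqrt(a_t/pi) - sqrt(a_0/pi)`` is tracked over time; its OLS slope
  is the progression rate;
* viability — live (calcein, green) and dead (PI, red) cells are counted;
  the live-cell fraction NL/(NL+ND) is reported under ``dcr_printed``
  together with the complementary ``dead_fraction``, and the proliferation
  rate CPR = (NL+ND)/(NL+ND)_control;
* cytoskeleton — the total skeletonized F-actin length per nucleus,
  LFC = Lf/Nn, a bulk multi-cell measure of filament elongation.

Counting uses Laplacian-of-Gaussian blob detection for rounded bright
cells and distance-transform watershed after Otsu/mean thresholding for
nuclei. All detectors normalize intensities first, so counts are invariant
to global affine rescaling of the input frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from skimage.feature import blob_log
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, h_maxima, skeletonize
from skimage.segmentation import watershed

__all__ = [
    "ColonyMeasure",
    "CellCounts",
    "ActinMeasure",
    "segment_colony",
    "progression_distance",
    "progression_rate",
    "count_live_cells",
    "count_nuclei",
    "viability",
    "actin_length",
    "lfc",
]


@dataclass
class ColonyMeasure:
    """Colony expansion record: times (h), areas (px^2 or mm^2), the t=0
    area, per-time progression distance, and its fitted rate."""

    times: np.ndarray
    areas: np.ndarray
    a0: float
    l_t: np.ndarray
    rate: float | None = None
    intercept: float | None = None


@dataclass
class CellCounts:
    """Live/dead counts with both readings of the viability ratio.

    ``dcr_printed`` is NL/(NL+ND) — the formula as printed in the source
    protocol (nominally a "dead cell rate", actually the live fraction);
    ``dead_fraction`` is ND/(NL+ND). They sum to one by construction.
    """

    n_live: int
    n_dead: int
    dcr_printed: float
    dead_fraction: float
    cpr: float | None = None


@dataclass
class ActinMeasure:
    lf: float
    nn: int
    lfc: float


def _normalize(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=np.float64)
    lo, hi = float(frame.min()), float(frame.max())
    if hi - lo <= 0:
        return np.zeros_like(frame)
    return (frame - lo) / (hi - lo)


# --------------------------------------------------------------------------
# colony progression
# --------------------------------------------------------------------------

def segment_colony(
    frame: np.ndarray,
    median_radius: int = 2,
    invert: bool = False,
) -> tuple[np.ndarray, float]:
    """Median filter + Otsu threshold; keep the largest connected
    component, fill holes, return (mask, area in px^2).

    ``invert=True`` handles dark colonies on a bright field (polarity
    flip); the area is the same for either contrast polarity.
    """
    img = _normalize(frame)
    if invert:
        img = 1.0 - img
    img = median_filter(img, disk(median_radius))
    if img.max() == img.min():
        raise ValueError("blank frame: nothing to segment")
    mask = img > threshold_otsu(img)
    if not mask.any():
        raise ValueError("empty mask after thresholding")
    lab = label(mask)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    biggest = lab == int(np.argmax(counts))
    biggest = ndi.binary_fill_holes(biggest)
    return biggest, float(biggest.sum())


def progression_distance(a_t: float, a0: float) -> float:
    """Equivalent-radius difference l_t = sqrt(a_t/pi) - sqrt(a0/pi).

    Negative when the occupied region shrinks; units follow the areas.
    """
    if a_t <= 0 or a0 <= 0:
        raise ValueError("areas must be strictly positive")
    return float(np.sqrt(a_t / np.pi) - np.sqrt(a0 / np.pi))


def progression_rate(measure: ColonyMeasure) -> tuple[float, float]:
    """Ordinary least-squares slope and intercept of l_t against time."""
    if len(measure.times) < 3:
        raise ValueError("progression rate needs >= 3 time points")
    fit = stats.linregress(measure.times, measure.l_t)
    measure.rate = float(fit.slope)
    measure.intercept = float(fit.intercept)
    return measure.rate, measure.intercept


def measure_colony_series(times, frames, pixel_size_um: float | None = None,
                          invert: bool = False) -> ColonyMeasure:
    """Segment every frame, convert to progression distances and fit the
    rate. Areas in px^2 (or mm^2 when a pixel size is given); distances in
    px (or mm)."""
    areas = np.array([segment_colony(f, invert=invert)[1] for f in frames])
    scale = 1.0
    if pixel_size_um is not None:
        scale = (pixel_size_um / 1000.0) ** 2  # px^2 -> mm^2
    areas = areas * scale
    l_t = np.array([progression_distance(a, areas[0]) for a in areas])
    m = ColonyMeasure(np.asarray(times, float), areas, float(areas[0]), l_t)
    progression_rate(m)
    return m


# --------------------------------------------------------------------------
# viability counting
# --------------------------------------------------------------------------

def count_live_cells(
    green_frame: np.ndarray,
    cell_diameter: float = 12.0,
    threshold: float = 0.1,
) -> int:
    """Count rounded bright cells by Laplacian-of-Gaussian blob detection.

    The LoG scale is matched to ``cell_diameter`` and nearby responses are
    suppressed within about half a diameter, which mirrors template-based
    nucleus counters for convex fluorescent cells. An empty frame counts 0.
    """
    if cell_diameter <= 2:
        raise ValueError("cell_diameter must exceed 2 px")
    img = _normalize(green_frame)
    if img.max() <= 0:
        return 0
    sigma = cell_diameter / (2.0 * np.sqrt(2.0))
    blobs = blob_log(
        img,
        min_sigma=sigma * 0.6,
        max_sigma=sigma * 1.6,
        num_sigma=5,
        threshold=threshold,
        overlap=0.5,
    )
    return int(len(blobs))


def count_nuclei(
    frame: np.ndarray,
    binarization: str = "otsu",
    min_area: int = 12,
    h_depth: float = 2.0,
) -> int:
    """Threshold + distance-transform watershed nucleus count.

    ``binarization`` selects the global threshold: ``otsu`` (between-class
    variance maximization; PI-stained nuclei) or ``mean`` (global image
    mean; DAPI). Touching nuclei are split by watershed seeded at h-maxima
    of the distance transform (depth ``h_depth`` px suppresses
    over-segmentation); components below ``min_area`` px are discarded.
    """
    if binarization not in ("otsu", "mean"):
        raise ValueError(f"unknown binarization {binarization!r}")
    img = _normalize(frame)
    if img.max() <= 0:
        return 0
    if binarization == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = float(img.mean())
    mask = img > thr
    if not mask.any():
        return 0
    dist = ndi.distance_transform_edt(mask)
    seeds = label(h_maxima(dist, h_depth))
    if seeds.max() == 0:
        seeds = label(mask)
    segmented = watershed(-dist, seeds, mask=mask)
    n = 0
    for region in range(1, segmented.max() + 1):
        if np.count_nonzero(segmented == region) >= min_area:
            n += 1
    return n


def viability(
    n_live: int, n_dead: int, control_total: int | None = None
) -> CellCounts:
    """Viability ratios from live/dead counts; CPR when a control total is
    supplied (control measured against itself gives CPR = 1)."""
    if n_live < 0 or n_dead < 0:
        raise ValueError("counts must be nonnegative")
    total = n_live + n_dead
    if total == 0:
        raise ValueError("NL + ND must be positive")
    cpr = None
    if control_total is not None:
        if control_total <= 0:
            raise ValueError("control_total must be positive")
        cpr = total / control_total
    return CellCounts(
        n_live=n_live,
        n_dead=n_dead,
        dcr_printed=n_live / total,
        dead_fraction=n_dead / total,
        cpr=cpr,
    )


# --------------------------------------------------------------------------
# F-actin length
# --------------------------------------------------------------------------

def actin_length(
    actin_frame: np.ndarray,
    sigma_low: float = 1.0,
    sigma_high: float = 13.3,
    diagonal_aware: bool = False,
) -> float:
    """Total skeletonized filament length Lf.

    Difference-of-Gaussians bandpass (pass structures between roughly
    3 and 40 px at the defaults) -> Otsu threshold -> morphological
    skeletonization. Length is the skeleton pixel count — the sum of the
    binary skeleton, matching a grayscale-sum readout divided by the
    foreground value. ``diagonal_aware=True`` instead accumulates 1 per
    4-connected step and sqrt(2) per diagonal step along the skeleton.
    Returns 0.0 for an empty skeleton.
    """
    img = _normalize(actin_frame)
    band = ndi.gaussian_filter(img, sigma_low) - ndi.gaussian_filter(img, sigma_high)
    if np.ptp(band) == 0:
        return 0.0
    mask = band > threshold_otsu(band)
    if not mask.any():
        return 0.0
    skel = skeletonize(mask)
    if not skel.any():
        return 0.0
    if not diagonal_aware:
        return float(skel.sum())
    s = skel.astype(np.int8)
    straight = ((s[:, :-1] & s[:, 1:]).sum() + (s[:-1, :] & s[1:, :]).sum())
    diag = ((s[:-1, :-1] & s[1:, 1:]).sum() + (s[:-1, 1:] & s[1:, :-1]).sum())
    return float(straight + np.sqrt(2.0) * diag)


def lfc(lf: float, nn: int) -> float:
    """F-actin length per cell, LFC = Lf / Nn (px per cell)."""
    if nn < 1:
        raise ValueError("Nn must be >= 1")
    if lf < 0:
        raise ValueError("Lf must be nonnegative")
    return lf / nn


def measure_actin_scene(
    actin_frame: np.ndarray,
    nuclei_frame: np.ndarray,
    sigma_low: float = 1.0,
    sigma_high: float = 13.3,
    nuclei_binarization: str = "mean",
) -> ActinMeasure:
    """Full Lf / Nn / LFC readout of one actin + nuclei channel pair."""
    lf_val = actin_length(actin_frame, sigma_low, sigma_high)
    nn_val = count_nuclei(nuclei_frame, binarization=nuclei_binarization)
    if nn_val < 1:
        raise ValueError("no nuclei detected; LFC undefined")
    return ActinMeasure(lf=lf_val, nn=nn_val, lfc=lfc(lf_val, nn_val))
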