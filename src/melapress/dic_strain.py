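"""Digital image correlation (DIC) and Green-Lagrange strain fields.

Subset-based DIC for tracking gel deformation between a reference frame
and a deformed frame: a square interrogation window is centred on each
node of a regular grid, matched into the deformed frame by maximising the
zero-normalized cross-correlation (ZNCC) over integer offsets within a
search radius, then refined to subpixel precision by a 1-D quadratic fit
through the correlation peak. Displacement gradients on the node lattice
give the finite-deformation (Green-Lagrange) strain tensor, which is
invariant to rigid rotation; a scalar "representative strain" summarises
a field as the Euclidean norm of the medians of the two normal components.

ZNCC (mean-subtracted, variance-normalized correlation) is used because it
is insensitive to the slow illumination drift typical of long time-lapse
phase-contrast acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PixelGrid",
    "DisplacementField",
    "StrainField",
    "FlatSubsetError",
    "build_grid",
    "match_subset",
    "displacement_field",
    "green_lagrange",
    "representative_strain",
]

_EPS = 1e-12


class FlatSubsetError(ValueError):
    """Interrogation window has (near-)zero intensity variance: unmatchable."""


@dataclass(frozen=True)
class PixelGrid:
    """Regular lattice of interrogation-window centres.

    ``x`` are node column coordinates, ``y`` node row coordinates (px,
    0-based). Every node keeps ``subset_size//2 + search_radius`` pixels of
    clearance from each image border so both the window and its search
    region stay inside the frame.
    """

    x: np.ndarray
    y: np.ndarray
    subset_size: int
    spacing: int
    search_radius: int

    @property
    def nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of node coordinates, shape (ny, nx) each (X, Y)."""
        return np.meshgrid(self.x, self.y)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.y), len(self.x)


@dataclass
class DisplacementField:
    """Per-node displacement (u rightward, v downward, px) with the peak
    ZNCC value; ``valid`` flags nodes where matching succeeded."""

    grid: PixelGrid
    u: np.ndarray
    v: np.ndarray
    peak_corr: np.ndarray
    valid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        X, Y = self.grid.nodes
        return pd.DataFrame(
            {
                "node_x": X.ravel(),
                "node_y": Y.ravel(),
                "u": self.u.ravel(),
                "v": self.v.ravel(),
                "corr": self.peak_corr.ravel(),
                "valid": self.valid.ravel(),
            }
        )


@dataclass
class StrainField:
    """Green-Lagrange strain components on the same node lattice as the
    source displacement field (dimensionless)."""

    grid: PixelGrid
    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        X, Y = self.grid.nodes
        return pd.DataFrame(
            {
                "node_x": X.ravel(),
                "node_y": Y.ravel(),
                "sxx": self.sxx.ravel(),
                "syy": self.syy.ravel(),
                "sxy": self.sxy.ravel(),
            }
        )


def build_grid(
    image_shape: tuple[int, int],
    subset_size: int = 31,
    spacing: int = 16,
    search_radius: int = 10,
    roi: tuple[int, int, int, int] | None = None,
) -> PixelGrid:
    """Lay out the interrogation-window lattice for an image.

    Parameters
    ----------
    image_shape : (rows, cols)
    subset_size : odd window edge length, >= 9 px
    spacing : node pitch, >= 1 px
    search_radius : integer search range, px
    roi : optional (min_row, min_col, max_row, max_col), exclusive maxima;
        node centres are restricted to it. Must be at least one subset.
    """
    rows, cols = image_shape
    if subset_size < 9 or subset_size % 2 == 0:
        raise ValueError("subset_size must be odd and >= 9 px")
    if spacing < 1:
        raise ValueError("spacing must be >= 1 px")
    if search_radius < 1:
        raise ValueError("search_radius must be >= 1 px")
    margin = (subset_size - 1) // 2 + search_radius

    r0, c0, r1, c1 = (0, 0, rows, cols) if roi is None else roi
    if (r1 - r0) < subset_size or (c1 - c0) < subset_size:
        raise ValueError("roi smaller than one interrogation window")

    x_lo, x_hi = max(margin, c0), min(cols - 1 - margin, c1 - 1)
    y_lo, y_hi = max(margin, r0), min(rows - 1 - margin, r1 - 1)
    x = np.arange(x_lo, x_hi + 1, spacing)
    y = np.arange(y_lo, y_hi + 1, spacing)
    if len(x) < 3 or len(y) < 3:
        need = 2 * margin + 2 * spacing + 1
        raise ValueError(
            f"image/roi too small for a 3x3 node lattice: needs at least "
            f"{need}x{need} px at subset {subset_size}, spacing {spacing}, "
            f"search {search_radius}"
        )
    return PixelGrid(x, y, subset_size, spacing, search_radius)


def _quadratic_peak_offset(cm1: float, c0: float, cp1: float) -> float:
    """Subpixel offset of a 1-D quadratic through three samples, in
    [-0.5, 0.5]; 0 when the points do not bracket a maximum."""
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= -_EPS:  # not a concave peak
        return 0.0
    delta = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(delta, -0.5, 0.5))


def match_subset(
    reference: np.ndarray,
    deformed: np.ndarray,
    node: tuple[int, int],
    subset_size: int = 31,
    search_radius: int = 10,
) -> tuple[float, float, float]:
    """Track one interrogation window from `reference` into `deformed`.

    Returns ``(u, v, peak_corr)`` where (u, v) maximises the ZNCC over
    integer offsets within ``±search_radius`` and is then refined per axis
    by quadratic interpolation of the correlation peak (clamped to
    ±0.5 px). ``peak_corr`` is the integer-lattice maximum.

    Raises
    ------
    FlatSubsetError
        If the reference window has no intensity variance.
    """
    x, y = int(node[0]), int(node[1])
    h = subset_size // 2
    r = search_radius
    ref = np.asarray(reference, dtype=np.float64)
    dfm = np.asarray(deformed, dtype=np.float64)
    if ref.shape != dfm.shape:
        raise ValueError("reference and deformed frames must share a shape")
    if not (h + r <= x < ref.shape[1] - h - r and h + r <= y < ref.shape[0] - h - r):
        raise ValueError(f"node ({x},{y}) too close to the border for "
                         f"subset {subset_size} + search {r}")

    tmpl = ref[y - h : y + h + 1, x - h : x + h + 1]
    tz = tmpl - tmpl.mean()
    tnorm = np.sqrt((tz * tz).sum())
    if tnorm <= _EPS * subset_size:
        raise FlatSubsetError(f"flat interrogation window at node ({x},{y})")

    region = dfm[y - h - r : y + h + r + 1, x - h - r : x + h + r + 1]
    win = sliding_window_view(region, (subset_size, subset_size))
    n_px = subset_size * subset_size
    wsum = win.sum(axis=(2, 3))
    wss = (win * win).sum(axis=(2, 3)) - wsum * wsum / n_px
    num = np.einsum("ijkl,kl->ij", win, tz)  # tz is zero-mean
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / (np.sqrt(np.maximum(wss, 0.0)) * tnorm)
    corr[~np.isfinite(corr)] = -np.inf  # flat windows can never win

    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    peak = float(corr[iy, ix])
    du = dv = 0.0
    if peak >= 1.0 - 1e-9:  # exact match: refinement could only add bias
        return float(ix - r), float(iy - r), peak
    if 0 < ix < 2 * r:
        du = _quadratic_peak_offset(corr[iy, ix - 1], peak, corr[iy, ix + 1])
    if 0 < iy < 2 * r:
        dv = _quadratic_peak_offset(corr[iy - 1, ix], peak, corr[iy + 1, ix])
    return float(ix - r + du), float(iy - r + dv), peak


def displacement_field(
    reference: np.ndarray, deformed: np.ndarray, grid: PixelGrid
) -> DisplacementField:
    """Run :func:`match_subset` at every grid node.

    Nodes with unmatchable (flat) windows are flagged invalid and carry
    NaN displacements rather than silent zeros. More than half the nodes
    failing marks the scene unusable.
    """
    ny, nx = grid.shape
    u = np.full((ny, nx), np.nan)
    v = np.full((ny, nx), np.nan)
    pc = np.full((ny, nx), np.nan)
    ok = np.zeros((ny, nx), dtype=bool)
    for j, yy in enumerate(grid.y):
        for i, xx in enumerate(grid.x):
            try:
                u[j, i], v[j, i], pc[j, i] = match_subset(
                    reference, deformed, (xx, yy), grid.subset_size, grid.search_radius
                )
                ok[j, i] = True
            except FlatSubsetError:
                continue
    if ok.sum() <= ok.size // 2:
        raise ValueError(
            f"only {int(ok.sum())}/{ok.size} nodes matched: scene unusable"
        )
    return DisplacementField(grid, u, v, pc, ok)


def green_lagrange(field: DisplacementField) -> StrainField:
    """Green-Lagrange strain from displacement gradients on the lattice.

    Gradients use central differences on the node lattice (one-sided at the
    edges); node coordinates are in pixels, displacements in pixels, so all
    components are dimensionless:

        Sxx = du/dx + 1/2 [(du/dx)^2 + (dv/dx)^2]
        Syy = dv/dy + 1/2 [(du/dy)^2 + (dv/dy)^2]
        Sxy = 1/2 [du/dy + dv/dx + (du/dx)(du/dy) + (dv/dx)(dv/dy)]
    """
    ny, nx = field.grid.shape
    if ny < 3 or nx < 3:
        raise ValueError("Green-Lagrange strain needs >= 3 nodes per axis")
    x = field.grid.x.astype(float)
    y = field.grid.y.astype(float)
    u = np.where(field.valid, field.u, np.nan)
    v = np.where(field.valid, field.v, np.nan)
    dudx = np.gradient(u, x, axis=1)
    dudy = np.gradient(u, y, axis=0)
    dvdx = np.gradient(v, x, axis=1)
    dvdy = np.gradient(v, y, axis=0)
    sxx = dudx + 0.5 * (dudx**2 + dvdx**2)
    syy = dvdy + 0.5 * (dudy**2 + dvdy**2)
    sxy = 0.5 * (dudy + dvdx + dudx * dudy + dvdx * dvdy)
    return StrainField(field.grid, sxx, syy, sxy)


def representative_strain(strain: StrainField, convention: str = "euclidean") -> float:
    """Collapse a strain field to one scalar from the normal components.

    ``euclidean`` (default): sqrt(median(Sxx)^2 + median(Syy)^2) — a strain,
    suitable as the ordinate of a creep curve. ``sum_of_squares``:
    median(Sxx)^2 + median(Syy)^2 (units of strain squared). Shear is
    excluded in both conventions. Medians ignore invalid (NaN) nodes.
    """
    sxx = strain.sxx[np.isfinite(strain.sxx)]
    syy = strain.syy[np.isfinite(strain.syy)]
    if sxx.size == 0 or syy.size == 0:
        raise ValueError("no valid nodes in strain field")
    q = float(np.median(sxx)) ** 2 + float(np.median(syy)) ** 2
    if convention == "euclidean":
        return float(np.sqrt(q))
    if convention == "sum_of_squares":
        return float(q)
    raise ValueError(f"unknown representative-strain convention: {convention!r}")
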