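"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The study's raw data are microscope images and qPCR threshold cycles; this
module fabricates stand-ins whose true quantities are known exactly, so the
downstream measurements (DIC strain, colony area, cell counts, filament
length, fold changes) can be validated as parameter-recovery problems:

* speckle images of microsphere-seeded gel under a prescribed displacement
  field (uniform translation, homogeneous strain, or a Kelvin-Voigt creep
  time course) — dark blurred discs on a bright background, the
  phase-contrast appearance of polystyrene beads;
* quasi-circular colonies whose equivalent radius grows linearly in time;
* live/dead fluorescence channel pairs with a set dead fraction;
* filament networks of known total centerline length plus a nuclei channel;
* Ct tables with set fold changes of a target gene versus a reference gene.

Every generator takes a mandatory integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk, skeletonize

from .core import ImageSequence
from .creep_model import KelvinVoigtParams, kv_strain
from .dic_strain import PixelGrid, build_grid

__all__ = [
    "Translation",
    "HomogeneousStrain",
    "SpecklePairSpec",
    "ColonySeriesSpec",
    "LiveDeadSpec",
    "FilamentSceneSpec",
    "CtTableSpec",
    "GroundTruthField",
    "CreepSequence",
    "ColonySeries",
    "LiveDeadScene",
    "FilamentScene",
    "gen_speckle_pair",
    "gen_creep_sequence",
    "gen_colony_series",
    "gen_livedead_pair",
    "gen_filament_scene",
    "gen_ct_table",
]


# --------------------------------------------------------------------------
# displacement prescriptions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Translation:
    """Rigid in-plane shift (px): u = tx, v = ty everywhere."""

    tx: float
    ty: float


@dataclass(frozen=True)
class HomogeneousStrain:
    """Symmetric displacement-gradient field applied as an affine map about
    the image centre: u(X) = G (X - c) with G = [[exx, exy], [exy, eyy]]."""

    exx: float
    eyy: float = 0.0
    exy: float = 0.0


def _centre(shape: tuple[int, int]) -> tuple[float, float]:
    return (shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0  # (cx, cy)


def _displacement_at(disp, shape, x, y):
    """Forward displacement (u, v) of material points at (x, y)."""
    if isinstance(disp, Translation):
        return np.full_like(x, disp.tx, dtype=float), np.full_like(y, disp.ty, dtype=float)
    if isinstance(disp, HomogeneousStrain):
        cx, cy = _centre(shape)
        u = disp.exx * (x - cx) + disp.exy * (y - cy)
        v = disp.exy * (x - cx) + disp.eyy * (y - cy)
        return u, v
    raise TypeError(f"unsupported displacement spec: {type(disp).__name__}")


def _warp(reference: np.ndarray, disp) -> np.ndarray:
    """Resample the reference through the prescribed forward map x = X + u(X)
    by inverse mapping with bicubic interpolation (no holes, preserves the
    correlation texture)."""
    h, w = reference.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    if isinstance(disp, Translation):
        xs, ys = xx - disp.tx, yy - disp.ty
    elif isinstance(disp, HomogeneousStrain):
        cx, cy = _centre(reference.shape)
        a = np.array([[1.0 + disp.exx, disp.exy], [disp.exy, 1.0 + disp.eyy]])
        if abs(np.linalg.det(a)) < 1e-9:
            raise ValueError("degenerate strain map (det(I+G) ~ 0)")
        inv = np.linalg.inv(a)
        dx, dy = xx - cx, yy - cy
        xs = cx + inv[0, 0] * dx + inv[0, 1] * dy
        ys = cy + inv[1, 0] * dx + inv[1, 1] * dy
    else:
        raise TypeError(f"unsupported displacement spec: {type(disp).__name__}")
    return ndi.map_coordinates(reference, [ys, xs], order=3, mode="constant", cval=1.0)


# --------------------------------------------------------------------------
# speckle scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecklePairSpec:
    """Microsphere-seeded gel scene: dark blurred spots on a bright field.

    ``displacement`` is a :class:`Translation` or :class:`HomogeneousStrain`
    (creep time courses are handled by :func:`gen_creep_sequence`). Grid
    parameters fix the lattice on which the ground-truth displacement is
    reported — the same lattice the DIC stage will use.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_spots: int = 400
    spot_radius: float = 3.0
    displacement: Translation | HomogeneousStrain = Translation(0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0
    subset_size: int = 31
    spacing: int = 16
    search_radius: int = 10

    def __post_init__(self) -> None:
        if self.n_spots < 10:
            raise ValueError("n_spots must be >= 10")
        if self.spot_radius < 1:
            raise ValueError("spot_radius must be >= 1 px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruthField:
    """True displacement sampled on the DIC node lattice."""

    grid: PixelGrid
    u: np.ndarray
    v: np.ndarray


def _render_spots(shape, centers, radius) -> np.ndarray:
    """Dark Gaussian-profile discs on a bright (1.0) background, float64."""
    img = np.ones(shape, dtype=np.float64)
    sigma = max(0.6 * radius, 0.8)
    ext = int(math.ceil(4 * sigma))
    h, w = shape
    for cy, cx in centers:
        y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] -= 0.85 * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
        )
    return np.clip(img, 0.0, 1.0)


def _speckle_reference(spec: SpecklePairSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.image_shape
    m = 2.0 * spec.spot_radius
    centers = rng.uniform([m, m], [h - 1 - m, w - 1 - m], size=(spec.n_spots, 2))
    return _render_spots(spec.image_shape, centers, spec.spot_radius), centers


def _check_spots_in_frame(spec: SpecklePairSpec, centers, disp) -> None:
    cy, cx = centers[:, 0], centers[:, 1]
    u, v = _displacement_at(disp, spec.image_shape, cx, cy)
    h, w = spec.image_shape
    out = (cx + u < 0) | (cx + u > w - 1) | (cy + v < 0) | (cy + v > h - 1)
    if out.mean() > 0.25:
        raise ValueError(
            f"{out.mean():.0%} of spots leave the frame: unmatchable scene"
        )


def gen_speckle_pair(
    spec: SpecklePairSpec,
) -> tuple[np.ndarray, np.ndarray, GroundTruthField]:
    """Reference frame, deformed frame, and the true per-node displacement.

    The deformed frame is the reference resampled through the prescribed
    displacement map plus additive Gaussian intensity noise (fraction of
    the [0, 1] range). The ground truth is the analytic forward
    displacement evaluated at the DIC grid nodes.
    """
    rng = np.random.default_rng(spec.seed)
    ref, centers = _speckle_reference(spec, rng)
    _check_spots_in_frame(spec, centers, spec.displacement)
    dfm = _warp(ref, spec.displacement)
    if spec.noise_sd > 0:
        dfm = dfm + rng.normal(0.0, spec.noise_sd, size=dfm.shape)
    grid = build_grid(
        spec.image_shape, spec.subset_size, spec.spacing, spec.search_radius
    )
    gx, gy = grid.nodes
    u, v = _displacement_at(spec.displacement, spec.image_shape, gx.astype(float), gy.astype(float))
    return ref, dfm, GroundTruthField(grid, u, v)


# --------------------------------------------------------------------------
# creep image sequences
# --------------------------------------------------------------------------

@dataclass
class CreepSequence:
    """Time-lapse speckle stack whose true Green-Lagrange normal strain
    follows the Kelvin-Voigt creep law; frame 0 is the pre-load reference
    (gamma_true[0] = 0)."""

    sequence: ImageSequence
    gamma_true: np.ndarray
    kv: KelvinVoigtParams

    @property
    def tau_true(self) -> float:
        return self.kv.tau


def gen_creep_sequence(
    kv: KelvinVoigtParams,
    duration: float,
    dt: float,
    spec: SpecklePairSpec,
) -> CreepSequence:
    """Speckle time-lapse under a creep-law deformation history.

    Frame 0 is the undeformed reference at t = 0 (the instant the load is
    applied); frame k (k >= 1) is the reference warped by a uniaxial
    horizontal stretch whose Green-Lagrange normal strain equals
    ``kv_strain(t_k)`` exactly (displacement gradient
    e_k = sqrt(1 + 2 gamma_k) - 1). Additive intensity noise, when
    requested, is independent per frame.
    """
    if duration <= 0 or dt <= 0 or duration / dt < 4:
        raise ValueError("creep sequence needs at least 5 frames (duration/dt >= 4)")
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    gamma = np.zeros(n_steps + 1)
    gamma[1:] = kv_strain(times[1:], kv)

    rng = np.random.default_rng(spec.seed)
    ref, centers = _speckle_reference(spec, rng)
    frames = [ref]
    for g in gamma[1:]:
        e = math.sqrt(1.0 + 2.0 * g) - 1.0
        disp = HomogeneousStrain(exx=e)
        _check_spots_in_frame(spec, centers, disp)
        frames.append(_warp(ref, disp))
    stack = np.stack(frames)
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)
    seq = ImageSequence(stack, times, meta={"kind": "creep_speckle"})
    return CreepSequence(seq, gamma, kv)


# --------------------------------------------------------------------------
# colony series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ColonySeriesSpec:
    """One quasi-circular colony whose equivalent radius grows linearly:
    r(t) = r0 + growth_rate * t, sampled at ``frame_times`` (hours)."""

    r0: float = 40.0
    growth_rate: float = 2.0
    frame_times: tuple[float, ...] = (0.0, 8.0, 16.0, 24.0)
    boundary_noise: float = 0.0
    image_shape: tuple[int, int] = (256, 256)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")
        t = np.asarray(self.frame_times, float)
        if t[0] != 0 or (len(t) > 1 and not np.all(np.diff(t) > 0)):
            raise ValueError("frame_times must start at 0 and strictly increase")
        if self.boundary_noise < 0:
            raise ValueError("boundary_noise must be >= 0")


@dataclass
class ColonySeries:
    sequence: ImageSequence
    areas_true: np.ndarray  # rasterized px^2, per frame
    radii_true: np.ndarray  # analytic equivalent radius, per frame


def _colony_mask(shape, radius, boundary_noise, rng) -> np.ndarray:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    edge = np.full(r.shape, radius, dtype=float)
    if boundary_noise > 0:
        # low-order Fourier perturbation of the boundary, zero-mean
        modes = np.arange(2, 7)
        amps = rng.normal(0.0, 1.0, size=modes.size)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=modes.size)
        wave = np.zeros_like(r)
        for m, a, p in zip(modes, amps, phases):
            wave += a * np.cos(m * theta + p)
        wave *= boundary_noise / max(np.std(wave), 1e-9)
        edge = edge + wave
    return r <= edge


def gen_colony_series(spec: ColonySeriesSpec) -> ColonySeries:
    """Phase-contrast-like colony frames (bright colony, dark field) with
    the rasterized colony area recorded as ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    times = np.asarray(spec.frame_times, float)
    radii = spec.r0 + spec.growth_rate * times
    if np.any(radii + spec.boundary_noise * 3 + 2 >= min(h, w) / 2):
        raise ValueError("colony radius exceeds frame half-size")
    frames, areas = [], []
    for r in radii:
        mask = _colony_mask(spec.image_shape, r, spec.boundary_noise, rng)
        areas.append(int(mask.sum()))
        img = 0.1 + 0.75 * ndi.gaussian_filter(mask.astype(float), 1.0)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames.append(img)
    seq = ImageSequence(np.stack(frames), times, meta={"kind": "colony"})
    return ColonySeries(seq, np.asarray(areas, float), radii)


# --------------------------------------------------------------------------
# live/dead scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LiveDeadSpec:
    """Two-channel fluorescence scene: live cells render in the green
    (calcein) channel, dead cells in the red (PI) channel."""

    n_cells: int = 100
    dead_fraction: float = 0.1
    cell_radius: float = 6.0
    overlap_allowance: float = 0.0
    image_shape: tuple[int, int] = (512, 512)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class LiveDeadScene:
    green: np.ndarray
    red: np.ndarray
    n_live_true: int
    n_dead_true: int


def _place_centers(rng, n, shape, min_sep, margin, max_tries_per_point=2000):
    h, w = shape
    if 2 * margin >= min(h, w):
        raise ValueError("impossible packing: margin exceeds frame")
    centers: list[np.ndarray] = []
    arr = np.empty((0, 2))
    for _ in range(n):
        for attempt in range(max_tries_per_point):
            p = rng.uniform([margin, margin], [h - 1 - margin, w - 1 - margin])
            if len(centers) == 0 or np.min(np.sum((arr - p) ** 2, axis=1)) >= min_sep**2:
                centers.append(p)
                arr = np.asarray(centers)
                break
        else:
            raise ValueError(
                f"impossible packing: placed {len(centers)}/{n} cells at "
                f"min separation {min_sep:.1f} px"
            )
    return arr


def _render_cells(shape, centers, radius, rng, noise_sd) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float64)
    sigma = max(radius / 1.8, 1.0)
    ext = int(math.ceil(4 * sigma))
    h, w = shape
    for cy, cx in centers:
        y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += 0.9 * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
        )
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


def gen_livedead_pair(spec: LiveDeadSpec) -> LiveDeadScene:
    """Green/red channel pair with exact live and dead counts."""
    rng = np.random.default_rng(spec.seed)
    n_dead = int(round(spec.n_cells * spec.dead_fraction))
    n_live = spec.n_cells - n_dead
    min_sep = max(2.0 * spec.cell_radius - spec.overlap_allowance, 1.0)
    centers = _place_centers(
        rng, spec.n_cells, spec.image_shape, min_sep, margin=2 * spec.cell_radius
    )
    order = rng.permutation(spec.n_cells)
    dead_idx, live_idx = order[:n_dead], order[n_dead:]
    green = _render_cells(spec.image_shape, centers[live_idx], spec.cell_radius, rng, spec.noise_sd)
    red = _render_cells(spec.image_shape, centers[dead_idx], spec.cell_radius, rng, spec.noise_sd)
    return LiveDeadScene(green, red, n_live, n_dead)


# --------------------------------------------------------------------------
# filament scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilamentSceneSpec:
    """Actin-like filament network plus a nuclei channel.

    ``total_length`` is the exact number of centerline pixels drawn (the
    same pixel-count length measure the skeleton analysis reports), split
    across ``n_filaments`` smooth random curves of the given stroke
    thickness.
    """

    n_filaments: int = 8
    total_length: int = 1200
    thickness: int = 3
    n_nuclei: int = 12
    nucleus_radius: float = 6.0
    image_shape: tuple[int, int] = (256, 256)
    curvature: float = 0.02  # rad/px direction noise; stress fibers are nearly straight
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError("total_length must be > 0")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.n_filaments < 1:
            raise ValueError("n_filaments must be >= 1")


@dataclass
class FilamentScene:
    actin: np.ndarray
    nuclei: np.ndarray
    lf_true: int
    nn_true: int


def _trace_filament(mask, rng, budget, margin, curvature) -> int:
    """Walk a smooth random curve, marking new pixels until ``budget`` new
    centerline pixels are set; returns the number actually drawn.

    Steps are emitted Bresenham-style (per-axis error accumulation), so the
    chain is a minimal 8-connected digital curve — the same pixel class a
    morphological skeleton retraces, which keeps the pixel-count ground
    truth commensurate with the skeleton-length measurement. A walk that
    reaches the field margin terminates and restarts elsewhere (fibers do
    not bounce off image borders).
    """
    h, w = mask.shape
    drawn = 0
    steps = 0
    restart = True
    while drawn < budget and steps < budget * 20:
        if restart:
            py = int(rng.integers(margin, h - margin))
            px = int(rng.integers(margin, w - margin))
            ang = rng.uniform(0.0, 2.0 * np.pi)
            ey = ex = 0.0
            restart = False
            if not mask[py, px]:
                mask[py, px] = True
                drawn += 1
            continue
        steps += 1
        ang += rng.normal(0.0, curvature)
        ey += math.sin(ang)
        ex += math.cos(ang)
        sy = int(round(ey))
        sx = int(round(ex))
        ey -= sy
        ex -= sx
        if sy == 0 and sx == 0:
            continue
        py += sy
        px += sx
        if not (margin <= py <= h - 1 - margin and margin <= px <= w - 1 - margin):
            restart = True
            continue
        if not mask[py, px]:
            mask[py, px] = True
            drawn += 1
    return drawn


def gen_filament_scene(spec: FilamentSceneSpec) -> FilamentScene:
    """Actin channel (thick bright curves) + nuclei channel, with the exact
    centerline pixel count and nucleus count as ground truth."""
    h, w = spec.image_shape
    margin = spec.thickness + 4
    usable = (h - 2 * margin) * (w - 2 * margin)
    if spec.total_length > 0.2 * usable:
        raise ValueError("total_length unrealizable in frame")
    rng = np.random.default_rng(spec.seed)

    mask = np.zeros(spec.image_shape, dtype=bool)
    per = [spec.total_length // spec.n_filaments] * spec.n_filaments
    per[-1] += spec.total_length - sum(per)
    drawn = 0
    for budget in per:
        drawn += _trace_filament(mask, rng, budget, margin, spec.curvature)
    if drawn < spec.total_length:
        raise ValueError("total_length unrealizable in frame (walk stalled)")
    # canonical digital length: the thinned centerline's pixel count (the
    # same length measure the skeleton analysis reports; thinning removes
    # redundant staircase pixels of the raw chain, not curve length)
    lf_true = int(skeletonize(mask).sum())

    stroke = dilation(mask, disk(max(spec.thickness // 2, 0)))
    actin = 0.85 * ndi.gaussian_filter(stroke.astype(float), 0.7)
    if spec.noise_sd > 0:
        actin = actin + rng.normal(0.0, spec.noise_sd, size=actin.shape)

    centers = _place_centers(
        rng, spec.n_nuclei, spec.image_shape, 2.5 * spec.nucleus_radius,
        margin=2 * spec.nucleus_radius,
    )
    nuclei = _render_cells(spec.image_shape, centers, spec.nucleus_radius, rng, spec.noise_sd)
    return FilamentScene(actin, nuclei, lf_true, spec.n_nuclei)


# --------------------------------------------------------------------------
# Ct tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CtTableSpec:
    """qPCR threshold-cycle table with known per-group fold changes of the
    target gene relative to the calibrator group, reference-normalized.

    Each measurement row is Ct(true) + N(0, ct_noise_sd); with zero noise
    the ddCt pipeline recovers every fold change exactly. Technical
    replicates appear as repeated (group, sample, gene) rows.
    """

    group_fold_changes: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1.0, "T4": 0.5, "T8": 4.0}
    )
    calibrator: str = "control"
    ct_reference_mean: float = 18.0
    delta_ct_calibrator: float = 4.0
    ct_noise_sd: float = 0.0
    replicates: int = 3
    technical_replicates: int = 3
    target_gene: str = "Mmp14"
    reference_gene: str = "Gapdh"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.group_fold_changes.values()):
            raise ValueError("fold changes must be > 0")
        if self.replicates < 1 or self.technical_replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.calibrator in self.group_fold_changes and not np.isclose(
            self.group_fold_changes[self.calibrator], 1.0
        ):
            raise ValueError("calibrator group must have fold change 1")


def gen_ct_table(spec: CtTableSpec) -> pd.DataFrame:
    """Tidy Ct table with columns (group, sample, gene, ct).

    Ct(target) = Ct(reference) + dCt_calibrator - log2(fold) per biological
    replicate, plus measurement noise per technical replicate.
    """
    folds = dict(spec.group_fold_changes)
    folds.setdefault(spec.calibrator, 1.0)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, fold in folds.items():
        dct = spec.delta_ct_calibrator - math.log2(fold)
        for b in range(1, spec.replicates + 1):
            sample = f"{group}_r{b}"
            for gene, true_ct in (
                (spec.reference_gene, spec.ct_reference_mean),
                (spec.target_gene, spec.ct_reference_mean + dct),
            ):
                for _ in range(spec.technical_replicates):
                    ct = true_ct + (
                        rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
                    )
                    rows.append((group, sample, gene, ct))
    return pd.DataFrame(rows, columns=["group", "sample", "gene", "ct"])
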