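"""Run configuration: one structured file drives every stage.

The configuration is a YAML mapping mirroring :class:`RunConfig` and its
nested parameter blocks. Unknown keys are rejected before any computation
so typos cannot silently fall back to defaults. A short hash of the
canonical configuration is stamped into every output table, which makes
mixing tables from different runs detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "DicConfig",
    "SegmentationConfig",
    "BandpassConfig",
    "FittingConfig",
    "StatsConfig",
    "DemoConfig",
    "RunConfig",
    "load_config",
    "config_hash",
]


@dataclass
class DicConfig:
    subset_size: int = 31          # interrogation window edge, px (odd)
    spacing: int = 16              # node pitch, px
    search_radius: int = 10        # integer search range, px
    convention: str = "euclidean"  # representative-strain convention


@dataclass
class SegmentationConfig:
    median_radius: int = 2
    invert: bool = False           # True for dark colonies on bright field
    cell_diameter: float = 12.0    # px, for LoG live-cell counting
    blob_threshold: float = 0.1
    nuclei_binarization: str = "otsu"   # dead-cell (PI) channel
    dapi_binarization: str = "mean"     # nuclei (DAPI) channel
    min_nucleus_area: int = 12
    h_depth: float = 2.0


@dataclass
class BandpassConfig:
    sigma_low: float = 1.0    # pass structures above ~3 px
    sigma_high: float = 13.3  # ... and below ~40 px


@dataclass
class FittingConfig:
    sigma0: float = 770.0  # applied stress, Pa (7.7e2 in the loading setup)
    max_iter: int = 500
    gtol: float = 1.0e-10


@dataclass
class StatsConfig:
    n_draws: int = 100_000
    mc_seed: int = 20210618
    alpha: tuple[float, ...] = (0.05, 0.001)
    target_gene: str = "Mmp14"
    reference_gene: str = "Gapdh"
    calibrator: str = "control"


@dataclass
class DemoConfig:
    """Synthetic-study sizes for the end-to-end demo run.

    Effects mirror the study conditions: the short-cycle group (T4,
    2 h on/2 h off) slows colony expansion, shortens F-actin and halves
    Mmp-14 expression; the long-cycle group (T8, 4 h on/4 h off) expands
    faster, proliferates more and quadruples Mmp-14 expression.
    """

    n_creep_samples: int = 3
    creep_duration_min: float = 30.0
    creep_dt_min: float = 3.0
    creep_tau_min: tuple[float, ...] = (6.5, 7.74, 9.0)
    creep_image_shape: tuple[int, int] = (192, 192)
    creep_subset_size: int = 21
    creep_search_radius: int = 6
    replicates: int = 3
    colony_r0: float = 40.0
    growth_rates_px_h: dict = field(
        default_factory=lambda: {"control": 2.0, "T4": 1.2, "T8": 2.8}
    )
    boundary_noise_px: float = 1.5
    n_cells: dict = field(
        default_factory=lambda: {"control": 100, "T4": 100, "T8": 130}
    )
    dead_fraction: float = 0.05
    actin_total_length: dict = field(
        default_factory=lambda: {"control": 1500, "T4": 900, "T8": 1400}
    )
    n_nuclei: int = 12
    fold_changes: dict = field(
        default_factory=lambda: {"control": 1.0, "T4": 0.5, "T8": 4.0}
    )
    ct_noise_sd: float = 0.15


@dataclass
class RunConfig:
    """Everything a full run consumes; see the nested blocks for stage
    parameters. ``groups`` carries the experiment vocabulary: an unloaded
    control, T4 = 2 h on/2 h off, T8 = 4 h on/4 h off compression."""

    groups: tuple[str, ...] = ("control", "T4", "T8")
    pixel_size_um: float | None = None
    frame_times_h: tuple[float, ...] = (0.0, 8.0, 16.0, 24.0)
    seed: int = 0
    outdir: str = "results"
    dic: DicConfig = field(default_factory=DicConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    bandpass: BandpassConfig = field(default_factory=BandpassConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    demo: DemoConfig = field(default_factory=DemoConfig)


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if isinstance(value, dict) and isinstance(ftype, str) and ftype in {
            "DicConfig", "SegmentationConfig", "BandpassConfig",
            "FittingConfig", "StatsConfig", "DemoConfig",
        }:
            kwargs[name] = _build(globals()[ftype], value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus flat overrides.

    Overrides (e.g. from CLI flags) take precedence over the file, which
    takes precedence over defaults. Unknown keys anywhere are an error.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a mapping")
            data = loaded
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return _build(RunConfig, data, "")


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the full configuration."""
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
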