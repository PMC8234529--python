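"""End-to-end runs: synthetic study generation, stage dispatch, provenance.

``run_demo`` fabricates a complete synthetic study (creep imaging, colony
time-lapses for three compression groups, live/dead and actin scenes, a Ct
table), pushes every dataset through the corresponding analysis stage and
writes tidy CSV tables plus a JSON run manifest. Given the same
configuration and seed the output bytes are identical.

``run_stage`` runs one named stage on user-supplied input files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assay_stats import dunnett_test, fold_change, significance_stars
from .cell_quant import (
    count_live_cells,
    count_nuclei,
    measure_actin_scene,
    measure_colony_series,
    viability,
)
from .config import RunConfig, config_hash
from .core import ImageSequence, load_frame, load_sequence, save_sequence
from .creep_model import KelvinVoigtParams, creep_batch
from .synth_data import (
    ColonySeriesSpec,
    CtTableSpec,
    FilamentSceneSpec,
    LiveDeadSpec,
    SpecklePairSpec,
    gen_colony_series,
    gen_creep_sequence,
    gen_ct_table,
    gen_filament_scene,
    gen_livedead_pair,
)

log = logging.getLogger("melapress")

STAGES = ("creep", "progress", "viability", "actin", "stats")


@dataclass
class ResultsBundle:
    tables: dict[str, pd.DataFrame]
    provenance: dict

    def __getitem__(self, key: str) -> pd.DataFrame:
        return self.tables[key]


def _write_table(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    """CSV with a provenance comment header (config hash, seed, version)."""
    header = (
        f"# melapress={provenance['version']} config_hash={provenance['config_hash']}"
        f" seed={provenance['seed']}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the provenance comment line."""
    return pd.read_csv(path, comment="#")


def _child_seed(seed: int, stream: int) -> int:
    # stable derived seeds, kept below 2**31
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def run_demo(seed: int, outdir: str | Path, cfg: RunConfig | None = None,
             save_images: bool = False) -> ResultsBundle:
    """Generate a synthetic three-group study and run every stage.

    Returns the tidy tables and writes them (plus ``manifest.json``) under
    ``outdir``. ``save_images`` additionally exports the generated image
    stacks as multi-page TIFFs with JSON sidecars.
    """
    cfg = cfg or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    demo = cfg.demo
    prov = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": int(seed),
        "config": dataclasses.asdict(cfg),
    }
    tables: dict[str, pd.DataFrame] = {}
    t_start = time.perf_counter()

    # ----- creep stage ------------------------------------------------
    t0 = time.perf_counter()
    sigma0 = cfg.fitting.sigma0
    sequences = []
    for i, tau in enumerate(demo.creep_tau_min):
        e1 = sigma0 / 0.010          # elastic jump 1.0% strain
        e2 = sigma0 / 0.015          # creep amplitude 1.5% strain
        kv = KelvinVoigtParams(sigma0, e1, e2, tau * e2)
        spec = SpecklePairSpec(
            image_shape=demo.creep_image_shape,
            noise_sd=0.01,
            seed=_child_seed(seed, 100 + i),
            subset_size=demo.creep_subset_size,
            search_radius=demo.creep_search_radius,
        )
        cs = gen_creep_sequence(kv, demo.creep_duration_min, demo.creep_dt_min, spec)
        sequences.append(cs.sequence)
        if save_images:
            save_sequence(cs.sequence, outdir / f"creep_{i}.tif",
                          {"tau_true_min": kv.tau, "gamma_true": cs.gamma_true.tolist()})
    fits, summary = creep_batch(
        sequences, sigma0,
        subset_size=demo.creep_subset_size, spacing=cfg.dic.spacing,
        search_radius=demo.creep_search_radius, convention=cfg.dic.convention,
    )
    tables["creep_fits"] = fits
    tables["creep_summary"] = pd.DataFrame([summary])
    log.info("stage creep: %d sequences in %.1fs", len(sequences), time.perf_counter() - t0)

    # ----- progression stage ------------------------------------------
    t0 = time.perf_counter()
    prog_rows, rate_rows = [], []
    for g, gi in zip(cfg.groups, range(len(cfg.groups))):
        rate = demo.growth_rates_px_h[g]
        for rep in range(demo.replicates):
            series = gen_colony_series(ColonySeriesSpec(
                r0=demo.colony_r0, growth_rate=rate,
                frame_times=cfg.frame_times_h,
                boundary_noise=demo.boundary_noise_px,
                seed=_child_seed(seed, 200 + 10 * gi + rep),
            ))
            m = measure_colony_series(series.sequence.times, series.sequence.frames,
                                      pixel_size_um=cfg.pixel_size_um,
                                      invert=cfg.segmentation.invert)
            for t, a, l in zip(m.times, m.areas, m.l_t):
                prog_rows.append({"group": g, "replicate": rep, "time_h": t,
                                  "area": a, "l_t": l})
            rate_rows.append({"group": g, "replicate": rep,
                              "rate": m.rate, "intercept": m.intercept})
    tables["progression"] = pd.DataFrame(prog_rows)
    tables["progression_rates"] = pd.DataFrame(rate_rows)
    log.info("stage progress: done in %.1fs", time.perf_counter() - t0)

    # ----- viability stage ---------------------------------------------
    t0 = time.perf_counter()
    via_rows = []
    for gi, g in enumerate(cfg.groups):
        for rep in range(demo.replicates):
            scene = gen_livedead_pair(LiveDeadSpec(
                n_cells=demo.n_cells[g], dead_fraction=demo.dead_fraction,
                seed=_child_seed(seed, 300 + 10 * gi + rep),
            ))
            nl = count_live_cells(scene.green, cfg.segmentation.cell_diameter,
                                  cfg.segmentation.blob_threshold)
            nd = count_nuclei(scene.red, cfg.segmentation.nuclei_binarization,
                              cfg.segmentation.min_nucleus_area, cfg.segmentation.h_depth)
            via_rows.append({"group": g, "replicate": rep, "NL": nl, "ND": nd})
    via = pd.DataFrame(via_rows)
    control_total = float(
        (via.loc[via.group == cfg.groups[0], "NL"]
         + via.loc[via.group == cfg.groups[0], "ND"]).mean()
    )
    metrics = [viability(r.NL, r.ND, control_total) for r in via.itertuples()]
    via["dcr_printed"] = [m.dcr_printed for m in metrics]
    via["dead_fraction"] = [m.dead_fraction for m in metrics]
    via["cpr"] = [m.cpr for m in metrics]
    tables["viability"] = via
    log.info("stage viability: done in %.1fs", time.perf_counter() - t0)

    # ----- actin stage --------------------------------------------------
    t0 = time.perf_counter()
    actin_rows = []
    for gi, g in enumerate(cfg.groups):
        for rep in range(demo.replicates):
            scene = gen_filament_scene(FilamentSceneSpec(
                total_length=demo.actin_total_length[g], n_nuclei=demo.n_nuclei,
                seed=_child_seed(seed, 400 + 10 * gi + rep),
            ))
            m = measure_actin_scene(scene.actin, scene.nuclei,
                                    cfg.bandpass.sigma_low, cfg.bandpass.sigma_high,
                                    cfg.segmentation.dapi_binarization)
            actin_rows.append({"group": g, "replicate": rep,
                               "Lf": m.lf, "Nn": m.nn, "LFC": m.lfc})
    tables["actin"] = pd.DataFrame(actin_rows)
    log.info("stage actin: done in %.1fs", time.perf_counter() - t0)

    # ----- expression + statistics --------------------------------------
    t0 = time.perf_counter()
    ct = gen_ct_table(CtTableSpec(
        group_fold_changes=demo.fold_changes, calibrator=cfg.stats.calibrator,
        ct_noise_sd=demo.ct_noise_sd, replicates=demo.replicates,
        target_gene=cfg.stats.target_gene, reference_gene=cfg.stats.reference_gene,
        seed=_child_seed(seed, 500),
    ))
    tables["ct_table"] = ct
    fc = fold_change(ct, cfg.stats.target_gene, cfg.stats.reference_gene,
                     cfg.stats.calibrator)
    tables["fold_change"] = fc.per_replicate
    tables["fold_change_summary"] = fc.per_group

    dun_rows = []
    endpoints = {
        "fold": fc.per_replicate.rename(columns={"fold": "value"})[["group", "value"]],
        "cpr": via.rename(columns={"cpr": "value"})[["group", "value"]],
        "dcr_printed": via.rename(columns={"dcr_printed": "value"})[["group", "value"]],
        "lfc": tables["actin"].rename(columns={"LFC": "value"})[["group", "value"]],
        "progression_rate": tables["progression_rates"].rename(
            columns={"rate": "value"})[["group", "value"]],
    }
    for name, df in endpoints.items():
        res = dunnett_test(df, control=cfg.stats.calibrator,
                           alpha=cfg.stats.alpha, n_draws=cfg.stats.n_draws,
                           seed=cfg.stats.mc_seed)
        for r in res.table.itertuples():
            dun_rows.append({
                "endpoint": name, "group": r.group, "mean_diff": r.mean_diff,
                "t": r.t, "p_adjusted": r.p_adjusted,
                "stars": significance_stars(r.p_adjusted, tuple(cfg.stats.alpha)),
            })
    tables["dunnett"] = pd.DataFrame(dun_rows)
    log.info("stage stats: done in %.1fs", time.perf_counter() - t0)

    for name, df in tables.items():
        _write_table(df, outdir / f"{name}.csv", prov)
    (outdir / "manifest.json").write_text(json.dumps(prov, indent=1, default=str))
    log.info("demo complete in %.1fs -> %s", time.perf_counter() - t_start, outdir)
    return ResultsBundle(tables, prov)


# --------------------------------------------------------------------------
# single-stage dispatch on user files
# --------------------------------------------------------------------------

def _load_sequences(paths: list[Path]) -> list[ImageSequence]:
    seqs = []
    for p in paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
        seqs.append(load_sequence(p))
    return seqs


def run_stage(stage: str, cfg: RunConfig, inputs: list[str | Path],
              outdir: str | Path, seed: int = 0) -> pd.DataFrame:
    """Run one pipeline stage on input files and write its CSV table.

    Input conventions: ``creep``/``progress`` take multi-page TIFF
    sequences; ``viability`` takes alternating green,red frames;
    ``actin`` alternating actin,nuclei frames; ``stats`` a Ct CSV with
    columns group, sample, gene, ct.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}: valid stages are {', '.join(STAGES)}")
    cfg = cfg or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [Path(p) for p in inputs]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    prov = {"version": __version__, "config_hash": config_hash(cfg), "seed": int(seed)}
    t0 = time.perf_counter()

    if stage == "creep":
        seqs = _load_sequences(paths)
        table, summary = creep_batch(
            seqs, cfg.fitting.sigma0,
            subset_size=cfg.dic.subset_size, spacing=cfg.dic.spacing,
            search_radius=cfg.dic.search_radius, convention=cfg.dic.convention,
        )
        table = pd.concat([table, pd.DataFrame([{
            "sample": "median", "tau_min": summary["median_tau_min"],
            "pearson_r": summary["median_pearson_r"],
        }])], ignore_index=True)
    elif stage == "progress":
        rows = []
        for i, seq in enumerate(_load_sequences(paths)):
            m = measure_colony_series(seq.times, seq.frames,
                                      pixel_size_um=cfg.pixel_size_um,
                                      invert=cfg.segmentation.invert)
            for t, a, l in zip(m.times, m.areas, m.l_t):
                rows.append({"sample": i, "time": t, "area": a, "l_t": l,
                             "rate": m.rate})
        table = pd.DataFrame(rows)
    elif stage == "viability":
        if len(paths) % 2:
            raise ValueError("viability needs green,red frame pairs")
        rows = []
        for i in range(0, len(paths), 2):
            green, red = load_frame(paths[i]), load_frame(paths[i + 1])
            nl = count_live_cells(green, cfg.segmentation.cell_diameter,
                                  cfg.segmentation.blob_threshold)
            nd = count_nuclei(red, cfg.segmentation.nuclei_binarization,
                              cfg.segmentation.min_nucleus_area, cfg.segmentation.h_depth)
            v = viability(nl, nd)
            rows.append({"pair": i // 2, "NL": nl, "ND": nd,
                         "dcr_printed": v.dcr_printed,
                         "dead_fraction": v.dead_fraction})
        table = pd.DataFrame(rows)
    elif stage == "actin":
        if len(paths) % 2:
            raise ValueError("actin needs actin,nuclei frame pairs")
        rows = []
        for i in range(0, len(paths), 2):
            m = measure_actin_scene(load_frame(paths[i]), load_frame(paths[i + 1]),
                                    cfg.bandpass.sigma_low, cfg.bandpass.sigma_high,
                                    cfg.segmentation.dapi_binarization)
            rows.append({"pair": i // 2, "Lf": m.lf, "Nn": m.nn, "LFC": m.lfc})
        table = pd.DataFrame(rows)
    else:  # stats
        ct = read_table(paths[0])
        fc = fold_change(ct, cfg.stats.target_gene, cfg.stats.reference_gene,
                         cfg.stats.calibrator)
        res = dunnett_test(
            fc.per_replicate.rename(columns={"fold": "value"})[["group", "value"]],
            control=cfg.stats.calibrator, alpha=cfg.stats.alpha,
            n_draws=cfg.stats.n_draws, seed=cfg.stats.mc_seed,
        )
        res.table["stars"] = [significance_stars(p, tuple(cfg.stats.alpha))
                              for p in res.table["p_adjusted"]]
        table = fc.per_replicate.merge(res.table, on="group", how="left")

    _write_table(table, outdir / f"{stage}.csv", prov)
    log.info("stage %s: %d rows in %.1fs", stage, len(table), time.perf_counter() - t0)
    return table
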