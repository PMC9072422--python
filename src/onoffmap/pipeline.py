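"""End-to-end driver: simulate -> kernels -> native domains -> CCA ->
canonical maps -> neighbourhood model, with per-stage seeding, caching and a
run manifest."""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cca as cca_mod
from . import domains as dom
from . import kernels as ker
from . import rfmodel as rfm
from . import synthetic as syn
from .errors import StageError, ValidationError
from .io import (PipelineConfig, file_digest, read_arrays, read_cells,
                 stage_seeds, write_arrays, write_cells)


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    seeds: dict
    stages: dict = field(default_factory=dict)   # stage -> {files: {path: digest}, seconds, cached}
    warnings: list = field(default_factory=list)

    def record(self, stage: str, files: list[Path], seconds: float,
               cached: bool) -> None:
        self.stages[stage] = dict(
            files={str(f.name): file_digest(f) for f in files},
            seconds=round(seconds, 3), cached=cached)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            dict(config_hash=self.config_hash, seeds=self.seeds,
                 stages=self.stages, warnings=self.warnings), indent=1))


def _stage_marker(out: Path, stage: str) -> Path:
    return out / f".{stage}.stage.json"


def _stage_cached(out: Path, stage: str, cfg_hash: str, files: list[Path]) -> bool:
    marker = _stage_marker(out, stage)
    if not marker.exists() or not all(f.exists() for f in files):
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == cfg_hash
    except (json.JSONDecodeError, OSError):
        return False


def run_pipeline(config: PipelineConfig, out_dir=None) -> RunManifest:
    """Run the full analysis under ``config``; returns the manifest.

    Stages whose outputs already exist under the same configuration hash are
    resumed from disk rather than recomputed.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.master_seed)
    cfg_hash = config.config_hash()
    manifest = RunManifest(config_hash=cfg_hash, seeds=seeds)
    config.save(out / "config.yaml")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _stage_simulate(config, seeds, out, cfg_hash, manifest)
        cells, kset = _stage_kernels(config, out, cfg_hash, manifest)
        _stage_domains(config, seeds, out, cfg_hash, manifest, cells)
        model, mono = _stage_cca(config, out, cfg_hash, manifest, cells)
        _stage_canonical_maps(config, seeds, out, cfg_hash, manifest, model, mono)
        _stage_rfmodel(config, out, cfg_hash, manifest, cells, kset)
    manifest.warnings = sorted({str(w.message) for w in caught})
    manifest.save(out / "manifest.json")
    return manifest


def _finish(out, stage, cfg_hash, manifest, files, t0):
    _stage_marker(out, stage).write_text(json.dumps(dict(config_hash=cfg_hash)))
    manifest.record(stage, files, time.perf_counter() - t0, cached=False)


def _stage_simulate(cfg, seeds, out, cfg_hash, manifest):
    stage = "simulate"
    files = [out / "stimulus.npz", out / "activity.npz", out / "truth_cells.csv",
             out / "truth_maps.npz"]
    t0 = time.perf_counter()
    if _stage_cached(out, stage, cfg_hash, files):
        manifest.record(stage, files, time.perf_counter() - t0, cached=True)
        return
    try:
        bias = syn.make_bias_field(amplitude=cfg.bias_amplitude,
                                   n_blobs=cfg.bias_n_blobs,
                                   length_scale=cfg.bias_length_scale,
                                   seed=seeds[stage])
        retin = syn.default_retinotopy(scatter_sigma_on=cfg.scatter_sigma_on,
                                       scatter_sigma_off=cfg.scatter_sigma_off)
        pop = syn.sample_population(bias, retin, n_on=cfg.n_on, n_off=cfg.n_off,
                                    n_simple=cfg.n_simple, n_complex=cfg.n_complex,
                                    rf_sigma_deg=cfg.rf_sigma_deg,
                                    seed=seeds[stage])
        stim = syn.make_stimulus(n_stimuli=cfg.n_stimuli, p_bright=cfg.p_bright,
                                 p_dark=cfg.p_dark, frame_rate=cfg.frame_rate,
                                 seed=seeds[stage])
        resp = syn.simulate_responses(pop, stim, gain=cfg.gain,
                                      baseline=cfg.baseline,
                                      delay_frames=cfg.delay_frames,
                                      seed=seeds[stage])
        write_arrays(out / "stimulus.npz",
                     dict(frames=stim.frames,
                          onset_frame_index=stim.onset_frame_index),
                     stim.scalar_metadata())
        write_arrays(out / "activity.npz", dict(activity=resp.activity),
                     dict(frame_rate=resp.frame_rate))
        truth = pop.cells.rename(columns={"true_class": "cell_class"})
        truth.to_csv(out / "truth_cells.csv", index=False)
        write_arrays(out / "truth_maps.npz",
                     dict(on_maps=pop.on_maps, off_maps=pop.off_maps))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    _finish(out, stage, cfg_hash, manifest, files, t0)


def _load_stimulus(out: Path) -> syn.StimulusEnsemble:
    arrays, meta = read_arrays(out / "stimulus.npz",
                               required=("frames", "onset_frame_index"))
    return syn.StimulusEnsemble(
        frames=arrays["frames"], onset_frame_index=arrays["onset_frame_index"],
        frame_rate=meta.get("frame_rate", syn.FRAME_RATE),
        tile_deg=meta.get("tile_deg", syn.TILE_DEG),
        p_bright=meta.get("p_bright", 0.1), p_dark=meta.get("p_dark", 0.1))


def _stage_kernels(cfg, out, cfg_hash, manifest):
    stage = "kernels"
    files = [out / "cells.csv", out / "kernels.npz"]
    t0 = time.perf_counter()
    try:
        stim = _load_stimulus(out)
        arrays, meta = read_arrays(out / "activity.npz", required=("activity",))
        resp = syn.ResponseMatrix(activity=arrays["activity"],
                                  frame_rate=meta.get("frame_rate", syn.FRAME_RATE))
        if _stage_cached(out, stage, cfg_hash, files):
            cells = read_cells(out / "cells.csv")
            karr, _ = read_arrays(out / "kernels.npz", required=("on", "off"))
            kset = ker.KernelSet(on=karr["on"], off=karr["off"],
                                 tile_deg=stim.tile_deg)
            manifest.record(stage, files, time.perf_counter() - t0, cached=True)
            return cells, kset
        truth = pd.read_csv(out / "truth_cells.csv")
        cells, kset = ker.classify_population(
            resp, stim, max_delay=cfg.max_delay,
            norm_threshold=cfg.norm_threshold, ve_threshold=cfg.ve_threshold,
            simple_threshold=cfg.simple_threshold,
            cortical=truth[["cell_id", "x1", "x2", "x3"]])
        write_cells(cells, out / "cells.csv")
        write_arrays(out / "kernels.npz", dict(on=kset.on, off=kset.off),
                     dict(tile_deg=kset.tile_deg))
    except (ValidationError, FileNotFoundError) as exc:
        raise StageError(stage, str(exc)) from exc
    _finish(out, stage, cfg_hash, manifest, files, t0)
    return cells, kset


def _stage_domains(cfg, seeds, out, cfg_hash, manifest, cells):
    stage = "domains"
    files = [out / "fluctuation_native.npz", out / "domains.csv"]
    t0 = time.perf_counter()
    if _stage_cached(out, stage, cfg_hash, files):
        manifest.record(stage, files, time.perf_counter() - t0, cached=True)
        return
    try:
        grid = dom.native_grid(spacing=cfg.native_spacing_um,
                               sigma=cfg.sigma_native_um)
        on_pts = cells.loc[cells.cell_class == "ON", ["x1", "x2"]].to_numpy()
        off_pts = cells.loc[cells.cell_class == "OFF", ["x1", "x2"]].to_numpy()
        fluct = dom.fluctuation_map(on_pts, off_pts, cfg.sigma_native_um, grid,
                                    n_shuffles=cfg.n_shuffles, alpha=cfg.alpha,
                                    seed=seeds[stage])
        dset = dom.extract_level_sets(fluct)
        write_arrays(out / "fluctuation_native.npz",
                     dict(values=fluct.values, null_low=fluct.null_low,
                          null_high=fluct.null_high,
                          sig_pos=fluct.sig_pos.astype(np.uint8),
                          sig_neg=fluct.sig_neg.astype(np.uint8)),
                     dict(alpha=fluct.alpha, n_shuffles=fluct.n_shuffles,
                          sigma=fluct.sigma, pointwise_significance=True))
        dset.table().to_csv(out / "domains.csv", index=False)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    _finish(out, stage, cfg_hash, manifest, files, t0)


def _mono_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Mono-contrast cells with one visual centre each (ON or OFF)."""
    mono = cells[cells.cell_class.isin(["ON", "OFF"])].copy()
    is_on = mono.cell_class == "ON"
    mono["y1"] = np.where(is_on, mono.on_y1, mono.off_y1)
    mono["y2"] = np.where(is_on, mono.on_y2, mono.off_y2)
    return mono


def _stage_cca(cfg, out, cfg_hash, manifest, cells):
    stage = "cca"
    files = [out / "cca_model.json", out / "cells_canonical.csv"]
    t0 = time.perf_counter()
    try:
        mono = _mono_table(cells)
        if _stage_cached(out, stage, cfg_hash, files):
            model = cca_mod.CcaModel.from_json(out / "cca_model.json")
            mono = read_cells(out / "cells_canonical.csv")
            manifest.record(stage, files, time.perf_counter() - t0, cached=True)
            return model, mono
        model = cca_mod.fit_cca(mono[["x1", "x2", "x3"]].to_numpy(),
                                mono[["y1", "y2"]].to_numpy())
        xh = cca_mod.transform(mono[["x1", "x2", "x3"]].to_numpy(), model,
                               "cortical")
        yh = cca_mod.transform(mono[["y1", "y2"]].to_numpy(), model, "visual")
        mono[["xhat1", "xhat2"]] = xh
        mono[["yhat1", "yhat2"]] = yh
        model.to_json(out / "cca_model.json")
        write_cells(mono, out / "cells_canonical.csv")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    _finish(out, stage, cfg_hash, manifest, files, t0)
    return model, mono


def _stage_canonical_maps(cfg, seeds, out, cfg_hash, manifest, model, mono):
    stage = "canonical_maps"
    files = [out / "map_correlation.json"]
    t0 = time.perf_counter()
    if _stage_cached(out, stage, cfg_hash, files):
        manifest.record(stage, files, time.perf_counter() - t0, cached=True)
        return
    try:
        grid = dom.canonical_grid(limit=cfg.canonical_limit,
                                  spacing=cfg.canonical_spacing)
        labels = (mono.cell_class == "ON").to_numpy()
        mc = cca_mod.map_correlation(
            labels, mono[["xhat1", "xhat2"]].to_numpy(),
            mono[["yhat1", "yhat2"]].to_numpy(), sigma=cfg.sigma_canonical,
            grid=grid, n_shuffles=cfg.n_shuffles, seed=seeds[stage])
        (out / "map_correlation.json").write_text(json.dumps(dict(
            r=mc.r, p_value=mc.p_value, n_shuffles=mc.n_shuffles,
            rho=[float(v) for v in model.rho], grid="full"), indent=1))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    _finish(out, stage, cfg_hash, manifest, files, t0)


def _stage_rfmodel(cfg, out, cfg_hash, manifest, cells, kset):
    stage = "rfmodel"
    files = [out / "fits.csv", out / "rf_summary.json"]
    t0 = time.perf_counter()
    if _stage_cached(out, stage, cfg_hash, files):
        manifest.record(stage, files, time.perf_counter() - t0, cached=True)
        return
    try:
        mono = cells[cells.cell_class.isin(["ON", "OFF"])]
        simple = cells[cells.cell_class == "SIMPLE"]
        mono_maps = {}
        for _, row in mono.iterrows():
            pol = row.cell_class
            st = kset.stack(int(row.cell_id), pol)
            mono_maps[int(row.cell_id)] = st.peak_map
        simple_rfs = {int(r.cell_id): ker.simple_rf(kset.stack(int(r.cell_id), "ON"),
                                                    kset.stack(int(r.cell_id), "OFF"))
                      for _, r in simple.iterrows()}
        summary: dict = {}
        if len(simple) and len(mono):
            on_maps = np.stack([mono_maps[i] for i in
                                mono.loc[mono.cell_class == "ON", "cell_id"]])
            off_maps = np.stack([mono_maps[i] for i in
                                 mono.loc[mono.cell_class == "OFF", "cell_id"]])
            srf = np.stack(list(simple_rfs.values()))
            mrs = rfm.mean_rf_comparison(on_maps, off_maps, srf,
                                         seed=stage_seeds(cfg.master_seed)["rfmodel"])
            summary["mean_rf_r"] = mrs.r_mean
            summary["mean_rf_p"] = mrs.p_value
            k_feasible = min(cfg.knn_k, (mono.cell_class == "ON").sum(),
                             (mono.cell_class == "OFF").sum())
            fits = rfm.fit_neighborhood_model(simple, simple_rfs, mono,
                                              mono_maps, k=int(k_feasible))
            fc = np.array([f.fit_corr for f in fits])
            summary["median_fit_corr"] = float(np.nanmedian(fc))
            sparsity = rfm.weight_sparsity(fits)
            summary["median_n90_on"] = float(np.median(sparsity["ON"]["n90"]))
            summary["median_n90_off"] = float(np.median(sparsity["OFF"]["n90"]))
            rows = []
            for f in fits:
                for pol in ("ON", "OFF"):
                    for nid, d, w in zip(f.neighbor_ids[pol], f.distances[pol],
                                         f.weights[pol]):
                        rows.append(dict(cell_id=f.cell_id, k=f.k, polarity=pol,
                                         neighbor_id=int(nid), distance_um=d,
                                         weight=w, fit_corr=f.fit_corr))
            pd.DataFrame(rows).to_csv(out / "fits.csv", index=False)
        else:
            pd.DataFrame(columns=["cell_id", "k", "polarity", "neighbor_id",
                                  "distance_um", "weight", "fit_corr"]
                         ).to_csv(out / "fits.csv", index=False)
        (out / "rf_summary.json").write_text(json.dumps(summary, indent=1))
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc
    _finish(out, stage, cfg_hash, manifest, files, t0)
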