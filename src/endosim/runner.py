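"""Reproducible experiment runner and output serialization."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import metrics as sm
from .config import ExperimentConfig, save_config
from .optics import probe_model
from .scanner import NoiseModel, TSeries, render_tseries
from .scene import place_neurons, simulate_activity
from .segmentation import ROISet, segment_and_extract

__all__ = ["simulate_fov", "run_fig4_experiment", "write_outputs"]


def simulate_fov(cfg: ExperimentConfig, probe: str, seed: int):
    """One FOV end to end: volume -> activity -> rendered t-series.

    The volume and activity depend only on ``seed`` (not on the probe), so
    corrected/uncorrected renders of the same seed share ground truth.
    """
    ss = np.random.SeedSequence(seed)
    rng_scene, rng_act, rng_render = (np.random.default_rng(s) for s in ss.spawn(3))
    vol = place_neurons(
        cfg.volume_extent_um, cfg.density_per_mm3, cfg.radius_mean_um,
        cfg.radius_sd_um, cfg.shell_mean_um, cfg.shell_sd_um, rng_scene)
    act = simulate_activity(
        vol.n_neurons, cfg.n_frames, cfg.frame_rate_hz, cfg.rho, cfg.gamma,
        cfg.common_input_probability, cfg.common_fraction, cfg.hill, rng_act)
    ts = render_tseries(
        vol, act, probe_model(probe), NoiseModel(), cfg.n_frames, rng_render,
        cfg.fov_size_um, cfg.pixel_size_um, cfg.edge_radius_um)
    return vol, act, ts


def analyze_fov(cfg: ExperimentConfig, vol, act, ts: TSeries,
                snr_threshold: float | None = None) -> dict:
    """Segmentation + metrics for one rendered FOV."""
    thr = cfg.snr_threshold if snr_threshold is None else snr_threshold
    # segment without the peak-SNR filter so the full threshold sweep can be
    # read off the table; per-ROI metrics below honor ``thr``
    all_rois, traces = segment_and_extract(
        ts, cfg.min_px, cfg.overlap_frac, snr_threshold=None)
    kept = [i for i, r in enumerate(all_rois) if r.peak_snr > thr]
    out = dict(probe=ts.probe, n_rois=len(kept), snr_threshold=thr,
               roi_table=None, pairs=None, snr=[], source_corr=[], contam=[])
    if len(all_rois) == 0 or traces is None:
        return out
    rows = []
    for i, roi in enumerate(all_rois):
        raw_z = sm.zscore(traces.raw[i])
        cdf_z = sm.zscore(traces.calcium[i])
        try:
            snr = sm.snr_power_ratio(raw_z, cdf_z)
        except ValueError:
            snr = np.nan
        matches = sm.ground_truth_match(
            traces.calcium[i], act.calcium[list(roi.source_neuron_ids)])
        src = matches[0][1] if matches else np.nan
        con = matches[1][1] if len(matches) > 1 else np.nan
        rows.append(dict(roi_id=i, n_px=roi.n_px, dist_r_um=roi.dist_r_um,
                         peak_snr=roi.peak_snr, snr=snr, source_corr=src,
                         second_corr=con,
                         n_sources=len(roi.source_neuron_ids)))
        if roi.peak_snr > thr:
            out["snr"].append(snr)
            out["source_corr"].append(src)
            if not np.isnan(con):
                out["contam"].append(con)
    out["roi_table"] = pd.DataFrame(rows)

    if len(kept) >= 2:
        positions = np.array([all_rois[i].centroid_um for i in kept])
        pairs = sm.normalized_pairwise_correlation(
            positions, traces.calcium[kept], cfg.nearby_max_um,
            cfg.distant_min_um, cfg.radial_bins, (0.0, cfg.edge_radius_um))
        out["pairs"] = pairs
    return out


def run_fig4_experiment(cfg: ExperimentConfig,
                        rng: np.random.Generator | None = None) -> dict:
    """Matched corrected/uncorrected simulation sweep.

    Simulates ``cfg.n_fov`` volumes, renders each with both probe types on
    the same ground truth, segments across the peak-SNR threshold sweep, and
    accumulates ROI counts, SNR distributions, ground-truth correlations and
    the normalized pairwise-correlation regression per probe.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    fov_seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in np.random.SeedSequence(cfg.seed).spawn(cfg.n_fov)]
    results = {p: dict(pairs=[], snr=[], source_corr=[], contam=[],
                       roi_counts={t: [] for t in cfg.snr_thresholds})
               for p in ("corrected", "uncorrected")}
    for seed in fov_seeds:
        for probe in ("corrected", "uncorrected"):
            vol, act, ts = simulate_fov(cfg, probe, seed)
            res = analyze_fov(cfg, vol, act, ts)
            acc = results[probe]
            acc["snr"].extend([s for s in res["snr"] if np.isfinite(s)])
            acc["source_corr"].extend([s for s in res["source_corr"] if np.isfinite(s)])
            acc["contam"].extend(res["contam"])
            if res["pairs"] is not None:
                acc["pairs"].append(res["pairs"])
            if res["roi_table"] is not None:
                for t in cfg.snr_thresholds:
                    acc["roi_counts"][t].append(
                        int((res["roi_table"]["peak_snr"] > t).sum()))

    summary = {}
    for probe, acc in results.items():
        entry = dict(
            mean_snr=float(np.mean(acc["snr"])) if acc["snr"] else np.nan,
            mean_source_corr=float(np.mean(acc["source_corr"])) if acc["source_corr"] else np.nan,
            mean_second_corr=float(np.mean(acc["contam"])) if acc["contam"] else np.nan,
            roi_counts={t: acc["roi_counts"][t] for t in cfg.snr_thresholds},
        )
        if acc["pairs"]:
            pairs = pd.concat(acc["pairs"], ignore_index=True)
            if len(pairs) >= 3:
                slope, p = sm.slope_permutation_test(
                    pairs["dist_r_um"].to_numpy(),
                    pairs["normalized_correlation"].to_numpy(),
                    n_perm=cfg.n_perm, rng=rng)
                entry.update(slope=slope, slope_p=p, n_pairs=len(pairs))
            entry["pair_table"] = pairs
        summary[probe] = entry
    return summary


def write_outputs(objects: dict, out_dir: str | Path) -> list[Path]:
    """Serialize run products: TIFF stacks, CSV tables, JSON summaries, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in objects.items():
        if isinstance(obj, TSeries):
            path = out / f"{name}.tif"
            tifffile.imwrite(path, obj.frames.astype(np.float32))
            written.append(path)
            prov = pd.DataFrame(dict(pixel=obj.contrib_pixel,
                                     neuron_id=obj.contrib_neuron,
                                     n_voxels=obj.contrib_voxels))
            ppath = out / f"{name}_provenance.csv"
            prov.to_csv(ppath, index=False)
            written.append(ppath)
        elif isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False)
            written.append(path)
        elif isinstance(obj, ExperimentConfig):
            path = out / f"{name}.yaml"
            save_config(obj, path)
            written.append(path)
        elif isinstance(obj, ROISet):
            rows = [dict(roi_id=i, n_px=r.n_px,
                         centroid_x_um=r.centroid_um[0] if r.centroid_um else np.nan,
                         centroid_y_um=r.centroid_um[1] if r.centroid_um else np.nan,
                         dist_r_um=r.dist_r_um, peak_snr=r.peak_snr,
                         source_neuron_ids=";".join(map(str, r.source_neuron_ids)))
                    for i, r in enumerate(obj)]
            path = out / f"{name}.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            written.append(path)
        else:
            path = out / f"{name}.json"
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, default=_json_default)
            written.append(path)
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="list")
    raise TypeError(f"not JSON serializable: {type(o)}")
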