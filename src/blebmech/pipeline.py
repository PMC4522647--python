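"""Batch orchestration: configuration, manifests, stages and summaries.

A run is described by a YAML config with per-stage blocks:

.. code-block:: yaml

    stages: [simulate, afm]
    simulate:
      scenario: control
      seed: 7
      n_cells: 3
      n_curves_per_cell: 10
    afm:
      curves_dir: null        # defaults to the simulate output
      calibration: null
      radius_um: 10.0
      fit_window_nm: 400
      r2_min: 0.9

Stages run in dependency order; every output directory gets exactly one
``manifest.json`` (config hash, input checksums, package version,
per-stage parameters, timestamp), so a run can be reproduced exactly:
deterministic stages bit-identical, stochastic stages identical given
their seeds.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as bio
from .afm import AfmConfig, CellGeometry, analyze_curve, summarize_cell
from .errors import ConfigInvalid, InputMissing, StageFailure, UnknownColumn
from .morphometry import leader_bleb_area_percent, regional_profile, measure_cortex_density
from .ratiometric import enrichment_ratio, fret_pipeline, photoconversion_retention
from .synthetic import SCENARIOS, gen_force_curve

log = logging.getLogger("blebmech")

KNOWN_STAGES = ("simulate", "afm", "morpho", "fret", "photoconv")

__all__ = ["run_pipeline", "summarize_conditions", "build_manifest", "KNOWN_STAGES"]


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(config: Dict, inputs: Sequence[Path]) -> Dict:
    return {
        "software": {"name": "blebmech", "version": __version__},
        "config_sha256": _sha256_text(yaml.safe_dump(config, sort_keys=True)),
        "parameters": config,
        "inputs": [
            {"path": str(p), "sha256": _sha256_file(Path(p))} for p in inputs
        ],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: Dict, out: Path) -> List[Path]:
    scenario = cfg.get("scenario", "control")
    if scenario not in SCENARIOS:
        raise StageFailure("simulate", f"unknown scenario '{scenario}'")
    preset = SCENARIOS[scenario]
    seed = int(cfg.get("seed", 0))
    n_cells = int(cfg.get("n_cells", 1))
    n_curves = int(cfg.get("n_curves_per_cell", 10))
    rng = np.random.default_rng(seed)
    written: List[Path] = []
    curve_dir = out / "curves"
    curve_dir.mkdir(parents=True, exist_ok=True)
    cal = None
    for ci in range(n_cells):
        for ki in range(n_curves):
            curve, truth = gen_force_curve(
                tension=preset["tension"],
                noise_sd_nm=float(cfg.get("noise_sd_nm", 0.5)),
                seed=rng,
                cell_id=f"cell{ci:02d}",
                curve_id=f"curve{ki:02d}",
            )
            cal = curve.calibration
            p = curve_dir / f"cell{ci:02d}_curve{ki:02d}.txt"
            bio.write_force_curve(curve, p, header=f"scenario={scenario}")
            bio.write_json(truth, p.with_suffix(".truth.json"))
            written.append(p)
    bio.write_calibration(cal, out / "calibration.yaml")
    bio.write_json(
        {"scenario": scenario, "seed": seed, "preset": preset,
         "n_cells": n_cells, "n_curves_per_cell": n_curves},
        out / "simulate_truth.json",
    )
    return written


def _stage_afm(cfg: Dict, out: Path, sim_out: Optional[Path]) -> None:
    curves_dir = cfg.get("curves_dir") or (sim_out / "curves" if sim_out else None)
    if curves_dir is None:
        raise StageFailure("afm", "no curves_dir configured and no simulate stage ran")
    curves_dir = Path(curves_dir)
    if not curves_dir.exists():
        raise InputMissing(str(curves_dir))
    cal_path = cfg.get("calibration") or (
        sim_out / "calibration.yaml" if sim_out else None
    )
    if cal_path is None or not Path(cal_path).exists():
        raise InputMissing(str(cal_path))
    cal = bio.read_calibration(cal_path)
    radius_um = cfg.get("radius_um")
    if radius_um is None and sim_out is not None:
        radius_um = bio.read_json(sim_out / "simulate_truth.json")["preset"]["radius_um"]
    if radius_um is None:
        raise StageFailure("afm", "radius_um not configured")
    geometry = CellGeometry(radius=float(radius_um) * 1e-6)
    acfg = AfmConfig(
        fit_window_nm=float(cfg.get("fit_window_nm", 400.0)),
        r2_min=float(cfg.get("r2_min", 0.9)),
    )
    estimates = []
    for p in sorted(curves_dir.glob("*.txt")):
        cell_id = p.stem.split("_")[0]
        curve = bio.read_force_curve(p, cal, cell_id=cell_id, curve_id=p.stem)
        est = analyze_curve(curve, geometry, acfg)
        log.debug("curve %s: accepted=%s reason=%s", p.stem, est.accepted, est.reason)
        estimates.append(est)
    if not estimates:
        raise StageFailure("afm", f"no .txt curves found in {curves_dir}")
    bio.write_estimates_csv(estimates, out / "afm_estimates.csv")
    cells = sorted({e.cell_id for e in estimates})
    summaries = [
        summarize_cell([e for e in estimates if e.cell_id == c], c) for c in cells
    ]
    bio.write_summaries_csv(summaries, out / "afm_cell_summaries.csv")


def _stage_morpho(cfg: Dict, out: Path) -> None:
    from .morphometry import segment_cell_and_bleb

    image = cfg.get("image")
    if image is None:
        raise StageFailure("morpho", "morpho stage needs an 'image' path")
    if not Path(image).exists():
        raise InputMissing(str(image))
    frame = bio.read_image(image, cfg.get("meta"))
    masks_path = cfg.get("masks")
    if masks_path:
        body = bio.read_mask(Path(masks_path) / "body.tif")
        bleb = bio.read_mask(Path(masks_path) / "bleb.tif")
        seg = segment_cell_and_bleb(None, "provided_masks", body_mask=body, bleb_mask=bleb)
    else:
        channel = cfg.get("channel", "fill")
        seg = segment_cell_and_bleb(frame, "threshold_auto", channel=channel)
    rows = {"bleb_area_percent": leader_bleb_area_percent(seg)}
    tasks = cfg.get("tasks", ["area", "profile"])
    if "profile" in tasks and seg.has_bleb:
        prof = regional_profile(frame, seg, channels=cfg.get("channels"))
        recs = []
        for ch, m in prof.mean_intensity.items():
            for b in range(prof.n_bins):
                recs.append({
                    "channel": ch, "bin": b,
                    "mean_intensity": m[b],
                    "normalized_intensity": prof.normalized_intensity[ch][b],
                })
        pd.DataFrame(recs).to_csv(out / "regional_profile.csv", index=False)
    bio.write_json(rows, out / "morpho_summary.json")


def _stage_fret(cfg: Dict, out: Path) -> None:
    import tifffile

    stack_path = cfg.get("stack")
    if stack_path is None or not Path(stack_path).exists():
        raise InputMissing(str(stack_path))
    with open(cfg["meta"]) as fh:
        meta = yaml.safe_load(fh)
    arr = tifffile.imread(stack_path)  # (2, T, H, W) or (T, 2, H, W)
    if arr.ndim != 4:
        raise StageFailure("fret", "expected a 4-D (channel, T, H, W) stack")
    if arr.shape[0] == 2:
        donor, acceptor = arr[meta["donor_channel"]], arr[meta["acceptor_channel"]]
    else:
        donor, acceptor = arr[:, meta["donor_channel"]], arr[:, meta["acceptor_channel"]]
    roi = np.zeros(donor.shape[1:], dtype=bool)
    r0, c0, r1, c1 = meta["background_roi"]
    roi[r0:r1, c0:c1] = True
    from .ratiometric import RatioStack

    stack = RatioStack(
        donor=donor, acceptor=acceptor, background_roi=roi,
        frame_interval=float(meta.get("frame_interval_s", 1.0)),
    )
    maps, rates = fret_pipeline(stack)
    tifffile.imwrite(
        out / "ratio_maps.tif",
        np.stack([m.ratio for m in maps]).astype(np.float32),
    )
    bio.write_json({"bleach_rates_per_s": rates}, out / "fret_rates.json")


def _stage_photoconv(cfg: Dict, out: Path) -> None:
    import tifffile

    stack_path = cfg.get("stack")
    if stack_path is None or not Path(stack_path).exists():
        raise InputMissing(str(stack_path))
    red = tifffile.imread(stack_path)
    masks_path = cfg.get("masks")
    if masks_path is None:
        raise StageFailure("photoconv", "photoconv needs a 'masks' directory")
    body = bio.read_mask(Path(masks_path) / "body.tif")
    bleb = bio.read_mask(Path(masks_path) / "bleb.tif")
    from .morphometry import BlebSegmentation

    seg = BlebSegmentation(body_mask=body, bleb_mask=bleb)
    exch = photoconversion_retention(
        red, seg,
        conversion_frame=int(cfg.get("conversion_frame", 0)),
        frame_interval=float(cfg.get("frame_interval_s", 1.0)),
    )
    bio.write_json({
        "exchange_rate_per_s": exch.rate,
        "equilibrium_fraction": exch.equilibrium_fraction,
        "initial_fraction": exch.initial_fraction,
        "retention_series": exch.retention_series,
    }, out / "photoconv_fit.json")


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config, out_dir) -> Path:
    """Execute the stages a config requests and write one manifest.

    ``config`` is a YAML path or an already-parsed dict.  Raises
    ConfigInvalid / InputMissing / StageFailure; an empty stage list
    writes a manifest-only output and succeeds.
    """
    inputs: List[Path] = []
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        if not cfg_path.exists():
            raise InputMissing(str(cfg_path))
        inputs.append(cfg_path)
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ConfigInvalid("config must be a mapping")
    stages = config.get("stages", [])
    if not isinstance(stages, list):
        raise ConfigInvalid("'stages' must be a list")
    for st in stages:
        if st not in KNOWN_STAGES:
            raise ConfigInvalid(f"unknown stage '{st}' (known: {KNOWN_STAGES})")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setLevel(logging.DEBUG)
    log.addHandler(handler)
    try:
        sim_out: Optional[Path] = None
        for st in stages:
            scfg = config.get(st, {}) or {}
            stage_out = out / st
            stage_out.mkdir(exist_ok=True)
            log.info("running stage %s", st)
            try:
                if st == "simulate":
                    _stage_simulate(scfg, stage_out)
                    sim_out = stage_out
                elif st == "afm":
                    _stage_afm(scfg, stage_out, sim_out)
                elif st == "morpho":
                    _stage_morpho(scfg, stage_out)
                elif st == "fret":
                    _stage_fret(scfg, stage_out)
                elif st == "photoconv":
                    _stage_photoconv(scfg, stage_out)
            except (InputMissing, StageFailure):
                raise
            except Exception as exc:
                raise StageFailure(st, str(exc)) from exc
        manifest = build_manifest(config, inputs)
        bio.write_json(manifest, out / "manifest.json")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_conditions(results, grouping, value_column: str) -> pd.DataFrame:
    """Per-group descriptive statistics matching a Tukey box plot.

    For each group: n, mean, median, SD, quartiles and the Tukey whisker
    bounds (last values within 1.5*IQR of the quartiles).  ``results``
    is a DataFrame or a CSV path; inferential tests are left to the
    caller's statistics environment.
    """
    if isinstance(results, (str, Path)):
        results = pd.read_csv(results)
    if isinstance(grouping, str):
        grouping = [grouping]
    for col in list(grouping) + [value_column]:
        if col not in results.columns:
            raise UnknownColumn(col)
    rows = []
    for keys, grp in results.groupby(list(grouping), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        v = grp[value_column].dropna().to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75]) if v.size else (np.nan,) * 3
        iqr = q3 - q1
        lo_candidates = v[v >= q1 - 1.5 * iqr]
        hi_candidates = v[v <= q3 + 1.5 * iqr]
        rows.append({
            **{g: k for g, k in zip(grouping, keys)},
            "n": int(v.size),
            "mean": float(v.mean()) if v.size else np.nan,
            "median": float(med),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(lo_candidates.min()) if v.size else np.nan,
            "whisker_high": float(hi_candidates.max()) if v.size else np.nan,
        })
    return pd.DataFrame(rows)
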