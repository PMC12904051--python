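"""Configured, logged, resumable orchestration of the correlative workflow.

Stages (dependency order): ``simulate`` → ``segment`` / ``register`` →
``traces`` / ``spots`` → ``integrate``.  Each stage reads only files written
by upstream stages, writes its outputs plus a manifest (parameters, input
and output checksums), and is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import io as cio
from .datatypes import StimulusSchedule
from .errors import DependencyError
from .integrate import (
    afferent_adjacency,
    build_cell_profiles,
    call_expression_class,
    classify_if_positive,
    roc_univariate,
    summarize_dual_tuning,
)
from .masks import save_mask, segment_cells
from .registration import (
    RigidTransform,
    apply_transform,
    register_nonrigid,
    register_rigid,
    registration_qc,
)
from .spots import SpotCallParams, count_spots_per_cell, detect_spots, spots_to_frame
from .synthetic import (
    NerveROI,
    generate_scene,
    render_functional_movie,
    render_histology_rounds,
    render_if_image,
)
from .traces import extract_traces, motion_correct, summaries_to_frame, summarize_responses

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "segment", "register", "traces", "spots", "integrate")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scene": {"n_cells": 12, "image_shape": [192, 192], "n_nerves": 6, "bud_diameter_um": 55.0},
    "schedule": {"tastants": ["sweet", "umami", "sour"], "frame_rate": 1.0},
    "movie": {"noise_sigma": 0.01, "motion_amplitude_px": 1.0, "n_planes": 3},
    "histology": {"n_rounds": 4, "spot_psf_sigma_px": 1.5},
    "segment": {"min_area_px": 50, "max_area_px": 2000},
    "register": {"grid_spacing_px": 32},
    "traces": {"sd_mult": 2.0, "mean_z_cutoff": 1.0},
    "spots": {"min_separation_px": 5.0, "threshold": "auto"},
    "integrate": {"adjacency_radius_um": 2.0, "control_percentile": 95.0},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _require(outdir: Path, stage: str, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise DependencyError(
            f"stage {stage!r} is missing upstream outputs: {missing}; "
            "run the producing stage first"
        )


def _manifest(outdir: Path, stage: str, params: dict, inputs: list, outputs: list, warnings_: list | None = None):
    man = {
        "stage": stage,
        "parameters": params,
        "inputs": {str(p): cio.sha256(p) for p in inputs},
        "outputs": {str(p): cio.sha256(p) for p in outputs},
        "warnings": warnings_ or [],
    }
    p = outdir / f"manifest_{stage}.json"
    p.write_text(json.dumps(man, indent=1, default=str))
    return man


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: dict, outdir: Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    scene_cfg = dict(config.get("scene", {}))
    scene_cfg["image_shape"] = tuple(scene_cfg.get("image_shape", (192, 192)))
    sched_cfg = dict(config.get("schedule", {}))
    schedule = StimulusSchedule.default(
        tastants=tuple(sched_cfg.get("tastants", ("sweet", "umami", "sour"))),
        frame_rate=float(sched_cfg.get("frame_rate", 1.0)),
    )
    scene = generate_scene(seed=seed, **scene_cfg)
    movie = render_functional_movie(scene, schedule, seed=seed + 1, **config.get("movie", {}))
    rounds = render_histology_rounds(scene, seed=seed + 2, **config.get("histology", {}))
    if_image = render_if_image(scene, "CA4", seed=seed + 3)

    outputs = []
    outputs += cio.write_movie(movie, outdir)
    outputs += cio.write_rounds(rounds, outdir)
    outputs += cio.write_scene_truth(scene, outdir)
    outputs.append(cio.write_nerve_rois(scene.nerve_rois, outdir / "nerve_rois.json"))
    if_path = outdir / "if_CA4.tif"
    cio.tifffile.imwrite(if_path, cio.to_uint16(if_image))
    outputs.append(if_path)
    sched_path = outdir / "schedule.yaml"
    sched_path.write_text(yaml.safe_dump(schedule.to_dict()))
    outputs.append(sched_path)
    return _manifest(outdir, "simulate", {**config.get("scene", {}), "seed": seed}, [], outputs)


def stage_segment(config: dict, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "segment", "round1_reporter.tif")
    rep = cio.read_round_image(outdir, 1, "reporter")
    mask = segment_cells(rep, **config.get("segment", {}))
    out = outdir / "masks.tif"
    save_mask(mask, out)
    return _manifest(
        outdir, "segment", config.get("segment", {}), [outdir / "round1_reporter.tif"], [out]
    )


def stage_register(config: dict, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "register", "round1_reporter.tif", "movie_red.tif", "rounds_meta.json")
    params = config.get("register", {})

    movie = cio.read_movie(outdir)
    invivo_ref = movie.red[:, movie.cell_plane].mean(axis=0)
    round1_rep = cio.read_round_image(outdir, 1, "reporter")
    field, _ = register_nonrigid(
        invivo_ref, round1_rep, grid_spacing_px=float(params.get("grid_spacing_px", 32))
    )
    outputs = [cio.write_deformation_field(field, outdir / "warp_field.tif")]

    meta = cio.read_rounds_meta(outdir)
    ref_nuc = cio.read_round_image(outdir, 1, "nuclear")
    qc_rows = []
    for k in range(2, int(meta["n_rounds"]) + 1):
        mov_nuc = cio.read_round_image(outdir, k, "nuclear")
        tf = register_rigid(ref_nuc, mov_nuc)
        p = outdir / f"rigid_round{k}.json"
        tf.to_json(p)
        outputs.append(p)
        aligned = apply_transform(mov_nuc, tf)
        qc = registration_qc(ref_nuc, aligned)
        qc_rows.append(
            {
                "round": k,
                "pearson_r": qc.pearson_r,
                "max_peak_offset_px": qc.max_peak_offset_px,
            }
        )
    qc_path = outdir / "registration_qc.csv"
    pd.DataFrame(qc_rows).to_csv(qc_path, index=False)
    outputs.append(qc_path)
    inputs = [outdir / "round1_reporter.tif", outdir / "round1_nuclear.tif"]
    return _manifest(outdir, "register", params, inputs, outputs)


def stage_traces(config: dict, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "traces", "movie_green.tif", "masks.tif", "warp_field.tif", "nerve_rois.json")
    params = config.get("traces", {})

    movie = cio.read_movie(outdir)
    movie, shifts = motion_correct(movie)
    masks_fixed = cio.tifffile.imread(outdir / "masks.tif").astype(np.int32)
    field = cio.read_deformation_field(outdir / "warp_field.tif")
    # masks live in the fixed round-1 frame; pull them into the in-vivo frame
    masks_invivo = apply_transform(masks_fixed, field, is_labels=True)

    rois = cio.read_nerve_rois(outdir / "nerve_rois.json")
    rois_invivo = [
        NerveROI(
            r.nerve_id,
            field.invert_points(r.polygon),
            r.tuning_class,
            r.attribution_truth,
            r.adjacent_cells,
            r.amplitude,
        )
        for r in rois
    ]
    trace_list = extract_traces(movie, masks_invivo, rois_invivo)
    summaries = [
        summarize_responses(
            t,
            movie.schedule,
            sd_mult=float(params.get("sd_mult", 2.0)),
            mean_z_cutoff=float(params.get("mean_z_cutoff", 1.0)),
        )
        for t in trace_list
    ]
    frame = summaries_to_frame(summaries)
    out_sum = outdir / "response_summaries.csv"
    frame.to_csv(out_sum)

    ratios = pd.DataFrame({t.roi_id: t.ratio for t in trace_list})
    out_tr = outdir / "traces.csv"
    ratios.to_csv(out_tr, index_label="frame")
    np.savetxt(outdir / "motion_shifts.csv", shifts, delimiter=",", header="dy,dx")
    inputs = [outdir / "movie_green.tif", outdir / "masks.tif", outdir / "warp_field.tif"]
    return _manifest(
        outdir, "traces", params, inputs, [out_sum, out_tr, outdir / "motion_shifts.csv"]
    )


def stage_spots(config: dict, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(outdir, "spots", "masks.tif", "rounds_meta.json")
    params = dict(config.get("spots", {}))
    meta = cio.read_rounds_meta(outdir)
    call_params = SpotCallParams(
        min_separation_px=float(params.get("min_separation_px", 5.0)),
        threshold=params.get("threshold", "auto"),
    )
    masks = cio.tifffile.imread(outdir / "masks.tif").astype(np.int32)

    all_spots = []
    count_tables = {}
    inputs = [outdir / "masks.tif"]
    for rnd, genes in sorted(meta["gene_rounds"].items()):
        if rnd > 1:
            _require(outdir, "spots", f"rigid_round{rnd}.json")
            tf = RigidTransform.from_json(outdir / f"rigid_round{rnd}.json")
        else:
            tf = None
        round_spots = []
        for gene in genes:
            img = cio.read_round_image(outdir, rnd, gene)
            inputs.append(outdir / f"round{rnd}_{gene}.tif")
            found = detect_spots(img, call_params, gene=gene, round=rnd)
            if tf is not None:  # map detections into the round-1 frame
                for s in found:
                    s.x, s.y = tf.apply_points(np.array([[s.x, s.y]]))[0]
            round_spots.extend(
                s for s in found if 0 <= s.x <= masks.shape[1] - 1 and 0 <= s.y <= masks.shape[0] - 1
            )
        if round_spots:
            count_tables[rnd] = count_spots_per_cell(
                round_spots, masks, assign_radius_px=float(params.get("assign_radius_px", 2.0))
            )
            count_tables[rnd].to_csv(outdir / f"counts_round{rnd}.csv")
        all_spots.extend(round_spots)

    out_spots = outdir / "spots.csv"
    spots_to_frame(all_spots).to_csv(out_spots, index=False)
    outputs = [out_spots] + [outdir / f"counts_round{r}.csv" for r in count_tables]
    return _manifest(outdir, "spots", params, inputs, outputs)


def stage_integrate(config: dict, outdir: Path) -> dict:
    outdir = Path(outdir)
    _require(
        outdir, "integrate",
        "masks.tif", "response_summaries.csv", "spots.csv", "if_CA4.tif",
        "nerve_rois.json", "registration_qc.csv",
    )
    params = config.get("integrate", {})
    masks = cio.tifffile.imread(outdir / "masks.tif").astype(np.int32)
    summaries = pd.read_csv(outdir / "response_summaries.csv", index_col="roi_id")

    count_tables = {}
    for p in sorted(outdir.glob("counts_round*.csv")):
        rnd = int(p.stem.replace("counts_round", ""))
        count_tables[rnd] = pd.read_csv(p, index_col="cell")

    if_img = cio.from_uint16(cio.tifffile.imread(outdir / "if_CA4.tif"))
    labels_present = np.unique(masks)
    labels_present = labels_present[labels_present > 0]
    if_table = pd.DataFrame(
        {
            "if_intensity": ndimage.mean(if_img, labels=masks, index=labels_present)
        },
        index=pd.Index(labels_present, name="cell"),
    )
    if_table["if_positive"] = classify_if_positive(if_table["if_intensity"].to_numpy())

    cell_rows = summaries[~summaries.index.astype(str).str.startswith("nerve_")]
    cell_rows.index = cell_rows.index.astype(int)
    nerve_rows = summaries[summaries.index.astype(str).str.startswith("nerve_")]

    profiles = build_cell_profiles(
        masks, count_tables, {"CA4": if_table}, cell_rows
    )

    report: dict = {"parameters": dict(params)}
    rocs = {}
    for feature in ("mean_z_sour", "count_CA4"):
        if feature in profiles.columns:
            try:
                r = roc_univariate(profiles, feature, "if_CA4")
                rocs[feature] = {
                    "auc": r.auc,
                    "optimal_threshold": r.optimal_threshold,
                    "youden_j": r.youden_j,
                }
            except Exception as exc:  # single-class cohorts stay reportable
                rocs[feature] = {"error": str(exc)}
    report["roc"] = rocs

    control = profiles.index[profiles.get("if_CA4", pd.Series(False, index=profiles.index)).fillna(False).astype(bool)]
    classes = call_expression_class(
        profiles, control_cells=control, percentile=float(params.get("control_percentile", 95.0))
    )
    profiles["expression_class"] = classes
    report["expression_thresholds"] = classes.attrs.get("thresholds", {})

    rois = cio.read_nerve_rois(outdir / "nerve_rois.json")
    adjacency = afferent_adjacency(
        rois, masks,
        radius_um=float(params.get("adjacency_radius_um", 2.0)),
        pixel_size_um=float(params.get("pixel_size_um", 0.5)),
    )
    attribution = summarize_dual_tuning(nerve_rows, adjacency, classes)
    report["dual_tuning"] = {
        "counts": attribution["counts"],
        "fractions": attribution["fractions"],
        "n_dual_nerves": attribution["n_dual_nerves"],
        "zero_denominator": attribution["zero_denominator"],
    }
    report["adjacency_radius_um"] = float(params.get("adjacency_radius_um", 2.0))
    report["registration_qc"] = pd.read_csv(outdir / "registration_qc.csv").to_dict("records")

    out_prof = outdir / "profiles.csv"
    profiles.to_csv(out_prof)
    out_report = outdir / "report.json"
    out_report.write_text(json.dumps(report, indent=1, default=float))
    inputs = [outdir / "masks.tif", outdir / "response_summaries.csv", outdir / "spots.csv"]
    return _manifest(outdir, "integrate", params, inputs, [out_prof, out_report])


STAGES = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "register": stage_register,
    "traces": stage_traces,
    "spots": stage_spots,
    "integrate": stage_integrate,
}


def run_pipeline(config: dict, outdir, stages=None) -> dict:
    """Run the requested stages in dependency order; returns the stage manifests."""
    outdir = Path(outdir)
    todo = [s for s in STAGE_ORDER if stages is None or s in set(stages)]
    manifests = {}
    for stage in todo:
        logger.info("running stage %s", stage)
        manifests[stage] = STAGES[stage](config, outdir)
    return manifests
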