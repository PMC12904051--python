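"""TIFF/CSV/JSON artifact I/O for pipeline stages.

Images are written as 16-bit TIFF with a fixed intensity scale (stored in a
sidecar JSON) so that float renderings round-trip; label masks are 16-bit
TIFF; tabular artifacts are CSV; transforms, schedules and ground-truth
scalars are JSON/YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import StimulusSchedule, TasteBudMovie
from .registration import DeformationField
from .synthetic import NerveROI, RoundImage, SceneGroundTruth

INTENSITY_SCALE = 10000.0  # float intensity 1.0 -> 10000 counts in uint16


def to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(img * INTENSITY_SCALE, 0, 65535).astype(np.uint16)


def from_uint16(img: np.ndarray) -> np.ndarray:
    return img.astype(float) / INTENSITY_SCALE


def sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# movies


def write_movie(movie: TasteBudMovie, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in (("green", movie.green), ("red", movie.red)):
        p = outdir / f"movie_{name}.tif"
        tifffile.imwrite(p, to_uint16(arr))
        paths.append(p)
    meta = {
        "schedule": movie.schedule.to_dict(),
        "cell_plane": movie.cell_plane,
        "nerve_plane": movie.nerve_plane,
        "intensity_scale": INTENSITY_SCALE,
    }
    p = outdir / "movie_meta.json"
    p.write_text(json.dumps(meta, indent=1))
    paths.append(p)
    return paths


def read_movie(outdir: Path) -> TasteBudMovie:
    outdir = Path(outdir)
    meta = json.loads((outdir / "movie_meta.json").read_text())
    green = from_uint16(tifffile.imread(outdir / "movie_green.tif"))
    red = from_uint16(tifffile.imread(outdir / "movie_red.tif"))
    return TasteBudMovie(
        green=green,
        red=red,
        schedule=StimulusSchedule.from_dict(meta["schedule"]),
        cell_plane=int(meta["cell_plane"]),
        nerve_plane=int(meta["nerve_plane"]),
    )


# ---------------------------------------------------------------------------
# histology rounds


def write_rounds(rounds: list[RoundImage], outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    plan = {}
    for r in rounds:
        stem = f"round{r.round}"
        tifffile.imwrite(outdir / f"{stem}_nuclear.tif", to_uint16(r.nuclear))
        paths.append(outdir / f"{stem}_nuclear.tif")
        if r.reporter is not None:
            tifffile.imwrite(outdir / f"{stem}_reporter.tif", to_uint16(r.reporter))
            paths.append(outdir / f"{stem}_reporter.tif")
        for gene, img in r.payload.items():
            tifffile.imwrite(outdir / f"{stem}_{gene}.tif", to_uint16(img))
            paths.append(outdir / f"{stem}_{gene}.tif")
        plan[str(r.round)] = sorted(r.payload)
    p = outdir / "rounds_meta.json"
    p.write_text(json.dumps({"gene_rounds": plan, "n_rounds": len(rounds)}, indent=1))
    paths.append(p)
    return paths


def read_round_image(outdir: Path, round: int, channel: str) -> np.ndarray:
    return from_uint16(tifffile.imread(Path(outdir) / f"round{round}_{channel}.tif"))


def read_rounds_meta(outdir: Path) -> dict:
    meta = json.loads((Path(outdir) / "rounds_meta.json").read_text())
    meta["gene_rounds"] = {int(k): v for k, v in meta["gene_rounds"].items()}
    return meta


# ---------------------------------------------------------------------------
# ground truth, fields, nerve ROIs


def write_scene_truth(scene: SceneGroundTruth, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    tifffile.imwrite(outdir / "truth_labels.tif", scene.cell_labels.astype(np.uint16))
    paths.append(outdir / "truth_labels.tif")

    rows = []
    for gene, pts in scene.true_spot_positions.items():
        for x, y, z, cell in pts:
            rows.append({"x": x, "y": y, "z": z, "gene": gene, "cell": int(cell)})
    pd.DataFrame(rows).to_csv(outdir / "truth_spots.csv", index=False)
    paths.append(outdir / "truth_spots.csv")

    scene.true_counts.to_csv(outdir / "truth_counts.csv")
    paths.append(outdir / "truth_counts.csv")

    scalars = {
        "seed": scene.seed,
        "pixel_size_um": scene.pixel_size_um,
        "cell_class": scene.cell_class,
        "cell_centroids_um": scene.cell_centroids_um.tolist(),
        "fiducial_blobs": scene.fiducial_blobs.tolist(),
        "rigid_truth": {str(k): t.to_dict() for k, t in scene.rigid_truth.items()},
        "response_amplitude": scene.response_amplitude.to_dict(),
    }
    (outdir / "truth_scene.json").write_text(json.dumps(scalars, indent=1))
    paths.append(outdir / "truth_scene.json")

    write_deformation_field(scene.warp_truth, outdir / "truth_warp.tif")
    paths.append(outdir / "truth_warp.tif")
    return paths


def write_nerve_rois(rois: list[NerveROI], path: Path) -> Path:
    payload = [
        {
            "nerve_id": r.nerve_id,
            "polygon": np.asarray(r.polygon).tolist(),
            "tuning_class": r.tuning_class,
            "attribution_truth": r.attribution_truth,
            "adjacent_cells": list(r.adjacent_cells),
            "amplitude": r.amplitude,
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


def read_nerve_rois(path: Path) -> list[NerveROI]:
    return [
        NerveROI(
            int(d["nerve_id"]),
            np.asarray(d["polygon"], dtype=float),
            d["tuning_class"],
            d.get("attribution_truth", "unknown"),
            tuple(d.get("adjacent_cells", ())),
            float(d.get("amplitude", 0.5)),
        )
        for d in json.loads(Path(path).read_text())
    ]


def write_deformation_field(field: DeformationField, path: Path) -> Path:
    tifffile.imwrite(
        path,
        np.moveaxis(field.displacement.astype(np.float32), -1, 0),
        metadata={"control_grid_spacing_px": field.control_grid_spacing_px},
    )
    return Path(path)


def read_deformation_field(path: Path) -> DeformationField:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    spacing = float(meta.get("control_grid_spacing_px", 32.0))
    return DeformationField(np.moveaxis(arr.astype(float), 0, -1), spacing)
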