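"""Self-contained validation experiments on synthetic ground truth.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage, and measures recovery against the generator's truth.  They back the
acceptance checks and are handy as quick health checks after changes.
"""

from __future__ import annotations

import numpy as np

from .datatypes import StimulusSchedule
from .registration import (
    RigidTransform,
    apply_transform,
    deformation_rms_error,
    register_nonrigid,
    register_rigid,
    registration_qc,
)
from .synthetic import (
    generate_scene,
    render_histology_rounds,
    render_invivo_reference,
    render_reporter,
    render_functional_movie,
)
from .traces import ResponseSummary, extract_traces, response_index, summarize_responses

__all__ = [
    "response_index_endpoints",
    "nonrigid_deformation_benchmark",
    "rigid_round_benchmark",
    "tuning_recovery_benchmark",
]


def response_index_endpoints(
    sweet_z: float = 2.0, umami_z: float = 3.1, balanced_z: float = 1.7
) -> dict[str, float]:
    """Analytic endpoints of the sweet/umami response index.

    Evaluates the index for a sweet-only afferent (umami clamped to 0), an
    umami-only afferent (sweet clamped), and a balanced one.
    """

    def summary(s, u):
        return ResponseSummary(
            "roi", {"sweet": s, "umami": u},
            {"sweet": s > 0, "umami": u > 0}, {"sweet": s, "umami": u},
        )

    return {
        "sweet_only": response_index(summary(sweet_z, 0.0)),
        "umami_only": response_index(summary(0.0, umami_z)),
        "balanced": response_index(summary(balanced_z, balanced_z)),
    }


def nonrigid_deformation_benchmark(
    seed: int = 42,
    *,
    n_cells: int = 30,
    image_shape: tuple[int, int] = (256, 256),
    bud_diameter_um: float = 80.0,
    warp_max_px: float = 2.0,
    noise_sigma: float = 0.03,
    grid_spacing_px: float = 32.0,
    min_pair_distance_px: float = 20.0,
    max_pair_distance_px: float = 200.0,
) -> dict:
    """Deformation-tracking error of B-spline registration on a warped bud.

    A synthetic bud is warped by a smooth random field (max ``warp_max_px``),
    both renderings get Gaussian noise, and the in-vivo image is registered
    to the fixed one.  Returns the RMS residual of recovered vs true relative
    centroid displacement, as percent of pairwise distance, over pairs in the
    requested distance range.
    """
    scene = generate_scene(
        n_cells,
        seed=seed,
        image_shape=image_shape,
        bud_diameter_um=bud_diameter_um,
        warp_max_px=warp_max_px,
    )
    rng = np.random.default_rng(seed + 1)
    fixed = render_reporter(scene) + rng.normal(0, noise_sigma, image_shape)
    invivo = render_invivo_reference(scene, noise_sigma=noise_sigma, seed=seed + 2)

    field, _ = register_nonrigid(invivo, fixed, grid_spacing_px=grid_spacing_px)
    p_invivo = scene.invivo_centroids_px()
    p_fixed = scene.cell_centroids_px
    table = deformation_rms_error(
        field, p_invivo, p_fixed, min_distance_px=min_pair_distance_px,
        bin_edges_px=np.arange(0.0, max_pair_distance_px + 25.0, 25.0),
    )
    return {
        "rms_error_pct": table.attrs["overall_rms_pct"],
        "n_pairs": int(table["n_pairs"].sum()),
        "table": table,
    }


def rigid_round_benchmark(
    seed: int = 7,
    *,
    rotation_deg: float = 3.0,
    translation_px: tuple[float, float] = (15.0, -10.0),
    noise_sigma: float = 0.05,
    attenuation: float = 0.8,
    n_cells: int = 12,
    image_shape: tuple[int, int] = (192, 192),
    bud_diameter_um: float = 55.0,
) -> dict:
    """Multi-round rigid registration QC on synthetic nuclear images.

    Round 2 is rendered at a known rotation/translation with per-round
    nuclear attenuation and noise; after registering it back to round 1 the
    image Pearson correlation (over the reference foreground) and the
    line-profile peak offsets are measured.
    """
    scene = generate_scene(
        n_cells, seed=seed, image_shape=image_shape, bud_diameter_um=bud_diameter_um
    )
    center = scene.rigid_truth[1].center
    scene.rigid_truth[2] = RigidTransform(rotation_deg, translation_px, center)
    rounds = render_histology_rounds(
        scene, n_rounds=2, seed=seed + 1, noise_sigma=noise_sigma,
        nuclear_attenuation=attenuation,
    )
    tf = register_rigid(rounds[0].nuclear, rounds[1].nuclear)
    aligned = apply_transform(rounds[1].nuclear, tf)
    qc = registration_qc(rounds[0].nuclear, aligned)
    truth_inv = scene.rigid_truth[2].inverse()
    return {
        "pearson_r": qc.pearson_r,
        "max_peak_offset_px": qc.max_peak_offset_px,
        "rotation_error_deg": abs(tf.rotation_deg - truth_inv.rotation_deg),
        "translation_error_px": float(
            np.abs(np.asarray(tf.translation_px) - truth_inv.translation_px).max()
        ),
        "n_pixels": int(np.prod(image_shape)),
    }


def tuning_recovery_benchmark(
    n_buds: int = 200,
    seed: int = 0,
    *,
    n_cells: int = 8,
    image_shape: tuple[int, int] = (96, 96),
    bud_diameter_um: float = 40.0,
    amplitude: float = 0.5,
    noise_sigma: float = 0.02,
) -> dict:
    """Fraction of cells whose tuning class is recovered from rendered movies.

    Expected classes: sweet→sweet, umami→umami, dual→dual; sour and silent
    cells respond to neither sweet nor umami, so both clamped mean Z-scores
    are 0 and the index is excluded.
    """
    schedule = StimulusSchedule.default(tastants=("sweet", "umami"))
    expect = {
        "sweet": "sweet", "umami": "umami", "dual": "dual",
        "sour": "excluded", "silent": "excluded",
    }
    correct = total = 0
    for k in range(n_buds):
        scene = generate_scene(
            n_cells, seed=seed + k, image_shape=image_shape,
            bud_diameter_um=bud_diameter_um, response_amplitude=amplitude,
        )
        movie = render_functional_movie(
            scene, schedule, noise_sigma=noise_sigma, seed=seed + k + 100_000,
            n_planes=2,
        )
        for trace in extract_traces(movie, movie.invivo_labels):
            s = summarize_responses(trace, schedule)
            total += 1
            correct += s.tuning_class == expect[scene.cell_class[trace.roi_id - 1]]
    return {"recovery": correct / total, "n_cells": total, "n_buds": n_buds}
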