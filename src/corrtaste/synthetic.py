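"""Ground-truthed synthetic correlative datasets.

This module emulates the statistical structure of an in-vivo/fixed-tissue
correlative taste-bud experiment so that every downstream stage — trace
classification, registration, spot calling, counting, and the correlative
statistics — can be tested against known truth:

* a circular taste bud of elongated, radially packed cells, each assigned a
  receptor class (sweet Tas1R2+/R3+, umami Tas1R1+/R3+, dual
  Tas1R1+/R2+/R3+, sour CA4+, or silent);
* per-cell per-gene true mRNA counts: negative-binomial for high expressers,
  low Poisson for negative cells;
* a two-channel (GCaMP green / tdTomato red) pseudo-volumetric functional
  movie driven by a stimulus schedule, with rigid frame jitter and noise;
* multi-round fixed-tissue images: nuclear channel every round (attenuating
  progressively), a cytosolic reporter channel in round 1 only (quenched
  afterwards), per-gene Gaussian spot fields moved by per-round rigid
  transforms, and persistent fiducial landmark blobs;
* a small smooth non-rigid deformation between the in-vivo frame and the
  fixed round-1 frame.

Scene geometry (centroids, labels, spot positions, nerve ROIs) is defined in
the *fixed round-1 frame*; the in-vivo renderings are produced by warping
through the inverse of ``warp_truth``, so ``warp_truth`` is the in-vivo→fixed
point mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import StimulusSchedule, TasteBudMovie
from .errors import ChannelBudgetError, PackingError, ParameterError
from .registration import DeformationField, RigidTransform

GENES = ("Tas1R1", "Tas1R2", "Tas1R3", "CA4")

#: genes each receptor class expresses at high level
CLASS_HIGH_GENES: dict[str, frozenset] = {
    "sweet": frozenset({"Tas1R2", "Tas1R3"}),
    "umami": frozenset({"Tas1R1", "Tas1R3"}),
    "dual": frozenset({"Tas1R1", "Tas1R2", "Tas1R3"}),
    "sour": frozenset({"CA4"}),
    "silent": frozenset(),
}

#: tastants each receptor class responds to
CLASS_TASTANTS: dict[str, tuple[str, ...]] = {
    "sweet": ("sweet",),
    "umami": ("umami",),
    "dual": ("sweet", "umami"),
    "sour": ("sour",),
    "silent": (),
}

DEFAULT_CLASS_FRACTIONS = {
    "sweet": 0.3,
    "umami": 0.3,
    "dual": 0.2,
    "sour": 0.1,
    "silent": 0.1,
}

#: negative-binomial(mean, dispersion) for expressed genes, Poisson(mean) for
#: negative ones; the sour-cell floor/ceiling enforce a usable negative control
DEFAULT_COUNT_PARAMS = {
    "high_mean": 25.0,
    "high_dispersion": 5.0,
    "neg_mean": 1.0,
    "sour_ca4_floor": 14,
    "sour_tas1r_ceiling": 8,
}

#: default gene→round probing plan (≤3 payload channels per round; Tas1R3
#: re-probed in the final round for count-stability QC)
DEFAULT_GENE_ROUNDS = {
    1: ("Tas1R2", "Tas1R3", "CA4"),
    2: ("Tas1R1",),
    3: ("CA4",),
    4: ("Tas1R3",),
}


@dataclass
class NerveROI:
    """Basolateral afferent-nerve region with its ground-truth tuning."""

    nerve_id: int
    polygon: np.ndarray  # (k, 2) of (x, y), fixed frame
    tuning_class: str  # sweet | umami | dual
    attribution_truth: str  # intrinsic | spillover | single
    adjacent_cells: tuple[int, ...]
    amplitude: float = 0.5


@dataclass
class SceneGroundTruth:
    """Complete ground truth for one synthetic taste bud."""

    cell_centroids_um: np.ndarray  # (n, 3) of (x, y, z) in µm, fixed frame
    cell_labels: np.ndarray  # (H, W) int, 0 = background
    cell_class: list[str]
    true_counts: pd.DataFrame  # index = cell label, columns = GENES
    true_spot_positions: dict[str, np.ndarray]  # gene -> (m, 4): x, y, z, cell
    response_amplitude: pd.DataFrame  # index = cell label, columns = tastants
    nerve_rois: list[NerveROI]
    rigid_truth: dict[int, RigidTransform]  # round -> round1->round point map
    warp_truth: DeformationField  # in-vivo -> fixed displacement
    fiducial_blobs: np.ndarray  # (k, 2) of (x, y)
    nuclei: np.ndarray  # (n, 2) of (x, y), fixed frame
    reporter_intensity: np.ndarray  # per cell, arbitrary units in (0, 1]
    pixel_size_um: float
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.cell_class)

    @property
    def labels(self) -> np.ndarray:
        return np.arange(1, self.n_cells + 1)

    @property
    def cell_centroids_px(self) -> np.ndarray:
        return self.cell_centroids_um[:, :2] / self.pixel_size_um

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_labels.shape

    def invivo_centroids_px(self, n_iter: int = 8) -> np.ndarray:
        """Cell centroids in the in-vivo frame (fixed-point inversion of the warp)."""
        fixed = self.cell_centroids_px
        pts = fixed.copy()
        for _ in range(n_iter):
            pts = fixed - self.warp_truth.sample(pts)
        return pts


@dataclass
class RoundImage:
    """One staining round: nuclear channel, ≤3 payload channels, reporter in round 1."""

    round: int
    nuclear: np.ndarray
    payload: dict[str, np.ndarray]  # gene -> image
    reporter: np.ndarray | None  # quenched (None) from round 2 on
    transform_truth: RigidTransform


# ---------------------------------------------------------------------------
# scene generation


def _draw_classes(rng: np.random.Generator, n_cells: int, fractions: dict[str, float]) -> list[str]:
    names = list(fractions)
    probs = np.array([fractions[k] for k in names], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ParameterError(f"class fractions sum to {probs.sum()}, not 1")
    if np.any(probs < 0):
        raise ParameterError("class fractions must be nonnegative")
    return [names[i] for i in rng.choice(len(names), size=n_cells, p=probs)]


def _negbin(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    # NB with Var = mean + mean^2/dispersion
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _draw_counts(
    rng: np.random.Generator, classes: list[str], params: dict
) -> pd.DataFrame:
    rows = []
    for cls in classes:
        high = CLASS_HIGH_GENES[cls]
        row = {}
        for gene in GENES:
            if gene in high:
                c = int(_negbin(rng, params["high_mean"], params["high_dispersion"]))
                if cls == "sour" and gene == "CA4":
                    while c < params["sour_ca4_floor"]:
                        c = int(_negbin(rng, params["high_mean"], params["high_dispersion"]))
            else:
                c = int(rng.poisson(params["neg_mean"]))
                if cls == "sour" and gene.startswith("Tas1R"):
                    while c > params["sour_tas1r_ceiling"]:
                        c = int(rng.poisson(params["neg_mean"]))
            row[gene] = c
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(GENES))
    df.index = pd.RangeIndex(1, len(classes) + 1, name="cell")
    return df


def _pack_cells(
    rng: np.random.Generator,
    n_cells: int,
    shape: tuple[int, int],
    bud_radius_px: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pack elongated cell footprints radially inside a circular bud.

    Cells occupy angular slots around the bud center, elongated along the
    radial axis (taste cells are spindle-shaped, apex pointing to the pore).
    Returns the label image and (n, 2) centroid array; raises PackingError
    when the tangential half-width would collapse below 2 px.
    """
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    if bud_radius_px > min(cx, cy):
        raise ParameterError("bud does not fit in the image")

    # cells are annular wedges converging on the apical pore at the bud
    # center, as in a transverse taste-bud section; a constant physical gap
    # separates neighbors so footprints never touch
    slot = 2 * np.pi / n_cells
    half_gap_px = 1.75
    # innermost radius at which a wedge still has a >=3 px wide body; crowded
    # buds push the wedges outward
    r0_frac = max(0.10, (2 * half_gap_px + 3.0) / (slot * bud_radius_px))
    if r0_frac > 0.6:
        raise PackingError(
            f"cannot pack {n_cells} cells in a bud of radius {bud_radius_px:.0f} px"
        )

    labels = np.zeros(shape, dtype=np.int32)
    centroids = np.zeros((n_cells, 2))
    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - cx, ys - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    theta0 = rng.uniform(0, 2 * np.pi)
    for i in range(n_cells):
        th_c = theta0 + slot * i
        r0 = bud_radius_px * r0_frac * rng.uniform(1.0, 1.3)
        r1 = bud_radius_px * rng.uniform(0.85, 0.97)
        dth = np.abs(np.angle(np.exp(1j * (theta - th_c))))
        with np.errstate(divide="ignore", invalid="ignore"):
            inside = (r >= r0) & (r <= r1) & (dth < slot / 2 - half_gap_px / np.maximum(r, 1e-9))
        inside &= labels == 0  # footprints never overlap
        if not np.any(inside):
            raise PackingError(f"cell {i + 1} footprint vanished during packing")
        labels[inside] = i + 1
        yy, xx = np.nonzero(labels == i + 1)
        centroids[i] = (xx.mean(), yy.mean())
    return labels, centroids


def _place_spots(
    rng: np.random.Generator, labels: np.ndarray, counts: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Drop each cell's true spots uniformly over its footprint (subpixel)."""
    cell_pixels = {
        lab: np.nonzero(labels == lab) for lab in range(1, int(labels.max()) + 1)
    }
    out = {}
    for gene in counts.columns:
        pts = []
        for lab, k in counts[gene].items():
            yy, xx = cell_pixels[lab]
            if k == 0:
                continue
            idx = rng.integers(0, len(xx), size=int(k))
            sx = xx[idx] + rng.uniform(-0.49, 0.49, size=int(k))
            sy = yy[idx] + rng.uniform(-0.49, 0.49, size=int(k))
            pts.append(np.column_stack([sx, sy, np.zeros(int(k)), np.full(int(k), lab)]))
        out[gene] = np.concatenate(pts, axis=0) if pts else np.zeros((0, 4))
    return out


def _smooth_warp(
    rng: np.random.Generator, shape: tuple[int, int], max_px: float, smooth_sigma: float = 40.0
) -> DeformationField:
    """Smooth random displacement field with maximum norm ``max_px``."""
    disp = rng.standard_normal((shape[0], shape[1], 2))
    for k in range(2):
        disp[..., k] = ndimage.gaussian_filter(disp[..., k], smooth_sigma)
    norm = np.linalg.norm(disp, axis=-1).max()
    if norm > 0:
        disp *= max_px / norm
    return DeformationField(disp, control_grid_spacing_px=smooth_sigma)


def _nerve_rois(
    rng: np.random.Generator,
    labels: np.ndarray,
    centroids: np.ndarray,
    classes: list[str],
    n_nerves: int,
    spillover_fraction: float,
    amplitude: float,
) -> list[NerveROI]:
    """Place small nerve ROIs just basolateral (bud-center side) of taste cells.

    Dual-tuned nerves are intrinsic (adjacent to one dual cell) with
    probability ``1 - spillover_fraction``, else spillover (adjacent to a
    sweet cell and an umami cell simultaneously, responding to both).
    """
    h, w = labels.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    n_cells = len(classes)
    by_class: dict[str, list[int]] = {}
    for i, c in enumerate(classes):
        by_class.setdefault(c, []).append(i)

    # per-cell angle and outer radius, from the footprints (nerves contact the
    # basolateral side of the cells, the outer rim of the bud section)
    angle = np.zeros(n_cells)
    r_max = np.zeros(n_cells)
    for i in range(n_cells):
        yy, xx = np.nonzero(labels == i + 1)
        angle[i] = np.arctan2(yy.mean() - cy, xx.mean() - cx)
        r_max[i] = np.hypot(yy - cy, xx - cx).max()

    def at_polar(th, rr):
        return np.array([cx + rr * np.cos(th), cy + rr * np.sin(th)])

    def square(p, half=2.0):
        return np.array(
            [
                [p[0] - half, p[1] - half],
                [p[0] + half, p[1] - half],
                [p[0] + half, p[1] + half],
                [p[0] - half, p[1] + half],
            ]
        )

    def ring_neighbors(i, j):
        return min((i - j) % n_cells, (j - i) % n_cells) == 1

    su_pairs = [
        (i, j)
        for i in by_class.get("sweet", [])
        for j in by_class.get("umami", [])
        if ring_neighbors(i, j)
    ]

    rois: list[NerveROI] = []
    nid = 0
    for _ in range(n_nerves):
        make_dual = rng.uniform() < 0.5 and (by_class.get("dual") or su_pairs)
        if make_dual:
            if rng.uniform() < spillover_fraction and su_pairs:
                i_s, i_u = su_pairs[int(rng.integers(len(su_pairs)))]
                # in the gap between the two cells, near their outer corners
                th_mid = np.angle(np.exp(1j * angle[i_s]) + np.exp(1j * angle[i_u]))
                p = at_polar(th_mid, min(r_max[i_s], r_max[i_u]) - 3.0)
                rois.append(
                    NerveROI(nid, square(p), "dual", "spillover", (i_s + 1, i_u + 1), amplitude)
                )
            elif by_class.get("dual"):
                i_d = int(rng.choice(by_class["dual"]))
                p = at_polar(angle[i_d], r_max[i_d] + 3.0)
                rois.append(
                    NerveROI(nid, square(p), "dual", "intrinsic", (i_d + 1,), amplitude)
                )
            else:
                continue
        else:
            pool = by_class.get("sweet", []) + by_class.get("umami", [])
            if not pool:
                continue
            i_c = int(rng.choice(pool))
            p = at_polar(angle[i_c], r_max[i_c] + 3.0)
            rois.append(
                NerveROI(nid, square(p), classes[i_c], "single", (i_c + 1,), amplitude)
            )
        nid += 1
    return rois


def generate_scene(
    n_cells: int,
    class_fractions: dict[str, float] | None = None,
    gene_count_params: dict | None = None,
    seed: int = 0,
    *,
    image_shape: tuple[int, int] = (256, 256),
    bud_diameter_um: float = 60.0,
    pixel_size_um: float = 0.5,
    response_amplitude: float = 0.5,
    n_rounds: int = 4,
    max_round_rotation_deg: float = 4.0,
    max_round_translation_px: float = 20.0,
    warp_max_px: float = 2.0,
    n_fiducials: int = 4,
    n_nerves: int = 0,
    nerve_spillover_fraction: float = 0.1,
) -> SceneGroundTruth:
    """Generate one ground-truthed taste-bud scene (deterministic per seed)."""
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    fractions = dict(class_fractions or DEFAULT_CLASS_FRACTIONS)
    params = {**DEFAULT_COUNT_PARAMS, **(gene_count_params or {})}
    rng = np.random.default_rng(seed)

    classes = _draw_classes(rng, n_cells, fractions)
    counts = _draw_counts(rng, classes, params)
    bud_radius_px = bud_diameter_um / 2.0 / pixel_size_um
    labels, centroids = _pack_cells(rng, n_cells, image_shape, bud_radius_px)
    spots = _place_spots(rng, labels, counts)

    amp = pd.DataFrame(
        0.0, index=counts.index, columns=list(dict.fromkeys(
            t for c in CLASS_TASTANTS.values() for t in c)) or ["sweet"]
    )
    for lab, cls in zip(counts.index, classes):
        for tastant in CLASS_TASTANTS[cls]:
            amp.loc[lab, tastant] = response_amplitude * rng.uniform(0.85, 1.15)

    rigid = {1: RigidTransform.identity(image_shape)}
    center = ((image_shape[1] - 1) / 2.0, (image_shape[0] - 1) / 2.0)
    for k in range(2, n_rounds + 1):
        rigid[k] = RigidTransform(
            float(rng.uniform(-max_round_rotation_deg, max_round_rotation_deg)),
            (
                float(rng.uniform(-max_round_translation_px, max_round_translation_px)),
                float(rng.uniform(-max_round_translation_px, max_round_translation_px)),
            ),
            center,
        )

    warp = _smooth_warp(rng, image_shape, warp_max_px)

    # fiducial landmark blobs sit outside the bud but inside every round's view
    margin = max_round_translation_px + 8
    fid = np.zeros((n_fiducials, 2))
    cx, cy = center
    for i in range(n_fiducials):
        th = rng.uniform(0, 2 * np.pi)
        rr = bud_radius_px + rng.uniform(6, 14)
        fid[i] = (
            np.clip(cx + rr * np.cos(th), margin, image_shape[1] - margin),
            np.clip(cy + rr * np.sin(th), margin, image_shape[0] - margin),
        )

    nuclei = centroids + rng.uniform(-2, 2, size=centroids.shape)
    reporter_intensity = rng.uniform(0.45, 1.0, size=n_cells)

    nerves = _nerve_rois(
        rng, labels, centroids, classes, n_nerves, nerve_spillover_fraction, response_amplitude
    ) if n_nerves else []

    centroids_um = np.column_stack(
        [centroids * pixel_size_um, np.zeros(len(centroids))]
    )
    return SceneGroundTruth(
        cell_centroids_um=centroids_um,
        cell_labels=labels,
        cell_class=classes,
        true_counts=counts,
        true_spot_positions=spots,
        response_amplitude=amp,
        nerve_rois=nerves,
        rigid_truth=rigid,
        warp_truth=warp,
        fiducial_blobs=fid,
        nuclei=nuclei,
        reporter_intensity=reporter_intensity,
        pixel_size_um=pixel_size_um,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering


def _gaussian_splat(img: np.ndarray, pts: np.ndarray, sigma: float, amplitudes) -> None:
    """Accumulate isotropic Gaussians at subpixel (x, y) positions, in place."""
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(pts),))
    for (x, y), a in zip(pts[:, :2], amplitudes):
        x0, y0 = int(round(x)), int(round(y))
        xs = np.arange(max(x0 - r, 0), min(x0 + r + 1, w))
        ys = np.arange(max(y0 - r, 0), min(y0 + r + 1, h))
        if not len(xs) or not len(ys):
            continue
        gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
        img[np.ix_(ys, xs)] += a * np.outer(gy, gx)


def render_reporter(scene: SceneGroundTruth, smooth_sigma: float = 1.0) -> np.ndarray:
    """Cytosolic tdTomato reporter image in the fixed round-1 frame."""
    img = np.zeros(scene.shape)
    for lab, inten in zip(scene.labels, scene.reporter_intensity):
        img[scene.cell_labels == lab] = inten
    return ndimage.gaussian_filter(img, smooth_sigma)


def warp_to_invivo(scene: SceneGroundTruth, img: np.ndarray, *, is_labels: bool = False) -> np.ndarray:
    """Resample a fixed-frame image into the in-vivo frame through warp_truth."""
    h, w = img.shape
    ys, xs = np.mgrid[0:h, 0:w]
    u = scene.warp_truth.displacement
    coords = np.stack([ys + u[..., 1], xs + u[..., 0]])
    return ndimage.map_coordinates(
        img, coords, order=0 if is_labels else 1, mode="constant", cval=0
    )


def render_invivo_reference(scene: SceneGroundTruth, noise_sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Reporter image as seen in vivo: the fixed rendering pulled through the warp."""
    img = warp_to_invivo(scene, render_reporter(scene))
    if noise_sigma > 0:
        img = img + np.random.default_rng(seed).normal(0, noise_sigma, img.shape)
    return img


def _dff_profile(
    schedule: StimulusSchedule,
    amplitudes: dict[str, float],
    n_frames: int,
    tau_on_s: float = 2.0,
    tau_off_s: float = 4.0,
) -> np.ndarray:
    """ΔF/F(t): exponential rise during each matching epoch, decay after offset."""
    t = np.arange(n_frames) / schedule.frame_rate
    dff = np.zeros(n_frames)
    for ep in schedule.epochs:
        a = amplitudes.get(ep.tastant, 0.0)
        if a == 0:
            continue
        rise = (t >= ep.onset_s) & (t < ep.offset_s)
        dff[rise] += a * (1 - np.exp(-(t[rise] - ep.onset_s) / tau_on_s))
        peak = a * (1 - np.exp(-(ep.offset_s - ep.onset_s) / tau_on_s))
        fall = t >= ep.offset_s
        dff[fall] += peak * np.exp(-(t[fall] - ep.offset_s) / tau_off_s)
    return dff


def mean_epoch_dff(
    schedule: StimulusSchedule, tastant: str, amplitude: float, tau_on_s: float = 2.0
) -> float:
    """Closed-form mean ΔF/F over a tastant's epoch under the rendering kinetics."""
    ep = next(e for e in schedule.epochs if e.tastant == tastant)
    sl = schedule.epoch_slice(tastant)
    t = np.arange(sl.start, sl.stop) / schedule.frame_rate
    return float(np.mean(amplitude * (1 - np.exp(-(t - ep.onset_s) / tau_on_s))))


def render_functional_movie(
    scene: SceneGroundTruth,
    schedule: StimulusSchedule,
    noise_sigma: float = 0.01,
    motion_amplitude_px: float = 0.0,
    seed: int = 0,
    *,
    n_planes: int = 3,
    background: float = 0.02,
) -> TasteBudMovie:
    """Render the two-channel functional movie in the in-vivo frame.

    The red channel is static per cell (up to noise and injected rigid
    jitter); the green channel is ``red × g0 × (1 + ΔF/F(t))`` with
    exponential response kinetics.  Cells appear on planes 0..P-2; nerve
    ROIs respond on the last (basolateral) plane.
    """
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    if not schedule.epochs:
        raise ParameterError("schedule carries no stimulus epochs")
    rng = np.random.default_rng(seed)
    h, w = scene.shape
    n_frames = schedule.n_frames()

    labels_iv = warp_to_invivo(scene, scene.cell_labels, is_labels=True)

    # static red plane for cells; per-cell green gain
    red_cells = np.full((h, w), background)
    g0 = rng.uniform(0.7, 1.1, size=scene.n_cells)
    cell_weight = []  # per-cell green ΔF/F weight image
    for i, lab in enumerate(scene.labels):
        m = labels_iv == lab
        red_cells[m] = scene.reporter_intensity[i]
        wimg = np.zeros((h, w))
        wimg[m] = scene.reporter_intensity[i] * g0[i]
        cell_weight.append(wimg)
    green_cells0 = sum(cell_weight) + background
    dff_cells = np.array(
        [
            _dff_profile(schedule, scene.response_amplitude.loc[lab].to_dict(), n_frames)
            for lab in scene.labels
        ]
    )

    # basolateral nerve plane
    red_nerve = np.full((h, w), background)
    nerve_weight, dff_nerves = [], []
    from skimage.draw import polygon as draw_polygon

    for roi in scene.nerve_rois:
        rr, cc = draw_polygon(roi.polygon[:, 1], roi.polygon[:, 0], shape=(h, w))
        m = np.zeros((h, w), dtype=bool)
        m[rr, cc] = True
        red_nerve[m] = 0.8
        wimg = np.zeros((h, w))
        wimg[m] = 0.8
        nerve_weight.append(wimg)
        amps = {t: roi.amplitude for t in (
            ("sweet", "umami") if roi.tuning_class == "dual" else (roi.tuning_class,)
        )}
        dff_nerves.append(_dff_profile(schedule, amps, n_frames))
    green_nerve0 = (sum(nerve_weight) if nerve_weight else 0.0) + background

    shifts = (
        rng.uniform(-motion_amplitude_px, motion_amplitude_px, size=(n_frames, 2))
        if motion_amplitude_px > 0
        else np.zeros((n_frames, 2))
    )

    green = np.empty((n_frames, n_planes, h, w))
    red = np.empty((n_frames, n_planes, h, w))
    for f in range(n_frames):
        g_cell = green_cells0.copy()
        for i in range(scene.n_cells):
            d = dff_cells[i, f]
            if d != 0:
                g_cell += cell_weight[i] * d
        g_nerve = np.full((h, w), background) + (green_nerve0 - background)
        for i in range(len(nerve_weight)):
            d = dff_nerves[i][f]
            if d != 0:
                g_nerve = g_nerve + nerve_weight[i] * d
        for p in range(n_planes - 1):
            green[f, p] = g_cell
            red[f, p] = red_cells
        green[f, n_planes - 1] = g_nerve
        red[f, n_planes - 1] = red_nerve
        if motion_amplitude_px > 0 and np.any(shifts[f]):
            for p in range(n_planes):
                green[f, p] = ndimage.shift(green[f, p], shifts[f], order=1, mode="nearest")
                red[f, p] = ndimage.shift(red[f, p], shifts[f], order=1, mode="nearest")
    if noise_sigma > 0:
        green += rng.normal(0, noise_sigma, green.shape)
        red += rng.normal(0, noise_sigma, red.shape)

    return TasteBudMovie(
        green=green,
        red=red,
        schedule=schedule,
        cell_plane=0,
        nerve_plane=n_planes - 1,
        true_shifts=shifts,
        invivo_labels=labels_iv,
    )


def render_histology_rounds(
    scene: SceneGroundTruth,
    n_rounds: int = 4,
    spot_psf_sigma_px: float = 1.5,
    seed: int = 0,
    *,
    gene_rounds: dict[int, tuple[str, ...]] | None = None,
    nuclear_attenuation: float = 0.8,
    noise_sigma: float = 0.01,
    spot_amplitude: float = 0.6,
    nuclear_sigma_px: float = 3.0,
    fiducial_amplitude: float = 0.9,
) -> list[RoundImage]:
    """Render the multi-round fixed-tissue image series.

    Round 1 carries the cytosolic reporter; later rounds omit it (reporter
    fluorescence is quenched by probe stripping).  The nuclear channel is
    re-rendered every round with ``nuclear_attenuation`` applied per round.
    Spots and fiducials are moved by each round's rigid ground-truth
    transform; fiducial blobs persist in every round.
    """
    if n_rounds < 1:
        raise ParameterError("n_rounds must be >= 1")
    plan = {
        k: tuple(v)
        for k, v in (gene_rounds or DEFAULT_GENE_ROUNDS).items()
        if k <= n_rounds
    }
    for k, genes in plan.items():
        if len(genes) > 3:
            raise ChannelBudgetError(
                f"round {k} requests {len(genes)} payload channels; at most 3 marker "
                "genes can be detected per round"
            )
    rng = np.random.default_rng(seed)
    h, w = scene.shape

    rounds: list[RoundImage] = []
    for k in range(1, n_rounds + 1):
        tf = scene.rigid_truth.get(k, RigidTransform.identity(scene.shape))
        att = nuclear_attenuation ** (k - 1)

        nuclear = np.zeros((h, w))
        _gaussian_splat(nuclear, tf.apply_points(scene.nuclei), nuclear_sigma_px, att)
        _gaussian_splat(
            nuclear, tf.apply_points(scene.fiducial_blobs), 2.0, fiducial_amplitude
        )

        payload = {}
        for gene in plan.get(k, ()):
            img = np.zeros((h, w))
            pts = scene.true_spot_positions[gene]
            if len(pts):
                _gaussian_splat(img, tf.apply_points(pts[:, :2]), spot_psf_sigma_px, spot_amplitude)
            _gaussian_splat(img, tf.apply_points(scene.fiducial_blobs), 2.0, 0.3 * fiducial_amplitude)
            if noise_sigma > 0:
                img += rng.normal(0, noise_sigma, img.shape)
            payload[gene] = img

        reporter = None
        if k == 1:
            reporter = render_reporter(scene)
            if noise_sigma > 0:
                reporter = reporter + rng.normal(0, noise_sigma, reporter.shape)
        if noise_sigma > 0:
            nuclear = nuclear + rng.normal(0, noise_sigma, nuclear.shape)
        rounds.append(RoundImage(k, nuclear, payload, reporter, tf))
    return rounds


def render_if_image(
    scene: SceneGroundTruth,
    protein: str = "CA4",
    seed: int = 0,
    *,
    positive_mean: float = 0.8,
    negative_mean: float = 0.12,
    noise_sigma: float = 0.02,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Immunofluorescence channel in the fixed frame: marker+ cells bright."""
    rng = np.random.default_rng(seed)
    img = np.zeros(scene.shape)
    for lab, cls in zip(scene.labels, scene.cell_class):
        level = positive_mean if protein in CLASS_HIGH_GENES[cls] else negative_mean
        img[scene.cell_labels == lab] = level * rng.uniform(0.85, 1.15)
    img = ndimage.gaussian_filter(img, smooth_sigma)
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, img.shape)
    return img


def render_if_table(
    scene: SceneGroundTruth,
    protein: str = "CA4",
    seed: int = 0,
    *,
    positive_mean: float = 0.8,
    negative_mean: float = 0.12,
    sigma: float = 0.05,
) -> pd.DataFrame:
    """Per-cell mean immunofluorescence intensity, bimodal by marker class."""
    rng = np.random.default_rng(seed)
    pos = np.array([protein in CLASS_HIGH_GENES[c] for c in scene.cell_class])
    vals = np.where(
        pos,
        rng.normal(positive_mean, sigma, scene.n_cells),
        rng.normal(negative_mean, sigma, scene.n_cells),
    ).clip(min=0)
    return pd.DataFrame(
        {"protein": protein, "if_intensity": vals, "truth_positive": pos},
        index=pd.Index(scene.labels, name="cell"),
    )
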