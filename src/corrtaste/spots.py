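"""smFISH spot detection and digital per-cell counting.

Detection follows the classic single-molecule recipe: a difference-of-
Gaussians bandpass, subtraction of the global background (image median),
thresholded local maxima with minimum-separation suppression (among maxima
closer than the separation radius only the brightest survives), then a 2D
Gaussian fit with a local background plane for subpixel centers and
background-corrected amplitudes.  Counting is digital: each amplified spot
is one molecule, tallied per segmented cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .errors import GeometryError, ParameterError

__all__ = [
    "Spot",
    "SpotCallParams",
    "detect_spots",
    "merge_spots_across_planes",
    "count_spots_per_cell",
    "spot_count_stability",
    "spots_to_frame",
]


@dataclass
class Spot:
    x: float
    y: float
    z_plane: int = 0
    gene: str = ""
    round: int = 1
    amplitude: float = 0.0
    sigma: float = float("nan")
    cell_label: int = 0  # 0 = unassigned
    fit_ok: bool = True


@dataclass(frozen=True)
class SpotCallParams:
    dog_sigma_small: float = 1.0
    dog_sigma_large: float = 2.0
    min_separation_px: float = 5.0
    threshold: float | str = "auto"  # absolute DoG intensity, or "auto"
    fit_window_px: int = 7
    auto_nsigma: float = 5.0  # robust SDs above median for the auto threshold

    def __post_init__(self):
        if self.dog_sigma_small >= self.dog_sigma_large:
            raise ParameterError("dog_sigma_small must be < dog_sigma_large")
        if self.min_separation_px <= 0:
            raise ParameterError("min_separation_px must be positive")
        if self.fit_window_px < 3:
            raise ParameterError("fit_window_px must be >= 3")


# ---------------------------------------------------------------------------
# detection


def _auto_threshold(dog: np.ndarray, nsigma: float) -> float:
    med = float(np.median(dog))
    mad = float(np.median(np.abs(dog - med)))
    return med + nsigma * 1.4826 * mad


def _local_maxima(img: np.ndarray, threshold: float) -> np.ndarray:
    mx = ndimage.maximum_filter(img, size=3, mode="nearest")
    yy, xx = np.nonzero((img >= mx) & (img > threshold))
    return np.column_stack([xx, yy])


def _suppress(cands: np.ndarray, values: np.ndarray, radius: float) -> np.ndarray:
    """Greedy minimum-separation suppression, brightest first (deterministic)."""
    order = np.lexsort((cands[:, 0], cands[:, 1], -values))
    kept: list[int] = []
    for i in order:
        p = cands[i]
        if all(np.hypot(*(p - cands[j])) >= radius for j in kept):
            kept.append(i)
    return np.array(kept, dtype=int)


def _fit_gaussian(img: np.ndarray, x0: int, y0: int, half: int, sigma0: float):
    """2D Gaussian + background plane fit in a window; None on divergence."""
    h, w = img.shape
    xs = np.arange(max(x0 - half, 0), min(x0 + half + 1, w))
    ys = np.arange(max(y0 - half, 0), min(y0 + half + 1, h))
    X, Y = np.meshgrid(xs, ys)
    Z = img[np.ix_(ys, xs)].astype(float)

    def model(p):
        a, mx, my, s, b0, b1, b2 = p
        return a * np.exp(-((X - mx) ** 2 + (Y - my) ** 2) / (2 * s**2)) + b0 + b1 * (
            X - x0
        ) + b2 * (Y - y0)

    p0 = [float(img[y0, x0] - np.median(Z)), float(x0), float(y0), sigma0, float(np.median(Z)), 0.0, 0.0]
    lo = [0.0, xs[0] - 0.5, ys[0] - 0.5, 0.3, -np.inf, -np.inf, -np.inf]
    hi = [np.inf, xs[-1] + 0.5, ys[-1] + 0.5, 2.0 * half, np.inf, np.inf, np.inf]
    p0 = np.clip(p0, lo, hi)
    try:
        res = optimize.least_squares(
            lambda p: (model(p) - Z).ravel(), p0, bounds=(lo, hi), max_nfev=200
        )
    except Exception:
        return None
    if not res.success or res.x[0] <= 0:
        return None
    return res.x


def detect_spots(
    image: np.ndarray,
    params: SpotCallParams | None = None,
    *,
    gene: str = "",
    round: int = 1,
    z_plane: int = 0,
) -> list[Spot]:
    """Detect diffraction-limited spots in a single-channel 2D image.

    Pipeline: DoG bandpass → global background (median) subtraction →
    thresholded local maxima with minimum-separation suppression → subpixel
    2D Gaussian fit with a local background plane.  A diverging fit falls
    back to the integer maximum and is flagged (``fit_ok=False``).  An empty
    image under the "auto" threshold yields an empty list, not an error.
    """
    if image.ndim != 2:
        raise ParameterError("detect_spots expects a single-channel 2D image")
    params = params or SpotCallParams()

    img = image.astype(float)
    dog = ndimage.gaussian_filter(img, params.dog_sigma_small) - ndimage.gaussian_filter(
        img, params.dog_sigma_large
    )
    dog = dog - np.median(dog)
    thr = (
        _auto_threshold(dog, params.auto_nsigma)
        if params.threshold == "auto"
        else float(params.threshold)
    )
    cands = _local_maxima(dog, thr)
    if len(cands) == 0:
        return []
    vals = dog[cands[:, 1], cands[:, 0]]
    keep = _suppress(cands, vals, params.min_separation_px)

    half = params.fit_window_px // 2
    sigma0 = 0.5 * (params.dog_sigma_small + params.dog_sigma_large)
    spots: list[Spot] = []
    h, w = img.shape
    for i in keep:
        cx, cy = int(cands[i, 0]), int(cands[i, 1])
        fit = _fit_gaussian(img, cx, cy, half, sigma0)
        if fit is not None:
            a, mx, my, s = float(fit[0]), float(fit[1]), float(fit[2]), float(fit[3])
            if 0 <= mx <= w - 1 and 0 <= my <= h - 1:
                spots.append(Spot(mx, my, z_plane, gene, round, a, s, fit_ok=True))
                continue
        local = img[
            max(cy - half, 0) : cy + half + 1, max(cx - half, 0) : cx + half + 1
        ]
        spots.append(
            Spot(
                float(cx),
                float(cy),
                z_plane,
                gene,
                round,
                float(img[cy, cx] - np.median(local)),
                fit_ok=False,
            )
        )
    return spots


def merge_spots_across_planes(
    spots: list[Spot], max_lateral_px: float = 2.0
) -> list[Spot]:
    """Collapse duplicate detections of one molecule on adjacent axial planes.

    Spots of the same gene/round on adjacent z-planes within
    ``max_lateral_px`` laterally are one molecule; duplicate chains spanning
    several planes collapse transitively, and the brightest detection of
    each chain is kept.
    """
    by_key: dict[tuple, list[Spot]] = {}
    for s in spots:
        by_key.setdefault((s.gene, s.round), []).append(s)
    merged: list[Spot] = []
    for group in by_key.values():
        n = len(group)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = group[i], group[j]
                if (
                    abs(a.z_plane - b.z_plane) == 1
                    and np.hypot(a.x - b.x, a.y - b.y) <= max_lateral_px
                ):
                    parent[find(i)] = find(j)
        components: dict[int, list[Spot]] = {}
        for i, s in enumerate(group):
            components.setdefault(find(i), []).append(s)
        for comp in components.values():
            merged.append(max(comp, key=lambda s: s.amplitude))
    return merged


# ---------------------------------------------------------------------------
# counting


def _distance_to_label(mask: np.ndarray, lab: int, x: float, y: float, search: int) -> float:
    h, w = mask.shape
    x0, y0 = int(round(x)), int(round(y))
    xs = np.arange(max(x0 - search, 0), min(x0 + search + 1, w))
    ys = np.arange(max(y0 - search, 0), min(y0 + search + 1, h))
    sub = mask[np.ix_(ys, xs)] == lab
    if not sub.any():
        return np.inf
    yy, xx = np.nonzero(sub)
    return float(np.min(np.hypot(xs[xx] - x, ys[yy] - y)))


def count_spots_per_cell(
    spots: list[Spot],
    mask: np.ndarray,
    assign_radius_px: float = 2.0,
) -> pd.DataFrame:
    """Assign spots to cells and tally digital per-cell per-gene counts.

    A spot inside a label belongs to that cell.  A background spot within
    ``assign_radius_px`` of exactly one label joins it; within reach of
    several, the nearest boundary wins (a deterministic stand-in for manual
    dense-region curation) and exact ties stay unassigned; beyond the radius
    it stays unassigned (label 0).  Spots and mask must share the round-1
    frame — transform spots first.  Assignment is recorded on each spot.
    """
    h, w = mask.shape
    labels = np.unique(mask)
    labels = labels[labels > 0]
    genes = sorted({s.gene for s in spots}) or []
    counts = pd.DataFrame(
        0, index=pd.Index(labels, name="cell"), columns=genes, dtype=int
    )
    search = int(np.ceil(assign_radius_px)) + 2
    for s in spots:
        if not (0 <= s.x <= w - 1 and 0 <= s.y <= h - 1):
            raise GeometryError(
                f"spot at ({s.x:.1f}, {s.y:.1f}) lies outside the mask frame {mask.shape}"
            )
        lab = int(mask[int(round(s.y)), int(round(s.x))])
        if lab == 0:
            x0, y0 = int(round(s.x)), int(round(s.y))
            nearby = np.unique(
                mask[
                    max(y0 - search, 0) : y0 + search + 1,
                    max(x0 - search, 0) : x0 + search + 1,
                ]
            )
            nearby = nearby[nearby > 0]
            dists = {
                int(l): _distance_to_label(mask, int(l), s.x, s.y, search) for l in nearby
            }
            dists = {l: d for l, d in dists.items() if d <= assign_radius_px}
            if len(dists) == 1:
                lab = next(iter(dists))
            elif len(dists) > 1:
                best = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
                lab = best[0][0] if best[0][1] < best[1][1] - 1e-9 else 0
        s.cell_label = lab
        if lab > 0 and s.gene in counts.columns:
            counts.loc[lab, s.gene] += 1
    return counts


def spot_count_stability(
    counts_round_a: pd.Series, counts_round_b: pd.Series
) -> dict:
    """Paired round-to-round count comparison for re-probed genes.

    Returns per-cell deltas, the least-squares slope through the origin of
    round-b on round-a counts, and a two-sided Wilcoxon matched-pairs test.
    """
    a = pd.Series(counts_round_a).astype(float)
    b = pd.Series(counts_round_b).astype(float)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ParameterError("count tables share no cells")
    a, b = a.loc[common], b.loc[common]
    denom = float((a**2).sum())
    slope = float((a * b).sum() / denom) if denom > 0 else float("nan")
    deltas = (b - a).rename("delta")
    diffs = deltas.to_numpy()
    if np.allclose(diffs, 0):
        pvalue = 1.0
    else:
        pvalue = float(stats.wilcoxon(a.to_numpy(), b.to_numpy()).pvalue)
    return {"deltas": deltas, "slope": slope, "wilcoxon_p": pvalue, "n": len(common)}


def spots_to_frame(spots: list[Spot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x": s.x,
                "y": s.y,
                "z_plane": s.z_plane,
                "gene": s.gene,
                "round": s.round,
                "amplitude": s.amplitude,
                "cell_label": s.cell_label,
                "fit_ok": s.fit_ok,
            }
            for s in spots
        ]
    )
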