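"""Functional-trace analysis: motion correction, ratio traces, ΔF/F, Z-scores,
responsiveness and tuning classification.

The activity readout is ratiometric: per-frame ROI-mean green (GCaMP) divided
by ROI-mean red (tdTomato), which cancels motion- and expression-driven
intensity changes.  ΔF/F and Z-score are taken relative to the pre-stimulus
baseline window.  A trace counts as responsive to a tastant when the Z-score
during the stimulus epoch both peaks above ``sd_mult`` (default 2 baseline
SDs) and averages above ``mean_z_cutoff`` (default 1); non-responsive mean
Z-scores are clamped to 0 before any downstream use.

The sweet/umami response index is

    index = (S - U) / (S + U)

on the clamped mean Z-scores S and U: +1 is a pure sweet response, -1 a pure
umami response, intermediate values are dual-tuned, and S = U = 0 is
excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.registration import phase_cross_correlation

from .datatypes import StimulusSchedule, TasteBudMovie
from .errors import (
    DegenerateBaselineError,
    DegenerateReferenceError,
    GeometryError,
    ParameterError,
)

logger = logging.getLogger(__name__)

EXCLUDED = "excluded"


@dataclass
class CalciumTrace:
    roi_id: int | str
    compartment: str  # cell_apical | nerve_basolateral
    ratio: np.ndarray
    frame_rate: float
    dff: np.ndarray | None = None
    zscore: np.ndarray | None = None
    baseline_mean: float | None = None
    baseline_sd: float | None = None


@dataclass
class ResponseSummary:
    roi_id: int | str
    mean_z: dict[str, float]
    responsive: dict[str, bool]
    mean_z_clamped: dict[str, float]
    response_index: float | None = None
    tuning_class: str | None = None


# ---------------------------------------------------------------------------
# motion correction


def motion_correct(
    movie: TasteBudMovie, *, upsample_factor: int = 10, reference_plane: int | None = None
) -> tuple[TasteBudMovie, np.ndarray]:
    """Rigid (translation) motion correction against the temporal mean of red.

    The anatomy channel (red) is stable over time, so its temporal mean is
    the registration reference.  The per-frame shift is estimated by
    subpixel cross-correlation on one plane and applied identically to both
    channels on all planes.  Returns the corrected movie and the (T, 2)
    applied shifts in (dy, dx) px.
    """
    plane = movie.cell_plane if reference_plane is None else reference_plane
    ref = movie.red[:, plane].mean(axis=0)
    if float(np.std(ref)) == 0.0:
        raise DegenerateReferenceError("red-channel reference is uniform; cannot anchor")

    n = movie.n_frames
    if n < 2:
        raise ParameterError("motion correction needs >= 2 frames")
    shifts = np.zeros((n, 2))
    green = np.empty_like(movie.green)
    red = np.empty_like(movie.red)
    for f in range(n):
        # plain cross-correlation: the temporal-mean reference is motion-blurred,
        # which biases the phase-normalized variant
        sh, _, _ = phase_cross_correlation(
            ref, movie.red[f, plane], upsample_factor=upsample_factor, normalization=None
        )
        shifts[f] = sh
        for p in range(movie.n_planes):
            if np.any(np.abs(sh) > 1e-6):
                green[f, p] = ndimage.shift(movie.green[f, p], sh, order=1, mode="nearest")
                red[f, p] = ndimage.shift(movie.red[f, p], sh, order=1, mode="nearest")
            else:
                green[f, p] = movie.green[f, p]
                red[f, p] = movie.red[f, p]
    corrected = TasteBudMovie(
        green=green,
        red=red,
        schedule=movie.schedule,
        cell_plane=movie.cell_plane,
        nerve_plane=movie.nerve_plane,
        true_shifts=movie.true_shifts,
        invivo_labels=movie.invivo_labels,
    )
    return corrected, shifts


# ---------------------------------------------------------------------------
# trace extraction


def _roi_ratio(movie: TasteBudMovie, mask: np.ndarray, plane: int) -> np.ndarray:
    g = movie.green[:, plane][:, mask].mean(axis=1)
    r = movie.red[:, plane][:, mask].mean(axis=1)
    return g / r


def extract_traces(
    movie: TasteBudMovie,
    masks: np.ndarray,
    nerve_rois=None,
) -> list[CalciumTrace]:
    """One ratio trace per cell label (apical plane) and per nerve ROI (basolateral).

    The ratio uses per-frame ROI means (mean green over mean red), not a
    pixelwise ratio, which would blow up wherever red is dim.  Empty ROIs are
    skipped with a logged warning.
    """
    if masks.shape != movie.frame_shape:
        raise GeometryError(
            f"mask geometry {masks.shape} does not match movie frames {movie.frame_shape}"
        )
    traces: list[CalciumTrace] = []
    for lab in np.unique(masks):
        if lab == 0:
            continue
        m = masks == lab
        if not m.any():  # pragma: no cover - unique() guarantees nonempty
            continue
        traces.append(
            CalciumTrace(
                int(lab), "cell_apical", _roi_ratio(movie, m, movie.cell_plane),
                movie.schedule.frame_rate,
            )
        )
    for roi in nerve_rois or []:
        poly = roi.polygon if hasattr(roi, "polygon") else np.asarray(roi)
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=movie.frame_shape)
        m = np.zeros(movie.frame_shape, dtype=bool)
        m[rr, cc] = True
        rid = getattr(roi, "nerve_id", len(traces))
        if not m.any():
            logger.warning("nerve ROI %s rasterizes to an empty region; skipped", rid)
            continue
        traces.append(
            CalciumTrace(
                f"nerve_{rid}", "nerve_basolateral",
                _roi_ratio(movie, m, movie.nerve_plane % movie.n_planes),
                movie.schedule.frame_rate,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# ΔF/F, Z-score


def compute_dff_zscore(
    trace: CalciumTrace, baseline_window: tuple[float, float]
) -> CalciumTrace:
    """Annotate a trace with ΔF/F and Z-score relative to the baseline window.

    ``dff = ratio / baseline_mean - 1``; ``z = (ratio - mean) / sd`` with the
    baseline mean/SD.  A constant baseline (SD = 0) is an error, never a
    silent zero.
    """
    t0, t1 = baseline_window
    lo = int(np.ceil(t0 * trace.frame_rate - 1e-9))
    hi = int(np.ceil(t1 * trace.frame_rate - 1e-9))
    base = trace.ratio[lo:hi]
    if len(base) < 5:
        raise ParameterError(f"baseline window holds {len(base)} frames; need >= 5")
    mean = float(np.mean(base))
    sd = float(np.std(base))
    if sd == 0:
        raise DegenerateBaselineError("baseline has zero variance; Z-score undefined")
    trace.baseline_mean = mean
    trace.baseline_sd = sd
    trace.dff = trace.ratio / mean - 1.0
    trace.zscore = (trace.ratio - mean) / sd
    return trace


# ---------------------------------------------------------------------------
# responsiveness, response index, tuning


def classify_responsiveness(
    trace: CalciumTrace,
    schedule: StimulusSchedule,
    sd_mult: float = 2.0,
    mean_z_cutoff: float = 1.0,
) -> ResponseSummary:
    """Per-tastant responsiveness from the Z-score trace.

    A tastant epoch is responsive when the Z-score peaks above ``sd_mult``
    baseline SDs *and* its epoch mean exceeds ``mean_z_cutoff``; otherwise
    the mean Z is clamped to 0.  Both thresholds are parameters.
    """
    if trace.zscore is None:
        trace = compute_dff_zscore(trace, schedule.baseline_window)
    n = len(trace.ratio)
    mean_z, resp, clamped = {}, {}, {}
    for ep in schedule.epochs:
        sl = schedule.epoch_slice(ep.tastant)
        if sl.stop > n:
            raise ParameterError(
                f"epoch {ep.tastant!r} extends past the end of the trace"
            )
        z = trace.zscore[sl]
        mz = float(np.mean(z))
        ok = bool(np.max(z) > sd_mult and mz > mean_z_cutoff)
        mean_z[ep.tastant] = mz
        resp[ep.tastant] = ok
        clamped[ep.tastant] = mz if ok else 0.0
    return ResponseSummary(trace.roi_id, mean_z, resp, clamped)


def response_index(
    summary: ResponseSummary, sweet: str = "sweet", umami: str = "umami"
) -> float | None:
    """Sweet/umami response index on clamped mean Z-scores; ``None`` = excluded.

    ``(S - U) / (S + U)``: +1 for sweet-only, -1 for umami-only, 0 balanced.
    When both clamped values are 0 the case is excluded (a value, not an
    error).  Clamping floors both terms at 0, so the denominator is positive
    whenever the index is defined.
    """
    s = summary.mean_z_clamped.get(sweet, 0.0)
    u = summary.mean_z_clamped.get(umami, 0.0)
    if s == 0.0 and u == 0.0:
        summary.response_index = None
        return None
    idx = (s - u) / (s + u)
    summary.response_index = idx
    return idx


def classify_tuning(index: float | None) -> str:
    """Map a response index to a tuning class.

    +1 → sweet, -1 → umami, any intermediate value → dual; an excluded index
    (``None``) stays excluded.
    """
    if index is None:
        return EXCLUDED
    if math.isnan(index) or abs(index) > 1:
        raise ParameterError(f"response index {index} outside [-1, 1]")
    if index == 1:
        return "sweet"
    if index == -1:
        return "umami"
    return "dual"


def summarize_responses(
    trace: CalciumTrace,
    schedule: StimulusSchedule,
    sd_mult: float = 2.0,
    mean_z_cutoff: float = 1.0,
    sweet: str = "sweet",
    umami: str = "umami",
) -> ResponseSummary:
    """Full per-ROI summary: responsiveness, response index, tuning class."""
    summary = classify_responsiveness(trace, schedule, sd_mult, mean_z_cutoff)
    response_index(summary, sweet, umami)
    summary.tuning_class = classify_tuning(summary.response_index)
    return summary


def summaries_to_frame(summaries: list[ResponseSummary]) -> pd.DataFrame:
    """Tabulate summaries: one row per ROI, columns per tastant plus index/class."""
    rows = []
    for s in summaries:
        row: dict = {"roi_id": s.roi_id}
        for t, v in s.mean_z.items():
            row[f"mean_z_{t}"] = v
            row[f"responsive_{t}"] = s.responsive[t]
            row[f"clamped_{t}"] = s.mean_z_clamped[t]
        row["response_index"] = np.nan if s.response_index is None else s.response_index
        row["tuning_class"] = s.tuning_class
        rows.append(row)
    return pd.DataFrame(rows).set_index("roi_id")
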