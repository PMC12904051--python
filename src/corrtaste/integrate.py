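"""Correlative single-cell integration and statistics.

Merges the three per-cell modalities — functional (mean Z per tastant,
responsiveness, tuning), mRNA (digital spot counts per gene), and protein
(IF status/intensity) — into one multimodal profile per cell, then runs the
correlative statistics: univariate ROC linking a marker to function,
receptor-class calling against a CA4+ negative control, afferent-nerve
adjacency, and attribution of dual-tuned nerve responses to intrinsic
(dual-receptor cell) versus spillover (neighboring sweet + umami cells)
origins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.draw import polygon as draw_polygon

from .errors import (
    ConfigurationError,
    ConsistencyError,
    GeometryError,
    ParameterError,
)

TAS1R_GENES = ("Tas1R1", "Tas1R2", "Tas1R3")

__all__ = [
    "RocResult",
    "build_cell_profiles",
    "classify_if_positive",
    "roc_curve",
    "roc_univariate",
    "call_expression_class",
    "afferent_adjacency",
    "summarize_dual_tuning",
    "wilcoxon_paired",
    "mann_whitney",
    "ks_compare",
]


# ---------------------------------------------------------------------------
# profiles


def build_cell_profiles(
    mask_labels: np.ndarray,
    count_tables: dict[int, pd.DataFrame] | None = None,
    if_tables: dict[str, pd.DataFrame] | None = None,
    response_summaries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One multimodal row per segmented cell.

    ``count_tables`` maps round → (cell × gene) counts; a gene probed in
    several rounds keeps its earliest-round counts (later rounds are
    stability re-probes).  ``if_tables`` maps protein → table with an
    ``if_intensity`` column (and optionally ``if_positive``).
    ``response_summaries`` is indexed by cell label with ``mean_z_*`` /
    ``responsive_*`` / ``tuning_class`` columns.  A modality absent for a
    cell stays NA — never a silent zero.  A label appearing in a table but
    not in the mask is a consistency error.
    """
    ids = np.unique(np.asarray(mask_labels))
    ids = ids[ids > 0]
    prof = pd.DataFrame(index=pd.Index(ids, name="cell"))

    for rnd in sorted(count_tables or {}):
        tab = count_tables[rnd]
        extra = tab.index.difference(prof.index)
        if len(extra):
            raise ConsistencyError(
                f"round {rnd} counts carry labels absent from the mask: {list(extra)[:5]}"
            )
        for gene in tab.columns:
            col = f"count_{gene}"
            if col not in prof.columns:
                prof[col] = pd.array([pd.NA] * len(prof), dtype="Int64")
                prof.loc[tab.index, col] = tab[gene].astype("Int64").to_numpy()
    for protein, tab in (if_tables or {}).items():
        extra = tab.index.difference(prof.index)
        if len(extra):
            raise ConsistencyError(
                f"IF table for {protein} carries labels absent from the mask"
            )
        prof[f"ifint_{protein}"] = np.nan
        prof.loc[tab.index, f"ifint_{protein}"] = tab["if_intensity"].to_numpy()
        if "if_positive" in tab.columns:
            prof[f"if_{protein}"] = pd.array([pd.NA] * len(prof), dtype="boolean")
            prof.loc[tab.index, f"if_{protein}"] = tab["if_positive"].astype(bool).to_numpy()
    if response_summaries is not None:
        cell_rows = response_summaries[
            response_summaries.index.map(lambda i: isinstance(i, (int, np.integer)))
        ]
        extra = cell_rows.index.difference(prof.index)
        if len(extra):
            raise ConsistencyError("response summaries carry labels absent from the mask")
        for col in cell_rows.columns:
            prof[col] = np.nan if cell_rows[col].dtype.kind == "f" else pd.NA
            prof.loc[cell_rows.index, col] = cell_rows[col].to_numpy()
    return prof


def classify_if_positive(
    if_intensity: np.ndarray | pd.Series, method: str | float = "otsu"
) -> np.ndarray:
    """Binary IF positivity per cell from mean in-mask intensities.

    Default is a two-component split (Otsu on the per-cell means); a fixed
    numeric threshold is also supported.  Scale-invariant under Otsu.
    """
    vals = np.asarray(if_intensity, dtype=float)
    if len(vals) < 4:
        raise ParameterError("IF classification needs >= 4 cells")
    if isinstance(method, str):
        if method != "otsu":
            raise ParameterError(f"unknown IF method {method!r}")
        if np.ptp(vals) == 0:
            raise ParameterError("all IF intensities equal; split undefined")
        # Otsu's between-class-variance criterion evaluated exactly over the
        # sample splits (histogram binning is unreliable for tens of cells)
        s = np.sort(vals)
        best_bc, thr = -np.inf, s[0]
        n = len(s)
        for i in range(1, n):
            lo, hi = s[:i], s[i:]
            bc = (i / n) * ((n - i) / n) * (lo.mean() - hi.mean()) ** 2
            if bc > best_bc:
                best_bc, thr = bc, 0.5 * (s[i - 1] + s[i])
    else:
        thr = float(method)
    return vals > thr


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_threshold: float
    youden_j: float


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Empirical ROC of a scalar feature against a binary label.

    Thresholds sweep the observed feature values (rule: positive if score ≥
    threshold); AUC by the trapezoid rule; the operating threshold maximizes
    Youden's J = TPR − FPR, ties resolved toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ParameterError("scores and labels differ in length")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("ROC needs both classes non-empty")

    thr = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.array([(scores[labels] >= t).mean() for t in thr])
    fpr = np.array([(scores[~labels] >= t).mean() for t in thr])
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best_j = j.max()
    # among maximizers pick the lowest threshold
    candidates = thr[np.isclose(j, best_j)]
    opt = float(candidates.min())
    return RocResult(thr, tpr, fpr, auc, opt, float(best_j))


def roc_univariate(
    profiles: pd.DataFrame, feature: str, label: str
) -> RocResult:
    """ROC of one profile column (e.g. ``mean_z_sour`` or ``count_CA4``)
    against a boolean profile column (e.g. ``if_CA4``), NA rows dropped."""
    sub = profiles[[feature, label]].dropna()
    return roc_curve(sub[feature].astype(float).to_numpy(), sub[label].astype(bool).to_numpy())


# ---------------------------------------------------------------------------
# expression-class calling


def call_expression_class(
    profiles: pd.DataFrame,
    control_cells: pd.Index | np.ndarray | list | None = None,
    *,
    percentile: float = 95.0,
    fixed_thresholds: dict[str, float] | None = None,
) -> pd.Series:
    """Receptor-class call per cell from Tas1R spot counts.

    Sweet/umami receptors are heterodimers, so the classes are positivity
    patterns: Tas1R2+/R3+ → sweet, Tas1R1+/R3+ → umami, all three → dual.
    Positivity thresholds come from the counts observed in CA4+ cells
    (``control_cells``), which do not express Tas1Rs and hence bound the
    background: threshold(gene) = the given percentile of control counts.
    Alternatively supply ``fixed_thresholds`` per gene.  Cells listed as
    controls are called sour.
    """
    thresholds: dict[str, float] = {}
    if fixed_thresholds:
        thresholds.update(fixed_thresholds)
    control_idx = pd.Index(control_cells) if control_cells is not None else pd.Index([])
    missing = [g for g in TAS1R_GENES if g not in thresholds]
    if missing:
        if len(control_idx) == 0:
            raise ConfigurationError(
                "expression calling needs CA4+ control cells or fixed thresholds"
            )
        for gene in missing:
            col = f"count_{gene}"
            ctrl = profiles.loc[profiles.index.intersection(control_idx), col].dropna()
            if len(ctrl) == 0:
                raise ConfigurationError(f"no control counts available for {gene}")
            thresholds[gene] = float(np.percentile(ctrl.astype(float), percentile))

    out = {}
    for cell, row in profiles.iterrows():
        if cell in control_idx:
            out[cell] = "sour"
            continue
        pos = {}
        for gene in TAS1R_GENES:
            v = row.get(f"count_{gene}")
            pos[gene] = (not pd.isna(v)) and float(v) > thresholds[gene]
        if pos["Tas1R1"] and pos["Tas1R2"] and pos["Tas1R3"]:
            out[cell] = "dual"
        elif pos["Tas1R2"] and pos["Tas1R3"]:
            out[cell] = "sweet"
        elif pos["Tas1R1"] and pos["Tas1R3"]:
            out[cell] = "umami"
        else:
            out[cell] = "negative"
    calls = pd.Series(out, name="expression_class")
    calls.index.name = profiles.index.name
    calls.attrs["thresholds"] = thresholds
    return calls


# ---------------------------------------------------------------------------
# adjacency and dual-tuning attribution


def afferent_adjacency(
    nerve_rois,
    mask: np.ndarray,
    radius_um: float = 2.0,
    pixel_size_um: float = 0.5,
) -> dict[int, tuple[int, ...]]:
    """Cells whose label comes within ``radius_um`` of each nerve ROI.

    Implemented as a dilation test on the rasterized ROI polygon; cell ids
    are reported in ascending order.  An ROI that rasterizes to nothing is a
    geometry error.
    """
    h, w = mask.shape
    radius_px = radius_um / pixel_size_um
    out: dict[int, tuple[int, ...]] = {}
    for roi in nerve_rois:
        poly = np.asarray(roi.polygon if hasattr(roi, "polygon") else roi, dtype=float)
        nid = getattr(roi, "nerve_id", len(out))
        # shoelace area: a degenerate (zero-area) polygon encloses nothing
        x, y = poly[:, 0], poly[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area == 0:
            raise GeometryError(f"nerve ROI {nid} has zero area")
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        if len(rr) == 0:
            raise GeometryError(f"nerve ROI {nid} rasterizes to an empty region")
        m = np.zeros((h, w), dtype=bool)
        m[rr, cc] = True
        dist = ndimage.distance_transform_edt(~m)
        near = np.unique(mask[dist <= radius_px])
        out[int(nid)] = tuple(int(v) for v in near[near > 0])
    return out


def summarize_dual_tuning(
    nerve_summaries: pd.DataFrame,
    adjacency: dict[int, tuple[int, ...]],
    expression_class: pd.Series,
) -> dict:
    """Attribute each dual-tuned afferent nerve to a cellular origin.

    ``intrinsic``: at least one adjacent cell expresses all three receptors
    (the dual-tuned-cell explanation; takes precedence).  ``spillover``: no
    adjacent dual cell, but both a sweet and an umami cell are adjacent, so
    transmitter spillover can explain the dual response.  Anything else is
    ``unexplained``.  Returns per-nerve records plus counts and fractions;
    with no dual-tuned nerves the fractions carry an explicit
    zero-denominator flag.
    """
    records = []
    for nid, row in nerve_summaries.iterrows():
        if row.get("tuning_class") != "dual":
            continue
        key = int(str(nid).replace("nerve_", "")) if isinstance(nid, str) else int(nid)
        if key not in adjacency:
            raise ConsistencyError(f"dual-tuned nerve {nid} has no adjacency entry")
        classes = {expression_class.get(c, "missing") for c in adjacency[key]}
        if "dual" in classes:
            attribution = "intrinsic"
        elif "sweet" in classes and "umami" in classes:
            attribution = "spillover"
        else:
            attribution = "unexplained"
        records.append(
            {"nerve_id": nid, "adjacent_cells": adjacency[key], "attribution": attribution}
        )
    table = pd.DataFrame(records)
    n = len(table)
    cats = ("intrinsic", "spillover", "unexplained")
    counts = {c: int((table["attribution"] == c).sum()) if n else 0 for c in cats}
    fractions = {c: (counts[c] / n if n else float("nan")) for c in cats}
    return {
        "per_nerve": table,
        "counts": counts,
        "fractions": fractions,
        "n_dual_nerves": n,
        "zero_denominator": n == 0,
    }


# ---------------------------------------------------------------------------
# thin statistical utilities


def wilcoxon_paired(a, b) -> tuple[float, float]:
    res = stats.wilcoxon(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a, b) -> tuple[float, float]:
    res = stats.mannwhitneyu(np.asarray(a, float), np.asarray(b, float), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def ks_compare(a, b) -> tuple[float, float]:
    res = stats.ks_2samp(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
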