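"""Image registration: in-vivo→fixed non-rigid alignment and multi-round rigid alignment.

Two alignment problems are solved here.  The live two-photon frame and the
first-round fixed-tissue frame differ by a small smooth fixation-induced
deformation; an intensity-based B-spline registration on the cytosolic
reporter channel recovers it as a dense deformation vector field, whose
accuracy is quantified as an RMS error expressed as percent of the measured
(pairwise centroid) distance.  Successive staining rounds differ only by a
rigid move of the section; a rigid registration anchored on the nuclear
channel recovers rotation + translation, validated by the image Pearson
correlation and by line-profile peak offsets.

Transform conventions
---------------------
A :class:`RigidTransform` is a point map ``p' = R(p - c) + c + t`` acting on
(x, y) pixel coordinates about center ``c``.  ``register_rigid(ref, mov)``
returns the map taking *moving-frame* points into the *reference* frame, so
``apply_transform(mov_img, T)`` resamples the moving image onto the reference
grid and ``apply_transform(points_in_mov, T)`` sends detections (e.g. smFISH
spots) into the reference frame.

A :class:`DeformationField` stores per-pixel displacement ``u`` on the fixed
grid such that ``warped(x) = moving(x + u(x))``; i.e. ``u(x)`` is the offset
from a fixed-frame point to its matching moving-frame point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .errors import (
    ConvergenceError,
    DegenerateContentError,
    GeometryError,
    ParameterError,
)

__all__ = [
    "RigidTransform",
    "DeformationField",
    "RegistrationQC",
    "register_rigid",
    "register_nonrigid",
    "apply_transform",
    "deformation_rms_error",
    "registration_qc",
    "default_profile_lines",
]


# ---------------------------------------------------------------------------
# transforms


@dataclass(frozen=True)
class RigidTransform:
    """2D rotation + translation about ``center``, in pixel units."""

    rotation_deg: float
    translation_px: tuple[float, float]  # (dx, dy)
    center: tuple[float, float]  # (cx, cy)

    @classmethod
    def identity(cls, shape: tuple[int, int] | None = None) -> "RigidTransform":
        c = (0.0, 0.0) if shape is None else ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
        return cls(0.0, (0.0, 0.0), c)

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (n, 2) array of (x, y) points through the transform."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(self.center)
        return (pts - c) @ self.matrix.T + c + np.asarray(self.translation_px)

    def inverse(self) -> "RigidTransform":
        t_inv = -self.matrix.T @ np.asarray(self.translation_px)
        return RigidTransform(-self.rotation_deg, (float(t_inv[0]), float(t_inv[1])), self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the map ``p -> self(other(p))`` (centers must agree)."""
        if not np.allclose(self.center, other.center):
            raise ParameterError("can only compose transforms sharing a center")
        rot = self.rotation_deg + other.rotation_deg
        c = np.asarray(self.center)
        t = self.apply_points(other.apply_points(c)) - c  # net displacement of center
        return RigidTransform(rot, (float(t[0]), float(t[1])), self.center)

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation_deg,
            "translation_px": list(self.translation_px),
            "center": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(float(d["rotation_deg"]), tuple(d["translation_px"]), tuple(d["center"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DeformationField:
    """Dense displacement field on the fixed grid; ``displacement[y, x] = (ux, uy)``."""

    displacement: np.ndarray  # (H, W, 2) in (ux, uy) order
    control_grid_spacing_px: float
    rms_vs_distance: pd.DataFrame | None = None

    def __post_init__(self):
        if self.displacement.ndim != 3 or self.displacement.shape[-1] != 2:
            raise ParameterError("displacement must be (H, W, 2)")
        if not np.all(np.isfinite(self.displacement)):
            raise ParameterError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacement.shape[:2]

    def sample(self, pts: np.ndarray) -> np.ndarray:
        """Bilinearly interpolate the displacement at (n, 2) (x, y) points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        coords = np.stack([pts[:, 1], pts[:, 0]])  # (row, col)
        ux = ndimage.map_coordinates(self.displacement[..., 0], coords, order=1, mode="nearest")
        uy = ndimage.map_coordinates(self.displacement[..., 1], coords, order=1, mode="nearest")
        return np.stack([ux, uy], axis=1)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map fixed-frame points to their moving-frame positions."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts + self.sample(pts)

    def invert_points(self, pts: np.ndarray, n_iter: int = 8) -> np.ndarray:
        """Map moving-frame points back to the fixed frame (fixed-point iteration).

        Accurate for the small smooth deformations this field models, where
        the iteration ``x <- p - u(x)`` contracts.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        x = pts.copy()
        for _ in range(n_iter):
            x = pts - self.sample(x)
        return x


@dataclass
class RegistrationQC:
    """Registration quality report: image correlation and line-profile peak offsets."""

    pearson_r: float
    peak_offsets_px: list[float]
    max_peak_offset_px: float
    flat_profiles: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers


def _as_sitk(img: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.ascontiguousarray(img, dtype=np.float64))


def _check_geometry(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise GeometryError(f"image geometries differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise GeometryError("expected 2D images")


# ---------------------------------------------------------------------------
# rigid


def register_rigid(
    reference_nuclear: np.ndarray,
    round_nuclear: np.ndarray,
    *,
    n_iterations: int = 300,
    shrink_factors: tuple[int, ...] = (4, 2, 1),
) -> RigidTransform:
    """Estimate the rigid move taking ``round_nuclear`` onto ``reference_nuclear``.

    Translation is initialized by phase correlation; rotation + translation
    are then refined by mean-squared-difference gradient descent over a
    3-level multiresolution pyramid.  Deterministic for fixed inputs.
    Returns the point map from the round frame into the reference frame.
    """
    _check_geometry(reference_nuclear, round_nuclear)
    if float(np.std(reference_nuclear)) == 0.0 or float(np.std(round_nuclear)) == 0.0:
        raise DegenerateContentError("featureless image: rigid registration has no anchor")

    shift, _, _ = phase_cross_correlation(
        reference_nuclear.astype(float), round_nuclear.astype(float), upsample_factor=4
    )
    # skimage shift (dy, dx) moves the round image onto the reference; the
    # resampling map reference->round therefore starts at -shift.
    init_t = (-float(shift[1]), -float(shift[0]))

    h, w = reference_nuclear.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)

    fixed = _as_sitk(reference_nuclear)
    moving = _as_sitk(round_nuclear)
    tx = sitk.Euler2DTransform()
    tx.SetCenter(center)
    tx.SetTranslation(init_t)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0,
        minStep=1e-5,
        numberOfIterations=n_iterations,
        gradientMagnitudeTolerance=1e-9,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel([max(f // 2, 0) for f in shrink_factors])
    reg.SetInitialTransform(tx, inPlace=True)
    reg.Execute(fixed, moving)

    # sitk's Euler2D maps reference-frame points to round-frame points
    # (resampling convention); invert to get the round->reference point map.
    ref_to_round = RigidTransform(
        float(np.rad2deg(tx.GetAngle())), tuple(float(v) for v in tx.GetTranslation()), center
    )
    return ref_to_round.inverse()


# ---------------------------------------------------------------------------
# non-rigid


def register_nonrigid(
    fixed_img: np.ndarray,
    moving_img: np.ndarray,
    grid_spacing_px: float = 32.0,
    *,
    n_iterations: int = 200,
    shrink_factors: tuple[int, ...] = (4, 2, 1),
    convergence_tol: float = 1e-8,
) -> tuple[DeformationField, np.ndarray]:
    """B-spline non-rigid registration of ``moving_img`` onto ``fixed_img``.

    Multi-resolution, mean-squared-difference metric, LBFGSB optimizer.
    Returns the dense deformation field on the fixed grid and the warped
    moving image (linear interpolation).
    """
    _check_geometry(fixed_img, moving_img)
    if grid_spacing_px <= 1:
        raise ParameterError("grid_spacing_px must exceed 1 px")

    h, w = fixed_img.shape
    fixed = _as_sitk(fixed_img)
    moving = _as_sitk(moving_img)

    mesh = [max(int(round(w / grid_spacing_px)), 2), max(int(round(h / grid_spacing_px)), 2)]
    tx = sitk.BSplineTransformInitializer(fixed, mesh, order=3)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=convergence_tol,
        numberOfIterations=n_iterations,
        maximumNumberOfCorrections=8,
        maximumNumberOfFunctionEvaluations=2000,
    )
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel([max(f // 2, 0) for f in shrink_factors])
    reg.SetInitialTransform(tx, inPlace=True)
    reg.Execute(fixed, moving)

    to_field = sitk.TransformToDisplacementFieldFilter()
    to_field.SetReferenceImage(fixed)
    disp = sitk.GetArrayFromImage(to_field.Execute(tx))  # (H, W, 2) as (ux, uy)
    if not np.all(np.isfinite(disp)):
        raise ConvergenceError(
            "B-spline optimization produced a non-finite displacement field",
            residual=float(reg.GetMetricValue()),
        )
    warped = sitk.GetArrayFromImage(sitk.Resample(moving, fixed, tx, sitk.sitkLinear, 0.0))
    return DeformationField(disp, grid_spacing_px), warped


def deformation_rms_error(
    deformation: DeformationField,
    fixed_points: np.ndarray,
    moving_points: np.ndarray,
    *,
    bin_edges_px: np.ndarray | None = None,
    min_distance_px: float = 1.0,
) -> pd.DataFrame:
    """RMS deformation-tracking error as percent of pairwise centroid distance.

    ``fixed_points``/``moving_points`` are matched (n, 2) centroids in the two
    frames.  For every unordered pair of centroids the true relative
    displacement ``(m_i - f_i) - (m_j - f_j)`` is compared with the
    field-predicted one ``u(f_i) - u(f_j)``; the residual norm is expressed as
    percent of the pair's fixed-frame distance.  A pairwise relative measure
    is used so that a constant offset between the frames does not count as
    tracking error.  Results are RMS-aggregated into distance bins; the table
    is also stored on ``deformation.rms_vs_distance``.
    """
    fixed_points = np.atleast_2d(np.asarray(fixed_points, dtype=float))
    moving_points = np.atleast_2d(np.asarray(moving_points, dtype=float))
    if fixed_points.shape != moving_points.shape or len(fixed_points) < 2:
        raise ParameterError("need >= 2 matched centroid pairs of equal shape")

    true_disp = moving_points - fixed_points
    pred_disp = deformation.sample(fixed_points)

    i, j = np.triu_indices(len(fixed_points), k=1)
    dist = np.linalg.norm(fixed_points[i] - fixed_points[j], axis=1)
    keep = dist >= min_distance_px
    i, j, dist = i[keep], j[keep], dist[keep]
    resid = np.linalg.norm(
        (true_disp[i] - true_disp[j]) - (pred_disp[i] - pred_disp[j]), axis=1
    )
    pct = 100.0 * resid / dist

    if bin_edges_px is None:
        bin_edges_px = np.arange(0.0, dist.max() + 25.0, 25.0)
    which = np.digitize(dist, bin_edges_px) - 1
    rows = []
    for b in range(len(bin_edges_px) - 1):
        sel = which == b
        if not np.any(sel):
            continue
        rows.append(
            {
                "distance_px": 0.5 * (bin_edges_px[b] + bin_edges_px[b + 1]),
                "rms_error_pct": float(np.sqrt(np.mean(pct[sel] ** 2))),
                "n_pairs": int(sel.sum()),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["overall_rms_pct"] = float(np.sqrt(np.mean(pct**2)))
    deformation.rms_vs_distance = table
    return table


# ---------------------------------------------------------------------------
# applying transforms


def _grid_points(shape: tuple[int, int]) -> np.ndarray:
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)


def apply_transform(obj, transform: "RigidTransform | DeformationField", *, is_labels: bool | None = None):
    """Apply a rigid or deformation transform to an image, label mask, or point set.

    Point sets (n, 2) arrays of (x, y) are mapped analytically through the
    point map.  Images are resampled onto the output grid — linear
    interpolation for intensity images, nearest-neighbor for label masks
    (labels are never blended).  An integer-typed image is treated as a label
    mask unless ``is_labels`` says otherwise.
    """
    if isinstance(obj, np.ndarray) and obj.ndim == 2 and obj.shape[1] == 2 and obj.shape[0] != 2:
        # unambiguous (n, 2) point set with n != 2
        return transform.apply_points(obj)
    if not isinstance(obj, np.ndarray) or obj.ndim != 2:
        raise TypeError(f"cannot transform object of type {type(obj).__name__} / shape")

    labels = is_labels if is_labels is not None else np.issubdtype(obj.dtype, np.integer)
    order = 0 if labels else 1

    # Resampling pulls back through the inverse point map: out(y) = in(T^-1 y).
    if isinstance(transform, RigidTransform):
        src = transform.inverse().apply_points(_grid_points(obj.shape))
    elif isinstance(transform, DeformationField):
        # the field's point map fixed->moving is itself the pull-back map for
        # resampling the moving image onto the fixed grid
        src = transform.apply_points(_grid_points(obj.shape))
    else:
        raise TypeError(f"unknown transform type {type(transform).__name__}")

    coords = np.stack([src[:, 1], src[:, 0]])
    out = ndimage.map_coordinates(
        obj.astype(float) if not labels else obj,
        coords,
        order=order,
        mode="constant",
        cval=0,
    )
    return out.reshape(obj.shape).astype(obj.dtype if labels else float)


# ---------------------------------------------------------------------------
# QC


def default_profile_lines(
    shape: tuple[int, int],
    n: int = 4,
    center: tuple[float, float] | None = None,
    radius: float | None = None,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Lines through ``center`` (default: image center) at evenly spaced angles."""
    h, w = shape
    cx, cy = center if center is not None else ((w - 1) / 2.0, (h - 1) / 2.0)
    r = radius if radius is not None else 0.45 * min(h, w)
    lines = []
    for k in range(n):
        th = np.pi * k / n
        dx, dy = r * np.cos(th), r * np.sin(th)
        lines.append(((cx - dx, cy - dy), (cx + dx, cy + dy)))
    return lines


def _profile(img: np.ndarray, p0, p1, smooth_sigma: float) -> np.ndarray:
    n = int(np.ceil(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))) + 1
    xs = np.linspace(p0[0], p1[0], n)
    ys = np.linspace(p0[1], p1[1], n)
    vals = ndimage.map_coordinates(img.astype(float), np.stack([ys, xs]), order=1)
    if smooth_sigma > 0:
        vals = ndimage.gaussian_filter1d(vals, smooth_sigma)
    return vals


def registration_qc(
    reference: np.ndarray,
    registered: np.ndarray,
    profile_lines=None,
    *,
    smooth_sigma: float = 1.0,
) -> RegistrationQC:
    """Pearson correlation over the reference foreground plus line-profile peak offsets.

    Foreground is an Otsu threshold on the reference.  Each profile is sampled
    at 1 px steps, Gaussian-smoothed, and the offset is the distance between
    the two argmax positions (ties broken leftmost); flat profiles are
    flagged and excluded from the max.
    """
    _check_geometry(reference, registered)
    if profile_lines is None:
        # anchor the default profiles on the brightest landmark so each line
        # has one dominant peak; argmax comparison is meaningless on lines
        # crossing several equally bright structures
        smooth_ref = ndimage.gaussian_filter(reference.astype(float), 2.0)
        my, mx = np.unravel_index(int(np.argmax(smooth_ref)), reference.shape)
        h, w = reference.shape
        r = min(12.0, mx, my, w - 1 - mx, h - 1 - my)
        profile_lines = default_profile_lines(
            reference.shape, center=(float(mx), float(my)), radius=max(r, 6.0)
        )

    fg = reference > threshold_otsu(reference.astype(float))
    a = reference[fg].astype(float)
    b = registered[fg].astype(float)
    if a.std() == 0 or b.std() == 0:
        raise DegenerateContentError("foreground has no variance; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])

    offsets, flat = [], []
    for idx, (p0, p1) in enumerate(profile_lines):
        pa = _profile(reference, p0, p1, smooth_sigma)
        pb = _profile(registered, p0, p1, smooth_sigma)
        if np.ptp(pa) < 1e-12 or np.ptp(pb) < 1e-12:
            flat.append(idx)
            offsets.append(float("nan"))
            continue
        offsets.append(float(abs(int(np.argmax(pa)) - int(np.argmax(pb)))))
    finite = [o for o in offsets if np.isfinite(o)]
    return RegistrationQC(
        pearson_r=r,
        peak_offsets_px=offsets,
        max_peak_offset_px=float(max(finite)) if finite else float("nan"),
        flat_profiles=flat,
    )
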