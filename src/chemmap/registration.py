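"""Landmark registration of slice photographs onto hypercube rasters.

The distorted frame is the photograph taken after cylindrical sampling; the
reference frame is the hypercube raster.  Three nested planar families are
fitted on control-point pairs — non-reflective similarity (translation,
rotation, uniform scale), affine (adds shear) and projective (adds
perspective) — scored on held-out check points, and the winner maps the
detected sampling circles into the hypercube frame as a labelled ROI mask.

Coordinates are 0-based pixel centres with x = column and y = row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import least_squares
from skimage.feature import canny
from skimage.transform import (AffineTransform, ProjectiveTransform,
                               SimilarityTransform, hough_circle,
                               hough_circle_peaks)

log = logging.getLogger(__name__)

KINDS = ("nonreflective_similarity", "affine", "projective")

#: minimum control-point pairs per family
MIN_PAIRS = {"nonreflective_similarity": 2, "affine": 3, "projective": 4}


@dataclass
class Transform2D:
    """3x3 homogeneous planar transform with a family tag."""

    kind: str
    matrix: np.ndarray
    source_frame: str = "distorted"
    target_frame: str = "reference"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}; got {self.kind!r}")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) xy points from the source to the target frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return hom[:, :2] / hom[:, 2:3]

    def inverse(self) -> "Transform2D":
        return Transform2D(self.kind, np.linalg.inv(self.matrix),
                           source_frame=self.target_frame, target_frame=self.source_frame)

    @staticmethod
    def identity(kind: str = "affine") -> "Transform2D":
        return Transform2D(kind, np.eye(3))


@dataclass
class RegistrationReport:
    """Per-family control/check-point errors and the selected family."""

    entries: dict[str, dict] = field(default_factory=dict)
    chosen_kind: str | None = None


def _check_degeneracy(src: np.ndarray, kind: str) -> None:
    n = len(src)
    if n < MIN_PAIRS[kind]:
        raise ValueError(f"{kind} needs >= {MIN_PAIRS[kind]} control pairs; got {n}")
    if kind == "nonreflective_similarity":
        if np.allclose(src, src[0], atol=1e-9):
            raise ValueError("similarity fit is degenerate: all control points coincide")
        return
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(src).max())) < 2:
        raise ValueError(f"{kind} fit is degenerate: control points are collinear")
    if kind == "projective":
        for (i, j, k) in combinations(range(n), 3):
            u, v = src[j] - src[i], src[k] - src[i]
            area = u[0] * v[1] - u[1] * v[0]
            if abs(area) < 1e-8 * max(1.0, np.abs(src).max()) ** 2:
                raise ValueError(
                    f"projective fit is degenerate: control points {i}, {j}, {k} are collinear"
                )


def _refine_projective(matrix: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Polish the DLT solution to a geometric least-squares optimum."""

    def resid(p):
        H = np.append(p, 1.0).reshape(3, 3)
        hom = np.column_stack([src, np.ones(len(src))]) @ H.T
        return (hom[:, :2] / hom[:, 2:3] - dst).ravel()

    best = None
    for x0 in (matrix.ravel()[:8] / matrix[2, 2],):
        sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    return np.append(best.x, 1.0).reshape(3, 3)


def fit_transform(control_pairs: np.ndarray, kind: str,
                  source_frame: str = "distorted",
                  target_frame: str = "reference") -> Transform2D:
    """Least-squares fit of one transform family on control-point pairs.

    ``control_pairs`` has shape (N, 2, 2): ``[:, 0]`` are source-frame xy
    points, ``[:, 1]`` the corresponding target-frame points.
    """
    pairs = np.asarray(control_pairs, dtype=float)
    if pairs.ndim != 3 or pairs.shape[1:] != (2, 2):
        raise ValueError("control_pairs must have shape (N, 2, 2)")
    src, dst = pairs[:, 0], pairs[:, 1]
    _check_degeneracy(src, kind)

    cls = {"nonreflective_similarity": SimilarityTransform,
           "affine": AffineTransform,
           "projective": ProjectiveTransform}[kind]
    t = cls.from_estimate(src, dst)
    ok = bool(t)
    matrix = t.params if ok else None
    if kind == "projective":
        if ok and np.all(np.isfinite(matrix)):
            matrix = _refine_projective(matrix, src, dst)
            # the affine subfamily is nested: never return a worse optimum
            if len(src) > 4:
                aff = fit_transform(pairs, "affine", source_frame, target_frame)
                if _control_sse(matrix, src, dst) > _control_sse(aff.matrix, src, dst):
                    matrix = _refine_projective(aff.matrix, src, dst)
    if not ok or not np.all(np.isfinite(matrix)):
        raise ValueError(f"{kind} fit failed on the given control points")
    return Transform2D(kind, matrix, source_frame, target_frame)


def _control_sse(matrix: np.ndarray, src: np.ndarray, dst: np.ndarray) -> float:
    hom = np.column_stack([src, np.ones(len(src))]) @ matrix.T
    return float(np.sum((hom[:, :2] / hom[:, 2:3] - dst) ** 2))


def point_errors(transform: Transform2D, pairs: np.ndarray) -> tuple[float, float]:
    """(RMSE, MAPE) of mapped source points against target points.

    RMSE pools squared Euclidean point distances (pixels); MAPE pools the
    per-coordinate absolute percentage errors.
    """
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) == 0:
        raise ValueError("empty point set")
    src, dst = pairs[:, 0], pairs[:, 1]
    if np.any(np.abs(dst) < 1e-12):
        raise ValueError(
            "target coordinate equal to zero: MAPE is undefined; offset the "
            "frame origin so all coordinates are non-zero"
        )
    mapped = transform.apply(src)
    rmse = float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))
    mape = float(np.mean(np.abs(mapped - dst) / np.abs(dst)) * 100.0)
    return rmse, mape


def registration_errors(transform: Transform2D, control_pairs: np.ndarray,
                        check_pairs: np.ndarray) -> dict:
    """Control- and check-point RMSE/MAPE for one fitted transform."""
    rmse_reg, mape_reg = point_errors(transform, control_pairs)
    rmse_ch, mape_ch = point_errors(transform, check_pairs)
    return {
        "kind": transform.kind,
        "rmse_reg": rmse_reg,
        "mape_reg": mape_reg,
        "rmse_ch": rmse_ch,
        "mape_ch": mape_ch,
    }


def select_best_transform(reports: dict[str, dict]) -> str:
    """Family with the lowest check-point RMSE.

    Ties break on check-point MAPE, then on the family needing fewer
    control points (similarity before affine before projective).
    """
    if not reports:
        raise ValueError("no registration reports to select from")
    return min(reports, key=lambda k: (reports[k]["rmse_ch"], reports[k]["mape_ch"],
                                       MIN_PAIRS[k]))


def compare_transforms(control_pairs: np.ndarray, check_pairs: np.ndarray,
                       kinds=KINDS) -> RegistrationReport:
    """Fit every family, score it, and pick the winner."""
    report = RegistrationReport()
    for kind in kinds:
        t = fit_transform(control_pairs, kind)
        report.entries[kind] = registration_errors(t, control_pairs, check_pairs)
        report.entries[kind]["transform"] = t
    report.chosen_kind = select_best_transform(report.entries)
    return report


def detect_circles(image: np.ndarray, radius_range: tuple[int, int],
                   expected_count: int = 10, canny_sigma: float = 2.0,
                   score_threshold: float = 0.3):
    """Locate circular sampling holes with a circular Hough accumulator.

    Returns ``(circles, scores)`` where ``circles`` is (k, 3) rows of
    ``(x, y, radius)`` in pixels, ranked by accumulator score.  Emits a
    warning (and returns the partial list) when fewer than
    ``expected_count`` circles clear ``score_threshold``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_circles expects a grayscale image")
    lo, hi = radius_range
    if lo <= 0 or hi < lo:
        raise ValueError("radius_range must be positive and increasing")
    radii = np.arange(lo, hi + 1)
    edges = canny(image, sigma=canny_sigma)
    accum = hough_circle(edges, radii)
    scores, cx, cy, rad = hough_circle_peaks(
        accum, radii, total_num_peaks=expected_count,
        min_xdistance=lo, min_ydistance=lo, threshold=score_threshold,
    )
    keep = scores >= score_threshold
    circles = np.column_stack([cx[keep], cy[keep], rad[keep]]).astype(float)
    scores = np.asarray(scores[keep], dtype=float)
    if len(circles) < expected_count:
        warnings.warn(
            f"found {len(circles)} of {expected_count} expected circles above "
            f"score {score_threshold}"
        )
    return circles, scores


def build_roi_mask(circles: np.ndarray, image_shape: tuple[int, int],
                   transform: Transform2D | None = None) -> np.ndarray:
    """Labelled ROI mask in the target (hypercube) frame.

    Circle centres are mapped through ``transform`` (identity if None);
    disc membership is centre distance <= radius.  Overlapping discs raise;
    discs clipped by the image edge are kept and logged.
    """
    circles = np.atleast_2d(np.asarray(circles, dtype=float))
    centers = circles[:, :2]
    radii = circles[:, 2]
    if transform is not None:
        centers = transform.apply(centers)

    d = np.sqrt(np.sum((centers[:, None, :] - centers[None, :, :]) ** 2, axis=-1))
    rr_sum = radii[:, None] + radii[None, :]
    overlaps = [
        (i + 1, j + 1)
        for i in range(len(circles))
        for j in range(i + 1, len(circles))
        if d[i, j] < rr_sum[i, j]
    ]
    if overlaps:
        raise ValueError(f"ROI discs overlap after mapping: label pairs {overlaps}")

    h, w = image_shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    mask = np.zeros(image_shape, dtype=np.int32)
    for label, ((x, y), r) in enumerate(zip(centers, radii), start=1):
        member = (cols - x) ** 2 + (rows - y) ** 2 <= r**2
        full_area = np.pi * r**2
        if member.sum() < 0.95 * full_area:
            log.info("ROI %d clipped at image edge: %d of ~%.0f pixels",
                     label, member.sum(), full_area)
        mask[member] = label
    return mask
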