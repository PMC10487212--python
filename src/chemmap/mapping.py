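"""Spatial distribution maps of predicted chemical composition.

Calibrated models are applied to every pixel of a flattened reflectance
cube, background and fiducials are masked out, and the resulting maps are
summarised by region-wise reliability (mean absolute percentage difference
between ROI-mean prediction and the wet-chemistry reference, compared
across regions with Tukey's HSD) and by histogram shape statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_multiotsu, threshold_otsu

from .calibration import CalibrationModel
from .hypercube import Hypercube
from .synthetic import COLUMN_OF


# --------------------------------------------------------------------------
# flattening
# --------------------------------------------------------------------------

def flatten_hypercube(cube: Hypercube):
    """Reshape to a (pixels x bands) matrix, row-major, plus the shape record."""
    rows, cols, bands = cube.shape
    return cube.data.reshape(rows * cols, bands), (rows, cols)


def unflatten(matrix: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`flatten_hypercube` for per-pixel vectors or matrices."""
    matrix = np.asarray(matrix)
    if matrix.ndim == 1:
        return matrix.reshape(shape)
    return matrix.reshape(shape + (matrix.shape[1],))


# --------------------------------------------------------------------------
# background masking
# --------------------------------------------------------------------------

def background_mask(cube_or_image, method: str = "otsu", threshold: float | None = None,
                    classes: int = 2) -> np.ndarray:
    """Binary foreground mask of the slice.

    ``method="fixed"`` thresholds at ``threshold``; ``method="otsu"`` finds
    the threshold automatically.  With ``classes=3`` a multi-level Otsu is
    used and the *middle* class is selected — this excludes both the dark
    background and bright fiducial screws.  A cube is reduced to its mean
    reflectance image first.
    """
    if isinstance(cube_or_image, Hypercube):
        image = np.nanmean(cube_or_image.data, axis=2)
    else:
        image = np.asarray(cube_or_image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")

    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        mask = image > threshold
    elif method == "otsu":
        if classes == 2:
            mask = image > threshold_otsu(image)
        else:
            cuts = threshold_multiotsu(image, classes=classes)
            mask = (image > cuts[0]) & (image <= cuts[-1])
    else:
        raise ValueError(f"unknown masking method {method!r}")
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    return mask


# --------------------------------------------------------------------------
# pixel-wise prediction
# --------------------------------------------------------------------------

@dataclass
class DistributionMap:
    """2-D predicted-composition image; background pixels are NaN."""

    values: np.ndarray
    mask: np.ndarray
    composition: str
    wavelengths_nm: list[float]
    units: str = ""
    provenance: dict = field(default_factory=dict)

    def foreground(self) -> np.ndarray:
        return self.values[self.mask]


def predict_map(model: CalibrationModel, flat: np.ndarray, mask: np.ndarray,
                shape: tuple[int, int], grid_wavelengths) -> DistributionMap:
    """Apply a calibration model to every pixel, then mask the background.

    ``flat`` holds full-grid spectra (pixels x bands); the model's input
    wavelengths are looked up on ``grid_wavelengths`` and must all be
    present (missing ones are named in the error).
    """
    grid = np.asarray(grid_wavelengths, dtype=float)
    cols = []
    missing = []
    for w in model.wavelengths_nm:
        hits = np.where(np.isclose(grid, w))[0]
        (cols if hits.size else missing).append(hits[0] if hits.size else w)
    if missing:
        raise KeyError(f"cube grid lacks model wavelengths {missing} nm")

    pred = model.estimator.predict(np.asarray(flat, dtype=float)[:, cols])
    img = unflatten(pred, shape)
    mask = np.asarray(mask, dtype=bool)
    values = np.where(mask, img, np.nan)
    return DistributionMap(
        values=values,
        mask=mask,
        composition=model.composition,
        wavelengths_nm=list(model.wavelengths_nm),
        provenance={"replicate_id": model.replicate_id, "seed": model.seed},
    )


# --------------------------------------------------------------------------
# region-wise reliability (Table-5-style summary)
# --------------------------------------------------------------------------

def regionwise_errors(maps: dict, roi_masks: dict, ref: pd.DataFrame,
                      composition: str):
    """Per-region absolute percentage error of ROI-mean map predictions.

    ``maps``/``roi_masks`` are keyed by (origin, fruit); for each fruit and
    region 1..10 the error is ``|mean(map over ROI) - reference| /
    reference * 100``.  Returns ``(table, per_region)`` where ``table``
    reports mean +- SD over fruit per region and ``per_region`` maps region
    id to the vector of per-fruit errors.
    """
    ycol = COLUMN_OF[composition]
    per_region: dict[int, list[float]] = {r: [] for r in range(1, 11)}
    for key, dmap in maps.items():
        origin, fruit = key
        labels = roi_masks[key]
        sub = ref[(ref["origin"] == origin) & (ref["fruit"] == fruit)]
        for region in range(1, 11):
            member = labels == region
            if not member.any():
                raise ValueError(f"fruit {key}: ROI label {region} missing from mask")
            pred_mean = float(np.nanmean(dmap.values[member]))
            ref_val = float(sub.loc[sub["region"] == region, ycol].iloc[0])
            per_region[region].append(abs(pred_mean - ref_val) / abs(ref_val) * 100.0)
    table = pd.DataFrame(
        {
            "region": list(per_region),
            "mape_mean": [float(np.mean(v)) for v in per_region.values()],
            "mape_sd": [float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                        for v in per_region.values()],
            "n_fruit": [len(v) for v in per_region.values()],
        }
    )
    return table, {r: np.array(v) for r, v in per_region.items()}


# --------------------------------------------------------------------------
# Tukey comparison of regions
# --------------------------------------------------------------------------

def _maximal_cliques(adjacency: np.ndarray) -> list[frozenset]:
    """All maximal cliques of a small graph by subset enumeration."""
    n = adjacency.shape[0]
    cliques: list[frozenset] = []
    nodes = list(range(n))
    for size in range(n, 0, -1):
        for sub in combinations(nodes, size):
            if all(adjacency[i, j] for i, j in combinations(sub, 2)):
                s = frozenset(sub)
                if not any(s < c for c in cliques):
                    cliques.append(s)
    return cliques


def compact_letter_display(nonsig: np.ndarray, order: np.ndarray) -> list[str]:
    """Letters such that two groups share one iff they are not significantly
    different; cliques are lettered in order of decreasing group mean."""
    cliques = _maximal_cliques(nonsig)
    cliques.sort(key=lambda c: min(np.where(order == i)[0][0] for i in c))
    letters = [""] * nonsig.shape[0]
    for li, clique in enumerate(cliques):
        ch = chr(ord("a") + li)
        for g in clique:
            letters[g] += ch
    return letters


def tukey_regions(per_region: dict[int, np.ndarray], alpha: float = 0.05) -> dict[int, str]:
    """One-way ANOVA, then Tukey HSD grouping letters for the region errors.

    If the ANOVA is not significant at ``alpha`` (or all groups are
    identical), every region shares the letter ``'a'``.
    """
    regions = sorted(per_region)
    groups = [np.asarray(per_region[r], dtype=float) for r in regions]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 observations per region")

    pooled_within = np.concatenate([g - g.mean() for g in groups])
    if np.allclose(pooled_within, 0):
        if all(np.allclose(g.mean(), groups[0].mean()) for g in groups):
            return {r: "a" for r in regions}
        warnings.warn("zero within-region variance: every region differs trivially")

    f_stat, p = stats.f_oneway(*groups)
    if not np.isfinite(p) or p >= alpha:
        return {r: "a" for r in regions}

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(groups)
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    k = len(groups)
    nonsig = np.eye(k, dtype=bool)
    for (i, j), reject in zip(combinations(range(k), 2), res.reject):
        nonsig[i, j] = nonsig[j, i] = not reject
    order = np.argsort([-g.mean() for g in groups], kind="stable")
    letters = compact_letter_display(nonsig, order)
    return {r: letters[i] for i, r in enumerate(regions)}


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def export_map_png(dmap: DistributionMap, path, cmap: str = "viridis") -> dict:
    """Write an 8-bit pseudo-colour rendering plus a JSON colourbar sidecar.

    The sidecar records the value range and units so the colours remain
    interpretable; background pixels are rendered black.  Returns the
    sidecar dict.
    """
    import matplotlib
    matplotlib.use("Agg")

    fg = dmap.foreground()
    fg = fg[np.isfinite(fg)]
    vmin, vmax = float(fg.min()), float(fg.max())
    span = vmax - vmin or 1.0
    norm = np.clip((np.nan_to_num(dmap.values, nan=vmin) - vmin) / span, 0, 1)
    rgba = (matplotlib.colormaps[cmap](norm) * 255).astype(np.uint8)
    rgba[~dmap.mask] = (0, 0, 0, 255)

    from PIL import Image

    path = str(path)
    Image.fromarray(rgba).save(path)
    sidecar = {"min": vmin, "max": vmax, "units": dmap.units,
               "composition": dmap.composition, "cmap": cmap,
               "wavelengths_nm": list(map(float, dmap.wavelengths_nm))}
    with open(path.rsplit(".", 1)[0] + "_colorbar.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar


# --------------------------------------------------------------------------
# histogram statistics
# --------------------------------------------------------------------------

def map_histogram_stats(dmap: DistributionMap) -> dict:
    """Mean, skewness and kurtosis of the foreground pixel distribution.

    Skewness is the standardised third central moment; kurtosis is the
    standardised fourth central moment in the non-excess convention
    (normal = 3), recorded in the output.  A zero-variance map reports both
    as 0 with ``degenerate=True``.
    """
    fg = dmap.foreground()
    fg = fg[np.isfinite(fg)]
    if fg.size < 3:
        raise ValueError("need at least 3 foreground pixels")
    out = {"mean": float(fg.mean()), "n_pixels": int(fg.size),
           "kurtosis_convention": "non-excess"}
    if fg.std() == 0:
        out.update({"skewness": 0.0, "kurtosis": 0.0, "degenerate": True})
    else:
        out.update({
            "skewness": float(stats.skew(fg)),
            "kurtosis": float(stats.kurtosis(fg, fisher=False)),
            "degenerate": False,
        })
    return out
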