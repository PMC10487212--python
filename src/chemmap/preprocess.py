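"""Reflectance calibration, smoothing, trimming, sensor fusion, ROI binning.

Raw scene frames are normalised by white/black reference frames, smoothed
with a Savitzky-Golay filter, trimmed to the trustworthy 420-1600 nm range,
fused across the two sensors onto a common 5 nm grid, and binned to one
mean spectrum per circular ROI.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .hypercube import Hypercube
from .synthetic import WAVELENGTH_GRID

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# reflectance calibration
# --------------------------------------------------------------------------

def calibrate_reflectance(raw: Hypercube, white: Hypercube, black: Hypercube,
                          clip_negative: bool = True) -> Hypercube:
    """Normalise raw intensity by the white/black references, band by band:
    ``R = (I - B) / (W - B)``.

    Negative reflectances are clipped to 0 and counted; values above 1
    (white-reference imperfection) are preserved and counted.  Both counts
    land in the returned cube's ``meta``.

    Raises
    ------
    ValueError
        If shapes or wavelength axes disagree, or the white reference does
        not exceed the black reference at some band (saturation); the error
        names the offending bands.
    """
    for other, name in ((white, "white"), (black, "black")):
        if other.shape != raw.shape:
            raise ValueError(f"{name} frame shape {other.shape} != raw shape {raw.shape}")
        if not np.allclose(other.wavelengths, raw.wavelengths):
            raise ValueError(f"{name} frame wavelength axis differs from raw")

    denom = white.data - black.data
    band_min = denom.min(axis=(0, 1))
    bad = np.where(band_min <= 0)[0]
    if bad.size:
        raise ValueError(
            "white reference does not exceed black reference (sensor saturation?) "
            f"at bands {raw.wavelengths[bad].tolist()} nm"
        )

    refl = (raw.data - black.data) / denom
    n_neg = int((refl < 0).sum())
    n_over = int((refl > 1).sum())
    if clip_negative:
        refl = np.clip(refl, 0.0, None)
    log.info("calibration: clipped %d negative values, kept %d values > 1", n_neg, n_over)

    out = raw.with_data(refl, frame_kind="reflectance")
    out.meta = {**raw.meta, "n_clipped_negative": n_neg, "n_above_one": n_over}
    return out


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

def smooth_savitzky_golay(spectra, window_len: int = 11, poly_order: int = 2):
    """Savitzky-Golay smoothing along the band axis.

    Mirror padding keeps the spectrum length unchanged; polynomials of
    degree <= ``poly_order`` are reproduced exactly on interior points.
    Accepts a bare array (last axis = bands) or a :class:`Hypercube`.
    """
    if window_len % 2 == 0 or window_len <= poly_order:
        raise ValueError("window_len must be odd and greater than poly_order")
    if isinstance(spectra, Hypercube):
        return spectra.with_data(smooth_savitzky_golay(spectra.data, window_len, poly_order))
    arr = np.asarray(spectra, dtype=float)
    if arr.shape[-1] < window_len:
        raise ValueError(
            f"window of {window_len} points exceeds spectrum length {arr.shape[-1]}"
        )
    return savgol_filter(arr, window_len, poly_order, axis=-1, mode="mirror")


# --------------------------------------------------------------------------
# trimming and fusion
# --------------------------------------------------------------------------

def trim_spectral_range(cube_or_spectra, lo: float = 420.0, hi: float = 1600.0):
    """Drop noisy edge bands, keeping wavelengths with ``lo <= w <= hi``.

    Accepts a :class:`Hypercube` (returns a trimmed cube) or a tuple
    ``(wavelengths, spectra)`` with bands on the last axis.
    """
    if isinstance(cube_or_spectra, Hypercube):
        cube = cube_or_spectra
        keep = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
        if not keep.any():
            raise ValueError(f"no bands inside [{lo}, {hi}] nm")
        return Hypercube(cube.data[:, :, keep], cube.wavelengths[keep],
                         cube.sensor_id, cube.frame_kind, dict(cube.meta))
    wavelengths, spectra = cube_or_spectra
    wavelengths = np.asarray(wavelengths, dtype=float)
    keep = (wavelengths >= lo) & (wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"no bands inside [{lo}, {hi}] nm")
    return wavelengths[keep], np.asarray(spectra)[..., keep]


def fuse_sensors(vis_wavelengths, vis_spectra, nir_wavelengths, nir_spectra,
                 boundary: float = 1000.0, grid_step: float = 5.0,
                 lo: float = 420.0, hi: float = 1600.0,
                 match_scale: bool = False):
    """Merge the two sensor ranges onto the common grid with a hard switch.

    Grid points below ``boundary`` are linearly interpolated from the
    visible sensor, points at or above it from the NIR sensor; within the
    860-1000 nm overlap the visible sensor is used exclusively.  With
    ``match_scale`` the NIR side is multiplied by the ratio of the two
    sensors' mean response over their overlap, removing a gain step at the
    seam; the default leaves both sensors untouched.  Returns
    ``(grid, fused, source)`` where ``source`` marks each grid band
    ``"vis"`` or ``"nir"``.
    """
    vis_w = np.asarray(vis_wavelengths, dtype=float)
    nir_w = np.asarray(nir_wavelengths, dtype=float)
    grid = np.arange(lo, hi + 1e-9, grid_step)

    vis_part = grid[grid < boundary]
    nir_part = grid[grid >= boundary]
    if vis_part.size and (vis_w.min() > vis_part.min() or vis_w.max() < vis_part.max()):
        raise ValueError(
            f"coverage gap: visible sensor spans [{vis_w.min()}, {vis_w.max()}] nm "
            f"but must cover [{vis_part.min()}, {vis_part.max()}] nm"
        )
    if nir_part.size and (nir_w.min() > nir_part.min() or nir_w.max() < nir_part.max()):
        raise ValueError(
            f"coverage gap: NIR sensor spans [{nir_w.min()}, {nir_w.max()}] nm "
            f"but must cover [{nir_part.min()}, {nir_part.max()}] nm"
        )

    vis_arr = np.asarray(vis_spectra, dtype=float)
    nir_arr = np.asarray(nir_spectra, dtype=float)
    if match_scale:
        olo, ohi = max(vis_w.min(), nir_w.min()), min(vis_w.max(), nir_w.max())
        if ohi <= olo:
            raise ValueError("match_scale requires overlapping sensor ranges")
        overlap = np.arange(olo, ohi + 1e-9, grid_step)
        v = np.mean(np.interp(overlap, vis_w, np.atleast_2d(
            vis_arr.reshape(-1, vis_arr.shape[-1])).mean(axis=0)))
        m = np.mean(np.interp(overlap, nir_w, np.atleast_2d(
            nir_arr.reshape(-1, nir_arr.shape[-1])).mean(axis=0)))
        if m > 0:
            nir_arr = nir_arr * (v / m)
    lead_shape = vis_arr.shape[:-1]
    fused = np.empty(lead_shape + (len(grid),))
    flat_vis = vis_arr.reshape(-1, vis_arr.shape[-1])
    flat_nir = nir_arr.reshape(-1, nir_arr.shape[-1])
    flat_out = fused.reshape(-1, len(grid))
    for i in range(flat_out.shape[0]):
        flat_out[i, : len(vis_part)] = np.interp(vis_part, vis_w, flat_vis[i])
        flat_out[i, len(vis_part):] = np.interp(nir_part, nir_w, flat_nir[i])
    source = np.array(["vis"] * len(vis_part) + ["nir"] * len(nir_part))
    return grid, fused, source


# --------------------------------------------------------------------------
# ROI binning
# --------------------------------------------------------------------------

def spectra_columns(wavelengths) -> list[str]:
    return [f"r{int(round(w)):04d}" for w in np.asarray(wavelengths)]


def spectra_matrix(df: pd.DataFrame):
    """Split a spectra table into (wavelengths, X) from its ``r<nm>`` columns."""
    cols = [c for c in df.columns if c.startswith("r") and c[1:].isdigit()]
    wavelengths = np.array([float(c[1:]) for c in cols])
    order = np.argsort(wavelengths)
    cols = [cols[i] for i in order]
    return wavelengths[order], df[cols].to_numpy(dtype=float)


def extract_roi_mean_spectra(cube: Hypercube, roi_mask: np.ndarray,
                             keys: dict | None = None,
                             expected_labels=None) -> pd.DataFrame:
    """Mean spectrum of the pixels in each labelled ROI disc.

    Returns one row per label (ascending), with any ``keys`` columns
    (e.g. origin/fruit ids), a ``region`` column, the binned pixel count,
    and one ``r<nm>`` reflectance column per band.  If ``expected_labels``
    is given, a label with no member pixels raises and is named.
    """
    roi_mask = np.asarray(roi_mask)
    if roi_mask.shape != cube.shape[:2]:
        raise ValueError(f"mask shape {roi_mask.shape} != raster {cube.shape[:2]}")
    labels = [int(v) for v in np.unique(roi_mask) if v > 0]
    if not labels:
        raise ValueError("ROI mask contains no labels")
    if expected_labels is not None:
        missing = sorted(set(expected_labels) - set(labels))
        if missing:
            raise ValueError(f"ROI labels {missing} are empty (no member pixels)")
    rows = []
    for label in labels:
        member = roi_mask == label
        if not member.any():
            raise ValueError(f"ROI label {label} has no member pixels")
        mean_spec = cube.data[member].mean(axis=0)
        row = {**(keys or {}), "region": label, "n_pixels": int(member.sum())}
        row.update(dict(zip(spectra_columns(cube.wavelengths), mean_spec)))
        rows.append(row)
    return pd.DataFrame(rows)
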