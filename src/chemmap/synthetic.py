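"""Synthetic fruit-slice data with the statistical structure the pipeline assumes.

The study system is fresh-cut pineapple: slices cut across the stem axis,
ten 18-mm cylindrical samples per slice assayed for moisture content (MC, %),
soluble solids content (SSC, %), titratable acidity (TA, g/100 mL citric
acid) and total carotenoids (CC, mg/100 g dry matter), imaged by two
line-scan spectral cameras before sampling.  No public dataset exists, so
everything downstream is exercised against generators that reproduce the
key statistical features: origin-level composition means/SDs, pooled
inter-composition correlations, an axial maturity gradient within the
slice, and sign-correct spectral responses of the flesh.

Every generator is a pure function of its configuration and a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .hypercube import Hypercube

# --------------------------------------------------------------------------
# study conditions: origin-level composition statistics and pooled correlations
# --------------------------------------------------------------------------

COMPOSITIONS = ("mc", "ssc", "ta", "cc")

#: canonical CSV/DataFrame column per composition
COLUMN_OF = {
    "mc": "mc_pct",
    "ssc": "ssc_pct",
    "ta": "ta_gpct",
    "cc": "cc_mg100gdm",
}

UNITS = {"mc": "%", "ssc": "%", "ta": "g/100 mL", "cc": "mg/100 g DM"}

#: per-origin (mean, SD) for the six geographic origins of the study fruit
ORIGIN_STATS: dict[int, dict[str, tuple[float, float]]] = {
    1: {"mc": (86.51, 1.34), "ssc": (13.02, 1.19), "ta": (0.96, 0.07), "cc": (0.34, 0.12)},
    2: {"mc": (86.70, 2.24), "ssc": (12.42, 2.19), "ta": (0.95, 0.21), "cc": (0.42, 0.05)},
    3: {"mc": (85.14, 1.81), "ssc": (13.76, 1.17), "ta": (0.92, 0.15), "cc": (0.35, 0.12)},
    4: {"mc": (88.54, 1.28), "ssc": (10.52, 1.63), "ta": (0.98, 0.16), "cc": (0.23, 0.10)},
    5: {"mc": (86.13, 0.58), "ssc": (12.92, 0.53), "ta": (0.61, 0.14), "cc": (0.35, 0.09)},
    6: {"mc": (86.35, 1.10), "ssc": (13.18, 0.91), "ta": (0.93, 0.17), "cc": (0.21, 0.11)},
}

#: pooled (across-origin) Pearson correlations of carotenoids with the others
POOLED_CORRELATIONS = {("cc", "mc"): -0.56, ("cc", "ssc"): 0.52, ("cc", "ta"): -0.14}

#: copula completion for pairs without a configured pooled target.  Moisture
#: and soluble solids are compositionally complementary (more dry-matter
#: solids means less water), so their within-origin correlation is negative;
#: this also keeps the completed matrix positive definite once the three
#: carotenoid pairs are calibrated.
COMPLETION_CORRELATIONS = {("mc", "ssc"): -0.30}

#: physiological bounds used for the truncated-normal marginals
BOUNDS = {"mc": (0.0, 100.0), "ssc": (0.0, np.inf), "ta": (0.0, np.inf), "cc": (0.0, np.inf)}

REFERENCE_COLUMNS = ["origin", "fruit", "region", "mc_pct", "ssc_pct", "ta_gpct", "cc_mg100gdm"]

WAVELENGTH_GRID = np.arange(420.0, 1600.0 + 1e-9, 5.0)  # 237-point common grid

SENSOR_GRIDS = {
    "vis": np.arange(380.0, 1000.0 + 1e-9, 5.0),
    "nir": np.arange(860.0, 1690.0 + 1e-9, 5.0),
}


# --------------------------------------------------------------------------
# reference chemistry table
# --------------------------------------------------------------------------

def _origin_moment_arrays(params):
    origins = sorted(params)
    means = np.array([[params[o][c][0] for c in COMPOSITIONS] for o in origins])
    sds = np.array([[params[o][c][1] for c in COMPOSITIONS] for o in origins])
    return origins, means, sds


def _truncnorm_on_gh(mu, sd, bounds, z):
    """Truncated-normal marginal transform evaluated at standard-normal nodes."""
    lo, hi = bounds
    a, b = (lo - mu) / sd, (hi - mu) / sd
    u = np.clip(stats.norm.cdf(z), 1e-14, 1 - 1e-14)
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sd)


def _within_correlation_matrix(params, correlations, calibrate_pooled, n_gh: int = 32):
    """4x4 within-origin copula correlation matrix.

    With ``calibrate_pooled`` the within-origin copula correlation of each
    configured pair is solved (by Gauss-Hermite quadrature on the actual
    truncated-normal margins and Brent root finding) so that the *pooled*
    Pearson correlation — which also carries the covariance of the
    origin-level means and the attenuation of the marginal transforms —
    converges to the configured value as the table grows.  Otherwise the
    configured value is used directly as the copula correlation.
    """
    from scipy.optimize import brentq

    origins = sorted(params)
    comp_idx = {c: i for i, c in enumerate(COMPOSITIONS)}

    x, w = np.polynomial.hermite_e.hermegauss(n_gh)   # nodes for N(0,1)
    w = w / w.sum()

    # per origin and composition: transformed values on the 1-D grid + moments
    g1 = {}
    mean_t = np.zeros((len(origins), len(COMPOSITIONS)))
    var_t = np.zeros_like(mean_t)
    for oi, o in enumerate(origins):
        for c in COMPOSITIONS:
            vals = _truncnorm_on_gh(*params[o][c], BOUNDS[c], x)
            g1[(o, c)] = vals
            mean_t[oi, comp_idx[c]] = vals @ w
            var_t[oi, comp_idx[c]] = (vals**2) @ w - (vals @ w) ** 2

    between_cov = np.cov(mean_t, rowvar=False, bias=True)
    pooled_var = var_t.mean(axis=0) + np.diag(between_cov)

    W2 = np.outer(w, w)

    def pooled_corr(rho, a, b):
        i, j = comp_idx[a], comp_idx[b]
        zb = rho * x[:, None] + np.sqrt(max(1.0 - rho**2, 0.0)) * x[None, :]
        cov_within = 0.0
        for oi, o in enumerate(origins):
            gb = _truncnorm_on_gh(*params[o][b], BOUNDS[b], zb)
            e_ab = float(np.sum(g1[(o, a)][:, None] * gb * W2))
            cov_within += e_ab - mean_t[oi, i] * mean_t[oi, j]
        cov_within /= len(origins)
        return (cov_within + between_cov[i, j]) / np.sqrt(pooled_var[i] * pooled_var[j])

    R = np.eye(len(COMPOSITIONS))
    for (a, b), rho in COMPLETION_CORRELATIONS.items():
        if (a, b) not in correlations and (b, a) not in correlations:
            R[comp_idx[a], comp_idx[b]] = R[comp_idx[b], comp_idx[a]] = rho
    for (a, b), rho in correlations.items():
        i, j = comp_idx[a], comp_idx[b]
        if calibrate_pooled:
            f = lambda r: pooled_corr(r, a, b) - rho
            lo_v, hi_v = f(-0.995), f(0.995)
            if lo_v * hi_v > 0:
                warnings.warn(
                    f"pooled correlation target {rho} for ({a},{b}) is unreachable "
                    f"(attainable range [{lo_v + rho:.3f}, {hi_v + rho:.3f}]); "
                    "using the boundary copula correlation"
                )
                rho_w = -0.995 if abs(lo_v) < abs(hi_v) else 0.995
            else:
                rho_w = brentq(f, -0.995, 0.995, xtol=1e-4)
        else:
            rho_w = rho
        R[i, j] = R[j, i] = rho_w

    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-10:
        if not calibrate_pooled:
            raise ValueError(
                "correlation specification is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g}); completed matrix:\n{R}"
            )
        # calibrated targets can be jointly infeasible for unusual designs:
        # shrink the off-diagonal block toward independence until admissible
        shrink = 1.0
        off = R - np.eye(len(COMPOSITIONS))
        while shrink > 0.05:
            shrink *= 0.9
            cand = np.eye(len(COMPOSITIONS)) + shrink * off
            if np.linalg.eigvalsh(cand).min() >= 1e-8:
                warnings.warn(
                    "calibrated correlation targets are jointly infeasible for "
                    f"this design; shrinking correlations by {shrink:.2f}"
                )
                return cand
        raise ValueError(
            "correlation calibration failed: no admissible matrix near the "
            f"requested targets (min eigenvalue {eigvals.min():.3g})"
        )
    return R


def generate_reference_table(
    design: dict | None = None,
    params: dict | None = None,
    correlations: dict | None = None,
    seed: int = 0,
    fruit_effect_frac: float = 0.5,
    calibrate_pooled: bool = True,
) -> pd.DataFrame:
    """Generate a full-factorial per-ROI chemistry table.

    The joint distribution is a Gaussian copula: a latent 4-variate normal
    with the (completed) correlation matrix is split into a fruit-level
    random effect and a within-fruit residual (variance fractions
    ``fruit_effect_frac`` / 1 - ``fruit_effect_frac``), then each margin is
    mapped to a truncated normal with the per-origin mean/SD.

    Parameters
    ----------
    design : dict
        ``{"origins": 6, "fruit_per_origin": 10, "regions_per_fruit": 10}``
        (the defaults give the 600-row study design).
    params : dict
        ``{origin_id: {comp: (mean, sd)}}``; defaults to :data:`ORIGIN_STATS`.
    correlations : dict
        ``{(comp_a, comp_b): pooled_r}``; defaults to
        :data:`POOLED_CORRELATIONS`.
    """
    design = {"origins": 6, "fruit_per_origin": 10, "regions_per_fruit": 10, **(design or {})}
    params = params if params is not None else ORIGIN_STATS
    correlations = correlations if correlations is not None else POOLED_CORRELATIONS
    if not 0.0 <= fruit_effect_frac <= 1.0:
        raise ValueError("fruit_effect_frac must be in [0, 1]")

    origins = sorted(params)[: design["origins"]]
    if len(origins) < design["origins"]:
        raise ValueError(f"params cover {len(origins)} origins; design needs {design['origins']}")
    for o in origins:
        for c in COMPOSITIONS:
            sd = params[o][c][1]
            if sd <= 0:
                raise ValueError(f"SD for origin {o} {c} must be > 0 (got {sd})")
            if sd < 1e-6 * max(abs(params[o][c][0]), 1.0):
                warnings.warn(
                    f"near-zero SD for origin {o} {c}: column will be almost constant "
                    "and correlation targets are unreachable"
                )

    sub_params = {o: params[o] for o in origins}
    R = _within_correlation_matrix(sub_params, correlations, calibrate_pooled)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(COMPOSITIONS)))

    rng = np.random.default_rng(seed)
    n_fruit, n_reg = design["fruit_per_origin"], design["regions_per_fruit"]
    rows = []
    sf, sr = np.sqrt(fruit_effect_frac), np.sqrt(1.0 - fruit_effect_frac)
    for o in origins:
        for f in range(1, n_fruit + 1):
            z_fruit = L @ rng.standard_normal(len(COMPOSITIONS))
            z_reg = (L @ rng.standard_normal((len(COMPOSITIONS), n_reg))).T
            z = sf * z_fruit[None, :] + sr * z_reg
            u = stats.norm.cdf(z)
            vals = np.empty_like(u)
            for ci, c in enumerate(COMPOSITIONS):
                mu, sd = params[o][c]
                lo, hi = BOUNDS[c]
                a, b = (lo - mu) / sd, (hi - mu) / sd
                vals[:, ci] = stats.truncnorm.ppf(
                    np.clip(u[:, ci], 1e-12, 1 - 1e-12), a, b, loc=mu, scale=sd
                )
            for r in range(1, n_reg + 1):
                rows.append((o, f, r, *vals[r - 1]))

    df = pd.DataFrame(rows, columns=REFERENCE_COLUMNS)
    return df


def write_reference_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def read_reference_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REFERENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    return df


def pooled_correlations(df: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Pearson correlations of CC with the other compositions, pooled over all rows."""
    out = {}
    for (a, b) in POOLED_CORRELATIONS:
        out[(a, b)] = float(np.corrcoef(df[COLUMN_OF[a]], df[COLUMN_OF[b]])[0, 1])
    return out


# --------------------------------------------------------------------------
# per-slice chemistry fields
# --------------------------------------------------------------------------

@dataclass
class ChemistryField:
    """Per-composition 2-D fields over a slice raster plus the ROI geometry."""

    fields: dict[str, np.ndarray]
    mask: np.ndarray                      # slice foreground (bool)
    roi_centers: np.ndarray               # (10, 2) as (row, col)
    roi_radius_px: float
    mm_per_px: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def roi_mask(self) -> np.ndarray:
        """Labelled image: 0 background, 1..10 the ROI discs."""
        rr, cc = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        lab = np.zeros(self.shape, dtype=np.int32)
        for k, (r0, c0) in enumerate(self.roi_centers, start=1):
            lab[(rr - r0) ** 2 + (cc - c0) ** 2 <= self.roi_radius_px**2] = k
        return lab


def roi_layout(raster_shape, slice_radius_px: float) -> np.ndarray:
    """Ten ROI centres on a 2 x 5 grid inside the slice disc.

    Regions 1-5 run along the stem axis (image rows, bottom to top) in the
    left column, 6-10 in the right column.
    """
    cr, cc = (raster_shape[0] - 1) / 2.0, (raster_shape[1] - 1) / 2.0
    dys = np.array([0.68, 0.34, 0.0, -0.34, -0.68])  # bottom (large row) to top
    centers = []
    for dx in (-0.38, 0.38):
        for dy in dys:
            centers.append((cr + dy * slice_radius_px, cc + dx * slice_radius_px))
    return np.array(centers)


def generate_chemistry_field(
    ref_rows: pd.DataFrame,
    raster_shape: tuple[int, int] = (256, 256),
    mm_per_px: float = 0.5,
    gradient_spec: dict | None = None,
    seed: int = 0,
    roi_diameter_mm: float = 18.0,
) -> ChemistryField:
    """Build smooth composition fields whose ROI-disc means equal the table values.

    Each field is a low-order base surface (optional axial/radial gradient)
    plus a Gaussian radial-basis correction anchored at the ten ROI centres;
    the correction coefficients are solved so the mean over each ROI disc
    reproduces the corresponding reference value essentially exactly.

    ``gradient_spec``: ``{comp: {"axial": slope, "radial": slope}}`` in
    composition units per normalised coordinate (axial in [-1, 1] bottom to
    top, radial in [0, 1]).
    """
    if len(ref_rows) != 10 or sorted(ref_rows["region"]) != list(range(1, 11)):
        raise ValueError("ref_rows must contain exactly regions 1..10 of one fruit")
    gradient_spec = gradient_spec or {}

    h, w = raster_shape
    slice_radius = 0.47 * min(h, w)
    roi_radius = roi_diameter_mm / 2.0 / mm_per_px
    centers = roi_layout(raster_shape, slice_radius)

    # geometry guards: discs disjoint and inside the slice
    d2 = np.sum((centers[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    if np.sqrt(d2.min()) < 2 * roi_radius or slice_radius < 4 * roi_radius:
        raise ValueError(
            f"raster {raster_shape} at {mm_per_px} mm/px cannot fit ten disjoint "
            f"{roi_diameter_mm} mm discs (disc radius {roi_radius:.1f} px, "
            f"slice radius {slice_radius:.1f} px)"
        )

    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    cr, ccol = (h - 1) / 2.0, (w - 1) / 2.0
    mask = (rr - cr) ** 2 + (cc - ccol) ** 2 <= slice_radius**2
    axial = -(rr - cr) / slice_radius          # +1 at top row
    radial = np.sqrt((rr - cr) ** 2 + (cc - ccol) ** 2) / slice_radius

    # RBF basis evaluated on the raster and averaged over each ROI disc
    sigma = 0.8 * np.sqrt(d2.min())
    disc_members = [
        (rr - r0) ** 2 + (cc - c0) ** 2 <= roi_radius**2 for (r0, c0) in centers
    ]
    phi = [
        np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)) for (r0, c0) in centers
    ]
    A = np.array([[phi_k[m].mean() for phi_k in phi] for m in disc_members])

    order = ref_rows.sort_values("region")
    fields: dict[str, np.ndarray] = {}
    for comp in COMPOSITIONS:
        targets = order[COLUMN_OF[comp]].to_numpy(dtype=float)
        g = gradient_spec.get(comp, {})
        base = (
            targets.mean()
            + g.get("axial", 0.0) * axial
            + g.get("radial", 0.0) * radial
        )
        resid = targets - np.array([base[m].mean() for m in disc_members])
        coef = np.linalg.solve(A, resid)
        fld = base + sum(a * p for a, p in zip(coef, phi))
        fields[comp] = np.where(mask, fld, np.nan)

    return ChemistryField(
        fields=fields,
        mask=mask,
        roi_centers=centers,
        roi_radius_px=roi_radius,
        mm_per_px=mm_per_px,
    )


# --------------------------------------------------------------------------
# optics forward model and hypercube rendering
# --------------------------------------------------------------------------

@dataclass
class AbsorptionBand:
    composition: str
    center_nm: float
    width_nm: float
    amplitude: float      # reflectance change per unit composition (sign included)


@dataclass
class OpticsModel:
    """Linear Gaussian-band reflectance model of the fruit flesh.

    Reflectance at wavelength ``w`` for chemistry ``c`` is::

        R(w) = baseline(w) + sum_b amp_b * exp(-(w-mu_b)^2 / (2 s_b^2)) * (c_b - ref_b)

    clipped to [0, 1.2].  Band signs encode the observed directions of the
    reflectance-composition correlations: moisture positive near 490-500 nm,
    soluble solids negative near 485-495 nm, carotenoids negative near
    505-510 nm, plus water/sugar overtone bands in the NIR.
    """

    bands: list[AbsorptionBand]
    reference_chemistry: dict[str, float]
    noise_sd: float = 0.01            # fraction of white level, on raw scene frames
    edge_inflation: float = 5.0       # noise multiplier outside 420-1600 nm
    white_level: float = 0.9
    black_level: float = 0.05

    def baseline(self, wavelengths: np.ndarray) -> np.ndarray:
        w = np.asarray(wavelengths, dtype=float)
        return 0.45 + 0.12 * np.exp(-(((w - 850.0) / 450.0) ** 2))

    def response_matrix(self, wavelengths: np.ndarray) -> dict[str, np.ndarray]:
        """Per-composition reflectance response spectrum (per unit composition)."""
        w = np.asarray(wavelengths, dtype=float)
        out = {c: np.zeros_like(w) for c in COMPOSITIONS}
        for b in self.bands:
            out[b.composition] += b.amplitude * np.exp(
                -((w - b.center_nm) ** 2) / (2 * b.width_nm**2)
            )
        return out

    def reflectance(self, wavelengths: np.ndarray, chemistry: dict[str, np.ndarray]) -> np.ndarray:
        """Forward reflectance; chemistry values broadcast against wavelengths.

        Returns an array of shape ``chemistry_shape + (n_bands,)``.
        """
        w = np.asarray(wavelengths, dtype=float)
        resp = self.response_matrix(w)
        some = next(iter(chemistry.values()))
        base = np.broadcast_to(self.baseline(w), np.shape(some) + w.shape).copy()
        for c, vals in chemistry.items():
            delta = np.asarray(vals, dtype=float) - self.reference_chemistry[c]
            base += delta[..., None] * resp[c]
        return np.clip(base, 0.0, 1.2)


def default_optics(noise_sd: float = 0.01) -> OpticsModel:
    """Optics model whose band signs match the observed reflectance correlations."""
    bands = [
        AbsorptionBand("mc", 492.0, 12.0, +0.012),
        AbsorptionBand("mc", 960.0, 30.0, -0.008),
        AbsorptionBand("mc", 1425.0, 40.0, -0.010),
        AbsorptionBand("ssc", 488.0, 12.0, -0.010),
        AbsorptionBand("ssc", 1215.0, 18.0, -0.006),
        AbsorptionBand("ssc", 1240.0, 18.0, -0.006),
        AbsorptionBand("ta", 512.0, 15.0, +0.080),
        AbsorptionBand("cc", 507.0, 15.0, -0.450),
    ]
    reference = {c: float(np.mean([ORIGIN_STATS[o][c][0] for o in ORIGIN_STATS]))
                 for c in COMPOSITIONS}
    return OpticsModel(bands=bands, reference_chemistry=reference, noise_sd=noise_sd)


def generate_hypercube(
    field: ChemistryField,
    optics: OpticsModel,
    sensor: str = "vis",
    seed: int = 0,
    background_reflectance: float = 0.02,
) -> dict[str, Hypercube]:
    """Render raw scene, white and black frames for one sensor.

    The raw scene frame is ``B + R_true * (W - B)`` plus additive Gaussian
    noise (SD = ``optics.noise_sd`` x white level, inflated by
    ``optics.edge_inflation`` outside the trustworthy 420-1600 nm range).
    Reference frames are noise-free, emulating multi-scan averaging.
    """
    if sensor not in SENSOR_GRIDS:
        raise ValueError(f"sensor must be one of {sorted(SENSOR_GRIDS)}")
    wavelengths = SENSOR_GRIDS[sensor]
    rng = np.random.default_rng(seed)

    h, w = field.shape
    chem = {
        c: np.where(field.mask, np.nan_to_num(field.fields[c], nan=0.0), 0.0)
        for c in COMPOSITIONS
    }
    refl = optics.reflectance(wavelengths, chem)          # (h, w, bands)
    refl[~field.mask] = background_reflectance

    white = np.broadcast_to(
        optics.white_level * (1.0 - 0.1 * ((wavelengths - 1000.0) / 700.0) ** 2),
        (h, w, len(wavelengths)),
    ).astype(np.float64)
    black = np.full((h, w, len(wavelengths)), optics.black_level)

    raw = black + refl * (white - black)
    if optics.noise_sd > 0:
        sd = optics.noise_sd * optics.white_level * np.ones_like(wavelengths)
        sd[(wavelengths < 420.0) | (wavelengths > 1600.0)] *= optics.edge_inflation
        raw = raw + rng.standard_normal(raw.shape) * sd

    mk = lambda d, kind: Hypercube(d, wavelengths, sensor_id=sensor, frame_kind=kind)
    return {"raw": mk(raw, "raw"), "white": mk(white.copy(), "white"), "black": mk(black, "black")}


def simulate_roi_spectra(
    ref_table: pd.DataFrame,
    optics: OpticsModel | None = None,
    wavelengths: np.ndarray | None = None,
    noise_sd: float = 0.002,
    seed: int = 0,
) -> pd.DataFrame:
    """ROI mean spectra straight from the forward model (no raster rendering).

    Emulates the per-ROI binned spectra the imaging pipeline would produce:
    forward reflectance at each row's chemistry plus iid Gaussian noise of
    SD ``noise_sd`` (residual noise after binning hundreds of pixels).
    Returns a table with the key columns plus one ``r<nm>`` column per band.
    """
    optics = optics or default_optics()
    wavelengths = WAVELENGTH_GRID if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(seed)
    chem = {c: ref_table[COLUMN_OF[c]].to_numpy(dtype=float) for c in COMPOSITIONS}
    spectra = optics.reflectance(wavelengths, chem)
    if noise_sd > 0:
        spectra = spectra + noise_sd * rng.standard_normal(spectra.shape)
    cols = {f"r{int(round(wl)):04d}": spectra[:, i] for i, wl in enumerate(wavelengths)}
    out = ref_table[REFERENCE_COLUMNS].reset_index(drop=True)
    return pd.concat([out, pd.DataFrame(cols)], axis=1)


# --------------------------------------------------------------------------
# landmark (fiducial screw) scenes for registration
# --------------------------------------------------------------------------

@dataclass
class LandmarkScene:
    image_reference: np.ndarray       # grayscale render in the hypercube frame
    image_distorted: np.ndarray       # same scene after the inverse true transform
    control_pairs: np.ndarray         # (6, 2, 2): [:, 0] distorted xy, [:, 1] reference xy
    check_pairs: np.ndarray           # (3, 2, 2)
    true_transform: object            # Transform2D, distorted -> reference


def render_slice_image(
    field: ChemistryField,
    hole_value: float = 0.08,
    slice_value: float = 0.55,
    background_value: float = 0.02,
    screw_value: float = 0.95,
    screw_positions: np.ndarray | None = None,
    screw_radius_px: float = 5.0,
) -> np.ndarray:
    """Grayscale render: slice disc with dark circular sampling holes and
    bright fiducial screws."""
    rr, cc = np.mgrid[0 : field.shape[0], 0 : field.shape[1]].astype(float)
    img = np.full(field.shape, background_value)
    img[field.mask] = slice_value
    for (r0, c0) in field.roi_centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= field.roi_radius_px**2] = hole_value
    if screw_positions is not None:
        for (r0, c0) in screw_positions:
            img[(rr - r0) ** 2 + (cc - c0) ** 2 <= screw_radius_px**2] = screw_value
    return img


def _screw_points(field: ChemistryField, slit_len_mm: float = 5.0):
    """Fiducial geometry for registration scenes.

    Three binding-head screws sit near the slice rim; the two endpoints of
    each screw's ~5 mm head slit are the six control points.  The three
    check landmarks are placed on the rim *between* the screws: check
    points that are spatially independent of the control clusters (rather
    than slit midpoints, which are linear interpolants of the control
    pairs) retain diagnostic power for choosing among nested transform
    families.
    """
    h, w = field.shape
    cr, ccol = (h - 1) / 2.0, (w - 1) / 2.0
    rim = 0.47 * min(h, w) * 0.90
    half = slit_len_mm / 2.0 / field.mm_per_px
    screw_angles = np.deg2rad([90.0, 210.0, 330.0])
    slit_angles = np.deg2rad([20.0, 135.0, 80.0])
    check_angles = np.deg2rad([30.0, 150.0, 270.0])
    controls, screw_centers = [], []
    for sa, ta in zip(screw_angles, slit_angles):
        # x = col, y = row
        center = np.array([ccol + rim * np.cos(sa), cr - rim * np.sin(sa)])
        d = np.array([np.cos(ta), -np.sin(ta)]) * half
        controls += [center - d, center + d]
        screw_centers.append(center[::-1])  # (row, col) for rendering
    checks = [np.array([ccol + rim * np.cos(a), cr - rim * np.sin(a)])
              for a in check_angles]
    return np.array(controls), np.array(checks), np.array(screw_centers)


def generate_landmark_scene(
    field: ChemistryField,
    true_transform,
    seed: int = 0,
    jitter_sd: float = 0.5,
) -> LandmarkScene:
    """Reference/distorted point correspondences under a known planar transform.

    ``true_transform`` maps the distorted (RGB) frame to the reference
    (hypercube) frame.  Distorted-frame points are the inverse-mapped
    reference points plus isotropic Gaussian jitter of SD ``jitter_sd`` px.
    """
    from skimage.transform import warp

    from .registration import Transform2D

    if not isinstance(true_transform, Transform2D):
        raise TypeError("true_transform must be a Transform2D")
    rng = np.random.default_rng(seed)

    controls_ref, checks_ref, screw_centers = _screw_points(field)
    img_ref = render_slice_image(field, screw_positions=screw_centers)

    inv = true_transform.inverse()
    controls_dist = inv.apply(controls_ref) + jitter_sd * rng.standard_normal((6, 2))
    checks_dist = inv.apply(checks_ref) + jitter_sd * rng.standard_normal((3, 2))

    # warp pulls output pixels through the map distorted -> reference
    img_dist = warp(img_ref, true_transform.matrix, output_shape=img_ref.shape,
                    preserve_range=True)

    return LandmarkScene(
        image_reference=img_ref,
        image_distorted=img_dist,
        control_pairs=np.stack([controls_dist, controls_ref], axis=1),
        check_pairs=np.stack([checks_dist, checks_ref], axis=1),
        true_transform=true_transform,
    )


def write_points_csv(path, control_pairs: np.ndarray, check_pairs: np.ndarray,
                     frames=("distorted", "reference")) -> None:
    rows = []
    for role, pairs in (("control", control_pairs), ("check", check_pairs)):
        for idx, pair in enumerate(pairs, start=1):
            for frame, (x, y) in zip(frames, pair):
                rows.append((frame, x, y, role, idx))
    pd.DataFrame(rows, columns=["frame", "x", "y", "role", "index"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_points_csv(path, frames=("distorted", "reference")):
    df = pd.read_csv(path)
    out = {}
    for role in ("control", "check"):
        sub = df[df["role"] == role]
        idx = sorted(sub["index"].unique())
        pairs = np.array(
            [
                [
                    sub[(sub["index"] == i) & (sub["frame"] == fr)][["x", "y"]].to_numpy()[0]
                    for fr in frames
                ]
                for i in idx
            ]
        )
        out[role] = pairs
    return out["control"], out["check"]


# --------------------------------------------------------------------------
# commercial availability tables
# --------------------------------------------------------------------------

AVAILABILITY_COLUMNS = ["wavelength", "available_filter", "available_led", "available_laser"]


def generate_availability_table(spec: str = "dense", seed: int = 0,
                                path=None) -> pd.DataFrame:
    """Commercial-availability flags on the 420-1600 nm, 5 nm grid.

    ``dense``: every wavelength available for every modality.  ``sparse``:
    seeded random availability with realistic densities (filters widely
    stocked, LEDs moderately, lasers sparsely), guaranteed non-empty per
    modality.  ``from_file``: read and validate a user-supplied CSV.
    """
    grid = WAVELENGTH_GRID.astype(int)
    if spec == "dense":
        flags = {m: np.ones(len(grid), dtype=bool) for m in ("filter", "led", "laser")}
    elif spec == "sparse":
        rng = np.random.default_rng(seed)
        dens = {"filter": 0.6, "led": 0.35, "laser": 0.2}
        flags = {m: rng.random(len(grid)) < p for m, p in dens.items()}
        for m in flags:
            if not flags[m].any():
                flags[m][rng.integers(len(grid))] = True
    elif spec == "from_file":
        if path is None:
            raise ValueError("spec='from_file' requires a path")
        return read_availability_table(path)
    else:
        raise ValueError(f"unknown availability spec {spec!r}")
    return pd.DataFrame(
        {
            "wavelength": grid,
            "available_filter": flags["filter"],
            "available_led": flags["led"],
            "available_laser": flags["laser"],
        }
    )


def write_availability_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for c in AVAILABILITY_COLUMNS[1:]:
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False)


def read_availability_table(path) -> pd.DataFrame:
    text = Path(path).read_text() if not hasattr(path, "read") else path.read()
    lines = text.strip().splitlines()
    header = lines[0].strip().split(",")
    if header != AVAILABILITY_COLUMNS:
        raise ValueError(f"availability header must be {AVAILABILITY_COLUMNS}; got {header}")
    bad = []
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.strip().split(",")
        try:
            wl = int(parts[0])
            fl = [int(p) for p in parts[1:4]]
            if len(parts) != 4 or any(f not in (0, 1) for f in fl):
                raise ValueError
            rows.append((wl, *[bool(f) for f in fl]))
        except (ValueError, IndexError):
            bad.append(ln)
    if bad:
        raise ValueError(f"malformed availability rows at lines: {bad}")
    df = pd.DataFrame(rows, columns=AVAILABILITY_COLUMNS)
    wl = df["wavelength"].to_numpy()
    if not (np.all(np.diff(wl) == 5) and wl[0] == 420 and wl[-1] == 1600):
        raise ValueError("availability grid must be 420..1600 nm in 5 nm steps")
    return df
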