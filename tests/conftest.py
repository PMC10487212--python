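import numpy as np
import pytest

from chemmap import synthetic as syn


@pytest.fixture(scope="session")
def ref_table():
    """Study-scale (600-row) reference chemistry table."""
    return syn.generate_reference_table(seed=0)


@pytest.fixture(scope="session")
def small_field(ref_table):
    """One fruit's chemistry field on a coarse raster (1 mm/px)."""
    rows = ref_table[(ref_table.origin == 1) & (ref_table.fruit == 1)]
    return syn.generate_chemistry_field(rows, raster_shape=(128, 128), mm_per_px=1.0,
                                        seed=0)


@pytest.fixture(scope="session")
def noiseless_optics():
    return syn.default_optics(noise_sd=0.0)


def uncorrelated_params():
    """Single-population chemistry: all origins share pooled moments and the
    compositions are statistically independent — the setting for
    parameter-recovery experiments."""
    return {o: {"mc": (86.56, 1.5), "ssc": (12.64, 1.6),
                "ta": (0.89, 0.16), "cc": (0.32, 0.10)} for o in range(1, 7)}


def recovery_optics(noise_sd: float = 0.01):
    """Optics coupling moisture to 495/500 nm and carotenoids negatively to
    505 nm only, with spectrally resolvable (8 nm) bands."""
    return syn.OpticsModel(
        bands=[
            syn.AbsorptionBand("mc", 495.0, 8.0, +0.012),
            syn.AbsorptionBand("mc", 500.0, 8.0, +0.012),
            syn.AbsorptionBand("cc", 505.0, 8.0, -0.45),
        ],
        reference_chemistry={"mc": 86.56, "ssc": 12.64, "ta": 0.89, "cc": 0.32},
        noise_sd=noise_sd,
    )


def random_affine(rng, raster=(128, 128)):
    """A mild affine distortion (slight rotation/scale, visible shear)."""
    from chemmap.registration import Transform2D

    cy, cx = (raster[0] - 1) / 2.0, (raster[1] - 1) / 2.0
    ang = np.deg2rad(rng.uniform(-4, 4))
    scale = rng.uniform(0.97, 1.03)
    shear = rng.uniform(0.03, 0.07) * rng.choice([-1, 1])
    A = scale * np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    A = A @ np.array([[1.0, shear], [0.0, 1.0]])
    t = rng.uniform(-4, 4, size=2)
    center = np.array([cx, cy])
    M = np.eye(3)
    M[:2, :2] = A
    M[:2, 2] = center - A @ center + t
    return Transform2D("affine", M)
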