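"""In-memory container for line-scan reflectance image stacks.

A hypercube is a ``rows x cols x bands`` array with a strictly increasing
wavelength axis.  Four frame kinds circulate through the pipeline: the raw
scene intensity, the white (Teflon) reference, the black (capped-lens)
reference, and calibrated reflectance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: recognised frame kinds, in acquisition order
FRAME_KINDS = ("raw", "white", "black", "reflectance")


@dataclass
class Hypercube:
    """3-D spectral image with its wavelength axis.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Pixel values; raw counts or reflectance depending on ``frame_kind``.
    wavelengths : ndarray, shape (bands,)
        Band centres in nm, strictly increasing.
    sensor_id : str
        Originating sensor, e.g. ``"vis"`` (420-1000 nm unit) or ``"nir"``
        (1000-1600 nm unit).
    frame_kind : str
        One of :data:`FRAME_KINDS`.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    sensor_id: str = "vis"
    frame_kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (rows, cols, bands); got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {len(self.wavelengths)} does not match "
                f"band count {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.frame_kind not in FRAME_KINDS:
            raise ValueError(f"frame_kind must be one of {FRAME_KINDS}; got {self.frame_kind!r}")

    # -- convenience ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float, atol: float = 1e-6) -> int:
        """Index of the band whose centre equals ``wavelength_nm``."""
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        if abs(self.wavelengths[idx] - wavelength_nm) > atol:
            raise KeyError(f"no band at {wavelength_nm} nm (nearest: {self.wavelengths[idx]} nm)")
        return idx

    def with_data(self, data: np.ndarray, frame_kind: str | None = None) -> "Hypercube":
        return replace(self, data=data, frame_kind=frame_kind or self.frame_kind)
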