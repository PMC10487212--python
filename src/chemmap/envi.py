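"""ENVI header + flat-binary hypercube I/O.

Reads and writes the classic two-file layout: a text ``.hdr`` describing
``samples`` (columns), ``lines`` (rows), ``bands``, ``data type``,
``interleave`` and the wavelength list, next to a raw binary file holding
the pixel values in BSQ, BIL or BIP order.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .hypercube import Hypercube

# ENVI "data type" codes <-> numpy dtypes (the subset this pipeline emits)
_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


class EnviFormatError(ValueError):
    """Raised when a header/binary pair is inconsistent or malformed."""


def _data_path(header_path: Path) -> Path:
    for candidate in (header_path.with_suffix(".img"), header_path.with_suffix(".dat"),
                      header_path.with_suffix("")):
        if candidate.exists() and candidate != header_path:
            return candidate
    raise EnviFormatError(f"no binary file found next to header {header_path}")


def parse_header(text: str) -> dict:
    """Parse ENVI header text into a key -> string/list dict."""
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError("missing ENVI magic line")
    body = text.split("\n", 1)[1] if "\n" in text else ""
    fields: dict = {}
    # brace-delimited values may span lines
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            items = [s.strip() for s in val.strip("{}").replace("\n", " ").split(",")]
            fields[key] = [s for s in items if s]
        else:
            fields[key] = val
    return fields


def read_envi(header_path: str | Path) -> Hypercube:
    """Load a hypercube from an ENVI header path.

    Raises
    ------
    EnviFormatError
        If the declared shape, dtype, wavelength count and binary size
        disagree; messages name the offending counts.
    """
    header_path = Path(header_path)
    fields = parse_header(header_path.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field {exc}") from exc
    if dtype_code not in _DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type code {dtype_code}")
    interleave = str(fields.get("interleave", "bsq")).lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unknown interleave {interleave!r}")

    wavelengths = fields.get("wavelength")
    if wavelengths is not None:
        wavelengths = np.array([float(w) for w in wavelengths])
        if len(wavelengths) != bands:
            raise EnviFormatError(
                f"header declares bands={bands} but wavelength list has "
                f"{len(wavelengths)} entries"
            )
    else:
        wavelengths = np.arange(bands, dtype=float)

    dtype = np.dtype(_DTYPES[dtype_code])
    raw = np.fromfile(_data_path(header_path), dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"binary holds {raw.size} values but header shape "
            f"{lines}x{samples}x{bands} requires {expected}"
        )

    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)

    return Hypercube(
        data=np.ascontiguousarray(data),
        wavelengths=wavelengths,
        sensor_id=str(fields.get("sensor type", "unknown")),
        frame_kind=str(fields.get("frame kind", "reflectance")),
    )


def write_envi(header_path: str | Path, cube: Hypercube, interleave: str = "bsq",
               dtype=np.float32) -> Path:
    """Write a hypercube as header + raw binary; returns the binary path."""
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unknown interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise EnviFormatError(f"dtype {dtype} has no ENVI data type code")

    rows, cols, bands = cube.shape
    if interleave == "bsq":
        arr = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    else:
        arr = cube.data

    data_path = header_path.with_suffix(".img")
    np.ascontiguousarray(arr, dtype=dtype).tofile(data_path)

    wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"sensor type = {cube.sensor_id}\n"
        f"frame kind = {cube.frame_kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return data_path
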