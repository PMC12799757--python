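"""Minimal ENVI cube I/O for one fixed dialect.

Cameras of the push-broom class ship cubes as an ASCII ``.hdr`` header next to
a headerless binary file. This module reads and writes exactly one dialect —
BIL interleave, 32-bit little-endian IEEE float (`data type = 4`,
`byte order = 0`), wavelength list embedded in the header — and rejects
everything else by name, so a round trip is bit-exact and unambiguous.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .errors import EnviFormatError
from .grids import WavelengthGrid
from .spectra import HyperCube

__all__ = ["read_envi", "write_envi"]

_REQUIRED = ("samples", "lines", "bands", "interleave", "data type", "byte order")


def write_envi(cube: HyperCube, header_path: str | Path, data_path: str | Path) -> None:
    """Write ``cube`` as an ENVI BIL float32 file pair.

    Data are stored as little-endian float32; a cube already in float32
    round-trips bit-exactly.
    """
    header_path, data_path = Path(header_path), Path(data_path)
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        "description = {hemaspec reflectance cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bil\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    # BIL: per line, all bands of that line, each as a run of samples
    bil = np.ascontiguousarray(cube.data.transpose(0, 2, 1), dtype="<f4")
    bil.tofile(data_path)


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError("missing ENVI magic line in header")
    # collapse brace-delimited multi-line values onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path: str | Path, data_path: str | Path) -> HyperCube:
    """Read an ENVI BIL float32 little-endian cube written by :func:`write_envi`.

    Raises
    ------
    EnviFormatError
        If a required header field is missing or names an unsupported
        interleave, data type, or byte order.
    """
    fields = _parse_header(Path(header_path).read_text())
    for name in _REQUIRED:
        if name not in fields:
            raise EnviFormatError(f"header field missing: {name!r}")
    if fields["interleave"].lower() != "bil":
        raise EnviFormatError(f"unsupported interleave: {fields['interleave']!r}")
    if fields["data type"] != "4":
        raise EnviFormatError(f"unsupported data type: {fields['data type']!r}")
    if fields["byte order"] != "0":
        raise EnviFormatError(f"unsupported byte order: {fields['byte order']!r}")

    cols, rows, bands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip().strip("{}")
        wavelengths = [float(w) for w in wl_text.replace(",", " ").split()]
        if len(wavelengths) != bands:
            raise EnviFormatError(
                f"wavelength list length {len(wavelengths)} != bands {bands}"
            )
        grid = WavelengthGrid(bands, wavelengths[0], wavelengths[-1])
    else:
        raise EnviFormatError("header field missing: 'wavelength'")

    raw = np.fromfile(data_path, dtype="<f4")
    if raw.size != rows * cols * bands:
        raise EnviFormatError(
            f"data file holds {raw.size} values, expected {rows * cols * bands}"
        )
    data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    return HyperCube(data, grid)
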