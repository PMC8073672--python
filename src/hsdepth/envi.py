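"""Minimal ENVI cube I/O.

Reads and writes the classic two-file ENVI layout: a raw binary cube
plus a text header carrying dimensions, interleave, data type and the
per-band wavelength list in nm.  Writing always produces
band-sequential (BSQ) little-endian 32-bit float files with
deterministic bytes; reading accepts BSQ, BIL and BIP with the data
types produced by common instruments (unsigned 16-bit, 32/64-bit
float).

Axis convention: ENVI ``lines`` map to the cube's x (scan) axis and
``samples`` to y, so a cube of shape (n_x, n_y, n_bands) is stored as
(bands, n_x, n_y) in BSQ order.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .cube import SpectralCube
from .errors import FormatError

__all__ = ["read_envi", "write_envi", "header_path"]

_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}


def header_path(data_path) -> Path:
    """The ``.hdr`` companion of an ENVI data file."""
    p = Path(data_path)
    return p.with_suffix(".hdr") if p.suffix != ".hdr" else p


def write_envi(cube: SpectralCube, path) -> tuple[Path, Path]:
    """Write ``cube`` as BSQ float32 little-endian; returns (data, header) paths.

    Two writes of the same cube produce byte-identical files.
    """
    if cube.values.size == 0:
        raise ValueError("refusing to write an empty cube")
    path = Path(path)
    hdr = header_path(path)
    if hdr == path:
        raise ValueError("data path must not carry the .hdr extension")
    bsq = np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype="<f4")
    path.write_bytes(bsq.tobytes())
    wav = ",\n ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr.write_text(
        "ENVI\n"
        "description = {hsdepth synthetic phantom cube}\n"
        f"samples = {cube.n_y}\n"
        f"lines = {cube.n_x}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"pixel size = {{{cube.pitch_x_um:.3f}, {cube.pitch_y_um:.3f}}}\n"
        f"wavelength = {{\n {wav}}}\n"
    )
    return path, hdr


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header: missing 'ENVI' magic line")
    # join brace-delimited multi-line values before splitting into fields
    text = text.lstrip()[4:]
    fields: dict[str, str] = {}
    for m in re.finditer(r"(?ms)^\s*([\w ]+?)\s*=\s*(\{.*?\}|[^\n]*)$", text):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1]
        fields[key] = val
    return fields


def read_envi(path) -> SpectralCube:
    """Read an ENVI cube (BSQ/BIL/BIP) into a :class:`SpectralCube`.

    Raises :class:`~hsdepth.errors.FormatError` naming the offending
    header field on a malformed or inconsistent pair of files.
    """
    path = Path(path)
    hdr = header_path(path)
    if not hdr.exists():
        raise FormatError(f"missing header file {hdr}")
    fields = _parse_header(hdr.read_text())

    def geti(key: str) -> int:
        if key not in fields:
            raise FormatError(f"header field '{key}' missing")
        try:
            return int(fields[key])
        except ValueError as exc:
            raise FormatError(f"header field '{key}' is not an integer: {fields[key]!r}") from exc

    samples, lines, bands = geti("samples"), geti("lines"), geti("bands")
    dtype_code = geti("data type")
    if dtype_code not in _DTYPES:
        raise FormatError(f"header field 'data type' = {dtype_code} unsupported")
    byte_order = int(fields.get("byte order", "0"))
    dtype = np.dtype(_DTYPES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")
    offset = int(fields.get("header offset", "0"))
    interleave = fields.get("interleave", "bsq").lower()

    if "wavelength" not in fields:
        raise FormatError("header field 'wavelength' missing")
    wavelengths = np.array([float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",") if tok.strip()])
    if len(wavelengths) != bands:
        raise FormatError(
            f"header field 'wavelength' has {len(wavelengths)} entries but 'bands' = {bands}"
        )

    raw = np.fromfile(path, dtype=dtype, offset=offset)
    if raw.size != samples * lines * bands:
        raise FormatError(
            f"data file holds {raw.size} values, header promises "
            f"samples×lines×bands = {samples * lines * bands}"
        )
    if interleave == "bsq":
        arr = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        arr = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"header field 'interleave' = {interleave!r} unsupported")

    pitch = dict(pitch_x_um=260.0, pitch_y_um=43.0)
    if "pixel size" in fields:
        try:
            px, py = [float(t) for t in fields["pixel size"].split(",")[:2]]
            pitch = dict(pitch_x_um=px, pitch_y_um=py)
        except ValueError:
            pass
    return SpectralCube(np.ascontiguousarray(arr), wavelengths, **pitch)
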