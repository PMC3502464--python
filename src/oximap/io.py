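"""Cube file I/O: ENVI-style header+raw and multi-page TIFF dialects.

The primary dialect is ENVI-style — a text header (``.hdr``) next to a raw
band-sequential binary (``.img``), little-endian float — which round-trips a
cube bit-exactly (float32 cubes as ENVI data type 4, float64 as type 5). The
portable alternative is a multi-page TIFF (one page per band) with a
``.wavelengths.csv`` sidecar. JSON-serializable metadata rides in the header
(or TIFF description); the ground-truth label image, when present, is written
as a sidecar ``.labels.tif``.
"""

from __future__ import annotations

import json
import os

import numpy as np
import tifffile

from .exceptions import FormatError
from .vessel_extraction import HyperspectralCube

__all__ = ["read_cube", "write_cube", "DIALECTS"]

DIALECTS = ("envi", "tiff")

_DTYPE_TO_ENVI = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}
_ENVI_TO_DTYPE = {4: np.dtype("<f4"), 5: np.dtype("<f8")}


def _json_safe_metadata(metadata: dict) -> dict:
    out = {}
    for key, val in metadata.items():
        if key == "labels":
            continue
        try:
            json.dumps(val)
            out[key] = val
        except TypeError:
            out[key] = repr(val)
    return out


def _base(path: str) -> str:
    root, ext = os.path.splitext(path)
    return root if ext in (".hdr", ".img", ".tif", ".tiff") else path


def _write_labels(base: str, metadata: dict) -> None:
    labels = metadata.get("labels")
    if labels is not None:
        tifffile.imwrite(base + ".labels.tif", np.asarray(labels, dtype=np.int32))


def _read_labels(base: str, metadata: dict) -> None:
    path = base + ".labels.tif"
    if os.path.exists(path):
        metadata["labels"] = tifffile.imread(path)


def write_cube(cube: HyperspectralCube, path: str, dialect: str = "envi") -> str:
    """Write a cube; returns the primary file path written."""
    if dialect not in DIALECTS:
        raise ValueError(f"unsupported dialect {dialect!r}; choose from {DIALECTS}")
    base = _base(path)
    meta = _json_safe_metadata(cube.metadata)
    if dialect == "envi":
        return _write_envi(cube, base, meta)
    return _write_tiff(cube, base, meta)


def read_cube(path: str, dialect: str = "envi") -> HyperspectralCube:
    """Read a cube written by :func:`write_cube` (lossless round trip)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unsupported dialect {dialect!r}; choose from {DIALECTS}")
    base = _base(path)
    cube = _read_envi(base) if dialect == "envi" else _read_tiff(base)
    _read_labels(base, cube.metadata)
    return cube


# ---------------------------------------------------------------------------
# ENVI-style dialect


def _write_envi(cube: HyperspectralCube, base: str, meta: dict) -> str:
    data = cube.intensities
    dtype = np.dtype(np.float32) if data.dtype not in _DTYPE_TO_ENVI else data.dtype
    nrows, ncols, nbands = data.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {ncols}\n"
        f"lines = {nrows}\n"
        f"bands = {nbands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
        f"oximap metadata = {{ {json.dumps(meta)} }}\n"
    )
    with open(base + ".hdr", "w") as fh:
        fh.write(header)
    bsq = np.ascontiguousarray(np.transpose(data, (2, 0, 1)), dtype=dtype.newbyteorder("<"))
    bsq.tofile(base + ".img")
    _write_labels(base, cube.metadata)
    return base + ".hdr"


def _parse_envi_header(path: str) -> dict:
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise FormatError(f"cannot read ENVI header {path}: {exc}") from exc
    if not text.startswith("ENVI"):
        raise FormatError(f"{path}: missing ENVI magic line")
    fields: dict[str, str] = {}
    body = text[4:]
    pos = 0
    while pos < len(body):
        eq = body.find("=", pos)
        if eq == -1:
            break
        key = body[pos:eq].strip().lower()
        rest = body[eq + 1 :].lstrip()
        offset = len(body) - len(rest)
        if rest.startswith("{"):
            depth = 0
            close = -1
            for i, ch in enumerate(rest):  # balanced scan: JSON metadata nests braces
                if ch == "{":
                    depth += 1
                elif ch == "}":
                    depth -= 1
                    if depth == 0:
                        close = i
                        break
            if close == -1:
                raise FormatError(f"{path}: unterminated '{{' for field '{key}'")
            val = rest[1:close].strip()
            pos = offset + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl == -1 else nl
            val = rest[:nl].strip()
            pos = offset + nl + 1
        if key:
            fields[key] = val
    return fields


def _read_envi(base: str) -> HyperspectralCube:
    fields = _parse_envi_header(base + ".hdr")
    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise FormatError(f"{base}.hdr: missing required field '{req}'")
    ncols, nrows, nbands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    if fields["interleave"].lower() != "bsq":
        raise FormatError(f"{base}.hdr: unsupported interleave '{fields['interleave']}'")
    dtype_code = int(fields["data type"])
    if dtype_code not in _ENVI_TO_DTYPE:
        raise FormatError(f"{base}.hdr: unsupported data type {dtype_code}")
    dtype = _ENVI_TO_DTYPE[dtype_code]
    if "wavelength" not in fields:
        raise FormatError(f"{base}.hdr: missing field 'wavelength'")
    wavelengths = np.array(
        [float(v) for v in fields["wavelength"].split(",") if v.strip()]
    )
    if len(wavelengths) != nbands:
        raise FormatError(
            f"{base}.hdr: field 'bands' declares {nbands} bands but field "
            f"'wavelength' lists {len(wavelengths)}"
        )
    raw = np.fromfile(base + ".img", dtype=dtype)
    expected = nrows * ncols * nbands
    if raw.size != expected:
        raise FormatError(
            f"{base}.img: truncated or oversized binary "
            f"({raw.size} values, expected {expected})"
        )
    data = np.transpose(raw.reshape(nbands, nrows, ncols), (1, 2, 0))
    meta = {}
    if "oximap metadata" in fields:
        meta = json.loads(fields["oximap metadata"])
    return HyperspectralCube(np.ascontiguousarray(data), wavelengths, meta)


# ---------------------------------------------------------------------------
# TIFF-stack dialect


def _write_tiff(cube: HyperspectralCube, base: str, meta: dict) -> str:
    pages = np.transpose(cube.intensities, (2, 0, 1))
    tifffile.imwrite(base + ".tif", pages, description=json.dumps(meta))
    np.savetxt(
        base + ".wavelengths.csv",
        cube.wavelengths,
        header="wavelength_nm",
        comments="",
        fmt="%.6f",
    )
    _write_labels(base, cube.metadata)
    return base + ".tif"


def _read_tiff(base: str) -> HyperspectralCube:
    sidecar = base + ".wavelengths.csv"
    if not os.path.exists(sidecar):
        raise FormatError(
            f"missing wavelength sidecar {sidecar}; the TIFF-stack dialect "
            "expects band wavelengths in a CSV next to the stack"
        )
    wavelengths = np.atleast_1d(np.loadtxt(sidecar, skiprows=1))
    with tifffile.TiffFile(base + ".tif") as tif:
        pages = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None and desc.value else {}
    if pages.ndim == 2:
        pages = pages[None, ...]
    if pages.shape[0] != len(wavelengths):
        raise FormatError(
            f"{base}.tif: {pages.shape[0]} pages but sidecar lists "
            f"{len(wavelengths)} wavelengths"
        )
    data = np.transpose(pages, (1, 2, 0))
    return HyperspectralCube(np.ascontiguousarray(data), wavelengths, meta)
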