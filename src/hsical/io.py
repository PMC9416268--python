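"""Reading and writing hypercubes.

Two dialects are supported:

* an ENVI-style pair — a plain-text ``.hdr`` with ``key = value`` entries and
  a raw little-endian binary payload, band-interleaved-by-line (BIL): the file
  runs scan line by scan line, each line holding all bands, each band all
  slit samples;
* an HDF5 container with ``/cube`` (scan, slit, spectral), ``/wavelength_nm``
  and a ``/meta`` group of scalar attributes.

Values are stored as float64 so a write/read round trip is bit exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np

from .cube import HyperCube, ReflectanceCube
from .errors import CubeFormatError, CubeSizeError

_META_KEYS = (
    "focal_length_mm",
    "exposure_ms",
    "binning",
    "pixel_pitch_um",
    "scan_speed_factor",
)

_REQUIRED_HDR = ("samples", "lines", "bands", "interleave", "data type", "byte order")

# ENVI numeric data-type codes for the payload dtypes we emit/accept
_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8")}


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr") if path.suffix != ".hdr" else path


def write_cube(
    cube: HyperCube | ReflectanceCube, path: str | Path, dialect: str = "envi"
) -> None:
    """Write ``cube`` to ``path`` in the requested dialect.

    For ``envi`` the payload goes to ``path`` and the text header to
    ``path + '.hdr'``.  A missing wavelength axis is omitted from the header
    (never written as zeros).  A reflectance cube's mask, when present, is
    written to a companion ``path + '.mask'`` as uint8 in the same BIL order.
    """
    path = Path(path)
    if dialect == "envi":
        _write_envi(cube, path)
    elif dialect == "hdf5":
        _write_hdf5(cube, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'envi' or 'hdf5'")


def read_cube(path: str | Path, dialect: str = "envi") -> HyperCube:
    """Read a cube written by :func:`write_cube`."""
    path = Path(path)
    if dialect == "envi":
        return _read_envi(path)
    if dialect == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'envi' or 'hdf5'")


# ---------------------------------------------------------------- ENVI


def _write_envi(cube: HyperCube | ReflectanceCube, path: Path) -> None:
    lines = {
        "samples": cube.n_slit,        # slit pixels per line
        "lines": cube.n_scan,          # scan lines
        "bands": cube.n_spectral,
        "interleave": "bil",
        "data type": 5,
        "byte order": 0,
        "dialect": "hsical-envi",
    }
    hdr = ["ENVI"]
    hdr += [f"{k} = {v}" for k, v in lines.items()]
    if cube.wavelength_nm is not None:
        wl = ", ".join(repr(float(w)) for w in cube.wavelength_nm)
        hdr.append("wavelength units = nm")
        hdr.append("wavelength = {" + wl + "}")
    for key in _META_KEYS:
        if key in cube.meta and cube.meta[key] is not None:
            hdr.append(f"{key} = {cube.meta[key]}")
    _header_path(path).write_text("\n".join(hdr) + "\n")
    # BIL: (line, band, sample)
    payload = np.ascontiguousarray(
        np.transpose(cube.values, (0, 2, 1)), dtype="<f8"
    )
    payload.tofile(path)
    mask = getattr(cube, "mask", None)
    if mask is not None:
        np.ascontiguousarray(
            np.transpose(mask, (0, 2, 1)), dtype=np.uint8
        ).tofile(path.with_suffix(path.suffix + ".mask"))


def _parse_hdr(text: str, path: Path) -> dict[str, str]:
    # collapse {...} blocks spanning several physical lines
    body = text
    if body.startswith("ENVI"):
        body = body[4:]
    entries: dict[str, str] = {}
    buf = ""
    for raw in body.splitlines():
        buf = (buf + " " + raw).strip() if buf else raw.strip()
        if not buf or buf.startswith(";"):
            buf = ""
            continue
        if "{" in buf and "}" not in buf:
            continue  # multi-line value, keep accumulating
        if "=" not in buf:
            raise CubeFormatError(f"{path}: malformed header line {buf!r} (no '=')")
        key, _, value = buf.partition("=")
        entries[key.strip().lower()] = value.strip()
        buf = ""
    return entries

def _read_envi(path: Path) -> HyperCube:
    hdr_path = _header_path(path)
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    entries = _parse_hdr(hdr_path.read_text(), hdr_path)
    for key in _REQUIRED_HDR:
        if key not in entries:
            raise CubeFormatError(f"{hdr_path}: missing required header key {key!r}")

    def _int(key: str) -> int:
        try:
            return int(entries[key])
        except ValueError as exc:
            raise CubeFormatError(
                f"{hdr_path}: header key {key!r} is not an integer "
                f"({entries[key]!r})"
            ) from exc

    n_slit, n_scan, n_spectral = _int("samples"), _int("lines"), _int("bands")
    if entries["interleave"].lower() != "bil":
        raise CubeFormatError(
            f"{hdr_path}: unsupported interleave {entries['interleave']!r}"
        )
    dtype_code = _int("data type")
    if dtype_code not in _DTYPES:
        raise CubeFormatError(f"{hdr_path}: unsupported data type {dtype_code}")
    if _int("byte order") != 0:
        raise CubeFormatError(f"{hdr_path}: unsupported byte order")
    dtype = _DTYPES[dtype_code]
    expected = n_slit * n_scan * n_spectral
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != expected:
        raise CubeSizeError(
            f"{path}: payload holds {raw.size} values but header declares "
            f"{n_scan}x{n_slit}x{n_spectral} = {expected}"
        )
    values = np.transpose(raw.reshape(n_scan, n_spectral, n_slit), (0, 2, 1))
    wavelength = None
    if "wavelength" in entries:
        inner = entries["wavelength"].strip().lstrip("{").rstrip("}")
        wavelength = np.array([float(tok) for tok in inner.split(",") if tok.strip()])
    meta: dict[str, Any] = {}
    for key in _META_KEYS:
        if key in entries:
            text = entries[key]
            meta[key] = int(text) if key == "binning" else float(text)
    return HyperCube(values.astype(np.float64), wavelength, meta)


# ---------------------------------------------------------------- HDF5


def _write_hdf5(cube: HyperCube | ReflectanceCube, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.values)
        if cube.wavelength_nm is not None:
            f.create_dataset("wavelength_nm", data=cube.wavelength_nm)
        grp = f.create_group("meta")
        grp.attrs["dialect"] = "hsical-hdf5"
        for key, value in cube.meta.items():
            if np.isscalar(value):
                grp.attrs[key] = value
        mask = getattr(cube, "mask", None)
        if mask is not None:
            f.create_dataset("mask", data=mask.astype(np.uint8))


def _read_hdf5(path: Path) -> HyperCube:
    with h5py.File(path, "r") as f:
        if "cube" not in f:
            raise CubeFormatError(f"{path}: missing required dataset 'cube'")
        values = f["cube"][...]
        wavelength = f["wavelength_nm"][...] if "wavelength_nm" in f else None
        meta = {}
        if "meta" in f:
            for key, value in f["meta"].attrs.items():
                if key != "dialect":
                    meta[key] = value.item() if hasattr(value, "item") else value
    return HyperCube(values, wavelength, meta)


def write_ground_truth(record: dict, path: str | Path) -> None:
    """Write a simulator ground-truth record as a JSON sidecar."""
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True, default=_json))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
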