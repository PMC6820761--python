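"""Hyperspectral cube and map I/O: HDF5 (primary) and ENVI (interop).

HDF5 layout::

    /data          rows x cols x bands (float32 by default)
    /wavenumbers   bands, descending cm^-1
    /mask          rows x cols uint8, optional (0 = tissue, 1 = background)
    attrs          stage, seed, config (JSON string), free-form meta

ENVI export writes band-sequential (BSQ) float32 raw data next to a plain
text ``.hdr`` carrying the wavenumber list, which any hyperspectral viewer
can open.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .assembly import HyperCube
from .spatial import ConcentrationMaps, TissueMask
from .spectral import SpectralAxis

__all__ = [
    "write_cube",
    "read_cube",
    "read_mask",
    "write_maps",
    "read_maps",
    "write_envi",
    "read_envi",
]

_META_ATTR = "meta_json"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if suffix in (".hdr", ".img", ".dat", ".envi"):
        return "envi"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass fmt=")


def write_cube(
    cube: HyperCube,
    path,
    fmt: str | None = None,
    *,
    mask: TissueMask | None = None,
    dtype: str = "float32",
) -> Path:
    """Write a cube to HDF5 or ENVI; returns the path written."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "w", track_order=True) as f:
            f.create_dataset("data", data=cube.data.astype(dtype, copy=False),
                             track_times=False)
            f.create_dataset("wavenumbers", data=cube.axis.wavenumbers,
                             track_times=False)
            if mask is not None:
                f.create_dataset("mask", data=mask.mask, track_times=False)
            f.attrs[_META_ATTR] = json.dumps(cube.meta, sort_keys=True)
        return path
    if fmt == "envi":
        return write_envi(cube, path, dtype=dtype)
    raise ValueError(f"unknown format {fmt!r}; expected 'hdf5' or 'envi'")


def read_cube(path, fmt: str | None = None) -> HyperCube:
    """Read a cube from HDF5 or ENVI (axis and meta restored)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "envi":
        return read_envi(path)
    with h5py.File(path, "r") as f:
        for name in ("data", "wavenumbers"):
            if name not in f:
                raise ValueError(
                    f"{path} is missing the required dataset '/{name}'"
                )
        data = f["data"][...]
        axis = SpectralAxis(f["wavenumbers"][...])
        meta = json.loads(f.attrs.get(_META_ATTR, "{}"))
    return HyperCube(data=data, axis=axis, meta=meta)


def read_mask(path) -> TissueMask:
    with h5py.File(path, "r") as f:
        if "mask" not in f:
            raise ValueError(f"{path} is missing the dataset '/mask'")
        return TissueMask(f["mask"][...])


def write_maps(maps: ConcentrationMaps, path) -> Path:
    """Write concentration maps as HDF5 (class_maps: rows x cols x 3)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("class_maps", data=maps.class_maps, track_times=False)
        f.create_dataset("co2_map", data=maps.co2_map, track_times=False)
    return path


def read_maps(path) -> ConcentrationMaps:
    with h5py.File(path, "r") as f:
        for name in ("class_maps", "co2_map"):
            if name not in f:
                raise ValueError(f"{path} is missing the dataset '/{name}'")
        return ConcentrationMaps(
            class_maps=f["class_maps"][...], co2_map=f["co2_map"][...]
        )


# -- ENVI -----------------------------------------------------------------

_ENVI_DTYPES = {"float32": 4, "float64": 5}
_ENVI_DTYPES_INV = {4: np.float32, 5: np.float64}


def write_envi(cube: HyperCube, path, dtype: str = "float32") -> Path:
    """Write band-sequential ENVI: raw ``.img`` plus text ``.hdr``."""
    path = Path(path)
    if dtype not in _ENVI_DTYPES:
        raise ValueError("ENVI export supports float32/float64 only")
    img = path.with_suffix(".img")
    hdr = path.with_suffix(".hdr")
    rows, cols, bands = cube.shape
    # BSQ: band-major on disk
    np.ascontiguousarray(
        cube.data.transpose(2, 0, 1).astype(dtype)
    ).tofile(img)
    wl = ", ".join(f"{w:.6f}" for w in cube.axis.wavenumbers)
    hdr.write_text(
        "ENVI\n"
        "description = {ftirsim simulated FT-IR cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_DTYPES[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Wavenumber (cm-1)\n"
        f"wavelength = {{{wl}}}\n",
        encoding="utf-8",
    )
    return img


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_block = None, [], False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if not in_block:
            if "=" not in line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip().lower(), val.strip()
            if val.startswith("{") and not val.endswith("}"):
                in_block, buf = True, [val.lstrip("{")]
            else:
                fields[key] = val.strip("{}").strip()
        else:
            if line.endswith("}"):
                buf.append(line.rstrip("}"))
                fields[key] = " ".join(buf).strip()
                in_block = False
            else:
                buf.append(line)
    return fields


def read_envi(path) -> HyperCube:
    """Read a BSQ float ENVI cube written by this package or another tool."""
    path = Path(path)
    hdr = path.with_suffix(".hdr")
    img = path.with_suffix(".img") if path.suffix == ".hdr" else path
    if not hdr.exists():
        raise ValueError(f"ENVI header {hdr} not found")
    fields = _parse_envi_header(hdr.read_text(encoding="utf-8"))
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as e:
        raise ValueError(f"ENVI header {hdr} is missing field {e}") from None
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    if dtype_code not in _ENVI_DTYPES_INV:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    offset = int(fields.get("header offset", 0))
    raw = np.fromfile(img, dtype=_ENVI_DTYPES_INV[dtype_code], offset=offset)
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"{img} holds {raw.size} values, expected {rows * cols * bands}"
        )
    data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    if "wavelength" not in fields:
        raise ValueError(f"ENVI header {hdr} is missing the wavelength list")
    wn = np.array([float(v) for v in fields["wavelength"].split(",")])
    return HyperCube(
        data=data, axis=SpectralAxis(wn), meta={"stage": "unknown"}
    )
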