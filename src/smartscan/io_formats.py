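"""File I/O: hyperspectral cube containers, images, label maps and tables.

Cubes live in an HDF5 container (datasets ``data`` and ``wavenumber_axis``
plus free-form root attributes that round-trip losslessly); ENVI
header+binary pairs can be imported for real instrument exports. Images and
label maps go through TIFF/PNG at 8 or 16 bit; tables are plain CSV with a
header row and '.' decimals.

Coordinates in exported files are 0-based, row-major (x, y) = (row, column);
wavenumber axes are stored explicitly so band indices never leak into files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .acquisition import ScanTimings

__all__ = [
    "CubeContainer",
    "CubeFormatError",
    "AxisMismatchError",
    "UnknownDialectError",
    "TruncatedFileError",
    "read_cube",
    "write_cube",
    "read_envi",
    "read_image",
    "write_image",
    "write_table",
    "read_table",
    "timings_table",
    "save_scene",
    "load_scene",
]


class CubeFormatError(Exception):
    """Base class for cube container errors."""


class AxisMismatchError(CubeFormatError):
    """Wavenumber axis length does not match the cube's spectral dimension."""


class UnknownDialectError(CubeFormatError):
    """File is neither an HDF5 container nor an ENVI header+binary pair."""


class TruncatedFileError(CubeFormatError):
    """Binary payload shorter than the header-declared shape."""


@dataclass
class CubeContainer:
    """X x Y x L cube with its wavenumber axis and free-form metadata."""

    data: np.ndarray
    wavenumber_axis: np.ndarray
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavenumber_axis = np.asarray(self.wavenumber_axis, dtype=float)
        if self.data.ndim != 3:
            raise CubeFormatError("cube data must be 3-D (X x Y x L)")
        if len(self.wavenumber_axis) != self.data.shape[2]:
            raise AxisMismatchError(
                f"axis length {len(self.wavenumber_axis)} != L={self.data.shape[2]}"
            )


def write_cube(container: CubeContainer, path) -> None:
    """Write a cube container to HDF5; write-then-read round-trips bit-exactly."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=container.data)
        f.create_dataset("wavenumber_axis", data=container.wavenumber_axis)
        f.attrs["attributes_json"] = json.dumps(container.attributes, sort_keys=True)


def read_cube(path) -> CubeContainer:
    """Read a cube: HDF5 container by default, ENVI when a header is given."""
    path = os.fspath(path)
    if path.lower().endswith(".hdr") or os.path.exists(path + ".hdr"):
        return read_envi(path)
    if not h5py.is_hdf5(path):
        raise UnknownDialectError(f"{path}: not an HDF5 container or ENVI header")
    with h5py.File(path, "r") as f:
        if "data" not in f or "wavenumber_axis" not in f:
            raise UnknownDialectError(f"{path}: missing cube datasets")
        data = f["data"][...]
        axis = f["wavenumber_axis"][...]
        attrs = json.loads(f.attrs.get("attributes_json", "{}"))
    if data.shape[2] != len(axis):
        raise AxisMismatchError(f"axis length {len(axis)} != L={data.shape[2]}")
    return CubeContainer(data=data, wavenumber_axis=axis, attributes=attrs)


_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}


def _parse_envi_header(text: str) -> dict:
    fields = {}
    key, buf = None, ""
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            key = key.lower()
            if val.startswith("{") and "}" not in val:
                buf = val
                continue
            fields[key] = val.strip("{} ")
            key = None
        else:
            buf += " " + line
            if "}" in line:
                fields[key] = buf.strip("{} ")
                key = None
                buf = ""
    return fields


def read_envi(header_path) -> CubeContainer:
    """Import an ENVI header + flat-binary cube (BSQ/BIL/BIP interleaves).

    The cube is returned in (lines, samples, bands) order with the header's
    wavelength list as the spectral axis (band indices when absent).
    """
    header_path = os.fspath(header_path)
    if not header_path.lower().endswith(".hdr"):
        header_path = header_path + ".hdr"
    with open(header_path) as f:
        h = _parse_envi_header(f.read())
    try:
        samples = int(h["samples"])
        lines = int(h["lines"])
        bands = int(h["bands"])
        dtype = _ENVI_DTYPES[int(h["data type"])]
    except KeyError as e:
        raise UnknownDialectError(f"ENVI header missing field: {e}") from e
    interleave = h.get("interleave", "bsq").lower()
    byte_order = int(h.get("byte order", 0))
    data_path = header_path[:-4]
    for ext in ("", ".img", ".dat", ".raw"):
        if os.path.exists(data_path + ext):
            data_path = data_path + ext
            break
    else:
        raise UnknownDialectError(f"no binary payload found for {header_path}")
    raw = np.fromfile(data_path, dtype=dtype, offset=int(h.get("header offset", 0)))
    if byte_order == 1:
        raw = raw.byteswap()
    if raw.size < samples * lines * bands:
        raise TruncatedFileError(
            f"{data_path}: {raw.size} values, header declares {samples*lines*bands}"
        )
    raw = raw[: samples * lines * bands]
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise UnknownDialectError(f"unknown interleave {interleave!r}")
    if "wavelength" in h:
        axis = np.array([float(v) for v in h["wavelength"].split(",")])
        if len(axis) != bands:
            raise AxisMismatchError(
                f"wavelength list length {len(axis)} != bands {bands}"
            )
    else:
        axis = np.arange(bands, dtype=float)
    attrs = {k: v for k, v in h.items() if k not in ("wavelength",)}
    return CubeContainer(data=np.ascontiguousarray(cube), wavenumber_axis=axis, attributes=attrs)


def write_image(image, path, dtype="uint16") -> None:
    """Write a grayscale image or label map as TIFF/PNG at 8 or 16 bit.

    Values must already fit the integer range — no silent rescaling.
    """
    arr = np.asarray(image)
    dt = np.dtype(dtype)
    if dt not in (np.dtype("uint8"), np.dtype("uint16")):
        raise ValueError("dtype must be uint8 or uint16")
    info = np.iinfo(dt)
    if arr.min() < info.min or arr.max() > info.max:
        raise ValueError(f"values outside {dt} range [{info.min}, {info.max}]")
    if np.issubdtype(arr.dtype, np.floating) and not np.allclose(arr, np.round(arr)):
        raise ValueError("refusing to quantize non-integer values; scale first")
    out = arr.astype(dt)
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_image(path) -> np.ndarray:
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        return tifffile.imread(path)
    return np.asarray(iio.imread(path))


def write_table(df: pd.DataFrame, path) -> None:
    """CSV with a header row, '.' decimals, no index column."""
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def timings_table(named_timings) -> pd.DataFrame:
    """Tabulate {protocol: ScanTimings} with one column per time component:
    first modality, low-SNR pass, processing, high-SNR pass, total (seconds).
    """
    rows = []
    for name, t in named_timings.items():
        if not isinstance(t, ScanTimings):
            raise TypeError("values must be ScanTimings")
        rows.append(
            {
                "protocol": name,
                "first_modality_s": t.first_modality_s,
                "low_pass_s": t.low_pass_s,
                "processing_s": t.processing_s,
                "high_pass_s": t.high_pass_s,
                "total_s": t.total_s,
            }
        )
    return pd.DataFrame(rows)


def save_scene(scene, sem_image, path, extra_attrs=None) -> None:
    """Serialize a phantom scene (+ optional SEM image) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("abundances", data=scene.abundances)
        f.create_dataset("wavenumber_axis", data=scene.wavenumber_axis)
        spectra = np.stack([e.spectrum for e in scene.endmembers])
        f.create_dataset("endmember_spectra", data=spectra)
        f.attrs["endmember_names"] = json.dumps([e.name for e in scene.endmembers])
        f.attrs["endmember_peaks"] = json.dumps(
            [list(map(float, e.peak_centers)) for e in scene.endmembers]
        )
        f.attrs["class_label"] = scene.class_label
        if scene.seed is not None:
            f.attrs["seed"] = int(scene.seed)
        if sem_image is not None:
            f.create_dataset("sem_pixels", data=sem_image.pixels)
            f.attrs["sem_pixel_pitch"] = float(sem_image.pixel_pitch)
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def load_scene(path):
    """Inverse of save_scene: returns (Scene, SEMImage or None)."""
    from .phantom import Endmember, Scene, SEMImage

    with h5py.File(path, "r") as f:
        abund = f["abundances"][...]
        axis = f["wavenumber_axis"][...]
        spectra = f["endmember_spectra"][...]
        names = json.loads(f.attrs["endmember_names"])
        peaks = json.loads(f.attrs["endmember_peaks"])
        ems = [
            Endmember(name=n, spectrum=s, peak_centers=p)
            for n, s, p in zip(names, spectra, peaks)
        ]
        scene = Scene(
            abundances=abund,
            endmembers=ems,
            wavenumber_axis=axis,
            class_label=str(f.attrs.get("class_label", "healthy")),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
        sem = None
        if "sem_pixels" in f:
            sem = SEMImage(
                pixels=f["sem_pixels"][...],
                pixel_pitch=float(f.attrs.get("sem_pixel_pitch", 10.0)),
            )
    return scene, sem
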