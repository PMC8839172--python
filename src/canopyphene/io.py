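"""File I/O for the pipeline's on-disk formats.

Hyperspectral cubes are stored as ENVI band-sequential (BSQ) rasters with a
plain-text ``.hdr`` carrying the wavelength list; thermal rasters as 32-bit
float TIFF; masks as 8-bit PNG; tables as CSV.  The ENVI reader/writer here
covers exactly the subset of the header specification the pipeline emits
(byte order 0, BSQ interleave, data types 4/5/12).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .hyperspec import SpectralCube

__all__ = [
    "write_envi",
    "read_envi",
    "write_thermal_tiff",
    "read_thermal_tiff",
    "write_mask_png",
    "read_mask_png",
]

_DTYPE_TO_ENVI = {"float32": 4, "float64": 5, "uint16": 12}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}


def write_envi(cube: SpectralCube, path: str | Path, dtype: str = "float32") -> Path:
    """Write a cube as ENVI BSQ (``path`` + ``path.hdr``)."""
    path = Path(path)
    if dtype not in _DTYPE_TO_ENVI:
        raise ValueError(f"unsupported ENVI dtype {dtype!r}")
    rows, cols, bands = cube.shape
    data = np.ascontiguousarray(
        np.transpose(cube.values.astype(dtype), (2, 0, 1))
    )  # BSQ: band, row, col
    data.tofile(path)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{canopyphene cube, state={cube.state}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    Path(str(path) + ".hdr").write_text(header)
    return path


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf = ""
    in_braces = False
    for line in text.splitlines():
        if in_braces:
            buf += " " + line.strip()
            if "}" in line:
                fields[key] = buf.strip()
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            buf = val
            in_braces = True
        else:
            fields[key] = val
    return fields


def read_envi(path: str | Path) -> SpectralCube:
    """Read an ENVI BSQ cube written by :func:`write_envi`."""
    path = Path(path)
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    if "wavelength" not in fields:
        raise ValueError("ENVI header lacks required wavelength list")
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = _ENVI_TO_DTYPE[int(fields["data type"])]
    data = np.fromfile(path, dtype=dtype)
    if data.size != rows * cols * bands:
        raise ValueError("ENVI data size does not match header dimensions")
    cube = np.transpose(data.reshape(bands, rows, cols), (1, 2, 0))
    wl = np.array(
        [float(w) for w in fields["wavelength"].strip("{}").split(",") if w.strip()]
    )
    state = "raw"
    if "state=" in fields.get("description", ""):
        state = fields["description"].split("state=")[1].rstrip("}").strip()
    return SpectralCube(cube.astype(float), wl, state=state)


def write_thermal_tiff(raster: np.ndarray, path: str | Path) -> Path:
    """Write a °C raster as 32-bit float TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(raster, dtype=np.float32))
    return path


def read_thermal_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as 8-bit PNG (255 = True)."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127
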