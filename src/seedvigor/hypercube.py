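"""Hyperspectral cubes: ENVI-style I/O and reflectance calibration.

A hypercube is an ``m x n x w`` array (rows x cols x bands) with a strictly
increasing wavelength axis in nm.  Raw sensor counts are converted to
reflectance with dark-current and white-panel references::

    I = (I_org - I_dark) / (I_white - I_dark)

Calibrated values are deliberately not clipped to [0, 1]; noise can push
pixels slightly outside and :func:`calibration_validity` reports how many.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Hypercube",
    "CalibrationRefs",
    "EnviFormatError",
    "read_envi",
    "write_envi",
    "calibrate",
    "band_at_wavelength",
    "calibration_validity",
]

# ENVI numeric data-type codes supported here
_DTYPE_CODES = {12: np.dtype("<u2"), 4: np.dtype("<f4")}
_DTYPE_TO_CODE = {np.dtype("uint16"): 12, np.dtype("float32"): 4}
_INTERLEAVES = ("bil", "bip", "bsq")


class EnviFormatError(ValueError):
    """Raised for malformed or unsupported ENVI files."""


@dataclass
class Hypercube:
    """An m x n x w data cube with its wavelength axis.

    ``domain`` is ``"raw"`` for sensor counts and ``"reflectance"`` after
    calibration.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    domain: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows x cols x bands)")
        if self.wavelengths.ndim != 1 or self.data.shape[2] != self.wavelengths.size:
            raise ValueError("band count must match wavelength vector length")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.domain not in ("raw", "reflectance"):
            raise ValueError(f"unknown value domain {self.domain!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationRefs:
    """Dark and white references, as full cubes or per-band vectors.

    Full cubes are averaged over pixels band-wise before use.
    """

    dark: np.ndarray
    white: np.ndarray
    _dark_mean: np.ndarray = field(init=False, repr=False)
    _white_mean: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._dark_mean = self._band_mean(self.dark)
        self._white_mean = self._band_mean(self.white)
        if self._dark_mean.shape != self._white_mean.shape:
            raise ValueError("dark and white references must share band count")
        if not np.all(self._white_mean > self._dark_mean):
            raise ValueError(
                "degenerate references: white must exceed dark in every band"
            )

    @staticmethod
    def _band_mean(ref) -> np.ndarray:
        arr = np.asarray(ref, dtype=float)
        if arr.ndim == 3:
            return arr.mean(axis=(0, 1))
        if arr.ndim == 1:
            return arr
        raise ValueError("reference must be a cube or a per-band vector")

    @property
    def dark_per_band(self) -> np.ndarray:
        return self._dark_mean

    @property
    def white_per_band(self) -> np.ndarray:
        return self._white_mean


def calibrate(raw: Hypercube, refs: CalibrationRefs) -> Hypercube:
    """Black/white reference correction of raw counts to reflectance."""
    if raw.domain != "raw":
        raise ValueError("cube is already calibrated")
    dark = refs.dark_per_band
    white = refs.white_per_band
    if dark.size != raw.n_bands:
        raise ValueError("reference band count does not match cube")
    out = (raw.data.astype(float) - dark) / (white - dark)
    return Hypercube(out, raw.wavelengths, domain="reflectance")


def calibration_validity(cube: Hypercube, lo: float = 0.0, hi: float = 1.5) -> dict:
    """Count out-of-range pixels in a calibrated cube (nothing is clipped)."""
    below = int(np.count_nonzero(cube.data < lo))
    above = int(np.count_nonzero(cube.data > hi))
    return {"below": below, "above": above, "total": int(cube.data.size)}


def band_at_wavelength(cube: Hypercube, target_nm: float) -> int:
    """Index of the band nearest ``target_nm``; ties break to the lower index."""
    wl = cube.wavelengths
    spacing = np.diff(wl).max() if wl.size > 1 else 1.0
    if target_nm < wl[0] - spacing / 2 or target_nm > wl[-1] + spacing / 2:
        raise ValueError(
            f"target {target_nm} nm outside wavelength range "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    dist = np.abs(wl - target_nm)
    return int(np.argmin(dist))  # argmin returns the first (lower) index on ties


# ---------------------------------------------------------------------------
# ENVI header + flat-binary I/O
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic line")
    fields: dict[str, str] = {}
    # join brace-delimited blocks onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path, data_path=None) -> Hypercube:
    """Read an ENVI header (.hdr) + flat binary pair into a :class:`Hypercube`."""
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".img")
    fields = _parse_header(header_path.read_text())
    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in fields:
            raise EnviFormatError(f"header missing required field {key!r}")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    code = int(fields["data type"])
    if code not in _DTYPE_CODES:
        raise EnviFormatError(f"unsupported ENVI data type code {code}")
    dtype = _DTYPE_CODES[code]
    if "wavelength" not in fields:
        raise EnviFormatError("header missing wavelength block")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array(
        [float(tok) for tok in wl_text.replace(",", " ").split()], dtype=float
    )
    if wavelengths.size != bands:
        raise EnviFormatError("wavelength list length does not match band count")

    buf = Path(data_path).read_bytes()
    expected = lines * samples * bands * dtype.itemsize
    if len(buf) < expected:
        raise EnviFormatError(
            f"binary file truncated: {len(buf)} bytes, expected {expected}"
        )
    flat = np.frombuffer(buf[:expected], dtype=dtype)
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(lines, samples, bands)
    domain = fields.get("value domain", "raw")
    return Hypercube(np.ascontiguousarray(data), wavelengths, domain=domain)


def write_envi(cube: Hypercube, header_path, data_path=None, interleave: str = "bsq") -> None:
    """Write a cube as an ENVI header + flat binary pair (lossless round trip)."""
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".img")
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    dtype = cube.data.dtype
    if dtype not in _DTYPE_TO_CODE:
        raise EnviFormatError(
            f"unsupported dtype {dtype}; use uint16 or float32 for ENVI output"
        )
    lines, samples, bands = cube.shape
    if interleave == "bsq":
        ordered = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = cube.data.transpose(0, 2, 1)
    else:
        ordered = cube.data
    wl = ", ".join(f"{w:.2f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_CODE[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"value domain = {cube.domain}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    Path(data_path).write_bytes(np.ascontiguousarray(ordered).tobytes())
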