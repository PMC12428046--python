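"""ENVI-style hyperspectral cubes and black/white reflectance correction.

A cube is stored on disk as a plain-text header (``*.hdr``) next to a
headerless little-endian binary, in one of the three standard interleaves
(BSQ: band-sequential, BIL: band-interleaved-by-line, BIP: by-pixel).  In
memory the data always lives as a ``(rows, cols, bands)`` array.

Raw push-broom frames are digital numbers (DN).  Reflectance is recovered
with the usual black/white correction

    R = (I_raw - I_dark) / (I_white - I_dark)

where the white reference is a PTFE panel capture and the dark reference a
closed-shutter capture of the sensor's dark current.  References may be full
cubes or single line frames (``1 x cols x bands``) broadcast across rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np

from .errors import FormatError, ShapeError, UnsupportedDialectError, ValidationError

__all__ = ["SpectralCube", "ReferencePair", "read_envi", "write_envi", "calibrate"]

# ENVI data-type codes supported by this reader: the camera writes 14-bit DNs
# in unsigned 16-bit words; processed cubes are 32-bit float.
_DTYPES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_DTYPE_CODES = {np.dtype("float32"): 4, np.dtype("uint16"): 12}
_INTERLEAVES = ("bil", "bip", "bsq")
_KINDS = ("raw", "white", "dark", "reflectance")


@dataclass
class SpectralCube:
    """``(rows, cols, bands)`` block with wavelength axis and ENVI metadata."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    interleave: str = "bil"
    dtype_code: int = 4
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("cube data must be 3-D (rows, cols, bands)")
        if self.wavelengths_nm.shape != (self.data.shape[2],):
            raise ValidationError("wavelength list length must equal band count")
        if len(self.wavelengths_nm) > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValidationError("wavelengths must be strictly ascending")
        if self.interleave not in _INTERLEAVES:
            raise ValidationError(f"interleave must be one of {_INTERLEAVES}")
        if self.dtype_code not in _DTYPES:
            raise UnsupportedDialectError(
                f"ENVI data type {self.dtype_code} unsupported (only 4=float32, 12=uint16)"
            )
        if self.kind not in _KINDS:
            raise ValidationError(f"kind must be one of {_KINDS}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ValidationError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class ReferencePair:
    """White (bright PTFE) and dark (shutter-closed) reference captures."""

    white: SpectralCube
    dark: SpectralCube

    def __post_init__(self) -> None:
        if self.white.kind != "white" or self.dark.kind != "dark":
            raise ValidationError("references must have kind 'white' and 'dark'")
        if self.white.shape != self.dark.shape:
            raise ShapeError("white and dark references must share a shape")


def _binary_path(header_path: Union[str, Path]) -> Path:
    p = Path(header_path)
    return p.with_suffix("") if p.suffix == ".hdr" else Path(str(p) + ".bin")


def write_envi(cube: SpectralCube, header_path: Union[str, Path]) -> None:
    """Write ``cube`` as an ENVI text header plus sibling binary."""
    header_path = Path(header_path)
    rows, cols, bands = cube.shape
    dtype = _DTYPES[cube.dtype_code]
    arr = np.ascontiguousarray(cube.data.astype(dtype.newbyteorder("<"), copy=False))
    if cube.interleave == "bsq":
        ordered = arr.transpose(2, 0, 1)  # (bands, lines, samples)
    elif cube.interleave == "bil":
        ordered = arr.transpose(0, 2, 1)  # (lines, bands, samples)
    else:  # bip
        ordered = arr  # (lines, samples, bands)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths_nm)
    header = (
        "ENVI\n"
        "description = {seedspectra cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {cube.dtype_code}\n"
        f"interleave = {cube.interleave}\n"
        "byte order = 0\n"
        f"kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    header_path.write_text(header)
    np.ascontiguousarray(ordered).tofile(_binary_path(header_path))


def _parse_header(text: str) -> dict:
    """Parse the ``key = value`` / ``key = {multi, line, list}`` ENVI grammar."""
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for raw_line in text.splitlines():
        line = raw_line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if not in_braces:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip().lower()
            value = value.strip()
            if value.startswith("{") and not value.endswith("}"):
                in_braces, buf = True, [value[1:]]
            else:
                fields[key] = value.strip("{}").strip()
        else:
            if line.endswith("}"):
                buf.append(line[:-1])
                fields[key] = " ".join(buf).strip()  # type: ignore[index]
                in_braces = False
            else:
                buf.append(line)
    return fields


def read_envi(header_path: Union[str, Path]) -> SpectralCube:
    """Read an ENVI header + binary pair written by :func:`write_envi` (or ENVI)."""
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"header not found: {header_path}")
    fields = _parse_header(header_path.read_text())
    required = ("samples", "lines", "bands", "data type", "interleave")
    missing = [k for k in required if k not in fields]
    if missing:
        raise FormatError(f"header missing required field(s): {missing}")
    cols, rows, bands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    dtype_code = int(fields["data type"])
    if dtype_code not in _DTYPES:
        raise UnsupportedDialectError(f"ENVI data type {dtype_code} unsupported")
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unknown interleave {interleave!r}")
    if int(fields.get("byte order", "0")) != 0:
        raise UnsupportedDialectError("only little-endian (byte order = 0) is supported")
    if "wavelength" in fields:
        wavelengths = np.array([float(t) for t in fields["wavelength"].split(",") if t.strip()])
        if wavelengths.shape != (bands,):
            raise FormatError(
                f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
            )
    else:
        wavelengths = np.arange(bands, dtype=float)
    binary = _binary_path(header_path)
    if not binary.exists():
        raise FormatError(f"binary file not found next to header: {binary}")
    flat = np.fromfile(binary, dtype=_DTYPES[dtype_code])
    if flat.size != rows * cols * bands:
        raise FormatError(
            f"binary holds {flat.size} values, header implies {rows * cols * bands}"
        )
    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        data = flat.reshape(rows, cols, bands)
    return SpectralCube(
        data=np.ascontiguousarray(data),
        wavelengths_nm=wavelengths,
        interleave=interleave,
        dtype_code=dtype_code,
        kind=fields.get("kind", "raw"),
    )


def average_reference_rows(ref: SpectralCube) -> SpectralCube:
    """Collapse a full reference cube to a single mean line frame (1, cols, bands)."""
    return replace(ref, data=ref.data.astype(np.float64).mean(axis=0, keepdims=True), dtype_code=4)


def calibrate(
    raw: SpectralCube,
    refs: ReferencePair,
    epsilon: float = 1e-6,
    average_rows: bool = False,
) -> SpectralCube:
    """Black/white correction: ``R = (raw - dark) / (white - dark)``.

    The denominator is floored at ``epsilon`` (with a warning counting the
    affected elements); references of shape ``(1, cols, bands)`` broadcast
    across the raw cube's rows.  Inputs are left unmodified.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    white, dark = refs.white, refs.dark
    if average_rows:
        white, dark = average_reference_rows(white), average_reference_rows(dark)
    for ref in (white, dark):
        ok = ref.shape == raw.shape or (
            ref.shape[0] == 1 and ref.shape[1:] == raw.shape[1:]
        )
        if not ok:
            raise ShapeError(
                f"reference shape {ref.shape} incompatible with raw shape {raw.shape}"
            )
    w = white.data.astype(np.float64)
    d = dark.data.astype(np.float64)
    denom = w - d
    n_floored = int((denom < epsilon).sum())
    if n_floored:
        warnings.warn(f"{n_floored} element(s) had white - dark < {epsilon}; denominator floored")
    refl = (raw.data.astype(np.float64) - d) / np.maximum(denom, epsilon)
    return SpectralCube(
        data=refl,
        wavelengths_nm=raw.wavelengths_nm.copy(),
        interleave=raw.interleave,
        dtype_code=4,
        kind="reflectance",
    )
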