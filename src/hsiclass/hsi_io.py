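"""Hyperspectral cube and label-map containers with canonical file I/O.

A hyperspectral cube is a ``height x width x n_bands`` reflectance array
with values in [0, 1]; each pixel carries a full spectral signature
(116 bands over 450-950 nm for the snapshot-camera data this package
emulates).  The canonical on-disk container is a two-file pair:

* ``<path>`` -- flat little-endian binary, band-interleaved-by-pixel
  (BIP): the bytes of pixel 0's spectrum, then pixel 1's, row-major.
  BIP matches the per-pixel access pattern of classification.
* ``<path>.json`` -- sidecar declaring dims, dtype, byte order and the
  spectral band range.

Label maps reuse the same container with an integer dtype.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HSICube",
    "LabelMap",
    "read_cube",
    "write_cube",
    "read_labels",
    "write_labels",
    "normalize_cube",
    "read_envi_cube",
]

_CUBE_DTYPE = np.dtype("<f8")
_LABEL_DTYPE = np.dtype("<i4")


@dataclass
class HSICube:
    """A reflectance cube; pixels are indexed 0-based, row-major.

    The linear pixel index is ``p = row * width + col``.
    """

    reflectance: np.ndarray  # (height, width, n_bands) float64
    band_range_nm: tuple[float, float] = (450.0, 950.0)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        if self.reflectance.ndim != 3:
            raise ValueError(
                f"reflectance must be 3-D (height, width, bands), got "
                f"{self.reflectance.ndim}-D"
            )
        h, w, b = self.reflectance.shape
        if min(h, w, b) < 1:
            raise ValueError(f"all cube dimensions must be >= 1, got {h}x{w}x{b}")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("cube contains non-finite reflectance values")

    @property
    def height(self) -> int:
        return self.reflectance.shape[0]

    @property
    def width(self) -> int:
        return self.reflectance.shape[1]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def pixels(self) -> np.ndarray:
        """Spectra as an (n_pixels, n_bands) matrix in linear-index order."""
        return self.reflectance.reshape(self.n_pixels, self.n_bands)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HSICube):
            return NotImplemented
        return (
            self.reflectance.shape == other.reflectance.shape
            and np.array_equal(self.reflectance, other.reflectance)
            and tuple(self.band_range_nm) == tuple(other.band_range_nm)
        )


@dataclass
class LabelMap:
    """Per-pixel class indices aligned with a source cube."""

    labels: np.ndarray  # (height, width) int
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D (height, width)")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_classes
        ):
            raise ValueError(
                f"labels must lie in [0, {self.n_classes}), got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.labels.size

    def flat(self) -> np.ndarray:
        return self.labels.reshape(-1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMap):
            return NotImplemented
        return self.n_classes == other.n_classes and np.array_equal(
            self.labels, other.labels
        )


def _sidecar_path(path: str | os.PathLike) -> str:
    return os.fspath(path) + ".json"


def write_cube(cube: HSICube, path: str | os.PathLike) -> None:
    """Write a cube as flat BIP binary plus a JSON sidecar."""
    path = os.fspath(path)
    header = {
        "container": "hsiclass-cube",
        "height": cube.height,
        "width": cube.width,
        "n_bands": cube.n_bands,
        "dtype": _CUBE_DTYPE.str,
        "interleave": "bip",
        "band_range_nm": list(cube.band_range_nm),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(header, fh, indent=1)
    cube.reflectance.astype(_CUBE_DTYPE).tofile(path)


def read_cube(path: str | os.PathLike) -> HSICube:
    """Read a cube written by :func:`write_cube`.

    Raises ``FileNotFoundError`` for missing files and ``ValueError``
    when the payload size disagrees with the header or values are
    non-finite.
    """
    path = os.fspath(path)
    with open(_sidecar_path(path)) as fh:
        header = json.load(fh)
    for key in ("height", "width", "n_bands", "dtype"):
        if key not in header:
            raise ValueError(f"cube sidecar missing required key {key!r}")
    h, w, b = int(header["height"]), int(header["width"]), int(header["n_bands"])
    dtype = np.dtype(header["dtype"])
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != h * w * b:
        raise ValueError(
            f"payload holds {raw.size} values but header declares "
            f"{h}x{w}x{b} = {h * w * b}"
        )
    data = raw.reshape(h, w, b)
    if not np.all(np.isfinite(data)):
        raise ValueError("cube payload contains non-finite values")
    band_range = tuple(header.get("band_range_nm", (450.0, 950.0)))
    return HSICube(reflectance=data, band_range_nm=band_range)  # type: ignore[arg-type]


def write_labels(labels: LabelMap, path: str | os.PathLike) -> None:
    """Write a label map in the same two-file container (int32 payload)."""
    path = os.fspath(path)
    header = {
        "container": "hsiclass-labels",
        "height": labels.height,
        "width": labels.width,
        "n_classes": labels.n_classes,
        "dtype": _LABEL_DTYPE.str,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(header, fh, indent=1)
    labels.labels.astype(_LABEL_DTYPE).tofile(path)


def read_labels(path: str | os.PathLike) -> LabelMap:
    path = os.fspath(path)
    with open(_sidecar_path(path)) as fh:
        header = json.load(fh)
    h, w = int(header["height"]), int(header["width"])
    n_classes = int(header["n_classes"])
    raw = np.fromfile(path, dtype=np.dtype(header["dtype"]))
    if raw.size != h * w:
        raise ValueError(
            f"payload holds {raw.size} labels but header declares {h}x{w}"
        )
    return LabelMap(labels=raw.reshape(h, w), n_classes=n_classes)


def normalize_cube(cube: HSICube) -> HSICube:
    """Min-max scale every pixel spectrum into [0, 1] independently.

    A stand-in for the patient-level illumination normalization applied
    to the clinical data upstream of classification (whose exact
    procedure is external to this package).  Constant spectra map to
    all-zeros by convention, making this a total, idempotent function.
    """
    spectra = cube.pixels()
    lo = spectra.min(axis=1, keepdims=True)
    hi = spectra.max(axis=1, keepdims=True)
    span = hi - lo
    # constant spectra: span == 0 -> force 0/1 = 0 without warnings
    safe = np.where(span > 0, span, 1.0)
    out = (spectra - lo) / safe
    return HSICube(
        reflectance=out.reshape(cube.reflectance.shape),
        band_range_nm=cube.band_range_nm,
    )


def read_envi_cube(header_path: str | os.PathLike) -> HSICube:
    """Convenience import of an ENVI-format cube (not the canonical format).

    Supports the plain-text ENVI header (``samples``, ``lines``,
    ``bands``, ``data type``, ``interleave``, ``byte order``) with bip,
    bil or bsq interleave and floating payloads.  The binary payload is
    expected at the header path minus its ``.hdr`` suffix.
    """
    header_path = os.fspath(header_path)
    fields: dict[str, str] = {}
    with open(header_path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip().lower()] = val.strip().strip("{}").strip()
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise ValueError(f"ENVI header missing field {exc}") from exc
    envi_dtypes = {1: "u1", 2: "<i2", 3: "<i4", 4: "<f4", 5: "<f8", 12: "<u2"}
    code = int(fields.get("data type", 4))
    if code not in envi_dtypes:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(envi_dtypes[code])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bip").lower()
    payload_path = (
        header_path[:-4] if header_path.endswith(".hdr") else header_path + ".img"
    )
    raw = np.fromfile(payload_path, dtype=dtype)
    if raw.size != lines * samples * bands:
        raise ValueError("ENVI payload size disagrees with header dims")
    if interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    return HSICube(reflectance=np.ascontiguousarray(data, dtype=np.float64))
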