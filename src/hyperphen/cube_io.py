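"""Ingestion and calibration of line-scan hyperspectral data.

A push-broom hyperspectral camera emits a flat binary stream of unsigned
integer samples.  This module reorganizes such streams into per-band images,
calibrates raw intensities to reflectance against dark-current and white
reference frames, and maps band indices to wavelengths.

The instrument geometry emulated here covers 400–1000 nm in 250 bands
(~2.4 nm sampling) with 1,004 cross-track pixels and 900 scan lines, so a
single plant scan is a 1,004 x 250 x 900 stream.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "N_BANDS",
    "WAVELENGTH_MIN_NM",
    "WAVELENGTH_MAX_NM",
    "RawStream",
    "CalibrationFrames",
    "SpectralCube",
    "band_wavelength",
    "default_wavelengths",
    "reorganize_stream",
    "average_streams",
    "calibrate_reflectance",
    "cube_from_stream",
    "read_cube",
    "write_cube",
    "read_raw_stream",
    "write_raw_stream",
]

N_BANDS = 250
WAVELENGTH_MIN_NM = 400.0
WAVELENGTH_MAX_NM = 1000.0

#: Reflectance above this is flagged as suspicious (specular glint, etc.).
REFLECTANCE_FLAG_CEILING = 1.2


def default_wavelengths(n_bands: int = N_BANDS) -> np.ndarray:
    """Linear band-center wavelengths in nm over [400, 1000]."""
    return np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, n_bands)


def band_wavelength(i: int, n_bands: int = N_BANDS) -> float:
    """Wavelength in nm of 1-based band index ``i``.

    lambda(i) = 400 + (i - 1) * 600 / (n_bands - 1); with the default 250
    bands the step is 600/249 ~ 2.41 nm.  Round the result when labelling
    bands (e.g. band 106 -> 653 nm).
    """
    if not 1 <= i <= n_bands:
        raise ValueError(f"band index {i} out of range [1, {n_bands}]")
    return WAVELENGTH_MIN_NM + (i - 1) * (
        WAVELENGTH_MAX_NM - WAVELENGTH_MIN_NM
    ) / (n_bands - 1)


@dataclass
class RawStream:
    """A flat binary acquisition stream plus its layout metadata.

    Parameters
    ----------
    payload
        Raw bytes of ``spatial_width * n_bands * n_lines`` samples.
    dims
        ``(spatial_width, n_bands, n_lines)``.
    interleave
        ``"bil"`` (band-interleaved-by-line, the default), ``"bsq"`` or
        ``"bip"``.
    dtype
        Sample dtype; 16-bit unsigned little-endian by default.  Floating
        dtypes are accepted for loss-free synthetic streams.
    """

    payload: bytes
    dims: tuple[int, int, int]
    interleave: str = "bil"
    dtype: str = "<u2"

    def __post_init__(self) -> None:
        if self.interleave not in ("bil", "bsq", "bip"):
            raise ValueError(f"unknown interleave {self.interleave!r}")
        width, n_bands, n_lines = self.dims
        expected = width * n_bands * n_lines * np.dtype(self.dtype).itemsize
        actual = len(self.payload)
        if actual != expected:
            raise ValueError(
                f"payload size mismatch: expected {expected} bytes for dims "
                f"{self.dims} ({self.dtype}), got {actual}"
            )

    @property
    def n_samples(self) -> int:
        width, n_bands, n_lines = self.dims
        return width * n_bands * n_lines


@dataclass
class CalibrationFrames:
    """Dark-current and white-reference frames, one image per band.

    Both arrays are shaped like a reorganized stream: (bands, width, lines).
    The white frame must exceed the dark frame wherever calibration is to be
    defined.
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ValueError(
                f"dark {self.dark.shape} and white {self.white.shape} "
                "frames must share a shape"
            )


@dataclass
class SpectralCube:
    """Calibrated reflectance over bands x rows x cols.

    ``reflectance`` is unitless, nominally in [0, ~1.2]; ``wavelengths`` is
    strictly increasing, in nm, one entry per band.
    """

    reflectance: np.ndarray
    wavelengths: np.ndarray
    stage_label: str | None = None
    view_angle: int | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be bands x rows x cols")
        if len(self.wavelengths) != self.reflectance.shape[0]:
            raise ValueError(
                f"{len(self.wavelengths)} wavelengths for "
                f"{self.reflectance.shape[0]} bands"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.reflectance.shape[1:]

    def nearest_band(self, nm: float) -> int:
        """0-based index of the band whose center is nearest ``nm``."""
        return int(np.argmin(np.abs(self.wavelengths - nm)))


def reorganize_stream(stream: RawStream) -> np.ndarray:
    """Unpack a flat stream into per-band images.

    Returns an array of shape (n_bands, spatial_width, n_lines): one image
    per band.  The inverse (flattening in the stream's interleave order)
    reproduces the payload bit for bit.
    """
    width, n_bands, n_lines = stream.dims
    flat = np.frombuffer(stream.payload, dtype=stream.dtype)
    if stream.interleave == "bil":
        # line-major: (line, band, pixel)
        cube = flat.reshape(n_lines, n_bands, width).transpose(1, 2, 0)
    elif stream.interleave == "bsq":
        # band-major: (band, line, pixel)
        cube = flat.reshape(n_bands, n_lines, width).transpose(0, 2, 1)
    else:  # bip: (line, pixel, band)
        cube = flat.reshape(n_lines, width, n_bands).transpose(2, 1, 0)
    return np.ascontiguousarray(cube)


def flatten_to_stream(images: np.ndarray, interleave: str = "bil") -> bytes:
    """Inverse of :func:`reorganize_stream` (bands, width, lines) -> payload."""
    if interleave == "bil":
        flat = images.transpose(2, 0, 1)
    elif interleave == "bsq":
        flat = images.transpose(0, 2, 1)
    elif interleave == "bip":
        flat = images.transpose(2, 1, 0)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    return np.ascontiguousarray(flat).tobytes()


def average_streams(streams: list[RawStream]) -> RawStream:
    """Average repeated scans of the same plant into one stream.

    Acquisition protocols often average three repeated scans to improve the
    signal-to-noise ratio; this accepts any number >= 1.  Integer payloads
    are rounded back to the stream dtype.
    """
    if not streams:
        raise ValueError("no streams to average")
    first = streams[0]
    for s in streams[1:]:
        if s.dims != first.dims or s.interleave != first.interleave:
            raise ValueError("streams must share dims and interleave")
    stacked = np.mean(
        [np.frombuffer(s.payload, dtype=s.dtype).astype(float) for s in streams],
        axis=0,
    )
    dt = np.dtype(first.dtype)
    if dt.kind in "ui":
        stacked = np.rint(stacked)
    payload = stacked.astype(dt).tobytes()
    return RawStream(payload, first.dims, first.interleave, first.dtype)


def calibrate_reflectance(
    raw: np.ndarray,
    dark: np.ndarray,
    white: np.ndarray,
    *,
    clip_negative: bool = True,
    flag_ceiling: float = REFLECTANCE_FLAG_CEILING,
) -> np.ndarray:
    """Convert raw intensity to reflectance, r = (I - I_dark)/(I_ref - I_dark).

    Pixels where the white reference equals the dark frame carry no
    calibration information and are returned as NaN.  Negative reflectance
    (sensor noise below dark current) is clipped at 0 unless disabled;
    values above ``flag_ceiling`` trigger a warning but are kept.
    """
    raw = np.asarray(raw, dtype=float)
    dark = np.asarray(dark, dtype=float)
    white = np.asarray(white, dtype=float)
    if not (raw.shape == dark.shape == white.shape):
        raise ValueError(
            f"shape mismatch: raw {raw.shape}, dark {dark.shape}, "
            f"white {white.shape}"
        )
    denom = white - dark
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom != 0, (raw - dark) / np.where(denom == 0, 1, denom), np.nan)
    if clip_negative:
        r = np.where(np.isnan(r), r, np.maximum(r, 0.0))
    n_high = int(np.sum(r > flag_ceiling))
    if n_high:
        warnings.warn(
            f"{n_high} pixels exceed reflectance {flag_ceiling}", stacklevel=2
        )
    return r


def cube_from_stream(
    stream: RawStream,
    frames: CalibrationFrames,
    wavelengths: np.ndarray | None = None,
    **meta,
) -> SpectralCube:
    """Reorganize, calibrate and wrap a raw stream as a :class:`SpectralCube`."""
    images = reorganize_stream(stream).astype(float)
    if frames.dark.shape != images.shape:
        raise ValueError(
            f"calibration frames {frames.dark.shape} do not match "
            f"reorganized stream {images.shape}"
        )
    refl = calibrate_reflectance(images, frames.dark, frames.white)
    if wavelengths is None:
        wavelengths = default_wavelengths(stream.dims[1])
    return SpectralCube(refl, wavelengths, **meta)


# ---------------------------------------------------------------------------
# ENVI-style container (plain-text .hdr + raw binary), and raw stream files.
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: "u1", 2: "<i2", 3: "<i4", 4: "<f4", 5: "<f8", 12: "<u2"}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_cube(path: str | Path, cube: SpectralCube) -> Path:
    """Write a cube as an ENVI header/data pair (``<path>.hdr`` + ``<path>.img``).

    Data are stored band-sequential as 64-bit floats so reflectance and the
    wavelength vector round-trip losslessly.
    """
    base = Path(path)
    data = np.ascontiguousarray(cube.reflectance, dtype="<f8")
    bands, rows, cols = data.shape
    lines = [
        "ENVI",
        "description = {hyperphen reflectance cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[np.dtype('<f8')]}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + ", ".join(repr(float(w)) for w in cube.wavelengths) + "}",
    ]
    if cube.stage_label is not None:
        lines.append(f"stage label = {{{cube.stage_label}}}")
    if cube.view_angle is not None:
        lines.append(f"view angle = {{{cube.view_angle}}}")
    if cube.accession is not None:
        lines.append(f"accession = {{{cube.accession}}}")
    base.with_suffix(".hdr").write_text("\n".join(lines) + "\n")
    base.with_suffix(".img").write_bytes(data.tobytes())
    return base


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_cube(path: str | Path) -> SpectralCube:
    """Read an ENVI header/data pair written by :func:`write_cube`."""
    base = Path(path)
    hdr = _parse_envi_header(base.with_suffix(".hdr").read_text())
    try:
        cols = int(hdr["samples"])
        rows = int(hdr["lines"])
        bands = int(hdr["bands"])
        code = int(hdr["data type"])
        interleave = hdr.get("interleave", "bsq").lower()
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed ENVI header: {exc}") from exc
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    raw = base.with_suffix(".img").read_bytes()
    expected = bands * rows * cols * dtype.itemsize
    if len(raw) != expected:
        raise ValueError(
            f"data size mismatch: header promises {expected} bytes "
            f"({bands} bands x {rows} x {cols}), file has {len(raw)}"
        )
    flat = np.frombuffer(raw, dtype=dtype)
    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(1, 0, 2)
    elif interleave == "bip":
        data = flat.reshape(rows, cols, bands).transpose(2, 0, 1)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    wl_match = re.search(r"\{([^}]*)\}", hdr.get("wavelength", ""))
    if wl_match:
        wavelengths = np.array(
            [float(tok) for tok in wl_match.group(1).split(",") if tok.strip()]
        )
    else:
        wavelengths = default_wavelengths(bands)

    def _brace(key: str) -> str | None:
        m = re.search(r"\{([^}]*)\}", hdr.get(key, ""))
        return m.group(1).strip() if m else None

    view = _brace("view angle")
    return SpectralCube(
        data.astype(float),
        wavelengths,
        stage_label=_brace("stage label"),
        view_angle=int(view) if view else None,
        accession=_brace("accession"),
    )


def write_raw_stream(path: str | Path, stream: RawStream) -> Path:
    """Write ``<path>.bil`` plus a plain-text ``<path>.dims`` sidecar."""
    base = Path(path)
    base.with_suffix(".bil").write_bytes(stream.payload)
    width, n_bands, n_lines = stream.dims
    base.with_suffix(".dims").write_text(
        f"width={width}\nbands={n_bands}\nlines={n_lines}\n"
        f"interleave={stream.interleave}\ndtype={stream.dtype}\n"
    )
    return base


def read_raw_stream(path: str | Path, dims: tuple[int, int, int] | None = None,
                    interleave: str = "bil", dtype: str = "<u2") -> RawStream:
    """Read a raw stream; layout from the ``.dims`` sidecar unless given."""
    base = Path(path)
    sidecar = base.with_suffix(".dims")
    if dims is None:
        if not sidecar.exists():
            raise ValueError(f"no dims given and no sidecar {sidecar}")
        kv = dict(
            line.split("=", 1) for line in sidecar.read_text().splitlines() if line
        )
        dims = (int(kv["width"]), int(kv["bands"]), int(kv["lines"]))
        interleave = kv.get("interleave", interleave)
        dtype = kv.get("dtype", dtype)
    payload = base.with_suffix(".bil").read_bytes()
    return RawStream(payload, dims, interleave, dtype)
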