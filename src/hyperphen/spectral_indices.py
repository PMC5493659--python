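"""The whole-plant hyperspectral index catalog.

Eight index families are computed per plant from the masked reflectance
cube:

===== ===============================================  ====
T     per-band total reflectance (sum over plant px)    250
A     per-band average reflectance, A_i = T_i / S       250
dT    first derivative of T w.r.t. wavelength           250
dA    first derivative of A                             250
ddT   second derivative of T                            250
ddA   second derivative of A                            250
CPT   characteristic features of the T spectrum          20
CPA   characteristic features of the A spectrum          20
===== ===============================================  ====

for a catalog of exactly 1,540 named indices; the projected area S is
carried alongside, giving 1,541 candidate predictors for trait models.

Derivatives are taken with respect to wavelength (per nm, not per band
index) using central differences at interior bands and one-sided stencils
at the ends, so every family keeps the full 250-band length.

The 20 characteristic features are a registry of standard vegetation
spectroscopy quantities (edge positions/amplitudes/areas, green peak, red
valley, plateau means and ratio combinations); slot 9 is the red-edge area,
the integral of the first derivative over 680-760 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube_io import SpectralCube
from .segmentation import PlantMask, apply_mask

__all__ = [
    "BAND_FAMILIES",
    "CHARACTERISTIC_NAMES",
    "IndexCatalogSpec",
    "IndexVector",
    "catalog_spec",
    "feature_names",
    "feature_wavelength",
    "band_stats",
    "derivative_spectrum",
    "characteristic_indices",
    "assemble_index_vector",
    "combine_views",
    "index_table",
]

BAND_FAMILIES = ("T", "A", "dT", "dA", "ddT", "ddA")
CHARACTERISTIC_FAMILIES = ("CPT", "CPA")

# Spectral windows (nm) for the characteristic features.
WINDOWS = {
    "blue_edge": (490.0, 530.0),
    "yellow_edge": (560.0, 640.0),
    "red_edge": (680.0, 760.0),
    "green_peak": (510.0, 560.0),
    "red_valley": (640.0, 700.0),
    "nir_plateau": (780.0, 1000.0),
    "visible": (400.0, 760.0),
}

#: (slot name, nominal wavelength for frequency tallies).  Slot 9 is the
#: red-edge area by construction; re-bind slots here if a different catalog
#: convention is needed.
CHARACTERISTIC_SLOTS: list[tuple[str, float]] = [
    ("blue_edge_position", 510.0),
    ("blue_edge_amplitude", 510.0),
    ("blue_edge_area", 510.0),
    ("yellow_edge_position", 600.0),
    ("yellow_edge_amplitude", 600.0),
    ("yellow_edge_area", 600.0),
    ("red_edge_position", 720.0),
    ("red_edge_amplitude", 720.0),
    ("red_edge_area", 720.0),  # slot 9
    ("green_peak_position", 535.0),
    ("green_peak_height", 535.0),
    ("red_valley_position", 670.0),
    ("red_valley_depth", 670.0),
    ("nir_plateau_mean", 890.0),
    ("visible_mean", 580.0),
    ("ratio_green_peak_red_valley", 550.0),
    ("nd_green_peak_red_valley", 550.0),
    ("ratio_red_blue_edge_area", 615.0),
    ("nd_red_blue_edge_area", 615.0),
    ("ratio_nir_visible", 735.0),
]
CHARACTERISTIC_NAMES = [name for name, _ in CHARACTERISTIC_SLOTS]
N_CHARACTERISTIC = len(CHARACTERISTIC_SLOTS)
assert N_CHARACTERISTIC == 20


@dataclass(frozen=True)
class IndexCatalogSpec:
    """Family names, sizes and the full ordered feature-name list."""

    n_bands: int = 250

    @property
    def family_sizes(self) -> dict[str, int]:
        sizes = {fam: self.n_bands for fam in BAND_FAMILIES}
        sizes.update({fam: N_CHARACTERISTIC for fam in CHARACTERISTIC_FAMILIES})
        return sizes

    @property
    def total(self) -> int:
        return sum(self.family_sizes.values())

    @property
    def names(self) -> list[str]:
        out: list[str] = []
        for fam in BAND_FAMILIES:
            out.extend(f"{fam}_{i}" for i in range(1, self.n_bands + 1))
        for fam in CHARACTERISTIC_FAMILIES:
            out.extend(f"{fam}_{i}" for i in range(1, N_CHARACTERISTIC + 1))
        return out


def catalog_spec(n_bands: int = 250) -> IndexCatalogSpec:
    return IndexCatalogSpec(n_bands)


def feature_names(n_bands: int = 250) -> list[str]:
    """All 1,540 feature names in catalog order."""
    return IndexCatalogSpec(n_bands).names


def feature_wavelength(name: str, wavelengths: np.ndarray) -> float:
    """Nominal wavelength (nm) a feature is tallied at.

    Band-wise features map through their band index; characteristic features
    through the center of their defining window.
    """
    fam, _, idx = name.partition("_")
    i = int(idx)
    if fam in BAND_FAMILIES:
        return float(wavelengths[i - 1])
    if fam in CHARACTERISTIC_FAMILIES:
        return CHARACTERISTIC_SLOTS[i - 1][1]
    raise ValueError(f"unknown feature {name!r}")


@dataclass
class IndexVector:
    """One plant's named index values plus its projected area."""

    values: pd.Series
    s_pixels: float
    stage_label: str | None = None
    view_angle: int | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature names in index vector")

    def __len__(self) -> int:
        return len(self.values)

    def with_area(self) -> pd.Series:
        """The 1,541-variable view: catalog values plus S."""
        out = self.values.copy()
        out["S"] = self.s_pixels
        return out


def band_stats(cube: SpectralCube, mask: PlantMask | np.ndarray):
    """Per-band total (T) and average (A) reflectance over plant pixels.

    T_i sums reflectance at band i over the mask; A_i = T_i / S.  Raises if
    the mask is empty since A is then undefined.
    """
    pixels = apply_mask(cube, mask)
    s = pixels.shape[1]
    if s == 0:
        raise ValueError("empty mask: projected area S = 0, band stats undefined")
    T = pixels.sum(axis=1)
    A = T / s
    return T, A


def derivative_spectrum(values: np.ndarray, wavelengths: np.ndarray):
    """First and second derivative of a spectrum w.r.t. wavelength.

    Central differences at interior bands, second-order one-sided stencils
    at the two ends, so both outputs keep the input length.
    """
    values = np.asarray(values, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if values.shape != wavelengths.shape:
        raise ValueError("values and wavelengths must have equal length")
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in spectrum")
    d1 = np.gradient(values, wavelengths)
    d2 = np.gradient(d1, wavelengths)
    return d1, d2


def _window(wavelengths: np.ndarray, key: str) -> np.ndarray:
    lo, hi = WINDOWS[key]
    if lo < wavelengths[0] - 1e-9 or hi > wavelengths[-1] + 1e-9:
        raise ValueError(
            f"window {key} [{lo}, {hi}] nm outside spectral range "
            f"[{wavelengths[0]}, {wavelengths[-1]}]"
        )
    return (wavelengths >= lo) & (wavelengths <= hi)


def _safe_div(a: float, b: float) -> float:
    return a / b if b != 0 else np.nan


def _norm_diff(a: float, b: float) -> float:
    return _safe_div(a - b, a + b)


def characteristic_indices(
    spectrum: np.ndarray, wavelengths: np.ndarray
) -> np.ndarray:
    """The 20 characteristic features of one spectrum, in slot order.

    Computed identically for total- and average-reflectance spectra (CPT
    and CPA differ only in their input).  Edge positions/amplitudes come
    from the first derivative inside the window; areas are trapezoidal
    integrals of the first derivative; the red-valley depth is measured
    against the chord between the window endpoints.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    d1, _ = derivative_spectrum(spectrum, wavelengths)

    def edge(key):
        m = _window(wavelengths, key)
        wl, dv = wavelengths[m], d1[m]
        k = int(np.argmax(dv))
        position = wl[k]
        amplitude = dv[k]
        area = np.trapezoid(dv, wl)
        return position, amplitude, area

    blue_pos, blue_amp, blue_area = edge("blue_edge")
    yellow_pos, yellow_amp, yellow_area = edge("yellow_edge")
    red_pos, red_amp, red_area = edge("red_edge")

    m = _window(wavelengths, "green_peak")
    k = int(np.argmax(spectrum[m]))
    green_pos = wavelengths[m][k]
    green_height = spectrum[m][k]

    m = _window(wavelengths, "red_valley")
    wl_v, r_v = wavelengths[m], spectrum[m]
    k = int(np.argmin(r_v))
    valley_pos = wl_v[k]
    # depth below the chord joining the window endpoints
    chord = r_v[0] + (r_v[-1] - r_v[0]) * (valley_pos - wl_v[0]) / (wl_v[-1] - wl_v[0])
    valley_depth = chord - r_v[k]
    valley_refl = r_v[k]

    nir_mean = float(spectrum[_window(wavelengths, "nir_plateau")].mean())
    vis_mean = float(spectrum[_window(wavelengths, "visible")].mean())

    return np.array(
        [
            blue_pos,
            blue_amp,
            blue_area,
            yellow_pos,
            yellow_amp,
            yellow_area,
            red_pos,
            red_amp,
            red_area,
            green_pos,
            green_height,
            valley_pos,
            valley_depth,
            nir_mean,
            vis_mean,
            _safe_div(green_height, valley_refl),
            _norm_diff(green_height, valley_refl),
            _safe_div(red_area, blue_area),
            _norm_diff(red_area, blue_area),
            _safe_div(nir_mean, vis_mean),
        ]
    )


def assemble_index_vector(
    cube: SpectralCube, mask: PlantMask | np.ndarray
) -> IndexVector:
    """Compute the full named catalog (1,540 values) for one segmented cube."""
    T, A = band_stats(cube, mask)
    wl = cube.wavelengths
    dT, ddT = derivative_spectrum(T, wl)
    dA, ddA = derivative_spectrum(A, wl)
    cpt = characteristic_indices(T, wl)
    cpa = characteristic_indices(A, wl)

    blocks = {"T": T, "A": A, "dT": dT, "dA": dA, "ddT": ddT, "ddA": ddA,
              "CPT": cpt, "CPA": cpa}
    spec = IndexCatalogSpec(cube.n_bands)
    for fam, size in spec.family_sizes.items():
        if len(blocks[fam]) != size:
            raise ValueError(
                f"family {fam} has {len(blocks[fam])} values, expected {size}"
            )
    values = pd.Series(
        np.concatenate([blocks[fam] for fam in (*BAND_FAMILIES,
                                                *CHARACTERISTIC_FAMILIES)]),
        index=spec.names,
    )
    s = int(np.asarray(mask.mask if isinstance(mask, PlantMask) else mask).sum())
    return IndexVector(
        values,
        s_pixels=s,
        stage_label=cube.stage_label,
        view_angle=cube.view_angle,
        accession=cube.accession,
    )


def combine_views(view0: IndexVector, view90: IndexVector) -> IndexVector:
    """Average the two imaging angles (0 and 90 degrees) of one plant.

    Index values and the projected area S are both arithmetic means of the
    two views.
    """
    if not view0.values.index.equals(view90.values.index):
        raise ValueError("views carry different catalogs")
    return IndexVector(
        (view0.values + view90.values) / 2.0,
        s_pixels=(view0.s_pixels + view90.s_pixels) / 2.0,
        stage_label=view0.stage_label,
        view_angle=None,
        accession=view0.accession,
    )


def index_table(vectors: list[IndexVector]) -> pd.DataFrame:
    """Stack index vectors into a wide table (one row per plant).

    Columns: accession, stage, S, then the 1,540 named indices.
    """
    rows = []
    for v in vectors:
        row = {"accession": v.accession, "stage": v.stage_label, "S": v.s_pixels}
        row.update(v.values.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
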