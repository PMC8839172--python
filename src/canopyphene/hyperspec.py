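"""Hyperspectral cube processing: reflectance calibration, canopy segmentation,
spectral smoothing, vegetation indices and representative-band selection.

The processing chain mirrors a proximal-sensing field workflow for a
visible/near-infrared push-broom camera (400–1000 nm, 204 bands, 512×512 px):

1. locate the white reference tile in the raw digital-number (DN) image,
2. convert DN to relative reflectance with the white/dark references,
3. segment sunlit canopy with an NDVI threshold plus near-infrared (838 nm)
   and green (554 nm) shadow thresholds,
4. smooth each pixel spectrum with a Savitzky–Golay filter (order 3, window 11),
5. compute vegetation indices over the canopy mask,
6. reduce the band axis to one representative wavelength per correlated group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from skimage.measure import label, regionprops

__all__ = [
    "SpectralCube",
    "CanopyMask",
    "select_white_tile",
    "calibrate",
    "segment_canopy",
    "smooth",
    "compute_vi",
    "select_representative_bands",
]


@dataclass
class SpectralCube:
    """A (rows, cols, bands) image with a strictly increasing wavelength axis.

    ``state`` tracks provenance: ``raw`` digital numbers, calibrated
    ``reflectance``, or ``smoothed`` reflectance.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be a (rows, cols, bands) array")
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count {self.values.shape[2]} != wavelength count "
                f"{self.wavelengths.size}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if self.state not in {"raw", "reflectance", "smoothed"}:
            raise ValueError(f"unknown cube state {self.state!r}")
        if self.state != "raw" and not np.all(np.isfinite(self.values)):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def band_index(self, wavelength: float, tol: float = 5.0) -> int:
        """Index of the band nearest ``wavelength`` (nm), within ``tol`` nm."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[i] - wavelength) > tol:
            raise ValueError(
                f"no band within {tol} nm of {wavelength} nm "
                f"(nearest: {self.wavelengths[i]:.1f} nm)"
            )
        return i

    def band(self, wavelength: float, tol: float = 5.0) -> np.ndarray:
        """Image plane of the band nearest ``wavelength``."""
        return self.values[:, :, self.band_index(wavelength, tol)]


@dataclass
class CanopyMask:
    """Boolean sunlit-canopy mask with the thresholds that produced it."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def select_white_tile(
    raw: SpectralCube,
    dn_quantile: float = 0.99,
    cv_bound: float = 0.05,
    min_pixels: int = 9,
    min_contrast: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate the white reference tile and return (mask, mean white spectrum).

    Bright pixels (mean DN above the ``dn_quantile`` quantile) are grouped into
    connected components.  Other bright objects — crumpled aluminium foil in
    particular — are rejected by a spectral-uniformity test: for each component
    the per-pixel coefficient of variation of the ratio to the component mean
    spectrum must stay below ``cv_bound`` (median over pixels).  A candidate
    must also be genuinely bright — mean DN at least ``min_contrast`` times the
    scene median — so that in a tile-less scene the brightest ordinary material
    is not mistaken for the reference.  The largest component passing both
    tests is the tile.

    Raises ``ValueError`` ("no tile found") when no component passes.
    """
    if raw.state != "raw":
        raise ValueError("white-tile selection expects a raw DN cube")
    mean_dn = raw.values.mean(axis=2)
    thresh = np.quantile(mean_dn, dn_quantile)
    scene_median = float(np.median(mean_dn))
    bright = mean_dn >= thresh
    labels = label(bright, connectivity=2)

    best_area = 0
    best_mask = None
    for region in regionprops(labels):
        if region.area < min_pixels:
            continue
        comp = labels == region.label
        if scene_median > 0 and mean_dn[comp].mean() < min_contrast * scene_median:
            continue
        spectra = raw.values[comp]  # (n_pixels, bands)
        mean_spec = spectra.mean(axis=0)
        if np.any(mean_spec <= 0):
            continue
        ratio = spectra / mean_spec
        cv = ratio.std(axis=1) / ratio.mean(axis=1)
        if np.median(cv) >= cv_bound:
            continue
        if region.area > best_area:
            best_area = region.area
            best_mask = comp
    if best_mask is None:
        raise ValueError("no tile found: no bright component passes the uniformity bound")
    white = raw.values[best_mask].mean(axis=0)
    return best_mask, white


def calibrate(raw: SpectralCube, white: np.ndarray, dark: np.ndarray) -> SpectralCube:
    """Convert DN to relative reflectance: (DN − dark) / (white − dark) per band."""
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if white.shape != raw.wavelengths.shape or dark.shape != raw.wavelengths.shape:
        raise ValueError("white/dark spectra must have one value per band")
    span = white - dark
    bad = np.flatnonzero(span <= 0)
    if bad.size:
        wl = ", ".join(f"{raw.wavelengths[i]:.1f}" for i in bad[:5])
        raise ValueError(f"white <= dark in {bad.size} band(s), e.g. at {wl} nm")
    refl = (raw.values - dark) / span
    return SpectralCube(refl, raw.wavelengths, state="reflectance")


def ndvi_map(
    refl: SpectralCube, red_nm: float = 670.0, nir_nm: float = 800.0
) -> np.ndarray:
    """Per-pixel NDVI = (R_NIR − R_red)/(R_NIR + R_red)."""
    nir = refl.band(nir_nm)
    red = refl.band(red_nm)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (nir - red) / denom, 0.0)
    return out


def segment_canopy(
    refl: SpectralCube,
    ndvi_min: float = 0.4,
    nir_shadow_min: float = 0.15,
    green_shadow_min: float = 0.04,
    nir_shadow_nm: float = 838.0,
    green_shadow_nm: float = 554.0,
) -> CanopyMask:
    """Sunlit-canopy mask: NDVI, near-infrared and green thresholds jointly.

    A pixel is kept iff NDVI > ``ndvi_min`` and reflectance at the band nearest
    838 nm > ``nir_shadow_min`` and at the band nearest 554 nm >
    ``green_shadow_min``.  The NIR/green thresholds remove shaded background
    and shaded plant parts, whose spectra are scaled-down copies of the sunlit
    material.  Thresholds are recorded in the mask provenance.
    """
    if refl.state == "raw":
        raise ValueError("segmentation expects a reflectance cube")
    if not -1.0 <= ndvi_min <= 1.0:
        raise ValueError(f"ndvi_min {ndvi_min} outside [-1, 1]")
    mask = (
        (ndvi_map(refl) > ndvi_min)
        & (refl.band(nir_shadow_nm) > nir_shadow_min)
        & (refl.band(green_shadow_nm) > green_shadow_min)
    )
    provenance = {
        "ndvi_min": ndvi_min,
        "nir_shadow_min": nir_shadow_min,
        "green_shadow_min": green_shadow_min,
        "nir_shadow_nm": nir_shadow_nm,
        "green_shadow_nm": green_shadow_nm,
    }
    return CanopyMask(mask, provenance)


def smooth(refl: SpectralCube, window: int = 11, polyorder: int = 3) -> SpectralCube:
    """Savitzky–Golay smoothing along the band axis of every pixel spectrum.

    Edges are handled by evaluating the terminal-window polynomial fits
    (``mode='interp'``), i.e. polynomial extrapolation within the first and
    last half-windows.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    values = savgol_filter(refl.values, window, polyorder, axis=2, mode="interp")
    return SpectralCube(values, refl.wavelengths, state="smoothed")


def compute_vi(
    cube: SpectralCube,
    name: str,
    catalog=None,
    mask: CanopyMask | np.ndarray | None = None,
    per_pixel: bool = False,
):
    """Compute a vegetation index over the canopy mask.

    The plot-level value is the mean of the per-pixel index over masked pixels.
    With ``per_pixel=True`` the (scalar, map) pair is returned instead.
    """
    from .vicatalog import default_catalog

    if catalog is None:
        catalog = default_catalog()
    entry = catalog[name]
    vi_map = entry.evaluate_cube(cube)
    if mask is None:
        m = np.ones(vi_map.shape, dtype=bool)
    else:
        m = mask.mask if isinstance(mask, CanopyMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask: no canopy pixels to average")
    scalar = float(vi_map[m].mean())
    if per_pixel:
        return scalar, vi_map
    return scalar


def select_representative_bands(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    r_threshold: float = 0.8,
    nir_min_nm: float = 760.0,
):
    """Greedy contiguous grouping of correlated bands; one representative each.

    Scanning bands in wavelength order, a new group starts whenever the Pearson
    correlation between the current band and the group's seed (first) band
    drops below ``r_threshold``.  The representative of a group is its central
    band.  A mean-NIR pseudo-band (average reflectance over wavelengths >=
    ``nir_min_nm``) is reported alongside.

    Parameters
    ----------
    spectra : (n_observations, n_bands) matrix of per-plot mean spectra.

    Returns
    -------
    dict with ``representatives`` (wavelengths, nm), ``groups`` (list of
    (start_idx, stop_idx) half-open index ranges), and ``nir_mean``
    (per-observation average NIR reflectance).
    """
    spectra = np.asarray(spectra, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    n_obs, n_bands = spectra.shape
    if n_obs < 3:
        raise ValueError("need at least 3 observations per band")
    if wavelengths.size != n_bands:
        raise ValueError("wavelength count does not match spectra columns")

    def corr(i: int, j: int) -> float:
        a, b = spectra[:, i], spectra[:, j]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            # constant band: treat as belonging to the current group
            import warnings

            warnings.warn(f"band {wavelengths[j]:.1f} nm has zero variance", stacklevel=3)
            return 1.0
        return float(np.corrcoef(a, b)[0, 1])

    groups: list[tuple[int, int]] = []
    seed = 0
    for j in range(1, n_bands):
        if corr(seed, j) < r_threshold:
            groups.append((seed, j))
            seed = j
    groups.append((seed, n_bands))

    representatives = [
        float(wavelengths[(start + stop - 1) // 2]) for start, stop in groups
    ]
    nir_mask = wavelengths >= nir_min_nm
    nir_mean = spectra[:, nir_mask].mean(axis=1) if nir_mask.any() else None
    return {
        "representatives": representatives,
        "groups": groups,
        "nir_mean": nir_mean,
    }
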