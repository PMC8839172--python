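"""Synthetic trials, hyperspectral scenes and thermal scenes with known truth.

Every downstream stage of the pipeline (calibration, segmentation, index
computation, emissivity correction, trial statistics, tolerance indices) is
exercised against data whose generating parameters are recorded, so recovery
can be checked exactly in noiseless limits and within Monte-Carlo error
otherwise.

The trial generator emulates a balanced split-plot field trial: 10 genotypes
× 2 irrigation treatments (FI full, RI reduced) × 6 blocks, with a
multiplicative per-genotype treatment factor on yield, additive genotype and
block effects, and Gaussian residuals.  Default means follow the study
conditions the pipeline targets (FI 3.24 t ha⁻¹, RI factor 0.756 → 2.45
t ha⁻¹).

Vegetation spectra are a parametric Gaussian-feature template — blue and red
chlorophyll absorption scaled by ``chlorophyll_level``, a green peak, a
sigmoid red edge, a near-infrared plateau and a 970 nm water depression that
deepens as ``water_level`` drops — not a radiative-transfer model: the
pipeline only needs the index-relevant features to be realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hyperspec import SpectralCube
from .thermal import ThermalScene, apparent_from_object

__all__ = [
    "TrialDesign",
    "TrialTruth",
    "SceneTruth",
    "generate_trial",
    "make_scene_truth",
    "vegetation_reflectance",
    "soil_reflectance",
    "generate_hyperspectral_scene",
    "generate_thermal_scene",
    "default_wavelengths",
]

SIEVE_CALIBERS = (1.7, 1.4, 1.18)  # mm mesh openings


def default_wavelengths(n_bands: int = 204, lo: float = 400.0, hi: float = 1000.0):
    """The instrument band grid: ``n_bands`` samples spanning 400–1000 nm."""
    return np.linspace(lo, hi, n_bands)


# --------------------------------------------------------------------------
# trial
# --------------------------------------------------------------------------

@dataclass
class TrialDesign:
    """Balanced split-plot layout: every genotype × treatment × block once."""

    n_genotypes: int = 10
    n_blocks: int = 6
    treatments: tuple[str, ...] = ("FI", "RI")
    plot_geometry: str = "4 rows x 2x4 m"

    @property
    def genotypes(self) -> list[str]:
        names = [f"CLS-{i}" for i in range(1, self.n_genotypes)]
        names.append("Regalona")
        return names

    @property
    def n_plots(self) -> int:
        return self.n_genotypes * len(self.treatments) * self.n_blocks


@dataclass
class TrialTruth:
    """Generating parameters of a synthetic trial (the ground truth)."""

    mu_FI: float = 3.24  # t/ha, control mean yield
    treatment_effect: float | np.ndarray = 0.756  # multiplicative RI factor
    genotype_effects: np.ndarray | None = None  # additive, t/ha
    block_effects: np.ndarray | None = None  # additive, t/ha
    residual_sd: float = 0.3  # t/ha
    thousand_seed_weight: np.ndarray | None = None  # g, per genotype (FI)
    tsw_ri_factor: float = 0.93  # RI shift of 1000-seed weight
    sieve_mean_fi: tuple[float, float, float] = (0.50, 0.30, 0.20)
    sieve_mean_ri: tuple[float, float, float] = (0.40, 0.34, 0.26)
    sieve_concentration: float = 300.0
    height_fi: float = 115.0  # cm
    height_ri: float = 97.0  # cm
    height_sd: float = 6.0
    seeds_per_plant_scale: float = 0.747  # g seed/plant per t/ha yield
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


def generate_trial(design: TrialDesign, truth: TrialTruth) -> pd.DataFrame:
    """One record per plot: yield, seed metrics, plant height.

    Deterministic for a fixed ``truth.rng_seed``.  Yield model:
    ``(mu_FI + genotype_effect + block_effect) × treatment_factor + ε`` with
    ``ε ~ N(0, residual_sd)``; the treatment factor is 1 for FI and the
    per-genotype (or shared) RI factor otherwise.
    """
    if truth.residual_sd < 0:
        raise ValueError("residual_sd must be non-negative")
    rng = np.random.default_rng(truth.rng_seed)
    genotypes = design.genotypes
    g_eff = np.zeros(design.n_genotypes) if truth.genotype_effects is None else np.asarray(
        truth.genotype_effects, float
    )
    b_eff = np.zeros(design.n_blocks) if truth.block_effects is None else np.asarray(
        truth.block_effects, float
    )
    if g_eff.size != design.n_genotypes or b_eff.size != design.n_blocks:
        raise ValueError("effect vectors must match design dimensions")
    ri_factor = np.broadcast_to(
        np.asarray(truth.treatment_effect, float), (design.n_genotypes,)
    )
    tsw = (
        np.linspace(2.6, 3.3, design.n_genotypes)
        if truth.thousand_seed_weight is None
        else np.asarray(truth.thousand_seed_weight, float)
    )

    records = []
    for b in range(design.n_blocks):
        for t in design.treatments:
            for g in range(design.n_genotypes):
                is_ri = t != design.treatments[0]
                factor = ri_factor[g] if is_ri else 1.0
                y = (truth.mu_FI + g_eff[g] + b_eff[b]) * factor
                if truth.residual_sd > 0:
                    y += rng.normal(0.0, truth.residual_sd)
                tsw_plot = tsw[g] * (truth.tsw_ri_factor if is_ri else 1.0)
                if truth.residual_sd > 0:
                    tsw_plot += rng.normal(0.0, 0.05 * truth.residual_sd / 0.3)
                sieve_mean = truth.sieve_mean_ri if is_ri else truth.sieve_mean_fi
                if truth.residual_sd > 0:
                    fractions = rng.dirichlet(
                        np.asarray(sieve_mean) * truth.sieve_concentration
                    )
                else:
                    fractions = np.asarray(sieve_mean, float)
                height_mu = truth.height_ri if is_ri else truth.height_fi
                height = height_mu + (
                    rng.normal(0.0, truth.height_sd) if truth.residual_sd > 0 else 0.0
                )
                records.append(
                    {
                        "plot": f"B{b+1}-{t}-{genotypes[g]}",
                        "block": f"B{b+1}",
                        "treatment": t,
                        "genotype": genotypes[g],
                        "yield": y,
                        "seed_weight_per_plant": y * truth.seeds_per_plant_scale,
                        "thousand_seed_weight": tsw_plot,
                        "sieve_1.7mm": fractions[0],
                        "sieve_1.4mm": fractions[1],
                        "sieve_1.18mm": fractions[2],
                        "plant_height": height,
                    }
                )
    return pd.DataFrame(records)


# --------------------------------------------------------------------------
# scenes
# --------------------------------------------------------------------------

@dataclass
class SceneTruth:
    """Ground truth of one synthetic scene (spectral and thermal).

    Masks are mutually exclusive and jointly cover the raster.  The optional
    foil mask carves a spectrally noisy bright target out of the soil area.
    """

    plant_mask: np.ndarray
    shadow_mask: np.ndarray
    soil_mask: np.ndarray
    tile_mask: np.ndarray
    foil_mask: np.ndarray | None = None
    chlorophyll_level: float = 0.8
    water_level: float = 0.8
    true_leaf_T: np.ndarray | None = None  # °C raster (plant pixels used)
    soil_T: float = 38.0
    T_air: float = 26.0
    rh: float = 40.0

    def __post_init__(self) -> None:
        masks = [self.plant_mask, self.shadow_mask, self.soil_mask, self.tile_mask]
        if self.foil_mask is not None:
            masks.append(self.foil_mask)
        masks = [np.asarray(m, bool) for m in masks]
        total = np.zeros(masks[0].shape, dtype=int)
        for m in masks:
            if m.shape != masks[0].shape:
                raise ValueError("scene masks must share one shape")
            total += m.astype(int)
        if not np.all(total == 1):
            raise ValueError("scene masks must be mutually exclusive and cover the raster")
        for name in ("chlorophyll_level", "water_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.plant_mask).shape


def make_scene_truth(
    shape: tuple[int, int] = (64, 64),
    chlorophyll_level: float = 0.8,
    water_level: float = 0.8,
    T_air: float = 26.0,
    leaf_dT: float = -2.0,
    with_foil: bool = False,
    rng: np.random.Generator | None = None,
) -> SceneTruth:
    """A canonical scene layout: central plant blob with a shadow fringe,
    reference tile in the top-left corner, soil elsewhere."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    cy, cx = rows / 2, cols / 2
    r_plant = min(rows, cols) * 0.28
    dist = np.hypot(yy - cy, xx - cx)
    plant = dist <= r_plant
    shadow = (dist > r_plant) & (dist <= r_plant * 1.25)
    tile = np.zeros(shape, bool)
    ts = max(3, rows // 8)
    tile[1 : 1 + ts, 1 : 1 + ts] = True
    plant &= ~tile
    shadow &= ~tile
    foil = None
    if with_foil:
        foil = np.zeros(shape, bool)
        foil[1 : 1 + ts, cols - 1 - ts : cols - 1] = True
        plant &= ~foil
        shadow &= ~foil
    soil = ~(plant | shadow | tile | (foil if foil is not None else False))
    leaf_T = np.full(shape, T_air + leaf_dT, dtype=float)
    if rng is not None:
        leaf_T += rng.normal(0.0, 0.15, size=shape)
    return SceneTruth(
        plant_mask=plant,
        shadow_mask=shadow,
        soil_mask=soil,
        tile_mask=tile,
        foil_mask=foil,
        chlorophyll_level=chlorophyll_level,
        water_level=water_level,
        true_leaf_T=leaf_T,
        T_air=T_air,
    )


def vegetation_reflectance(
    wavelengths: np.ndarray, chlorophyll_level: float = 0.8, water_level: float = 0.8
) -> np.ndarray:
    """Parametric canopy reflectance template.

    Visible: 0.10 baseline, +0.08 green peak (555 nm), blue (455 nm) and red
    (672 nm) chlorophyll absorption dips of depth 0.07 × chlorophyll_level.
    A sigmoid red edge at 715 nm joins a 0.48 NIR plateau carrying a 970 nm
    water depression of depth 0.18 × (1 − water_level).
    """
    wl = np.asarray(wavelengths, float)

    def g(center, width):
        return np.exp(-(((wl - center) / width) ** 2))

    vis = 0.10 + 0.08 * g(555, 28) - 0.07 * chlorophyll_level * (g(455, 22) + g(672, 25))
    nir = 0.48 - 0.18 * (1.0 - water_level) * g(970, 28)
    edge = 1.0 / (1.0 + np.exp(-(wl - 715.0) / 16.0))
    return vis * (1 - edge) + nir * edge


def soil_reflectance(wavelengths: np.ndarray) -> np.ndarray:
    """Bright-soil template: a gentle linear ramp, spectrally featureless."""
    wl = np.asarray(wavelengths, float)
    return 0.12 + 0.0003 * (wl - 400.0)


SHADOW_SCALE = 0.25  # shadow pixels: scaled-down copy of the underlying spectrum
TILE_REFLECTANCE = 0.95


def true_reflectance_cube(scene: SceneTruth, wavelengths: np.ndarray) -> np.ndarray:
    """The noiseless reflectance cube implied by the scene truth."""
    wl = np.asarray(wavelengths, float)
    veg = vegetation_reflectance(wl, scene.chlorophyll_level, scene.water_level)
    soil = soil_reflectance(wl)
    cube = np.empty(scene.shape + (wl.size,), dtype=float)
    cube[scene.plant_mask] = veg
    cube[scene.soil_mask] = soil
    cube[scene.shadow_mask] = SHADOW_SCALE * veg  # shaded plant parts
    cube[scene.tile_mask] = TILE_REFLECTANCE
    if scene.foil_mask is not None:
        cube[scene.foil_mask] = TILE_REFLECTANCE
    return cube


def generate_hyperspectral_scene(
    scene: SceneTruth,
    wavelengths: np.ndarray | None = None,
    noise_sd: float = 2.0,
    foil_noise_sd: float = 300.0,
    white_dn: float = 2500.0,
    dark_dn: float = 96.0,
    rng: np.random.Generator | None = None,
):
    """Raw digital-number cube plus white/dark reference spectra.

    Forward model per pixel and band: ``DN = dark + (white − dark) × R + ε``
    with ``ε ~ N(0, noise_sd)``.  The white spectrum carries a broad
    illumination curve.  Foil pixels (if present) get additional heavy
    per-band noise so they fail spectral-uniformity screening while matching
    the tile in brightness.

    Returns ``(raw_cube, white, dark, scene)``.
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength axis must be strictly increasing")
    rng = rng or np.random.default_rng(0)
    illum = 1.0 - 0.3 * ((wl - 700.0) / 300.0) ** 2
    white = dark_dn + (white_dn - dark_dn) * illum
    dark = np.full(wl.size, dark_dn)
    refl = true_reflectance_cube(scene, wl)
    dn = dark + (white - dark) * refl
    if noise_sd > 0:
        dn = dn + rng.normal(0.0, noise_sd, size=dn.shape)
    if scene.foil_mask is not None and foil_noise_sd > 0:
        n_foil = int(scene.foil_mask.sum())
        dn[scene.foil_mask] += rng.normal(0.0, foil_noise_sd, size=(n_foil, wl.size))
    return SpectralCube(dn, wl, state="raw"), white, dark, scene


def generate_thermal_scene(
    scene: SceneTruth,
    emissivity: float = 0.96,
    foil_T_reflected: float = 42.0,
    dew: bool = False,
    wet_depression: float = 4.0,
    dry_leaf_offset: float = 2.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[ThermalScene, SceneTruth]:
    """Apparent-temperature raster via the graybody forward model.

    Plant pixels radiate at ``true_leaf_T`` (or ``T_air − wet_depression``
    everywhere when ``dew`` is set), soil at ``scene.soil_T``, and the shadow
    fringe doubles as the petroleum-jelly dry-reference leaf at
    ``T_air + dry_leaf_offset``.  The reference-tile area holds the crumpled
    foil, whose apparent temperature IS the reflected temperature (it is
    imaged at emissivity 1).  ROIs: foil, dry_leaf, sunlit_soil.
    """
    if not 0 < emissivity <= 1:
        raise ValueError(f"emissivity {emissivity} outside (0, 1]")
    if scene.true_leaf_T is None:
        raise ValueError("scene truth lacks a true_leaf_T raster")
    rng = rng or np.random.default_rng(0)
    shape = scene.shape
    leaf_T = (
        np.full(shape, scene.T_air - wet_depression)
        if dew
        else np.asarray(scene.true_leaf_T, float)
    )
    t_obj = np.empty(shape, dtype=float)
    t_obj[scene.plant_mask] = leaf_T[scene.plant_mask]
    t_obj[scene.soil_mask] = scene.soil_T
    t_obj[scene.shadow_mask] = scene.T_air + dry_leaf_offset
    t_obj[scene.tile_mask] = foil_T_reflected  # placeholder, overwritten below
    if scene.foil_mask is not None:
        t_obj[scene.foil_mask] = foil_T_reflected

    apparent = apparent_from_object(t_obj, foil_T_reflected, emissivity)
    apparent[scene.tile_mask] = foil_T_reflected
    if scene.foil_mask is not None:
        apparent[scene.foil_mask] = foil_T_reflected
    if noise_sd > 0:
        apparent = apparent + rng.normal(0.0, noise_sd, size=shape)

    foil_roi = scene.tile_mask if scene.foil_mask is None else scene.foil_mask
    thermal = ThermalScene(
        T_apparent=apparent,
        rois={
            "foil": foil_roi,
            "dry_leaf": scene.shadow_mask,
            "sunlit_soil": scene.soil_mask,
        },
        T_air=scene.T_air,
        rh=scene.rh,
    )
    return thermal, scene
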