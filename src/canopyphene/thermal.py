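"""Canopy thermal imaging: reflected-temperature reference, emissivity
correction and the wet-reference thermal index TI1.

Apparent temperatures come from a longwave camera with emissivity set to 1,
so the raster mixes emitted and reflected radiation.  A crumpled aluminium
foil target (near-zero emissivity, fully reflective) provides the reflected
temperature; leaf temperature is then recovered with a graybody
Stefan–Boltzmann balance at leaf emissivity 0.96.  Reference regions (foil,
petroleum-jelly dry leaf, sunlit soil) are excluded before averaging.

TI1 = dT_wet_mean − dT, where dT = mean leaf temperature − air temperature
and dT_wet_mean is the same difference for dew-wet leaves imaged in the late
morning.  TI1 near zero means leaves as cool as the wet reference (high
transpiration); more negative values mean warmer leaves (stomatal closure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThermalScene",
    "ThermalSummary",
    "reflected_temperature",
    "correct_emissivity",
    "leaf_mean",
    "thermal_index_1",
]

_ZERO_C = 273.15


@dataclass
class ThermalScene:
    """Apparent-temperature raster (°C) with reference ROIs and ambient data."""

    T_apparent: np.ndarray
    rois: dict = field(default_factory=dict)  # name -> boolean mask
    T_air: float = 25.0
    rh: float = 40.0
    timestamp: str | None = None
    plot: str | None = None
    genotype: str | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        self.T_apparent = np.asarray(self.T_apparent, dtype=float)
        if not np.isfinite(self.T_air):
            raise ValueError("T_air must be finite")
        for name, mask in self.rois.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.T_apparent.shape:
                raise ValueError(f"ROI {name!r} shape {mask.shape} != raster shape")
            self.rois[name] = mask


@dataclass
class ThermalSummary:
    """Per-plot thermal quantities; TI1 = dT_wet_mean − dT by construction."""

    T_reflected: float
    T_leaf_mean: float
    dT: float
    dT_wet_mean: float
    TI1: float

    def __post_init__(self) -> None:
        vals = [self.T_reflected, self.T_leaf_mean, self.dT, self.dT_wet_mean, self.TI1]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("thermal summary contains non-finite values")


def reflected_temperature(scene: ThermalScene, roi: str = "foil") -> float:
    """Mean apparent temperature over the foil ROI (the reflected temperature)."""
    mask = scene.rois.get(roi)
    if mask is None or not mask.any():
        raise ValueError(f"empty or missing {roi!r} ROI")
    return float(scene.T_apparent[mask].mean())


def apparent_from_object(
    T_obj, T_reflected: float, emissivity: float = 0.96
):
    """Forward graybody model: the apparent (emissivity-1) temperature of an
    object at ``T_obj`` °C with reflected temperature ``T_reflected`` °C.

    T_app⁴ = ε·T_obj⁴ + (1 − ε)·T_refl⁴ in kelvin (fourth-power radiance
    balance, atmospheric transmission ignored).
    """
    if not 0 < emissivity <= 1:
        raise ValueError(f"emissivity {emissivity} outside (0, 1]")
    t_obj = np.asarray(T_obj, dtype=float) + _ZERO_C
    t_ref = T_reflected + _ZERO_C
    rad = emissivity * t_obj**4 + (1 - emissivity) * t_ref**4
    return rad**0.25 - _ZERO_C


def correct_emissivity(
    T_apparent, T_reflected: float, emissivity: float = 0.96
):
    """Invert the graybody model to recover object temperature in °C.

    T_obj = [(T_app⁴ − (1 − ε)·T_refl⁴)/ε]^(1/4), all in kelvin.
    """
    if not 0 < emissivity <= 1:
        raise ValueError(f"emissivity {emissivity} outside (0, 1]")
    t_app = np.asarray(T_apparent, dtype=float) + _ZERO_C
    if np.any(t_app <= 0):
        raise ValueError("apparent temperature below 0 K")
    if emissivity == 1.0:  # exact identity, no radiance round trip
        out = np.asarray(T_apparent, dtype=float)
        return float(out) if np.isscalar(T_apparent) else out
    t_ref = T_reflected + _ZERO_C
    radicand = (t_app**4 - (1 - emissivity) * t_ref**4) / emissivity
    if np.any(radicand <= 0):
        raise ValueError("non-physical input: radicand <= 0 in emissivity correction")
    out = radicand**0.25 - _ZERO_C
    if np.isscalar(T_apparent):
        return float(out)
    return out


def leaf_mean(
    corrected: np.ndarray,
    rois: dict | None = None,
    exclude: tuple[str, ...] = ("foil", "dry_leaf", "sunlit_soil"),
) -> float:
    """Mean leaf temperature: average outside the excluded reference ROIs."""
    corrected = np.asarray(corrected, dtype=float)
    keep = np.ones(corrected.shape, dtype=bool)
    for name in exclude:
        mask = (rois or {}).get(name)
        if mask is not None:
            keep &= ~np.asarray(mask, dtype=bool)
    if not keep.any():
        raise ValueError("no pixels left after ROI exclusion")
    return float(corrected[keep].mean())


def thermal_index_1(dT: float, dT_wet_mean: float) -> float:
    """TI1 = dT_wet_mean − dT (both in K, leaf minus air)."""
    if not (np.isfinite(dT) and np.isfinite(dT_wet_mean)):
        raise ValueError("dT and dT_wet_mean must be finite")
    return float(dT_wet_mean - dT)


def summarize_scene(
    scene: ThermalScene,
    dT_wet_mean: float,
    emissivity: float = 0.96,
) -> ThermalSummary:
    """Full per-scene chain: reflected T → emissivity correction → leaf mean →
    dT → TI1 against the supplied per-plot wet reference."""
    t_refl = reflected_temperature(scene)
    corrected = correct_emissivity(scene.T_apparent, t_refl, emissivity)
    t_leaf = leaf_mean(corrected, scene.rois)
    dT = t_leaf - scene.T_air
    return ThermalSummary(
        T_reflected=t_refl,
        T_leaf_mean=t_leaf,
        dT=dT,
        dT_wet_mean=dT_wet_mean,
        TI1=thermal_index_1(dT, dT_wet_mean),
    )


def wet_reference_dT(
    scene: ThermalScene, emissivity: float = 0.96
) -> float:
    """dT of a dew-wet scene: mean wet-leaf temperature minus air temperature."""
    t_refl = reflected_temperature(scene)
    corrected = correct_emissivity(scene.T_apparent, t_refl, emissivity)
    return leaf_mean(corrected, scene.rois) - scene.T_air
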