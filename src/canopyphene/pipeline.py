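"""End-to-end orchestration: generate → process → summarise → report.

A run takes a single serialisable :class:`RunConfig`, generates a synthetic
trial plus hyperspectral and thermal scenes, pushes them through calibration,
segmentation, index computation and the thermal chain, computes tolerance
indices and the trial statistics, and writes every stage's output as plain
files under the run directory together with a JSON manifest (seed,
thresholds, software versions).  Re-running from a saved config is
bit-identical for deterministic stages.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import fieldstats, hyperspec, synthgen, thermal, tolerance
from .vicatalog import default_catalog

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    # trial
    n_genotypes: int = 10
    n_blocks: int = 6
    mu_FI: float = 3.24
    ri_factor: float = 0.756
    residual_sd: float = 0.3
    reference_genotype: str = "Regalona"
    # scenes
    scene_shape: tuple[int, int] = (64, 64)
    n_bands: int = 204
    scene_noise_sd: float = 2.0
    thermal_noise_sd: float = 0.05
    emissivity: float = 0.96
    foil_T_reflected: float = 42.0
    wet_depression: float = 4.0
    # processing thresholds
    ndvi_min: float = 0.4
    nir_shadow_min: float = 0.15
    green_shadow_min: float = 0.04
    sg_window: int = 11
    sg_polyorder: int = 3
    band_r_threshold: float = 0.8
    # statistics
    cluster_k: int = 5
    contrast_threshold: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.scene_shape, list):
            cfg.scene_shape = tuple(cfg.scene_shape)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["scene_shape"] = list(self.scene_shape)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _scene_for_plot(cfg: RunConfig, rng: np.random.Generator, water_level: float):
    return synthgen.make_scene_truth(
        shape=tuple(cfg.scene_shape),
        water_level=water_level,
        chlorophyll_level=0.8,
        leaf_dT=-2.0 if water_level > 0.5 else 0.5,
        rng=rng,
    )


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stage failures abort with the stage name prefixed to the error message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {**asdict(config), "scene_shape": list(config.scene_shape)},
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)

    try:
        stage("simulate-trial")
        design = synthgen.TrialDesign(
            n_genotypes=config.n_genotypes, n_blocks=config.n_blocks
        )
        truth = synthgen.TrialTruth(
            mu_FI=config.mu_FI,
            treatment_effect=config.ri_factor,
            residual_sd=config.residual_sd,
            rng_seed=int(rng.integers(2**31)),
        )
        plots = synthgen.generate_trial(design, truth)
        plots.to_csv(out / "trait_table.csv", index=False)
    except Exception as e:  # pragma: no cover - error path
        raise RuntimeError(f"stage simulate-trial failed: {e}") from e

    try:
        stage("hyperspec")
        catalog = default_catalog()
        wl = synthgen.default_wavelengths(config.n_bands)
        vi_rows = []
        # one scene per genotype x treatment (block 1 imaging set)
        for g in design.genotypes:
            for t in design.treatments:
                water = 0.85 if t == "FI" else 0.45
                scene = _scene_for_plot(config, rng, water)
                raw, white, dark, _ = synthgen.generate_hyperspectral_scene(
                    scene, wl, noise_sd=config.scene_noise_sd, rng=rng
                )
                refl = hyperspec.calibrate(raw, white, dark)
                mask = hyperspec.segment_canopy(
                    refl,
                    ndvi_min=config.ndvi_min,
                    nir_shadow_min=config.nir_shadow_min,
                    green_shadow_min=config.green_shadow_min,
                )
                smoothed = hyperspec.smooth(
                    refl, window=config.sg_window, polyorder=config.sg_polyorder
                )
                for name in catalog.names:
                    value = hyperspec.compute_vi(smoothed, name, catalog, mask)
                    vi_rows.append(
                        {
                            "plot": f"B1-{t}-{g}",
                            "genotype": g,
                            "treatment": t,
                            "repetition": 1,
                            "vi_name": name,
                            "value": value,
                            "n_pixels": mask.n_pixels,
                        }
                    )
        vi_table = pd.DataFrame(vi_rows)
        vi_table.to_csv(out / "vi_table.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"stage hyperspec failed: {e}") from e

    try:
        stage("thermal")
        rows = []
        for g in design.genotypes:
            for t in design.treatments:
                leaf_dT = -1.0 if t == "FI" else 1.5
                scene = synthgen.make_scene_truth(
                    shape=tuple(config.scene_shape), leaf_dT=leaf_dT, rng=rng
                )
                wet_scene, _ = synthgen.generate_thermal_scene(
                    scene,
                    emissivity=config.emissivity,
                    foil_T_reflected=config.foil_T_reflected,
                    dew=True,
                    wet_depression=config.wet_depression,
                    noise_sd=config.thermal_noise_sd,
                    rng=rng,
                )
                dT_wet = thermal.wet_reference_dT(wet_scene, config.emissivity)
                day_scene, _ = synthgen.generate_thermal_scene(
                    scene,
                    emissivity=config.emissivity,
                    foil_T_reflected=config.foil_T_reflected,
                    noise_sd=config.thermal_noise_sd,
                    rng=rng,
                )
                summary = thermal.summarize_scene(day_scene, dT_wet, config.emissivity)
                rows.append(
                    {
                        "plot": f"B1-{t}-{g}",
                        "genotype": g,
                        "treatment": t,
                        "T_reflected": summary.T_reflected,
                        "T_leaf_mean": summary.T_leaf_mean,
                        "dT": summary.dT,
                        "dT_wet_mean": summary.dT_wet_mean,
                        "TI1": summary.TI1,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "thermal_summary.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"stage thermal failed: {e}") from e

    try:
        stage("tolerance")
        tol = tolerance.tolerance_table(plots, reference=config.reference_genotype)
        tol_out = tol.reset_index()
        tol_out.to_csv(out / "tolerance_table.csv", index=False)
        manifest["DII"] = tol.attrs["DII"]
        manifest["yield_loss_pct"] = tol.attrs["yield_loss_pct"]
    except Exception as e:
        raise RuntimeError(f"stage tolerance failed: {e}") from e

    try:
        stage("stats")
        anova = fieldstats.factorial_anova(
            plots, "yield", ["treatment", "genotype"], block="block"
        )
        ges = fieldstats.generalized_eta_squared(anova)
        report = anova.table.copy()
        report["ges"] = ges
        report.to_csv(out / "anova_yield.csv")

        d_table = fieldstats.pairwise_effect_sizes(
            plots, "yield", group="genotype", within="treatment", anova=anova
        )
        d_table.to_csv(out / "pairwise_effect_sizes.csv", index=False)

        trait_cols = ["yield", "seed_weight_per_plant", "thousand_seed_weight",
                      "plant_height"]
        corr = fieldstats.correlate_traits(plots[trait_cols])
        corr.to_csv(out / "correlations.csv", index=False)

        means = plots.groupby(["genotype", "treatment"], observed=True)[
            trait_cols
        ].mean()
        scores, loadings, var_frac = fieldstats.pca_traits(means)
        scores.to_csv(out / "pca_scores.csv")
        loadings.to_csv(out / "pca_loadings.csv")

        vi_means = vi_table.pivot_table(
            index=["genotype", "treatment"], columns="vi_name", values="value"
        )
        scaled = (vi_means - vi_means.mean()) / vi_means.std(ddof=0)
        labels, _ = fieldstats.cluster_genotypes(scaled, k=config.cluster_k)
        labels.to_frame().to_csv(out / "clusters.csv")
    except Exception as e:
        raise RuntimeError(f"stage stats failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return out
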