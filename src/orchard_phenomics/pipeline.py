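"""End-to-end orchestration: synthetic inputs -> crown geometry + airborne
indices + I_PL -> phenotype table -> mixed models / BLUPs / heritability ->
multivariate clustering.

A single :class:`RunConfig` drives the run; every output lands in one results
directory together with a ``manifest.json`` recording the config hash, the
seed and the conventions in force (alpha-shape convention, K_O/K_C constants),
so a run can be reproduced bit-for-bit.  Stages execute in dependency order; a
failing stage halts the pipeline with the stage named, keeping the outputs of
earlier stages on disk.

In the synthetic campaign, genotype structure is planted at three levels —
crown size (log-scale factor), stress susceptibility (shifts the planted
stress level, hence canopy temperature and WDI), and photosynthetic level
(shifts P_KO/KC, hence I_PL) — so that heritable contrasts propagate through
every measurement stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, imagery, multivariate, quantgen
from .ipl import DEFAULT_CONSTANTS, calibrate_ipl, ko_kc_ratio, predict_ipl
from .synthdata import (
    CrownSpec,
    IplTruth,
    OrchardDesign,
    generate_crown,
    generate_gas_exchange,
    generate_orchard_images,
    stage_rng,
)

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline", "demo_config"]

PIPELINE_TRAITS = ["c_volume", "a_volume", "STAR", "I_PL", "WDI", "NDVI", "MCARI2", "dT"]
CLUSTER_TRAITS = ["c_volume", "a_volume", "STAR", "I_PL", "WDI", "NDVI", "MCARI2"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic campaign by default)."""

    seed: int = 0
    out_dir: str = "results"
    # genetic design
    n_genotypes: int = 12
    n_replicates: int = 4  # trees per genotype, split between WW and WD rows
    sigma_g_size: float = 0.20  # genotype SD of the log crown-size factor
    sigma_g_stress: float = 0.08  # genotype SD of the planted stress level
    sigma_g_ipl: float = 8.0  # genotype SD of P_KO/KC (umol m-2 s-1) at HT
    # crowns
    n_leaves: int = 350
    leaf_radius: float = 0.05
    crown_semi_axes: tuple = (0.9, 0.9, 1.1)
    points_per_leaf: int = 5
    # geometry
    alpha: float = 0.30  # m; matched to the synthetic cloud density
    star_directions: int = 6
    # imagery
    pixel_size: float = 0.10
    buffer_radius: float = imagery.DEFAULT_BUFFER_RADIUS
    ndvi_threshold: float = imagery.DEFAULT_NDVI_THRESHOLD
    trapezoid: str = "auto"  # "auto" or "t_sat_soil,t_ww_veg,t_dry_soil,t_ws_veg"
    # I_PL
    ipl_split: float = 2.0 / 3.0
    # clustering
    k_groups: int = 3
    # user-supplied rasters (synthetic when None)
    bands_dir: str | None = None
    thermal_path: str | None = None
    trees_path: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.crown_semi_axes, list):
            cfg.crown_semi_axes = tuple(cfg.crown_semi_axes)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["crown_semi_axes"] = list(self.crown_semi_axes)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def demo_config(out_dir: str = "results", seed: int = 0) -> RunConfig:
    """The bundled synthetic end-to-end demonstration campaign."""
    return RunConfig(seed=seed, out_dir=out_dir)


@dataclass
class PipelineResult:
    """Tables and paths produced by one run."""

    out_dir: Path
    tree_metrics: pd.DataFrame
    trait_models: pd.DataFrame
    blups: pd.DataFrame
    clusters: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _genetic_layout(config: RunConfig) -> pd.DataFrame:
    """Tree-level design: genotypes in columns, replicate rows alternating
    WW/WD, with the three planted genotype effects."""
    rng = stage_rng(config.seed, "design")
    g_size = rng.normal(0.0, config.sigma_g_size, size=config.n_genotypes)
    g_stress = rng.normal(0.0, config.sigma_g_stress, size=config.n_genotypes)
    g_ipl = rng.normal(0.0, config.sigma_g_ipl, size=config.n_genotypes)
    rows = []
    for row in range(config.n_replicates):
        scenario = "WW" if row % 2 == 0 else "WD"
        base_stress = 0.15 if scenario == "WW" else 0.75
        for col in range(config.n_genotypes):
            stress = float(
                np.clip(base_stress + g_stress[col] + rng.normal(0.0, 0.03), 0.0, 1.0)
            )
            rows.append(
                {
                    "tree_id": f"T{row:02d}{col:02d}",
                    "genotype": f"G{col:03d}",
                    "scenario": scenario,
                    "replicate": row,
                    "g_size": g_size[col],
                    "g_ipl": g_ipl[col],
                    "stress": stress,
                }
            )
    return pd.DataFrame(rows)


def _stage_geometry(config: RunConfig, design: pd.DataFrame) -> pd.DataFrame:
    rng = stage_rng(config.seed, "crowns")
    dirs = geometry.upper_hemisphere_directions(config.star_directions)
    out = []
    for rec in design.itertuples():
        scale = float(np.exp(rec.g_size + rng.normal(0.0, 0.05)))
        spec = CrownSpec(
            n_leaves=config.n_leaves,
            leaf_radius=config.leaf_radius,
            semi_axes=tuple(a * scale for a in config.crown_semi_axes),
            points_per_leaf=config.points_per_leaf,
            seed=int(rng.integers(2**31)),
        )
        cloud, truth = generate_crown(spec)
        hull = geometry.hull_descriptors(cloud, alpha=config.alpha)
        star = geometry.compute_star(
            truth["leaf_centers"],
            directions=dirs,
            leaf_radius=config.leaf_radius,
            grid_resolution=config.leaf_radius / 5.0,
            total_leaf_area=truth["TLA"],
        )
        out.append(
            {
                "tree_id": rec.tree_id,
                "TLA": truth["TLA"],
                "c_volume": hull.c_volume,
                "a_volume": hull.a_volume,
                "c_i": hull.c_i,
                "STAR": star.star,
            }
        )
    return pd.DataFrame(out)


def _stage_imagery(config: RunConfig, design: pd.DataFrame) -> pd.DataFrame:
    if config.bands_dir is not None or config.thermal_path is not None:
        from .io import read_band_stack, read_raster, read_tree_centers

        if config.thermal_path is None or not Path(config.thermal_path).exists():
            raise FileNotFoundError(
                f"thermal raster not found: {config.thermal_path!r}"
            )
        stack = read_band_stack(config.bands_dir)
        thermal, _ = read_raster(config.thermal_path)
        centers = read_tree_centers(config.trees_path)
        t_air = 27.5
        truth = centers
    else:
        orchard = OrchardDesign(
            n_rows=config.n_replicates,
            trees_per_row=config.n_genotypes,
            pixel_size=config.pixel_size,
            seed=config.seed,
        )
        stress = (
            design.pivot(index="replicate", columns="genotype", values="stress")
            .sort_index()
            .to_numpy()
        )
        stack, thermal, truth = generate_orchard_images(orchard, tree_stress=stress)
        t_air = orchard.air_temperature

    mask = imagery.classify_vegetation(stack, config.ndvi_threshold)
    if config.trapezoid == "auto":
        idx = imagery.compute_indices(stack)
        trap = imagery.fit_trapezoid(idx["NDVI"].ravel(), (thermal - t_air).ravel())
    else:
        vertices = tuple(float(v) for v in config.trapezoid.split(","))
        trap = imagery.fit_trapezoid([], [], manual_vertices=vertices)

    rows = []
    for rec in truth.itertuples():
        pixels = imagery.extract_buffer(
            stack,
            thermal,
            (rec.x, rec.y),
            radius=config.buffer_radius,
            vegetation_mask=mask,
            tree_id=rec.tree_id,
        )
        s = imagery.summarize_tree(pixels, t_air, trap)
        rows.append(
            {
                "tree_id": s.tree_id,
                "NDVI": s.ndvi,
                "GNDVI": s.gndvi,
                "MCARI2": s.mcari2,
                "PRI": s.pri,
                "dT": s.dt_mean,
                "dT_sd": s.dt_sd,
                "pix_num": s.pix_num,
                "WDI": s.wdi,
            }
        )
    return pd.DataFrame(rows)


def _stage_ipl(config: RunConfig, design: pd.DataFrame):
    """Calibrate I_PL on a simulated IRGA campaign, then predict it at high
    throughput from per-tree fluorescence records."""
    truth = IplTruth()
    cal_records = generate_gas_exchange(truth, seed=config.seed)
    models = calibrate_ipl(
        cal_records, split_fraction=config.ipl_split, seed=config.seed % (2**31)
    )
    rng = stage_rng(config.seed, "ht_ipl")
    devices = sorted(models)
    const = DEFAULT_CONSTANTS
    rows = []
    for i, rec in enumerate(design.itertuples()):
        device = devices[i % len(devices)]
        p = float(np.clip(75.0 + rec.g_ipl - 35.0 * rec.stress + rng.normal(0, 4.0), 5.0, 400.0))
        dt = -1.0 + 5.0 * rec.stress + rng.normal(0.0, 0.5)
        t_air = rng.uniform(25.0, 30.0)
        t_leaf = t_air + dt
        j = p / ko_kc_ratio(t_leaf, const)
        phi = j / (truth.ppfd * const.absorptance * const.f_psii)
        fm = 1500.0
        rows.append(
            {
                "tree_id": rec.tree_id,
                "device": device,
                "Fs": fm * (1.0 - phi),
                "Fm_prime": fm,
                "PPFD": truth.ppfd,
                "T_leaf": t_leaf,
                "T_air": t_air,
            }
        )
    ht = pd.DataFrame(rows)
    parts = []
    for device in devices:
        sub = ht[ht["device"] == device].copy()
        sub["I_PL"] = predict_ipl(models[device], sub)
        parts.append(sub[["tree_id", "I_PL"]])
    return pd.concat(parts).sort_index(), models


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis under ``config``; return tables and paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "alpha_convention": geometry.ALPHA_CONVENTION,
        "stages": [],
        "counts": {},
    }

    stage = "design"
    try:
        design = _genetic_layout(config)
        manifest["stages"].append(stage)
        manifest["counts"]["trees"] = len(design)

        stage = "geometry"
        tree_geom = _stage_geometry(config, design)
        manifest["stages"].append(stage)

        stage = "imagery"
        tree_img = _stage_imagery(config, design)
        manifest["stages"].append(stage)
        manifest["counts"]["vegetation_pixels"] = int(tree_img["pix_num"].sum())

        stage = "ipl"
        tree_ipl, ipl_models = _stage_ipl(config, design)
        for device, model in ipl_models.items():
            model.to_json(out / f"ipl_model_{device.replace(' ', '_')}.json")
        manifest["stages"].append(stage)

        stage = "assemble"
        metrics = (
            design.drop(columns=["g_size", "g_ipl"])
            .merge(tree_geom, on="tree_id")
            .merge(tree_img, on="tree_id")
            .merge(tree_ipl, on="tree_id")
        )
        _write_csv(metrics, out / "tree_metrics.csv")
        manifest["stages"].append(stage)

        stage = "quantgen"
        model_rows, blup_cols = [], {}
        for trait in PIPELINE_TRAITS:
            fit = quantgen.fit_mixed(
                metrics.rename(columns={trait: "value"}), fixed="scenario", trait=trait
            )
            model_rows.append(
                {
                    "trait": trait,
                    "sigma_g2": fit.sigma_g2,
                    "sigma_r2": fit.sigma_r2,
                    "n_replicates": fit.n_replicates,
                    "h2": fit.h2,
                    "bic": fit.bic,
                    "converged": fit.converged,
                    "boundary": fit.boundary,
                }
            )
            blup_cols[trait] = fit.blups
        trait_models = pd.DataFrame(model_rows)
        blups = pd.DataFrame(blup_cols)
        blups.index.name = "genotype"
        _write_csv(trait_models, out / "trait_models.csv")
        _write_csv(blups.reset_index(), out / "blups.csv")
        manifest["stages"].append(stage)

        stage = "multivariate"
        pca_res = multivariate.pca(blups[CLUSTER_TRAITS])
        pca_table = pd.DataFrame(
            {
                "axis": [f"PC{i + 1}" for i in range(pca_res.n_axes)],
                "pct_variance": pca_res.pct_variance,
            }
        )
        clustering = multivariate.hac_ward(blups[CLUSTER_TRAITS], k=config.k_groups)
        clusters = clustering.labels.rename("group").reset_index()
        summary = multivariate.group_summary(clustering, blups[CLUSTER_TRAITS])
        _write_csv(pca_table, out / "pca_variance.csv")
        _write_csv(clusters, out / "clusters.csv")
        _write_csv(summary, out / "group_summary.csv")
        manifest["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as exc:
        _dump_manifest(manifest, out, failed_stage=stage, error=str(exc))
        raise PipelineError(stage, str(exc)) from exc

    _dump_manifest(manifest, out)
    return PipelineResult(
        out_dir=out,
        tree_metrics=metrics,
        trait_models=trait_models,
        blups=blups,
        clusters=clusters,
        manifest=manifest,
    )


def _dump_manifest(manifest: dict, out: Path, failed_stage: str | None = None,
                   error: str | None = None) -> None:
    if failed_stage is not None:
        manifest = dict(manifest, failed_stage=failed_stage, error=error)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
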