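"""Synthetic orchard inputs with known ground truth.

Four generators emulate the four input families of the phenotyping pipeline so
that every downstream stage can be tested against a known truth without any
field data:

* :func:`generate_crown` — a tree crown point cloud built from planar leaf
  disks inside a parametric envelope; truth carries the total leaf area
  (TLA = n_leaves * pi * leaf_radius^2) and the envelope volume.
* :func:`generate_orchard_images` — multiband reflectance + thermal rasters of
  a gridded orchard (rows alternately well-watered / water-deficit, the usual
  trial layout) with a per-tree truth table (centre, true canopy temperature,
  planted stress level, vegetation pixel count).
* :func:`generate_gas_exchange` — leaf fluorescence / gas-exchange records
  whose A_n follows a planted per-device linear model in P_KO/KC and
  (T_leaf - T_air); fluorescence raw values are back-computed to be exactly
  consistent with the planted predictors.
* :func:`generate_phenotypes` — long-format trait tables from the standard
  random-genotype mixed model, with the true heritability recorded.

All generators are bit-reproducible under a fixed seed; a single global seed
fans out to per-stage substreams (:func:`stage_rng`).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import PointCloud
from .imagery import BandStack, RasterTransform
from .ipl import DEFAULT_CONSTANTS, IplConstants, ko_kc_ratio

__all__ = [
    "CrownSpec",
    "OrchardDesign",
    "IplTruth",
    "GeneticDesign",
    "EmptyCrownError",
    "ResolutionError",
    "stage_rng",
    "generate_crown",
    "generate_orchard_images",
    "generate_gas_exchange",
    "generate_phenotypes",
]

#: Default spectral signatures (reflectance in [0,1] per band nm).
VEGETATION_REFLECTANCE = {450: 0.05, 530: 0.08, 570: 0.10, 675: 0.05, 730: 0.30, 850: 0.50}
SOIL_REFLECTANCE = {450: 0.10, 530: 0.13, 570: 0.15, 675: 0.15, 730: 0.17, 850: 0.18}


class EmptyCrownError(ValueError):
    """A crown with no leaves cannot support 3D geometry (needs >= 4 points)."""


class ResolutionError(ValueError):
    """Raster resolution too coarse for the requested canopy footprints."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage substream of a single global seed (stage-level reproducibility)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


# ---------------------------------------------------------------------------
# Crowns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrownSpec:
    """Parametric crown: ``n_leaves`` planar disks of radius ``leaf_radius``
    (m) inside an ellipsoidal envelope with semi-axes ``semi_axes`` (m).

    ``clumping`` in [0, 1] concentrates leaves around a few cluster centres
    (0 = uniform foliage, 1 = fully clumped); ``lobes`` > 0 replaces the single
    ellipsoid by that many half-size displaced sub-ellipsoids, giving the union
    a concave outline.  ``points_per_leaf`` points are sampled on each disk.
    """

    n_leaves: int = 500
    leaf_radius: float = 0.05
    semi_axes: tuple = (1.0, 1.0, 1.2)
    clumping: float = 0.0
    lobes: int = 0
    points_per_leaf: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_leaves < 0:
            raise ValueError("n_leaves must be >= 0")
        if self.leaf_radius <= 0:
            raise ValueError("leaf_radius must be > 0")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("ellipsoid semi-axes must be > 0")
        if not 0 <= self.clumping <= 1:
            raise ValueError("clumping must lie in [0, 1]")
        if self.points_per_leaf < 1:
            raise ValueError("points_per_leaf must be >= 1")


def _uniform_in_ellipsoid(rng: np.random.Generator, n: int, semi_axes) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * r * np.asarray(semi_axes)


def generate_crown(spec: CrownSpec):
    """Sample a crown point cloud; return ``(PointCloud, truth)``.

    ``truth`` holds ``TLA`` (m^2, = n_leaves * pi * leaf_radius^2) and
    ``envelope_volume`` (m^3; 4/3 pi abc for the plain ellipsoid, NaN for lobed
    envelopes whose union volume has no simple closed form).
    """
    if spec.n_leaves == 0:
        raise EmptyCrownError("crown has no leaves; geometry needs >= 4 non-coplanar points")
    rng = np.random.default_rng(spec.seed)
    a, b, c = spec.semi_axes

    if spec.lobes > 0:
        lobe_axes = (a / 2, b / 2, c / 2)
        ang = 2 * np.pi * np.arange(spec.lobes) / spec.lobes
        lobe_centers = np.column_stack(
            [a / 2 * np.cos(ang), b / 2 * np.sin(ang), np.zeros(spec.lobes)]
        )
        which = rng.integers(spec.lobes, size=spec.n_leaves)
        centers = lobe_centers[which] + _uniform_in_ellipsoid(rng, spec.n_leaves, lobe_axes)
    else:
        centers = _uniform_in_ellipsoid(rng, spec.n_leaves, spec.semi_axes)

    if spec.clumping > 0:
        n_clusters = max(2, int(round(spec.n_leaves * 0.02)))
        hubs = centers[rng.integers(len(centers), size=n_clusters)]
        assign = rng.integers(n_clusters, size=spec.n_leaves)
        centers = hubs[assign] + (1.0 - spec.clumping) * (centers - hubs[assign])

    normals = rng.normal(size=(spec.n_leaves, 3))
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    if spec.points_per_leaf == 1:
        points = centers
    else:
        k = spec.points_per_leaf
        # orthonormal in-plane basis per leaf
        helper = np.where(np.abs(normals[:, :1]) < 0.9, [1.0, 0, 0], [0, 1.0, 0])
        u = np.cross(normals, helper)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(normals, u)
        theta = rng.uniform(0, 2 * np.pi, size=(spec.n_leaves, k))
        rad = spec.leaf_radius * np.sqrt(rng.uniform(size=(spec.n_leaves, k)))
        points = (
            centers[:, None, :]
            + rad[..., None] * np.cos(theta)[..., None] * u[:, None, :]
            + rad[..., None] * np.sin(theta)[..., None] * v[:, None, :]
        ).reshape(-1, 3)

    tla = spec.n_leaves * np.pi * spec.leaf_radius**2
    envelope = 4.0 / 3.0 * np.pi * a * b * c if spec.lobes == 0 else float("nan")
    cloud = PointCloud(points=points, tree_id="synthetic")
    return cloud, {
        "TLA": float(tla),
        "envelope_volume": float(envelope),
        "leaf_centers": centers,
    }


# ---------------------------------------------------------------------------
# Orchard rasters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrchardDesign:
    """Layout and radiometry of the synthetic orchard.

    Rows alternate well-watered (WW) and water-deficit (WD); each tree gets a
    planted stress level in [0, 1] (WW low, WD high) that drives its true
    canopy temperature linearly between ``t_veg_offsets`` (offsets from air
    temperature, deg C).  Default spacing follows the 5 x 2 m orchard planting.
    """

    n_rows: int = 4
    trees_per_row: int = 6
    spacing: tuple = (5.0, 2.0)  # (between rows, within row), m
    margin: float = 0.0  # bare-soil border around the grid, m
    pixel_size: float = 0.10  # m
    canopy_radius: float = 0.60  # m
    air_temperature: float = 27.5  # deg C
    t_veg_offsets: tuple = (-2.0, 6.0)  # dT at stress 0 and 1, deg C
    stress_ranges: dict = field(
        default_factory=lambda: {"WW": (0.0, 0.30), "WD": (0.55, 1.0)}
    )
    soil_t_offsets: tuple = (2.0, 22.0)  # soil dT range, deg C
    band_noise_sd: float = 0.01  # reflectance units
    thermal_noise_sd: float = 0.5  # deg C
    seed: int = 0

    def __post_init__(self):
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("spacing must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


def generate_orchard_images(design: OrchardDesign, tree_stress=None):
    """Render the orchard; return ``(BandStack, thermal array degC, truth table)``.

    Vegetation pixels (centres inside a tree's circular footprint) draw from
    the vegetation spectral signature and the tree's true canopy temperature;
    all other pixels draw from soil.  The truth table records, per tree, the
    centre, scenario, planted stress, true canopy temperature and the exact
    vegetation pixel count.

    ``tree_stress`` optionally plants the stress levels directly, as an
    (n_rows, trees_per_row) array in [0, 1], overriding the per-scenario
    random draws (used when stress must carry a genotype structure).
    """
    if design.pixel_size >= design.canopy_radius:
        raise ResolutionError(
            f"pixel_size ({design.pixel_size} m) must be finer than the canopy "
            f"radius ({design.canopy_radius} m)"
        )
    if design.canopy_radius >= min(design.spacing) / 2:
        warnings.warn(
            "canopy radius reaches half the tree spacing: footprints may overlap",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = stage_rng(design.seed, "orchard")
    row_sp, col_sp = design.spacing
    height = design.n_rows * row_sp + 2 * design.margin
    width = design.trees_per_row * col_sp + 2 * design.margin
    p = design.pixel_size
    nrow_px = max(int(np.ceil(height / p)), 1)
    ncol_px = max(int(np.ceil(width / p)), 1)
    transform = RasterTransform(x_origin=0.0, y_origin=0.0, pixel_size=p)
    x, y = transform.pixel_centers((nrow_px, ncol_px))

    # soil background
    bands = {
        nm: SOIL_REFLECTANCE[nm] + rng.normal(0, design.band_noise_sd, size=(nrow_px, ncol_px))
        for nm in SOIL_REFLECTANCE
    }
    thermal = (
        design.air_temperature
        + rng.uniform(*design.soil_t_offsets, size=(nrow_px, ncol_px))
        + rng.normal(0, design.thermal_noise_sd, size=(nrow_px, ncol_px))
    )

    records = []
    veg_noise = {
        nm: rng.normal(0, design.band_noise_sd, size=(nrow_px, ncol_px))
        for nm in VEGETATION_REFLECTANCE
    }
    thermal_veg_noise = rng.normal(0, design.thermal_noise_sd, size=(nrow_px, ncol_px))
    lo, hi = design.t_veg_offsets
    for row in range(design.n_rows):
        scenario = "WW" if row % 2 == 0 else "WD"
        for col in range(design.trees_per_row):
            cx = design.margin + (col + 0.5) * col_sp
            cy = -(design.margin + (row + 0.5) * row_sp)
            drawn = float(rng.uniform(*design.stress_ranges[scenario]))
            stress = drawn if tree_stress is None else float(tree_stress[row][col])
            t_true = design.air_temperature + lo + stress * (hi - lo)
            inside = (x - cx) ** 2 + (y - cy) ** 2 <= design.canopy_radius**2
            for nm in bands:
                bands[nm] = np.where(
                    inside, VEGETATION_REFLECTANCE[nm] + veg_noise[nm], bands[nm]
                )
            thermal = np.where(inside, t_true + thermal_veg_noise, thermal)
            records.append(
                {
                    "tree_id": f"T{row:02d}{col:02d}",
                    "row": row,
                    "col": col,
                    "x": cx,
                    "y": cy,
                    "scenario": scenario,
                    "stress": stress,
                    "true_canopy_temperature": t_true,
                    "true_vegetation_pixels": int(np.count_nonzero(inside)),
                }
            )
    for nm in bands:
        bands[nm] = np.clip(bands[nm], 0.0, 1.0)
    stack = BandStack(bands=bands, transform=transform)
    truth = pd.DataFrame(records)
    return stack, thermal, truth


# ---------------------------------------------------------------------------
# Gas exchange / fluorescence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IplTruth:
    """Planted per-device I_PL coefficients and campaign conditions.

    ``devices`` maps a device id to its (b0, b1, b2); A_n noise SD in
    umol m-2 s-1; predictor ranges give P_KO/KC and (T_leaf - T_air) spans.
    """

    devices: dict = field(
        default_factory=lambda: {
            "LI-COR 1": (3.0, 0.24, -1.20),
            "LI-COR 2": (1.5, 0.30, -0.95),
        }
    )
    an_noise_sd: float = 3.0
    p_range: tuple = (20.0, 120.0)
    dt_range: tuple = (-2.0, 8.0)
    air_temp_range: tuple = (24.0, 32.0)
    ppfd: float = 1500.0
    constants: IplConstants = DEFAULT_CONSTANTS

    def __post_init__(self):
        if self.an_noise_sd < 0:
            raise ValueError("A_n noise SD must be >= 0")


def generate_gas_exchange(truth: IplTruth, n_records=None, seed: int = 0) -> pd.DataFrame:
    """Simulate a calibration campaign; one row per leaf measurement.

    ``n_records`` is an int (same for every device) or a dict device -> count;
    defaults to the typical campaign sizes (98 and 132 records for the two
    devices, in device order).  Fs and Fm' are back-computed so that the
    fluorescence chain reproduces exactly the planted P_KO/KC of each record;
    A_n = b0 + b1 P_KO/KC + b2 dT + N(0, sd^2).
    """
    devices = list(truth.devices)
    if n_records is None:
        defaults = [98, 132]
        n_records = {d: defaults[i % 2] for i, d in enumerate(devices)}
    elif isinstance(n_records, int):
        n_records = {d: n_records for d in devices}
    for d, n in n_records.items():
        if n < 10:
            raise ValueError(f"device {d!r}: need >= 10 records per device, got {n}")
    rng = stage_rng(seed, "gas_exchange")
    frames = []
    for device in devices:
        b0, b1, b2 = truth.devices[device]
        n = n_records[device]
        p = rng.uniform(*truth.p_range, size=n)
        dt = rng.uniform(*truth.dt_range, size=n)
        t_air = rng.uniform(*truth.air_temp_range, size=n)
        t_leaf = t_air + dt
        ratio = ko_kc_ratio(t_leaf, truth.constants)
        j = p / ratio
        phi = j / (truth.ppfd * truth.constants.absorptance * truth.constants.f_psii)
        if np.any(phi > 1):
            raise ValueError(
                "planted P_KO/KC range implies PhiPSII > 1; lower p_range or raise PPFD"
            )
        fm = rng.uniform(1000.0, 2000.0, size=n)
        fs = fm * (1.0 - phi)
        an = b0 + b1 * p + b2 * dt + rng.normal(0.0, truth.an_noise_sd, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "device": device,
                    "Fs": fs,
                    "Fm_prime": fm,
                    "PPFD": truth.ppfd,
                    "T_leaf": t_leaf,
                    "T_air": t_air,
                    "An": an,
                    "gs": np.clip(10.0 * an + rng.normal(0, 15.0, size=n), 5.0, None),
                    "period": np.take(
                        ["morning", "midday", "afternoon"], np.arange(n) % 3
                    ),
                    "scenario": np.take(["WW", "WD"], np.arange(n) % 2),
                    "true_p_kokc": p,
                    "true_An": b0 + b1 * p + b2 * dt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticDesign:
    """Structure of a simulated trait table.

    ``n_replicates`` trees per genotype are split evenly between the WW and WD
    scenarios; ``scenario_effect`` is added to WD trees.  Optional covariates:
    ``date_effect`` (second date offset), ``vpd_effect`` (slope on a uniform
    VPD draw), ``device_effect`` (offset for the second device).
    """

    n_genotypes: int = 240
    n_replicates: int = 4
    sigma_g2: float = 1.0
    sigma_r2: float = 1.0
    mu: float = 10.0
    scenario_effect: float = -1.0
    date_effect: float = 0.0
    vpd_effect: float = 0.0
    device_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_g2 < 0 or self.sigma_r2 < 0:
            raise ValueError("variances must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate per genotype")

    @property
    def true_h2(self) -> float:
        """Broad-sense heritability implied by the planted variances."""
        if self.sigma_g2 == 0:
            return 0.0
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_r2 / self.n_replicates)


def generate_phenotypes(design: GeneticDesign, trait: str = "trait"):
    """Simulate a long-format phenotype table; return ``(table, truth)``.

    ``truth`` carries the planted H^2 and the per-genotype genetic effects.
    """
    rng = stage_rng(design.seed, "phenotypes")
    genotypes = [f"G{i:04d}" for i in range(design.n_genotypes)]
    g_effects = rng.normal(0.0, np.sqrt(design.sigma_g2), size=design.n_genotypes)
    rows = []
    for gi, g in enumerate(genotypes):
        for rep in range(design.n_replicates):
            scenario = "WW" if rep % 2 == 0 else "WD"
            date = "d1" if rep < design.n_replicates / 2 else "d2"
            device = "dev1" if rep % 2 == 0 else "dev2"
            vpd = rng.uniform(1.0, 3.5)
            value = (
                design.mu
                + g_effects[gi]
                + (design.scenario_effect if scenario == "WD" else 0.0)
                + (design.date_effect if date == "d2" else 0.0)
                + (design.device_effect if device == "dev2" else 0.0)
                + design.vpd_effect * vpd
                + rng.normal(0.0, np.sqrt(design.sigma_r2))
            )
            rows.append(
                {
                    "genotype": g,
                    "scenario": scenario,
                    "replicate": rep,
                    "date": date,
                    "device": device,
                    "vpd": vpd,
                    "trait": trait,
                    "value": value,
                }
            )
    table = pd.DataFrame(rows)
    truth = {
        "h2": design.true_h2,
        "genotype_effects": pd.Series(g_effects, index=genotypes, name="g"),
    }
    return table, truth
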