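"""Per-tree vegetation indices, canopy temperature statistics and the
trapezoid-based Water Deficit Index (WDI) from multiband + thermal rasters.

Rasters are plain 2D arrays sharing a simple affine georeferencing
(:class:`RasterTransform`: x/y origin of the top-left corner and square pixel
size, metres).  The multispectral stack carries six reflectance bands (450,
530, 570, 675, 730, 850 nm); the thermal raster holds surface temperature,
either already in degrees Celsius or as digital numbers to be converted with a
linear target-based calibration.

The WDI locates a pixel (or a tree mean) between the "wet" and "dry" edges of
the trapezoid formed by the scatter of surface-minus-air temperature against
NDVI: 0 means the surface is as cool as a fully transpiring canopy, 1 as warm
as a non-transpiring one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BANDS_NM",
    "RasterTransform",
    "BandStack",
    "ThermalCalibration",
    "TreePixelSet",
    "Trapezoid",
    "TreeSummary",
    "BandMissingError",
    "calibrate_thermal",
    "compute_indices",
    "classify_vegetation",
    "extract_buffer",
    "tree_temperature",
    "fit_trapezoid",
    "compute_wdi",
    "summarize_tree",
]

#: Nominal band centres of the multispectral camera, nm.
BANDS_NM = (450, 530, 570, 675, 730, 850)

#: Default buffer radius around tree centres, metres.
DEFAULT_BUFFER_RADIUS = 0.70

#: Default NDVI threshold separating vegetation from soil pixels.
DEFAULT_NDVI_THRESHOLD = 0.3


class BandMissingError(KeyError):
    """A required spectral band is absent from the stack."""


@dataclass(frozen=True)
class RasterTransform:
    """Affine georeferencing: map (row, col) to metres.

    ``x = x_origin + (col + 0.5) * pixel_size`` (pixel centres);
    ``y = y_origin - (row + 0.5) * pixel_size`` (north-up).
    """

    x_origin: float
    y_origin: float
    pixel_size: float

    def pixel_centers(self, shape):
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        x = self.x_origin + (cols + 0.5) * self.pixel_size
        y = self.y_origin - (rows + 0.5) * self.pixel_size
        return x, y


@dataclass
class BandStack:
    """Co-registered reflectance bands (values in [0, 1]) keyed by centre wavelength."""

    bands: dict
    transform: RasterTransform

    def __post_init__(self):
        shapes = {b: a.shape for b, a in self.bands.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"bands disagree in shape: {shapes}")

    @property
    def shape(self):
        return next(iter(self.bands.values())).shape

    def band(self, nm: int) -> np.ndarray:
        try:
            return self.bands[nm]
        except KeyError:
            raise BandMissingError(
                f"band {nm} nm missing (have {sorted(self.bands)})"
            ) from None


@dataclass(frozen=True)
class ThermalCalibration:
    """Linear map from thermal digital numbers to degrees Celsius."""

    slope: float
    intercept: float
    r_squared: float

    def apply(self, dn):
        return self.slope * np.asarray(dn, dtype=float) + self.intercept


def calibrate_thermal(dn_targets, temp_targets) -> ThermalCalibration:
    """OLS line through (digital number, reference temperature) target pairs.

    Needs at least two targets with distinct digital numbers (ground targets
    measured by thermoradiometers during the flight).
    """
    dn = np.asarray(dn_targets, dtype=float)
    temp = np.asarray(temp_targets, dtype=float)
    if dn.shape != temp.shape or dn.ndim != 1:
        raise ValueError("dn_targets and temp_targets must be 1-D and paired")
    if len(dn) < 2:
        raise ValueError(f"need >= 2 calibration targets, got {len(dn)}")
    if np.ptp(dn) == 0:
        raise ValueError("all targets share one digital number: singular fit")
    coeffs = np.polyfit(dn, temp, 1)
    fitted = np.polyval(coeffs, dn)
    ss_res = float(np.sum((temp - fitted) ** 2))
    ss_tot = float(np.sum((temp - temp.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ThermalCalibration(slope=float(coeffs[0]), intercept=float(coeffs[1]), r_squared=r2)


def _safe_ratio(num, den):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(np.isfinite(out), out, np.nan)


def compute_indices(stack: BandStack, gndvi_green_nm: int = 570) -> dict:
    """Per-pixel NDVI, GNDVI, MCARI2 and PRI from the band stack.

    NDVI  = (rho850 - rho675) / (rho850 + rho675)
    GNDVI = (rho850 - rho_green) / (rho850 + rho_green); green defaults to the
            570 nm band (530 nm is reserved for PRI), configurable.
    PRI   = (rho530 - rho570) / (rho530 + rho570)
    MCARI2 (improved modified chlorophyll absorption ratio index) uses the
    850/675/570 nm bands in its published closed form.

    Division-by-zero pixels come back as NaN (flagged missing).
    """
    nir = stack.band(850)
    red = stack.band(675)
    green = stack.band(gndvi_green_nm)
    g530 = stack.band(530)
    g570 = stack.band(570)
    ndvi = _safe_ratio(nir - red, nir + red)
    gndvi = _safe_ratio(nir - green, nir + green)
    pri = _safe_ratio(g530 - g570, g530 + g570)
    with np.errstate(invalid="ignore"):
        disc = (2.0 * nir + 1.0) ** 2 - (6.0 * nir - 5.0 * np.sqrt(red)) - 0.5
        disc = np.where(disc > 0, disc, np.nan)
        mcari2 = _safe_ratio(
            1.5 * (2.5 * (nir - red) - 1.3 * (nir - g570)), np.sqrt(disc)
        )
    return {"NDVI": ndvi, "GNDVI": gndvi, "MCARI2": mcari2, "PRI": pri}


def classify_vegetation(stack: BandStack, threshold: float = DEFAULT_NDVI_THRESHOLD):
    """Boolean vegetation mask: NDVI > threshold (soil pixels are discarded
    from temperature statistics downstream)."""
    ndvi = compute_indices(stack)["NDVI"]
    with np.errstate(invalid="ignore"):
        return np.asarray(ndvi > threshold)


@dataclass
class TreePixelSet:
    """Pixels inside one tree's buffer zone with their band values,
    surface temperature and vegetation flag."""

    tree_id: str
    center: tuple
    buffer_radius: float
    reflectance: dict  # band nm -> 1-D array over buffer pixels
    t_surf: np.ndarray
    vegetation: np.ndarray  # boolean
    indices: dict = field(default_factory=dict)  # index name -> 1-D array

    @property
    def pix_num(self) -> int:
        """Vegetation pixel count inside the buffer."""
        return int(np.count_nonzero(self.vegetation))


def extract_buffer(
    stack: BandStack,
    thermal: np.ndarray,
    center,
    radius: float = DEFAULT_BUFFER_RADIUS,
    vegetation_mask=None,
    tree_id: str = "",
    ndvi_threshold: float = DEFAULT_NDVI_THRESHOLD,
) -> TreePixelSet:
    """All pixels whose centres fall within ``radius`` metres of ``center``.

    Membership is pixel-centre-in-circle.  An empty buffer (centre outside the
    raster extent) is returned with a warning rather than raising.
    """
    if vegetation_mask is None:
        vegetation_mask = classify_vegetation(stack, ndvi_threshold)
    x, y = stack.transform.pixel_centers(stack.shape)
    inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2
    if not inside.any():
        warnings.warn(
            f"buffer around {center} (r={radius} m) contains no pixel",
            RuntimeWarning,
            stacklevel=2,
        )
    refl = {b: a[inside] for b, a in stack.bands.items()}
    idx = compute_indices(stack)
    return TreePixelSet(
        tree_id=tree_id,
        center=tuple(center),
        buffer_radius=radius,
        reflectance=refl,
        t_surf=np.asarray(thermal, dtype=float)[inside],
        vegetation=np.asarray(vegetation_mask)[inside],
        indices={k: v[inside] for k, v in idx.items()},
    )


def tree_temperature(pixels: TreePixelSet, t_air: float):
    """Mean and sample SD of (T_surf - T_air) over vegetation pixels only.

    Zero vegetation pixels yield (nan, nan) — a missing value, not a crash.
    SD uses the n-1 (sample) convention; it is NaN for a single pixel.
    """
    veg = np.asarray(pixels.vegetation, dtype=bool)
    dt = pixels.t_surf[veg] - t_air
    if dt.size == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(dt))
    sd = float(np.std(dt, ddof=1)) if dt.size > 1 else float("nan")
    return mean, sd


@dataclass(frozen=True)
class Trapezoid:
    """Vertices of the NDVI x (T_surf - T_air) trapezoid, degrees C.

    The wet edge joins (ndvi_soil, t_sat_soil) to (ndvi_veg, t_ww_veg); the dry
    edge joins (ndvi_soil, t_dry_soil) to (ndvi_veg, t_ws_veg).
    """

    t_sat_soil: float
    t_ww_veg: float
    t_dry_soil: float
    t_ws_veg: float
    ndvi_soil: float = 0.0
    ndvi_veg: float = 1.0

    def __post_init__(self):
        if not self.ndvi_soil < self.ndvi_veg:
            raise ValueError("need ndvi_soil < ndvi_veg")
        if not self.t_ww_veg < self.t_ws_veg:
            raise ValueError("well-watered vegetation must be cooler than water-stressed")
        if not self.t_sat_soil < self.t_dry_soil:
            raise ValueError("saturated soil must be cooler than dry soil")

    def wet_edge(self, ndvi):
        return np.interp(
            ndvi, [self.ndvi_soil, self.ndvi_veg], [self.t_sat_soil, self.t_ww_veg]
        )

    def dry_edge(self, ndvi):
        return np.interp(
            ndvi, [self.ndvi_soil, self.ndvi_veg], [self.t_dry_soil, self.t_ws_veg]
        )


def fit_trapezoid(
    ndvi,
    dt,
    n_bins: int = 20,
    ndvi_percentiles=(5.0, 95.0),
    temp_percentiles=(2.5, 97.5),
    debias: bool = True,
    manual_vertices=None,
) -> Trapezoid:
    """Estimate the WDI trapezoid from the all-pixel (NDVI, T_surf - T_air) scatter.

    Automatic mode: the soil and vegetation abscissae are the 5th/95th NDVI
    percentiles; within NDVI bins, the 2.5th and 97.5th temperature percentiles
    trace the wet and dry envelopes, each regressed on bin-centre NDVI; vertex
    temperatures are the two lines evaluated at the soil/vegetation abscissae.
    Because an inner quantile of a filled trapezoid sits inside the true edge
    by a known fraction of the local height, the two lines are linearly
    de-biased back to the 0/100% envelope (``debias=True``, assumes roughly
    uniform fill in the temperature direction).

    Manual mode: ``manual_vertices = (t_sat_soil, t_ww_veg, t_dry_soil,
    t_ws_veg)`` (optionally ``+ (ndvi_soil, ndvi_veg)``) bypasses the fit and
    echoes the supplied trapezoid — the escape hatch for vertices read off a
    published scatter.
    """
    if manual_vertices is not None:
        return Trapezoid(*manual_vertices)
    ndvi = np.asarray(ndvi, dtype=float).ravel()
    dt = np.asarray(dt, dtype=float).ravel()
    ok = np.isfinite(ndvi) & np.isfinite(dt)
    ndvi, dt = ndvi[ok], dt[ok]
    if len(ndvi) < 100:
        raise ValueError(f"need >= 100 pixels to fit a trapezoid, got {len(ndvi)}")
    ndvi_soil, ndvi_veg = np.percentile(ndvi, ndvi_percentiles)
    if ndvi_veg - ndvi_soil < 0.05:
        raise ValueError(
            "NDVI spread too small to span soil and vegetation "
            f"(5th-95th percentile span {ndvi_veg - ndvi_soil:.3g} < 0.05)"
        )
    edges = np.linspace(ndvi.min(), ndvi.max(), n_bins + 1)
    centers, lo, hi = [], [], []
    for i in range(n_bins):
        sel = (ndvi >= edges[i]) & (
            ndvi < edges[i + 1] if i < n_bins - 1 else ndvi <= edges[i + 1]
        )
        if np.count_nonzero(sel) < 10:
            continue
        centers.append(0.5 * (edges[i] + edges[i + 1]))
        q = np.percentile(dt[sel], temp_percentiles)
        lo.append(q[0])
        hi.append(q[1])
    if len(centers) < 3:
        raise ValueError(f"only {len(centers)} usable NDVI bins (< 3): cannot fit edges")
    centers = np.asarray(centers)
    wet_line = np.polyfit(centers, lo, 1)
    dry_line = np.polyfit(centers, hi, 1)
    x = np.array([ndvi_soil, ndvi_veg])
    q_lo = np.polyval(wet_line, x)
    q_hi = np.polyval(dry_line, x)
    if debias:
        p_lo, p_hi = np.asarray(temp_percentiles) / 100.0
        span = p_hi - p_lo
        wet = q_lo - p_lo * (q_hi - q_lo) / span
        dry = q_hi + (1.0 - p_hi) * (q_hi - q_lo) / span
    else:
        wet, dry = q_lo, q_hi
    if np.any(wet >= dry):
        raise ValueError("fitted wet edge meets or crosses the dry edge: invalid geometry")
    return Trapezoid(
        t_sat_soil=float(wet[0]),
        t_ww_veg=float(wet[1]),
        t_dry_soil=float(dry[0]),
        t_ws_veg=float(dry[1]),
        ndvi_soil=float(ndvi_soil),
        ndvi_veg=float(ndvi_veg),
    )


def compute_wdi(ndvi, dt, trap: Trapezoid):
    """Water Deficit Index at the query (NDVI, T_surf - T_air) point(s).

    WDI = (dT - T_wet(NDVI)) / (T_dry(NDVI) - T_wet(NDVI)), clipped to [0, 1]:
    0 = surface as cool as the wet (fully transpiring) edge, 1 = as warm as the
    dry (non-transpiring) edge.  Per-tree WDI is conventionally computed at the
    tree's mean NDVI and mean dT.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    dt = np.asarray(dt, dtype=float)
    wet = trap.wet_edge(ndvi)
    dry = trap.dry_edge(ndvi)
    denom = dry - wet
    if np.any(np.asarray(denom) <= 0):
        raise ValueError("degenerate trapezoid edge: T_dry <= T_wet at the query NDVI")
    out = np.clip((dt - wet) / denom, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TreeSummary:
    """Per-tree statistics over the buffer zone (Celsius for temperatures)."""

    tree_id: str
    dt_mean: float
    dt_sd: float
    pix_num: int
    ndvi: float
    gndvi: float
    mcari2: float
    pri: float
    wdi: float


def summarize_tree(pixels: TreePixelSet, t_air: float, trap: Trapezoid | None) -> TreeSummary:
    """Tree-level summary: temperature stats over vegetation pixels, spectral
    index means over all buffer pixels, and WDI at the tree's mean NDVI/dT."""
    dt_mean, dt_sd = tree_temperature(pixels, t_air)
    means = {k: float(np.nanmean(v)) if v.size else float("nan")
             for k, v in pixels.indices.items()}
    wdi = float("nan")
    if trap is not None and np.isfinite(dt_mean) and np.isfinite(means["NDVI"]):
        wdi = float(compute_wdi(means["NDVI"], dt_mean, trap))
    return TreeSummary(
        tree_id=pixels.tree_id,
        dt_mean=dt_mean,
        dt_sd=dt_sd,
        pix_num=pixels.pix_num,
        ndvi=means["NDVI"],
        gndvi=means["GNDVI"],
        mcari2=means["MCARI2"],
        pri=means["PRI"],
        wdi=wdi,
    )
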