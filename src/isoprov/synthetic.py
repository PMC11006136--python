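"""Synthetic landscape, tissue samples and atmosphere with known ground truth.

Every downstream stage of the provenance workflow (isoscape fitting, 1-sigma
local/non-local classification, calibration, Bayesian assignment, Suess
correction) can be exercised against this module's outputs, because the true
bioavailable 87Sr/86Sr field, the true precipitation d18O field and every
individual's true origin are known by construction.

The landscape emulates the statistical structure of a Scandinavian-type
setting: a piecewise geology-driven Sr field with spatially correlated noise,
a coastal sea-spray pull toward the marine ratio 0.7092, and a precipitation
d18O field declining with latitude and elevation.  It does not attempt to
reproduce real Scandinavian geology or moose demography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .raster import GridTransform, RasterGrid, destination_point, haversine_km

SEA_SALT_RATIO = 0.7092  # modern seawater 87Sr/86Sr

__all__ = [
    "SyntheticTruth",
    "make_landscape",
    "sample_training_points",
    "simulate_individuals",
    "make_atmosphere_record",
]


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic landscape.

    ``predictor_stack`` maps predictor name -> co-registered RasterGrid.
    ``individuals`` is populated by :func:`simulate_individuals`.
    """

    seed: int
    sr_field: RasterGrid
    o_field: RasterGrid
    predictor_stack: dict[str, RasterGrid]
    correlation_length_km: float
    individuals: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def land_mask(self) -> np.ndarray:
        return self.sr_field.valid_mask()

    def rasters(self) -> dict[str, RasterGrid]:
        out = {"sr_field": self.sr_field, "o_field": self.o_field}
        out.update(self.predictor_stack)
        return out


def _correlated_noise(rng, shape, sd, kernel_cells):
    """Gaussian-smoothed white noise rescaled to the requested pointwise SD."""
    white = rng.standard_normal(shape)
    if kernel_cells > 0:
        smooth = gaussian_filter(white, sigma=kernel_cells, mode="nearest")
        s = smooth.std()
        smooth = smooth / s if s > 0 else smooth
    else:
        smooth = white
    return smooth * sd


def _voronoi_units(rng, shape, n_units):
    """Partition the grid into n_units nearest-seed (Voronoi) regions."""
    nr, nc = shape
    seeds_r = rng.uniform(0, nr, n_units)
    seeds_c = rng.uniform(0, nc, n_units)
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    d2 = (rows[..., None] - seeds_r) ** 2 + (cols[..., None] - seeds_c) ** 2
    return np.argmin(d2, axis=-1)


def make_landscape(
    seed: int,
    n_rows: int = 100,
    n_cols: int = 100,
    n_geo_units: int = 4,
    sr_noise_sd: float = 0.002,
    o_lapse: float = 0.6,
    *,
    bounds: tuple[float, float, float, float] = (10.0, 55.0, 25.0, 70.0),
    unit_ratio_range: tuple[float, float] = (0.708, 0.748),
    proxy_noise_sd: float = 0.001,
    elevation_max_m: float = 1500.0,
    o_elevation_lapse_per_km: float = 2.8,
    o_south_value: float = -8.0,
    o_noise_sd: float = 0.5,
    noise_kernel_cells: float = 5.0,
    coast_decay_km: float = 60.0,
    sea_margin_cols: int = 0,
) -> SyntheticTruth:
    """Build a synthetic dual-isotope landscape with ground truth.

    Parameters
    ----------
    n_geo_units : number of geology units (Voronoi regions), each with its own
        base 87Sr/86Sr drawn from ``unit_ratio_range``.
    sr_noise_sd : pointwise SD of the spatially correlated noise added to the
        Sr field (dimensionless ratio).
    o_lapse : decline of precipitation d18O per degree of latitude (permil).
    proxy_noise_sd : SD of the error in the geochemical proxy predictor
        (analog of a prior Sr model product, the dominant external predictor).
    sea_margin_cols : if > 0, a western strip this many columns wide is set to
        nodata (sea), exercising nodata handling.

    The predictor stack contains a geochemical proxy correlated with the true
    field, elevation, a coast-distance sea-salt proxy, a mean-annual-
    temperature-like latitude proxy and one pure-noise predictor.
    """
    if n_rows < 20 or n_cols < 20:
        raise ValueError("grid must be at least 20x20")
    if n_geo_units < 1:
        raise ValueError("n_geo_units must be >= 1")
    lon_min, lat_min, lon_max, lat_max = bounds
    dx = (lon_max - lon_min) / n_cols
    dy = (lat_max - lat_min) / n_rows
    transform = GridTransform(x0=lon_min, y0=lat_max, dx=dx, dy=-dy)
    shape = (n_rows, n_cols)
    rng = np.random.default_rng(seed)

    units = _voronoi_units(rng, shape, n_geo_units)
    if n_geo_units > 1:
        base_ratios = np.sort(rng.uniform(*unit_ratio_range, n_geo_units))
    else:
        base_ratios = np.array([float(np.mean(unit_ratio_range))])
    sr_base = base_ratios[units]

    # elevation: smooth correlated relief, nonnegative
    relief = _correlated_noise(rng, shape, 1.0, 2 * noise_kernel_cells)
    relief = relief - relief.min()
    elevation = relief / max(relief.max(), 1e-12) * elevation_max_m

    # coast distance from the western edge (or sea strip), in km
    land = np.ones(shape, dtype=bool)
    if sea_margin_cols > 0:
        land[:, :sea_margin_cols] = False
    lat_mid = 0.5 * (lat_min + lat_max)
    km_per_col = haversine_km(lon_min, lat_mid, lon_min + dx, lat_mid)
    km_per_row = haversine_km(lon_min, lat_mid, lon_min, lat_mid + dy)
    if sea_margin_cols > 0:
        coast_dist_km = distance_transform_edt(land, sampling=(km_per_row, abs(km_per_col)))
        # sea-salt pull toward the marine end-member near the coast
        w_sea = np.exp(-coast_dist_km / coast_decay_km)
    else:
        # all-land grid: no coastline, the proxy is plain distance to the
        # western grid edge and exerts no pull
        cols = np.arange(n_cols) + 0.5
        coast_dist_km = np.broadcast_to(cols * abs(km_per_col), shape).copy()
        w_sea = np.zeros(shape)
    sr_noise = _correlated_noise(rng, shape, sr_noise_sd, noise_kernel_cells)
    sr = (1.0 - w_sea) * (sr_base + sr_noise) + w_sea * SEA_SALT_RATIO

    lon2d, lat2d = RasterGrid(np.zeros(shape), transform).cell_centers()
    o_noise = _correlated_noise(rng, shape, o_noise_sd, noise_kernel_cells)
    o = (
        o_south_value
        - o_lapse * (lat2d - lat_min)
        - o_elevation_lapse_per_km * elevation / 1000.0
        + o_noise
    )

    # geochemical proxy: prior-model analog carrying the geology signal plus
    # its own smaller error, so it predicts well but not perfectly
    proxy = sr + _correlated_noise(rng, shape, proxy_noise_sd, noise_kernel_cells)
    pure_noise = rng.standard_normal(shape)
    mat = 10.0 - 0.5 * (lat2d - lat_min) + rng.standard_normal(shape) * 0.3

    def grid(vals, **md):
        v = np.asarray(vals, dtype=float).copy()
        v[~land] = np.nan
        return RasterGrid(v, transform, metadata=md)

    sr_grid = grid(sr, quantity="sr87_86", seed=seed)
    if not (0.702 <= np.nanmin(sr_grid.values) and np.nanmax(sr_grid.values) <= 0.760):
        raise ValueError("synthetic Sr field left the plausible bioavailable range")
    o_grid = grid(o, quantity="d18O_precip_vsmow", seed=seed)

    stack = {
        "geo_proxy": grid(proxy, quantity="prior_sr_model"),
        "elevation": grid(elevation, quantity="elevation_m"),
        "coast_dist": grid(coast_dist_km, quantity="coast_distance_km"),
        "mat": grid(mat, quantity="mean_annual_temp_C"),
        "noise": grid(pure_noise, quantity="pure_noise"),
    }
    # e-folding scale of the smoothed-noise autocorrelation: smoothing white
    # noise with a Gaussian kernel of scale s gives rho(d) = exp(-d^2/(4 s^2)),
    # which drops to 1/e at d = 2 s
    corr_len = 2.0 * noise_kernel_cells * 0.5 * (abs(km_per_col) + abs(km_per_row))
    return SyntheticTruth(
        seed=seed,
        sr_field=sr_grid,
        o_field=o_grid,
        predictor_stack=stack,
        correlation_length_km=float(corr_len),
        params={
            "n_rows": n_rows,
            "n_cols": n_cols,
            "n_geo_units": n_geo_units,
            "sr_noise_sd": sr_noise_sd,
            "o_lapse": o_lapse,
            "bounds": bounds,
            "sea_margin_cols": sea_margin_cols,
        },
    )


def _draw_land_cells(truth, n, rng, replace):
    mask = truth.land_mask()
    rows, cols = np.nonzero(mask)
    if not replace and n > rows.size:
        raise ValueError(f"cannot draw {n} distinct cells from {rows.size} land cells")
    idx = rng.choice(rows.size, size=n, replace=replace)
    return rows[idx], cols[idx]


def sample_training_points(
    truth: SyntheticTruth,
    n: int,
    meas_noise_sd: float,
    seed: int,
    *,
    replace: bool = False,
) -> pd.DataFrame:
    """Draw Sr training points uniformly over land cells.

    Values are the true field at the cell center plus Normal(0, meas_noise_sd)
    measurement noise.  Stands in for a literature compilation of bioavailable
    Sr samples (plants, waters, soil leachates).
    """
    if n < 10:
        raise ValueError("need at least 10 training points")
    rng = np.random.default_rng(seed)
    rows, cols = _draw_land_cells(truth, n, rng, replace)
    lon, lat = truth.sr_field.transform.cell_center(rows, cols)
    values = truth.sr_field.values[rows, cols] + rng.normal(0.0, meas_noise_sd, n)
    return pd.DataFrame({"lon": lon, "lat": lat, "sr87_86": values})


def simulate_individuals(
    truth: SyntheticTruth,
    n: int,
    frac_nonlocal: float,
    displacement_km: float,
    tissue_sr_sd: float = 0.002,
    tissue_o_sd: float = 0.5,
    seed: int = 0,
    *,
    antler_offset_permil: float = 1.0,
    bone_offset_permil: float = 0.0,
    p_antler: float = 15 / 65,
    sex_probs: tuple[float, float, float] = (29 / 65, 17 / 65, 19 / 65),
    year_range: tuple[int, int] = (1800, 1994),
    max_bearing_tries: int = 200,
) -> pd.DataFrame:
    """Simulate tissue samples with known origins and death sites.

    A fraction ``frac_nonlocal`` of individuals died ``displacement_km`` away
    from their origin, at a uniform random bearing (redrawn until the death
    site falls on land).  Tissue Sr is the true field at the *origin* plus
    noise; tissue d18O (water-equivalent, permil VSMOW) is the o-field at the
    origin plus a tissue-type offset (antler forms in spring/summer and sits
    ~1 permil above bone) plus noise.

    Returns a table with one row per individual carrying both the
    observation-like columns (death lon/lat, tissue, sex, year, isotope
    values) and the truth columns (origin, displacement, is_local).
    """
    if not 0.0 <= frac_nonlocal <= 1.0:
        raise ValueError("frac_nonlocal must be in [0, 1]")
    grid = truth.sr_field
    nr, nc = grid.shape
    t = grid.transform
    extent_km = haversine_km(t.x0, t.y0 + nr * t.dy, t.x0 + nc * t.dx, t.y0)
    if displacement_km > extent_km:
        raise ValueError(
            f"displacement {displacement_km} km exceeds grid extent (~{extent_km:.0f} km)"
        )
    rng = np.random.default_rng(seed)
    rows, cols = _draw_land_cells(truth, n, rng, replace=True)
    olon, olat = t.cell_center(rows, cols)
    n_nonlocal = int(round(frac_nonlocal * n))
    is_nonlocal = np.zeros(n, dtype=bool)
    is_nonlocal[rng.choice(n, size=n_nonlocal, replace=False)] = True

    dlon, dlat = olon.astype(float).copy(), olat.astype(float).copy()
    land = truth.land_mask()
    for i in np.nonzero(is_nonlocal)[0]:
        if displacement_km == 0:
            continue
        for _ in range(max_bearing_tries):
            bearing = rng.uniform(0.0, 360.0)
            lon2, lat2 = destination_point(olon[i], olat[i], bearing, displacement_km)
            if grid.contains(lon2, lat2):
                r2, c2 = t.index_of(lon2, lat2)
                if land[r2, c2]:
                    dlon[i], dlat[i] = float(lon2), float(lat2)
                    break
        else:
            raise RuntimeError(
                f"could not place a displaced death site for individual {i}"
            )

    tissue = np.where(rng.random(n) < p_antler, "antler", "bone")
    sex = rng.choice(["M", "F", "U"], size=n, p=sex_probs)
    year = rng.integers(year_range[0], year_range[1] + 1, n)
    sr_true = truth.sr_field.values[rows, cols]
    o_true = truth.o_field.values[rows, cols]
    offset = np.where(tissue == "antler", antler_offset_permil, bone_offset_permil)
    sr_tissue = sr_true + rng.normal(0.0, tissue_sr_sd, n)
    o_tissue = o_true + offset + rng.normal(0.0, tissue_o_sd, n)

    return pd.DataFrame(
        {
            "sample_id": [f"SYN_{seed}_{i:04d}" for i in range(n)],
            "tissue": tissue,
            "sex": sex,
            "year": year,
            "lon": dlon,
            "lat": dlat,
            "sr87_86": sr_tissue,
            "d18O_water_vsmow": o_tissue,
            "true_origin_lon": olon,
            "true_origin_lat": olat,
            "displacement_km": np.where(is_nonlocal, displacement_km, 0.0),
            "is_local": ~is_nonlocal,
        }
    )


def make_atmosphere_record(
    year_start: int,
    year_end: int,
    total_decline: float,
    *,
    start_value: float = -6.4,
    steepness: float = 0.04,
    inflection_frac: float = 0.8,
) -> pd.DataFrame:
    """Annual atmospheric CO2 d13C record declining smoothly (Suess effect).

    The decline follows a logistic ramp — slow through the 19th century,
    accelerating toward the end of the record, as in ice-core/firn
    reconstructions — normalized so the total drop from ``year_start`` to
    ``year_end`` equals ``total_decline`` exactly.
    """
    if year_start >= year_end:
        raise ValueError("year_start must precede year_end")
    years = np.arange(year_start, year_end + 1)
    t0 = year_start + inflection_frac * (year_end - year_start)
    s = 1.0 / (1.0 + np.exp(-steepness * (years - t0)))
    s = (s - s[0]) / (s[-1] - s[0]) if s[-1] > s[0] else np.zeros_like(s)
    return pd.DataFrame({"year": years, "d13C_atm": start_value - total_decline * s})
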