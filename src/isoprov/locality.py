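"""Sample-vs-isoscape comparison: buffered extraction, delta distributions,
the 1-sigma local/non-local rule, group tests and the forest-cover check.

The central quantity is the per-sample signed difference
``delta = tissue value - buffered isoscape mean`` at the death location,
computed for Sr and for water-equivalent d18O.  A sample is "local" when both
deltas lie within one standard deviation of their respective distributions
(mean and SD taken over ALL samples in a single pass, outliers included).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .raster import RasterGrid, haversine_km

__all__ = [
    "DeltaTable",
    "extract_buffered",
    "compute_deltas",
    "scan_buffer_radius",
    "classify_local",
    "group_difference_test",
    "delta_group_tests",
    "forest_cover_regression",
]


@dataclass
class DeltaTable:
    """Per-sample deltas plus the table-level statistics of both axes."""

    per_sample: pd.DataFrame  # sample_id, delta_sr, delta_o, buffered_sr, buffered_o, local_flag
    mean_sr: float
    sd_sr: float
    mean_o: float
    sd_o: float
    radius_km: float
    sigma: float = 1.0


def extract_buffered(raster: RasterGrid, lon: float, lat: float, radius_km: float) -> float:
    """Unweighted mean over non-nodata cells whose centers lie within the
    great-circle radius of the point.

    Falls back to the single containing cell when no center is inside the
    circle; NaN (with a warning) when every candidate cell is nodata.
    """
    if not raster.contains(lon, lat):
        raise ValueError(f"point ({lon}, {lat}) outside raster footprint")
    t = raster.transform
    nr, nc = raster.shape
    # bounding box in cells, padded by one cell for the center-in-circle test
    deg_lat = radius_km / 111.19
    cos = max(math.cos(math.radians(lat)), 1e-6)
    deg_lon = radius_km / (111.19 * cos)
    r0, c0 = t.index_of(lon, lat - math.copysign(deg_lat, t.dy))
    r1, c1 = t.index_of(lon, lat + math.copysign(deg_lat, t.dy))
    c_lo = t.index_of(lon - math.copysign(deg_lon, t.dx), lat)[1]
    c_hi = t.index_of(lon + math.copysign(deg_lon, t.dx), lat)[1]
    r_lo, r_hi = sorted((int(r0), int(r1)))
    c_lo, c_hi = sorted((int(c_lo), int(c_hi)))
    r_lo, r_hi = max(r_lo - 1, 0), min(r_hi + 1, nr - 1)
    c_lo, c_hi = max(c_lo - 1, 0), min(c_hi + 1, nc - 1)
    rows, cols = np.meshgrid(np.arange(r_lo, r_hi + 1), np.arange(c_lo, c_hi + 1), indexing="ij")
    clon, clat = t.cell_center(rows, cols)
    inside = haversine_km(lon, lat, clon, clat) <= radius_km
    vals = raster.values[rows, cols][inside]
    if vals.size == 0:  # radius smaller than half a cell: containing cell
        row, col = t.index_of(lon, lat)
        vals = np.array([raster.values[row, col]])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn(f"all cells nodata within {radius_km} km of ({lon}, {lat})", stacklevel=2)
        return float("nan")
    return float(vals.mean())


def compute_deltas(
    samples: pd.DataFrame,
    sr_surface: RasterGrid,
    o_surface: RasterGrid,
    radius_km: float = 10.0,
    *,
    sr_col: str = "sr87_86",
    o_col: str = "d18O_water_vsmow",
) -> DeltaTable:
    """Per-sample sample-minus-isoscape deltas at the death location.

    Oxygen deltas compare the drinking-water-equivalent tissue value against
    the precipitation surface, so conversions must be applied first.
    """
    buf_sr = np.array([
        extract_buffered(sr_surface, lo, la, radius_km)
        for lo, la in zip(samples["lon"], samples["lat"])
    ])
    buf_o = np.array([
        extract_buffered(o_surface, lo, la, radius_km)
        for lo, la in zip(samples["lon"], samples["lat"])
    ])
    d_sr = samples[sr_col].to_numpy(dtype=float) - buf_sr
    d_o = samples[o_col].to_numpy(dtype=float) - buf_o
    per = pd.DataFrame(
        {
            "sample_id": samples["sample_id"].to_numpy(),
            "delta_sr": d_sr,
            "delta_o": d_o,
            "buffered_sr": buf_sr,
            "buffered_o": buf_o,
            "local_flag": True,
        }
    )
    return DeltaTable(
        per_sample=per,
        mean_sr=float(np.nanmean(d_sr)),
        sd_sr=float(np.nanstd(d_sr, ddof=1)),
        mean_o=float(np.nanmean(d_o)),
        sd_o=float(np.nanstd(d_o, ddof=1)),
        radius_km=radius_km,
    )


def scan_buffer_radius(
    samples: pd.DataFrame,
    surface: RasterGrid,
    radii: list[float],
    *,
    value_col: str = "sr87_86",
) -> tuple[float, pd.DataFrame]:
    """Choose the buffer radius maximizing the sample-vs-isoscape OLS R2.

    Each radius gets an OLS of tissue value on buffered isoscape value; ties
    are broken toward the smallest radius.  Radii with fewer than 3 valid
    pairs are skipped with a warning.
    """
    if len(radii) < 2 and len(radii) != 1:
        raise ValueError("need at least one radius")
    rows = []
    y_all = samples[value_col].to_numpy(dtype=float)
    for r in radii:
        buf = np.array([
            extract_buffered(surface, lo, la, r)
            for lo, la in zip(samples["lon"], samples["lat"])
        ])
        ok = np.isfinite(buf) & np.isfinite(y_all)
        if ok.sum() < 3:
            warnings.warn(f"radius {r} km: fewer than 3 valid pairs, skipped", stacklevel=2)
            continue
        fit = sm.OLS(y_all[ok], sm.add_constant(buf[ok])).fit()
        rows.append({"radius_km": r, "r2": float(fit.rsquared), "n": int(ok.sum())})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no radius yielded enough valid pairs")
    best = table.sort_values(["r2", "radius_km"], ascending=[False, True]).iloc[0]
    return float(best["radius_km"]), table


def classify_local(deltas: DeltaTable, sigma: float = 1.0) -> DeltaTable:
    """Flag samples outside ``sigma`` standard deviations of either delta
    distribution as non-local.

    Statistics are the single-pass mean/SD over all samples (no iterative
    re-trimming); a zero SD on both axes flags everything local with a
    warning.
    """
    per = deltas.per_sample
    if len(per) < 3:
        raise ValueError("need at least 3 samples to classify")
    if deltas.sd_sr == 0 and deltas.sd_o == 0:
        warnings.warn("all deltas identical; everything classified local", stacklevel=2)
        flags = np.ones(len(per), dtype=bool)
    else:
        ok_sr = np.abs(per["delta_sr"] - deltas.mean_sr) <= sigma * deltas.sd_sr
        ok_o = np.abs(per["delta_o"] - deltas.mean_o) <= sigma * deltas.sd_o
        if deltas.sd_sr == 0:
            ok_sr = np.ones(len(per), dtype=bool)
        if deltas.sd_o == 0:
            ok_o = np.ones(len(per), dtype=bool)
        flags = (ok_sr & ok_o).to_numpy()
    per = per.copy()
    per["local_flag"] = flags
    return DeltaTable(
        per_sample=per,
        mean_sr=deltas.mean_sr,
        sd_sr=deltas.sd_sr,
        mean_o=deltas.mean_o,
        sd_o=deltas.sd_o,
        radius_km=deltas.radius_km,
        sigma=sigma,
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def group_difference_test(values, group_labels) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration over all assignments of the pooled midranks when
    both groups have n <= 8 (correct under ties); tie-corrected normal
    approximation otherwise.  Returns (U of the first group, p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {len(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    ranks = _midranks(np.concatenate([a, b]))
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    if n_a <= 8 and n_b <= 8:
        # exhaustive enumeration of which pooled observations belong to group A
        mu = n_a * n_b / 2.0
        obs_dev = abs(u_a - mu)
        hits = total = 0
        rank_sum_offset = n_a * (n_a + 1) / 2.0
        for comb in itertools.combinations(range(n_a + n_b), n_a):
            u = ranks[list(comb)].sum() - rank_sum_offset
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                hits += 1
        return u_a, hits / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def delta_group_tests(deltas: DeltaTable, samples: pd.DataFrame) -> pd.DataFrame:
    """The standard suite of group comparisons on the delta distributions.

    Runs sex comparisons (M vs F) on all samples and on bones only, and the
    antler-vs-bone comparison on all samples and on males only, for both
    isotope axes.  Samples of unknown sex are excluded from sex tests.
    """
    df = deltas.per_sample.merge(
        samples[["sample_id", "tissue", "sex"]], on="sample_id", how="left"
    )
    rows = []

    def run(name, sub, label_col, axis):
        sub = sub.dropna(subset=[axis])
        counts = sub[label_col].value_counts()
        if len(counts) != 2 or counts.min() < 1:
            return
        u, p = group_difference_test(sub[axis].to_numpy(), sub[label_col].to_numpy())
        rows.append({"comparison": name, "axis": axis, "U": u, "p": p, "n": len(sub)})

    known = df[df["sex"].isin(["M", "F"])]
    bones = known[df.loc[known.index, "tissue"] == "bone"]
    males = df[df["sex"] == "M"]
    for axis in ("delta_sr", "delta_o"):
        run("sex_all", known, "sex", axis)
        run("sex_bones_only", bones, "sex", axis)
        run("tissue_all", df, "tissue", axis)
        run("tissue_males_only", males, "tissue", axis)
    return pd.DataFrame(rows)


def forest_cover_regression(
    samples: pd.DataFrame,
    cover_raster: RasterGrid,
    radius_km: float = 10.0,
    *,
    d13c_col: str = "d13C_vpdb_1994",
) -> pd.DataFrame:
    """OLS of tissue d13C on buffered %-forest cover, per tissue and combined.

    Non-local samples must already be excluded upstream (the caller passes
    locals only).  Rejects a spatially constant cover regressor.
    """
    cover = np.array([
        extract_buffered(cover_raster, lo, la, radius_km)
        for lo, la in zip(samples["lon"], samples["lat"])
    ])
    y = samples[d13c_col].to_numpy(dtype=float)
    tissue = samples["tissue"].to_numpy()
    rows = []
    for name, mask in (
        ("bone", tissue == "bone"),
        ("antler", tissue == "antler"),
        ("combined", np.ones(len(samples), dtype=bool)),
    ):
        x, yy = cover[mask], y[mask]
        ok = np.isfinite(x) & np.isfinite(yy)
        x, yy = x[ok], yy[ok]
        if x.size < 3:
            continue
        if np.ptp(x) == 0:
            raise ValueError(f"forest cover constant across {name} samples; slope undefined")
        fit = sm.OLS(yy, sm.add_constant(x)).fit()
        rows.append(
            {
                "group": name,
                "r2": float(fit.rsquared),
                "p": float(fit.pvalues[1]),
                "slope": float(fit.params[1]),
                "n": int(x.size),
            }
        )
    return pd.DataFrame(rows)
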