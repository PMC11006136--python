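"""Linear calibration of an isoscape against local tissue samples.

Classical calibration: ordinary least squares of the tissue value (response)
on the buffered isoscape value (predictor), fitted on samples classified as
local, then applied cell-wise to the raster.  The calibration's residual
scatter is propagated into the uncertainty surface in quadrature.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import statsmodels.api as sm

from .raster import RasterGrid

__all__ = ["CalibrationFit", "fit_calibration", "apply_calibration", "calibrated_uncertainty"]


@dataclass
class CalibrationFit:
    """An OLS sample-on-isoscape calibration for one isotope system."""

    system: str  # "Sr" or "O"
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float
    p_value: float
    residual_sd: float  # sqrt(SS_res / (n - 2)), response units
    n_used: int
    excluded_ids: tuple = ()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationFit":
        with open(path) as fh:
            d = json.load(fh)
        d["excluded_ids"] = tuple(d.get("excluded_ids", ()))
        return cls(**d)

    @classmethod
    def identity(cls, system: str) -> "CalibrationFit":
        return cls(system, 1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0)


def fit_calibration(
    isoscape_values,
    sample_values,
    system: str = "Sr",
    excluded_ids=(),
) -> CalibrationFit:
    """OLS of sample value on isoscape value over local pairs."""
    x = np.asarray(isoscape_values, dtype=float)
    y = np.asarray(sample_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 local pairs to calibrate")
    if np.ptp(x) == 0:
        raise ValueError("isoscape values are constant; calibration degenerate")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(res.ssr / (x.size - 2))) if x.size > 2 else 0.0
    return CalibrationFit(
        system=system,
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        r2=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        residual_sd=resid_sd,
        n_used=int(x.size),
        excluded_ids=tuple(excluded_ids),
    )


def apply_calibration(surface: RasterGrid, fit: CalibrationFit) -> RasterGrid:
    """Cell-wise ``intercept + slope * value``; nodata preserved."""
    values = fit.intercept + fit.slope * surface.values
    return surface.copy_with(values, calibrated=True, system=fit.system)


def calibrated_uncertainty(surface_sd: RasterGrid, fit: CalibrationFit) -> RasterGrid:
    """Propagate the map uncertainty through the calibration:
    per-cell sqrt((slope * sd)^2 + residual_sd^2)."""
    if np.nanmin(surface_sd.values) < 0:
        raise ValueError("uncertainty raster has negative cells")
    if fit.residual_sd < 0:
        raise ValueError("residual_sd must be nonnegative")
    values = np.sqrt((fit.slope * surface_sd.values) ** 2 + fit.residual_sd**2)
    return surface_sd.copy_with(values, calibrated=True, system=fit.system)
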