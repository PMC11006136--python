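"""Stable-isotope unit conversions and the Suess-effect correction.

Chains measured carbonate d18O (VSMOW) through phosphate to drinking-water
equivalents, inter-converts the VPDB and VSMOW oxygen scales, and corrects
tissue d13C for the secular decline of atmospheric CO2 d13C (the Suess
effect) to a common reference year using a LOESS fit of an atmospheric
record.

All conversions are affine with constants held in a versioned YAML
configuration (each with a citation string), never hard-coded in the
operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConversionConfig",
    "carbonate_to_phosphate",
    "phosphate_to_carbonate",
    "phosphate_to_water",
    "water_to_phosphate",
    "vpdb_to_vsmow",
    "vsmow_to_vpdb",
    "carbonate_vsmow_to_water",
    "loess_fit",
    "suess_correct",
    "apply_conversions",
]


@dataclass(frozen=True)
class ConversionConfig:
    """Affine conversion constants with provenance.

    Forward conventions (all permil):
      carbonate = cp_slope * phosphate + cp_intercept          (VSMOW)
      phosphate = pw_slope * drinking_water + pw_intercept     (VSMOW)
      d18O_VSMOW = vs_slope * d18O_VPDB + vs_intercept
    """

    cp_slope: float = 1.037
    cp_intercept: float = 8.57
    pw_slope: float = 0.813
    pw_intercept: float = 22.02
    vs_slope: float = 1.03091
    vs_intercept: float = 30.91
    loess_span: float = 0.3
    loess_degree: int = 2
    ref_year: int = 1994
    citations: tuple = ()

    @classmethod
    def from_yaml(cls, path=None) -> "ConversionConfig":
        """Load constants from YAML; defaults to the packaged file."""
        if path is None:
            text = (
                resources.files("isoprov").joinpath("data/conversion_constants.yml")
            ).read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        raw = yaml.safe_load(text)
        cp, pw, vs = raw["carbonate_phosphate"], raw["phosphate_water"], raw["vpdb_vsmow"]
        su = raw.get("suess", {})
        return cls(
            cp_slope=float(cp["slope"]),
            cp_intercept=float(cp["intercept"]),
            pw_slope=float(pw["slope"]),
            pw_intercept=float(pw["intercept"]),
            vs_slope=float(vs["slope"]),
            vs_intercept=float(vs["intercept"]),
            loess_span=float(su.get("loess_span", 0.3)),
            loess_degree=int(su.get("loess_degree", 2)),
            ref_year=int(su.get("ref_year", 1994)),
            citations=tuple(
                sec.get("citation", "") for sec in (cp, pw, vs) if "citation" in sec
            ),
        )


_DEFAULT = ConversionConfig()


def _check_finite(x, name):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def carbonate_to_phosphate(d18o_carb, config: ConversionConfig = _DEFAULT):
    """Carbonate d18O (VSMOW) -> phosphate d18O (VSMOW), exact inverse of the
    forward carbonate = slope*phosphate + intercept relation."""
    x = _check_finite(d18o_carb, "d18O_carb")
    return (x - config.cp_intercept) / config.cp_slope


def phosphate_to_carbonate(d18o_phos, config: ConversionConfig = _DEFAULT):
    x = _check_finite(d18o_phos, "d18O_phos")
    return config.cp_slope * x + config.cp_intercept


def phosphate_to_water(d18o_phos, config: ConversionConfig = _DEFAULT):
    """Phosphate d18O (VSMOW) -> ingested (drinking) water d18O (VSMOW)."""
    if config.pw_slope == 0:
        raise ValueError("phosphate-water slope must be nonzero")
    x = _check_finite(d18o_phos, "d18O_phos")
    return (x - config.pw_intercept) / config.pw_slope


def water_to_phosphate(d18o_water, config: ConversionConfig = _DEFAULT):
    x = _check_finite(d18o_water, "d18O_water")
    return config.pw_slope * x + config.pw_intercept


def vpdb_to_vsmow(d18o_vpdb, config: ConversionConfig = _DEFAULT):
    """IAEA linear inter-scale conversion, VPDB -> VSMOW (oxygen)."""
    x = _check_finite(d18o_vpdb, "d18O_vpdb")
    return config.vs_slope * x + config.vs_intercept


def vsmow_to_vpdb(d18o_vsmow, config: ConversionConfig = _DEFAULT):
    x = _check_finite(d18o_vsmow, "d18O_vsmow")
    return (x - config.vs_intercept) / config.vs_slope


def carbonate_vsmow_to_water(d18o_carb_vsmow, config: ConversionConfig = _DEFAULT):
    """Carbonate (VSMOW) -> drinking-water equivalent, chaining both steps."""
    return phosphate_to_water(carbonate_to_phosphate(d18o_carb_vsmow, config), config)


def water_to_carbonate_vsmow(d18o_water, config: ConversionConfig = _DEFAULT):
    return phosphate_to_carbonate(water_to_phosphate(d18o_water, config), config)


# ---------------------------------------------------------------------------
# LOESS (local polynomial regression, tricube weights)
# ---------------------------------------------------------------------------


def loess_fit(x, y, x_new, span: float = 0.3, degree: int = 2):
    """Local polynomial regression with tricube weights.

    For each point in ``x_new`` a weighted polynomial of the given degree is
    fitted over the ``span`` fraction of nearest observations.  Returns the
    fitted values at ``x_new``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
    if x.size != y.size or x.size < degree + 1:
        raise ValueError("need at least degree+1 observations")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = max(int(np.ceil(span * x.size)), degree + 1)
    out = np.empty(x_new.size)
    for i, x0 in enumerate(x_new):
        d = np.abs(x - x0)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        w = (1 - (d[idx] / h) ** 3) ** 3 if h > 0 else np.ones(k)
        w = np.clip(w, 0.0, None)
        # weighted polynomial fit centered at x0 for conditioning
        xs = x[idx] - x0
        V = np.vander(xs, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = coef[0]
    return out if out.size > 1 else float(out[0])


def suess_correct(
    d13c_measured,
    year_death,
    atm_record: pd.DataFrame,
    ref_year: int = 1994,
    *,
    span: float = 0.3,
    degree: int = 2,
    extrapolate: bool = False,
):
    """Correct tissue d13C (VPDB) for the atmospheric Suess effect.

    Returns ``d13C - [L(year_death) - L(ref_year)]`` where ``L`` is a LOESS
    fit of the atmospheric CO2 d13C record against year.  ``extrapolate``
    continues the terminal fitted value as a constant beyond the record span;
    off by default, in which case out-of-span years are rejected.
    """
    years = atm_record["year"].to_numpy(dtype=float)
    vals = atm_record["d13C_atm"].to_numpy(dtype=float)
    yd = np.atleast_1d(np.asarray(year_death, dtype=float))
    lo, hi = years.min(), years.max()
    query = np.append(yd, float(ref_year))
    if not extrapolate and (query.min() < lo or query.max() > hi):
        raise ValueError(
            f"year outside atmospheric record span [{lo:.0f}, {hi:.0f}] "
            "and extrapolation is disabled"
        )
    clipped = np.clip(query, lo, hi)
    fitted = np.atleast_1d(loess_fit(years, vals, clipped, span=span, degree=degree))
    l_death, l_ref = fitted[:-1], fitted[-1]
    corrected = np.atleast_1d(np.asarray(d13c_measured, dtype=float)) - (l_death - l_ref)
    return corrected if corrected.size > 1 else float(corrected[0])


def apply_conversions(
    samples: pd.DataFrame,
    atm_record: pd.DataFrame | None = None,
    config: ConversionConfig = _DEFAULT,
    ref_year: int | None = None,
) -> pd.DataFrame:
    """Add derived isotope columns to a sample table.

    From ``d18O_carb_vsmow`` derives ``d18O_phos_vsmow`` and
    ``d18O_water_vsmow``; from ``d13C_vpdb`` (needs ``year`` and an
    atmospheric record) derives ``d13C_vpdb_ref``.  Sr ratios outside
    (0.60, 0.90) are rejected as physically impossible.
    """
    out = samples.copy()
    if "sr87_86" in out:
        sr = out["sr87_86"].to_numpy(dtype=float)
        bad = np.isfinite(sr) & ((sr <= 0.60) | (sr >= 0.90))
        if bad.any():
            raise ValueError(
                f"implausible 87Sr/86Sr ratios in rows {np.nonzero(bad)[0].tolist()}"
            )
    if "d18O_carb_vsmow" in out:
        phos = carbonate_to_phosphate(out["d18O_carb_vsmow"].to_numpy(float), config)
        out["d18O_phos_vsmow"] = phos
        out["d18O_water_vsmow"] = phosphate_to_water(phos, config)
    if "d13C_vpdb" in out and atm_record is not None:
        ry = config.ref_year if ref_year is None else ref_year
        out[f"d13C_vpdb_{ry}"] = suess_correct(
            out["d13C_vpdb"].to_numpy(float),
            out["year"].to_numpy(float),
            atm_record,
            ref_year=ry,
            span=config.loess_span,
            degree=config.loess_degree,
        )
    return out
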