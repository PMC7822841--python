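"""Lifetime migration metrics from planar coordinates and a density raster.

Coordinates are kilometres on a planar national-grid-like system (easting,
northing).  Local-authority polygons are abstracted to a regular raster of
population density; a polygon-based lookup can be substituted by any object
exposing the same ``lookup(easting, northing)`` interface.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm


class DensityMap:
    """Regular raster of population density (persons/km^2) on a planar grid.

    Cells are half-open ``[x, x+cell) x [y, y+cell)``: every boundary point
    belongs to the cell at its lower-left, so lookups are total and
    deterministic over the covered region.
    """

    def __init__(self, x_min: float, y_min: float, cell_km: float, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D raster")
        if (values < 0).any():
            raise ValueError("densities must be non-negative")
        if cell_km <= 0:
            raise ValueError("cell size must be positive")
        self.x_min = float(x_min)
        self.y_min = float(y_min)
        self.cell_km = float(cell_km)
        self.values = values  # shape (ny, nx), rows from y_min upward

    @property
    def x_max(self) -> float:
        return self.x_min + self.values.shape[1] * self.cell_km

    @property
    def y_max(self) -> float:
        return self.y_min + self.values.shape[0] * self.cell_km

    def lookup(self, easting, northing):
        """Density of the containing cell; raises outside the map bounds."""
        e = np.asarray(easting, dtype=float)
        n = np.asarray(northing, dtype=float)
        if not (np.isfinite(e).all() and np.isfinite(n).all()):
            raise ValueError("coordinates must be finite")
        ix = np.floor((e - self.x_min) / self.cell_km).astype(int)
        iy = np.floor((n - self.y_min) / self.cell_km).astype(int)
        ny, nx = self.values.shape
        if ((ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)).any():
            raise ValueError("location outside density map bounds")
        return self.values[iy, ix]


def distance_km(birth_e, birth_n, current_e, current_n):
    """Euclidean distance between birth and current residence, to the
    nearest kilometre (round-half-to-even, as in IEEE rounding)."""
    d = np.hypot(
        np.asarray(current_e, float) - np.asarray(birth_e, float),
        np.asarray(current_n, float) - np.asarray(birth_n, float),
    )
    out = np.rint(d).astype(int)
    return out if out.ndim else int(out)


def density_at(easting, northing, dmap: DensityMap):
    """Population density at a coordinate (containing-cell value)."""
    return dmap.lookup(easting, northing)


def migration_table(locations: pd.DataFrame, dmap: DensityMap) -> pd.DataFrame:
    """Per-sample migration variables.

    ``density_change`` is current minus birth density, so a move to a less
    dense area is negative.
    """
    be = locations["birth_easting"].to_numpy()
    bn = locations["birth_northing"].to_numpy()
    ce = locations["current_easting"].to_numpy()
    cn = locations["current_northing"].to_numpy()
    d_birth = density_at(be, bn, dmap)
    d_cur = density_at(ce, cn, dmap)
    out = pd.DataFrame(
        {
            "distance_km": distance_km(be, bn, ce, cn),
            "density_birth": d_birth,
            "density_current": d_cur,
            "density_change": d_cur - d_birth,
        }
    )
    if "years_at_residence" in locations:
        out["years_at_residence"] = locations["years_at_residence"].to_numpy()
    return out


def _tier_fit(y: np.ndarray, x: np.ndarray, cov: pd.DataFrame) -> dict:
    X = np.column_stack([np.ones_like(x), x, cov.to_numpy()]) if cov.shape[1] else np.column_stack(
        [np.ones_like(x), x]
    )
    if cov.shape[1] and (cov.std(axis=0) == 0).any():
        raise ValueError("constant covariate column")
    res = sm.OLS(y, X).fit()
    return {"beta": res.params[1], "se": res.bse[1], "p": res.pvalues[1], "r2": res.rsquared}


def follow_up_associations(
    migration: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    base: tuple[str, ...] = ("age", "sex"),
    extended: tuple[str, ...] = ("age", "sex", "deprivation", "education"),
) -> pd.DataFrame:
    """Regress each migration variable on each exposure under two covariate
    tiers and report the attenuation ratio beta_extended / beta_base.

    ``exposures`` typically holds the risk-taking-like trait and the PRS;
    attenuation below 1 indicates that deprivation/education absorb part of
    the association, mirroring a mediated or confounded pathway.
    """
    rows = []
    for var in migration.columns:
        y = migration[var].to_numpy(dtype=float)
        for exp_name in exposures.columns:
            x = exposures[exp_name].to_numpy(dtype=float)
            fit_base = _tier_fit(y, x, covariates[list(base)])
            fit_ext = _tier_fit(y, x, covariates[list(extended)])
            atten = (
                fit_ext["beta"] / fit_base["beta"] if fit_base["beta"] != 0 else np.nan
            )
            rows.append(
                {
                    "variable": var,
                    "exposure": exp_name,
                    "beta_base": fit_base["beta"],
                    "p_base": fit_base["p"],
                    "r2_base": fit_base["r2"],
                    "beta_extended": fit_ext["beta"],
                    "p_extended": fit_ext["p"],
                    "r2_extended": fit_ext["r2"],
                    "attenuation_ratio": atten,
                }
            )
    return pd.DataFrame(rows)
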