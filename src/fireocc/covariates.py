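"""Covariate construction for multi-scale occupancy models.

Burn-severity summaries are computed inside circular buffers around each
survey point at radii of 50, 100, 250 and 500 m: the buffer mean (`sev`)
and standard deviation (`sev_sd`) of percent basal-area mortality.
Pyrodiversity is the heterogeneity of burn severity corrected for its mean:
the residual of an ordinary least-squares regression of `sev_sd` on
`sev` and `sev**2`, so that it is orthogonal to mean severity by
construction. All continuous predictors are standardized (mean 0, SD 1);
quadratic terms are squares of the standardized variable.

Conventions (sample SD with ``ddof=1``, squaring after standardization,
buffer membership by cell center) are module constants so either choice is
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from fireocc.exceptions import (
    CollinearityError,
    DataValidationError,
    DegenerateCovariateError,
    EmptyBufferError,
)

if TYPE_CHECKING:  # pragma: no cover
    from fireocc.synthetic import Landscape, SurveyDesign

#: Buffer radii (m) at which severity statistics are computed.
RADII_M: tuple[float, ...] = (50.0, 100.0, 250.0, 500.0)

#: Delta degrees of freedom for every SD in this module (sample SD).
SD_DDOF: int = 1

#: Quadratic terms (day^2, severity^2) are squares of the standardized value.
SQUARE_AFTER_STANDARDIZE: bool = True

#: Fixed column order of the detection design matrix.
DET_COLUMNS: tuple[str, ...] = (
    "intercept", "day", "day2", "canopy", "noise", "temperature", "smm",
)

#: Fixed column order of the occurrence design matrix.
OCC_COLUMNS: tuple[str, ...] = (
    "intercept", "elevation", "water_distance",
    "severity", "severity2", "pyrodiversity",
)


def standardize(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Center and scale to mean 0, SD 1.

    Returns ``(standardized, center, scale)`` where ``scale`` is the sample
    SD (``ddof=1``). The center/scale pair is kept so predictions on the
    standardized scale can be mapped back to natural units.

    Raises
    ------
    DegenerateCovariateError
        If fewer than 2 values or the input is constant.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateCovariateError("need a 1-d vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise DataValidationError("covariate contains non-finite values")
    center = float(x.mean())
    scale = float(x.std(ddof=SD_DDOF))
    if scale == 0.0:
        raise DegenerateCovariateError("constant covariate cannot be standardized")
    return (x - center) / scale, center, scale


def buffer_stats(
    landscape: "Landscape", site_xy: tuple[float, float], radius_m: float
) -> tuple[float, float]:
    """Mean and sample SD of severity within ``radius_m`` of a point.

    A raster cell belongs to the buffer when its center falls strictly
    within the circle. A single-cell buffer has SD 0 by convention.

    Raises
    ------
    EmptyBufferError
        If no cell center falls inside the circle.
    """
    if radius_m <= 0:
        raise EmptyBufferError("radius must be positive")
    x, y = float(site_xy[0]), float(site_xy[1])
    cell = landscape.cell_m
    ny, nx = landscape.severity.shape
    # restrict to the bounding box of the circle for speed
    i_lo = max(int((y - radius_m) / cell) - 1, 0)
    i_hi = min(int((y + radius_m) / cell) + 2, ny)
    j_lo = max(int((x - radius_m) / cell) - 1, 0)
    j_hi = min(int((x + radius_m) / cell) + 2, nx)
    if i_lo >= i_hi or j_lo >= j_hi:
        raise EmptyBufferError("buffer lies entirely off the raster")
    ii, jj = np.meshgrid(
        np.arange(i_lo, i_hi), np.arange(j_lo, j_hi), indexing="ij"
    )
    cy = (ii + 0.5) * cell
    cx = (jj + 0.5) * cell
    inside = (cx - x) ** 2 + (cy - y) ** 2 <= radius_m**2
    if not inside.any():
        raise EmptyBufferError("buffer intersects zero raster cells")
    vals = landscape.severity[i_lo:i_hi, j_lo:j_hi][inside]
    mean = float(vals.mean())
    sd = 0.0 if vals.size < 2 else float(vals.std(ddof=SD_DDOF))
    return mean, sd


def pyrodiversity_residuals(
    sev_vec: Sequence[float], sev_sd_vec: Sequence[float]
) -> np.ndarray:
    """Residuals of the OLS fit of buffer-severity SD on mean severity.

    Fits ``sev_sd ~ 1 + sev + sev^2`` and returns the residual vector: the
    pyrodiversity covariate. Residuals sum to zero and are orthogonal to
    ``sev`` and ``sev^2``.

    Raises
    ------
    CollinearityError
        If the quadratic design is rank deficient (e.g. fewer than 3
        distinct severity values).
    """
    sev = np.asarray(sev_vec, dtype=float)
    sev_sd = np.asarray(sev_sd_vec, dtype=float)
    if sev.shape != sev_sd.shape or sev.ndim != 1 or sev.size < 3:
        raise DataValidationError("sev and sev_sd must be equal-length vectors, n >= 3")
    if not (np.all(np.isfinite(sev)) and np.all(np.isfinite(sev_sd))):
        raise DataValidationError("non-finite values in severity vectors")
    X = np.column_stack([np.ones_like(sev), sev, sev**2])
    coef, _, rank, _ = np.linalg.lstsq(X, sev_sd, rcond=None)
    if rank < 3:
        raise CollinearityError(
            "severity design {1, sev, sev^2} is rank deficient "
            "(need >= 3 distinct severity values)"
        )
    return sev_sd - X @ coef


@dataclass
class DesignMatrices:
    """Standardized design matrices for one species-independent model scale.

    Attributes
    ----------
    X_det : (n_obs, 7) detection design; columns ``DET_COLUMNS``.
    X_occ : (n_periods, 6) occurrence design; columns ``OCC_COLUMNS``.
    obs_period : (n_obs,) index of the survey period of each nightly record.
    site_idx : (n_periods,) site index of each period (random-intercept group).
    area_idx : (n_periods,) wildfire-area index of each period.
    centers_scales : per-covariate ``{"center": c, "scale": s}`` used for
        standardization, for back-transforming predictions.
    radius_m : buffer radius the severity covariates were computed at.
    """

    X_det: np.ndarray
    X_occ: np.ndarray
    obs_period: np.ndarray
    site_idx: np.ndarray
    area_idx: np.ndarray
    centers_scales: dict[str, dict[str, float]] = field(default_factory=dict)
    radius_m: float | None = None
    det_columns: tuple[str, ...] = DET_COLUMNS
    occ_columns: tuple[str, ...] = OCC_COLUMNS

    @property
    def n_obs(self) -> int:
        return self.X_det.shape[0]

    @property
    def n_periods(self) -> int:
        return self.X_occ.shape[0]

    @property
    def n_sites(self) -> int:
        return int(self.site_idx.max()) + 1

    @property
    def n_areas(self) -> int:
        return int(self.area_idx.max()) + 1

    def validate(self) -> None:
        if not (np.all(np.isfinite(self.X_det)) and np.all(np.isfinite(self.X_occ))):
            raise DataValidationError("design matrices contain non-finite values")
        if self.obs_period.min() < 0 or self.obs_period.max() >= self.n_periods:
            raise DataValidationError("obs_period indexes outside the period range")


def site_severity_table(
    landscape: "Landscape",
    sites: pd.DataFrame,
    radii: Sequence[float] = RADII_M,
) -> pd.DataFrame:
    """Buffer severity mean/SD per site and radius.

    ``sites`` needs columns ``site_id, x, y``. Returns a copy with
    ``sev_<r>`` and ``sev_sd_<r>`` columns appended for each radius.
    """
    out = sites.copy()
    for r in radii:
        means, sds = [], []
        for _, row in sites.iterrows():
            m, s = buffer_stats(landscape, (row["x"], row["y"]), r)
            means.append(m)
            sds.append(s)
        out[f"sev_{int(r)}"] = means
        out[f"sev_sd_{int(r)}"] = sds
    return out


def build_design_matrices(
    design: "SurveyDesign",
    site_covs: pd.DataFrame,
    radius_m: float,
) -> DesignMatrices:
    """Assemble standardized detection and occurrence design matrices.

    The pyrodiversity residual regression is fitted across all survey
    periods entering the model at this scale (unburned periods included,
    with sev = sev_sd = 0), then standardized like every other continuous
    predictor. ``smm`` is a 0/1 indicator and is not standardized.
    """
    periods = design.periods.reset_index(drop=True)
    nights = design.nights
    sites = site_covs.set_index("site_id")

    period_pos = {pid: k for k, pid in enumerate(periods["period_id"])}
    obs_period = nights["period_id"].map(period_pos).to_numpy()

    cs: dict[str, dict[str, float]] = {}

    def _std(name: str, values: np.ndarray) -> np.ndarray:
        z, c, s = standardize(values)
        cs[name] = {"center": c, "scale": s}
        return z

    day = _std("day", nights["day"].to_numpy(dtype=float))
    day2 = day**2 if SQUARE_AFTER_STANDARDIZE else _std(
        "day2", nights["day"].to_numpy(dtype=float) ** 2
    )
    canopy = _std("canopy", periods["canopy"].to_numpy(dtype=float))
    noise = _std("noise", nights["noise"].to_numpy(dtype=float))
    temperature = _std("temperature", nights["temperature"].to_numpy(dtype=float))
    smm = periods["smm"].to_numpy(dtype=float)

    X_det = np.column_stack([
        np.ones(len(nights)),
        day,
        day2,
        canopy[obs_period],
        noise,
        temperature,
        smm[obs_period],
    ])

    site_rows = sites.loc[periods["site_id"]]
    elevation = _std("elevation", site_rows["elevation"].to_numpy(dtype=float))
    water = _std("water_distance", site_rows["water_distance"].to_numpy(dtype=float))
    sev_raw = site_rows[f"sev_{int(radius_m)}"].to_numpy(dtype=float)
    sev_sd_raw = site_rows[f"sev_sd_{int(radius_m)}"].to_numpy(dtype=float)
    pyro_raw = pyrodiversity_residuals(sev_raw, sev_sd_raw)
    sev = _std("severity", sev_raw)
    sev2 = sev**2 if SQUARE_AFTER_STANDARDIZE else _std("severity2", sev_raw**2)
    pyro = _std("pyrodiversity", pyro_raw)

    X_occ = np.column_stack([
        np.ones(len(periods)), elevation, water, sev, sev2, pyro,
    ])

    site_pos = {sid: k for k, sid in enumerate(sites.index)}
    site_idx = periods["site_id"].map(site_pos).to_numpy()
    area_ids = sites["area_id"]
    area_pos = {aid: k for k, aid in enumerate(sorted(area_ids.unique()))}
    area_idx = area_ids.loc[periods["site_id"]].map(area_pos).to_numpy()

    dm = DesignMatrices(
        X_det=X_det,
        X_occ=X_occ,
        obs_period=obs_period,
        site_idx=site_idx,
        area_idx=area_idx,
        centers_scales=cs,
        radius_m=float(radius_m),
    )
    dm.validate()
    return dm


def write_covariates(
    dm: DesignMatrices, out_dir: str | Path, prefix: str = "covariates"
) -> None:
    """Write occurrence-design covariates and the centers/scales sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r = int(dm.radius_m) if dm.radius_m else 0
    pd.DataFrame(dm.X_occ, columns=dm.occ_columns).assign(
        site_idx=dm.site_idx, area_idx=dm.area_idx
    ).to_csv(out / f"{prefix}_{r}.csv", index=False)
    with open(out / f"centers_scales_{r}.json", "w") as fh:
        json.dump(dm.centers_scales, fh, indent=2)
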