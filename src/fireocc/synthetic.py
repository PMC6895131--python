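"""Synthetic landscapes, survey designs and detection histories.

Generates data under exactly the model the analysis assumes, with known
parameters, for parameter-recovery and calibration studies. The landscape
is a spatially autocorrelated field of percent basal-area mortality
(smoothed Gaussian noise — only its marginal and buffer statistics matter
downstream, so no fire-spread mechanics are modeled), zeroed outside a
generated burn perimeter. Survey designs mirror the structure of a
multi-year acoustic monitoring program: sites at least 500 m apart, each
surveyed in one or more years (a site x year combination is a survey
period), with 1-17 survey nights per period and a median of 6.

All randomness flows from a single seed through named substreams
(landscape / design / detections).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from fireocc.exceptions import (
    InfeasibleDesignError,
    InvalidArgumentError,
    ShapeError,
)
from fireocc.occupancy import DetectionHistory

#: Four-letter codes for the 17-species Sierra Nevada bat community.
DEFAULT_SPECIES: tuple[str, ...] = (
    "ANPA", "COTO", "EPFU", "EUMA", "EUPE", "LABL", "LACI", "LANO",
    "MYCA", "MYCI", "MYEV", "MYLU", "MYTH", "MYVO", "MYYU", "PAHE", "TABR",
)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

@dataclass
class Landscape:
    """Raster of percent basal-area mortality with a burn-perimeter mask.

    Cells outside the perimeter are exactly 0 (area outside burn perimeters
    is unchanged forest). All severities lie in [0, 100].
    """

    severity: np.ndarray
    perimeter: np.ndarray
    cell_m: float

    def __post_init__(self) -> None:
        self.severity = np.asarray(self.severity, dtype=float)
        self.perimeter = np.asarray(self.perimeter, dtype=bool)
        if self.severity.shape != self.perimeter.shape:
            raise ShapeError("severity and perimeter rasters must align")
        if self.severity.min() < 0 or self.severity.max() > 100:
            raise InvalidArgumentError("severity must lie in [0, 100]")
        if np.any(self.severity[~self.perimeter] != 0.0):
            raise InvalidArgumentError("cells outside the perimeter must be 0")

    @property
    def extent_m(self) -> tuple[float, float]:
        """(x, y) extent in meters."""
        ny, nx = self.severity.shape
        return nx * self.cell_m, ny * self.cell_m


def generate_landscape(
    seed: int | np.random.SeedSequence | None,
    grid_size: int = 200,
    cell_m: float = 25.0,
    spatial_corr_length_m: float = 100.0,
    mean_severity: float = 45.0,
    sd_severity: float = 30.0,
    perimeter_frac: float = 0.65,
) -> Landscape:
    """Generate a spatially autocorrelated burn-severity raster.

    Gaussian white noise is smoothed with a Gaussian kernel of SD
    ``spatial_corr_length_m`` (0 disables smoothing), rescaled to the target
    mean/SD, clipped to [0, 100], and zeroed outside an irregular perimeter
    covering roughly ``perimeter_frac`` of the raster.
    """
    if grid_size < 20:
        raise InvalidArgumentError("grid_size must be >= 20 cells per side")
    if spatial_corr_length_m < 0 or cell_m <= 0:
        raise InvalidArgumentError("cell size must be positive and correlation length non-negative")
    if not 0.0 < perimeter_frac <= 1.0:
        raise InvalidArgumentError("perimeter_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((grid_size, grid_size))
    if spatial_corr_length_m > 0:
        fld = gaussian_filter(white, sigma=spatial_corr_length_m / cell_m,
                              mode="reflect")
        fld = (fld - fld.mean()) / fld.std()
    else:
        fld = white
    sev = np.clip(mean_severity + sd_severity * fld, 0.0, 100.0)

    if perimeter_frac >= 1.0:
        perim = np.ones_like(sev, dtype=bool)
    else:
        blob = gaussian_filter(rng.standard_normal((grid_size, grid_size)),
                               sigma=grid_size / 8, mode="reflect")
        perim = blob >= np.quantile(blob, 1.0 - perimeter_frac)
    sev = np.where(perim, sev, 0.0)
    return Landscape(severity=sev, perimeter=perim, cell_m=cell_m)


# ---------------------------------------------------------------------------
# survey design
# ---------------------------------------------------------------------------

@dataclass
class DesignConfig:
    """Distributions used to simulate the survey design.

    Nights per period follow a rounded lognormal (median
    ``exp(nights_log_median)`` = 6) truncated to [1, 17]. The remaining
    covariate distributions are design choices, documented here, since the
    monitoring protocol does not prescribe them.
    """

    min_separation_m: float = 500.0
    n_fire_areas: int = 3
    years_surveyed_probs: tuple[float, ...] = (0.52, 0.31, 0.15, 0.02)
    nights_log_median: float = float(np.log(6.0))
    nights_log_sd: float = 0.5
    nights_min: int = 1
    nights_max: int = 17
    season_length_days: float = 120.0
    noise_beta: tuple[float, float] = (1.5, 8.0)
    temperature_mean_c: float = 15.0
    temperature_sd_c: float = 5.0
    canopy_range: tuple[float, float] = (0.0, 90.0)
    smm_prob: float = 0.5
    elevation_range_m: tuple[float, float] = (1150.0, 2150.0)
    water_distance_scale_m: float = 300.0
    water_distance_max_m: float = 3000.0


@dataclass
class SurveyDesign:
    """Sites, survey periods (site x year) and survey nights.

    ``sites``: site_id, x, y (m), elevation, water_distance, area_id.
    ``periods``: period_id, site_id, year, n_nights, canopy, smm.
    ``nights``: period_id, night_index, day, noise, temperature.
    """

    sites: pd.DataFrame
    periods: pd.DataFrame
    nights: pd.DataFrame
    config: DesignConfig = field(default_factory=DesignConfig)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def n_nights(self) -> int:
        return len(self.nights)

    def nights_per_period(self) -> np.ndarray:
        return self.periods["n_nights"].to_numpy()


def draw_nights(rng: np.random.Generator, n: int,
                nights_rule: int | tuple | None,
                config: DesignConfig | None = None) -> np.ndarray:
    """Draw nights-per-period counts.

    ``nights_rule`` may be an int (every period has exactly that many
    nights), None (default rounded-lognormal rule, median 6, truncated to
    [1, 17]) or a callable ``rule(rng, n) -> array``.
    """
    cfg = config or DesignConfig()
    if callable(nights_rule):
        return np.asarray(nights_rule(rng, n), dtype=int)
    if nights_rule is not None:
        k = int(nights_rule)
        if not cfg.nights_min <= k <= cfg.nights_max:
            raise InvalidArgumentError("fixed night count outside [1, 17]")
        return np.full(n, k, dtype=int)
    raw = np.exp(rng.normal(cfg.nights_log_median, cfg.nights_log_sd, size=n))
    return np.clip(np.rint(raw), cfg.nights_min, cfg.nights_max).astype(int)


def _place_sites(rng, landscape, n_sites, min_sep):
    ex, ey = landscape.extent_m
    margin = min(ex, ey) * 0.02
    placed: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * n_sites
    min_sep2 = min_sep**2
    while len(placed) < n_sites:
        if attempts >= max_attempts:
            raise InfeasibleDesignError(
                f"could not place {n_sites} sites >= {min_sep} m apart "
                f"on a {ex:.0f} x {ey:.0f} m landscape"
            )
        attempts += 1
        x = rng.uniform(margin, ex - margin)
        y = rng.uniform(margin, ey - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep2 for px, py in placed):
            placed.append((x, y))
    return np.array(placed)


def sample_design(
    landscape: Landscape,
    n_sites: int = 122,
    n_years: int = 4,
    nights_rule: int | Callable | None = None,
    seed: int | np.random.SeedSequence | None = None,
    config: DesignConfig | None = None,
) -> SurveyDesign:
    """Simulate a multi-year acoustic survey design on a landscape.

    Sites are placed uniformly at random subject to the minimum-separation
    constraint; each is surveyed in a random subset of years (most sites in
    one year, few in all). Fire-area membership is assigned by equal
    vertical bands of the landscape, the nearest-fire analogue for unburned
    sites.

    Raises
    ------
    InfeasibleDesignError
        If the separation constraint cannot be met on this landscape.
    """
    cfg = config or DesignConfig()
    if n_sites < 1 or n_years < 1:
        raise InvalidArgumentError("need at least one site and one year")
    rng = np.random.default_rng(seed)
    xy = _place_sites(rng, landscape, n_sites, cfg.min_separation_m)
    ex, _ = landscape.extent_m
    area_id = np.minimum(
        (xy[:, 0] / (ex / cfg.n_fire_areas)).astype(int), cfg.n_fire_areas - 1
    )
    sites = pd.DataFrame({
        "site_id": [f"S{i:03d}" for i in range(n_sites)],
        "x": xy[:, 0],
        "y": xy[:, 1],
        "elevation": rng.uniform(*cfg.elevation_range_m, size=n_sites),
        "water_distance": np.minimum(
            rng.exponential(cfg.water_distance_scale_m, size=n_sites),
            cfg.water_distance_max_m,
        ),
        "area_id": area_id,
    })

    probs = np.asarray(cfg.years_surveyed_probs[:n_years], dtype=float)
    probs = probs / probs.sum()
    period_rows = []
    for i in range(n_sites):
        k = rng.choice(np.arange(1, len(probs) + 1), p=probs)
        years = np.sort(rng.choice(n_years, size=k, replace=False))
        for yr in years:
            period_rows.append((sites.loc[i, "site_id"], int(yr)))
    periods = pd.DataFrame(period_rows, columns=["site_id", "year"])
    periods.insert(0, "period_id",
                   [f"P{k:04d}" for k in range(len(periods))])
    n_p = len(periods)
    periods["n_nights"] = draw_nights(rng, n_p, nights_rule, cfg)
    periods["canopy"] = rng.uniform(*cfg.canopy_range, size=n_p)
    periods["smm"] = rng.random(n_p) < cfg.smm_prob

    night_rows = []
    for _, prow in periods.iterrows():
        j_n = int(prow["n_nights"])
        # alternate-night recording within a two-week deployment window
        start = rng.uniform(0.0, max(cfg.season_length_days - 2.0 * j_n, 1.0))
        for j in range(j_n):
            night_rows.append((prow["period_id"], j, start + 2.0 * j))
    nights = pd.DataFrame(night_rows,
                          columns=["period_id", "night_index", "day"])
    a, b = cfg.noise_beta
    nights["noise"] = rng.beta(a, b, size=len(nights))
    nights["temperature"] = rng.normal(cfg.temperature_mean_c,
                                       cfg.temperature_sd_c, size=len(nights))
    return SurveyDesign(sites=sites, periods=periods, nights=nights, config=cfg)


# ---------------------------------------------------------------------------
# detection simulation
# ---------------------------------------------------------------------------

@dataclass
class TrueParameters:
    """Generating parameters for one species (all on the logit scale)."""

    alpha: np.ndarray
    beta: np.ndarray
    sigma_site: float = 0.3
    sigma_area: float = 0.3
    species: str | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if not (np.all(np.isfinite(self.alpha)) and np.all(np.isfinite(self.beta))):
            raise InvalidArgumentError("coefficients must be finite")
        if self.sigma_site < 0 or self.sigma_area < 0:
            raise InvalidArgumentError("random-intercept SDs must be >= 0")

    @classmethod
    def random(cls, rng: np.random.Generator, n_det: int = 7, n_occ: int = 6,
               effect_sd: float = 0.5, sigma_site: float = 0.3,
               sigma_area: float = 0.3, species: str | None = None):
        """Draw a realistic coefficient set: modest logit-scale effects."""
        return cls(
            alpha=rng.normal(0.0, effect_sd, size=n_det),
            beta=rng.normal(0.0, effect_sd, size=n_occ),
            sigma_site=sigma_site, sigma_area=sigma_area, species=species,
        )


@dataclass
class SimulationTruth:
    """Latent quantities realized while simulating one species."""

    psi: np.ndarray
    z: np.ndarray
    p: np.ndarray
    b_site: np.ndarray
    b_area: np.ndarray
    params: TrueParameters


def simulate_detections(
    design_matrices,
    true_params: TrueParameters,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[DetectionHistory, SimulationTruth]:
    """Simulate one species' detection history from standardized designs.

    Occurrence ``z`` is drawn once per survey period (closure within the
    season; re-drawn across years), nightly detections independently given
    ``z``; an unoccupied period yields an all-zero history by construction.
    """
    dm = design_matrices
    params = true_params
    if dm.X_det.shape[1] != params.alpha.size or dm.X_occ.shape[1] != params.beta.size:
        raise ShapeError("design matrices and parameter dimensions disagree")
    rng = np.random.default_rng(seed)
    b_site = params.sigma_site * rng.standard_normal(dm.n_sites)
    b_area = params.sigma_area * rng.standard_normal(dm.n_areas)
    psi = expit(dm.X_occ @ params.beta + b_site[dm.site_idx] + b_area[dm.area_idx])
    z = (rng.random(dm.n_periods) < psi).astype(np.int8)
    p = expit(dm.X_det @ params.alpha)
    y = ((rng.random(dm.n_obs) < p) & (z[dm.obs_period] == 1)).astype(np.int8)
    hist = DetectionHistory(
        y=y, obs_period=dm.obs_period.copy(), n_periods=dm.n_periods,
        period_site=dm.site_idx.copy(), period_area=dm.area_idx.copy(),
        species=params.species,
    )
    truth = SimulationTruth(psi=psi, z=z, p=p, b_site=b_site, b_area=b_area,
                            params=params)
    return hist, truth


# ---------------------------------------------------------------------------
# end-to-end community simulation and file I/O
# ---------------------------------------------------------------------------

@dataclass
class CommunityDataset:
    """A complete simulated multi-species survey with known truth."""

    landscape: Landscape
    design: SurveyDesign
    site_covariates: pd.DataFrame
    design_matrices: object
    histories: dict[str, DetectionHistory]
    truths: dict[str, SimulationTruth]
    seed: int | None = None

    @property
    def species(self) -> list[str]:
        return list(self.histories)


def simulate_community(
    seed: int | None = None,
    species: Sequence[str] = DEFAULT_SPECIES,
    n_sites: int = 122,
    n_years: int = 4,
    radius_m: float = 250.0,
    landscape_kwargs: dict | None = None,
    design_kwargs: dict | None = None,
    params: dict[str, TrueParameters] | None = None,
    effect_sd: float = 0.5,
) -> CommunityDataset:
    """Simulate a full multi-species dataset end to end.

    Landscape, design and per-species detection randomness run on named
    substreams of ``seed``, so the landscape is reproducible independently
    of, say, the number of species simulated.
    """
    from fireocc import covariates as cov

    root = np.random.SeedSequence(seed)
    ss_land, ss_design, ss_pars, ss_det = root.spawn(4)
    # default to a 10 km landscape so the full 122-site design fits at
    # the 500 m minimum spacing
    land_kwargs = {"grid_size": 400, **(landscape_kwargs or {})}
    landscape = generate_landscape(ss_land, **land_kwargs)
    design = sample_design(landscape, n_sites=n_sites, n_years=n_years,
                           seed=ss_design, **(design_kwargs or {}))
    site_covs = cov.site_severity_table(landscape, design.sites)
    dm = cov.build_design_matrices(design, site_covs, radius_m)

    rng_pars = np.random.default_rng(ss_pars)
    if params is None:
        params = {
            sp: TrueParameters.random(rng_pars, n_det=dm.X_det.shape[1],
                                      n_occ=dm.X_occ.shape[1],
                                      effect_sd=effect_sd, species=sp)
            for sp in species
        }
    histories, truths = {}, {}
    for sp, sub in zip(params, ss_det.spawn(len(params))):
        histories[sp], truths[sp] = simulate_detections(dm, params[sp], sub)
    return CommunityDataset(
        landscape=landscape, design=design, site_covariates=site_covs,
        design_matrices=dm, histories=histories, truths=truths, seed=seed,
    )


def write_dataset(dataset: CommunityDataset, out_dir: str | Path) -> None:
    """Write the simulated dataset as plain-text files.

    Produces ``detections.csv`` (long format), ``sites.csv``,
    ``periods.csv``, ``nights.csv``, ``truth.json`` and the landscape as a
    plain-array raster with a JSON sidecar.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = dataset.design
    d.sites.merge(dataset.site_covariates.drop(columns=["x", "y", "elevation",
                                                        "water_distance",
                                                        "area_id"]),
                  on="site_id").to_csv(out / "sites.csv", index=False)
    d.periods.to_csv(out / "periods.csv", index=False)
    d.nights.to_csv(out / "nights.csv", index=False)

    period_ids = d.periods["period_id"].to_numpy()
    site_ids = d.periods["site_id"].to_numpy()
    years = d.periods["year"].to_numpy()
    rows = []
    for sp, hist in dataset.histories.items():
        night_idx = d.nights["night_index"].to_numpy()
        for k in range(hist.n_obs):
            i = hist.obs_period[k]
            rows.append((sp, site_ids[i], int(years[i]), int(night_idx[k]),
                         int(hist.y[k])))
    pd.DataFrame(rows, columns=["species", "site_id", "year", "night_index",
                                "y"]).to_csv(out / "detections.csv", index=False)

    truth = {
        sp: {
            "alpha": t.params.alpha.tolist(),
            "beta": t.params.beta.tolist(),
            "sigma_site": t.params.sigma_site,
            "sigma_area": t.params.sigma_area,
        }
        for sp, t in dataset.truths.items()
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)

    np.savetxt(out / "landscape_severity.txt", dataset.landscape.severity,
               fmt="%.3f")
    with open(out / "landscape_meta.json", "w") as fh:
        json.dump({"cell_m": dataset.landscape.cell_m,
                   "shape": list(dataset.landscape.severity.shape)}, fh)
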