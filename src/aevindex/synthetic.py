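"""Synthetic Earth-system-model output and penguin data.

Emulates the statistical structure the analysis assumes, so every stage
of the pipeline runs without downloads: monthly sea-ice concentration
and thickness with an austral seasonal cycle (September maximum,
February minimum) and a prescribed decline; coastal low-ice polynya
pockets with amplified chlorophyll and productivity during the growing
season; meridional temperature gradients with a warming trend; a
shelf-confined demersal-fish biomass field; ensemble members that
differ only through noise draws; colony tables on coastal cells; and
nest-count series drawn from the Adélie hierarchical growth model (the
generative twin used for parameter recovery).

The generator makes no attempt at ocean physics: noise is independent
Gaussian per cell and month (truncated to physical ranges), polynyas
are fixed circular pockets, and there is no spatial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage, stats

from aevindex.grid import Grid, ParameterError, great_circle_km, make_grid

#: monthly sea-ice amplitude (fraction of the latitudinal maximum);
#: September is the seasonal maximum, February the minimum
SEASONAL_ICE_FACTOR = {
    1: 0.30, 2: 0.22, 3: 0.28, 4: 0.45, 5: 0.60, 6: 0.72,
    7: 0.85, 8: 0.95, 9: 1.00, 10: 0.92, 11: 0.75, 12: 0.50,
}

GROWING_SEASON = (10, 11, 12, 1, 2, 3)

DEFAULT_NOISE_SD = {
    "SIC": 0.02, "SIT": 0.05, "SST": 0.10, "TBOT": 0.05,
    "CHL": 0.05, "NPP": 0.50, "DFP": 0.20,
}

FIELD_UNITS = {
    "SIC": "1", "SIT": "m", "SST": "degC", "TBOT": "degC",
    "CHL": "mg m-3", "NPP": "g C m-2 month-1", "DFP": "g m-2",
}


@dataclass
class PolynyaSpec:
    """A fixed circular low-ice pocket: center, radius, and openness.

    ``openness`` multiplies SIC and SIT inside the pocket (0 < openness
    ≤ 1; smaller = more open water).
    """

    lat: float
    lon: float
    radius_km: float
    openness: float

    def __post_init__(self):
        if self.radius_km <= 0:
            raise ParameterError("polynya radius must be positive")
        if not (0 < self.openness <= 1):
            raise ParameterError("openness factor must be in (0, 1]")


@dataclass
class ScenarioConfig:
    """Study conditions for the synthetic environment.

    Defaults are the desk-scale configuration: a 2° grid (built
    separately), 10 ensemble members, 1990–2100, ~0.25 °C of surface
    warming and 3% sea-ice decline per decade under a mid-high forcing
    trajectory, three coastal polynyas, and a two-fold chlorophyll bloom
    amplification inside them.
    """

    years: tuple[int, int] = (1990, 2100)
    n_members: int = 10
    warming_rate: float = 0.25  # °C per decade (SST; half applied to TBOT)
    ice_decline_rate: float = 0.03  # fraction per decade on SIC/SIT
    polynya_spec: list[PolynyaSpec] = dc_field(default_factory=lambda: [
        PolynyaSpec(-72.0, 15.0, 450.0, 0.3),   # Weddell sector
        PolynyaSpec(-73.0, 90.0, 450.0, 0.3),   # East Antarctic sector
        PolynyaSpec(-73.0, 185.0, 450.0, 0.3),  # Ross sector
        PolynyaSpec(-72.0, 245.0, 450.0, 0.3),  # Amundsen sector
        PolynyaSpec(-73.0, 285.0, 400.0, 0.3),  # Peninsula sector
    ])
    bloom_amplification: float = 2.0
    noise_sd: dict[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    seed: int = 0

    def __post_init__(self):
        if self.n_members < 1:
            raise ParameterError("need at least one ensemble member")
        if self.years[1] < self.years[0]:
            raise ParameterError("empty year range")


def antarctic_grid(lat_step: float = 2.0, lon_step: float = 2.0) -> Grid:
    """Desk-scale circumpolar grid with a synthetic continent.

    Land covers cells south of a gently undulating coastline around
    73–76°S, giving a wrap-continuous coast with embayments for colonies
    and polynyas to sit against.
    """
    grid = make_grid((-78.0, -50.0), lon_step=lon_step, lat_step=lat_step)
    lat2d, lon2d = grid.lat2d(), grid.lon2d()
    coast = -74.5 + 1.5 * np.sin(np.deg2rad(2.0 * lon2d))
    grid.land_mask = lat2d < coast
    return grid


def _ice_profile(lat: np.ndarray) -> np.ndarray:
    """Latitudinal sea-ice amplitude: 1 at the coast, 0 north of ~52°S."""
    return np.clip((-52.0 - lat) / 18.0, 0.0, 1.0)


def _polynya_mask(grid: Grid, spec: PolynyaSpec) -> np.ndarray:
    d = great_circle_km(spec.lat, spec.lon, grid.lat2d(), grid.lon2d())
    return (d <= spec.radius_km) & grid.ocean_mask


def shelf_mask(grid: Grid, width_cells: int = 2) -> np.ndarray:
    """Ocean cells within ``width_cells`` of land (longitude-wrap aware)."""
    land = np.concatenate([grid.land_mask[:, -width_cells:],
                           grid.land_mask,
                           grid.land_mask[:, :width_cells]], axis=1)
    near = ndimage.binary_dilation(land, iterations=width_cells)
    return near[:, width_cells:-width_cells] & grid.ocean_mask


def _time_axis(years: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    yy = np.repeat(np.arange(years[0], years[1] + 1), 12)
    mm = np.tile(np.arange(1, 13), years[1] - years[0] + 1)
    return yy, mm


def _wrap(arr: np.ndarray, year: np.ndarray, month: np.ndarray,
          grid: Grid, name: str) -> xr.DataArray:
    da = xr.DataArray(
        arr,
        dims=("member", "time", "lat", "lon"),
        coords={
            "member": np.arange(arr.shape[0]),
            "time": np.arange(arr.shape[1]),
            "lat": ("lat", grid.lat_centers),
            "lon": ("lon", grid.lon_centers),
            "year": ("time", year),
            "month": ("time", month),
        },
        name=name,
        attrs={"units": FIELD_UNITS[name]},
    )
    return da


def generate_environment(grid: Grid, config: ScenarioConfig) -> dict[str, xr.DataArray]:
    """Monthly environmental fields per ensemble member.

    Returns SIC, SIT, SST, TBOT, CHL, NPP, DFP as (member, time, lat,
    lon) arrays with ``year``/``month`` time coordinates.  Identical
    seeds give bit-identical output; members differ only through their
    noise draws.
    """
    rng = np.random.default_rng(config.seed)
    year, month = _time_axis(config.years)
    nt = year.size
    nm = config.n_members
    nlat, nlon = grid.shape
    lat2d = grid.lat2d()

    profile = _ice_profile(lat2d)  # (nlat, nlon)
    seas = np.array([SEASONAL_ICE_FACTOR[m] for m in month])  # (nt,)
    decade = (year - config.years[0]) / 10.0
    decline = (1.0 - config.ice_decline_rate) ** decade  # (nt,)
    grow = np.isin(month, GROWING_SEASON)

    poly_masks = [_polynya_mask(grid, p) for p in config.polynya_spec]

    def noise(name: str) -> np.ndarray:
        sd = config.noise_sd.get(name, 0.0)
        if sd == 0.0:
            return np.zeros((nm, nt, nlat, nlon))
        return rng.normal(0.0, sd, size=(nm, nt, nlat, nlon))

    # --- sea ice ---
    sic_base = profile[None, :, :] * (seas * decline)[:, None, None]  # (nt, nlat, nlon)
    sic = sic_base[None, ...] + noise("SIC")
    sit_base = 1.2 * sic_base**1.5
    sit = sit_base[None, ...] + noise("SIT")
    for p, mask in zip(config.polynya_spec, poly_masks):
        sic[..., mask] *= p.openness
        sit[..., mask] *= p.openness
    sic = np.clip(sic, 0.0, 1.0)
    sit = np.clip(sit, 0.0, None)

    # --- temperatures ---
    warm = config.warming_rate * decade  # (nt,)
    sst_base = (
        -1.5
        + 3.9 * (1.0 - profile)[None, :, :]
        + 1.2 * (1.0 - seas)[:, None, None]
        + warm[:, None, None]
    )
    sst = sst_base[None, ...] + noise("SST")
    tbot_base = -1.0 + 2.8 * (1.0 - profile)[None, :, :] + 0.5 * warm[:, None, None]
    tbot = tbot_base[None, ...] + noise("TBOT")

    # --- biology: chlorophyll blooms and productivity in ONDJFM ---
    bloom_season = np.where(grow, 1.0, 0.1)  # (nt,)
    chl_space = 0.3 + 2.0 * profile**2
    chl_base = chl_space[None, :, :] * bloom_season[:, None, None]
    chl = chl_base[None, ...] + noise("CHL")
    npp_base = 8.0 * chl_base
    npp = npp_base[None, ...] + noise("NPP")
    amp = np.where(grow, config.bloom_amplification, 1.0)  # (nt,)
    for mask in poly_masks:
        chl[..., mask] *= amp[None, :, None]
        npp[..., mask] *= amp[None, :, None]
    chl = np.clip(chl, 0.0, None)
    npp = np.clip(npp, 0.0, None)

    # --- demersal fish potential: elevated on the shelf band ---
    shelf = shelf_mask(grid)
    dfp_space = np.where(shelf, 4.0, 0.3)
    dfp = np.broadcast_to(dfp_space, (nm, nt, nlat, nlon)) + noise("DFP")
    dfp = np.clip(dfp, 0.0, None)

    land = grid.land_mask
    out = {}
    for name, arr in [("SIC", sic), ("SIT", sit), ("SST", sst), ("TBOT", tbot),
                      ("CHL", chl), ("NPP", npp), ("DFP", dfp)]:
        arr = np.asarray(arr, dtype=float).copy()
        arr[..., land] = np.nan
        out[name] = _wrap(arr, year, month, grid, name)
    return out


def generate_colonies(
    grid: Grid,
    n_colonies: int,
    abundance_range: tuple[float, float] = (500.0, 50000.0),
    seed: int = 0,
    species: str = "adelie",
) -> pd.DataFrame:
    """Colony table on coastal ocean cells, log-uniform abundances."""
    if n_colonies < 1:
        raise ParameterError("need at least one colony")
    coastal = shelf_mask(grid, width_cells=1)
    idx = np.argwhere(coastal)
    if idx.size == 0:
        raise ParameterError("grid has no coastal ocean cells")
    rng = np.random.default_rng(seed)
    replace = idx.shape[0] < n_colonies
    pick = rng.choice(idx.shape[0], size=n_colonies, replace=replace)
    lo, hi = abundance_range
    if lo <= 0 or hi < lo:
        raise ParameterError("abundance_range must be positive and increasing")
    abund = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_colonies))
    rows = idx[pick]
    return pd.DataFrame({
        "colony_id": [f"{species[:3]}_{i:03d}" for i in range(n_colonies)],
        "lat": grid.lat_centers[rows[:, 0]],
        "lon": grid.lon_centers[rows[:, 1]],
        "abundance": abund,
        "species": species,
    })


def generate_nest_counts(
    truth,
    sic_by_colony: np.ndarray,
    obs_error_sd: float | np.ndarray = 0.05,
    seed: int = 0,
    n_years: int = 40,
    start_year: int = 1979,
    lz0_range: tuple[float, float] = (4.0, 8.0),
):
    """Nest-count series from the hierarchical growth model (generative twin).

    Per colony *i*: mean growth μ_ri ~ N(β0 + β1·SIC̄_i + β2·SIC̄_i²,
    σ_r²); process sd σ_i ~ N⁺(γ, τ²); true log abundance lz_{i,t} ~
    N(lz_{i,t−1} + μ_ri, σ_i²); observed log count y_{i,t} ~ N(lz_{i,t},
    s_{i,t}²).  ``sic_by_colony`` may be per-colony long-term means or a
    (colony, year) series, which is averaged.  Returns a
    :class:`~aevindex.popdyn.NestCountSeries` carrying the latent truth
    (``lz_true``, ``mu_r_true``, ``sigma_i_true``) for recovery tests.
    """
    from aevindex.popdyn import NestCountSeries  # deferred: avoid cycle

    for name in ("sigma_r", "gamma", "tau"):
        if getattr(truth, name) < 0:
            raise ParameterError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    sic = np.asarray(sic_by_colony, dtype=float)
    sic_bar = sic.mean(axis=1) if sic.ndim == 2 else sic
    ncol = sic_bar.size
    quad = truth.beta0 + truth.beta1 * sic_bar + truth.beta2 * sic_bar**2
    mu_r = quad if truth.sigma_r == 0 else rng.normal(quad, truth.sigma_r)
    if truth.tau == 0:
        sigma_i = np.full(ncol, float(truth.gamma))
    else:
        a = -truth.gamma / truth.tau
        sigma_i = stats.truncnorm.rvs(
            a, np.inf, loc=truth.gamma, scale=truth.tau, size=ncol, random_state=rng
        )
    lz = np.empty((ncol, n_years))
    lz[:, 0] = rng.uniform(*lz0_range, size=ncol)
    for t in range(1, n_years):
        step = mu_r if np.all(sigma_i == 0) else rng.normal(mu_r, sigma_i)
        lz[:, t] = lz[:, t - 1] + step
    s = np.broadcast_to(np.asarray(obs_error_sd, dtype=float), (ncol, n_years)).copy()
    if np.any(s < 0):
        raise ParameterError("observation error sd must be non-negative")
    y = lz if np.all(s == 0) else rng.normal(lz, s)
    years = np.arange(start_year, start_year + n_years)
    series = NestCountSeries(
        colony_ids=[f"col_{i:03d}" for i in range(ncol)],
        years=years,
        log_counts=y,
        obs_sd=s,
        sic_bar=sic_bar,
    )
    series.lz_true = lz
    series.mu_r_true = np.asarray(mu_r, dtype=float)
    series.sigma_i_true = sigma_i
    return series
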