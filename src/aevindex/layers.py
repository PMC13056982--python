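"""The five trophic input layers of the ecosystem-value index.

NPP — net primary productivity summed over the austral growing season
(October–March); KGP — empirical Antarctic krill growth potential from
surface chlorophyll and SST; DFP — demersal fish biomass potential
masked to toothfish-habitable bottom temperatures (≤ 1 °C); EPP/APP —
Emperor and Adélie penguin accessibility, colony abundance spread over
the ocean by an exponential distance-decay kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from aevindex.grid import Grid, ParameterError, great_circle_km

GROWING_SEASON_MONTHS = (10, 11, 12, 1, 2, 3)  # ONDJFM

#: KGP validity range of the empirical model, °C
KGP_SST_RANGE = (-1.0, 5.0)
#: initial adult krill length, mm
KGP_DEFAULT_LENGTH_MM = 40.0

#: toothfish habitat limit on bottom temperature, °C (inclusive)
DFP_TBOT_MAX = 1.0

#: (calibration distance km, fraction of the colony that reaches it)
EPP_CALIBRATION = (414.0, 0.5)  # Emperor: mean dispersal distance, half reach it
APP_CALIBRATION = (1933.0, 1e-6)  # Adélie: maximum dispersal distance, one in 10⁶


@dataclass
class LayerStack:
    """The five input layers on a common grid, pre-scaling.

    Units: NPP g C m⁻² season⁻¹; KGP empirical growth-increment units
    (may be negative — the length term is negative at 40 mm); DFP g wet
    weight m⁻²; EPP/APP individuals with access.  NaN marks cells where
    a layer is undefined (e.g. SST outside the KGP range).
    """

    grid: Grid
    npp: np.ndarray
    kgp: np.ndarray
    dfp: np.ndarray
    epp: np.ndarray
    app: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"NPP": self.npp, "KGP": self.kgp, "DFP": self.dfp, "EPP": self.epp, "APP": self.app}


def growing_season_npp(npp_monthly: xr.DataArray, years: range | list[int]) -> np.ndarray:
    """Mean over seasons of the total ONDJFM NPP.

    A season labelled by start year *y* spans October–December of *y* and
    January–March of *y*+1; monthly values are summed within each season
    and averaged across the requested seasons (and ensemble members, if
    present).  Missing months raise with the offending (year, month)
    pairs listed.
    """
    years = list(years)
    if not years:
        raise ParameterError("empty season list")
    year = np.asarray(npp_monthly.year.values)
    month = np.asarray(npp_monthly.month.values)
    missing: list[tuple[int, int]] = []
    season_totals = []
    for y in years:
        want = [(y, m) for m in (10, 11, 12)] + [(y + 1, m) for m in (1, 2, 3)]
        idx = []
        for yy, mm in want:
            hit = np.nonzero((year == yy) & (month == mm))[0]
            if hit.size == 0:
                missing.append((yy, mm))
            else:
                idx.append(hit[0])
        if not missing:
            season_totals.append(npp_monthly.isel(time=idx).sum("time"))
    if missing:
        raise ParameterError(f"missing growing-season months (year, month): {missing}")
    total = xr.concat(season_totals, dim="season").mean("season")
    if "member" in total.dims:
        total = total.mean("member")
    return np.asarray(total.values, dtype=float)


def kgp_length(length_mm: float = KGP_DEFAULT_LENGTH_MM):
    """Length term of the krill growth model (negative for adult krill)."""
    L = np.asarray(length_mm, dtype=float)
    return -0.066 + 0.002 * L - 0.000061 * L**2


def kgp_food(chl, literal_form: bool = False):
    """Food (chlorophyll) term of the krill growth model.

    The default is the saturating form 0.385·Chl/(0.328 + Chl) from the
    underlying empirical krill-growth model: zero at zero chlorophyll and
    approaching 0.385 under ample food.  ``literal_form=True`` exposes
    the multiplicative variant 0.385·Chl/(0.328·Chl) for auditability;
    it is constant in chlorophyll and undefined at zero, so it is not
    used by default.
    """
    chl = np.asarray(chl, dtype=float)
    if np.any(chl < 0):
        raise ParameterError("chlorophyll must be non-negative")
    if literal_form:
        with np.errstate(divide="ignore", invalid="ignore"):
            return 0.385 * chl / (0.328 * chl)
    return 0.385 * chl / (0.328 + chl)


def kgp_temp(sst):
    """Temperature term: 0.0078·SST − 0.0101·SST², peaking at 0.386 °C."""
    sst = np.asarray(sst, dtype=float)
    return 0.0078 * sst - 0.0101 * sst**2


def kgp_temp_optimum() -> float:
    """Closed-form argmax of the temperature term (°C)."""
    return 0.0078 / (2.0 * 0.0101)


def kgp(
    chl,
    sst,
    length_mm: float = KGP_DEFAULT_LENGTH_MM,
    literal_food_form: bool = False,
):
    """Krill growth potential = length + food + temperature terms.

    NaN where SST is outside the [−1, 5] °C validity range of the
    empirical model.  Inputs broadcast; chlorophyll in mg m⁻³, SST in °C.
    """
    sst = np.asarray(sst, dtype=float)
    value = kgp_length(length_mm) + kgp_food(chl, literal_food_form) + kgp_temp(sst)
    valid = (sst >= KGP_SST_RANGE[0]) & (sst <= KGP_SST_RANGE[1])
    return np.where(valid, value, np.nan)


def seasonal_kgp(chl_monthly: xr.DataArray, sst_monthly: xr.DataArray) -> np.ndarray:
    """Growing-season (ONDJFM) mean KGP from monthly chlorophyll and SST.

    KGP is evaluated month by month (so the SST validity window applies
    per month) and averaged over growing-season months, members, and
    years; cells valid in no month are NaN.
    """
    sel = chl_monthly.month.isin(list(GROWING_SEASON_MONTHS))
    chl = chl_monthly.sel(time=sel)
    sst = sst_monthly.sel(time=chl.time)
    monthly = kgp(chl.values, sst.values)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(monthly, axis=tuple(range(monthly.ndim - 2)))
    return out


def dfp(fish_biomass, tbot) -> np.ndarray:
    """Demersal fish biomass potential masked to habitable bottom water.

    ``fish_biomass`` may carry a leading size-class axis, which is summed.
    Cells with bottom temperature above 1 °C (exclusive) are NaN:
    Antarctic toothfish habitat degrades above that limit.
    """
    biomass = np.asarray(fish_biomass, dtype=float)
    tbot = np.asarray(tbot, dtype=float)
    if biomass.ndim == tbot.ndim + 1:
        biomass = biomass.sum(axis=0)
    if biomass.shape != tbot.shape:
        raise ParameterError("fish biomass and bottom temperature are not congruent")
    return np.where(tbot <= DFP_TBOT_MAX, biomass, np.nan)


def decay_rate(calibration: tuple[float, float]) -> float:
    """Exponential decay rate k from (distance km, surviving fraction)."""
    distance, fraction = calibration
    if not (0.0 < fraction < 1.0):
        raise ParameterError("surviving fraction must be in (0, 1)")
    if distance <= 0:
        raise ParameterError("calibration distance must be positive")
    return -np.log(fraction) / distance


def accessibility(
    colonies: pd.DataFrame,
    grid: Grid,
    calibration: tuple[float, float],
) -> np.ndarray:
    """Penguin accessibility layer: Σ_colonies abundance·exp(−k·distance).

    ``colonies`` needs columns lat, lon, abundance.  Distances are
    great-circle from colony to cell center; k is set so the calibration
    fraction of a colony reaches the calibration distance (Emperor:
    half at 414 km; Adélie: 10⁻⁶ at 1933 km).
    """
    k = decay_rate(calibration)
    lat2d, lon2d = grid.lat2d(), grid.lon2d()
    out = np.zeros(grid.shape, dtype=float)
    for row in colonies.itertuples():
        d = great_circle_km(row.lat, row.lon, lat2d, lon2d)
        out += row.abundance * np.exp(-k * d)
    out[grid.land_mask] = np.nan
    return out


def compute_layers(
    grid: Grid,
    fields: dict[str, xr.DataArray],
    emperor_colonies: pd.DataFrame,
    adelie_colonies: pd.DataFrame,
    years: range | list[int],
) -> LayerStack:
    """Assemble the five-layer stack from monthly fields and colony tables.

    ``fields`` must hold NPP, CHL, SST, TBOT, and DFP monthly arrays (the
    DFP forcing is the raw biomass-potential field, masked here by the
    annual-mean bottom temperature).
    """
    npp = growing_season_npp(fields["NPP"], years)
    kgp_layer = seasonal_kgp(fields["CHL"], fields["SST"])
    tbot_mean = fields["TBOT"].mean([d for d in ("member", "time") if d in fields["TBOT"].dims])
    dfp_mean = fields["DFP"].mean([d for d in ("member", "time") if d in fields["DFP"].dims])
    dfp_layer = dfp(dfp_mean.values, tbot_mean.values)
    epp = accessibility(emperor_colonies, grid, EPP_CALIBRATION)
    app = accessibility(adelie_colonies, grid, APP_CALIBRATION)
    land = grid.land_mask
    for arr in (npp, kgp_layer, dfp_layer):
        arr[land] = np.nan
    return LayerStack(grid, npp, kgp_layer, dfp_layer, epp, app)
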