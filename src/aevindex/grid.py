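"""Grid geometry, management-region masks, and area-weighted statistics.

The analysis domain is a regular latitude/longitude grid south of 50°S.
Cell areas use the mid-latitude cosine rule A = R² cosφ Δφ Δλ (radians),
which for 1–2° cells agrees with the exact spherical expression to well
under a percent.  Longitudes live on [0, 360) and wrap: the cell at the
largest longitude is adjacent to the cell at the smallest.

Five circumpolar management regions (Weddell Sea WS, East Antarctic EA,
Ross Sea RS, Amundsen Sea AS, Antarctic Peninsula AP) are defined as
longitude sectors approximating the CCAMLR Marine Protected Area
planning domains; "Hemi" is their union.  Region statistics are computed
only over ocean cells south of 60°S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: Default longitude sectors (degrees east, [start, end) wrap-aware) for the
#: five management regions.  WS spans the 0°/360° seam (60°W–30°E).
DEFAULT_REGION_SECTORS: dict[str, list[tuple[float, float]]] = {
    "WS": [(300.0, 30.0)],
    "EA": [(30.0, 150.0)],
    "RS": [(150.0, 220.0)],
    "AS": [(220.0, 270.0)],
    "AP": [(270.0, 300.0)],
}

REGION_NAMES = ("WS", "EA", "RS", "AS", "AP")


class ParameterError(ValueError):
    """An argument is outside its documented range."""


class EmptyDomainError(ValueError):
    """A reduction was requested over an empty selection."""


@dataclass
class Grid:
    """Regular lat/lon grid with cell areas and a land mask.

    Attributes
    ----------
    lat_centers : (nlat,) array, degrees north, strictly increasing.
    lon_centers : (nlon,) array, degrees east in [0, 360).
    cell_area : (nlat, nlon) array, km² per cell.
    land_mask : (nlat, nlon) boolean array, True over land.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    cell_area: np.ndarray
    land_mask: np.ndarray

    def __post_init__(self) -> None:
        self.lat_centers = np.asarray(self.lat_centers, dtype=float)
        self.lon_centers = np.asarray(self.lon_centers, dtype=float)
        self.cell_area = np.asarray(self.cell_area, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if np.any(np.diff(self.lat_centers) <= 0):
            raise ParameterError("lat_centers must be strictly increasing")
        if np.any((self.lon_centers < 0) | (self.lon_centers >= 360)):
            raise ParameterError("lon_centers must lie in [0, 360)")
        if self.cell_area.shape != self.shape or self.land_mask.shape != self.shape:
            raise ParameterError("cell_area/land_mask shape mismatch with coordinates")
        if np.any(self.cell_area <= 0):
            raise ParameterError("cell areas must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)

    @property
    def ocean_mask(self) -> np.ndarray:
        return ~self.land_mask

    @property
    def lat_step(self) -> float:
        return float(self.lat_centers[1] - self.lat_centers[0]) if self.lat_centers.size > 1 else 0.0

    def lat2d(self) -> np.ndarray:
        return np.broadcast_to(self.lat_centers[:, None], self.shape)

    def lon2d(self) -> np.ndarray:
        return np.broadcast_to(self.lon_centers[None, :], self.shape)


def make_grid(
    lat_range: tuple[float, float] = (-78.0, -50.0),
    lon_step: float = 1.0,
    lat_step: float = 1.0,
) -> Grid:
    """Build a circumpolar grid of cell centers south of 50°S.

    ``lat_range`` gives the outer edges of the latitude band; cell centers
    are placed mid-cell so a −78..−60 band at 1° yields 18 rows.  The
    longitude axis always covers the full circle.  The default land mask is
    all ocean; callers (or the synthetic generator) stamp in a continent.
    """
    lat_lo, lat_hi = float(lat_range[0]), float(lat_range[1])
    if lat_step <= 0 or lon_step <= 0:
        raise ParameterError("grid steps must be positive")
    if not (-90.0 <= lat_lo < lat_hi <= -50.0):
        raise ParameterError("lat_range must be an increasing pair within [-90, -50]")
    nlat = (lat_hi - lat_lo) / lat_step
    nlon = 360.0 / lon_step
    if abs(nlat - round(nlat)) > 1e-9 or abs(nlon - round(nlon)) > 1e-9:
        raise ParameterError("steps must divide the latitude band and 360° evenly")
    nlat, nlon = int(round(nlat)), int(round(nlon))
    lats = lat_lo + lat_step * (np.arange(nlat) + 0.5)
    lons = lon_step * (np.arange(nlon) + 0.5)
    area_row = (
        EARTH_RADIUS_KM**2
        * np.cos(np.deg2rad(lats))
        * np.deg2rad(lat_step)
        * np.deg2rad(lon_step)
    )
    cell_area = np.broadcast_to(area_row[:, None], (nlat, nlon)).copy()
    return Grid(lats, lons, cell_area, np.zeros((nlat, nlon), dtype=bool))


def _sector_membership(lon: np.ndarray, sectors: list[tuple[float, float]]) -> np.ndarray:
    """Wrap-aware membership of longitudes in a list of [start, end) sectors."""
    member = np.zeros(lon.shape, dtype=bool)
    for start, end in sectors:
        start, end = start % 360.0, end % 360.0
        if start < end:
            member |= (lon >= start) & (lon < end)
        else:  # sector crosses the 0/360 seam
            member |= (lon >= start) | (lon < end)
    return member


@dataclass
class RegionSet:
    """Named boolean masks for the management regions plus their union.

    Masks are pairwise disjoint, cover only ocean cells south of 60°S, and
    ``hemi`` equals their union.
    """

    grid: Grid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def hemi(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out

    def names(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def validate(self) -> None:
        total = np.zeros(self.grid.shape, dtype=int)
        for m in self.masks.values():
            total += m.astype(int)
        if np.any(total > 1):
            raise ValueError("region masks overlap")
        union = self.hemi
        if np.any(union & self.grid.land_mask):
            raise ValueError("region masks cover land cells")
        if np.any(union & (self.grid.lat2d() >= -60.0)):
            raise ValueError("region masks extend north of 60°S")


def region_masks(
    grid: Grid,
    boundaries: dict[str, list[tuple[float, float]]] | None = None,
) -> RegionSet:
    """Build the region masks from a {name: [(lon_start, lon_end), ...]} spec.

    Sectors are half-open [start, end) in degrees east and may cross the
    0°/360° seam.  Overlapping sectors across regions raise.  Cells outside
    every sector, on land, or north of 60°S are unassigned.
    """
    if boundaries is None:
        boundaries = DEFAULT_REGION_SECTORS
    lon = grid.lon2d()
    south = grid.lat2d() < -60.0
    masks: dict[str, np.ndarray] = {}
    claimed = np.zeros(grid.shape, dtype=bool)
    for name, sectors in boundaries.items():
        m = _sector_membership(lon, sectors) & south & grid.ocean_mask
        if np.any(m & claimed):
            raise ParameterError(f"region {name!r} overlaps a previously defined region")
        claimed |= m
        masks[name] = m
    rs = RegionSet(grid, masks)
    rs.validate()
    return rs


def area_weighted_mean(
    field: np.ndarray,
    mask: np.ndarray,
    grid: Grid,
) -> tuple[float, float, int]:
    """Area-weighted mean, population std, and cell count over ``mask``.

    Weights are cell areas restricted to the mask; NaN cells are excluded
    from both the numerator and the weights.  The std divides by the total
    weight (weighted population formula, no dof correction).
    """
    field = np.asarray(field, dtype=float)
    sel = np.asarray(mask, dtype=bool) & np.isfinite(field)
    if not np.any(sel):
        raise EmptyDomainError("no finite cells selected")
    w = grid.cell_area[sel]
    v = field[sel]
    wsum = w.sum()
    mean = float(np.sum(w * v) / wsum)
    var = float(np.sum(w * (v - mean) ** 2) / wsum)
    return mean, float(np.sqrt(var)), int(sel.sum())


def great_circle_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth (haversine)."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(lon2) - np.deg2rad(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
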