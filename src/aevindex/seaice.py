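"""Seasonal sea-ice zone and polynya detection.

Polynyas are areas of reduced sea-ice concentration (SIC) or thickness
(SIT) enclosed by coastline and/or consolidated ice.  They are detected
as connected components of below-threshold cells, with two refinements
over a plain labelling:

* the longitude axis wraps, so a component spanning the 0°/360° seam is
  a single polynya;
* a below-threshold component in contact with the open ocean — here
  operationalized as touching the northernmost row of the analysis
  domain — is the ambient ice-free ocean, not a polynya, and is
  discarded.  What remains is enclosed by land and/or above-threshold
  ice, which is the defining property of a polynya.

Default thresholds: 0.4 m SIT for model fields, 85% SIC for
satellite-like fields; the variable choice is a configuration switch
with SIT as the model default.  "Typical" polynya cells are those inside
a detected polynya in strictly more than 10% of time steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import ndimage

from aevindex.grid import ParameterError

#: polynya thresholds by variable: model SIT in metres, satellite SIC fraction
DEFAULT_THRESHOLDS = {"sit": 0.4, "sic": 0.85}
DEFAULT_FREQ_CUTOFF = 0.10
SIZ_SIC_THRESHOLD = 0.15


@dataclass
class PolynyaMap:
    """Labelled polynya components and the frequency-derived typical mask.

    ``labels`` has shape (ntime, nlat, nlon) with 0 meaning "not in a
    polynya"; positive integers number the components per time step.
    """

    labels: np.ndarray
    frequency_field: np.ndarray
    typical_mask: np.ndarray
    threshold_used: float
    variable: str
    connectivity: int
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF


def seasonal_ice_zone(sic: xr.DataArray, years: range | list[int] | None = None) -> np.ndarray:
    """Ocean cells whose multi-year September-mean SIC is ≥ 15%.

    ``sic`` must carry ``year`` and ``month`` coordinates on its time
    dimension (fraction units).  An ensemble ``member`` dimension, if
    present, is averaged over.
    """
    sel = sic.month == 9
    if years is not None:
        sel = sel & sic.year.isin(list(years))
    sep = sic.sel(time=sel)
    if sep.sizes.get("time", 0) == 0:
        raise ParameterError("no September time steps in the requested years")
    dims = [d for d in ("member", "time") if d in sep.dims]
    mean = sep.mean(dim=dims)
    return np.asarray(mean.values >= SIZ_SIC_THRESHOLD)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ParameterError("connectivity must be 4 or 8")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _merge_wrap(labels: np.ndarray, connectivity: int) -> np.ndarray:
    """Merge components adjacent across the 0°/360° longitude seam."""
    nlab = labels.max()
    if nlab == 0:
        return labels
    uf = _UnionFind(nlab + 1)
    left, right = labels[:, 0], labels[:, -1]
    nlat = labels.shape[0]
    pairs = []
    for i in range(nlat):
        if left[i] and right[i]:
            pairs.append((left[i], right[i]))
        if connectivity == 8:
            for j in (i - 1, i + 1):
                if 0 <= j < nlat and left[i] and right[j]:
                    pairs.append((left[i], right[j]))
    for a, b in pairs:
        uf.union(int(a), int(b))
    if not pairs:
        return labels
    remap = np.arange(nlab + 1)
    for k in range(1, nlab + 1):
        remap[k] = uf.find(k)
    return remap[labels]


def detect_polynyas(
    field: np.ndarray,
    threshold: float,
    land_mask: np.ndarray,
    connectivity: int = 4,
) -> np.ndarray:
    """Label enclosed below-threshold components at one time step.

    Returns an integer label field (0 = none), with components numbered
    1..n.  Cells with ``field < threshold`` over ocean are candidates;
    candidate components touching the northernmost row (open-ocean
    contact) are discarded; labelling is longitude-wrap aware.
    """
    field = np.asarray(field, dtype=float)
    land_mask = np.asarray(land_mask, dtype=bool)
    if field.shape != land_mask.shape:
        raise ParameterError("field and land mask shapes differ")
    if land_mask.all():
        raise ParameterError("all-land field: nothing to detect")
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    below = (field < threshold) & ~land_mask & np.isfinite(field)
    labels, _ = ndimage.label(below, structure=_structure(connectivity))
    labels = _merge_wrap(labels, connectivity)
    # discard the open-ocean component(s): any component with a cell in the
    # northernmost row of the domain is connected to the open boundary
    open_labels = np.unique(labels[-1, :])
    open_labels = open_labels[open_labels > 0]
    if open_labels.size:
        labels = np.where(np.isin(labels, open_labels), 0, labels)
    # renumber 1..n
    kept = np.unique(labels)
    kept = kept[kept > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=int)
    remap[kept] = np.arange(1, kept.size + 1)
    return remap[labels]


def polynya_frequency(
    label_maps: np.ndarray, cutoff: float = DEFAULT_FREQ_CUTOFF
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell polynya occurrence fraction and the typical-polynya mask.

    A cell is "typical" when it is inside a detected polynya in strictly
    more than ``cutoff`` of the supplied time steps (default 10%).
    """
    label_maps = np.asarray(label_maps)
    if label_maps.ndim == 2:
        label_maps = label_maps[None, ...]
    if label_maps.shape[0] == 0:
        raise ParameterError("need at least one time step")
    freq = (label_maps > 0).mean(axis=0)
    return freq, freq > cutoff


def detect_polynya_series(
    field: xr.DataArray,
    land_mask: np.ndarray,
    variable: str = "sit",
    threshold: float | None = None,
    connectivity: int = 4,
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
) -> PolynyaMap:
    """Run the detector over every time step of a (time, lat, lon) field.

    An ensemble ``member`` dimension, if present, is averaged over before
    detection (detection operates on the ensemble-mean ice state).
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[variable]
    if "member" in field.dims:
        field = field.mean("member")
    arr = np.asarray(field.transpose("time", "lat", "lon").values)
    labels = np.stack(
        [detect_polynyas(arr[t], threshold, land_mask, connectivity) for t in range(arr.shape[0])]
    )
    freq, typical = polynya_frequency(labels, freq_cutoff)
    return PolynyaMap(labels, freq, typical, threshold, variable, connectivity, freq_cutoff)
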