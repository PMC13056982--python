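"""The composite ecosystem-value index and its summary statistics.

Each of the five trophic layers is scaled by its maximum over the whole
domain and the scaled layers are summed cell-wise; the sum is then
rescaled to [0, 1] by the maximum within each management region
("regional" mode) or over all regions at once ("hemispheric" mode).
Cells are binned by within-region percentile rank — exceptional (top
5%), very high (next 5%), high (next 15%), other — and summarised
against polynya and protected-area masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aevindex.grid import (
    EmptyDomainError,
    Grid,
    ParameterError,
    RegionSet,
    area_weighted_mean,
)
from aevindex.layers import LayerStack

LAYER_NAMES = ("NPP", "KGP", "DFP", "EPP", "APP")
BIN_LABELS = ("other", "high", "very_high", "exceptional")
DEFAULT_CUTOFFS = (5.0, 10.0, 25.0)  # top-percent thresholds


@dataclass
class AevResult:
    """Index values, bins, scaled layers, and region assignment per cell.

    ``aev`` is NaN outside the evaluated domain; ``bins`` holds codes
    indexing :data:`BIN_LABELS` (−1 where undefined); ``region_tag``
    holds region names ('' where unassigned).
    """

    grid: Grid
    regions: RegionSet
    mode: str
    aevsum: np.ndarray
    aev: np.ndarray
    scaled_layers: dict[str, np.ndarray]
    bins: np.ndarray | None = None
    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS
    region_tag: np.ndarray = field(default=None)

    def bin_mask(self, label: str) -> np.ndarray:
        if self.bins is None:
            raise ValueError("bins not computed; call bin_percentiles first")
        return self.bins == BIN_LABELS.index(label)


def scale_and_sum(
    layers: LayerStack, zone_mask: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Max-scale each layer over the domain and sum them cell-wise.

    ``zone_mask`` restricts the domain (seasonal sea-ice zone ∩ ocean).
    Within the zone a layer's missing cells contribute 0 — otherwise the
    shelf-only fish layer and the SST-limited krill layer would erase
    most of the domain; outside the zone the sum is NaN.  A layer with
    no positive value anywhere contributes 0 everywhere (warned).
    """
    zone = np.asarray(zone_mask, dtype=bool) & layers.grid.ocean_mask
    total = np.zeros(layers.grid.shape, dtype=float)
    scaled: dict[str, np.ndarray] = {}
    for name, arr in layers.as_dict().items():
        vals = np.where(zone, arr, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mx = np.nanmax(vals) if np.isfinite(vals).any() else np.nan
        if not np.isfinite(mx) or mx <= 0:
            warnings.warn(f"layer {name} has no positive values; it contributes 0")
            s = np.zeros_like(total)
        else:
            s = np.where(np.isfinite(vals), vals / mx, 0.0)
        s = np.where(zone, s, np.nan)
        scaled[name] = s
        total += np.where(zone, np.nan_to_num(s), 0.0)
    total = np.where(zone, total, np.nan)
    return total, scaled


def regional_index(
    layers_or_sum,
    regions: RegionSet,
    mode: str = "regional",
    zone_mask: np.ndarray | None = None,
    scaled_layers: dict[str, np.ndarray] | None = None,
) -> AevResult:
    """Rescale the summed field to [0, 1] by the per-region (or overall) max.

    Accepts either a :class:`LayerStack` (with ``zone_mask``) or a
    pre-computed summed field plus its scaled layers.  In regional mode
    each region is divided by its own maximum; in hemispheric mode the
    single maximum over the union of regions is used.  Cells outside all
    regions are NaN.
    """
    if mode not in ("regional", "hemispheric"):
        raise ParameterError("mode must be 'regional' or 'hemispheric'")
    if isinstance(layers_or_sum, LayerStack):
        if zone_mask is None:
            raise ParameterError("zone_mask required when passing a LayerStack")
        aevsum, scaled_layers = scale_and_sum(layers_or_sum, zone_mask)
        grid = layers_or_sum.grid
    else:
        aevsum = np.asarray(layers_or_sum, dtype=float)
        grid = regions.grid
        if scaled_layers is None:
            scaled_layers = {}
    aev = np.full(grid.shape, np.nan)
    tag = np.full(grid.shape, "", dtype=object)
    if mode == "hemispheric":
        groups = [("Hemi", regions.hemi)]
    else:
        groups = list(regions.masks.items())
    for name, mask in groups:
        sel = mask & np.isfinite(aevsum)
        if not np.any(sel):
            continue
        mx = np.max(aevsum[sel])
        if mx <= 0:
            warnings.warn(f"region {name} has an all-zero index sum; left missing")
            continue
        aev[sel] = aevsum[sel] / mx
    for name, mask in regions.masks.items():
        tag[mask] = name
    return AevResult(grid, regions, mode, aevsum, aev, scaled_layers, region_tag=tag)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Linear-interpolated quantile of values under weights."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return float(np.interp(q, cw, v))


def bin_percentiles(
    result: AevResult,
    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS,
    area_weighted: bool = False,
) -> np.ndarray:
    """Assign percentile bins per region: top 5% / 5–10% / 10–25% / rest.

    Quantiles use linear interpolation of order statistics and the strict
    rule "cells strictly above the cutoff enter the higher bin" (so a
    constant region is entirely 'other').  Percentiles are unweighted
    cell counts by default; ``area_weighted=True`` weights by cell area.
    The bin codes are stored on ``result.bins`` and returned.
    """
    c1, c2, c3 = cutoffs
    if not (0 < c1 < c2 < c3 < 100):
        raise ParameterError("cutoffs must be increasing percentages in (0, 100)")
    bins = np.full(result.grid.shape, -1, dtype=int)
    groups = (
        [("Hemi", result.regions.hemi)]
        if result.mode == "hemispheric"
        else list(result.regions.masks.items())
    )
    for name, mask in groups:
        sel = mask & np.isfinite(result.aev)
        vals = result.aev[sel]
        if vals.size == 0:
            warnings.warn(f"region {name} empty; skipped in binning")
            continue
        if area_weighted:
            w = result.grid.cell_area[sel]
            qs = [_weighted_quantile(vals, w, 1 - c / 100.0) for c in cutoffs]
        else:
            qs = [float(np.quantile(vals, 1 - c / 100.0)) for c in cutoffs]
        code = np.zeros(vals.size, dtype=int)
        code[vals > qs[2]] = 1  # high
        code[vals > qs[1]] = 2  # very high
        code[vals > qs[0]] = 3  # exceptional
        bins[sel] = code
    result.bins = bins
    result.cutoffs = tuple(cutoffs)
    return bins


def percent_difference(mean_in: float, mean_out: float) -> float:
    """Symmetric percent difference 100·(in − out) / (½·(in + out))."""
    denom = 0.5 * (mean_in + mean_out)
    if denom == 0:
        raise ParameterError("zero denominator in percent difference")
    return 100.0 * (mean_in - mean_out) / denom


def _pct_area(inside: np.ndarray, of: np.ndarray, grid: Grid) -> float:
    denom = grid.cell_area[of].sum()
    if denom == 0:
        return np.nan
    return 100.0 * grid.cell_area[of & inside].sum() / denom


def polynya_region_stats(
    result: AevResult,
    typical_mask: np.ndarray,
    include_hemi: bool = True,
) -> pd.DataFrame:
    """Per-region index statistics inside vs outside typical polynyas.

    Rows: area-weighted mean/std of the index inside and outside the
    polynya mask, their symmetric percent difference, the percent of
    regional area inside polynyas, and the percent of each bin's area
    inside polynyas.  Columns: regions (plus 'Hemi').
    """
    grid = result.grid
    poly = np.asarray(typical_mask, dtype=bool)
    cols = list(result.regions.masks.items())
    if include_hemi:
        cols.append(("Hemi", result.regions.hemi))
    rows = {}
    for name, mask in cols:
        domain = mask & np.isfinite(result.aev)
        entry: dict[str, float] = {}
        inside = domain & poly
        outside = domain & ~poly
        for tag, m in (("inside", inside), ("outside", outside)):
            try:
                mean, std, _ = area_weighted_mean(result.aev, m, grid)
            except EmptyDomainError:
                mean, std = np.nan, np.nan
                warnings.warn(f"region {name}: no cells {tag} polynyas")
            entry[f"avg_{tag}_poly"] = mean
            entry[f"std_{tag}_poly"] = std
        if np.isfinite(entry["avg_inside_poly"]) and np.isfinite(entry["avg_outside_poly"]):
            entry["pct_difference"] = percent_difference(
                entry["avg_inside_poly"], entry["avg_outside_poly"]
            )
        else:
            entry["pct_difference"] = np.nan
        entry["pct_area_inside_poly"] = _pct_area(poly, domain, grid)
        if result.bins is not None:
            for label in BIN_LABELS:
                bmask = domain & (result.bins == BIN_LABELS.index(label))
                entry[f"pct_{label}_inside_poly"] = (
                    _pct_area(poly, bmask, grid) if bmask.any() else np.nan
                )
        rows[name] = entry
    return pd.DataFrame(rows)


def mpa_overlap(result: AevResult, mpa_mask: np.ndarray, include_hemi: bool = True) -> pd.DataFrame:
    """Percent of each region's (and bin's) area inside the protected mask."""
    grid = result.grid
    mpa = np.asarray(mpa_mask, dtype=bool)
    cols = list(result.regions.masks.items())
    if include_hemi:
        cols.append(("Hemi", result.regions.hemi))
    rows = {}
    for name, mask in cols:
        domain = mask & np.isfinite(result.aev)
        entry = {"pct_area_inside_mpa": _pct_area(mpa, domain, grid)}
        if result.bins is not None:
            for label in BIN_LABELS:
                bmask = domain & (result.bins == BIN_LABELS.index(label))
                entry[f"pct_{label}_inside_mpa"] = (
                    _pct_area(mpa, bmask, grid) if bmask.any() else np.nan
                )
        rows[name] = entry
    return pd.DataFrame(rows)


def layer_contributions(
    result: AevResult,
    masks: dict[str, np.ndarray] | None = None,
    ambiguity_factor: float = 1.1,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-cell percent contribution of each layer, averaged over masks.

    contribution_k = 100·scaled_k / AEVsum, so contributions sum to 100
    at every cell with a positive sum.  Returns (table, dominant, ambiguous):
    the table holds area-weighted mean contributions per mask; ``dominant``
    is the argmax layer index per cell (−1 undefined); ``ambiguous`` flags
    cells where the top contribution is less than ``ambiguity_factor``
    times the second.
    """
    if not result.scaled_layers:
        raise ParameterError("scaled layers unavailable on this result")
    grid = result.grid
    stack = np.stack([np.nan_to_num(result.scaled_layers[k]) for k in LAYER_NAMES])
    valid = np.isfinite(result.aevsum) & (result.aevsum > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(valid, 100.0 * stack / result.aevsum, np.nan)
    order = np.sort(contrib, axis=0)
    top, second = order[-1], order[-2]
    dominant = np.where(valid, np.argmax(contrib, axis=0), -1)
    with np.errstate(invalid="ignore"):
        ambiguous = valid & (top < ambiguity_factor * second)
    if masks is None:
        masks = {"domain": valid}
    rows = {}
    for name, mask in masks.items():
        sel = np.asarray(mask, dtype=bool) & valid
        entry = {}
        for k, lname in enumerate(LAYER_NAMES):
            try:
                mean, _, _ = area_weighted_mean(contrib[k], sel, grid)
            except EmptyDomainError:
                mean = np.nan
            entry[lname] = mean
        rows[name] = entry
    return pd.DataFrame(rows), dominant, ambiguous
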