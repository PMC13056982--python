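"""End-to-end pipeline: synthetic or file inputs → layers → masks → index → tables.

The default configuration is a desk-scale demonstration: the synthetic
2° environment over 1998–2003 with 5 ensemble members, the 2000s
analysis window (1998–2002), model-style polynya detection on sea-ice
thickness, and the regional index with 5/10/25 percentile bins.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import xarray as xr
import yaml

from aevindex import io as aev_io
from aevindex.grid import DEFAULT_REGION_SECTORS, ParameterError, region_masks
from aevindex.index import (
    DEFAULT_CUTOFFS,
    bin_percentiles,
    layer_contributions,
    mpa_overlap,
    polynya_region_stats,
    regional_index,
)
from aevindex.layers import compute_layers
from aevindex.seaice import (
    DEFAULT_FREQ_CUTOFF,
    DEFAULT_THRESHOLDS,
    SIZ_SIC_THRESHOLD,
    detect_polynya_series,
    seasonal_ice_zone,
)
from aevindex.synthetic import ScenarioConfig, antarctic_grid, generate_colonies

log = logging.getLogger("aevindex")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, round-trippable through YAML."""

    scenario: ScenarioConfig = dc_field(default_factory=lambda: ScenarioConfig(
        years=(1998, 2003), n_members=5))
    lat_step: float = 2.0
    lon_step: float = 2.0
    analysis_years: tuple[int, int] = (1998, 2002)
    region_sectors: dict = dc_field(default_factory=lambda: {
        k: [list(s) for s in v] for k, v in DEFAULT_REGION_SECTORS.items()})
    siz_threshold: float = SIZ_SIC_THRESHOLD
    polynya_variable: str = "sit"
    polynya_threshold: float | None = None
    polynya_connectivity: int = 4
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF
    bin_cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS
    mode: str = "regional"
    n_emperor_colonies: int = 66
    n_adelie_colonies: int = 287
    seed: int = 0
    fields_path: str | None = None  # read inputs instead of simulating

    def validate(self) -> None:
        problems = []
        if not (0 < self.siz_threshold < 1):
            problems.append("siz_threshold must be a fraction in (0, 1)")
        if self.polynya_variable not in ("sic", "sit"):
            problems.append("polynya_variable must be 'sic' or 'sit'")
        thr = self.polynya_threshold
        if thr is not None and thr <= 0:
            problems.append("polynya_threshold must be positive")
        if not (0 <= self.freq_cutoff < 1):
            problems.append("freq_cutoff must be in [0, 1)")
        if self.polynya_connectivity not in (4, 8):
            problems.append("polynya_connectivity must be 4 or 8")
        c = self.bin_cutoffs
        if not (0 < c[0] < c[1] < c[2] < 100):
            problems.append("bin_cutoffs must be increasing percentages")
        if self.mode not in ("regional", "hemispheric"):
            problems.append("mode must be 'regional' or 'hemispheric'")
        y0, y1 = self.analysis_years
        sy0, sy1 = self.scenario.years
        if self.fields_path is None and not (sy0 <= y0 <= y1 < sy1):
            problems.append(
                "analysis_years must lie inside scenario years with one spare "
                "year for the final growing season")
        if self.fields_path is not None and not Path(self.fields_path).exists():
            problems.append(f"fields_path does not exist: {self.fields_path}")
        if problems:
            raise ParameterError("invalid configuration: " + "; ".join(problems))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scenario" in d and isinstance(d["scenario"], dict):
            sc = dict(d["scenario"])
            if "years" in sc:
                sc["years"] = tuple(sc["years"])
            if "polynya_spec" in sc:
                from aevindex.synthetic import PolynyaSpec
                sc["polynya_spec"] = [PolynyaSpec(**p) for p in sc["polynya_spec"]]
            d["scenario"] = ScenarioConfig(**sc)
        for key in ("analysis_years", "bin_cutoffs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run ingestion → layers → sea-ice masks → index → summary tables.

    Returns a dict with the :class:`~aevindex.index.AevResult`, the
    polynya/MPA/contribution tables, the masks, and (when ``outdir`` is
    given) the paths written.  Deterministic under a fixed config.
    """
    config.validate()
    grid = antarctic_grid(config.lat_step, config.lon_step)
    if config.fields_path is not None:
        fields = aev_io.read_fields(config.fields_path)
    else:
        fields = __import__("aevindex.synthetic", fromlist=["generate_environment"]) \
            .generate_environment(grid, config.scenario)
    y0, y1 = config.analysis_years
    years = range(y0, y1 + 1)
    log.info("thresholds: SIZ SIC >= %.2f; polynya %s < %s; frequency > %.2f",
             config.siz_threshold, config.polynya_variable,
             config.polynya_threshold or DEFAULT_THRESHOLDS[config.polynya_variable],
             config.freq_cutoff)

    regions = region_masks(grid, {k: [tuple(s) for s in v]
                                  for k, v in config.region_sectors.items()})
    zone = seasonal_ice_zone(fields["SIC"], years) & grid.ocean_mask
    zone &= grid.lat2d() < -60.0

    ice_var = fields["SIC" if config.polynya_variable == "sic" else "SIT"]
    ice_sel = ice_var.sel(time=ice_var.year.isin(list(years)))
    polynyas = detect_polynya_series(
        ice_sel, grid.land_mask, config.polynya_variable,
        config.polynya_threshold, config.polynya_connectivity, config.freq_cutoff)

    emperor = generate_colonies(grid, config.n_emperor_colonies,
                                (200.0, 30000.0), seed=config.seed + 1, species="emperor")
    adelie = generate_colonies(grid, config.n_adelie_colonies,
                               (100.0, 60000.0), seed=config.seed + 2, species="adelie")

    layers = compute_layers(grid, fields, emperor, adelie, years)
    result = regional_index(layers, regions, config.mode, zone_mask=zone)
    bin_percentiles(result, config.bin_cutoffs)

    mpa = synthetic_mpa_mask(grid, regions)
    poly_table = polynya_region_stats(result, polynyas.typical_mask)
    mpa_table = mpa_overlap(result, mpa)
    contrib_table, dominant, ambiguous = layer_contributions(
        result, {"inside_polynya": polynyas.typical_mask,
                 "outside_polynya": ~polynyas.typical_mask})

    out = {
        "grid": grid, "regions": regions, "zone": zone, "polynyas": polynyas,
        "layers": layers, "result": result, "mpa_mask": mpa,
        "polynya_table": poly_table, "mpa_table": mpa_table,
        "contribution_table": contrib_table,
        "dominant_layer": dominant, "ambiguous": ambiguous,
        "colonies": {"emperor": emperor, "adelie": adelie},
    }
    if outdir is not None:
        out["paths"] = _write_outputs(config, out, Path(outdir))
    return out


def synthetic_mpa_mask(grid, regions) -> np.ndarray:
    """Stand-in protected-area mask (synthetic): the southern shelf of the
    Ross Sea and Weddell Sea sectors, mimicking large coastal MPAs."""
    mask = np.zeros(grid.shape, dtype=bool)
    for name in ("RS", "WS"):
        if name in regions.masks:
            mask |= regions.masks[name] & (grid.lat2d() < -68.0)
    return mask


def _write_outputs(config: PipelineConfig, out: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    grid, result = out["grid"], out["result"]
    coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}
    ds = xr.Dataset(
        {
            "aev": (("lat", "lon"), result.aev, {"units": "1"}),
            "aevsum": (("lat", "lon"), result.aevsum, {"units": "1"}),
            "bin": (("lat", "lon"), result.bins.astype("i1"),
                    {"units": "1", "flag_meanings": "other high very_high exceptional"}),
            "typical_polynya": (("lat", "lon"),
                                out["polynyas"].typical_mask.astype("i1"), {"units": "1"}),
            "seasonal_ice_zone": (("lat", "lon"), out["zone"].astype("i1"), {"units": "1"}),
        },
        coords=coords,
    )
    paths = {"aev": outdir / "aev.nc"}
    ds.to_netcdf(paths["aev"], engine="scipy")
    for key, name in [("polynya_table", "table_polynya.csv"),
                      ("mpa_table", "table_mpa.csv"),
                      ("contribution_table", "table_contributions.csv")]:
        paths[key] = outdir / name
        out[key].to_csv(paths[key])
    cfg_text = yaml.safe_dump(_as_plain(config))
    prov = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __import__("aevindex").__version__,
        "thresholds": {
            "siz_sic": config.siz_threshold,
            "polynya": config.polynya_threshold
            or DEFAULT_THRESHOLDS[config.polynya_variable],
            "polynya_variable": config.polynya_variable,
            "freq_cutoff": config.freq_cutoff,
            "bin_cutoffs": list(config.bin_cutoffs),
        },
    }
    paths["provenance"] = outdir / "provenance.json"
    paths["provenance"].write_text(json.dumps(prov, indent=2))
    (outdir / "config.yaml").write_text(cfg_text)
    return paths
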