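# aevindex

A tested, reusable pipeline for computing a multi-trophic **Antarctic
Ecosystem Value (AEV) index** over the Southern Ocean seasonal sea-ice
zone, for conservation planners and polar marine ecologists who want a
reproducible, model-based map of where ecological value concentrates —
today and under projected climate change.

From gridded monthly ocean / sea-ice / biogeochemistry fields (CF-style
NetCDF) and penguin colony tables, the package computes:

- **Five trophic input layers** — growing-season (ONDJFM) net primary
  productivity (NPP); empirical Antarctic krill growth potential
  (KGP = KGP_length + KGP_food + KGP_temp, valid for SST ∈ [−1, 5] °C);
  demersal fish biomass potential (DFP) masked to toothfish-habitable
  bottom water (TBOT ≤ 1 °C); and Emperor/Adélie penguin accessibility
  (EPP/APP), colony abundance spread by exponential distance decay
  calibrated so half a colony reaches 414 km (Emperor) and 10⁻⁶ of a
  colony reaches 1933 km (Adélie).
- **Sea-ice masks** — the seasonal sea-ice zone (September-mean SIC ≥ 15%)
  and polynyas detected as enclosed below-threshold connected components
  (0.4 m SIT for model fields, 85% SIC for satellite-like fields), with
  "typical polynya" cells occupied more than 10% of the year.
- **The index** — each layer is scaled by its domain maximum and summed,

      AEVsum_ij = NPP_ij/NPP_max + KGP_ij/KGP_max + DFP_ij/DFP_max
                + EPP_ij/EPP_max + APP_ij/APP_max,
      AEV_ij    = AEVsum_ij / AEVsum_max(region),

  yielding values in [0, 1] per management region (Weddell Sea, East
  Antarctic, Ross Sea, Amundsen Sea, Antarctic Peninsula), binned into
  exceptional / very high / high / other (top 5 / 10 / 25 percentiles),
  with polynya and protected-area overlap tables and per-layer
  contribution diagnostics.
- **Penguin population dynamics** — a hierarchical Bayesian state-space
  model of logged nest counts (colony growth quadratic in long-term
  sea-ice concentration, truncated-normal process-error hierarchy),
  climate-series bias correction and 40-year window averaging, intrinsic
  growth projection, and a conservative distance-decay metapopulation
  projection with colony-health classification (declines > 30 / 50 /
  90% from a baseline decade → vulnerable / endangered / quasi-extinct).

A synthetic-data module emulates Earth-system-model output (seasonal ice
cycle, coastal polynya pockets with amplified blooms, warming trends,
ensemble spread) and draws nest counts from the growth model itself, so
every stage runs and is tested without any download.

## Worked example

```python
from aevindex.pipeline import PipelineConfig, run_pipeline

out = run_pipeline(PipelineConfig(), outdir="demo")
print(out["polynya_table"].round(2))
```

On the default desk-scale synthetic scenario (2° grid, 5 members,
1998–2002 analysis window) this prints, per region:

```
                                WS     EA     RS      AS      AP   Hemi
avg_inside_poly               0.80   0.87   0.89    0.78    0.80   0.82
avg_outside_poly              0.41   0.41   0.40    0.36    0.34   0.40
pct_difference               65.66  71.58  75.44   74.23   80.98  69.97
pct_area_inside_poly          8.71   5.27   7.89   16.51   20.23   9.43
pct_exceptional_inside_poly  83.59  53.00  84.62  100.00  100.00  77.02
```

Read: index values inside typical polynyas average roughly twice the
outside values (+66 to +81% symmetric percent difference), and although
polynyas occupy only 5–20% of each region's area, they contain 53–100%
of the exceptional-value area — the co-location of polynyas and
ecological value that the index is designed to surface. The
accompanying contribution table shows which trophic layer drives the
value at each location (in this scenario KGP dominates the open ice
zone and NPP/DFP/EPP the polynya-rich shelf).

The same pipeline is scriptable from the shell:

```sh
aev simulate --out fields.nc
aev aev --out demo --mode regional --variable sit
aev fit-adelie --counts counts.csv --out draws.csv
aev report --outdir demo
```

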