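# Methods

This note documents the models implemented in `aevindex`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic data does and does not emulate.

## Domain and grid

The analysis domain is a regular latitude/longitude grid south of 50°S
with longitudes on [0, 360). Cell areas use the mid-latitude cosine
rule A = R² cos φ Δφ Δλ (R = 6371 km), which agrees with the exact
spherical expression to well under 1% at 1–2° resolution. Five
management regions approximate the CCAMLR MPA planning domains as pure
longitude sectors (WS 60°W–30°E, EA 30°E–150°E, RS 150°E–140°W, AS
140°W–90°W, AP 90°W–60°W); the sector table is editable configuration,
and statistics are restricted to ocean cells south of 60°S. The AP/WS
boundary is in reality not a meridian (biological connectivity argues
for moving part of the Weddell coast into AP); since no coordinates for
that adjustment are published, the default keeps reproducible pure
sectors, and a custom sector table can encode any variant.

Area-weighted statistics use the weighted population formula (divide by
total weight, no degrees-of-freedom correction), and missing cells are
excluded from both numerator and weights.

## Sea-ice masks

- **Seasonal sea-ice zone (SSIZ):** cells whose multi-year September
  mean SIC is ≥ 15% (SIC held internally as a fraction; percent inputs
  are converted on read).
- **Polynyas:** connected components of below-threshold cells
  (strictly `<`), longitude-wrap aware, that do *not* touch the
  northernmost row of the domain. Components touching that open
  boundary are the ambient ice-free ocean; what remains is enclosed by
  land and/or consolidated ice, which is the defining property of a
  polynya. Default connectivity is 4-neighbour (diagonal contact does
  not leak through single-cell barriers); 8-neighbour is available.
  Thresholds: 0.4 m sea-ice thickness for model fields (default), 85%
  SIC for satellite-like fields. Correctness is established against an
  independent brute-force flood-fill oracle on randomized grids.
- **Typical polynyas:** cells inside a detected polynya in strictly
  more than 10% of the monthly maps over the assessment period.

## Trophic layers

- **NPP:** monthly net primary productivity summed over each growing
  season (October–March; the season labelled *y* spans Oct *y* – Mar
  *y*+1) and averaged over seasons and ensemble members. Units
  g C m⁻² season⁻¹.
- **KGP:** empirical adult-krill growth increment,
  KGP = KGP_length + KGP_food + KGP_temp with
  KGP_length = −0.066 + 0.002 L − 0.000061 L² (L = 40 mm, giving
  −0.0836), KGP_food = 0.385 Chl/(0.328 + Chl), and
  KGP_temp = 0.0078 SST − 0.0101 SST² (optimum 0.386 °C), evaluated
  only for SST ∈ [−1, 5] °C (missing outside). The multiplicative food
  variant 0.385 Chl/(0.328 Chl) — which is constant in chlorophyll and
  undefined at zero, so it cannot express food limitation — is exposed
  behind `literal_form=True` for auditability but is not the default.
  KGP is evaluated month-by-month within ONDJFM (so the SST validity
  window applies per month) and averaged; cells valid in no month are
  missing.
- **DFP:** demersal fish biomass potential (size classes summed) kept
  where annual-mean bottom temperature ≤ 1 °C inclusive (the
  habitability limit for Antarctic toothfish), missing elsewhere.
- **EPP/APP accessibility:** per cell, Σ over colonies of
  abundance·exp(−k·d) with great-circle distances (spherical Earth;
  ocean-path routing is not attempted) and k = −ln(f)/D from a
  calibration point (D, f): Emperor (414 km, 0.5) — half a colony
  reaches the mean dispersal distance — and Adélie (1933 km, 10⁻⁶) —
  one in a million reaches the maximum dispersal distance.
  Accessibility is kept in absolute individuals; the index's
  max-scaling removes the absolute scale.

## The index

Each layer is divided by its maximum over the evaluated domain and the
five scaled layers are summed. Within the SSIZ a layer's missing cells
contribute 0 (otherwise the shelf-only DFP support and the SST-limited
KGP range would erase most of the domain); outside the SSIZ the index
is undefined. The sum is rescaled to [0, 1] by the maximum within each
region (regional mode, the default) or over the union of regions
(hemispheric mode). Sensitivity to the equal penguin weighting can be
explored by pre-scaling either penguin layer (the index is invariant to
per-layer rescaling, so only *relative* within-layer structure
matters).

**Bins:** per region (and per decade when projecting), cells rank by
index value; top 5% → exceptional, next 5% → very high, next 15% →
high, rest → other. Quantiles use linear interpolation of order
statistics and the strict rule "strictly above the cutoff enters the
higher bin", so a constant region is entirely "other". Percentiles are
unweighted cell counts by default (an area-weighted option exists):
the binning describes the distribution of index values, while all
reported means/percent-areas are area-weighted.

**Tables:** inside/outside-polynya area-weighted means and sds, the
symmetric percent difference 100·(in − out)/(½(in + out)), percent of
regional and per-bin area inside polynyas and inside a protected-area
mask, and per-layer percent contributions (100·scaled_k/AEVsum, summing
to 100 at every defined cell) with a dominant-layer map flagged
ambiguous where the top contribution is less than 1.1× the second.
Table rounding: values to 2 decimals, percents to integers.

## Penguin population dynamics

**Bias correction.** Model SIC series are affinely mapped per colony so
their 1979–2018 mean and standard deviation equal the observed ones:
corrected = (δ_obs/δ_model)(y − θ_model) + θ_obs. **Window averaging**
(Adélie): each year's SIC is the mean of the 40-year window ending that
year, then clamped to the observed min/max so projections never
extrapolate the fitted curve. Colony SIC uses March–June means within a
500 km great-circle catchment.

**Adélie hierarchical model.** Logged true nest abundance follows a
random walk with colony-specific drift; drift is quadratic in long-term
SIC with residual sd σ_r; per-colony process sds are exchangeable under
a truncated-normal N⁺(γ, τ²); observed log counts add known survey
errors. Only colonies with ≥ 10 counts enter the fit. Priors are
weakly informative — Normal(0, 10) on β₀, β₁, β₂ and Half-Normal(1) on
σ_r, γ, τ — and configurable. Inference is Metropolis-within-Gibbs:
the latent states are conditionally linear-Gaussian and drawn exactly
by forward-filter backward-sampling; μ_r and β have conjugate normal
updates; σ_r, σ_i, γ, τ move by log-scale random-walk Metropolis with
step adaptation during warmup. Four chains run jointly (vectorised);
convergence is summarised by split-R̂ with a < 1.05 criterion, and
near-rank-deficient designs (fewer than 3 distinct SIC values) are
flagged as weakly identifying the quadratic.

**Projection.** Per iteration (default 100), a posterior draw supplies
(β, σ_r, γ); mean growth is drawn around the quadratic curve with sd
σ_r and annual growth around it with sd γ. The Emperor pathway starts
from externally supplied stage-abundance trajectories (its
stage-structured demographic matrix is parameterised elsewhere) and
converts them to r = log of consecutive stage-total ratios.

**Metapopulation.** Each year is reproduction (multiply by exp r) then
dispersal: a fraction e (Adélie default 0.035, the highest observed
emigration rate) of each colony's post-reproduction abundance enters a
settlement pool distributed over colonies with weights ∝ exp(−k·d),
*including the source colony* (an emigrant may resettle at home). With
realistic inter-colony distances the home weight dominates, which is
why projected trajectories stay close to the no-dispersal case; with
two colonies and equal weights each transfers e/2 per year. Settlement
rows are normalised, so the dispersal phase conserves total abundance
exactly. A "semi-informed" option raises departure as local growth
falls (e·exp(−r/scale), capped at 1) while keeping random
distance-decayed settlement; it is off by default because its
functional form is a modelling choice, not an estimated quantity.

**Decadal statistics** pool all members × the 5 years centred on a
decade (50 members → n = 250) with a population sd. **Colony health**
compares a projection decade against the 2000s baseline: decline > 90%
quasi-extinct, > 50% endangered, > 30% vulnerable, else not threatened.

## Synthetic data

The generator emulates only the statistical structure the analysis
assumes: a monthly seasonal SIC cycle (September max, February min,
fixed monthly amplitude table) scaled by a latitudinal profile and a
compounding per-decade decline; SIT co-varying as 1.2·SIC^1.5 m;
circular coastal polynya pockets whose openness factor multiplies
SIC/SIT (default 0.3, chosen so a pocket is simultaneously below the
0.4 m SIT detection threshold in winter, above the 15% September SIC
zone cutoff, and below the 85% satellite SIC threshold); chlorophyll
and NPP concentrated in ONDJFM and amplified (default 2×) inside
polynyas; linear meridional temperature gradients with a warming trend
(default 0.25 °C/decade at the surface, half at the bottom); and a
shelf-band demersal-fish field. Noise is independent truncated Gaussian
per cell/month — there is no spatial correlation, advection, or real
polynya dynamics — so passing tests demonstrate algorithmic
correctness and internal consistency, not skill against real CESM
output; the published regional magnitudes depend on the real forcing
and are not reproduced at desk scale. Ensemble members differ only in
noise draws and all output is bit-reproducible under a seed.

Defaults: generator 2° grid / 10 members / 1990–2100 (minutes-scale);
the pipeline demo narrows to 1998–2003 × 5 members because the index
needs one decade. Colonies (66 Emperor, 287 Adélie by default) sit on
coastal cells with log-uniform abundances. Nest counts come from the
generative twin of the hierarchical model; the standard recovery design
uses 38 colonies × 40 years, β = (−0.10, 0.60, −0.55), σ_r = 0.02,
γ = 0.10, τ = 0.05, survey error sd 0.05, and colony SIC̄ ~ U(0.05,
0.95) — variance values chosen once as plausible for multi-decadal
nest-count series (growth rates of a few percent per year, survey CVs
of ~5%) and spread wide enough in SIC̄ to identify the quadratic.

## Numerical choices and degenerate inputs

- Missing data: NaN propagates by exclusion in all reductions.
- Sd parameters are floored at 1e-8 inside the sampler to keep the
  degenerate zero-noise cases (exact data) well-posed.
- A single colony projects with settlement = identity; a region whose
  index sum is all zero is left missing with a warning; an empty
  selection in any area-weighted statistic raises rather than returning
  silence.
- NetCDF I/O uses the classic format (scipy engine); round-trips are
  bit-exact and unit attributes are mandatory.

## Known limitations

Pure-longitude region boundaries (no shapefile ingestion); great-circle
rather than ocean-path distances; the Emperor demographic matrix is out
of scope (stage trajectories are inputs); no sea-ice algae, pelagic
fish, or other predator guilds in the index; percentile bins are
cell-count based by default; the synthetic environment is statistical,
not dynamical.
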