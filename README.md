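# psrr — scale dependence of productivity–species-richness relationships

`psrr` is a Python library for asking *over what geographic distances* the
relationship between vegetation productivity and species richness changes
form, and *where* that relationship is positive, negative, or absent. It
implements a complete, testable version of a spatially varying coefficient
(SVC) workflow for species-richness macroecology:

1. **Dynamic habitat indices (DHI).** From an intra-annual gross primary
   productivity (GPP) raster time series it computes three per-pixel
   summaries of the productivity year — the cumulative **sum** (available
   energy), the monthly **minimum** (the environmental-stress bottleneck)
   and the **seasonality** (coefficient of variation; resource
   instability) — averaged across years and summarized over 39.4-km
   landscape buffers around survey-route start points.
2. **Route filters.** Routes are retained only if less than 50% of the
   buffer is human-dominated land cover (croplands, urban/built-up,
   cropland mosaics) and the whole buffer lies inside the study boundary.
3. **The SVC model.** Mean richness S_i at route location s_i with
   standardized productivity covariate PM_i follows

   S_i = α(s_i) + β(s_i)·PM_i + ε_i,  ε_i ~ N(0, τ_ε⁻¹),

   where α and β are Matérn (ν = 1) Gaussian fields represented through the
   SPDE/finite-element approach as Gaussian Markov random fields on a
   triangulated mesh. Penalized-complexity priors calibrate the spatial
   range ρ (P(ρ > 2,243 km) = 0.5) and marginal standard deviation σ
   (P(σ > 1) = 0.5); the noise precision gets a Gamma(1, 10⁻⁵) prior.
   The posterior of the slope field's range ρ_β answers the headline
   question: it is the distance within which the productivity–richness
   relationship keeps a similar magnitude and sign.
4. **Form maps.** The slope posterior is projected onto a regular grid
   (default 40 km) and each cell is classified **positive** / **negative**
   / **non-existent** according to whether the 95% credible interval of
   β excludes zero, plus boxplot-style summaries of the productivity
   measure by form.

A first-class synthetic-data generator simulates all inputs (seasonal GPP
stacks, land-cover mosaics, routes, and richness drawn from the SVC model
with known truth surfaces), so the whole pipeline is testable end to end
without any download.

## Worked example

```python
import psrr

TRUE_RANGE = 800.0  # km
cfg = psrr.SimulationConfig(
    domain_extent=(0.0, 3000.0, 0.0, 2000.0), n_routes=300,
    intercept_field=psrr.FieldParams(56.0, TRUE_RANGE, 3.0),
    slope_field=psrr.FieldParams(1.0, TRUE_RANGE, 0.5),
    noise_sd=1.0, seed=8)
ds = psrr.simulate_routes_and_richness(cfg)
mesh = psrr.build_mesh(ds.routes[["x_km", "y_km"]].to_numpy(), max_edge_km=300.0)
fit = psrr.fit_svc(ds.routes, mesh,
                   psrr.PriorConfig.with_range_threshold(1800.0),
                   psrr.InferenceConfig(seed=1, n_iter=3000, n_burn=1000, thin=5))
print(psrr.posterior_range_summary(fit, "beta"))
```

This prints (examples/03_svc_fit_and_range.py):

```
300 routes, mean richness 56.3
mesh: 460 vertices, max edge 297 km
acceptance rate 0.33, converged=True, flags=[]
slope-field range: median 1111 km, 95% CI [439, 23187] km (truth 800 km)
residual variogram: 92% of lag bins inside the permutation envelope ...
```

The median is the point estimate of the distance at which the
productivity–richness relationship decorrelates; the credible interval is
wide because a 3,000-km domain holds only a few independent replicates of
an 800-km-range field — exactly the uncertainty the Bayesian analysis is
meant to expose. The flat residual variogram says the spatial fields
absorbed the spatial autocorrelation.

The `examples/` directory holds one short script per capability (DHI
computation, route filters, SVC fitting, form maps, the full pipeline).
The pipeline is also runnable from a shell:

```bash
psrr run --seed 7 --out runs/demo        # full synthetic analysis
psrr simulate --seed 2 --out data/sim    # inputs only
```

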