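# mesfsurv

Multilevel spatial survival modelling with Moran eigenvector spatial
filtering.

## The problem

Survival outcomes of patients treated across a state are rarely independent
of geography: counties share healthcare infrastructure, environment and
policy, so mortality risk clusters in space. A Cox model with county-level
random intercepts absorbs unobserved regional heterogeneity, but those
intercepts mix two very different things — a spatially *structured*
component (neighboring counties alike) and a spatially *unstructured* one
(county-specific idiosyncrasies). `mesfsurv` separates them, for
biostatisticians and spatial epidemiologists analysing region-tagged
time-to-event registries.

The package fits three nested models:

1. **Cox proportional hazards** — `h(t|x) = h0(t)·exp(x'β)`;
2. **+ Gaussian region intercepts** — `h(t|x,r) = h0(t)·exp(x'β + r)`,
   `r ~ N(0, σ²)` i.i.d. over regions, estimated by penalized partial
   likelihood with a Laplace-profiled variance;
3. **+ Moran eigenvector spatial filter** — the Model 2 intercepts r̂ are
   regressed on stepwise-selected eigenvectors `E_k` of the doubly centered
   contiguity matrix `M C M` (`M = I − 11'/n`), `r̂ = E_k β_Ek + e`, and the
   survival model is refit as `h0(t)·exp(x'β + E_k β_Ek + r)`. The term
   `E_k β̂_Ek` is the spatially structured random effect (**SSRE**); the
   refit intercepts are the spatially unstructured remainder (**SURE**).

Moran's I (analytic and permutation inference), Schoenfeld
proportional-hazards checks, VIF, likelihood-ratio tests and AIC complete
the toolkit, along with a synthetic-data generator whose frailty has a
*known* SSRE/SURE split, so the whole pipeline is testable end to end.

## Worked example

```python
import mesfsurv as ms

# synthetic registry: 10x10 county lattice, 50 patients per county,
# frailty = two top-autocorrelation eigenvectors + white noise
dataset, graph, truth, specs = ms.simulate_dataset(
    rows=10, cols=10, n_per_region=50, covariate_model="simple",
    spatial_indices=[0, 1], spatial_sd=0.3, noise_sd=0.1, seed=11,
)
report = ms.run_pipeline(dataset, graph, specs, ms.PipelineConfig(seed=11))

print("selected eigenvectors:", report.selection.selected_indices)
print("sigma, Model 2 -> SURE:", round(report.model2.sigma, 4),
      "->", round(report.model3.sigma, 4))
for tag, m in [("r_hat(M2)", report.moran_m2),
               ("SSRE", report.moran_ssre), ("SURE", report.moran_sure)]:
    print(f"Moran I({tag}) = {m.i_value:+.4f}  p = {m.display_p()}")
```

prints

```
selected eigenvectors: (1,)
sigma, Model 2 -> SURE: 0.3247 -> 0.0633
Moran I(r_hat(M2)) = +0.6529  p = 0.0000
Moran I(SSRE) = +0.9986  p = 0.0000
Moran I(SURE) = -0.0894  p = 0.9361
```

Read: the Model 2 intercepts are strongly clustered (I = 0.65, significant);
after filtering, the structured surface carries essentially all of the
spatial signal (I ≈ 1.0) while the remaining intercepts are spatially
indistinguishable from noise (I = −0.09, p = 0.94) and their standard
deviation drops from 0.32 to 0.06 — the decomposition recovered the
generating structure. `report.comparison` holds the log-likelihood / AIC /
LRT table for the three nested fits, and `report.save(outdir)` writes the
JSON report plus per-region and per-model CSV tables.

The same analysis is available from the shell:

```bash
mesfsurv simulate --rows 10 --cols 10 --n-per-region 50 --seed 11 --out sim/
mesfsurv run-pipeline --data sim/patients.csv --graph sim/adjacency.gal \
    --config covariates.json --seed 11 --out results/
```

Real data enter as a patient CSV (`region_id,time_months,event,` covariates),
an adjacency structure (GAL file, edge-list CSV, or polygon contiguity from
GeoJSON — queen or rook), and a covariate declaration (JSON/YAML).

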