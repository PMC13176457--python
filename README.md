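# escarp

Threshold analysis of ecosystem-service supply–demand balance along
landscape-configuration gradients, stratified by landscape-composition
clusters.

Large heterogeneous basins mix very different landscape backgrounds —
forest-dominated, desert, urban, cropland mosaics. Whether fragmenting
or aggregating the land cover helps or hurts an ecosystem service often
depends on that background, and the response is rarely linear: past a
critical edge density or aggregation level, a service can tip from
surplus toward deficit. `escarp` is a pipeline for detecting exactly
such turning points. It is aimed at landscape ecologists and
quantitative geographers working with gridded land-use data, and ships
with a synthetic-basin generator so every stage can be validated
against planted ground truth.

## What it computes

Units are square grid cells of a categorical land-cover raster. For
each unit the package computes FRAGSTATS-style **composition** metrics
(PRD, SHDI, PLAND₁–₆) and **configuration** metrics (PD, LPI, ED,
PAFRAC, AI), clusters units into composition backgrounds by k-means
(with silhouette / Dunn / Calinski–Harabasz / adjusted-Rand screening
of k and Moran's I label diagnostics), and forms per-unit
supply–demand ratios for water yield, carbon sequestration, soil
conservation and food production:

    ESDR_s(u) = (S_s(u) − D_s(u)) / ((max_u S_s + max_u D_s) / 2)

with CESDR the mean of the four. Negative values mark a deficit.
Within each cluster, every configuration-metric–response pair is then
screened (Spearman + Benjamini–Hochberg FDR, correlation-strength and
sample-size floors), its upper boundary extracted as per-bin 0.90
quantiles (constraint-line analysis), and three candidate threshold
models fitted to the boundary — quadratic polynomial, single-breakpoint
segmented regression `y = β₀ + β₁x + β₂(x − ψ)₊`, and a penalized
cubic-spline GAM. The best-supported model is chosen by BIC with a
ΔBIC ≤ 2 parsimony rule, and each detected threshold is reported with
pre/post boundary means, a bootstrap confidence interval and a
redetection success rate. Details and operating characteristics are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a 400-unit synthetic basin whose carbon-sequestration ESDR has
a planted upper-boundary breakpoint at aggregation index 60, then
recover it:

```python
from escarp import synthetic as syn
from escarp.metrics import zonal_metrics
from escarp.services import compute_esdr
from escarp.thresholds import analyze_pair

cfg = syn.hinge_scenario(seed=7)          # 400 units, breakpoint at AI = 60
raster, assignment = syn.generate_landuse(cfg)
metrics = zonal_metrics(raster, cfg.cells_per_unit)
surfaces = syn.generate_service_surfaces(cfg, metrics, assignment)
esdr, _ = compute_esdr(surfaces["service_table"])

pair = metrics.merge(esdr, on="unit_id")
result, diag = analyze_pair(pair["AI"].to_numpy(),
                            pair["ESDR_CS"].to_numpy(), B=200, seed=1)
```

This prints (via the fields of `result`):

```
model:      segmented
threshold:  AI = 60.03
pre/post:   ESDR_CS 0.535 -> 0.502 (decrease)
95% CI:     [59.73, 60.61]
success:    100.00% of 200 replicates
```

The segmented model wins the BIC contest, the breakpoint lands within
0.03 AI units of the planted truth, the bootstrap interval covers it,
and every resample re-detects a segmented threshold. The pre/post
values are the mean boundary ESDR below and above the threshold: here
carbon-sequestration surplus stops growing and starts declining once
the landscape aggregates beyond AI ≈ 60.

The same analysis runs end to end from the shell:

```bash
escarp pipeline run --config cfg.json    # synth → metrics → cluster → esdr → thresholds
escarp pipeline report --run out/        # composition profiles, ESDR summaries, threshold table
```

where `cfg.json` is a `RunConfig` document (schema-validated, unknown
keys rejected; see `escarp.pipeline.RunConfig`). Runs are resumable —
unchanged stages are skipped via the manifest — and byte-identical
under a fixed seed.

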