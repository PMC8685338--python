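# surfreho

Surface-based regional homogeneity analysis for resting-state functional
time series. For every vertex of a triangulated cortical surface, the
package computes Kendall's coefficient of concordance (W) over the vertex
and its two-ring mesh neighborhood (19 series at a regular degree-6
vertex), smooths the resulting maps with a geodesic Gaussian kernel, and
runs group-level statistics: vertex-wise two-sample t-tests with
Benjamini–Hochberg FDR, signed cluster extraction, a global-mean
comparison, and covariate-adjusted Spearman correlations with clinical
variables. A synthetic-cohort generator with plantable group effects and
clinical coupling makes the whole pipeline testable end to end.

## Layout

- `surfreho.mesh` — triangle-mesh model, FreeSurfer/GIFTI I/O, icosphere
  construction, k-ring neighborhoods, vertex areas, geodesic distances.
- `surfreho.preprocess` — mid-thickness surfaces, trilinear
  volume-to-surface sampling, 24-parameter motion expansion, nuisance
  regression, band-pass filtering, initial-volume dropping.
- `surfreho.reho` — Kendall's W, whole-surface homogeneity maps, geodesic
  Gaussian smoothing, global mean.
- `surfreho.stats` — t-tests, BH-FDR, cluster tables, partial Spearman
  correlations, demographics tables.
- `surfreho.synthetic` — cohort simulation (AR(1) signals with a shared
  latent per region, planted synchrony offsets of either sign, Gaussian-
  copula clinical coupling), QC rosters, analytic test volumes.
- `surfreho.pipeline` / `surfreho.cli` — YAML-configured end-to-end runner
  with provenance logging and a `surfreho` command-line interface.

## CLI

```sh
surfreho run --config config.yaml --seed 1 --out results/run1
surfreho simulate --config config.yaml --out results/cohort
surfreho reho --ts sub.func.gii --mesh mesh.surf.gii --tr 2.0 --out map.tsv
surfreho smooth --map map.tsv --mesh mesh.surf.gii --fwhm 10 --out map_sm.tsv
surfreho stats --mesh mesh.surf.gii --maps-a a1.tsv --maps-a a2.tsv \
    --maps-b b1.tsv --maps-b b2.tsv --q 0.05 --out results/stats
```

A minimal config:

```yaml
seed: 1
simulate:
  n_sz: 45
  n_hc: 45
  mesh_subdivisions: 3
  n_timepoints: 150
  rho0: 0.1
  clusters:
    - {seed_vertex: 30, ring_radius: 3, delta_sz: 0.06}
    - {seed_vertex: 400, ring_radius: 3, delta_sz: 0.0, delta_hc: 0.06}
  r_target: 0.5
  clinical_variable: illness_duration
smooth: {enabled: true, fwhm: 10.0}
stats: {q: 0.05, variance: pooled}
```

Re-running an identical config and seed reproduces all data outputs
bit-for-bit; `run_log.json` carries the provenance record (package
version, config hash, seed, timestamp).

## Conventions

- Vertex indices are 0-based in memory; table writers accept an index
  base. Coordinates are mm RAS; affines map world mm to 0-based continuous
  voxel indices with voxel centers at integer indices.
- Neighborhoods are graph rings (edge-graph distance), not Euclidean
  nearest neighbors; vertices of degree ≠ 6 keep their natural ring size.
- The band-pass default is an ideal FFT mask (a Butterworth option
  exists); the global signal is not regressed by default.
- Smoothing applies to homogeneity maps, not time series; σ = FWHM/2.3548
  with geodesic (Dijkstra) distances truncated at 3σ.
- Group contrasts are patients minus controls.
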