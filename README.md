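# spatialabm

Initialize spatial tumor–immune agent-based models (ABMs) from single-cell
and spatial-omics cell tables, simulate them, and quantify how the choice
of initialization shapes the emergent dynamics.

Spatial transcriptomics gives a static snapshot of a tissue — every cell's
position and type. A mechanistic ABM predicts how such a tissue evolves.
This package bridges the two for a minimal tumor–immune model of three
cell types (malignant epithelium, healthy epithelium, CD8+ T cells): it
reads measured cell tables (CSV or AnnData `.h5ad`), maps measured labels
onto model types, places model cells either synthetically (well-mixed
disc; structured disc-plus-immune-annulus) or *spatial-informed* — one
agent per measured cell at its measured coordinates — and runs an
off-lattice ABM in which only cancer cells divide (contact-inhibited) or
die, CD8+ T cells migrate by a persistent random walk and execute timed
attacks that kill cancer cells, and healthy cells are inert.

The spatial readouts are the ones used to compare initializations:

* cancer-cell count trajectories (replicate mean ± 1 SD),
* number of ongoing immune attacks over time,
* cross-pair correlation function (cross-PCF) g(r) of CD8+ T cells around
  cancer cells, as a time-series heatmap — g > 1 means T-cell enrichment
  at that distance, g < 1 depletion,
* the cumulative distribution of cancer cells over connected-component
  sizes of the contact neighbor graph at the endpoint.

A synthetic-tissue generator emulating an immune-infiltrated pancreatic
tumor (solid malignant core, healthy rim, immune density peaked at the
malignant border) makes the whole pipeline runnable with no data download.
See `docs/methods.md` for the model, estimators, and parameter defaults.

## Worked example

Generate a synthetic tissue, build an initial condition from it, and run
one replicate:

```bash
spatialabm synth --out sample.csv --seed 1
spatialabm init --scenario spatial --out cells.csv
spatialabm simulate --cells cells.csv --seed 1 --out run/
```

or, in Python, the full three-scenario experiment (three initializations x
three replicates x five simulated days, the default design):

```python
import spatialabm as sa

manifest = sa.run_experiment(sa.default_experiment_config(), "experiment/")
sa.report("experiment/manifest.json")
```

`experiment/<scenario>/aggregates.csv` then holds the replicate mean ± SD
cancer counts and ongoing attacks per saved hour, e.g. (well-mixed,
abridged):

```
time_min,cancer_mean,cancer_sd,attacks_mean,attacks_sd
0.0,1500.0,0.0,0.0,0.0
720.0,1285.0,28.8,19.7,1.5
7200.0,1414.0,98.1,11.0,3.0
```

Read: the well-mixed tumor loses about 14% of its 1500 cancer cells in the
first half-day of immune attack (with an early burst of ~45 simultaneous
attacks in the first hour), then stabilizes near 90% of the initial
population over the final day. The structured and spatial-informed
scenarios instead grow (replicate-mean endpoints 1723 and 1518 cancer
cells), and their cross-PCF heatmaps (`rep*/pcf.csv`, plotted by `report`)
show short-range T-cell enrichment rising over time — progressive immune
infiltration — where the well-mixed case shows depletion.
`component_cdf.csv` quantifies endpoint clustering: in the structured
scenario about 59% of all cancer cells end in connected components larger
than 100 cells, while the well-mixed endpoint is dominated by smaller
fragments.

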