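# windowscape

Multi-scale, multi-site sliding-window landscape genetics.

`windowscape` tests isolation-by-resistance (IBR) hypotheses against
isolation-by-distance (IBD) over thousands of circular study areas (sliding
windows) that vary in diameter and center location. It combines:

- **individual-based genetic distances** — diploid microsatellite genotypes
  are 0/1/2-encoded per allele and compared with Bray–Curtis dissimilarity
  (pairwise deletion of missing loci);
- **commute-time resistance distances** — environmental rasters become
  conductance surfaces per scenario (`T` temperature, `E` elevation, `Pr`
  pine-as-resistance, `Pc` pine-as-corridor); expected random-walk commute
  times on the lattice graph are computed exactly from the grounded weighted
  Laplacian;
- **partial Mantel tests with an explicit support criterion** — a hypothesis
  is supported in a window when IBR is significant given IBD (p < α) *and*
  IBD is non-significant given IBR (p ≥ α); one-tailed, permutation-based;
- **commonality analysis** — the all-subsets R² decomposition of the multiple
  regression of genetic distance on the resistance matrices;
- **aggregation** — per-scale support frequency and mean Mantel r,
  per-individual support surfaces with overlap correction, inverse-distance
  -weighted interpolation, and environmental-heterogeneity (per-window SD)
  comparisons;
- **a synthetic-data module** — smooth landscapes with an optional barrier
  strip and forward-time Wright–Fisher microsatellite genotypes whose
  migration decays with commute distance over a chosen conductance surface,
  giving every stage a ground truth.

Supporting tools: genotype I/O (CSV and GenePop), ESRI ASCII grid / GeoTIFF
rasters, labeled TSV distance matrices, deme summaries (Fis, Weir–Cockerham
Fst, rarefied allelic richness), PCA of allele dosages, empirical
semivariograms with exponential fits, and VIF collinearity checks.

## CLI

Every subcommand takes explicit I/O paths; `--config run.yaml` supplies a
`RunConfig` (scenario list, diameter range, permutations, α, seeds, ...).

```sh
windowscape simulate --seed 5 --out-dir fixtures/       # synthetic dataset
windowscape encode --genotypes g.csv --out am.tsv --summaries demes.tsv
windowscape distances --genotypes g.csv --genetic-out g.tsv --geographic-out ibd.tsv
windowscape resist --raster pine.asc --scenario Pr --points sites.tsv --out ibr_pr.tsv
windowscape variogram --values scores.tsv --lag 50 --out vgm.tsv --fit
windowscape windows --genotypes g.csv --out windows.tsv
windowscape analyze --g g.tsv --ibd ibd.tsv \
    --ibr T=ibr_t.tsv,E=ibr_e.tsv,Pr=ibr_pr.tsv,Pc=ibr_pc.tsv \
    --genotypes g.csv --seed 42 --out window_results.tsv
windowscape aggregate --results window_results.tsv --scale-out scale_summary.tsv
windowscape interpolate --points surface.tsv --template grid.asc --out map.asc
```

For a fully in-process run (windows, per-window results, per-scale
summaries) use `windowscape.pipeline.run_pipeline(table, rasters, config)`.

## Conventions

- Coordinates are WGS84 lon/lat; every ground distance is great-circle
  (haversine, R = 6371 km).
- Missing genotype calls are `0` in memory (the GenePop sentinel), empty
  cells in CSV.
- Conductance surfaces are min–max rescaled to [1e-3, 1] and flipped for
  "high value resists" scenarios, so `Pr` and `Pc` are exact complements.
- Commute time = component volume × effective resistance; pairs in different
  graph components are `inf`.
- Permutation p-values use the add-one estimator `(1 + hits) / (1 + n_perm)`
  and are reproducible bit-exactly given a seed; per-window seeds derive
  deterministically from the global seed and the window id.
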