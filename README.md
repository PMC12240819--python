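# coretrans

Biodiversity within a biogeographical region is not spread uniformly: regions
tend to organize into ordered layers, from species-rich, endemic-rich **cores**
to **transition zones** near permeable boundaries dominated by widespread
species and biotas overlapping from neighbouring regions. `coretrans` is a
Python library for macroecologists and biogeographers that quantifies this
core-to-transition organization from species-by-grid-cell presence records
and tests its statistical signatures, end to end.

## What it computes

Starting from long-format presences (taxon, species, grid cell):

1. **Bioregions.** Species and cells form a bipartite network; map-equation
   community detection (Infomap, via `igraph`) partitions both jointly into
   modules. A module's cells are a bioregion and its species that region's
   *characteristic* pool; the best of many heuristic runs is kept by lowest
   codelength *L*. Degenerate modules (no cells, no species, or constant
   richness/occupancy) are flagged and excluded from downstream scoring.

2. **Four biodiversity aspects per cell** (network cartography). With
   *I<sub>c</sub>* a cell's links to species of its module *m*,
   *L<sub>c</sub>* all its links, and *I<sub>s</sub>*, *L<sub>s</sub>* the
   analogues for a species:

   - relative species richness = (*I<sub>c</sub>* − Ī<sub>m</sub>) / σ<sub>m</sub>
   - biota overlap = *O<sub>c</sub>* / *L<sub>c</sub>* = 1 − *I<sub>c</sub>* / *L<sub>c</sub>*
   - endemicity = Mdn(*I<sub>s</sub>* / *L<sub>s</sub>*) over the cell's present characteristic species
   - relative occupancy = Mdn((*I<sub>s</sub>* − Ī<sub>m</sub>) / σ<sub>m</sub>) over the same species

3. **Biogeographical sectors.** A two-step weighted k-means on the
   standardized aspects: per-taxon clustering with the number of clusters
   chosen at the elbow of the goodness-of-fit curve (two-segment piecewise
   regression, lowest residual standard error), then a joint clustering of
   all taxa whose *k* maximizes the mean adjusted mutual information (AMI)
   with the taxon-specific partitions. Sectors are numbered by decreasing
   centroid relative richness — a canonical core→transition order.

4. **Downstream statistics.**
   - *Adjacency*: one-sided binomial tests of whether sector pairs neighbour
     each other more than the 1-in-6 chance expectation, both directions,
     within each bioregion (queen or rook neighbourhoods).
   - *Environment*: per-region multinomial logit of sector on environmental
     covariates vs an intercept-only null, compared by corrected AIC
     (ΔAICc > 10) with McFadden's pseudo-R².
   - *Beta diversity*: multi-site Sørensen dissimilarity among a region's
     sectors partitioned into turnover (β<sub>SIM</sub>) and nestedness
     (β<sub>SNE</sub>) components, separately for characteristic species and
     for non-characteristic species by region of origin.
   - *Richness variance*: weighted regression of cell richness on regional
     pool size and region-centred characteristic / non-characteristic
     richness, with leave-one-out variance fractions, plus a permutation
     test of core-area richness.

A **synthetic landscape generator** (`coretrans.synthetic`) plants all of
this structure with known ground truth — contiguous regions with hotspots,
right-skewed range sizes, and permeable boundaries — so every stage of the
pipeline is testable against what was planted.

## Worked example

```python
from coretrans import PipelineConfig, LandscapeConfig, run_pipeline, report

config = PipelineConfig(
    simulate=LandscapeConfig(grid_rows=24, grid_cols=24, n_regions=4,
                             species_per_region=60, range_size_mu=3.807,
                             range_size_sigma=0.5, seed=7),
    backend="mapeq", n_trials=10, restarts=30,
    k_range_taxon=(2, 12), k_range_general=(2, 8), seed=1,
)
bundle = run_pipeline(config, outdir="pipeline_output")
print(report(bundle))
```

prints

```
General biogeographical sectors: k = 4

Aspect medians by sector (1 = most core-like):
        relative_richness  biota_overlap  endemicity  relative_occupancy
sector
1                   1.755          0.000       1.000               0.145
2                   0.200          0.500       0.469               0.500
3                  -0.248          0.000       1.000               0.221
4                  -0.818          0.083       1.000               1.397
...
Higher-than-expected neighbouring (share of regions):
 sector_a  sector_b  n_regions  n_significant  frequency
        1         3          4              4        1.0
        ...
        3         4          4              4        1.0

Environment models: 4/4 regions significant (median pseudo-R2 = 0.418)
Nestedness > turnover in 100% of regions (characteristic species)
Richness variance fractions: pool_size=0.197, centred_char=0.767, centred_nonchar=0.011 (R2 full = 0.971)
```

Sector 1 (high richness, zero overlap, fully endemic species) is the core;
sector 2 (50% biota overlap, low endemicity) is the transition belt.
Significant adjacency links consecutive layers (1–3, 3–4), every region's
sectors occupy distinct climates, and sector dissimilarity is dominated by
nestedness — the core-to-transition fingerprint.

Each capability also has a short narrative script under `examples/`
(`python examples/delineate_bioregions.py`, run from that directory), and a
thin CLI covers batch use: `coretrans simulate|run|report`.

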