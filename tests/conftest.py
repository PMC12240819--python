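import math

import pandas as pd
import pytest

from coretrans import (
    LandscapeConfig,
    build_bipartite,
    cell_aspects,
    classify_presences,
    detect_bioregions,
    filter_modules,
    generate_landscape,
    species_aspects,
)


def small_config(**overrides) -> LandscapeConfig:
    """A scaled-down landscape for fast unit tests.

    Range sizes shrink with the region size (about a third of the 144-cell
    regions at the median), mirroring the default landscape's proportions.
    """
    base = dict(
        grid_rows=24, grid_cols=24, n_regions=4, species_per_region=60,
        range_size_mu=math.log(45.0), range_size_sigma=0.5, seed=7,
    )
    base.update(overrides)
    return LandscapeConfig(**base)


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(small_config())


@pytest.fixture(scope="session")
def small_partitioned(small_landscape):
    """Graph, filtered partition, classification and aspects for the small
    landscape, using the map-equation backend."""
    dataset, grid, env, truth = small_landscape
    graph = build_bipartite(dataset)
    partition = filter_modules(
        detect_bioregions(graph, backend="mapeq", n_trials=5, seed=3), graph
    )
    classification = classify_presences(graph, partition)
    spp = species_aspects(graph, partition)
    aspects = cell_aspects(graph, partition, spp)
    return {
        "dataset": dataset, "grid": grid, "env": env, "truth": truth,
        "graph": graph, "partition": partition,
        "classification": classification, "species_aspects": spp,
        "aspects": aspects,
    }


def toy_dataset():
    """Two clean blocks: species a,b on cells 1,2; species c,d on cells 3,4."""
    from coretrans import OccurrenceDataset

    records = pd.DataFrame(
        [("a", "c1"), ("a", "c2"), ("b", "c1"), ("b", "c2"),
         ("c", "c3"), ("c", "c4"), ("d", "c3"), ("d", "c4")],
        columns=["species_id", "cell_id"],
    )
    return OccurrenceDataset(taxon="toy", records=records)
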