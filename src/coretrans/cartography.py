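"""Network cartography: the four biodiversity aspects per grid cell.

For a cell c of module m with I_c links to species of m, O_c links to
outside species and L_c = I_c + O_c links in total, and a characteristic
species s with I_s within-module links out of L_s:

* relative richness  = (I_c - mean_m I) / sd_m I   (z-score within module)
* biota overlap      = O_c / L_c                   (fraction in [0, 1])
* endemicity         = median over the cell's present characteristic
                       species of I_s / L_s        (fraction in (0, 1])
* relative occupancy = median over the same species of
                       (I_s - mean_m I_s) / sd_m I_s

Standard deviations use the sample (n-1) convention by default; the
population convention is available via ``ddof=0``.  Medians of even-length
sets are the midpoint of the two central values.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .bioregions import BipartiteGraph, ModulePartition
from .errors import ValidationError

logger = logging.getLogger(__name__)

ASPECT_COLUMNS = (
    "relative_richness", "biota_overlap", "endemicity", "relative_occupancy",
)


def aspect_combination_count(n_levels: int = 3, n_aspects: int = len(ASPECT_COLUMNS)) -> int:
    """Number of distinct value combinations when each aspect is discretized.

    Counted by explicit enumeration of the level grid (e.g., low / medium /
    high across the four aspects).
    """
    return sum(1 for _ in itertools.product(range(n_levels), repeat=n_aspects))


def species_aspects(
    graph: BipartiteGraph, partition: ModulePartition, ddof: int = 1
) -> pd.DataFrame:
    """Occupancy z-score and endemicity per characteristic species.

    Only species of retained modules are returned.  Within each module,
    z_spp standardizes I_s over the module's characteristic species;
    endemicity is I_s / L_s.
    """
    links = graph.links.copy()
    links["species_module"] = links["species_id"].map(partition.species_modules)
    links["cell_module"] = links["cell_id"].map(partition.cell_modules)
    L_s = links.groupby("species_id").size()
    inside = links[links["species_module"] == links["cell_module"]]
    I_s = inside.groupby("species_id").size()

    retained = set(partition.retained_modules())
    sp_mod = partition.species_modules
    rows = []
    for m in retained:
        sps = sp_mod.index[sp_mod == m]
        if len(sps) == 0:
            continue
        i_vals = I_s.reindex(sps, fill_value=0).astype(float)
        sd = i_vals.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise AssertionError(
                f"module {m} has zero occupancy spread; filter_modules should "
                "have excluded it"
            )
        mean = i_vals.mean()
        l_vals = L_s.reindex(sps).astype(float)
        for s in sps:
            rows.append((
                s, m, i_vals[s], l_vals[s],
                (i_vals[s] - mean) / sd,
                i_vals[s] / l_vals[s] if l_vals[s] > 0 else np.nan,
            ))
    return pd.DataFrame(
        rows, columns=["species_id", "module", "I_s", "L_s", "z_spp", "C_endem"]
    )


def cell_aspects(
    graph: BipartiteGraph,
    partition: ModulePartition,
    spp: pd.DataFrame | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """The four biodiversity aspects for every cell of a retained module.

    A cell with no present characteristic species cannot receive the two
    median-based aspects; it is returned with ``valid=False`` and excluded
    from clustering downstream (logged, never imputed).  Links to species
    of excluded modules still count toward biota overlap: they are real
    presences of non-characteristic species.
    """
    if spp is None:
        spp = species_aspects(graph, partition, ddof=ddof)
    links = graph.links.copy()
    links["cell_module"] = links["cell_id"].map(partition.cell_modules)
    links["species_module"] = links["species_id"].map(partition.species_modules)
    links["inside"] = links["cell_module"] == links["species_module"]
    L_c = links.groupby("cell_id").size()
    I_c = links[links["inside"]].groupby("cell_id").size()

    sp_stats = spp.set_index("species_id")[["z_spp", "C_endem"]]
    retained = set(partition.retained_modules())
    cell_mod = partition.cell_modules
    rows = []
    n_invalid = 0
    for m in retained:
        cells = cell_mod.index[cell_mod == m]
        i_vals = I_c.reindex(cells, fill_value=0).astype(float)
        sd = i_vals.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise AssertionError(
                f"module {m} has identical cell richness; filter_modules "
                "should have excluded it"
            )
        mean = i_vals.mean()
        in_links = links[links["inside"] & (links["cell_module"] == m)]
        present = in_links.groupby("cell_id")["species_id"].agg(list)
        for c in cells:
            l_c = float(L_c.get(c, 0))
            i_c = float(i_vals[c])
            sp_here = present.get(c, [])
            valid = len(sp_here) > 0 and l_c > 0
            if valid:
                z_med = float(np.median(sp_stats.loc[sp_here, "z_spp"]))
                e_med = float(np.median(sp_stats.loc[sp_here, "C_endem"]))
            else:
                z_med = np.nan
                e_med = np.nan
                n_invalid += 1
            rows.append((
                c, graph.taxon, m,
                (i_c - mean) / sd,
                (l_c - i_c) / l_c if l_c > 0 else np.nan,
                e_med, z_med, valid,
            ))
    if n_invalid:
        logger.info("cell_aspects: %d cells without characteristic species flagged invalid", n_invalid)
    return pd.DataFrame(
        rows,
        columns=["cell_id", "taxon", "module", *ASPECT_COLUMNS, "valid"],
    )


def aspect_correlations(cells: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Pearson correlations between all aspect pairs, flagging |r| >= threshold.

    Constant aspects yield an undefined correlation, reported as missing and
    flagged.
    """
    valid = cells[cells["valid"]] if "valid" in cells.columns else cells
    if len(valid) < 3:
        raise ValidationError("need at least 3 valid cells for correlations")
    rows = []
    for a, b in itertools.combinations(ASPECT_COLUMNS, 2):
        x, y = valid[a].to_numpy(float), valid[b].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((a, b, np.nan, True))
            continue
        r = float(stats.pearsonr(x, y).statistic)
        rows.append((a, b, r, bool(abs(r) >= threshold)))
    return pd.DataFrame(rows, columns=["aspect_a", "aspect_b", "pearson_r", "flagged"])
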