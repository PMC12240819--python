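"""Multi-site Sorensen dissimilarity split into turnover and nestedness.

Sites are the sectors of one bioregion, with species presences pooled over
each sector's cells.  With S_i the richness of site i, S_T the pooled
richness and b_ij the number of species present in site i but not in j,
summing over unordered site pairs:

    beta_SIM = sum(min) / (sum(S_i) - S_T + sum(min))
    beta_SOR = (sum(min) + sum(max)) / (2 (sum(S_i) - S_T) + sum(min) + sum(max))
    beta_SNE = beta_SOR - beta_SIM

where sum(min) and sum(max) run over min(b_ij, b_ji) and max(b_ij, b_ji).
The nestedness share of total dissimilarity is beta_SNE / beta_SOR, and it
is computed separately for characteristic species and for non-characteristic
species grouped by the bioregion they originate from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class BetaPartitionResult:
    beta_sor: float
    beta_sim: float
    beta_sne: float
    nestedness_ratio: float  # NaN when beta_sor == 0
    n_sites: int
    n_species: int
    group: str = ""


def sector_site_matrix(
    classification: pd.DataFrame,
    sectors: pd.Series,
    regions: pd.Series,
    region,
    group: str = "characteristic",
    origin=None,
) -> pd.DataFrame | None:
    """Pool presences of one region into a sector-by-species matrix.

    ``classification`` is the per-presence table from
    :func:`coretrans.bioregions.classify_presences`; ``sectors`` and
    ``regions`` map cell_id to sector and region.  ``group`` selects
    characteristic presences of the region or, with
    ``group='non-characteristic'`` and an ``origin`` module, the region's
    non-characteristic presences originating from that module.  A species is
    present at a site (sector) iff it occurs in at least one of its cells.
    Returns a boolean DataFrame (sites x species), or None (with a log
    entry) when fewer than two sites carry presences of the group.
    """
    cls = classification.copy()
    cls["region"] = cls["cell_id"].map(regions)
    cls["sector"] = cls["cell_id"].map(sectors)
    cls = cls[(cls["region"] == region) & cls["sector"].notna()]
    if group == "characteristic":
        cls = cls[cls["characteristic"]]
    elif group == "non-characteristic":
        cls = cls[~cls["characteristic"]]
        if origin is not None:
            cls = cls[cls["origin_module"] == origin]
    else:
        raise ValidationError(f"unknown group {group!r}")
    if len(cls) == 0:
        logger.info("region %s: no %s presences", region, group)
        return None
    mat = (
        cls.assign(v=True)
        .pivot_table(index="sector", columns="species_id", values="v",
                     aggfunc="any", fill_value=False)
        .astype(bool)
    )
    if len(mat) < 2:
        logger.info("region %s (%s): fewer than 2 sectors with presences; skipped",
                    region, group)
        return None
    return mat


def multisite_sorensen_partition(sites: pd.DataFrame | np.ndarray) -> BetaPartitionResult:
    """Partition multi-site Sorensen dissimilarity into turnover + nestedness.

    ``sites`` is a boolean sites-by-species matrix.  Species absent from
    every site are dropped first.  Identical sites give beta_SOR = 0 and an
    undefined (missing) nestedness ratio.
    """
    M = np.asarray(sites, dtype=bool)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValidationError("need a sites-by-species matrix with >= 2 sites")
    M = M[:, M.any(axis=0)]
    n_sites, n_species = M.shape
    S_i = M.sum(axis=1)
    S_T = int(M.any(axis=0).sum())
    sum_min = 0
    sum_max = 0
    for i, j in combinations(range(n_sites), 2):
        b_ij = int((M[i] & ~M[j]).sum())
        b_ji = int((M[j] & ~M[i]).sum())
        sum_min += min(b_ij, b_ji)
        sum_max += max(b_ij, b_ji)
    core = int(S_i.sum()) - S_T
    denom_sor = 2 * core + sum_min + sum_max
    beta_sor = (sum_min + sum_max) / denom_sor if denom_sor > 0 else 0.0
    denom_sim = core + sum_min
    beta_sim = sum_min / denom_sim if denom_sim > 0 else 0.0
    beta_sne = beta_sor - beta_sim
    if beta_sor > 0:
        ratio = beta_sne / beta_sor
    else:
        ratio = np.nan
        logger.info("identical sites: total dissimilarity 0, ratio undefined")
    return BetaPartitionResult(
        beta_sor=float(beta_sor),
        beta_sim=float(beta_sim),
        beta_sne=float(beta_sne),
        nestedness_ratio=float(ratio) if ratio == ratio else np.nan,
        n_sites=n_sites,
        n_species=n_species,
    )


def nestedness_summary(results: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Share of analyses dominated by nestedness, per species group.

    ``results`` has one row per (region, group) analysis with a
    ``nestedness_ratio`` column; rows with an undefined ratio are ignored.
    Returns per group: the fraction of analyses with ratio above
    ``threshold`` plus distribution summaries.
    """
    if len(results) == 0:
        raise ValidationError("no beta-partition results to summarize")
    ok = results.dropna(subset=["nestedness_ratio"])
    rows = []
    for grp, sub in ok.groupby("group"):
        r = sub["nestedness_ratio"]
        rows.append((
            grp, len(sub), float((r > threshold).mean()),
            float(r.median()), float(r.mean()),
        ))
    return pd.DataFrame(
        rows,
        columns=["group", "n_analyses", "fraction_nested", "median_ratio", "mean_ratio"],
    )
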