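"""Richness decomposition, variance partitioning and the core-richness test.

Cell-level species richness is decomposed into (1) the size of the regional
characteristic species pool, (2) the centred richness of characteristic
species (sorting within the region) and (3) the centred richness of
non-characteristic species.  A weighted linear regression of richness on
these three variables partitions the explained variance; the individual
fraction of a variable is the drop in R^2 when it is removed from the full
model.  Weighting by inverse region size prevents large bioregions from
dominating the fit.

The core-richness randomization asks whether the most core-like sectors
(about 30% of a region's cells) hold more characteristic species than
expected when sector identities are shuffled within the region.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

PREDICTORS = ("pool_size", "centred_char", "centred_nonchar")


def decompose_richness(
    classification: pd.DataFrame,
    regions: pd.Series,
) -> pd.DataFrame:
    """Per-cell richness components.

    ``classification`` is the presence table from
    :func:`coretrans.bioregions.classify_presences`; ``regions`` maps
    cell_id to its bioregion.  Returns one row per cell with observed
    richness S, the regional pool size (total characteristic species of the
    cell's region) and region-centred characteristic / non-characteristic
    richness.  Within each region the centred columns sum to zero.
    """
    cls = classification.copy()
    cls["region"] = cls["cell_id"].map(regions)
    char = cls[cls["characteristic"]].groupby("cell_id").size()
    nonchar = cls[~cls["characteristic"]].groupby("cell_id").size()
    cells = pd.DataFrame({"region": regions})
    cells["char_richness"] = char.reindex(cells.index, fill_value=0)
    cells["nonchar_richness"] = nonchar.reindex(cells.index, fill_value=0)
    cells["S"] = cells["char_richness"] + cells["nonchar_richness"]
    pool = (
        cls[cls["characteristic"]]
        .groupby("region")["species_id"].nunique()
    )
    cells["pool_size"] = cells["region"].map(pool).fillna(0).astype(float)
    means = cells.groupby("region")[["char_richness", "nonchar_richness"]].transform("mean")
    cells["centred_char"] = cells["char_richness"] - means["char_richness"]
    cells["centred_nonchar"] = cells["nonchar_richness"] - means["nonchar_richness"]
    cells["region_size"] = cells.groupby("region")["region"].transform("size")
    return cells.rename_axis("cell_id").reset_index()


def _weighted_r2(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> float:
    """R^2 of a weighted least-squares fit with intercept."""
    sw = np.sqrt(w)
    Xc = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(Xc * sw[:, None], y * sw, rcond=None)
    resid = y - Xc @ coef
    ybar = np.average(y, weights=w)
    tss = float((w * (y - ybar) ** 2).sum())
    if tss == 0:
        return 0.0
    rss = float((w * resid ** 2).sum())
    return 1.0 - rss / tss


def weighted_variance_partition(
    dec: pd.DataFrame,
    weighting: str = "inverse-region-size",
) -> dict:
    """Individual explained-variance fractions of the three predictors.

    Fits richness S on pool_size, centred_char and centred_nonchar by
    (weighted) least squares; the individual fraction of a predictor is
    R^2_full minus the R^2 of the model without it.  Weights are normalized
    to sum to the number of cells, so inference is scale-invariant;
    ``weighting='none'`` is exactly the all-equal-weights run.  A constant
    predictor (e.g., pool size with a single region) gets a missing fraction
    with a reason.
    """
    if len(dec) < 10:
        raise ValidationError("need at least 10 cells for variance partitioning")
    if weighting == "inverse-region-size":
        w = 1.0 / dec["region_size"].to_numpy(float)
    elif weighting == "none":
        w = np.ones(len(dec))
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    w = w * len(w) / w.sum()
    y = dec["S"].to_numpy(float)
    X = dec[list(PREDICTORS)].to_numpy(float)
    r2_full = _weighted_r2(y, X, w)
    fractions = {}
    reasons = {}
    for i, name in enumerate(PREDICTORS):
        if np.allclose(X[:, i], X[0, i]):
            fractions[name] = np.nan
            reasons[name] = "constant predictor (collinear design)"
            continue
        others = np.delete(X, i, axis=1)
        r2_wo = _weighted_r2(y, others, w)
        fractions[name] = max(0.0, r2_full - r2_wo)
    return {
        "r2_full": r2_full,
        "fractions": fractions,
        "reasons": reasons,
        "weighting": weighting,
    }


def default_core_sectors(
    sectors: pd.Series, centroid_order: list, target_share: float = 0.3
) -> list:
    """Pick the most core-like sectors covering about 30% of a region.

    ``centroid_order`` lists sector labels from most to least core-like
    (decreasing centroid relative richness).  Among the prefixes of that
    order, the one whose cell coverage is closest to ``target_share`` is
    chosen (always at least one non-empty sector).
    """
    total = len(sectors)
    prefix: list = []
    covered = 0
    best: tuple[float, list] | None = None
    for s in centroid_order:
        n = int((sectors == s).sum())
        if n == 0:
            continue
        prefix = prefix + [s]
        covered += n
        gap = abs(covered / total - target_share)
        if best is None or gap < best[0]:
            best = (gap, prefix)
    return best[1] if best else []


def core_richness_test(
    classification: pd.DataFrame,
    sectors: pd.Series,
    region_cells: list,
    core_sectors: list,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Permutation test: is core characteristic richness higher than chance?

    The observed statistic is the number of distinct characteristic species
    present in the region's core-sector cells.  The null shuffles the
    sector labels across the region's cells (preserving each sector's cell
    count) and recomputes the statistic.  p = (1 + #{null >= obs}) /
    (n_perm + 1), so it is never exactly zero.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not core_sectors:
        raise ValidationError("core_sectors must be non-empty")
    cells = [c for c in region_cells if c in sectors.index]
    labels = sectors.loc[cells].to_numpy()
    core_mask = np.isin(labels, core_sectors)
    if core_mask.all():
        logger.warning("core covers the whole region; test degenerate")
    char = classification[classification["characteristic"]]
    by_cell = char.groupby("cell_id")["species_id"].agg(set)
    sp_sets = [by_cell.get(c, set()) for c in cells]

    def pooled(mask: np.ndarray) -> int:
        out: set = set()
        for s, m in zip(sp_sets, mask):
            if m:
                out |= s
        return len(out)

    observed = pooled(core_mask)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(cells))
        null[i] = pooled(core_mask[perm])
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return {
        "observed": observed,
        "core_fraction": float(core_mask.mean()),
        "null_mean": float(null.mean()),
        "null_max": float(null.max()),
        "p_value": p,
        "n_perm": n_perm,
        "degenerate": bool(core_mask.all()),
    }
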