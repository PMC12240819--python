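"""Neighbourhood tests between biogeographical sectors.

Within each bioregion, every ordered pair of sectors (A, B) is scored by
how often a cell of A has a cross-sector neighbour in B.  With seven
sectors the chance probability of a given different sector is 1 in 6; a
one-sided proportion test asks whether the observed adjacency exceeds it.
Both directions (A->B and B->A) are tested, and a pair counts as
significantly neighbouring when either direction rejects.  Pairs without
more than ``min_n`` neighbouring instances in either direction are left
untested, avoiding expected counts below five.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import GridGeometry

logger = logging.getLogger(__name__)

_QUEEN = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_ROOK = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def adjacency_counts(
    grid: GridGeometry,
    sectors: pd.Series,
    regions: pd.Series,
    scheme: str = "queen",
) -> pd.DataFrame:
    """Count cross-sector neighbour instances within each region.

    ``sectors`` and ``regions`` map cell_id to sector and region labels.
    For a directed pair (A, B) in a region, ``n`` counts every neighbour
    instance of an A-cell whose (same-region) neighbour lies in a different
    sector, and ``x`` counts those instances landing in B.  Each adjacent
    cell pair contributes one instance in each direction.
    Returns columns: region, sector_a, sector_b, n, x.
    """
    if scheme == "queen":
        offsets = _QUEEN
    elif scheme == "rook":
        offsets = _ROOK
    else:
        raise ValidationError(f"unknown neighbour scheme {scheme!r}")
    pos = grid.cells.set_index("cell_id")[["row", "col"]]
    missing = [c for c in sectors.index if c not in pos.index]
    if missing:
        raise ValidationError(f"assigned cells absent from grid: {missing[:5]}")
    cell_at = {(int(r), int(c)): cid for cid, r, c in
               pos.reset_index().itertuples(index=False, name=None)}
    n_counts: dict[tuple, int] = {}
    x_counts: dict[tuple, int] = {}
    for cid in sectors.index:
        sa = sectors[cid]
        reg = regions.get(cid)
        if reg is None:
            continue
        r, c = int(pos.at[cid, "row"]), int(pos.at[cid, "col"])
        for dr, dc in offsets:
            nb = cell_at.get((r + dr, c + dc))
            if nb is None or nb not in sectors.index:
                continue
            if regions.get(nb) != reg:
                continue
            sb = sectors[nb]
            if sb == sa:
                continue
            n_counts[(reg, sa)] = n_counts.get((reg, sa), 0) + 1
            x_counts[(reg, sa, sb)] = x_counts.get((reg, sa, sb), 0) + 1
    rows = [
        (reg, sa, sb, n_counts[(reg, sa)], x)
        for (reg, sa, sb), x in sorted(x_counts.items(), key=lambda kv: str(kv[0]))
    ]
    return pd.DataFrame(rows, columns=["region", "sector_a", "sector_b", "n", "x"])


def proportion_test_greater(
    x: int, n: int, p0: float = 1 / 6, method: str = "exact"
) -> float:
    """One-sided p-value for H1: true proportion > p0.

    ``exact`` evaluates the binomial tail directly; ``score`` is the
    normal-approximation test with Yates continuity correction (the
    behaviour of R's prop.test).  The exact test is the default because the
    corrected approximation can flip borderline decisions for moderate n.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if method == "exact":
        return float(stats.binomtest(x, n, p0, alternative="greater").pvalue)
    if method == "score":
        yates = min(0.5, abs(x - n * p0))
        chi = (abs(x - n * p0) - yates) ** 2 / (n * p0 * (1 - p0))
        z = np.sign(x - n * p0) * np.sqrt(chi)
        return float(stats.norm.sf(z))
    raise ValidationError(f"unknown method {method!r}")


def neighbor_tests(
    counts: pd.DataFrame,
    p0: float = 1 / 6,
    alpha: float = 0.05,
    min_n: int = 30,
    method: str = "exact",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directional proportion tests per (region, sector pair).

    A direction is tested only when its n exceeds ``min_n``; a pair with
    neither direction testable is reported untested with the reason
    "insufficient neighbours".  The aggregate table gives, per unordered
    sector pair, the relative frequency of significant neighbouring across
    regions (the share of evaluated regions where the pair rejected).

    Returns ``(results, pair_frequency)``.
    """
    lut = {
        (r.region, r.sector_a, r.sector_b): (int(r.n), int(r.x))
        for r in counts.itertuples(index=False)
    }
    pairs = set()
    for reg, sa, sb in ((r.region, r.sector_a, r.sector_b) for r in counts.itertuples(index=False)):
        pairs.add((reg, *sorted((sa, sb), key=str)))
    rows = []
    for reg, a, b in sorted(pairs, key=str):
        n_ab, x_ab = lut.get((reg, a, b), (0, 0))
        n_ba, x_ba = lut.get((reg, b, a), (0, 0))
        test_ab = n_ab > min_n
        test_ba = n_ba > min_n
        p_ab = proportion_test_greater(x_ab, n_ab, p0, method) if test_ab else np.nan
        p_ba = proportion_test_greater(x_ba, n_ba, p0, method) if test_ba else np.nan
        tested = test_ab or test_ba
        significant = bool(
            (test_ab and p_ab < alpha) or (test_ba and p_ba < alpha)
        )
        reason = "" if tested else "insufficient neighbours"
        rows.append((reg, a, b, n_ab, x_ab, n_ba, x_ba, p_ab, p_ba,
                     tested, significant, reason))
    results = pd.DataFrame(rows, columns=[
        "region", "sector_a", "sector_b", "n_ab", "x_ab", "n_ba", "x_ba",
        "p_ab", "p_ba", "tested", "significant", "exclusion_reason",
    ])
    tested = results[results["tested"]]
    if len(tested):
        freq = (
            tested.groupby(["sector_a", "sector_b"])
            .agg(n_regions=("region", "size"), n_significant=("significant", "sum"))
            .reset_index()
        )
        freq["frequency"] = freq["n_significant"] / freq["n_regions"]
    else:
        freq = pd.DataFrame(
            columns=["sector_a", "sector_b", "n_regions", "n_significant", "frequency"]
        )
    return results, freq
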