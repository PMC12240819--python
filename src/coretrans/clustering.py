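"""Two-step k-means delineation of biogeographical sectors.

Step one clusters each taxon's cells separately on the four standardized
biodiversity aspects, choosing the number of clusters by an elbow rule: the
goodness of fit (between-cluster variance over total variance) is computed
for a range of k and a continuous two-segment piecewise-linear model is
fitted at every interior breakpoint; the breakpoint with the lowest residual
standard error is the taxon's k.

Step two clusters all cells of all taxa jointly for each candidate k and
picks the k whose joint partition is most similar, on average across taxa,
to the taxon-specific partitions (adjusted mutual information).  Sectors of
the winning partition are renumbered by decreasing centroid relative
richness, giving a canonical core-to-transition ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_mutual_info_score

from .cartography import ASPECT_COLUMNS
from .errors import ValidationError

logger = logging.getLogger(__name__)


def candidate_partition_count(k_min: int = 2, k_max: int = 14) -> int:
    """How many joint partitions the general clustering sweep evaluates."""
    return len(range(k_min, k_max + 1))


@dataclass
class FeatureMatrix:
    """Standardized cell-by-aspect matrix with per-row weights."""

    frame: pd.DataFrame  # index: (taxon, cell_id); columns: aspects
    weights: np.ndarray
    means: pd.Series
    sds: pd.Series

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(float)


@dataclass
class TaxonSectors:
    """Outcome of one taxon-specific clustering."""

    taxon: str
    labels: pd.Series  # cell_id -> sector label (0-based, internal)
    k: int
    gof_curve: pd.DataFrame  # columns: k, gof


@dataclass
class SectorAssignment:
    """General sectors across all taxa.

    ``frame`` has columns taxon, cell_id, sector with sector labels 1..k
    ordered by decreasing centroid relative richness (1 = most core-like).
    """

    frame: pd.DataFrame
    centroids: pd.DataFrame  # index: sector 1..k; columns: aspects (standardized units)
    k: int
    ami_table: pd.DataFrame  # columns: k, <taxon columns>, mean_ami
    taxon_sectors: dict[str, TaxonSectors] = field(default_factory=dict)

    def sectors_of(self, taxon: str) -> pd.Series:
        sub = self.frame[self.frame["taxon"] == taxon]
        return sub.set_index("cell_id")["sector"]


def standardize(
    features: pd.DataFrame, weights: np.ndarray | None = None
) -> FeatureMatrix:
    """Column-wise z-scoring (sample sd); scaling parameters are stored.

    Idempotent up to numerical tolerance: standardizing an already
    standardized matrix leaves it unchanged.  A zero-variance column is an
    error; upstream validity filters should have removed it.
    """
    if len(features) < 2:
        raise ValidationError("need at least 2 rows to standardize")
    if features.isna().any().any():
        raise ValidationError("missing values in the feature matrix")
    means = features.mean()
    sds = features.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValidationError(f"zero-variance feature columns: {bad}")
    z = (features - means) / sds
    if weights is None:
        weights = np.ones(len(features))
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValidationError("weights must be nonnegative")
    return FeatureMatrix(frame=z, weights=weights, means=means, sds=sds)


def _gof(X: np.ndarray, labels: np.ndarray, centers: np.ndarray, w: np.ndarray) -> float:
    """Weighted between-cluster variance over weighted total variance."""
    mean = np.average(X, axis=0, weights=w)
    tss = float((w[:, None] * (X - mean) ** 2).sum())
    if tss == 0:
        return 0.0
    wss = float((w[:, None] * (X - centers[labels]) ** 2).sum())
    return 1.0 - wss / tss


def weighted_kmeans(
    features: FeatureMatrix,
    k: int,
    restarts: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Best-of-restarts weighted k-means; returns (labels, GoF, centroids).

    Each restart uses seeded random centroid initialization on an
    independent stream derived from ``seed``.  GoF is the weighted
    between-cluster sum of squares over the weighted total sum of squares,
    so uniform weights reduce exactly to unweighted k-means.
    """
    X = features.values
    w = features.weights
    n = len(X)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of rows ({n})")
    if k == 1:
        center = np.average(X, axis=0, weights=w)[None, :]
        return np.zeros(n, dtype=int), 0.0, center
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(restarts):
        rs = int(child.generate_state(1)[0] % (2**31))
        km = KMeans(n_clusters=k, n_init=1, init="random", random_state=rs)
        labels = km.fit_predict(X, sample_weight=w)
        gof = _gof(X, labels, km.cluster_centers_, w)
        if best is None or gof > best[1]:
            best = (labels, gof, km.cluster_centers_)
    return best


def select_k_elbow(ks: np.ndarray, gofs: np.ndarray) -> int:
    """Breakpoint of a continuous two-segment piecewise-linear fit.

    Every interior candidate k is tried as the breakpoint of a continuous
    two-slope least-squares model; the candidate minimizing the residual
    standard error wins, with ties resolved to the smallest k.
    """
    ks = np.asarray(ks, dtype=float)
    gofs = np.asarray(gofs, dtype=float)
    n = len(ks)
    if n < 4:
        raise ValidationError("elbow selection needs at least 4 (k, GoF) points")
    best_k, best_rse = None, np.inf
    for i in range(1, n - 1):
        b = ks[i]
        design = np.column_stack([
            np.ones(n), ks, np.maximum(ks - b, 0.0),
        ])
        coef, _, _, _ = np.linalg.lstsq(design, gofs, rcond=None)
        resid = gofs - design @ coef
        dof = n - 3
        rse = np.sqrt((resid ** 2).sum() / dof) if dof > 0 else np.inf
        if rse < best_rse - 1e-15:
            best_k, best_rse = int(ks[i]), rse
    return best_k


def select_k_by_ami(ami_table: pd.DataFrame) -> int:
    """Candidate k with the highest mean AMI; ties go to the smallest k."""
    t = ami_table.sort_values("k")
    return int(t.loc[t["mean_ami"].idxmax(), "k"])


def ami(labels_a, labels_b) -> float:
    """Adjusted mutual information between two labelings.

    1 iff the labelings are identical up to relabelling; about 0 for
    independent labelings.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValidationError("labelings must have equal length")
    if len(a) < 2:
        raise ValidationError("labelings must have length >= 2")
    return float(adjusted_mutual_info_score(a, b))


def taxon_specific_sectors(
    aspects: pd.DataFrame,
    k_range: tuple[int, int] = (2, 30),
    restarts: int = 100,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> TaxonSectors:
    """Step one: cluster one taxon's valid cells and pick k by the elbow."""
    k_lo, k_hi = k_range
    if k_hi - k_lo + 1 < 4:
        raise ValidationError("k_range must cover at least 4 values")
    taxon = aspects["taxon"].iloc[0] if "taxon" in aspects.columns else "taxon"
    feats = aspects.set_index("cell_id")[list(ASPECT_COLUMNS)]
    k_hi = min(k_hi, len(feats) - 1)
    fm = standardize(feats, weights)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(k_hi - k_lo + 1)
    rows = []
    labelings = {}
    for k, child in zip(range(k_lo, k_hi + 1), children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        labels, gof, _ = weighted_kmeans(fm, k, restarts=restarts, seed=sub_seed)
        rows.append((k, gof))
        labelings[k] = labels
    curve = pd.DataFrame(rows, columns=["k", "gof"])
    k_star = select_k_elbow(curve["k"].to_numpy(), curve["gof"].to_numpy())
    logger.info("taxon %s: elbow at k=%d", taxon, k_star)
    return TaxonSectors(
        taxon=taxon,
        labels=pd.Series(labelings[k_star], index=feats.index, name="sector"),
        k=k_star,
        gof_curve=curve,
    )


def general_sectors(
    aspects: pd.DataFrame,
    taxon_partitions: dict[str, TaxonSectors],
    k_range: tuple[int, int] = (2, 14),
    restarts: int = 100,
    seed: int = 0,
    weight_by_taxon: bool = False,
) -> SectorAssignment:
    """Step two: joint clustering across taxa; k chosen by maximal mean AMI.

    ``aspects`` holds all taxa's valid cells (columns taxon, cell_id and the
    four aspects).  For every candidate k the joint labels are compared,
    taxon by taxon, with the taxon-specific labels; the k with the highest
    across-taxa mean AMI wins (ties go to the smaller k).  With
    ``weight_by_taxon`` cells are weighted by the inverse cell count of
    their taxon, equalizing each taxon's pull on the centroids.
    """
    taxa = list(aspects["taxon"].unique())
    missing = [t for t in taxa if t not in taxon_partitions]
    if missing:
        raise ValidationError(f"missing taxon partitions for {missing}")
    idx = pd.MultiIndex.from_frame(aspects[["taxon", "cell_id"]])
    feats = pd.DataFrame(
        aspects[list(ASPECT_COLUMNS)].to_numpy(float), index=idx,
        columns=list(ASPECT_COLUMNS),
    )
    if weight_by_taxon:
        counts = aspects["taxon"].value_counts()
        weights = (1.0 / counts.loc[aspects["taxon"]]).to_numpy()
        weights *= len(weights) / weights.sum()
    else:
        weights = None
    fm = standardize(feats, weights)

    taxon_rows = {t: np.flatnonzero((aspects["taxon"] == t).to_numpy()) for t in taxa}
    ref_labels = {}
    for t in taxa:
        cells = aspects.loc[aspects["taxon"] == t, "cell_id"]
        ref_labels[t] = taxon_partitions[t].labels.loc[cells].to_numpy()

    k_lo, k_hi = k_range
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(k_hi - k_lo + 1)
    results = {}
    table_rows = []
    for k, child in zip(range(k_lo, k_hi + 1), children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        labels, gof, centers = weighted_kmeans(fm, k, restarts=restarts, seed=sub_seed)
        amis = {t: ami(labels[taxon_rows[t]], ref_labels[t]) for t in taxa}
        mean_ami = float(np.mean(list(amis.values())))
        results[k] = (labels, centers)
        table_rows.append({"k": k, **amis, "mean_ami": mean_ami})
    ami_table = pd.DataFrame(table_rows)
    k_star = select_k_by_ami(ami_table)
    labels, centers = results[k_star]
    logger.info("general sectors: k=%d, mean AMI %.3f", k_star,
                float(ami_table.loc[ami_table["k"] == k_star, "mean_ami"].iloc[0]))

    # canonical ordering: sector 1 = highest centroid relative richness
    rr = centers[:, list(ASPECT_COLUMNS).index("relative_richness")]
    order = np.argsort(-rr)
    rank_of = {int(old): i + 1 for i, old in enumerate(order)}
    sector = np.array([rank_of[int(l)] for l in labels])
    centroids = pd.DataFrame(
        centers[order], columns=list(ASPECT_COLUMNS),
        index=pd.Index(range(1, k_star + 1), name="sector"),
    )
    frame = aspects[["taxon", "cell_id"]].copy()
    frame["sector"] = sector
    return SectorAssignment(
        frame=frame.reset_index(drop=True),
        centroids=centroids,
        k=k_star,
        ami_table=ami_table,
        taxon_sectors=dict(taxon_partitions),
    )
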