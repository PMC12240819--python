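"""Synthetic landscapes with known regions, hotspots and permeable borders.

The generator is a statistical stand-in for rasterized range-map data, not a
mechanistic eco-evolutionary simulation.  It plants the structure the
downstream analysis is designed to detect:

* the lattice is tiled by contiguous regions, each with its own species pool;
* each species' range is a Chebyshev disc whose centroid is drawn with
  density decaying away from the regional hotspot;
* range sizes are right-skewed (log-normal) and larger for species seated
  closer to the region boundary, so occupancy rises toward the edges;
* with some probability a boundary-touching species spills a few cells into
  the neighbouring region, producing cross-region presences; widespread
  species spill preferentially;
* environmental covariates combine a region-specific mean, a within-region
  trend along the core-to-edge axis, and Gaussian noise.

All stochastic draws are made regardless of whether they end up used, so
datasets produced from the same seed under different ``permeability`` values
are coupled monotonically (more permeable never removes a spill).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, ValidationError
from .io import EnvTable, GridGeometry, OccurrenceDataset

logger = logging.getLogger(__name__)


@dataclass
class EnvGradient:
    """Covariate model: region mean + core-to-edge trend + noise.

    value(cell) = base[region, var] + gradient_strength * core_rank + noise

    ``region_separation`` is the s.d. of the region-level means, so regions
    occupy distinct environmental envelopes; ``gradient_strength`` makes
    concentric layers within a region environmentally distinct.
    """

    variables: tuple[str, ...] = ("temperature", "precipitation")
    region_separation: float = 6.0
    gradient_strength: float = 4.0
    noise_sd: float = 1.0


@dataclass
class LandscapeConfig:
    """Study conditions for one synthetic taxon.

    Defaults describe the reference landscape used throughout the test
    suite: a 60x60 lattice tiled by 4 rectangular regions of 200 species
    each, with strongly concentrated hotspots, right-skewed range sizes
    (the median characteristic species occupies about a third of its
    region) and 30% boundary permeability.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    n_regions: int = 4
    species_per_region: int = 200
    #: log-normal parameters of range size, in cells
    range_size_mu: float = math.log(300.0)
    range_size_sigma: float = 0.5
    #: decay rate of range-centroid density away from the hotspot
    hotspot_concentration: float = 8.0
    #: probability that a boundary-touching species spills across the border
    permeability: float = 0.3
    #: maximum depth (cells) a spill reaches into the neighbouring region
    spill_depth: int = 6
    #: rank-coupling noise between centroid distance and range size
    #: (fraction of the pool size; 0 = perfect rank matching)
    size_distance_noise: float = 0.15
    env: EnvGradient = field(default_factory=EnvGradient)
    region_layout: str = "blocks"  # or "voronoi"
    taxon: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if self.species_per_region * self.n_regions == 0:
            raise ConfigError("species_per_region x n_regions must be positive")
        if not 0.0 <= self.permeability <= 1.0:
            raise ConfigError("permeability must lie in [0, 1]")
        if self.grid_rows * self.grid_cols < self.n_regions:
            raise ConfigError("grid too small for the requested regions")
        if self.region_layout not in ("blocks", "voronoi"):
            raise ConfigError(f"unknown region_layout {self.region_layout!r}")


@dataclass
class GroundTruth:
    """Generator-side truth used by recovery tests.

    ``cells``: cell_id, region_id, distance_to_hotspot, core_rank.
    ``species``: species_id, origin_region, true_range_size (realized cells).
    """

    cells: pd.DataFrame
    species: pd.DataFrame

    def region_of(self) -> pd.Series:
        return self.cells.set_index("cell_id")["region_id"]


def _region_map(cfg: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Assign every lattice cell to a region; returns (rows, cols) int array."""
    R, C = cfg.grid_rows, cfg.grid_cols
    if cfg.region_layout == "voronoi":
        seeds = np.column_stack([
            rng.integers(0, R, cfg.n_regions),
            rng.integers(0, C, cfg.n_regions),
        ])
        rr, cc = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
        d = np.maximum(
            np.abs(rr[..., None] - seeds[:, 0]),
            np.abs(cc[..., None] - seeds[:, 1]),
        )
        return np.argmin(d, axis=-1)
    # rectangular blocks: factor n_regions into a near-square grid of blocks
    n = cfg.n_regions
    brows = int(math.floor(math.sqrt(n)))
    while n % brows != 0:
        brows -= 1
    bcols = n // brows
    row_edges = np.linspace(0, R, brows + 1).astype(int)
    col_edges = np.linspace(0, C, bcols + 1).astype(int)
    region = np.zeros((R, C), dtype=int)
    rid = 0
    for i in range(brows):
        for j in range(bcols):
            region[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = rid
            rid += 1
    return region


def _cell_id(r: int, c: int) -> str:
    return f"r{r}c{c}"


def generate_landscape(
    cfg: LandscapeConfig,
) -> tuple[OccurrenceDataset, GridGeometry, EnvTable, GroundTruth]:
    """Generate one taxon's occurrences plus geometry, environment and truth.

    Fully reproducible from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    R, C = cfg.grid_rows, cfg.grid_cols
    region = _region_map(cfg, rng)
    rr, cc = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")

    cell_rows = []
    region_cells: dict[int, np.ndarray] = {}
    dist_maps: dict[int, np.ndarray] = {}
    for rid in range(cfg.n_regions):
        mask = region == rid
        pos = np.column_stack([rr[mask], cc[mask]])
        region_cells[rid] = pos
        # hotspot = cell closest to the centroid of the region
        centroid = pos.mean(axis=0)
        d2 = np.abs(pos - centroid).max(axis=1)
        hotspot = pos[np.argmin(d2)]
        dist = np.abs(pos - hotspot).max(axis=1).astype(float)
        dist_maps[rid] = dist
        n = len(pos)
        core_rank = (rankdata(dist, method="average") - 1) / max(n - 1, 1)
        for (r, c), d, q in zip(pos, dist, core_rank):
            cell_rows.append((_cell_id(r, c), int(r), int(c), rid, float(d), float(q)))

    cells_df = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "row", "col", "region_id", "distance_to_hotspot", "core_rank"],
    ).sort_values(["row", "col"], ignore_index=True)
    core_rank_map = np.zeros((R, C))
    for rec in cells_df.itertuples(index=False):
        core_rank_map[rec.row, rec.col] = rec.core_rank

    links: list[tuple[str, str]] = []
    species_rows = []
    for rid in range(cfg.n_regions):
        pos = region_cells[rid]
        dist = dist_maps[rid]
        n_cells = len(pos)
        S = cfg.species_per_region
        dmax = max(dist.max(), 1.0)
        weights = np.exp(-cfg.hotspot_concentration * dist / dmax)
        weights /= weights.sum()
        centroid_idx = rng.choice(n_cells, size=S, p=weights)
        sizes = np.exp(rng.normal(cfg.range_size_mu, cfg.range_size_sigma, S))
        sizes = np.clip(sizes, 1.0, float(n_cells))
        # couple range size to centroid distance: species farther from the
        # hotspot get larger ranges (rank matching with noise keeps the
        # log-normal marginal intact)
        noisy_rank = rankdata(dist[centroid_idx], method="ordinal") + rng.normal(
            0.0, cfg.size_distance_noise * S, S
        )
        order = np.argsort(np.argsort(noisy_rank))
        sizes_sorted = np.sort(sizes)
        sizes = sizes_sorted[order]
        spill_u = rng.uniform(size=S)
        med_log = np.median(np.log(sizes))
        sigma = cfg.range_size_sigma if cfg.range_size_sigma > 0 else 1.0
        spill_w = 1.0 / (1.0 + np.exp(-(np.log(sizes) - med_log) / sigma))
        p_spill = np.clip(2.0 * cfg.permeability * spill_w, 0.0, 1.0)
        if cfg.permeability == 0.0:
            p_spill[:] = 0.0

        rmin, rmax = pos[:, 0].min(), pos[:, 0].max()
        cmin, cmax = pos[:, 1].min(), pos[:, 1].max()
        in_region = region == rid
        for j in range(S):
            sid = f"sp{rid}_{j}"
            cr, ccol = pos[centroid_idx[j]]
            radius = max(0, int(round((math.sqrt(sizes[j]) - 1) / 2)))
            r0, r1 = max(0, cr - radius), min(R - 1, cr + radius)
            c0, c1 = max(0, ccol - radius), min(C - 1, ccol + radius)
            block_r = slice(r0, r1 + 1)
            block_c = slice(c0, c1 + 1)
            sub_region = region[block_r, block_c]
            sub_rr = rr[block_r, block_c]
            sub_cc = cc[block_r, block_c]
            inside = sub_region == rid
            occ_r = list(sub_rr[inside])
            occ_c = list(sub_cc[inside])
            if spill_u[j] < p_spill[j]:
                outside = ~inside
                if cfg.region_layout == "blocks":
                    dxr = np.maximum(0, np.maximum(rmin - sub_rr, sub_rr - rmax))
                    dxc = np.maximum(0, np.maximum(cmin - sub_cc, sub_cc - cmax))
                    depth = np.maximum(dxr, dxc)
                else:
                    depth = np.where(outside, 1, 0)
                ok = outside & (depth <= cfg.spill_depth) & (depth > 0)
                occ_r += list(sub_rr[ok])
                occ_c += list(sub_cc[ok])
            if not occ_r:
                # disc clipped entirely outside its region (possible only for
                # centroids at the lattice edge); keep the centroid cell
                occ_r, occ_c = [cr], [ccol]
            for r_, c_ in zip(occ_r, occ_c):
                links.append((sid, _cell_id(r_, c_)))
            species_rows.append((sid, rid, len(occ_r)))

    occ = pd.DataFrame(links, columns=["species_id", "cell_id"]).drop_duplicates()
    present = set(occ["cell_id"])
    missing = len(cells_df) - len(present)
    if missing:
        logger.info("generate_landscape: %d cells without any presence", missing)
    dataset = OccurrenceDataset(taxon=cfg.taxon, records=occ.reset_index(drop=True))

    grid = GridGeometry(
        cells=cells_df[["cell_id", "row", "col"]].copy(), resolution=111.0
    )

    env_base = rng.normal(
        0.0, cfg.env.region_separation, size=(cfg.n_regions, len(cfg.env.variables))
    )
    env_noise = rng.normal(
        0.0, cfg.env.noise_sd, size=(len(cells_df), len(cfg.env.variables))
    )
    env_data = {}
    for v, var in enumerate(cfg.env.variables):
        env_data[var] = (
            env_base[cells_df["region_id"].to_numpy(), v]
            + cfg.env.gradient_strength * cells_df["core_rank"].to_numpy()
            + env_noise[:, v]
        )
    env = EnvTable(table=pd.DataFrame(env_data, index=pd.Index(cells_df["cell_id"], name="cell_id")))

    truth = GroundTruth(
        cells=cells_df[["cell_id", "region_id", "distance_to_hotspot", "core_rank"]].copy(),
        species=pd.DataFrame(
            species_rows, columns=["species_id", "origin_region", "true_range_size"]
        ),
    )
    return dataset, grid, env, truth


def truth_sector_layers(truth: GroundTruth, n_layers: int) -> pd.Series:
    """Discretize core_rank into concentric layers per region.

    Equal-frequency binning of core_rank within each region; ties at bin
    edges are broken by cell_id order, making the output deterministic.
    Regions with fewer cells than ``n_layers`` get fewer layers (warned).
    Returns a Series cell_id -> layer index (0 = innermost).
    """
    if n_layers < 2:
        raise ValidationError("n_layers must be >= 2")
    out = {}
    for rid, grp in truth.cells.groupby("region_id"):
        grp = grp.sort_values(["core_rank", "cell_id"])
        n = len(grp)
        k = min(n_layers, n)
        if k < n_layers:
            logger.warning("region %s has %d cells < %d layers; using %d", rid, n, n_layers, k)
        layers = np.floor(np.arange(n) * k / n).astype(int)
        out.update(dict(zip(grp["cell_id"], layers)))
    return pd.Series(out, name="layer").rename_axis("cell_id")


def planted_archetype_aspects(
    n_archetypes: int = 5,
    n_taxa: int = 3,
    cells_per_taxon: int = 150,
    separation: float = 6.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-aspect vectors drawn around shared archetype centroids.

    Every taxon's cells are sampled from the same ``n_archetypes`` Gaussian
    archetypes in the 4-dimensional aspect space, emulating biodiversity
    aspects organized the same way across taxa.  Up to five archetypes are
    placed at the vertices of a regular simplex so every pair is exactly
    ``separation`` apart; beyond five (which cannot be equidistant in four
    dimensions) the centers are drawn at random.  Returns a frame with
    columns taxon, cell_id, the four aspects, and the true archetype id.
    """
    rng = np.random.default_rng(seed)
    if n_archetypes <= 5:
        eye = np.eye(n_archetypes)
        simplex = eye - eye.mean(axis=0)
        simplex = simplex[:, : n_archetypes - 1]
        # embed into 4-D, scale so pairwise distances equal `separation`,
        # and rotate so every aspect column carries part of the signal
        centers = np.zeros((n_archetypes, 4))
        centers[:, : simplex.shape[1]] = simplex / np.sqrt(2.0) * separation
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        centers = centers @ q
    else:
        centers = rng.normal(0.0, separation, size=(n_archetypes, 4))
    rows = []
    cols = ["relative_richness", "biota_overlap", "endemicity", "relative_occupancy"]
    for t in range(n_taxa):
        arch = rng.integers(0, n_archetypes, size=cells_per_taxon)
        x = centers[arch] + rng.normal(0.0, noise_sd, size=(cells_per_taxon, 4))
        for i in range(cells_per_taxon):
            rows.append([f"taxon{t}", f"t{t}_c{i}", *x[i], int(arch[i])])
    return pd.DataFrame(rows, columns=["taxon", "cell_id", *cols, "archetype"])
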