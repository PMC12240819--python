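"""Tabular input/output: occurrences, grid geometry, environmental covariates.

All files are plain UTF-8 CSV with a header row.  The analysis operates on
per-cell presences; rasterization of range polygons happens upstream and is
out of scope here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: km per degree of latitude; used only to draw square cell polygons in
#: GeoJSON exports.  No analysis depends on this constant.
KM_PER_DEGREE = 111.32


@dataclass
class OccurrenceDataset:
    """Presence links between species and grid cells for one taxon.

    ``records`` holds one row per (species_id, cell_id) presence, with no
    duplicates; every species occurs in at least one cell and vice versa.
    """

    taxon: str
    records: pd.DataFrame  # columns: species_id, cell_id

    def __post_init__(self) -> None:
        req = {"species_id", "cell_id"}
        if not req.issubset(self.records.columns):
            raise FormatError(f"occurrence records need columns {sorted(req)}")
        if self.records.duplicated(["species_id", "cell_id"]).any():
            raise ValidationError("duplicate (species_id, cell_id) presences")
        if len(self.records) == 0:
            raise EmptyInputError("occurrence dataset has no presences")

    @property
    def n_species(self) -> int:
        return self.records["species_id"].nunique()

    @property
    def n_cells(self) -> int:
        return self.records["cell_id"].nunique()

    @property
    def n_links(self) -> int:
        return len(self.records)


@dataclass
class GridGeometry:
    """Regular-grid cell table: id, lattice position, optional lon/lat/area."""

    cells: pd.DataFrame  # columns: cell_id, row, col, lon, lat, area_km2
    resolution: float = 111.0  # km

    def __post_init__(self) -> None:
        req = {"cell_id", "row", "col"}
        if not req.issubset(self.cells.columns):
            raise FormatError(f"grid table needs columns {sorted(req)}")
        if self.cells["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell_id in grid")
        if self.cells.duplicated(["row", "col"]).any():
            raise ValidationError("duplicate (row, col) position in grid")
        cells = self.cells.copy()
        if "lon" not in cells.columns:
            cells["lon"] = cells["col"] * self.resolution / KM_PER_DEGREE
        if "lat" not in cells.columns:
            cells["lat"] = cells["row"] * self.resolution / KM_PER_DEGREE
        if "area_km2" not in cells.columns:
            cells["area_km2"] = float(self.resolution) ** 2
        if (cells["area_km2"] <= 0).any():
            raise ValidationError("cell areas must be positive")
        self.cells = cells

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def positions(self) -> pd.DataFrame:
        return self.cells.set_index("cell_id")[["row", "col"]]


@dataclass
class EnvTable:
    """Per-cell environmental covariates (one row per cell)."""

    table: pd.DataFrame  # index: cell_id; columns: covariates

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate cell_id in environmental table")
        if self.table.columns.duplicated().any():
            raise ValidationError("duplicate covariate name")

    @property
    def covariates(self) -> list[str]:
        return list(self.table.columns)


def read_occurrences(path: str | Path, taxon: str | None = None) -> OccurrenceDataset:
    """Read long-format presences (columns taxon, species_id, cell_id).

    Duplicate presences are collapsed with a warning.  If the file holds a
    single taxon the ``taxon`` argument may be omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    if len(df) == 0:
        raise EmptyInputError(f"{path} is empty")
    req = {"taxon", "species_id", "cell_id"}
    missing = req - set(df.columns)
    if missing:
        raise FormatError(f"{path} lacks columns {sorted(missing)}")
    if taxon is not None:
        df = df[df["taxon"] == taxon]
        if len(df) == 0:
            raise EmptyInputError(f"no records for taxon {taxon!r} in {path}")
    else:
        taxa = df["taxon"].unique()
        if len(taxa) > 1:
            raise FormatError(
                f"{path} holds {len(taxa)} taxa; pass taxon= to select one"
            )
        taxon = taxa[0]
    n_before = len(df)
    df = df.drop_duplicates(["species_id", "cell_id"])
    if len(df) < n_before:
        logger.warning(
            "collapsed %d duplicate presences in %s", n_before - len(df), path
        )
    ds = OccurrenceDataset(taxon=taxon, records=df[["species_id", "cell_id"]].reset_index(drop=True))
    logger.info(
        "read %s: %d species, %d cells, %d presences",
        path, ds.n_species, ds.n_cells, ds.n_links,
    )
    return ds


def read_grid(path: str | Path, resolution: float = 111.0) -> GridGeometry:
    """Read the grid geometry table (cell_id,row,col[,lon,lat,area_km2]).

    Missing areas are filled as resolution squared.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    req = {"cell_id", "row", "col"}
    missing = req - set(df.columns)
    if missing:
        raise FormatError(f"{path} lacks columns {sorted(missing)}")
    df["cell_id"] = df["cell_id"].astype(str)
    return GridGeometry(cells=df, resolution=resolution)


def read_env(path: str | Path) -> EnvTable:
    """Read per-cell covariates (cell_id,<var1>,<var2>,...)."""
    df = pd.read_csv(Path(path))
    if "cell_id" not in df.columns:
        raise FormatError(f"{path} lacks a cell_id column")
    df["cell_id"] = df["cell_id"].astype(str)
    return EnvTable(table=df.set_index("cell_id"))


def aggregate_env(pixel_table: pd.DataFrame, grid: GridGeometry) -> EnvTable:
    """Average pixel values within each grid cell.

    ``pixel_table`` has columns (cell_id, variable, value); the result has
    one row per cell and one column per variable, the mean over contributing
    pixels.  Cells without pixels for a variable get a missing value and are
    flagged in the log.  Idempotent on already-aggregated tables.
    """
    req = {"cell_id", "variable", "value"}
    if not req.issubset(pixel_table.columns):
        raise FormatError(f"pixel table needs columns {sorted(req)}")
    known = set(grid.cells["cell_id"].astype(str))
    bad = set(pixel_table["cell_id"].astype(str)) - known
    if bad:
        raise ValidationError(f"pixel rows reference unknown cells: {sorted(bad)[:5]}")
    wide = (
        pixel_table.assign(cell_id=pixel_table["cell_id"].astype(str))
        .groupby(["cell_id", "variable"])["value"].mean().unstack("variable")
    )
    wide = wide.reindex(grid.cells["cell_id"].astype(str))
    wide.columns.name = None
    n_missing = int(wide.isna().sum().sum())
    if n_missing:
        logger.warning("aggregate_env: %d (cell, variable) combinations have no pixels", n_missing)
    return EnvTable(table=wide)


def write_sector_map(
    assignment: pd.DataFrame,
    grid: GridGeometry,
    path: str | Path,
) -> None:
    """Export sector assignments as GeoJSON squares plus a flat CSV twin.

    ``assignment`` needs columns cell_id, taxon, bioregion, sector.  Cell
    polygons are axis-aligned squares centred on (lon, lat) with side equal
    to the grid resolution converted to degrees via ``KM_PER_DEGREE``;
    they exist for visualization only.
    """
    req = {"cell_id", "taxon", "bioregion", "sector"}
    missing = req - set(assignment.columns)
    if missing:
        raise FormatError(f"assignment lacks columns {sorted(missing)}")
    path = Path(path)
    geo = grid.cells.set_index("cell_id")
    unknown = set(assignment["cell_id"].astype(str)) - set(geo.index.astype(str))
    if unknown:
        raise ValidationError(f"assigned cells absent from grid: {sorted(unknown)[:5]}")
    if len(assignment) == 0:
        logger.warning("write_sector_map: empty assignment")
    half = grid.resolution / KM_PER_DEGREE / 2.0
    features = []
    for rec in assignment.itertuples(index=False):
        cell = geo.loc[str(rec.cell_id)]
        lon, lat = float(cell["lon"]), float(cell["lat"])
        ring = [
            [lon - half, lat - half], [lon + half, lat - half],
            [lon + half, lat + half], [lon - half, lat + half],
            [lon - half, lat - half],
        ]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {
                "cell_id": str(rec.cell_id),
                "taxon": rec.taxon,
                "bioregion": rec.bioregion,
                "sector": int(rec.sector),
            },
        })
    collection = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(collection))
    csv_path = path.with_suffix(".csv")
    assignment[["cell_id", "taxon", "bioregion", "sector"]].to_csv(csv_path, index=False)
    logger.info("wrote %d features to %s (+ %s)", len(features), path, csv_path)
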