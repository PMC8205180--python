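"""Occurrence curation and gridding onto a regular lat/lon lattice.

Records are curated (coordinate presence, world bounds, optional study-region
polygon), binned into half-open 0.25-degree cells, and poorly sampled cells
(< 5 records by default) are excluded with their records folded into a
neighbouring retained cell, mirroring the standard practice of integrating
sparse cells into their neighbours before turnover analysis.

Conventions the literature leaves unstated, fixed here for determinism:

* cells are half-open ``[edge, edge + size)`` in both axes, lower-left
  origin, 0-based integer indices;
* an excluded cell's records go to the retained queen-neighbour with the
  most records (ties: lowest cell id), searching outward ring by ring up to
  ``search_radius``; excluded cells are processed in ascending record-count
  order against the *original* retained set, so the result is
  order-independent;
* species names are whitespace-normalized and lower-cased; no synonym
  resolution is attempted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from ._geo import cell_polygon_coords, write_feature_collection

__all__ = [
    "GridSpec",
    "CellTable",
    "curate_records",
    "assign_to_grid",
    "filter_and_merge",
    "incidence_matrix",
    "read_occurrences_csv",
]

_WS = re.compile(r"\s+")


def normalize_species(name: str) -> str:
    return _WS.sub(" ", str(name).strip()).lower()


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: lower-left origin in degrees, square cells."""

    origin: tuple[float, float]
    cell_size: float = 0.25
    region_polygon: Optional[BaseGeometry] = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def cell_index(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ix = np.floor((np.asarray(lon) - self.origin[0]) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(lat) - self.origin[1]) / self.cell_size).astype(int)
        return ix, iy

    def cell_polygon(self, ix: int, iy: int) -> Polygon:
        return Polygon(cell_polygon_coords(ix, iy, self.origin, self.cell_size))


def _cell_id(ix: int, iy: int) -> str:
    if ix < 0 or iy < 0:
        raise ValueError(
            f"record maps to negative cell index ({ix}, {iy}); move the grid origin"
        )
    return f"c{ix:03d}_{iy:03d}"


@dataclass
class CellTable:
    """Grid cells with their records, species sets and merge provenance.

    ``records`` keeps every occurrence with its current ``cell_id`` so that
    record counts stay auditable through filtering and merging; ``merge_log``
    lists one row per excluded cell (receiving_cell is empty for dropped
    orphans).
    """

    grid: GridSpec
    cells: pd.DataFrame  # index cell_id; columns ix, iy, record_count
    records: pd.DataFrame  # species, lon, lat, cell_id (+ passthrough cols)
    merge_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["excluded_cell", "receiving_cell", "n_records"]
        )
    )

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cells.index)

    @property
    def total_records(self) -> int:
        return int(len(self.records))

    def species_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {cid: set() for cid in self.cells.index}
        for cid, grp in self.records.groupby("cell_id"):
            out[cid] = set(grp["species"])
        return out

    def write_long_csv(self, path) -> None:
        """Long-form cell/species presence table."""
        rows = [
            (cid, sp)
            for cid, spp in sorted(self.species_sets().items())
            for sp in sorted(spp)
        ]
        pd.DataFrame(rows, columns=["cell_id", "species"]).to_csv(path, index=False)

    def write_geojson(self, path) -> None:
        geoms = [self.grid.cell_polygon(int(r.ix), int(r.iy)) for r in self.cells.itertuples()]
        props = [
            {"cell_id": cid, "record_count": int(r["record_count"])}
            for cid, r in self.cells.iterrows()
        ]
        write_feature_collection(path, geoms, props)


def read_occurrences_csv(
    path,
    species_col: str = "species",
    lon_col: str = "decimalLongitude",
    lat_col: str = "decimalLatitude",
) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in (species_col, lon_col, lat_col) if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence file lacks columns {missing}")
    return df.rename(columns={species_col: "species", lon_col: "lon", lat_col: "lat"})


def curate_records(
    records: pd.DataFrame,
    region_polygon: Optional[BaseGeometry] = None,
    species_col: str = "species",
    lon_col: str = "lon",
    lat_col: str = "lat",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records without usable coordinates or outside the study region.

    Containment is closed: a point exactly on the region boundary is kept.
    Returns the curated table (columns ``species``, ``lon``, ``lat``) and a
    rejection report keyed by cause.
    """
    if len(records) == 0:
        raise ValueError("empty occurrence table")
    df = records.rename(columns={species_col: "species", lon_col: "lon", lat_col: "lat"}).copy()
    for c in ("species", "lon", "lat"):
        if c not in df.columns:
            raise ValueError(f"missing column {c!r}")

    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["species"] = df["species"].map(normalize_species)

    report = {"missing_coords": 0, "out_of_bounds": 0, "out_of_region": 0, "empty_species": 0}

    ok = df["lon"].notna() & df["lat"].notna()
    report["missing_coords"] = int((~ok).sum())
    df = df[ok]

    named = df["species"].str.len() > 0
    report["empty_species"] = int((~named).sum())
    df = df[named]

    in_world = df["lon"].between(-180, 180) & df["lat"].between(-90, 90)
    report["out_of_bounds"] = int((~in_world).sum())
    df = df[in_world]

    if region_polygon is not None and len(df):
        prepared = prep(region_polygon)
        # prepared.covers is closed containment: boundary points are kept
        inside = np.fromiter(
            (prepared.covers(Point(x, y)) for x, y in zip(df["lon"], df["lat"])),
            dtype=bool,
            count=len(df),
        )
        report["out_of_region"] = int((~inside).sum())
        df = df[inside]

    return df.reset_index(drop=True), report


def assign_to_grid(records: pd.DataFrame, grid: GridSpec) -> CellTable:
    """Bin curated records into half-open grid cells.

    A record at an interior cell edge belongs to the higher-index cell
    (floor rule). When the grid has a region polygon, only cells whose
    polygon intersects it are created; records falling in non-intersecting
    cells are discarded with a warning.
    """
    df = records.copy()
    ix, iy = grid.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
    df["cell_id"] = [_cell_id(i, j) for i, j in zip(ix, iy)]

    cells = (
        df.groupby("cell_id")
        .agg(record_count=("species", "size"))
        .join(
            pd.DataFrame(
                {"cell_id": df["cell_id"], "ix": ix, "iy": iy}
            ).drop_duplicates("cell_id").set_index("cell_id")
        )
        .sort_index()[["ix", "iy", "record_count"]]
    )

    if grid.region_polygon is not None:
        keep = [
            cid
            for cid, r in cells.iterrows()
            if grid.cell_polygon(int(r["ix"]), int(r["iy"])).intersects(grid.region_polygon)
        ]
        dropped = len(cells) - len(keep)
        if dropped:
            warnings.warn(f"{dropped} cells outside the region polygon discarded")
        cells = cells.loc[keep]
        df = df[df["cell_id"].isin(cells.index)].reset_index(drop=True)

    return CellTable(grid=grid, cells=cells, records=df)


def filter_and_merge(
    table: CellTable,
    min_records: int = 5,
    search_radius: int = 2,
    on_orphan: str = "drop",
) -> CellTable:
    """Exclude cells with fewer than ``min_records`` records, folding their
    records into a neighbouring retained cell.

    The receiving cell is the retained cell in the smallest Chebyshev ring
    around the excluded cell with the highest (original) record count, ties
    broken by lowest cell id. Orphans (no retained cell within
    ``search_radius`` rings) are dropped with a warning by default, or raise
    if ``on_orphan="error"``. Total record count is conserved up to logged
    orphan drops.
    """
    if on_orphan not in ("drop", "error"):
        raise ValueError("on_orphan must be 'drop' or 'error'")
    cells = table.cells
    retained = cells[cells["record_count"] >= min_records]
    excluded = cells[cells["record_count"] < min_records]

    if excluded.empty:
        return CellTable(
            grid=table.grid,
            cells=cells.copy(),
            records=table.records.copy(),
            merge_log=table.merge_log.iloc[0:0].copy(),
        )
    if retained.empty:
        raise ValueError(f"no cell reaches min_records={min_records}")

    ret_by_pos = {(int(r.ix), int(r.iy)): cid for cid, r in retained.iterrows()}
    log_rows = []
    target: dict[str, str | None] = {}
    order = excluded.loc[
        excluded.assign(_id=excluded.index)
        .sort_values(["record_count", "_id"], kind="mergesort")
        .index
    ]
    for cid, r in order.iterrows():
        cx, cy = int(r["ix"]), int(r["iy"])
        receiver = None
        for ring in range(1, search_radius + 1):
            candidates = []
            for dx in range(-ring, ring + 1):
                for dy in range(-ring, ring + 1):
                    if max(abs(dx), abs(dy)) != ring:
                        continue
                    ncid = ret_by_pos.get((cx + dx, cy + dy))
                    if ncid is not None:
                        candidates.append(ncid)
            if candidates:
                # highest original record count, then lowest cell id
                receiver = min(
                    candidates, key=lambda c: (-int(retained.at[c, "record_count"]), c)
                )
                break
        if receiver is None and on_orphan == "error":
            raise ValueError(
                f"cell {cid} has no retained neighbour within radius {search_radius}"
            )
        target[cid] = receiver
        log_rows.append((cid, receiver if receiver else "", int(r["record_count"])))

    orphans = [c for c, t in target.items() if t is None]
    if orphans:
        warnings.warn(
            f"{len(orphans)} excluded cells had no retained neighbour within "
            f"radius {search_radius}; their records were dropped"
        )

    records = table.records.copy()
    mapped = records["cell_id"].map(lambda c: target.get(c, c))
    keep = mapped.notna()
    records = records[keep].copy()
    records["cell_id"] = mapped[keep]

    new_cells = retained.copy()
    new_counts = records.groupby("cell_id").size()
    new_cells["record_count"] = new_counts.reindex(new_cells.index, fill_value=0).astype(int)

    merge_log = pd.DataFrame(log_rows, columns=["excluded_cell", "receiving_cell", "n_records"])
    return CellTable(
        grid=table.grid, cells=new_cells.sort_index(), records=records.reset_index(drop=True),
        merge_log=merge_log,
    )


def incidence_matrix(table: CellTable) -> pd.DataFrame:
    """Presence/absence matrix: rows = sorted cell ids, columns = sorted
    species names; entry 1 iff the species has at least one record in the
    cell."""
    pivot = (
        table.records.assign(v=1)
        .pivot_table(index="cell_id", columns="species", values="v", aggfunc="max", fill_value=0)
        .reindex(index=sorted(table.cells.index), fill_value=0)
        .astype(int)
    )
    pivot = pivot[sorted(pivot.columns)]
    pivot.index.name = "cell_id"
    return pivot
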