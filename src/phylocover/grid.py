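"""Presence grids, community matrices, taxon tables, and site cells.

Spatial data live on a regular ``n_rows x n_cols`` grid.  Cells are indexed
row-major and 0-based; ``cell = row * n_cols + col``.  The grid's y axis
increases downward (raster order): row 0 starts at ``origin_y`` and row
indices grow with y.  Cell intervals are half-open,
``[origin + i*cell_size, origin + (i+1)*cell_size)``.

Per-taxon presence is exchanged as a tiny text raster dialect:

    rows cols origin_x origin_y cell_size
    0 1 0 ...
    ...

one file per taxon per season, conventionally named ``<taxon>.<season>.grid``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "PresenceLayer",
    "CommunityMatrix",
    "SiteSet",
    "read_presence_raster",
    "write_presence_raster",
    "read_taxon_table",
    "write_taxon_table",
    "validate_taxon_table",
    "lump_taxa",
    "build_community_matrix",
    "map_points_to_cells",
    "read_sites_csv",
    "write_sites_csv",
]

SEASONS = ("breeding", "wintering")


@dataclass(frozen=True)
class GridSpec:
    """Regular grid geometry: shape, origin, and square cell size."""

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"(row, col) = ({row}, {col}) outside grid")
        return row * self.n_cols + col

    def rowcol(self, cell: int) -> tuple[int, int]:
        if not 0 <= cell < self.n_cells:
            raise IndexError(f"cell {cell} outside grid")
        return divmod(cell, self.n_cols)

    def cell_center(self, cell: int) -> tuple[float, float]:
        r, c = self.rowcol(cell)
        return (
            self.origin_x + (c + 0.5) * self.cell_size,
            self.origin_y + (r + 0.5) * self.cell_size,
        )


@dataclass(frozen=True)
class PresenceLayer:
    """Cells where one taxon is present in one season."""

    taxon: str
    season: str
    cells: frozenset[int]
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")
        bad = [c for c in self.cells if not 0 <= c < self.grid.n_cells]
        if bad:
            raise ValueError(f"cell indices outside grid: {sorted(bad)[:5]}...")

    def to_array(self) -> np.ndarray:
        a = np.zeros(self.grid.n_cells, dtype=bool)
        a[list(self.cells)] = True
        return a


@dataclass(frozen=True)
class CommunityMatrix:
    """Cells x taxa incidence for one season.

    ``incidence`` is a boolean DataFrame whose index is every cell id of
    the grid (0..n_cells-1) and whose columns are taxon labels.
    """

    grid: GridSpec
    season: str
    incidence: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.incidence) != self.grid.n_cells:
            raise ValueError("incidence rows must cover every grid cell")
        if self.incidence.columns.duplicated().any():
            raise ValueError("duplicate taxon columns")

    @property
    def taxa(self) -> list[str]:
        return list(self.incidence.columns)

    def values(self) -> np.ndarray:
        return self.incidence.to_numpy(dtype=bool)


@dataclass(frozen=True)
class SiteSet:
    """Ordered distinct grid cells, either focal (e.g. site centers) or random."""

    cell_ids: tuple[int, ...]
    source: str = "focal"

    def __post_init__(self) -> None:
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be distinct")
        if self.source not in ("focal", "random"):
            raise ValueError("source must be 'focal' or 'random'")

    def __len__(self) -> int:
        return len(self.cell_ids)


# ---------------------------------------------------------------------- #
# text raster dialect
# ---------------------------------------------------------------------- #


def _check_header(grid: GridSpec, parts: Sequence[str], path: str) -> None:
    rows, cols = int(parts[0]), int(parts[1])
    ox, oy, cs = (float(p) for p in parts[2:5])
    same = (
        rows == grid.n_rows
        and cols == grid.n_cols
        and math.isclose(ox, grid.origin_x, abs_tol=1e-9)
        and math.isclose(oy, grid.origin_y, abs_tol=1e-9)
        and math.isclose(cs, grid.cell_size, abs_tol=1e-9)
    )
    if not same:
        raise ValueError(
            f"{path}: raster header ({rows} {cols} {ox} {oy} {cs}) does not match "
            f"grid ({grid.n_rows} {grid.n_cols} {grid.origin_x} {grid.origin_y} "
            f"{grid.cell_size})"
        )


def read_presence_raster(path: str | Path, grid: GridSpec, taxon: str, season: str) -> PresenceLayer:
    """Read one 0/1 text raster into a :class:`PresenceLayer`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty raster file")
    header = lines[0].split()
    if len(header) != 5:
        raise ValueError(f"{path}: header must be 'rows cols origin_x origin_y cell_size'")
    _check_header(grid, header, str(path))
    body = [ln.split() for ln in lines[1:] if ln.strip()]
    if len(body) != grid.n_rows or any(len(row) != grid.n_cols for row in body):
        raise ValueError(f"{path}: raster body does not match {grid.n_rows}x{grid.n_cols}")
    flat = [v for row in body for v in row]
    bad = sorted({v for v in flat if v not in ("0", "1")})
    if bad:
        raise ValueError(f"{path}: entries other than 0/1: {bad}")
    cells = frozenset(i for i, v in enumerate(flat) if v == "1")
    return PresenceLayer(taxon=taxon, season=season, cells=cells, grid=grid)


def write_presence_raster(layer: PresenceLayer, path: str | Path) -> None:
    g = layer.grid
    a = layer.to_array().astype(int).reshape(g.n_rows, g.n_cols)
    with open(path, "w") as fh:
        fh.write(f"{g.n_rows} {g.n_cols} {g.origin_x:g} {g.origin_y:g} {g.cell_size:g}\n")
        for row in a:
            fh.write(" ".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------- #
# taxon table
# ---------------------------------------------------------------------- #


def validate_taxon_table(table: pd.DataFrame) -> None:
    """Check the taxon-table contract: unique taxa, groups of >= 2 members."""
    if table.index.name != "taxon":
        raise ValueError("taxon table index must be named 'taxon'")
    if table.index.duplicated().any():
        dupes = sorted(table.index[table.index.duplicated()].unique())
        raise ValueError(f"duplicate taxa in table: {dupes}")
    for col in ("rl_flag",):
        if col not in table.columns:
            raise ValueError(f"taxon table missing column {col!r}")
    if "lump_group" in table.columns:
        sizes = Counter(g for g in table["lump_group"] if isinstance(g, str) and g)
        tiny = sorted(g for g, c in sizes.items() if c < 2)
        if tiny:
            raise ValueError(f"lump groups with fewer than 2 members: {tiny}")


def read_taxon_table(path: str | Path) -> pd.DataFrame:
    """CSV with columns taxon, rl_flag (0/1), lump_group (may be empty)."""
    df = pd.read_csv(path, dtype={"taxon": str, "lump_group": str}, keep_default_na=False)
    if "lump_group" not in df.columns:
        df["lump_group"] = ""
    df["rl_flag"] = df["rl_flag"].astype(int).astype(bool)
    df["lump_group"] = df["lump_group"].replace({"": None})
    df = df.set_index("taxon")
    validate_taxon_table(df)
    return df


def write_taxon_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["rl_flag"] = out["rl_flag"].astype(int)
    if "lump_group" in out.columns:
        out["lump_group"] = out["lump_group"].fillna("")
    out.to_csv(path)


# ---------------------------------------------------------------------- #
# operations
# ---------------------------------------------------------------------- #


def lump_taxa(
    layers: Sequence[PresenceLayer], table: pd.DataFrame
) -> tuple[list[PresenceLayer], pd.DataFrame]:
    """Merge taxa that share a ``lump_group``.

    Per group and season the merged layer is named by the group label and its
    cell set is the union of the member cell sets; ungrouped taxa pass
    through.  Returns the merged layers together with the lumped taxon table,
    where a merged taxon's red-list flag is the OR of its members' flags.
    Idempotent: the returned table carries no lump groups.
    """
    validate_taxon_table(table)
    groups: dict[str, list[str]] = {}
    if "lump_group" in table.columns:
        for taxon, g in table["lump_group"].items():
            if isinstance(g, str) and g:
                groups.setdefault(g, []).append(taxon)

    layer_taxa = {ly.taxon for ly in layers}
    for g, members in groups.items():
        missing = sorted(set(members) - layer_taxa)
        if missing:
            raise ValueError(f"lump group {g!r}: members with no presence layer: {missing}")

    member_of = {t: g for g, ms in groups.items() for t in ms}
    merged: dict[tuple[str, str], set[int]] = {}
    out: list[PresenceLayer] = []
    grids: dict[tuple[str, str], GridSpec] = {}
    for ly in layers:
        g = member_of.get(ly.taxon)
        if g is None:
            out.append(ly)
        else:
            key = (g, ly.season)
            merged.setdefault(key, set()).update(ly.cells)
            grids[key] = ly.grid
    for (g, season), cells in merged.items():
        out.append(PresenceLayer(taxon=g, season=season, cells=frozenset(cells), grid=grids[(g, season)]))

    rows = []
    for taxon, rec in table.iterrows():
        g = member_of.get(taxon)
        if g is None:
            rows.append((taxon, bool(rec["rl_flag"]), None))
    for g, members in groups.items():
        rows.append((g, bool(table.loc[members, "rl_flag"].any()), None))
    new_table = pd.DataFrame(rows, columns=["taxon", "rl_flag", "lump_group"]).set_index("taxon")
    return out, new_table


def build_community_matrix(
    layers: Sequence[PresenceLayer], grid: GridSpec, season: str
) -> CommunityMatrix:
    """Assemble the cells x taxa incidence matrix for one season."""
    season_layers = [ly for ly in layers if ly.season == season]
    taxa = [ly.taxon for ly in season_layers]
    dupes = sorted(t for t, c in Counter(taxa).items() if c > 1)
    if dupes:
        raise ValueError(f"duplicate taxon layers for season {season!r}: {dupes}")
    for ly in season_layers:
        if ly.grid != grid:
            raise ValueError(f"layer {ly.taxon!r} is on a different grid")
    data = np.zeros((grid.n_cells, len(taxa)), dtype=bool)
    for j, ly in enumerate(season_layers):
        data[list(ly.cells), j] = True
    inc = pd.DataFrame(data, index=pd.RangeIndex(grid.n_cells, name="cell"), columns=taxa)
    return CommunityMatrix(grid=grid, season=season, incidence=inc)


def map_points_to_cells(points: Iterable[tuple[float, float]], grid: GridSpec) -> SiteSet:
    """Assign (x, y) site centers to grid cells.

    Cells use half-open intervals; points sharing a cell are collapsed to
    one entry, keeping first-occurrence order.  A point outside the grid
    extent is an error naming the point.
    """
    seen: dict[int, None] = {}
    for x, y in points:
        col = math.floor((x - grid.origin_x) / grid.cell_size)
        row = math.floor((y - grid.origin_y) / grid.cell_size)
        if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
            raise ValueError(f"point ({x}, {y}) falls outside the grid extent")
        seen.setdefault(grid.cell_id(row, col))
    return SiteSet(cell_ids=tuple(seen), source="focal")


def read_sites_csv(path: str | Path) -> list[tuple[float, float]]:
    """Site-center CSV with columns site_id, x, y -> list of (x, y)."""
    df = pd.read_csv(path)
    for col in ("site_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"sites CSV missing column {col!r}")
    return list(zip(df["x"].astype(float), df["y"].astype(float)))


def write_sites_csv(points: Sequence[tuple[float, float]], path: str | Path) -> None:
    df = pd.DataFrame(points, columns=["x", "y"])
    df.insert(0, "site_id", [f"site{i:04d}" for i in range(len(df))])
    df.to_csv(path, index=False)
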