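"""Rasterized dune-mosaic landscape generation.

The study area is a rectangular grid of square cells on which habitat
patches ("dunes") are grown by a random-walk algorithm: each dune starts
from a random free cell and repeatedly annexes one cell chosen uniformly
among the free cells orthogonally adjacent to the current shape.  Distinct
dunes must keep at least one empty cell between them (a 100 m gap at the
default resolution), which on the grid means that a cell bordering another
dune -- including diagonally -- is never available for growth.

One grid cell is one hectare at the default 100 m resolution, and one
mature plant needs 2 m x 2 m, so the carrying capacity of a dune is
2500 plants per cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

PLANTS_PER_CELL = 2500  # one adult per 2 m x 2 m on a 1-ha cell

QUALITY_COEFFICIENTS = {"low": 1.00, "moderate": 1.38, "high": 2.23}


class LandscapeInfeasibleError(RuntimeError):
    """Raised when dune placement cannot satisfy area and spacing demands."""


@dataclass(frozen=True)
class GridSpec:
    """Dimensions of the rasterized study area (metres)."""

    width_m: int = 3000
    height_m: int = 5000
    cell_m: int = 100

    def __post_init__(self) -> None:
        if self.width_m % self.cell_m or self.height_m % self.cell_m:
            raise ValueError("grid extent must be an integer multiple of the cell size")

    @property
    def n_cols(self) -> int:
        return self.width_m // self.cell_m

    @property
    def n_rows(self) -> int:
        return self.height_m // self.cell_m

    def cell_centers(self, cells: np.ndarray) -> np.ndarray:
        """(N, 2) array of (x, y) centre coordinates for (row, col) pairs."""
        cells = np.atleast_2d(np.asarray(cells))
        x = (cells[:, 1] + 0.5) * self.cell_m
        y = (cells[:, 0] + 0.5) * self.cell_m
        return np.column_stack([x, y])


@dataclass(frozen=True)
class DuneSpec:
    dune_id: int
    area_ha: int
    initially_occupied: bool
    quality_class: str = "low"

    def __post_init__(self) -> None:
        if self.area_ha < 1:
            raise ValueError(f"dune {self.dune_id}: area must be >= 1 ha")
        if self.quality_class not in QUALITY_COEFFICIENTS:
            raise ValueError(f"dune {self.dune_id}: unknown quality {self.quality_class!r}")

    @property
    def quality_coefficient(self) -> float:
        return QUALITY_COEFFICIENTS[self.quality_class]


@dataclass
class Dune:
    spec: DuneSpec
    cells: np.ndarray  # (area, 2) int array of (row, col)
    bird_target_cells: np.ndarray | None = None  # (M, 2), filled in later

    @property
    def dune_id(self) -> int:
        return self.spec.dune_id

    @property
    def carrying_capacity(self) -> int:
        return PLANTS_PER_CELL * len(self.cells)


@dataclass
class Landscape:
    grid: GridSpec
    dunes: list[Dune]
    cell_to_dune: np.ndarray = field(init=False)  # (rows, cols), -1 = swale

    def __post_init__(self) -> None:
        m = np.full((self.grid.n_rows, self.grid.n_cols), -1, dtype=int)
        for dune in self.dunes:
            m[dune.cells[:, 0], dune.cells[:, 1]] = dune.dune_id
        self.cell_to_dune = m

    def dune(self, dune_id: int) -> Dune:
        for d in self.dunes:
            if d.dune_id == dune_id:
                return d
        raise KeyError(dune_id)

    def min_interdune_distance(self) -> float:
        """Exhaustive minimum centre-to-centre distance between cells of
        different dunes, in metres."""
        coords, ids = [], []
        for d in self.dunes:
            coords.append(self.grid.cell_centers(d.cells))
            ids.append(np.full(len(d.cells), d.dune_id))
        xy = np.concatenate(coords)
        idv = np.concatenate(ids)
        from scipy.spatial.distance import cdist

        dist = cdist(xy, xy)
        dist[idv[:, None] == idv[None, :]] = np.inf
        return float(dist.min())

    def export_ascii(self, path: str | Path) -> None:
        """Write the dune-id raster plus a JSON sidecar of dune metadata."""
        path = Path(path)
        np.savetxt(path, self.cell_to_dune, fmt="%d")
        meta = {
            "grid": {"width_m": self.grid.width_m, "height_m": self.grid.height_m,
                     "cell_m": self.grid.cell_m},
            "dunes": [
                {
                    "dune_id": d.dune_id,
                    "area_ha": d.spec.area_ha,
                    "occupied": d.spec.initially_occupied,
                    "quality": d.spec.quality_class,
                    "carrying_capacity": d.carrying_capacity,
                }
                for d in self.dunes
            ],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_dune_table(path: str | Path | None = None) -> list[DuneSpec]:
    """Read a dune table CSV (`dune_id,area_ha,occupied,quality`).

    With no path, the packaged default is returned: a 37-dune configuration
    (18 initially occupied, areas spanning 1-54 ha).  The default table is a
    synthetic stand-in drawn once, since the per-dune survey table is not
    published; only the count, occupancy split and area range are matched.
    """
    if path is None:
        ref = resources.files("dunefire.data") / "dune_table_synthetic.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"dune_id", "area_ha", "occupied", "quality"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dune table missing columns: {sorted(missing)}")
    return [
        DuneSpec(int(r.dune_id), int(r.area_ha), bool(r.occupied), str(r.quality))
        for r in df.itertuples()
    ]


_ORTH = ((1, 0), (-1, 0), (0, 1), (0, -1))
_NEIGH8 = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


def grow_dune(free: np.ndarray, area_cells: int, rng: np.random.Generator) -> set[tuple[int, int]]:
    """Grow one orthogonally connected dune of exactly `area_cells` cells.

    `free` is a boolean (rows, cols) mask of cells available for growth.
    Each step picks uniformly among free cells orthogonally adjacent to the
    current shape.  Raises LandscapeInfeasibleError on a dead end so the
    caller can retry with a new start.
    """
    if area_cells < 1:
        raise ValueError("area_cells must be >= 1")
    rows, cols = free.shape
    free_cells = np.argwhere(free)
    if len(free_cells) == 0:
        raise LandscapeInfeasibleError("no free cells left")
    start = tuple(free_cells[rng.integers(len(free_cells))])
    shape = {start}
    frontier: set[tuple[int, int]] = set()

    def add_frontier(cell: tuple[int, int]) -> None:
        r, c = cell
        for dr, dc in _ORTH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and free[rr, cc] and (rr, cc) not in shape:
                frontier.add((rr, cc))

    add_frontier(start)
    while len(shape) < area_cells:
        if not frontier:
            raise LandscapeInfeasibleError("random-walk growth dead end")
        pick = sorted(frontier)[rng.integers(len(frontier))]
        shape.add(pick)
        frontier.discard(pick)
        add_frontier(pick)
    return shape


def generate_landscape(
    dune_table: list[DuneSpec] | None = None,
    grid: GridSpec | None = None,
    rng_seed: int | np.random.Generator = 0,
    max_dune_attempts: int = 1000,
    max_landscape_attempts: int = 100,
) -> Landscape:
    """Place every dune of the table on the grid with the spacing rule.

    A candidate growth cell is forbidden if any of its 8 neighbours belongs
    to another dune, which enforces the one-cell (100 m) gap.  Dunes are
    grown largest-first (placement order does not affect the per-dune shape
    distribution); whole-dune and whole-landscape retries bound the search.
    """
    if dune_table is None:
        dune_table = load_dune_table()
    if grid is None:
        grid = GridSpec()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    total = sum(s.area_ha for s in dune_table)
    if total > grid.n_rows * grid.n_cols:
        raise LandscapeInfeasibleError(
            f"requested {total} cells exceed the {grid.n_rows * grid.n_cols}-cell grid"
        )
    order = sorted(dune_table, key=lambda s: -s.area_ha)
    rows, cols = grid.n_rows, grid.n_cols

    for _ in range(max_landscape_attempts):
        free = np.ones((rows, cols), dtype=bool)
        placed: dict[int, np.ndarray] = {}
        ok = True
        for spec in order:
            shape = None
            for _ in range(max_dune_attempts):
                try:
                    shape = grow_dune(free, spec.area_ha, rng)
                    break
                except LandscapeInfeasibleError:
                    continue
            if shape is None:
                ok = False
                break
            cells = np.array(sorted(shape), dtype=int)
            placed[spec.dune_id] = cells
            # block the dune's cells and their 8-neighbour halo
            free[cells[:, 0], cells[:, 1]] = False
            for dr, dc in _NEIGH8:
                rr = cells[:, 0] + dr
                cc = cells[:, 1] + dc
                inside = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
                free[rr[inside], cc[inside]] = False
        if ok:
            dunes = [Dune(spec, placed[spec.dune_id]) for spec in dune_table]
            ls = Landscape(grid, dunes)
            precompute_bird_targets(ls)
            return ls
    raise LandscapeInfeasibleError(
        f"could not place {len(dune_table)} dunes after {max_landscape_attempts} landscape attempts"
    )


def precompute_bird_targets(landscape: Landscape, max_dist_m: float = 1250.0) -> None:
    """For every dune, list all dune cells (own or other dunes) whose centre
    lies within `max_dist_m` of the nearest cell centre of that dune.

    Bird-carried cones are assumed to always reach suitable habitat, so the
    candidate drop cells are dune cells only.  The list always contains the
    dune's own cells (distance zero).
    """
    from scipy.spatial.distance import cdist

    all_cells = np.concatenate([d.cells for d in landscape.dunes])
    all_xy = landscape.grid.cell_centers(all_cells)
    for dune in landscape.dunes:
        src_xy = landscape.grid.cell_centers(dune.cells)
        dmin = cdist(all_xy, src_xy).min(axis=1)
        dune.bird_target_cells = all_cells[dmin <= max_dist_m]
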