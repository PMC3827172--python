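"""Explicit spatial lattice: habitats, covariates, viability and richness caps.

The model world is a rectangular grid of square cells.  Each cell carries a
habitat class, a vector of environmental covariates, a viability flag (sea or
destroyed cells can never be occupied but still count toward dispersal
distance) and, through its habitat class, a cap on local species richness.
Distance between cells is chessboard (Chebyshev) distance measured in cells:
the first dispersal ring around an interior cell has 8 cells, the second 24,
and in general ring ``d`` completes a ``(2d+1)**2 - 1`` cell neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple

import numpy as np

__all__ = [
    "CellCoord",
    "Landscape",
    "UNBOUNDED",
    "chebyshev_distance",
    "neighbourhood",
    "richness_cap_at",
]

#: Sentinel richness cap meaning "no limit" (usable directly in comparisons).
UNBOUNDED = np.inf


class CellCoord(NamedTuple):
    """0-based (row, col) grid coordinate."""

    row: int
    col: int


@dataclass
class Landscape:
    """A rectangular lattice of habitat cells.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (cells).
    habitat
        ``(n_rows, n_cols)`` array of habitat-class labels (strings).
    viable
        ``(n_rows, n_cols)`` boolean array; non-viable cells can never be
        occupied but remain part of the distance geometry.
    covariates
        Mapping from covariate name to a ``(n_rows, n_cols)`` float array.
        All cells share one covariate schema.
    richness_cap
        Mapping from habitat class to the maximum number of species a cell
        of that class may hold (``None`` or ``inf`` for unbounded).
    cell_side_km
        Side length of a cell in km; used only for reporting distances.
    cell_ids
        Optional ``(n_rows, n_cols)`` object array of external cell ids, kept
        so that files written back use the caller's identifiers.
    """

    n_rows: int
    n_cols: int
    habitat: np.ndarray
    viable: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    richness_cap: dict[str, float | int | None] = field(default_factory=dict)
    cell_side_km: float = 1.0
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        shape = (self.n_rows, self.n_cols)
        self.habitat = np.asarray(self.habitat, dtype=object)
        self.viable = np.asarray(self.viable, dtype=bool)
        if self.habitat.shape != shape or self.viable.shape != shape:
            raise ValueError("habitat/viable arrays must match grid shape")
        for name, arr in list(self.covariates.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"covariate {name!r} has shape {arr.shape}, expected {shape}")
            self.covariates[name] = arr
        missing = sorted(
            {str(h) for h in self.habitat[self.viable]} - set(self.richness_cap)
        )
        if missing:
            raise ValueError(f"no richness cap configured for habitat(s): {missing}")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_viable(self) -> int:
        return int(self.viable.sum())

    def contains(self, c: CellCoord) -> bool:
        return 0 <= c.row < self.n_rows and 0 <= c.col < self.n_cols

    def cells(self, viable_only: bool = False) -> Iterator[CellCoord]:
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                if viable_only and not self.viable[r, c]:
                    continue
                yield CellCoord(r, c)

    # -- richness caps ------------------------------------------------------

    def cap_grid(self) -> np.ndarray:
        """Per-cell richness cap as a float grid (``inf`` where unbounded)."""
        caps = np.full(self.shape, UNBOUNDED, dtype=float)
        for r, c in zip(*np.nonzero(self.viable)):
            cap = self.richness_cap.get(str(self.habitat[r, c]))
            caps[r, c] = UNBOUNDED if cap is None else float(cap)
        return caps

    def covariates_at(self, e: CellCoord) -> dict[str, float]:
        return {name: float(arr[e.row, e.col]) for name, arr in self.covariates.items()}


def chebyshev_distance(a: CellCoord, b: CellCoord) -> int:
    """Chessboard distance in cells: ``max(|Δrow|, |Δcol|)``."""
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def neighbourhood(e: CellCoord, d_max: int, L: Landscape) -> set[CellCoord]:
    """All in-grid cells within Chebyshev distance ``d_max`` of ``e``, excluding ``e``.

    Cells beyond the grid edge simply do not exist (no wraparound), so edge
    and corner cells have smaller neighbourhoods than interior cells.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    r0, c0 = e
    out: set[CellCoord] = set()
    for r in range(max(0, r0 - d_max), min(L.n_rows, r0 + d_max + 1)):
        for c in range(max(0, c0 - d_max), min(L.n_cols, c0 + d_max + 1)):
            if (r, c) != (r0, c0):
                out.add(CellCoord(r, c))
    return out


def richness_cap_at(e: CellCoord, L: Landscape) -> float:
    """Richness cap for the habitat class of cell ``e`` (``inf`` if unbounded)."""
    if not L.contains(e):
        raise ValueError(f"cell {e} outside {L.n_rows}x{L.n_cols} grid")
    hab = str(L.habitat[e.row, e.col])
    if hab not in L.richness_cap:
        raise KeyError(f"habitat {hab!r} has no richness cap entry")
    cap = L.richness_cap[hab]
    return UNBOUNDED if cap is None else float(cap)


def homogeneous_landscape(
    n_rows: int,
    n_cols: int,
    habitat: str = "uniform",
    cap: float | int | None = None,
    cell_side_km: float = 1.0,
    covariates: Mapping[str, np.ndarray] | None = None,
    viable: np.ndarray | None = None,
) -> Landscape:
    """Convenience constructor for a single-habitat rectangular landscape."""
    shape = (n_rows, n_cols)
    return Landscape(
        n_rows=n_rows,
        n_cols=n_cols,
        habitat=np.full(shape, habitat, dtype=object),
        viable=np.ones(shape, dtype=bool) if viable is None else viable,
        covariates=dict(covariates or {}),
        richness_cap={habitat: cap},
        cell_side_km=cell_side_km,
    )
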