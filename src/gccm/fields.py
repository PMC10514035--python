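"""Spatial variables on their support: raster grids and polygon lattices.

A field holds the raw observations ``h(x)`` of one variable.  Missing
observations are represented as NaN throughout.  Georeferencing metadata
(affine transform, CRS tag) is carried through unchanged and never used
numerically: both variables of a causal pair must already be co-registered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from .errors import InvalidAdjacencyError

__all__ = ["RasterField", "PolygonField"]


@dataclass
class RasterField:
    """A variable on a regular grid; ``values`` is 2-D, NaN marks missing.

    Cells are identified internally by their row-major index
    ``r * ncols + c``.
    """

    values: np.ndarray
    transform: tuple | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.values.size == 0 or not np.isfinite(self.values).any():
            raise ValueError("raster must contain at least one non-missing cell")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def n_units(self) -> int:
        return self.values.size

    def flat(self) -> np.ndarray:
        """Row-major 1-D view of the observations."""
        return self.values.reshape(-1)

    def same_support(self, other: "RasterField") -> bool:
        return (
            isinstance(other, RasterField) and self.values.shape == other.values.shape
        )


@dataclass
class PolygonField:
    """A variable on an irregular lattice described by an adjacency graph.

    ``unit_ids`` fixes the ordering used everywhere (values, embeddings,
    neighbor tie-breaking).  ``adjacency`` must be symmetric and free of
    self-loops — the queen-contiguity builder and the edge-list reader both
    guarantee this; hand-built graphs are validated here.
    """

    unit_ids: Sequence[Hashable]
    adjacency: Mapping[Hashable, set]
    values: np.ndarray
    geometry: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.unit_ids = list(self.unit_ids)
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("unit_ids must be unique")
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.values) != len(self.unit_ids):
            raise ValueError("one value per unit required")
        if not np.isfinite(self.values).any():
            raise ValueError("at least one non-missing unit required")
        known = set(self.unit_ids)
        adj = {u: set(self.adjacency.get(u, ())) for u in self.unit_ids}
        for u, nbrs in adj.items():
            if u in nbrs:
                raise InvalidAdjacencyError(f"unit {u!r} is its own neighbor")
            for v in nbrs:
                if v not in known:
                    raise InvalidAdjacencyError(f"neighbor {v!r} of {u!r} is unknown")
                if u not in adj[v]:
                    raise InvalidAdjacencyError(
                        f"adjacency is asymmetric: {u!r}->{v!r} but not {v!r}->{u!r}"
                    )
        self.adjacency = adj
        self._index = {u: i for i, u in enumerate(self.unit_ids)}

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def index_of(self, unit_id: Hashable) -> int:
        return self._index[unit_id]

    def same_support(self, other: "PolygonField") -> bool:
        return (
            isinstance(other, PolygonField)
            and self.unit_ids == other.unit_ids
            and self.adjacency == other.adjacency
        )
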