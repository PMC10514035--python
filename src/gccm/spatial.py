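"""Spatial-lag rings: the spatial analogue of time-delay lags.

On a raster the order-k lag of a focal cell is the ring of cells at
Chebyshev distance exactly k (the Moore-neighborhood ring, 8k cells for an
interior cell).  On a polygon lattice it is the k-th breadth-first level of
the contiguity graph: the first-order lags are the units sharing an edge or
a vertex with the focal unit, and each next order consists of the neighbors
of the previous ring excluding every unit already reached.

Raster rings are direction-aware: each ring slot is keyed by its relative
offset (dr, dc) in a fixed row-major order, so that two states can be
compared direction by direction (anisotropic distance).  Offsets falling
outside the grid are kept as missing slots rather than dropped, preserving
the direction alignment for boundary cells.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Hashable, Sequence

from .fields import PolygonField, RasterField

__all__ = [
    "LagStructure",
    "raster_lag_rings",
    "polygon_lag_rings",
    "queen_adjacency",
    "raster_as_polygon",
    "ring_offsets",
]


def ring_offsets(order: int) -> list[tuple[int, int]]:
    """Relative offsets of the order-k Moore ring, in row-major order.

    For k = 1 this is NW, N, NE, W, E, SW, S, SE.  The ordering is shared
    by every focal cell, which is what lets the anisotropic distance pair
    cells "in the same direction".
    """
    if order < 1:
        raise ValueError("ring order must be >= 1")
    k = order
    offs = [
        (dr, dc)
        for dr in range(-k, k + 1)
        for dc in range(-k, k + 1)
        if max(abs(dr), abs(dc)) == k
    ]
    return offs


@dataclass
class LagStructure:
    """Per-unit spatial-lag rings up to ``max_order``.

    For rasters the rings are implicit in the shared offset lists
    (``offsets[k-1]``) plus the grid shape; ``rings_of`` materializes them
    for one focal unit, with ``None`` marking out-of-bounds slots.  For
    polygons the breadth-first levels are stored explicitly per unit,
    sorted by unit id within each ring.
    """

    kind: str  # "raster" | "polygon"
    max_order: int
    shape: tuple[int, int] | None = None
    offsets: list[list[tuple[int, int]]] | None = None
    rings: list[list[list[int]]] | None = field(default=None, repr=False)
    unit_ids: Sequence[Hashable] | None = None

    @property
    def n_units(self) -> int:
        if self.kind == "raster":
            return self.shape[0] * self.shape[1]
        return len(self.rings)

    def nominal_ring_size(self, order: int) -> int:
        """Slot count of ring ``order`` (raster only; 8k)."""
        if self.kind != "raster":
            raise ValueError("nominal ring size is a raster notion")
        return 8 * order

    def rings_of(self, unit: int) -> list[list]:
        """Rings 1..max_order of one focal unit (given as flat index).

        Raster: each ring is a list aligned with ``ring_offsets(k)`` whose
        entries are flat cell indices or ``None`` for out-of-bounds slots.
        Polygon: each ring is the list of unit indices at that graph
        distance (possibly empty).
        """
        if self.kind == "polygon":
            return [list(r) for r in self.rings[unit]]
        nrows, ncols = self.shape
        r, c = divmod(unit, ncols)
        out: list[list] = []
        for k in range(1, self.max_order + 1):
            ring: list = []
            for dr, dc in self.offsets[k - 1]:
                rr, cc = r + dr, c + dc
                ring.append(rr * ncols + cc if 0 <= rr < nrows and 0 <= cc < ncols else None)
            out.append(ring)
        return out


def raster_lag_rings(fld: RasterField, max_order: int) -> LagStructure:
    """Moore-neighborhood rings of order 1..max_order for every cell."""
    if max_order < 1:
        raise ValueError("max_order must be a positive integer")
    return LagStructure(
        kind="raster",
        max_order=max_order,
        shape=(fld.nrows, fld.ncols),
        offsets=[ring_offsets(k) for k in range(1, max_order + 1)],
    )


def polygon_lag_rings(fld: PolygonField, max_order: int) -> LagStructure:
    """Breadth-first contiguity levels 1..max_order for every unit.

    Ring k+1 consists of the neighbors of ring k excluding every unit
    already included (the focal unit and all earlier rings).  Rings may be
    empty once the connected component is exhausted.
    """
    if max_order < 1:
        raise ValueError("max_order must be a positive integer")
    n = fld.n_units
    idx_of = fld.index_of
    nbr_idx: list[list[int]] = [
        sorted(idx_of(v) for v in fld.adjacency[u]) for u in fld.unit_ids
    ]
    all_rings: list[list[list[int]]] = []
    for start in range(n):
        seen = {start}
        frontier = deque([start])
        rings_u: list[list[int]] = []
        for _ in range(max_order):
            nxt: set[int] = set()
            while frontier:
                u = frontier.popleft()
                for v in nbr_idx[u]:
                    if v not in seen:
                        nxt.add(v)
            level = sorted(nxt, key=lambda i: _sort_key(fld.unit_ids[i]))
            rings_u.append(level)
            seen |= nxt
            frontier = deque(level)
        all_rings.append(rings_u)
    return LagStructure(
        kind="polygon", max_order=max_order, rings=all_rings, unit_ids=list(fld.unit_ids)
    )


def _sort_key(uid):
    # unit ids may be ints or strings; sort within type, deterministic either way
    return (str(type(uid)), uid)


def queen_adjacency(geometries: Sequence) -> dict:
    """Queen contiguity: units are adjacent iff they share an edge or a vertex.

    ``geometries`` is a sequence of shapely polygons; the returned adjacency
    maps positional index -> set of positional indices.  Symmetric, no
    self-loops.
    """
    from shapely import STRtree
    from shapely.geometry.base import BaseGeometry

    geoms = list(geometries)
    if not geoms:
        raise ValueError("empty geometry set")
    for i, g in enumerate(geoms):
        if not isinstance(g, BaseGeometry) or g.is_empty or not g.is_valid:
            raise ValueError(f"geometry {i} is invalid or empty")
    tree = STRtree(geoms)
    adj: dict[int, set[int]] = {i: set() for i in range(len(geoms))}
    left, right = tree.query(geoms, predicate="intersects")
    for i, j in zip(left.tolist(), right.tolist()):
        if i != j:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def raster_as_polygon(fld: RasterField) -> PolygonField:
    """Express a raster as a polygon lattice under queen contiguity.

    Unit ids are the row-major flat cell indices; adjacency links every
    pair of cells at Chebyshev distance 1.  Useful for cross-checking the
    raster and polygon code paths on identical data.
    """
    nrows, ncols = fld.nrows, fld.ncols
    adj: dict[int, set[int]] = {}
    for r in range(nrows):
        for c in range(ncols):
            u = r * ncols + c
            nbrs = set()
            for dr, dc in ring_offsets(1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    nbrs.add(rr * ncols + cc)
            adj[u] = nbrs
    return PolygonField(
        unit_ids=list(range(nrows * ncols)), adjacency=adj, values=fld.flat().copy()
    )
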