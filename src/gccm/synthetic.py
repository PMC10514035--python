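"""Synthetic spatial systems with known causal structure.

The workhorse is a coupled logistic map lattice: the canonical chaotic
two-species system used to benchmark cross-mapping, with the time-delay
coupling replaced by diffusive Moore-neighborhood mixing so that a single
cross-sectional snapshot carries the system's dynamics in its spatial
pattern.  Per sweep,

    f(x) = r_x * x * (1 - x - beta_yx * y)
    f(y) = r_y * y * (1 - y - beta_xy * x)
    x <- (1 - diffusion) * f(x) + diffusion * <f(x)>_Moore  (+ noise, clip to [0, 1])

where <.>_Moore is the mean over the 8-neighborhood.  beta_xy > 0 with
beta_yx = 0 makes X a unidirectional driver of Y — the ground truth the
inference is asked to recover.

The default growth rates place the system in the unidirectional
(non-synchronized) regime at the default coupling of 0.3: the driver
(r_x = 3.55) sits at the edge of chaos and produces a spatially coherent
field, while the response (r_y = 4.0) is fully chaotic, so its conditional
dynamics stay expansive and it is not enslaved by the forcing.  A periodic
response map (e.g. the textbook r_y = 3.5) synchronizes to a beta = 0.3
drive and turns the system into the strongly-coupled/mirroring case.

Also provided: independent (optionally smoothed) Gaussian fields as the
null model, and the same coupled dynamics on a jittered-grid polygon
lattice for the vector-data code path.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import convolve2d

from .fields import PolygonField, RasterField
from .spatial import queen_adjacency

__all__ = [
    "CoupledLatticeParams",
    "simulate_coupled_lattice",
    "simulate_independent_fields",
    "simulate_polygon_system",
]

_MOORE = np.ones((3, 3))
_MOORE[1, 1] = 0.0


@dataclass
class CoupledLatticeParams:
    """Coupled logistic lattice parameters; the seed fixes the output."""

    nrows: int = 40
    ncols: int = 40
    steps: int = 40
    r_x: float = 3.55
    r_y: float = 4.0
    beta_xy: float = 0.3  # coupling strength X -> Y
    beta_yx: float = 0.0  # coupling strength Y -> X
    diffusion: float = 0.2
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 3 or self.ncols < 3:
            raise ValueError("lattice must be at least 3x3")
        if not 0.0 <= self.diffusion < 1.0:
            raise ValueError("diffusion must be in [0, 1)")
        if self.beta_xy < 0 or self.beta_yx < 0:
            raise ValueError("coupling strengths must be non-negative")
        if self.steps < 1:
            raise ValueError("steps must be positive")

    @property
    def true_direction(self) -> str:
        if self.beta_xy > 0 and self.beta_yx == 0:
            return "X_causes_Y"
        if self.beta_yx > 0 and self.beta_xy == 0:
            return "Y_causes_X"
        if self.beta_xy > 0 and self.beta_yx > 0:
            return "bidirectional"
        return "none"


def _moore_mean(a: np.ndarray) -> np.ndarray:
    """Edge-aware mean over the 8-neighborhood."""
    num = convolve2d(a, _MOORE, mode="same", boundary="fill", fillvalue=0.0)
    den = convolve2d(np.ones_like(a), _MOORE, mode="same", boundary="fill")
    return num / den


def simulate_coupled_lattice(
    params: CoupledLatticeParams | None = None, **kwargs
) -> tuple[RasterField, RasterField]:
    """Run the coupled logistic lattice and return the final (X, Y) snapshot."""
    params = params or CoupledLatticeParams(**kwargs)
    rng = np.random.default_rng(params.seed)
    shape = (params.nrows, params.ncols)
    x = rng.uniform(0.1, 0.9, shape)
    y = rng.uniform(0.1, 0.9, shape)
    d = params.diffusion
    for _ in range(params.steps):
        fx = params.r_x * x * (1.0 - x - params.beta_yx * y)
        fy = params.r_y * y * (1.0 - y - params.beta_xy * x)
        x = (1.0 - d) * fx + d * _moore_mean(fx)
        y = (1.0 - d) * fy + d * _moore_mean(fy)
        if params.noise_sd > 0:
            x = x + rng.normal(0.0, params.noise_sd, shape)
            y = y + rng.normal(0.0, params.noise_sd, shape)
        if np.abs(x).max() > 10 or np.abs(y).max() > 10:
            warnings.warn("lattice update diverged before clipping", RuntimeWarning)
        x = np.clip(x, 0.0, 1.0)
        y = np.clip(y, 0.0, 1.0)
    return RasterField(x), RasterField(y)


def simulate_independent_fields(
    nrows: int, ncols: int, smoothness: float = 0.0, seed: int = 0
) -> tuple[RasterField, RasterField]:
    """Two independent Gaussian fields (the no-causation null).

    ``smoothness`` is the sigma (in cells) of an optional Gaussian kernel
    giving each field positive spatial autocorrelation; 0 leaves white
    noise.  The two fields come from disjoint random streams of the seed.
    """
    if smoothness < 0:
        raise ValueError("smoothness must be non-negative")
    child_a, child_b = np.random.SeedSequence(seed).spawn(2)
    fields = []
    for child in (child_a, child_b):
        z = np.random.default_rng(child).standard_normal((nrows, ncols))
        if smoothness > 0:
            z = gaussian_filter(z, sigma=smoothness, mode="nearest")
        fields.append(RasterField(z))
    return fields[0], fields[1]


def jittered_grid_polygons(side: int, seed: int = 0, jitter: float = 0.25) -> list:
    """A side x side tiling of quadrilaterals with jittered shared vertices.

    Interior lattice nodes are displaced by up to ``jitter`` of a cell, so
    the cells are irregular but still tile the plane and keep the queen
    contiguity of the underlying grid.
    """
    from shapely.geometry import Polygon

    rng = np.random.default_rng(seed)
    nodes_x, nodes_y = np.meshgrid(
        np.arange(side + 1, dtype=float), np.arange(side + 1, dtype=float)
    )
    mask = np.zeros_like(nodes_x, dtype=bool)
    mask[1:-1, 1:-1] = True
    nodes_x[mask] += rng.uniform(-jitter, jitter, mask.sum())
    nodes_y[mask] += rng.uniform(-jitter, jitter, mask.sum())
    polys = []
    for r in range(side):
        for c in range(side):
            polys.append(
                Polygon(
                    [
                        (nodes_x[r, c], nodes_y[r, c]),
                        (nodes_x[r, c + 1], nodes_y[r, c + 1]),
                        (nodes_x[r + 1, c + 1], nodes_y[r + 1, c + 1]),
                        (nodes_x[r + 1, c], nodes_y[r + 1, c]),
                    ]
                )
            )
    return polys


def simulate_polygon_system(
    n_units: int,
    coupling: float = 0.3,
    seed: int = 0,
    steps: int = 40,
    r_x: float = 3.55,
    r_y: float = 4.0,
    diffusion: float = 0.2,
    noise_sd: float = 0.02,
) -> tuple[PolygonField, PolygonField]:
    """Coupled logistic dynamics on a jittered-grid polygon lattice.

    ``coupling`` is the X -> Y strength (the reverse coupling is zero), so
    the ground-truth verdict is X_causes_Y whenever coupling > 0.  The
    lattice has ceil(sqrt(n_units))^2 >= n_units cells; adjacency is queen
    contiguity of the jittered cells.
    """
    if n_units < 20:
        raise ValueError("need at least 20 units for a meaningful lattice")
    if coupling < 0:
        raise ValueError("coupling must be non-negative")
    side = math.ceil(math.sqrt(n_units))
    polys = jittered_grid_polygons(side, seed=seed)
    adj = queen_adjacency(polys)
    n = len(polys)
    # row-normalized neighbor averaging operator
    rng = np.random.default_rng(seed + 1)
    x = rng.uniform(0.1, 0.9, n)
    y = rng.uniform(0.1, 0.9, n)
    nbr_lists = [np.fromiter(adj[i], dtype=int) for i in range(n)]

    def nbr_mean(v: np.ndarray) -> np.ndarray:
        out = np.empty(n)
        for i, nb in enumerate(nbr_lists):
            out[i] = v[nb].mean() if nb.size else v[i]
        return out

    for _ in range(steps):
        fx = r_x * x * (1.0 - x)
        fy = r_y * y * (1.0 - y - coupling * x)
        x = (1.0 - diffusion) * fx + diffusion * nbr_mean(fx)
        y = (1.0 - diffusion) * fy + diffusion * nbr_mean(fy)
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, n)
            y = y + rng.normal(0.0, noise_sd, n)
        x = np.clip(x, 0.0, 1.0)
        y = np.clip(y, 0.0, 1.0)
    ids = list(range(n))
    fx_field = PolygonField(unit_ids=ids, adjacency=adj, values=x, geometry=polys)
    fy_field = PolygonField(unit_ids=ids, adjacency=adj, values=y, geometry=polys)
    return fx_field, fy_field
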