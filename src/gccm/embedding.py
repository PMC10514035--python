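"""Generalized-embedding state vectors built from spatial lags.

The state of a focal unit s is

    psi(x, s) = < h_s(x), h_s(1)(x), ..., h_s(L-1)(x) >

i.e. the focal observation followed by one summary per lag ring.  Two
summaries are supported:

``per_direction``
    Each raster ring contributes its full direction-indexed vector of
    neighbor values (8k entries for ring k), so that the anisotropic state
    distance can compare cells direction by direction.
``ring_mean``
    Each ring contributes the mean of its non-missing members — the only
    choice for polygon lattices, and an isotropic alternative for rasters.

States are marked invalid (and excluded from every neighbor search) when
the focal value is missing, when a per-direction ring has more than
``missing_tolerance`` of its slots missing, or when a ring-mean ring has no
non-missing member at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedSkillError
from .fields import PolygonField, RasterField
from .spatial import LagStructure, polygon_lag_rings, raster_lag_rings

__all__ = ["EmbeddingConfig", "Embedding", "embed", "select_embedding_dimension"]

PER_DIRECTION = "per_direction"
RING_MEAN = "ring_mean"


@dataclass
class EmbeddingConfig:
    """Embedding dimension and ring-summary choices.

    L counts the focal observation plus L-1 lag orders, so L >= 2.  The
    default L = 4 keeps the neighbor count (L + 1) modest while giving the
    state three rings of spatial context.
    """

    L: int = 4
    raster_summary: str = PER_DIRECTION
    missing_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("embedding dimension L must be >= 2")
        if self.raster_summary not in (PER_DIRECTION, RING_MEAN):
            raise ValueError(f"unknown raster summary {self.raster_summary!r}")
        if not 0.0 <= self.missing_tolerance < 1.0:
            raise ValueError("missing_tolerance must be in [0, 1)")


@dataclass
class Embedding:
    """The reconstructed shadow manifold: one state per spatial unit.

    ``states`` is (n_units, n_components); ``comp_ring`` labels each column
    with its lag order (0 = focal).  In per-direction mode ring k occupies
    8k columns in the shared offset order; in ring-mean mode each ring is a
    single column.  ``valid`` flags the states usable in neighbor searches.
    """

    states: np.ndarray
    valid: np.ndarray
    comp_ring: np.ndarray
    L: int
    mode: str
    lags: LagStructure = field(repr=False, default=None)

    @property
    def n_units(self) -> int:
        return self.states.shape[0]

    def component_weights(self) -> np.ndarray:
        """Per-column weights turning an L1 distance into the state distance.

        The state distance averages the focal difference and one summary
        per ring, each ring summary itself averaging over its D directions:
        weight 1/L for the focal column and 1/(L * D_k) for ring-k columns.
        """
        w = np.empty(self.states.shape[1])
        for k in np.unique(self.comp_ring):
            cols = self.comp_ring == k
            d = cols.sum() if k > 0 else 1
            w[cols] = 1.0 / (self.L * d)
        return w

    def to_frame(self) -> pd.DataFrame:
        """Columnar dump of the states for inspection/debugging."""
        cols = []
        counters: dict[int, int] = {}
        for k in self.comp_ring:
            if k == 0:
                cols.append("focal")
            else:
                counters[k] = counters.get(k, 0) + 1
                cols.append(f"ring{k}_{counters[k]}")
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "valid", self.valid)
        return df


def _shifted(values: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """values[r + dr, c + dc] with NaN outside the grid."""
    out = np.full_like(values, np.nan)
    nr, nc = values.shape
    rs = slice(max(0, -dr), min(nr, nr - dr))
    cs = slice(max(0, -dc), min(nc, nc - dc))
    if rs.start < rs.stop and cs.start < cs.stop:
        out[rs, cs] = values[
            rs.start + dr : rs.stop + dr, cs.start + dc : cs.stop + dc
        ]
    return out


def embed(
    fld: RasterField | PolygonField,
    lags: LagStructure | None = None,
    config: EmbeddingConfig | None = None,
) -> Embedding:
    """Assemble the state vectors psi(x, s) for every unit of a field."""
    config = config or EmbeddingConfig()
    if lags is None:
        lags = (
            raster_lag_rings(fld, config.L - 1)
            if isinstance(fld, RasterField)
            else polygon_lag_rings(fld, config.L - 1)
        )
    if config.L - 1 > lags.max_order:
        raise ValueError(
            f"L={config.L} needs {config.L - 1} lag orders, "
            f"lag structure provides {lags.max_order}"
        )
    if isinstance(fld, RasterField):
        if lags.kind != "raster" or lags.shape != (fld.nrows, fld.ncols):
            raise ValueError("lag structure was built on a different support")
        if config.raster_summary == PER_DIRECTION:
            return _embed_raster_per_direction(fld, lags, config)
        return _embed_raster_ring_mean(fld, lags, config)
    if lags.kind != "polygon" or lags.n_units != fld.n_units:
        raise ValueError("lag structure was built on a different support")
    return _embed_polygon(fld, lags, config)


def _embed_raster_per_direction(
    fld: RasterField, lags: LagStructure, cfg: EmbeddingConfig
) -> Embedding:
    vals = fld.values
    cols = [vals.reshape(-1)]
    ring_lbl = [0]
    valid = np.isfinite(vals).reshape(-1)
    for k in range(1, cfg.L):
        ring_cols = []
        for dr, dc in lags.offsets[k - 1]:
            ring_cols.append(_shifted(vals, dr, dc).reshape(-1))
            ring_lbl.append(k)
        ring = np.column_stack(ring_cols)
        frac_missing = np.mean(~np.isfinite(ring), axis=1)
        valid &= frac_missing <= cfg.missing_tolerance
        cols.extend(ring_cols)
    states = np.column_stack(cols)
    return Embedding(
        states=states,
        valid=valid,
        comp_ring=np.asarray(ring_lbl),
        L=cfg.L,
        mode=PER_DIRECTION,
        lags=lags,
    )


def _embed_raster_ring_mean(
    fld: RasterField, lags: LagStructure, cfg: EmbeddingConfig
) -> Embedding:
    vals = fld.values
    cols = [vals.reshape(-1)]
    valid = np.isfinite(vals).reshape(-1)
    with np.errstate(invalid="ignore"):
        for k in range(1, cfg.L):
            ring = np.column_stack(
                [_shifted(vals, dr, dc).reshape(-1) for dr, dc in lags.offsets[k - 1]]
            )
            any_ok = np.isfinite(ring).any(axis=1)
            mean_k = np.full(ring.shape[0], np.nan)
            mean_k[any_ok] = np.nanmean(ring[any_ok], axis=1)
            valid &= any_ok
            cols.append(mean_k)
    return Embedding(
        states=np.column_stack(cols),
        valid=valid,
        comp_ring=np.arange(cfg.L),
        L=cfg.L,
        mode=RING_MEAN,
        lags=lags,
    )


def _embed_polygon(
    fld: PolygonField, lags: LagStructure, cfg: EmbeddingConfig
) -> Embedding:
    vals = fld.values
    n = fld.n_units
    states = np.full((n, cfg.L), np.nan)
    states[:, 0] = vals
    valid = np.isfinite(vals)
    for u in range(n):
        rings = lags.rings[u]
        for k in range(1, cfg.L):
            members = vals[rings[k - 1]] if rings[k - 1] else np.array([])
            members = members[np.isfinite(members)] if members.size else members
            if members.size:
                states[u, k] = members.mean()
            else:
                valid[u] = False
    return Embedding(
        states=states,
        valid=valid,
        comp_ring=np.arange(cfg.L),
        L=cfg.L,
        mode=RING_MEAN,
        lags=lags,
    )


def select_embedding_dimension(
    field_x,
    field_y,
    candidate_Ls,
    direction: str = "Y xmap X",
    raster_summary: str = PER_DIRECTION,
    missing_tolerance: float = 0.0,
) -> int:
    """Pick L by maximizing cross-map skill at the full-support library.

    Runs the cross-mapping for the given direction once per candidate with
    the whole support as the library and returns the candidate with the
    highest skill; ties break toward the smaller (more parsimonious) L.
    """
    from .inference import convergence_curve
    from .crossmap import LibrarySpec

    cands = sorted(set(int(L) for L in candidate_Ls))
    if not cands:
        raise ValueError("candidate_Ls must be non-empty")
    best_L, best_rho = None, -np.inf
    for L in cands:
        cfg = EmbeddingConfig(
            L=L, raster_summary=raster_summary, missing_tolerance=missing_tolerance
        )
        if isinstance(field_x, RasterField):
            size = min(field_x.nrows, field_x.ncols)
            spec = LibrarySpec(mode="raster_window", sizes=[size])
        else:
            spec = LibrarySpec(mode="polygon_count", sizes=[field_x.n_units])
        try:
            curve = convergence_curve(field_x, field_y, direction, spec, cfg)
        except UndefinedSkillError:
            continue
        rho = curve[-1].rho
        if rho > best_rho:
            best_L, best_rho = L, rho
    if best_L is None:
        raise UndefinedSkillError("every candidate L yielded undefined skill")
    return best_L
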