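"""Cross-mapping core: state distances, neighbor weights, prediction, skill.

Given the shadow manifold Mx reconstructed from X, the value of Y at a
focal unit s is predicted from the L+1 nearest library states of psi(x, s):

    Yhat_s | Mx = sum_i w_si * Y_si,      i = 1 .. L+1

with exponentially decaying weights w proportional to
exp(-dis(psi_i, psi_focal) / dis(psi_1, psi_focal)), normalized to sum to
one.  Skill is the Pearson correlation between observed and predicted Y
over the successfully predicted units.  The library — the subset of units
whose states may serve as neighbors — is swept over increasing sizes:
square windows for rasters, unit counts for polygon lattices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .embedding import Embedding, PER_DIRECTION, RING_MEAN
from .errors import LibraryTooSmallError, UndefinedSkillError
from .fields import PolygonField, RasterField

__all__ = [
    "LibrarySpec",
    "PredictionResult",
    "state_distance",
    "pairwise_state_distances",
    "neighbor_weights",
    "cross_map_predict",
    "skill",
    "enumerate_libraries",
]

EXACT_MATCH_EPS = 1e-12


@dataclass
class LibrarySpec:
    """How libraries are drawn at each size of the convergence sweep.

    Raster mode slides side x side windows at stride max(1, side // 2);
    polygon mode draws random unit subsets of the given count.  At most
    ``max_windows_per_size`` libraries are kept per size (uniform
    subsample, reproducible under ``sampling_seed``).
    """

    mode: str  # "raster_window" | "polygon_count"
    sizes: Sequence[int]
    max_windows_per_size: int = 3
    sampling_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("raster_window", "polygon_count"):
            raise ValueError(f"unknown library mode {self.mode!r}")
        sizes = [int(s) for s in self.sizes]
        if not sizes or any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("library sizes must be a non-empty increasing sequence")
        self.sizes = sizes
        if self.max_windows_per_size < 1:
            raise ValueError("max_windows_per_size must be positive")


@dataclass
class PredictionResult:
    """Cross-map predictions for one (embedding, library) pair."""

    unit_indices: np.ndarray  # units actually predicted
    observed: np.ndarray
    predicted: np.ndarray
    neighbor_indices: np.ndarray  # (n_pred, L+1)
    weights: np.ndarray  # (n_pred, L+1)
    skipped: list = field(default_factory=list)  # (unit, reason)

    @property
    def n_predicted(self) -> int:
        return len(self.unit_indices)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "unit": self.unit_indices,
                "observed": self.observed,
                "predicted": self.predicted,
            }
        )
        for j in range(self.neighbor_indices.shape[1]):
            df[f"neighbor_{j + 1}"] = self.neighbor_indices[:, j]
            df[f"weight_{j + 1}"] = self.weights[:, j]
        return df


def state_distance(
    a: np.ndarray,
    b: np.ndarray,
    comp_ring: np.ndarray | None = None,
    mode: str = RING_MEAN,
) -> float:
    """Distance between two states of the shadow manifold.

    dis(a, b) = (1/L) * ( |focal_a - focal_b| + sum_k abs[ring_k(a), ring_k(b)] )

    where the ring term is the mean absolute per-direction difference over
    the directions both states observe (anisotropic raster mode) or the
    absolute difference of the ring summaries (ring-mean mode, where each
    ring is a single component).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("states must have equal dimension")
    if comp_ring is None:
        comp_ring = np.arange(a.size)
    comp_ring = np.asarray(comp_ring)
    orders = np.unique(comp_ring)
    L = len(orders)
    total = abs(a[comp_ring == 0][0] - b[comp_ring == 0][0])
    for k in orders:
        if k == 0:
            continue
        cols = comp_ring == k
        ak, bk = a[cols], b[cols]
        if mode == PER_DIRECTION:
            shared = np.isfinite(ak) & np.isfinite(bk)
            if not shared.any():
                raise ValueError(f"no shared non-missing direction in ring {k}")
            total += np.mean(np.abs(ak[shared] - bk[shared]))
        else:
            total += float(np.abs(ak - bk).sum())
    return total / L


def pairwise_state_distances(
    emb: Embedding, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """State-distance matrix between two index sets of one embedding.

    Complete states (the default: missing_tolerance = 0 leaves no NaN in
    valid states) take a vectorized weighted-L1 path; states with missing
    directions fall back to the pairwise definition.
    """
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    sub_r = emb.states[rows]
    sub_c = emb.states[cols]
    if np.isfinite(sub_r).all() and np.isfinite(sub_c).all():
        w = emb.component_weights()
        return cdist(sub_r * w, sub_c * w, metric="cityblock")
    out = np.empty((len(rows), len(cols)))
    for i in range(len(rows)):
        for j in range(len(cols)):
            out[i, j] = state_distance(
                sub_r[i], sub_c[j], emb.comp_ring, emb.mode
            )
    return out


def neighbor_weights(distances: np.ndarray, eps: float = EXACT_MATCH_EPS) -> np.ndarray:
    """Exponential neighbor weights from ascending neighbor distances.

    weight_i = exp(-d_i / d_1) normalized to sum to one.  When the nearest
    distance is (numerically) zero the exact matches take all the weight:
    every distance below ``eps`` gets raw weight 1 and the rest 0, which is
    the limit behavior of the exponential rule.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if np.any(np.diff(d) < 0):
        raise ValueError("distances must be sorted ascending")
    if d[0] < eps:
        raw = (d < eps).astype(float)
    else:
        raw = np.exp(-d / d[0])
    return raw / raw.sum()


def _exclusion_mask(emb: Embedding, pred_units: np.ndarray, lib: np.ndarray, radius: int):
    """Boolean (n_pred, n_lib) mask of library states too close in space.

    Always excludes the focal unit itself; with radius r > 0 additionally
    excludes every unit within the first r lag rings of the focal unit
    (Chebyshev distance <= r on rasters, graph distance <= r on polygons).
    """
    mask = pred_units[:, None] == lib[None, :]
    if radius <= 0:
        return mask
    lags = emb.lags
    if lags.kind == "raster":
        ncols = lags.shape[1]
        pr, pc = np.divmod(pred_units, ncols)
        lr, lc = np.divmod(lib, ncols)
        cheb = np.maximum(
            np.abs(pr[:, None] - lr[None, :]), np.abs(pc[:, None] - lc[None, :])
        )
        mask |= cheb <= radius
    else:
        lib_pos = {u: j for j, u in enumerate(lib.tolist())}
        for i, s in enumerate(pred_units.tolist()):
            for ring in lags.rings[s][:radius]:
                for v in ring:
                    j = lib_pos.get(v)
                    if j is not None:
                        mask[i, j] = True
    return mask


def cross_map_predict(
    source: Embedding,
    target_values: np.ndarray | RasterField | PolygonField,
    library: Sequence[int],
    prediction_units: Sequence[int] | None = None,
    exclusion_radius: int = 0,
) -> PredictionResult:
    """Predict the target variable from the source shadow manifold (Eq. above).

    ``library`` and ``prediction_units`` are flat unit indices; prediction
    defaults to every valid state of the full support.  For each focal unit
    the L+1 nearest valid library states (excluding the focal unit itself,
    ties broken toward the smaller unit index) supply the weighted mean of
    their co-located target values.  Units with missing neighbor targets or
    too few reachable neighbors are skipped and reported.
    """
    if isinstance(target_values, (RasterField,)):
        y = target_values.flat()
    elif isinstance(target_values, PolygonField):
        y = target_values.values
    else:
        y = np.asarray(target_values, dtype=float).reshape(-1)
    if y.size != source.n_units:
        raise ValueError("target values are not on the embedding's support")

    L = source.L
    lib = np.unique(np.asarray(library, dtype=int))
    lib = lib[source.valid[lib]]
    if lib.size < L + 1:
        raise LibraryTooSmallError(
            f"library holds {lib.size} valid states, need at least {L + 1}"
        )
    if prediction_units is None:
        pred = np.flatnonzero(source.valid)
    else:
        pred = np.unique(np.asarray(prediction_units, dtype=int))
        pred = pred[source.valid[pred]]
    if pred.size == 0:
        raise UndefinedSkillError("no valid prediction units")

    D = pairwise_state_distances(source, pred, lib)
    D = np.where(_exclusion_mask(source, pred, lib, exclusion_radius), np.inf, D)

    # stable sort on distance; lib is ascending, so ties fall to smaller ids
    order = np.argsort(D, axis=1, kind="stable")[:, : L + 1]
    rowsel = np.arange(pred.size)[:, None]
    nbr_dist = D[rowsel, order]
    nbr_units = lib[order]

    unit_idx, obs, predicted, nbrs, wts, skipped = [], [], [], [], [], []
    for i, s in enumerate(pred.tolist()):
        if not np.isfinite(nbr_dist[i]).all():
            skipped.append((s, "fewer than L+1 reachable neighbors"))
            continue
        y_n = y[nbr_units[i]]
        if not np.isfinite(y_n).all():
            skipped.append((s, "missing target value at a neighbor"))
            continue
        w = neighbor_weights(nbr_dist[i])
        unit_idx.append(s)
        obs.append(y[s])
        predicted.append(float(w @ y_n))
        nbrs.append(nbr_units[i])
        wts.append(w)
    if not unit_idx:
        raise UndefinedSkillError("every prediction unit was skipped")
    return PredictionResult(
        unit_indices=np.asarray(unit_idx),
        observed=np.asarray(obs),
        predicted=np.asarray(predicted),
        neighbor_indices=np.asarray(nbrs),
        weights=np.asarray(wts),
        skipped=skipped,
    )


def skill(result: PredictionResult) -> tuple[float, int]:
    """Cross-map prediction skill: Pearson rho over predicted units.

    Units whose own observation is missing contribute a prediction but not
    to the skill.  Undefined skill (n < 3 or zero variance on either side)
    raises rather than silently returning 0.
    """
    ok = np.isfinite(result.observed) & np.isfinite(result.predicted)
    yo = result.observed[ok]
    yp = result.predicted[ok]
    n = int(ok.sum())
    if n < 3:
        raise UndefinedSkillError(f"only {n} predicted units with observations")
    if np.var(yo) == 0 or np.var(yp) == 0:
        raise UndefinedSkillError("zero variance in observations or predictions")
    rho = float(np.corrcoef(yo, yp)[0, 1])
    return rho, n


def enumerate_libraries(
    spec: LibrarySpec,
    support: RasterField | PolygonField,
    valid: np.ndarray | None = None,
    min_states: int = 0,
) -> dict[int, list[np.ndarray]]:
    """Candidate libraries (arrays of flat unit indices) per library size.

    Raster windows: every side x side window at stride max(1, side // 2),
    dropped when it holds fewer than ``min_states`` valid states, then
    uniformly subsampled to the per-size cap.  Polygon counts: seeded
    random subsets, except the full support when size equals the unit
    count.
    """
    rng = np.random.default_rng(spec.sampling_seed)
    out: dict[int, list[np.ndarray]] = {}
    if spec.mode == "raster_window":
        if not isinstance(support, RasterField):
            raise ValueError("raster_window libraries need a RasterField support")
        nrows, ncols = support.nrows, support.ncols
        for side in spec.sizes:
            if side < 1 or side > min(nrows, ncols):
                raise ValueError(f"window side {side} infeasible on {nrows}x{ncols}")
            stride = max(1, side // 2)
            wins = []
            for r0 in range(0, nrows - side + 1, stride):
                for c0 in range(0, ncols - side + 1, stride):
                    rows = np.arange(r0, r0 + side)
                    idx = (rows[:, None] * ncols + np.arange(c0, c0 + side)).ravel()
                    if valid is None or valid[idx].sum() >= max(min_states, 1):
                        wins.append(idx)
            if not wins:
                raise LibraryTooSmallError(
                    f"no window of side {side} holds {min_states} valid states"
                )
            if len(wins) > spec.max_windows_per_size:
                keep = np.sort(
                    rng.choice(len(wins), spec.max_windows_per_size, replace=False)
                )
                wins = [wins[i] for i in keep]
            out[side] = wins
    else:
        n = support.n_units
        all_units = np.arange(n)
        pool = all_units if valid is None else all_units[valid]
        for size in spec.sizes:
            if size < 1 or size > n:
                raise ValueError(f"library size {size} infeasible with {n} units")
            if size >= n:
                out[size] = [all_units]
                continue
            subs = []
            for _ in range(spec.max_windows_per_size):
                take = min(size, pool.size)
                if take < max(min_states, 1):
                    raise LibraryTooSmallError(
                        f"size {size} cannot supply {min_states} valid states"
                    )
                subs.append(np.sort(rng.choice(pool, take, replace=False)))
            out[size] = subs
    return out
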