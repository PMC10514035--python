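"""Shared fixtures: small synthetic fields and a brute-force cross-map oracle.

The oracle deliberately re-implements neighbor search and prediction with
plain per-pair loops over the distance definition, independent of the
vectorized path it is used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from gccm import PolygonField, simulate_coupled_lattice
from gccm.crossmap import EXACT_MATCH_EPS, state_distance


@pytest.fixture(scope="session")
def lattice_pair_12():
    """One 12x12 coupled-lattice realization (X drives Y)."""
    return simulate_coupled_lattice(nrows=12, ncols=12, seed=7)


@pytest.fixture
def chain_field():
    """Three polygons in a line: A - B - C with values 1, 2, 3."""
    return PolygonField(
        unit_ids=["A", "B", "C"],
        adjacency={"A": {"B"}, "B": {"A", "C"}, "C": {"B"}},
        values=[1.0, 2.0, 3.0],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def brute_force_cross_map(emb, target, library, exclusion_radius=0):
    """Reference cross-mapping: exhaustive loops, no vectorization.

    Returns dict unit -> (prediction, neighbor id list) for every valid
    unit that can be predicted; mirrors the skip rules of the main path.
    """
    L = emb.L
    y = np.asarray(target, dtype=float).reshape(-1)
    lib = sorted(set(int(u) for u in library if emb.valid[u]))
    out = {}
    for s in range(emb.n_units):
        if not emb.valid[s]:
            continue
        cands = []
        for j in lib:
            if j == s:
                continue
            if exclusion_radius > 0 and emb.lags.kind == "raster":
                ncols = emb.lags.shape[1]
                rs, cs = divmod(s, ncols)
                rj, cj = divmod(j, ncols)
                if max(abs(rs - rj), abs(cs - cj)) <= exclusion_radius:
                    continue
            d = state_distance(emb.states[s], emb.states[j], emb.comp_ring, emb.mode)
            cands.append((d, j))
        cands.sort()
        if len(cands) < L + 1:
            continue
        picked = cands[: L + 1]
        dists = np.array([d for d, _ in picked])
        ids = [j for _, j in picked]
        if not np.isfinite(y[ids]).all():
            continue
        if dists[0] < EXACT_MATCH_EPS:
            raw = (dists < EXACT_MATCH_EPS).astype(float)
        else:
            raw = np.exp(-dists / dists[0])
        w = raw / raw.sum()
        out[s] = (float(w @ y[ids]), ids)
    return out


def pearson(a, b):
    """Textbook Pearson correlation, written out longhand."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a.mean(), b.mean()
    num = ((a - am) * (b - bm)).sum()
    den = math.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum())
    return num / den
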