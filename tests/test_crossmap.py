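"""Distances, weights, cross-map prediction, skill, library enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gccm import (
    EmbeddingConfig,
    LibrarySpec,
    RasterField,
    UndefinedSkillError,
    cross_map_predict,
    embed,
    enumerate_libraries,
    neighbor_weights,
    skill,
    state_distance,
)
from gccm.embedding import PER_DIRECTION, RING_MEAN

from conftest import brute_force_cross_map, pearson


class TestStateDistance:
    def test_identity_is_zero(self, rng):
        a = rng.random(4)
        assert state_distance(a, a) == 0.0

    def test_ring_mean_hand_example(self):
        # L = 2: (|1-3| + |2-6|) / 2 = 3
        assert state_distance([1.0, 2.0], [3.0, 6.0]) == 3.0

    def test_per_direction_hand_example(self):
        # equal focal, all 8 first-ring direction differences equal to 2
        ring = np.arange(1, 9, dtype=float)
        a = np.concatenate([[1.0], ring])
        b = np.concatenate([[1.0], ring + 2.0])
        comp_ring = np.array([0] + [1] * 8)
        assert state_distance(a, b, comp_ring, PER_DIRECTION) == pytest.approx(1.0)

    def test_shared_direction_rule_and_failure(self):
        comp_ring = np.array([0, 1, 1])
        a = np.array([0.0, 2.0, np.nan])
        b = np.array([0.0, 5.0, 7.0])
        # only one shared direction: (0 + |2-5|) / 2
        assert state_distance(a, b, comp_ring, PER_DIRECTION) == pytest.approx(1.5)
        c = np.array([0.0, np.nan, 7.0])
        with pytest.raises(ValueError):
            state_distance(a, c, comp_ring, PER_DIRECTION)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_nonnegative_pseudometric(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=5), r.normal(size=5)
        dab = state_distance(a, b)
        assert dab >= 0.0
        assert dab == state_distance(b, a)
        assert state_distance(a, a) == 0.0


class TestNeighborWeights:
    def test_equidistant_neighbors_share_weight(self):
        for L in (2, 3, 5):
            w = neighbor_weights(np.full(L + 1, 0.7))
            assert np.allclose(w, 1.0 / (L + 1))

    def test_two_distance_example(self):
        w = neighbor_weights([1.0, 2.0])
        assert w == pytest.approx([0.73105858, 0.26894142], abs=1e-8)

    def test_exact_match_dominates(self):
        assert neighbor_weights([0.0, 5.0, 7.0]).tolist() == [1.0, 0.0, 0.0]

    def test_weights_sum_to_one(self, rng):
        d = np.sort(rng.random(6))
        assert neighbor_weights(d).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [[], [-1.0, 2.0], [2.0, 1.0]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            neighbor_weights(bad)


@pytest.fixture
def small_embedding(rng):
    fld = RasterField(rng.random((6, 6)))
    emb = embed(fld, config=EmbeddingConfig(L=2))
    return fld, emb


class TestCrossMapPredict:
    def test_constant_target_predicts_constant(self, small_embedding):
        fld, emb = small_embedding
        res = cross_map_predict(emb, np.full(36, 3.25), library=range(36))
        assert np.allclose(res.predicted, 3.25)

    def test_weights_rows_sum_to_one(self, small_embedding, rng):
        fld, emb = small_embedding
        res = cross_map_predict(emb, rng.random(36), library=range(36))
        assert np.allclose(res.weights.sum(axis=1), 1.0, atol=1e-12)

    def test_neighbors_confined_to_window_library(self, small_embedding, rng):
        fld, emb = small_embedding
        window = [r * 6 + c for r in range(1, 4) for c in range(1, 4)]
        res = cross_map_predict(emb, rng.random(36), library=window)
        assert set(res.neighbor_indices.ravel()) <= set(window)

    def test_focal_never_its_own_neighbor(self, small_embedding, rng):
        fld, emb = small_embedding
        res = cross_map_predict(emb, rng.random(36), library=range(36))
        for s, nbrs in zip(res.unit_indices, res.neighbor_indices):
            assert s not in nbrs

    def test_shift_invariance_and_scale_equivariance(self, small_embedding, rng):
        fld, emb = small_embedding
        y = rng.random(36)
        base = cross_map_predict(emb, y, library=range(36))
        shifted = cross_map_predict(emb, y + 10.0, library=range(36))
        scaled = cross_map_predict(emb, 2.5 * y, library=range(36))
        assert np.allclose(shifted.predicted, base.predicted + 10.0)
        assert np.allclose(scaled.predicted, 2.5 * base.predicted)

    def test_library_too_small_raises(self, small_embedding):
        from gccm import LibraryTooSmallError

        fld, emb = small_embedding
        with pytest.raises(LibraryTooSmallError):
            cross_map_predict(emb, np.ones(36), library=[7, 8])

    @pytest.mark.parametrize("mode", [PER_DIRECTION, RING_MEAN])
    @pytest.mark.parametrize("side,L", [(6, 2), (8, 3)])
    def test_matches_brute_force_oracle(self, mode, side, L):
        r = np.random.default_rng(side * 10 + L)
        fld = RasterField(r.random((side, side)))
        y = r.random(side * side)
        emb = embed(fld, config=EmbeddingConfig(L=L, raster_summary=mode))
        lib = range(side * side)
        res = cross_map_predict(emb, y, library=lib)
        expected = brute_force_cross_map(emb, y, lib)
        assert set(res.unit_indices.tolist()) == set(expected)
        for s, pred, nbrs in zip(
            res.unit_indices, res.predicted, res.neighbor_indices
        ):
            exp_pred, exp_nbrs = expected[int(s)]
            assert pred == pytest.approx(exp_pred, abs=1e-12)
            assert set(nbrs.tolist()) == set(exp_nbrs)


class TestSkill:
    def test_perfect_prediction(self, small_embedding):
        from gccm.crossmap import PredictionResult

        obs = np.array([1.0, 2.0, 3.0, 4.0])
        res = PredictionResult(
            unit_indices=np.arange(4),
            observed=obs,
            predicted=obs.copy(),
            neighbor_indices=np.zeros((4, 3), int),
            weights=np.full((4, 3), 1 / 3),
        )
        rho, n = skill(res)
        assert rho == pytest.approx(1.0) and n == 4

    def test_affine_invariance_and_sign(self):
        from gccm.crossmap import PredictionResult

        obs = np.array([1.0, 2.0, 3.0, 5.0])
        for a, expected in [(2.0, 1.0), (-1.5, -1.0)]:
            res = PredictionResult(
                unit_indices=np.arange(4),
                observed=obs,
                predicted=a * obs + 1.0,
                neighbor_indices=np.zeros((4, 3), int),
                weights=np.full((4, 3), 1 / 3),
            )
            assert skill(res)[0] == pytest.approx(expected)

    def test_constant_prediction_is_undefined(self):
        from gccm.crossmap import PredictionResult

        res = PredictionResult(
            unit_indices=np.arange(4),
            observed=np.array([1.0, 2.0, 3.0, 4.0]),
            predicted=np.ones(4),
            neighbor_indices=np.zeros((4, 3), int),
            weights=np.full((4, 3), 1 / 3),
        )
        with pytest.raises(UndefinedSkillError):
            skill(res)

    def test_matches_textbook_pearson(self, small_embedding, rng):
        fld, emb = small_embedding
        y = rng.random(36)
        res = cross_map_predict(emb, y, library=range(36))
        rho, _ = skill(res)
        assert rho == pytest.approx(pearson(res.observed, res.predicted), abs=1e-12)


class TestEnumerateLibraries:
    def test_full_grid_single_window(self):
        fld = RasterField(np.ones((10, 10)))
        libs = enumerate_libraries(
            LibrarySpec(mode="raster_window", sizes=[10]), fld
        )
        assert len(libs[10]) == 1 and len(libs[10][0]) == 100

    def test_stride_half_side_window_count(self):
        # 10x10 grid, side 5, stride 2: origins {0, 2, 4} per axis
        fld = RasterField(np.ones((10, 10)))
        libs = enumerate_libraries(
            LibrarySpec(mode="raster_window", sizes=[5], max_windows_per_size=100),
            fld,
        )
        assert len(libs[5]) == 9

    def test_window_cap_is_seeded_subsample(self):
        fld = RasterField(np.ones((10, 10)))
        spec = LibrarySpec(
            mode="raster_window", sizes=[5], max_windows_per_size=4, sampling_seed=1
        )
        first = enumerate_libraries(spec, fld)
        second = enumerate_libraries(spec, fld)
        assert len(first[5]) == 4
        for a, b in zip(first[5], second[5]):
            assert np.array_equal(a, b)

    def test_polygon_full_size_is_whole_support(self, chain_field):
        libs = enumerate_libraries(
            LibrarySpec(mode="polygon_count", sizes=[3]), chain_field
        )
        assert len(libs[3]) == 1 and libs[3][0].tolist() == [0, 1, 2]

    def test_infeasible_sizes_rejected(self):
        fld = RasterField(np.ones((5, 5)))
        with pytest.raises(ValueError):
            enumerate_libraries(
                LibrarySpec(mode="raster_window", sizes=[6]), fld
            )
        with pytest.raises(ValueError):
            LibrarySpec(mode="raster_window", sizes=[5, 5])
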