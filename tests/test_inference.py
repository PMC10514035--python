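"""Significance, confidence intervals, convergence and verdict logic."""

import math

import pytest

from gccm import (
    CrossMapSkill,
    LibrarySpec,
    assess_causality,
    confidence_interval,
    convergence_curve,
    significance,
)
from gccm.inference import SYNCHRONIZATION_CAVEAT, trend_p_value


class TestSignificance:
    @pytest.mark.parametrize("n", [3, 10, 100, 5000])
    def test_zero_skill_gives_half(self, n):
        assert significance(0.0, n) == pytest.approx(0.5, abs=1e-12)

    def test_hand_worked_value(self):
        # t = 0.5 * sqrt(98 / 0.75) = 5.71548, upper tail of t_98
        assert significance(0.5, 100) == pytest.approx(5.9024601e-08, rel=1e-6)

    def test_monotone_in_rho(self):
        ps = [significance(r, 50) for r in (0.0, 0.2, 0.5, 0.9, 0.999)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert significance(1.0, 50) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            significance(0.5, 2)


class TestConfidenceInterval:
    def test_zero_rho_interval(self):
        lo, hi = confidence_interval(0.0, 103, 0.95)
        half = math.tanh(1.959963984540054 * 0.1)
        assert lo == pytest.approx(-half, abs=1e-10)
        assert hi == pytest.approx(half, abs=1e-10)

    def test_symmetry_about_zero(self):
        lo, hi = confidence_interval(0.0, 50)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_level_nesting(self):
        lo95, hi95 = confidence_interval(0.4, 60, 0.95)
        lo99, hi99 = confidence_interval(0.4, 60, 0.99)
        assert lo99 < lo95 < hi95 < hi99

    def test_textbook_fisher_formula_agreement(self):
        # written out longhand, independent of the implementation
        from scipy.stats import norm

        for rho, n in [(0.3, 40), (-0.6, 25), (0.85, 200)]:
            z = 0.5 * math.log((1 + rho) / (1 - rho))
            q = norm.ppf(0.975)
            lo = math.tanh(z - q / math.sqrt(n - 3))
            hi = math.tanh(z + q / math.sqrt(n - 3))
            got = confidence_interval(rho, n, 0.95)
            assert got[0] == pytest.approx(lo, abs=1e-10)
            assert got[1] == pytest.approx(hi, abs=1e-10)

    def test_contains_rho(self):
        lo, hi = confidence_interval(0.55, 30)
        assert lo <= 0.55 <= hi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            confidence_interval(0.2, 3)
        with pytest.raises(ValueError):
            confidence_interval(1.0, 50)


def _skill(direction, size, rho, n=500, p=None):
    from gccm import significance as sig

    p = sig(rho, n) if p is None else p
    return CrossMapSkill(
        direction=direction, library_size=size, rho=rho, n=n, p=p,
        ci_low=rho - 0.05, ci_high=rho + 0.05,
    )


def _curve(direction, rhos, n=500):
    return [_skill(direction, 10 * (i + 1), r, n) for i, r in enumerate(rhos)]


class TestAssessCausality:
    def test_unidirectional_call(self):
        # strong converging forward skill, flat insignificant reverse skill
        yx = _curve("Y xmap X", [0.15, 0.28, 0.37])
        xy = [
            _skill("X xmap Y", 10, 0.04, p=0.3),
            _skill("X xmap Y", 20, 0.06, p=0.2),
            _skill("X xmap Y", 30, 0.05, p=0.09),
        ]
        out = assess_causality(yx, xy)
        assert out.verdict == "X_causes_Y"
        assert out.leading_direction == "Y xmap X"
        assert not out.notes

    def test_flat_insignificant_curves_give_none(self):
        yx = [_skill("Y xmap X", s, 0.02, p=0.4) for s in (10, 20, 30)]
        xy = [_skill("X xmap Y", s, 0.01, p=0.45) for s in (10, 20, 30)]
        assert assess_causality(yx, xy).verdict == "none"

    def test_bidirectional_with_leading_direction_and_caveat(self):
        yx = _curve("Y xmap X", [0.3, 0.5, 0.64])
        xy = _curve("X xmap Y", [0.1, 0.2, 0.27])
        out = assess_causality(yx, xy)
        assert out.verdict == "bidirectional"
        assert out.leading_direction == "Y xmap X"
        assert SYNCHRONIZATION_CAVEAT in out.notes

    def test_label_symmetry(self):
        yx = _curve("Y xmap X", [0.15, 0.28, 0.37])
        xy = [_skill("X xmap Y", s, 0.02, p=0.4) for s in (10, 20, 30)]
        assert assess_causality(yx, xy).verdict == "X_causes_Y"
        assert assess_causality(xy, yx).verdict == "Y_causes_X"

    def test_trend_tightening_blocks_wiggle(self):
        # final point barely above the first, no coherent trend
        rhos = [0.30, 0.36, 0.28, 0.33, 0.27, 0.35, 0.29, 0.31]
        yx = _curve("Y xmap X", rhos)
        xy = [_skill("X xmap Y", 10 * (i + 1), 0.0, p=0.5) for i in range(8)]
        assert assess_causality(yx, xy).verdict == "X_causes_Y"
        assert assess_causality(yx, xy, trend_alpha=0.05).verdict == "none"

    def test_monotone_trend_passes_tightening(self):
        yx = _curve("Y xmap X", [0.1, 0.18, 0.25, 0.3, 0.34, 0.37, 0.39, 0.4])
        xy = [_skill("X xmap Y", 10 * (i + 1), 0.0, p=0.5) for i in range(8)]
        out = assess_causality(yx, xy, trend_alpha=0.05)
        assert out.verdict == "X_causes_Y"
        assert trend_p_value(yx) < 0.01

    def test_mismatched_grids_rejected(self):
        yx = _curve("Y xmap X", [0.1, 0.2])
        xy = [_skill("X xmap Y", 15, 0.1), _skill("X xmap Y", 30, 0.1)]
        with pytest.raises(ValueError):
            assess_causality(yx, xy)


class TestConvergenceCurve:
    def test_self_prediction_skill_near_one(self, lattice_pair_12):
        x, _ = lattice_pair_12
        spec = LibrarySpec(mode="raster_window", sizes=[8, 12])
        curve = convergence_curve(x, x, "Y xmap X", spec)
        assert all(s.rho > 0.9 for s in curve)
        assert [s.library_size for s in curve] == [8, 12]
        assert all(s.ci_low <= s.rho <= s.ci_high for s in curve)

    def test_support_mismatch_rejected(self, lattice_pair_12, rng):
        from gccm import RasterField, SupportMismatchError

        x, _ = lattice_pair_12
        other = RasterField(rng.random((5, 5)))
        with pytest.raises(SupportMismatchError):
            convergence_curve(
                x, other, "Y xmap X", LibrarySpec(mode="raster_window", sizes=[5])
            )

    def test_unknown_direction_rejected(self, lattice_pair_12):
        x, y = lattice_pair_12
        with pytest.raises(ValueError):
            convergence_curve(
                x, y, "sideways", LibrarySpec(mode="raster_window", sizes=[12])
            )
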