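"""Significance, confidence intervals, convergence curves, and verdicts.

The null hypothesis for the cross-map skill is H0: rho = 0, tested
one-sided (H1: rho > 0) with

    t = rho * sqrt((n - 2) / (1 - rho^2)),   df = n - 2,

where n is the number of predicted units — negative skill is never
evidence of causation.  Confidence intervals use the Fisher transform
z = atanh(rho) with standard error 1/sqrt(n - 3).

A direction "converges" when its skill at the largest library exceeds the
skill at the smallest library and is significant at the largest library.
"Y xmap X" — predicting X from the shadow manifold of Y — tests the
causation X -> Y: if X drives Y, then Y's spatial pattern carries X's
information and the cross-map succeeds.  When both directions converge the
verdict is bidirectional with a synchronization caveat: a strong cause can
enslave the effect variable so that the reverse skill reflects mirroring,
not feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crossmap import LibrarySpec, cross_map_predict, enumerate_libraries, skill
from .embedding import EmbeddingConfig, embed
from .errors import SupportMismatchError, UndefinedSkillError
from .fields import RasterField

__all__ = [
    "CrossMapSkill",
    "CausalAssessment",
    "significance",
    "confidence_interval",
    "convergence_curve",
    "assess_causality",
    "trend_p_value",
    "gccm_pair",
]

Y_XMAP_X = "Y xmap X"
X_XMAP_Y = "X xmap Y"

SYNCHRONIZATION_CAVEAT = (
    "both directions converge: the smaller skill may be feedback causation "
    "or mere reflection of the leading direction (synchronization); "
    "domain knowledge is needed to tell them apart"
)


@dataclass
class CrossMapSkill:
    """Aggregated cross-map skill at one library size for one direction."""

    direction: str
    library_size: int
    rho: float
    n: int
    p: float
    ci_low: float
    ci_high: float


@dataclass
class CausalAssessment:
    """Paired convergence curves and the causal verdict they support."""

    curve_y_xmap_x: list[CrossMapSkill]
    curve_x_xmap_y: list[CrossMapSkill]
    verdict: str  # X_causes_Y | Y_causes_X | bidirectional | none
    leading_direction: str | None = None
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "direction": s.direction,
                "lib_size": s.library_size,
                "rho": s.rho,
                "p": s.p,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "n": s.n,
            }
            for s in self.curve_y_xmap_x + self.curve_x_xmap_y
        ]
        return pd.DataFrame(rows)


def significance(rho: float, n: int) -> float:
    """One-sided p-value for H0: rho = 0 against H1: rho > 0."""
    if n < 3:
        raise ValueError("significance needs n >= 3")
    if abs(rho) >= 1.0:
        return 0.0 if rho > 0 else 1.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(stats.t.sf(t, df=n - 2))


def confidence_interval(
    rho: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient."""
    if n <= 3:
        raise ValueError("confidence interval needs n >= 4")
    if abs(rho) >= 1.0:
        raise ValueError("confidence interval undefined at |rho| = 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = np.arctanh(rho)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


def _orient(field_x, field_y, direction: str):
    """Return (source field to embed, target field to predict)."""
    if direction == Y_XMAP_X:
        return field_y, field_x  # embed My, predict X: tests X -> Y
    if direction == X_XMAP_Y:
        return field_x, field_y
    raise ValueError(f"unknown direction {direction!r}")


def convergence_curve(
    field_x,
    field_y,
    direction: str,
    library_spec: LibrarySpec,
    config: EmbeddingConfig | None = None,
    exclusion_radius: int = 0,
    level: float = 0.95,
    prediction_units=None,
) -> list[CrossMapSkill]:
    """Aggregated cross-map skill per library size for one direction.

    Per size, skill is computed for every candidate library; the curve
    point carries the unweighted mean of the defined skills and the median
    prediction count, from which p and the confidence interval follow.
    """
    if not field_x.same_support(field_y):
        raise SupportMismatchError("X and Y must live on the same support")
    config = config or EmbeddingConfig()
    src_field, tgt_field = _orient(field_x, field_y, direction)
    emb = embed(src_field, config=config)
    tgt = tgt_field.flat() if isinstance(tgt_field, RasterField) else tgt_field.values
    libs = enumerate_libraries(
        library_spec, src_field, valid=emb.valid, min_states=config.L + 2
    )
    curve: list[CrossMapSkill] = []
    for size in library_spec.sizes:
        rhos, ns = [], []
        for lib in libs[size]:
            try:
                res = cross_map_predict(
                    emb,
                    tgt,
                    lib,
                    prediction_units=prediction_units,
                    exclusion_radius=exclusion_radius,
                )
                rho, n = skill(res)
            except UndefinedSkillError:
                continue
            rhos.append(rho)
            ns.append(n)
        if not rhos:
            raise UndefinedSkillError(
                f"no defined skill at library size {size} ({direction})"
            )
        rho_agg = float(np.mean(rhos))
        n_agg = int(np.median(ns))
        p = significance(rho_agg, n_agg)
        if n_agg > 3 and abs(rho_agg) < 1.0:
            lo, hi = confidence_interval(rho_agg, n_agg, level)
        else:
            lo, hi = rho_agg, rho_agg
        curve.append(
            CrossMapSkill(
                direction=direction,
                library_size=int(size),
                rho=rho_agg,
                n=n_agg,
                p=p,
                ci_low=lo,
                ci_high=hi,
            )
        )
    return curve


def trend_p_value(curve: list[CrossMapSkill]) -> float:
    """One-sided Mann-Kendall p-value for an increasing skill trend.

    The Mann-Kendall statistic for trend against an ordered covariate is
    Kendall's tau of skill versus library size, tested one-sided
    (alternative: increasing).
    """
    sizes = [s.library_size for s in curve]
    rhos = [s.rho for s in curve]
    return float(stats.kendalltau(sizes, rhos, alternative="greater").pvalue)


def _converges(
    curve: list[CrossMapSkill], alpha: float, trend_alpha: float | None
) -> bool:
    ok = curve[-1].rho > curve[0].rho and curve[-1].p < alpha
    if ok and trend_alpha is not None and len(curve) > 2:
        ok = trend_p_value(curve) < trend_alpha
    return ok


def assess_causality(
    curve_y_xmap_x: list[CrossMapSkill],
    curve_x_xmap_y: list[CrossMapSkill],
    alpha: float = 0.05,
    trend_alpha: float | None = None,
) -> CausalAssessment:
    """Causal verdict from the two convergence curves.

    A direction converges when its final skill exceeds its initial skill
    and is significant at the largest library.  ``trend_alpha`` optionally
    tightens this with a one-sided Mann-Kendall test on the whole skill
    sequence, guarding against single-endpoint flukes.  One converging
    direction gives a unidirectional verdict; both give "bidirectional"
    with the leading direction set to the larger final skill and the
    synchronization caveat attached; neither gives "none".
    """
    if not curve_y_xmap_x or not curve_x_xmap_y:
        raise ValueError("both curves must be non-empty")
    grid_a = [s.library_size for s in curve_y_xmap_x]
    grid_b = [s.library_size for s in curve_x_xmap_y]
    if grid_a != grid_b:
        raise ValueError("curves were computed on different library grids")
    conv_yx = _converges(curve_y_xmap_x, alpha, trend_alpha)  # evidence for X -> Y
    conv_xy = _converges(curve_x_xmap_y, alpha, trend_alpha)  # evidence for Y -> X
    notes: list[str] = []
    leading = None
    if conv_yx and conv_xy:
        verdict = "bidirectional"
        leading = (
            Y_XMAP_X
            if curve_y_xmap_x[-1].rho >= curve_x_xmap_y[-1].rho
            else X_XMAP_Y
        )
        notes.append(SYNCHRONIZATION_CAVEAT)
    elif conv_yx:
        verdict = "X_causes_Y"
        leading = Y_XMAP_X
    elif conv_xy:
        verdict = "Y_causes_X"
        leading = X_XMAP_Y
    else:
        verdict = "none"
    return CausalAssessment(
        curve_y_xmap_x=curve_y_xmap_x,
        curve_x_xmap_y=curve_x_xmap_y,
        verdict=verdict,
        leading_direction=leading,
        notes=notes,
    )


def gccm_pair(
    field_x,
    field_y,
    library_spec: LibrarySpec,
    config: EmbeddingConfig | None = None,
    alpha: float = 0.05,
    exclusion_radius: int = 0,
    level: float = 0.95,
    trend_alpha: float | None = None,
) -> CausalAssessment:
    """Run the full procedure: both cross-map sweeps plus the verdict."""
    c_yx = convergence_curve(
        field_x, field_y, Y_XMAP_X, library_spec, config, exclusion_radius, level
    )
    c_xy = convergence_curve(
        field_x, field_y, X_XMAP_Y, library_spec, config, exclusion_radius, level
    )
    return assess_causality(c_yx, c_xy, alpha, trend_alpha)
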