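"""Pre-processing: linear-trend removal and noise injection.

Cross-mapping targets the *nonlinear* part of an association.  When two
variables are strongly linearly correlated, the dominant linear trend is
removed first by ordinary least squares: the tested effect variable is
regressed on the tested cause variable and its residual field enters the
cross-mapping in its place.

Noise injection supports robustness experiments: each observation gets an
additive perturbation scaled to a fraction of its own magnitude, so a
fraction of 0.9 corresponds to a signal-to-noise ratio near one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fields import PolygonField, RasterField

__all__ = ["DetrendReport", "remove_linear_trend", "add_noise"]


def _values(fld) -> np.ndarray:
    return fld.flat() if isinstance(fld, RasterField) else fld.values


def _with_values(fld, new: np.ndarray):
    if isinstance(fld, RasterField):
        return RasterField(
            new.reshape(fld.values.shape), transform=fld.transform, crs=fld.crs
        )
    return PolygonField(
        unit_ids=fld.unit_ids,
        adjacency=fld.adjacency,
        values=new,
        geometry=fld.geometry,
    )


@dataclass
class DetrendReport:
    """OLS fit of y on x and the residual field that replaces y."""

    slope: float
    intercept: float
    r_squared: float
    residual_field: RasterField | PolygonField


def remove_linear_trend(y_field, x_field) -> DetrendReport:
    """Residualize y on x with ordinary least squares.

    The fit uses the units where both variables are observed; the residual
    field is missing wherever either input is.  Residuals have zero mean
    and zero correlation with the regressor by construction.
    """
    if not y_field.same_support(x_field):
        raise ValueError("detrending needs both fields on the same support")
    y = _values(y_field)
    x = _values(x_field)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired non-missing units")
    if np.var(x[ok]) == 0:
        raise ValueError("degenerate regressor: Var(x) = 0")
    fit = stats.linregress(x[ok], y[ok])
    resid = np.full_like(y, np.nan)
    resid[ok] = y[ok] - (fit.intercept + fit.slope * x[ok])
    return DetrendReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residual_field=_with_values(y_field, resid),
    )


def add_noise(fld, fraction: float, seed: int, distribution: str = "uniform"):
    """Perturb each observation by noise scaled to its own magnitude.

    Uniform (default): eta_i ~ U(-fraction*|v_i|, +fraction*|v_i|).
    Gaussian alternative: eta_i ~ N(0, (fraction*|v_i|)^2).  Missing units
    stay missing; fraction 0 returns an identical copy.
    """
    if fraction < 0:
        raise ValueError("noise fraction must be non-negative")
    v = _values(fld).copy()
    ok = np.isfinite(v)
    if fraction > 0:
        rng = np.random.default_rng(seed)
        scale = fraction * np.abs(v[ok])
        if distribution == "uniform":
            v[ok] = v[ok] + rng.uniform(-1.0, 1.0, size=ok.sum()) * scale
        elif distribution == "gaussian":
            v[ok] = v[ok] + rng.normal(0.0, 1.0, size=ok.sum()) * scale
        else:
            raise ValueError(f"unknown noise distribution {distribution!r}")
    return _with_values(fld, v)
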