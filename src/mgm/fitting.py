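"""Calibration of the model from per-track damage summaries.

Four fitting problems arise:

* the saturating indirect-yield curve ``N_max (1 - exp(-a yF))`` — nonlinear
  least squares (scipy ``curve_fit``);
* the linear direct-yield and linear-quadratic DSB-site curves — linear least
  squares through the origin, with a non-negativity bound on the quadratic
  coefficient (scipy ``lsq_linear``);
* the Gamma law per radiation quality — either continuous maximum likelihood
  on the raw scores (default, statistically efficient) or least squares of
  the density against the unit-bin normalized histogram (the figure-style
  fit); R^2 is reported on the normalized-histogram scale in both modes;
* the quadratic trends of the Gamma parameters (a, b) versus yF — two
  independent polynomial least-squares fits, with positivity of both curves
  verified over the validity range.

``calibrate`` runs the whole pipeline on a per-quality yield table and
returns a complete :class:`~mgm.core.MGMParameters`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy import optimize, stats

from .core import (
    GammaComplexityParams,
    MGMParameters,
    SaturatingYield,
    YieldModelParams,
)
from .microdosimetry import YF_VALID_RANGE


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class FitResult:
    parameters: dict[str, float]
    covariance: np.ndarray | None
    r_squared: float
    residuals: np.ndarray
    method: str
    notes: list[str] = field(default_factory=list)


def _r_squared(y: np.ndarray, y_model: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_model) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_saturation(
    yF_values, N_indirect_values, weights=None
) -> FitResult:
    """Fit N_max*(1 - exp(-a*yF)) by nonlinear least squares.

    Starts at N_max = 1.2*max(N), a = 1/median(yF); optional inverse-variance
    weighting via ``weights`` = variances.  Requires >= 3 distinct yF values.
    """
    yF = np.asarray(yF_values, dtype=float)
    N = np.asarray(N_indirect_values, dtype=float)
    if len(np.unique(yF)) < 3:
        raise ValueError("need >= 3 distinct yF values for the saturation fit")

    def model(y, N_max, a):
        return N_max * (1.0 - np.exp(-a * y))

    p0 = (1.2 * float(np.max(N)) if np.max(N) > 0 else 1.0,
          1.0 / float(np.median(yF)))
    sigma = np.sqrt(np.asarray(weights, dtype=float)) if weights is not None else None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                model, yF, N, p0=p0, sigma=sigma,
                bounds=([0, 0], [np.inf, np.inf]),
                xtol=1e-10, ftol=1e-10, max_nfev=10_000,
            )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitConvergenceError(
            f"saturation fit did not converge: {exc}", last_iterate=p0
        ) from exc
    fitted = model(yF, *popt)
    notes = []
    if popt[1] < 1e-8:
        notes.append("a_sat ~ 0: data show no saturation (degenerate fit)")
    if popt[1] * float(np.min(yF)) > 5.0:
        notes.append(
            "saturation already complete at the smallest yF: a_sat is "
            "unidentified above a lower bound (constant data?)"
        )
    return FitResult(
        parameters={"N_max": float(popt[0]), "a_sat": float(popt[1])},
        covariance=pcov,
        r_squared=_r_squared(N, fitted),
        residuals=N - fitted,
        method="nonlinear-ls",
        notes=notes,
    )


def fit_linear(yF_values, N_direct_values, weights=None) -> FitResult:
    """Least-squares slope of a line through the origin: N = k * yF.

    ``weights`` are variances (inverse-variance weighting) when given.
    """
    yF = np.asarray(yF_values, dtype=float)
    N = np.asarray(N_direct_values, dtype=float)
    if len(yF) < 2:
        raise ValueError("need >= 2 points for the linear fit")
    w = 1.0 / np.asarray(weights, dtype=float) if weights is not None \
        else np.ones_like(yF)
    denom = float(np.sum(w * yF * yF))
    if denom == 0:
        raise ValueError("rank-deficient design: all yF are zero")
    k = float(np.sum(w * yF * N)) / denom
    fitted = k * yF
    resid = N - fitted
    dof = max(len(yF) - 1, 1)
    var_k = float(np.sum(resid**2)) / dof / denom
    return FitResult(
        parameters={"k_direct": k},
        covariance=np.array([[var_k]]),
        r_squared=_r_squared(N, fitted),
        residuals=resid,
        method="linear-ls-origin",
    )


def _nonneg_lstsq(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares with x >= 0: exact unconstrained solution when it is
    already feasible, bounded solver otherwise."""
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    tol = 1e-10 * max(float(np.max(np.abs(x))), 1.0)
    if np.all(x >= -tol):  # negatives at rounding level: clamp, not re-solve
        return np.maximum(x, 0.0)
    return optimize.lsq_linear(A, y, bounds=(0, np.inf)).x


def fit_linear_quadratic(yF_values, counts, weights=None) -> FitResult:
    """Fit N = c1*yF + c2*yF^2 through the origin with c1, c2 >= 0.

    ``weights`` are variances (inverse-variance weighting) when given.  An
    active non-negativity constraint (a coefficient pinned at zero) is
    reported in the result's notes.
    """
    yF = np.asarray(yF_values, dtype=float)
    N = np.asarray(counts, dtype=float)
    if len(np.unique(yF)) < 3:
        raise ValueError("need >= 3 distinct yF values for the linear-quadratic fit")
    A = np.column_stack([yF, yF**2])
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("rank-deficient design for the linear-quadratic fit")
    if weights is not None:
        scale = 1.0 / np.sqrt(np.asarray(weights, dtype=float))
        x = _nonneg_lstsq(A * scale[:, None], N * scale)
    else:
        x = _nonneg_lstsq(A, N)
    c1, c2 = x
    fitted = A @ x
    notes = [f"non-negativity constraint active on {name}"
             for name, value in (("c1", c1), ("c2", c2)) if value < 1e-14]
    return FitResult(
        parameters={"c1": float(c1), "c2": float(c2)},
        covariance=None,
        r_squared=_r_squared(N, fitted),
        residuals=N - fitted,
        method="bounded-linear-ls-origin",
        notes=notes,
    )


def _histogram_unit_bins(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized unit-width histogram on integer-centered bins."""
    lo = int(np.floor(scores.min()))
    hi = int(np.ceil(scores.max()))
    edges = np.arange(lo, hi + 2) - 0.5
    counts, _ = np.histogram(scores, bins=edges)
    centers = np.arange(lo, hi + 1, dtype=float)
    keep = counts > 0
    return centers[keep], counts[keep] / counts.sum()


def fit_gamma(complexities, method: str = "mle") -> FitResult:
    """Fit the two-parameter Gamma law (shape a, rate b) to complexity scores.

    ``method="mle"`` maximizes the continuous-Gamma likelihood on the raw
    scores (location fixed at 0); ``method="histogram-ls"`` least-squares the
    density against the unit-bin normalized histogram.  R^2 is computed
    against the histogram in both modes so the two are comparable.
    """
    x = np.asarray(complexities, dtype=float)
    if x.size < 30:
        raise ValueError("need >= 30 complexity scores to fit the Gamma law")
    if np.any(x < 2):
        raise ValueError("complexity scores are >= 2 by definition")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all complexity scores are equal")
    mean, var = float(np.mean(x)), float(np.var(x))
    a0, b0 = mean**2 / var, mean / var  # moment estimates
    if method == "mle":
        a_hat, _, scale = stats.gamma.fit(x, a0, floc=0, scale=1.0 / b0)
        params = {"a": float(a_hat), "b": float(1.0 / scale)}
    elif method == "histogram-ls":
        centers, masses = _histogram_unit_bins(x)

        def model(c, a, b):
            return stats.gamma.pdf(c, a, scale=1.0 / b)

        popt, _ = optimize.curve_fit(
            model, centers, masses, p0=(a0, b0),
            bounds=([1e-8, 1e-8], [np.inf, np.inf]), max_nfev=10_000,
        )
        params = {"a": float(popt[0]), "b": float(popt[1])}
    else:
        raise ValueError(f"unknown method {method!r}")
    centers, masses = _histogram_unit_bins(x)
    model_masses = stats.gamma.pdf(centers, params["a"], scale=1.0 / params["b"])
    return FitResult(
        parameters=params,
        covariance=None,
        r_squared=_r_squared(masses, model_masses),
        residuals=masses - model_masses,
        method=f"gamma-{method}",
    )


def fit_gamma_trend(
    per_quality, valid_range: tuple[float, float] = YF_VALID_RANGE,
    abscissa: str = "linear",
) -> GammaComplexityParams:
    """Fit the quadratic trends a(yF), b(yF) from per-quality Gamma fits.

    ``per_quality`` is a sequence of (yF, a, b) triples from >= 3 distinct
    radiation qualities.  Positivity of both fitted curves is verified on a
    dense grid over ``valid_range``; violations raise, since a non-positive
    Gamma parameter makes the law undefined there.
    """
    arr = np.asarray(list(per_quality), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or len(np.unique(arr[:, 0])) < 3:
        raise ValueError("need >= 3 distinct (yF, a, b) triples")
    yF, a_vals, b_vals = arr.T
    x = np.log10(yF) if abscissa == "log10" else yF
    poly_a = P.polyfit(x, a_vals, 2)
    poly_b = P.polyfit(x, b_vals, 2)
    params = GammaComplexityParams(
        poly_a=tuple(float(c) for c in poly_a),
        poly_b=tuple(float(c) for c in poly_b),
        abscissa=abscissa,
        valid_range_keV_um=valid_range,
    )
    grid = np.linspace(valid_range[0], valid_range[1], 512)
    gx = np.log10(grid) if abscissa == "log10" else grid
    if np.any(P.polyval(gx, poly_a) <= 0) or np.any(P.polyval(gx, poly_b) <= 0):
        raise ValueError(
            "fitted Gamma-parameter trend goes non-positive inside the "
            f"validity range {valid_range} keV/um"
        )
    return params


def calibrate(
    yield_table: pd.DataFrame,
    gamma_table: pd.DataFrame | None = None,
    provenance: dict | None = None,
    weighting: str = "relative",
) -> MGMParameters:
    """Full calibration from per-quality mean yields.

    ``yield_table`` columns (one row per radiation quality, yields per track):
    ``yF, sb_direct, sb_indirect, bd_direct, bd_indirect, ds_direct,
    ds_indirect, ds_with_dsb``.  ``gamma_table`` columns: ``yF, a, b`` —
    per-quality Gamma parameters (e.g. from :func:`fit_gamma` on each
    quality's complexity scores).

    ``weighting="relative"`` (default) treats yield errors as multiplicative
    — the natural error model for per-track yields whose dispersion scales
    with the mean — and weights each point by 1/value^2, which keeps the
    low-yF points informative for the weakly identified coefficients (a_sat,
    c1).  ``weighting="none"`` gives the plain unweighted fits.
    """
    if weighting not in ("relative", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    t = yield_table
    yF = t["yF"].to_numpy()

    def var_of(values: np.ndarray) -> np.ndarray | None:
        return values**2 if weighting == "relative" else None

    def sat_pair(prefix: str) -> SaturatingYield:
        direct = t[f"{prefix}_direct"].to_numpy()
        indirect = t[f"{prefix}_indirect"].to_numpy()
        lin = fit_linear(yF, direct, weights=var_of(direct))
        sat = fit_saturation(yF, indirect, weights=var_of(indirect))
        return SaturatingYield(
            k_direct=lin.parameters["k_direct"],
            N_max=sat.parameters["N_max"],
            a_sat=sat.parameters["a_sat"],
        )

    dsb = t["ds_with_dsb"].to_numpy()
    lq = fit_linear_quadratic(yF, dsb, weights=var_of(dsb))
    yields = YieldModelParams(
        sb=sat_pair("sb"),
        bd=sat_pair("bd"),
        ds_total=sat_pair("ds"),
        c1=lq.parameters["c1"],
        c2=lq.parameters["c2"],
    )
    if gamma_table is not None:
        gamma = fit_gamma_trend(
            gamma_table[["yF", "a", "b"]].to_numpy()
        )
    else:
        raise ValueError("gamma_table is required for a full calibration")
    return MGMParameters(yields=yields, gamma=gamma,
                         provenance=provenance or {})
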