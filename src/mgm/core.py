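"""Core model functions: per-track damage yields and the Gamma complexity law.

The model predicts, from the frequency-mean lineal energy yF (keV/um) alone:

* direct damage per track, linear in yF (energy deposition is proportional to
  yF under the short-track condition): ``N_D = k * yF``;
* indirect (radical-mediated) damage per track, saturating with ionization
  density because of radical recombination: ``N_I = N_max * (1 - exp(-a*yF))``;
* the number of damage sites containing at least one double-strand break,
  linear-quadratic in yF: ``N_DSB-sites = c1*yF + c2*yF^2``;
* the distribution of site complexity C (total strand breaks + base damages
  in a DSB-containing 10-bp site, minimum 2) as a Gamma density
  ``f(C; yF) = b^a / Gamma(a) * C^(a-1) * exp(-b C)`` whose shape ``a(yF)``
  and rate ``b(yF)`` follow second-order polynomials in yF.

All functions warn (do not fail) outside the 2-200 keV/um validity range.
No calibrated coefficients ship with the package: parameters come from
:mod:`mgm.fitting` applied to data, or from :mod:`mgm.synthetic` for tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from numpy.polynomial import polynomial as P
from scipy import stats

from .microdosimetry import YF_VALID_RANGE

logger = logging.getLogger(__name__)

MIN_COMPLEXITY = 2  # a simple DSB: one break on each strand


def _warn_if_outside_range(yF, what: str) -> None:
    lo, hi = YF_VALID_RANGE
    arr = np.atleast_1d(np.asarray(yF, dtype=float))
    if np.any((arr < lo) | (arr > hi)):
        logger.warning(
            "%s evaluated at yF outside the calibrated range %s keV/um", what,
            YF_VALID_RANGE,
        )


def n_direct(yF, k_direct: float):
    """Direct damage per track: k_direct * yF. Linear in energy deposition."""
    _warn_if_outside_range(yF, "n_direct")
    return k_direct * np.asarray(yF, dtype=float)[()]


def n_indirect(yF, N_max: float, a_sat: float):
    """Indirect damage per track: N_max * (1 - exp(-a_sat * yF)).

    Monotone increasing, bounded by N_max; the saturation reflects radical
    recombination at high ionization density.
    """
    _warn_if_outside_range(yF, "n_indirect")
    return N_max * (1.0 - np.exp(-a_sat * np.asarray(yF, dtype=float)))[()]


def n_ds_with_dsb(yF, c1: float, c2: float):
    """DSB-containing damage sites per track: c1*yF + c2*yF^2 (no intercept)."""
    _warn_if_outside_range(yF, "n_ds_with_dsb")
    y = np.asarray(yF, dtype=float)
    return (c1 * y + c2 * y**2)[()]


@dataclass
class SaturatingYield:
    """Direct + indirect components for one observable (SB, BD or total DS)."""

    k_direct: float
    N_max: float
    a_sat: float

    def direct(self, yF):
        return n_direct(yF, self.k_direct)

    def indirect(self, yF):
        return n_indirect(yF, self.N_max, self.a_sat)

    def total(self, yF):
        return self.direct(yF) + self.indirect(yF)


@dataclass
class YieldModelParams:
    """Yield-curve coefficients: one saturating pair per lesion observable
    plus the linear-quadratic law for DSB-containing sites."""

    sb: SaturatingYield
    bd: SaturatingYield
    ds_total: SaturatingYield
    c1: float = 0.0
    c2: float = 0.0

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be non-negative")

    def n_ds_with_dsb(self, yF):
        return n_ds_with_dsb(yF, self.c1, self.c2)


@dataclass
class GammaComplexityParams:
    """Quadratic trends of the Gamma parameters vs yF.

    ``poly_a`` / ``poly_b`` hold (const, linear, quadratic) coefficients in
    ascending order, evaluated on yF directly (``abscissa='linear'``) or on
    log10(yF) (``abscissa='log10'``).
    """

    poly_a: tuple[float, float, float]
    poly_b: tuple[float, float, float]
    abscissa: str = "linear"
    valid_range_keV_um: tuple[float, float] = YF_VALID_RANGE

    def __post_init__(self) -> None:
        if self.abscissa not in ("linear", "log10"):
            raise ValueError(f"unknown abscissa mode {self.abscissa!r}")

    def _x(self, yF):
        y = np.asarray(yF, dtype=float)
        return np.log10(y) if self.abscissa == "log10" else y


def gamma_params_at(yF, gamma: GammaComplexityParams) -> tuple[float, float]:
    """Evaluate the shape a(yF) and rate b(yF) polynomials.

    Raises a domain error if either parameter evaluates non-positive: the
    Gamma law is undefined there and the trend should be refit.
    """
    _warn_if_outside_range(yF, "gamma_params_at")
    x = gamma._x(yF)
    a = P.polyval(x, gamma.poly_a)
    b = P.polyval(x, gamma.poly_b)
    if np.any(np.asarray(a) <= 0) or np.any(np.asarray(b) <= 0):
        raise ValueError(
            f"Gamma parameters non-positive at yF={yF}: a={a}, b={b}"
        )
    return a[()], b[()]


def complexity_pdf(C, yF, gamma: GammaComplexityParams):
    """Gamma density of complexity at C (>0) for radiation quality yF."""
    c = np.asarray(C, dtype=float)
    if np.any(c <= 0):
        raise ValueError("complexity must be positive")
    a, b = gamma_params_at(yF, gamma)
    return stats.gamma.pdf(c, a, scale=1.0 / b)[()]


def discretized_complexity_pmf(
    yF, gamma: GammaComplexityParams, tail: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Probability mass function of round-and-clamp discretized complexities.

    A continuous Gamma draw X is reported as max(2, round(X)), so
    P(2) = F(2.5) and P(k) = F(k+0.5) - F(k-0.5) for k >= 3.  The support is
    truncated where the upper tail mass falls below ``tail`` and the last bin
    absorbs it, so the masses sum to one exactly.
    """
    a, b = gamma_params_at(yF, gamma)
    dist = stats.gamma(a, scale=1.0 / b)
    k_max = max(3, int(np.ceil(dist.ppf(1.0 - tail) + 1)))
    ks = np.arange(MIN_COMPLEXITY, k_max + 1)
    edges = ks + 0.5
    cdf = dist.cdf(edges)
    masses = np.diff(np.concatenate([[0.0], cdf]))
    masses[-1] += 1.0 - cdf[-1]
    return ks, masses


def sample_complexities(
    n: int,
    yF: float,
    gamma: GammaComplexityParams,
    rng: np.random.Generator | int | None = None,
    discretize: bool = True,
) -> np.ndarray:
    """Draw n iid complexities from the Gamma law at yF.

    With ``discretize`` (default) draws are rounded to the nearest integer and
    clamped to the minimum complexity of 2, matching the integer definition of
    the score; pass ``discretize=False`` for the raw continuous draws.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng)
    a, b = gamma_params_at(yF, gamma)
    x = rng.gamma(shape=a, scale=1.0 / b, size=n)
    if discretize:
        return np.maximum(np.rint(x), MIN_COMPLEXITY).astype(int)
    return x


@dataclass
class MGMParameters:
    """Full calibrated parameter set: yield curves + Gamma complexity trends.

    ``provenance`` is free-text metadata (simulator, damage-induction
    criteria, calibration data description); it is carried through
    serialization untouched.
    """

    yields: YieldModelParams
    gamma: GammaComplexityParams
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["units"] = {"yF": "keV/um", "yields": "per track", "dose": "Gy"}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MGMParameters":
        y = d["yields"]
        yields = YieldModelParams(
            sb=SaturatingYield(**y["sb"]),
            bd=SaturatingYield(**y["bd"]),
            ds_total=SaturatingYield(**y["ds_total"]),
            c1=y["c1"],
            c2=y["c2"],
        )
        g = d["gamma"]
        gamma = GammaComplexityParams(
            poly_a=tuple(g["poly_a"]),
            poly_b=tuple(g["poly_b"]),
            abscissa=g.get("abscissa", "linear"),
            valid_range_keV_um=tuple(g.get("valid_range_keV_um", YF_VALID_RANGE)),
        )
        return cls(yields=yields, gamma=gamma, provenance=d.get("provenance", {}))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix.lower() == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "MGMParameters":
        path = Path(path)
        with open(path) as fh:
            if path.suffix.lower() == ".json":
                d = json.load(fh)
            else:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)
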