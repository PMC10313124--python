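"""Sigmoid repair model and biological endpoints: survival and RBE.

Each DSB-containing damage site becomes lethal with a probability that grows
sigmoidally with its complexity C::

    p(C) = 1 / (1 + exp(-d (C - C_half)))

``d`` (per complexity unit) controls how sharply repair fails with increasing
complexity — an efficient-repair cell line has a steep sigmoid at higher
C_half, a repair-deficient line a shallower one — and ``C_half`` is the
complexity of 50% lethality: p(C_half) = 1/2 exactly, for any d.  A cell with
sites C_1..C_N dies unless every site is repaired, so

    P_lethal = 1 - prod_i (1 - p(C_i)),     S = prod_i (1 - p(C_i)).

Survival versus dose comes in two routes that must agree:

* Monte Carlo: generate damage realizations per dose and count cells with no
  lethal site (per-site Bernoulli lethality);
* closed form: the generator's damage hierarchy is compound Poisson — a
  Poisson number of tracks, each carrying a Poisson number of sites with iid
  complexities — and the probability generating functions give the exact
  survival expectation per spectral component::

      S(D) = exp( nu(D) * (exp(-m * E[p(C)]) - 1) )

  with nu(D) the expected track count at dose D, m the mean DSB-site count
  per track, and E[p(C)] taken under the same discretized complexity law the
  generator samples from.  When m*E[p] is small this reduces to the familiar
  exp(-mu(D) * E[p(C)]) with mu = nu*m the expected total site count; at high
  lethality per track the compound form survives more, because sites cluster
  on tracks instead of arriving independently.

The linear-quadratic (LQ) parameters come from -ln S = alpha*D + beta*D^2;
RBE at a survival level is the dose ratio reference/test at equal survival
(solved from the fitted LQ), and the low-dose limit is the alpha ratio
(labelled "RBE_min" in output for continuity with common usage in the
high-LET literature, where this limit is conventionally the maximum RBE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MGMParameters, discretized_complexity_pmf
from .fitting import _nonneg_lstsq
from .generator import NucleusGeometry, expected_tracks, generate
from .microdosimetry import BeamSpectrum


@dataclass(frozen=True)
class RepairModelParams:
    """Sigmoid lethality parameters for one cell line."""

    d: float  # steepness, per complexity unit
    C_half: float  # complexity of 50% lethality

    def __post_init__(self) -> None:
        if self.d <= 0 or self.C_half <= 0:
            raise ValueError("d and C_half must be positive")


def p_lethal(C, params: RepairModelParams):
    """Per-site lethality probability: logistic in complexity.

    Strictly increasing in C, equal to 1/2 at C = C_half for any steepness.
    """
    c = np.asarray(C, dtype=float)
    if np.any(c < 0):
        raise ValueError("complexity must be >= 0")
    # expit form, numerically safe for large |d (C - C_half)|
    z = params.d * (c - params.C_half)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    out[~pos] = np.exp(z[~pos]) / (1.0 + np.exp(z[~pos]))
    return out[()]


@dataclass
class SurvivalCurve:
    doses_Gy: np.ndarray
    survival: np.ndarray
    method: str  # "mc" | "closed_form"
    n_reps: int | None = None
    alpha: float | None = None
    beta: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.doses_Gy = np.asarray(self.doses_Gy, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.doses_Gy.shape != self.survival.shape:
            raise ValueError("doses and survival must have equal length")


def mean_lethality(
    yF: float, mgm_params: MGMParameters, repair: RepairModelParams
) -> float:
    """E[p(C)] under the discretized Gamma complexity law at quality yF."""
    ks, masses = discretized_complexity_pmf(yF, mgm_params.gamma)
    return float(np.dot(masses, p_lethal(ks.astype(float), repair)))


def survival_closed_form(
    doses_Gy,
    beam: BeamSpectrum,
    mgm_params: MGMParameters,
    nucleus: NucleusGeometry,
    repair: RepairModelParams,
    label: str = "",
) -> SurvivalCurve:
    """Analytic survival, exact for the generator's damage statistics.

    Per component: S(D) = exp(nu(D) * (exp(-m * E[p]) - 1)), from the Poisson
    probability generating function applied at both hierarchy levels (tracks,
    then sites per track).  This is the exact mean of the Monte Carlo route,
    monotone non-increasing in dose and in any upward shift of the complexity
    distribution.
    """
    doses = np.asarray(doses_Gy, dtype=float)
    log_s_per_gy = 0.0
    for weight, yF in beam.components:
        if weight == 0:
            continue
        tracks_per_gy = expected_tracks(weight * 1.0, yF, nucleus)
        m_sites = mgm_params.yields.n_ds_with_dsb(yF)
        e_p = mean_lethality(yF, mgm_params, repair)
        log_s_per_gy += tracks_per_gy * np.expm1(-m_sites * e_p)
    survival = np.exp(log_s_per_gy * doses)
    return SurvivalCurve(doses, survival, method="closed_form", label=label)


def survival_mc(
    doses_Gy,
    beam: BeamSpectrum,
    mgm_params: MGMParameters,
    nucleus: NucleusGeometry,
    repair: RepairModelParams,
    n_reps: int = 1000,
    seed: int | None = None,
    label: str = "",
) -> SurvivalCurve:
    """Monte Carlo survival: fraction of simulated cells with no lethal site.

    Per dose and repetition, a damage realization is generated and each site
    becomes lethal with probability p(C); the cell survives when no site is
    lethal.  Reproducible given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    doses = np.asarray(doses_Gy, dtype=float)
    rng = np.random.default_rng(seed)
    survival = np.empty_like(doses)
    for i, dose in enumerate(doses):
        if dose == 0:
            survival[i] = 1.0
            continue
        survived = 0
        for _ in range(n_reps):
            real = generate(
                dose, beam, mgm_params, nucleus,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            if real.n_sites == 0:
                survived += 1
                continue
            p = p_lethal(real.complexities.astype(float), repair)
            if not np.any(rng.uniform(size=p.shape) < p):
                survived += 1
        survival[i] = survived / n_reps
    return SurvivalCurve(doses, survival, method="mc", n_reps=n_reps, label=label)


def fit_lq(curve: SurvivalCurve) -> tuple[float, float]:
    """Fit -ln S = alpha*D + beta*D^2 with alpha, beta >= 0 (least squares,
    no intercept).  Stores alpha/beta on the curve and returns them."""
    doses = curve.doses_Gy
    S = curve.survival
    if len(np.unique(doses)) < 3:
        raise ValueError("need >= 3 distinct dose points for the LQ fit")
    if np.any(S <= 0) or np.any(S > 1):
        raise ValueError("survival must be in (0, 1] for the LQ fit")
    y = -np.log(S)
    A = np.column_stack([doses, doses**2])
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("degenerate dose grid for the LQ fit")
    x = _nonneg_lstsq(A, y)
    curve.alpha, curve.beta = float(x[0]), float(x[1])
    return curve.alpha, curve.beta


def dose_at_survival(alpha: float, beta: float, survival_level: float) -> float:
    """Invert the LQ model: solve alpha*D + beta*D^2 = -ln(level) for D >= 0."""
    if not 0 < survival_level < 1:
        raise ValueError("survival level must be in (0, 1)")
    target = -np.log(survival_level)
    if beta <= 1e-15:
        if alpha <= 0:
            raise ValueError("alpha and beta both ~ 0: no dose reaches the level")
        return target / alpha
    return (-alpha + np.sqrt(alpha**2 + 4.0 * beta * target)) / (2.0 * beta)


@dataclass(frozen=True)
class RBEResult:
    survival_level: float | str  # 0.9 / 0.5 / 0.1 or "alpha_ratio"
    rbe: float
    reference: str = ""
    test: str = ""

    def __post_init__(self) -> None:
        if self.rbe <= 0:
            raise ValueError("RBE must be positive")


def rbe(
    reference_curve: SurvivalCurve,
    test_curve: SurvivalCurve,
    survival_level: float,
) -> RBEResult:
    """RBE at a survival level: dose ratio D_reference / D_test at equal
    survival, with doses solved from each curve's fitted LQ model."""
    for curve in (reference_curve, test_curve):
        if curve.alpha is None or curve.beta is None:
            fit_lq(curve)
    d_ref = dose_at_survival(reference_curve.alpha, reference_curve.beta,
                             survival_level)
    d_test = dose_at_survival(test_curve.alpha, test_curve.beta, survival_level)
    if d_test <= 0:
        raise ValueError("test curve never reaches the survival level")
    return RBEResult(
        survival_level=survival_level,
        rbe=d_ref / d_test,
        reference=reference_curve.label,
        test=test_curve.label,
    )


def rbe_alpha_ratio(alpha_reference: float, alpha_test: float,
                    reference: str = "", test: str = "") -> RBEResult:
    """Low-dose-limit RBE as the ratio of LQ alpha parameters
    (alpha_test / alpha_reference); labelled RBE_min in exported tables."""
    if alpha_reference <= 0 or alpha_test <= 0:
        raise ValueError("alpha parameters must be positive")
    return RBEResult(
        survival_level="alpha_ratio",
        rbe=alpha_test / alpha_reference,
        reference=reference,
        test=test,
    )
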