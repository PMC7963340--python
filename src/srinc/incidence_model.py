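"""Closed-form hazard, survival and population incidence curves.

The model: disease onset is the first passage of an individual's
senescent-cell level X across a disease threshold ``Xc``.  The
first-passage hazard is logistic in age,

    h(t) = A e^{a t} / (1 + b e^{a t}),

with parameters that depend log-linearly on the threshold,

    ln A = A0 + A1*Xc,   ln b = b0 + b1*Xc,   a = a0 + a1*Xc.

Death is the same process with ``Xc = Xdeath = 17``.  A fraction ``s``
of the population is susceptible (their threshold is reachable); the
rest never develop the disease, which produces the characteristic drop
in incidence at very old ages.  The population incidence of the
two-parameter model (threshold Xc, susceptible fraction s) is

    I(t) = s h(t) S_s(t) / (s S_s(t) + (1 - s) S_d(t)),

where ``S_s`` is onset survival of susceptibles and ``S_d`` the death
survival of everyone else.  The three-parameter model replaces the
single threshold by a Gaussian threshold distribution N(Xc_mean, sigma)
within the susceptible fraction and integrates numerically over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "RegressionConstants",
    "HazardParameters",
    "DiseaseModel",
    "DEFAULT_CONSTANTS",
    "hazard_params_from_threshold",
    "hazard",
    "log_survival",
    "survival",
    "incidence_2p",
    "incidence_3p",
    "peak_age",
]

#: number of quadrature nodes used for the threshold distribution
QUAD_NODES = 201
#: half-width of the quadrature support, in standard deviations
QUAD_SPAN = 5.0


@dataclass(frozen=True)
class RegressionConstants:
    """Log-linear maps from threshold Xc to hazard parameters, plus the
    death-hazard parameters (the threshold-17 member of the family).

    ``ln A = A0 + A1*Xc``, ``ln b = b0 + b1*Xc``, ``a = a0 + a1*Xc``
    with natural logarithms.
    """

    A0: float = 4.14
    A1: float = -1.01
    b0: float = 2.24
    b1: float = -0.81
    a0: float = -0.0186
    a1: float = 0.0089
    Ad: float = 2.22e-6
    bd: float = 9.774e-6
    ad: float = 0.132
    Xdeath: float = 17.0

    def __post_init__(self) -> None:
        if not (self.ad > 0 and self.Ad > 0 and self.bd > 0):
            raise ValueError("death-hazard parameters Ad, bd, ad must be positive")

    @property
    def death_hazard(self) -> "HazardParameters":
        return HazardParameters(A=self.Ad, b=self.bd, a=self.ad)


DEFAULT_CONSTANTS = RegressionConstants()


@dataclass(frozen=True)
class HazardParameters:
    """Parameters (A, b, a) of the logistic-in-age hazard
    ``h(t) = A e^{at} / (1 + b e^{at})``.

    ``A`` and ``b`` must be positive; ``a`` may have either sign (it is
    negative for thresholds below ≈2.09 X-units).
    """

    A: float
    b: float
    a: float

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.b > 0):
            raise ValueError("A and b must be strictly positive")


@dataclass(frozen=True)
class DiseaseModel:
    """A disease in the threshold-mixture model.

    sigma = 0 gives the two-parameter model (single threshold Xc_mean);
    sigma > 0 the three-parameter model with Gaussian thresholds.
    Thresholds above the death threshold are permitted (used for
    dementia-like, very steep incidence curves) but flagged.
    """

    Xc_mean: float
    s: float
    sigma: float = 0.0
    constants: RegressionConstants = field(default=DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        if not (0.0 < self.s <= 1.0):
            raise ValueError(f"susceptible fraction s must be in (0, 1], got {self.s}")
        if self.Xc_mean <= 0:
            raise ValueError(f"Xc_mean must be positive, got {self.Xc_mean}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.Xc_mean > self.constants.Xdeath:
            warnings.warn(
                f"threshold Xc_mean={self.Xc_mean} exceeds the death threshold "
                f"Xdeath={self.constants.Xdeath}; the disease process is faster "
                "than mortality (dementia-like regime)",
                stacklevel=2,
            )


def hazard_params_from_threshold(
    Xc: float, constants: RegressionConstants = DEFAULT_CONSTANTS
) -> HazardParameters:
    """Map a disease threshold to its first-passage hazard parameters.

    The maps are log-linear with natural logarithms; at Xc = 17 they
    reproduce the death parameters (Ad, bd, ad) to within the rounding
    of the printed coefficients.
    """
    if Xc <= 0:
        raise ValueError(f"threshold Xc must be positive, got {Xc}")
    c = constants
    return HazardParameters(
        A=float(np.exp(c.A0 + c.A1 * Xc)),
        b=float(np.exp(c.b0 + c.b1 * Xc)),
        a=float(c.a0 + c.a1 * Xc),
    )


def hazard(t, hp: HazardParameters):
    """Instantaneous onset hazard h(t) = A e^{at}/(1 + b e^{at}), per year.

    Evaluated as (A/b)·sigmoid(a t + ln b), which is stable for large
    ``a·t`` (saturating at A/b) as well as for very negative exponents.
    """
    t = np.asarray(t, dtype=float)
    return (hp.A / hp.b) * expit(hp.a * t + np.log(hp.b))


# below this |a| the exact cumulative hazard is replaced by its a->0 limit
_A_TINY = 1e-12


def _cumulative_hazard(t, hp: HazardParameters):
    t = np.asarray(t, dtype=float)
    if abs(hp.a) < _A_TINY:
        return hp.A * t / (1.0 + hp.b)
    ln_b = np.log(hp.b)
    # ln(1 + b e^{at}) computed in log-space; exact integral of h
    log_num = np.logaddexp(0.0, ln_b + hp.a * t)
    log_den = np.logaddexp(0.0, ln_b)
    return (hp.A / (hp.a * hp.b)) * (log_num - log_den)


def log_survival(t, hp: HazardParameters):
    """ln S(t) where S(t) = ((1 + b e^{at})/(1 + b))^{-A/(ab)}."""
    return -_cumulative_hazard(t, hp)


def survival(t, hp: HazardParameters):
    """Event-free survival S(t) = exp(-∫₀ᵗ h(u) du), in closed form.

    S(0) = 1 and S is non-increasing.  The a → 0 degenerate case uses
    the limit exp(-A t/(1+b)).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival is defined for t >= 0")
    return np.exp(log_survival(t, hp))


def incidence_2p(
    t,
    model: DiseaseModel,
    constants: RegressionConstants | None = None,
):
    """Population incidence rate of the two-parameter model, per person-year.

    I(t) = s h S_s / (s S_s + (1-s) S_d): onsets among remaining
    susceptibles over the at-risk pool of not-yet-onset susceptibles
    plus surviving non-susceptibles.  Susceptibles leave the pool only
    by onset; this is the closed-form model's own accounting.
    """
    c = constants if constants is not None else model.constants
    t = np.asarray(t, dtype=float)
    hp = hazard_params_from_threshold(model.Xc_mean, c)
    s = model.s
    Ss = np.exp(log_survival(t, hp))
    Sd = np.exp(log_survival(t, c.death_hazard))
    return s * hazard(t, hp) * Ss / (s * Ss + (1.0 - s) * Sd)


def _threshold_quadrature(Xc_mean: float, sigma: float):
    """Evenly spaced nodes on ±QUAD_SPAN·sigma, truncated at Xc > 0,
    with renormalized Gaussian weights."""
    nodes = np.linspace(
        Xc_mean - QUAD_SPAN * sigma, Xc_mean + QUAD_SPAN * sigma, QUAD_NODES
    )
    keep = nodes > 0
    nodes = nodes[keep]
    if nodes.size == 0:
        raise ValueError("threshold distribution has no support above Xc = 0")
    w = np.exp(-0.5 * ((nodes - Xc_mean) / sigma) ** 2)
    w /= w.sum()
    return nodes, w


def incidence_3p(
    t,
    model: DiseaseModel,
    constants: RegressionConstants | None = None,
):
    """Population incidence of the three-parameter model, per person-year.

    I(t) = ∫ h(t|Xc) C_s(t|Xc) P(Xc) dXc / (∫ C_s(t|Xc) P(Xc) dXc + C)
    with C_s = s·S_s(t|Xc) and C = (1-s)·S_d(t), integrating the
    Gaussian threshold distribution on a truncated, renormalized
    equal-spacing grid.  sigma = 0 reduces exactly to the
    two-parameter model.
    """
    c = constants if constants is not None else model.constants
    if model.sigma == 0.0:
        return incidence_2p(t, model, c)
    t = np.asarray(t, dtype=float)
    nodes, w = _threshold_quadrature(model.Xc_mean, model.sigma)
    tt = np.atleast_1d(t)

    # (nodes, times) arrays of h and S_s for each threshold node
    A = np.exp(c.A0 + c.A1 * nodes)[:, None]
    b = np.exp(c.b0 + c.b1 * nodes)[:, None]
    a = (c.a0 + c.a1 * nodes)[:, None]
    ln_b = np.log(b)
    h = (A / b) * expit(a * tt[None, :] + ln_b)
    cumh = (A / (a * b)) * (np.logaddexp(0.0, ln_b + a * tt[None, :]) - np.logaddexp(0.0, ln_b))
    Ss = np.exp(-cumh)

    s = model.s
    Sd = np.exp(log_survival(tt, c.death_hazard))
    num = s * np.sum(w[:, None] * h * Ss, axis=0)
    den = s * np.sum(w[:, None] * Ss, axis=0) + (1.0 - s) * Sd
    out = num / den
    return out if np.ndim(t) else float(out[0])


def peak_age(
    model: DiseaseModel,
    constants: RegressionConstants | None = None,
    t_max: float = 110.0,
    dt: float = 0.1,
) -> float:
    """Age of maximal incidence on a regular grid (ties to youngest age).

    If the curve is monotone on the grid the endpoint is returned with
    a warning — for s = 1 the incidence equals the hazard, which is
    monotone increasing, so the peak is not interior.
    """
    grid = np.arange(0.0, t_max + 0.5 * dt, dt)
    inc_fn = incidence_3p if model.sigma > 0 else incidence_2p
    values = np.asarray(inc_fn(grid, model, constants))
    i = int(np.argmax(values))
    if i == 0 or i == len(grid) - 1:
        warnings.warn(
            "incidence is monotone on the grid; returning the grid endpoint",
            stacklevel=2,
        )
    return float(grid[i])
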