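"""Frontline-tissue homeostasis and senescent-cell driven collapse.

A "frontline" tissue (lung alveoli, joint cartilage) keeps its
progenitor cells S as exposed to damage as their differentiated progeny
D.  The population dynamics are

    dS/dt = p(S, D, X) S - q(S, D) S - r1 S
    dD/dt = q(S, D) S - r2 D,

where p is the proliferation rate (capped at ``p_max``), q the
differentiation rate and r1, r2 removal rates.  Secreted feedback
signals from S and D act on p and q; each of the four possible
regulatory arrows can be positive, negative or absent, giving 3^4 = 81
circuit topologies.  Responses are saturating hyperbolic factors.
Senescent cells reduce progenitor proliferation through the factor
``g_X(X) = 1/(1 + X/X_half)``.

No matter the feedback wiring, homeostasis is impossible once the
progenitor removal rate exceeds the maximal proliferation rate
(r1 > p_max): S then decays from any start and the tissue collapses.
Rising senescent-cell load pushes the effective proliferation
``p_max g_X(X)`` below the removal threshold at a senescent level
``Xc`` implied by the rates — tissue crash is therefore itself a
threshold-crossing event in X, and its incidence curve belongs to the
same two-parameter family as the other diseases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .curves import IncidenceCurve
from .sr_dynamics import FirstPassageSample, SRParameters, empirical_hazard

__all__ = [
    "TissueCircuit",
    "CollapseEvent",
    "all_sign_assignments",
    "circuit_dynamics",
    "steady_state",
    "is_homeostatic",
    "scan_topologies",
    "collapse_incidence",
]

#: eigenvalue real parts must be below this for linear stability
_STABILITY_MARGIN = -1e-6


@dataclass(frozen=True)
class TissueCircuit:
    """One feedback topology with shared rate constants.

    ``feedback_signs`` = (S->proliferation, D->proliferation,
    S->differentiation, D->differentiation), each in {-1, 0, +1}.
    ``half_sat`` is the shared half-saturation of the response factors
    and ``X_half`` that of the senescent inhibition of proliferation.
    """

    feedback_signs: tuple[int, int, int, int] = (0, -1, 0, 0)
    p_max: float = 20.0  # per year; frontline progenitors turn over in weeks
    q0: float = 3.0
    r1: float = 3.0
    r2: float = 3.0
    half_sat: float = 1.0
    X_half: float = 6.0

    def __post_init__(self) -> None:
        if any(sign not in (-1, 0, 1) for sign in self.feedback_signs):
            raise ValueError("feedback signs must be -1, 0 or +1")
        for name in ("p_max", "q0", "r1", "r2", "half_sat", "X_half"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate {name} must be strictly positive")

    def g_x(self, X):
        """Senescent-cell inhibition of proliferation; g(0) = 1,
        monotone decreasing."""
        return 1.0 / (1.0 + np.asarray(X, dtype=float) / self.X_half)

    def implied_collapse_threshold(self) -> float:
        """Senescent level at which even maximal proliferation cannot
        balance differentiation + removal: p_max g_X(Xc) = q0 + r1."""
        ratio = self.p_max / (self.q0 + self.r1)
        if ratio <= 1.0:
            return 0.0
        return self.X_half * (ratio - 1.0)


@dataclass(frozen=True)
class CollapseEvent:
    """Outcome of one individual's tissue-collapse simulation."""

    age: float
    occurred: bool


def all_sign_assignments():
    """The 81 possible feedback topologies."""
    return list(itertools.product((-1, 0, 1), repeat=4))


def _response(u, sign: int, K: float):
    if sign > 0:
        return u / (K + u)
    if sign < 0:
        return K / (K + u)
    return 1.0 if np.isscalar(u) else np.ones_like(u)


def circuit_dynamics(circuit: TissueCircuit, S, D, X=0.0):
    """(dS/dt, dD/dt) at state (S, D) under senescent load X."""
    S = np.asarray(S, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(S < 0) or np.any(D < 0) or np.any(np.asarray(X) < 0):
        raise ValueError("populations and senescent level must be non-negative")
    sp, dp, sq, dq = circuit.feedback_signs
    K = circuit.half_sat
    p = circuit.p_max * circuit.g_x(X) * _response(S, sp, K) * _response(D, dp, K)
    q = circuit.q0 * _response(S, sq, K) * _response(D, dq, K)
    dS = (p - q - circuit.r1) * S
    dD = q * S - circuit.r2 * D
    return dS, dD


_ROOT_STARTS = ((1.0, 1.0), (0.2, 0.2), (5.0, 5.0), (1.0, 10.0), (10.0, 1.0),
                (0.05, 1.0), (20.0, 20.0))


def steady_state(circuit: TissueCircuit, X: float = 0.0):
    """A positive steady state (S*, D*), or None if none is found."""

    def rhs(v):
        s, d = np.exp(np.clip(v, -40.0, 40.0))  # log coords stay positive
        ds, dd = circuit_dynamics(circuit, s, d, X)
        return [ds / s, dd / max(d, 1e-300)]

    for s0, d0 in _ROOT_STARTS:
        with np.errstate(all="ignore"):
            sol = root(rhs, np.log([s0, d0]), method="hybr")
        if not sol.success:
            continue
        s, d = np.exp(sol.x)
        if s > 1e-8 and d > 1e-8 and np.isfinite(s) and np.isfinite(d):
            ds, dd = circuit_dynamics(circuit, s, d, X)
            if abs(ds) < 1e-8 * max(s, 1.0) and abs(dd) < 1e-8 * max(d, 1.0):
                return float(s), float(d)
    return None


def _jacobian(circuit, s, d, X=0.0, h=1e-6):
    J = np.empty((2, 2))
    for j, (hs, hd) in enumerate(((h, 0.0), (0.0, h))):
        fp = circuit_dynamics(circuit, s + hs, d + hd, X)
        fm = circuit_dynamics(circuit, max(s - hs, 0.0), max(d - hd, 0.0), X)
        J[0, j] = (fp[0] - fm[0]) / (2 * h)
        J[1, j] = (fp[1] - fm[1]) / (2 * h)
    return J


def _returns_to(circuit, target, start, X=0.0, t_span=300.0, rtol_return=0.01):
    sol = solve_ivp(
        lambda _, v: circuit_dynamics(circuit, max(v[0], 0.0), max(v[1], 0.0), X),
        (0.0, t_span),
        start,
        rtol=1e-8,
        atol=1e-10,
    )
    end = sol.y[:, -1]
    return bool(
        np.all(np.abs(end - np.asarray(target)) <= rtol_return * np.asarray(target))
    )


def is_homeostatic(circuit: TissueCircuit, X: float = 0.0) -> bool:
    """A circuit is homeostatic if it has a linearly stable positive
    steady state that is robust to +-20% perturbations of the initial
    conditions (marginal cases are excluded)."""
    ss = steady_state(circuit, X)
    if ss is None:
        return False
    s, d = ss
    eig = np.linalg.eigvals(_jacobian(circuit, s, d, X))
    if np.any(eig.real > _STABILITY_MARGIN):
        return False
    for factor in (0.8, 1.2):
        if not _returns_to(circuit, (s, d), (factor * s, factor * d), X):
            return False
    return True


def scan_topologies(
    p_max: float = 20.0,
    q0: float = 3.0,
    r1: float = 3.0,
    r2: float = 3.0,
    half_sat: float = 1.0,
    X_half: float = 6.0,
):
    """Classify all 81 feedback topologies as homeostatic or not.

    Requires r1 < p_max (otherwise no topology can sustain the tissue).
    Returns a list of (signs, homeostatic_flag).
    """
    if r1 >= p_max:
        raise ValueError("homeostasis requires r1 < p_max")
    out = []
    for signs in all_sign_assignments():
        circuit = TissueCircuit(
            feedback_signs=signs, p_max=p_max, q0=q0, r1=r1, r2=r2,
            half_sat=half_sat, X_half=X_half,
        )
        out.append((signs, is_homeostatic(circuit)))
    return out


def collapse_incidence(
    circuit: TissueCircuit,
    sr: SRParameters,
    n: int,
    threshold_criterion: float = 0.1,
    seed: int = 0,
    dt: float = 0.02,
    horizon: float = 110.0,
    bin_width: float = 2.0,
) -> IncidenceCurve:
    """Incidence of tissue-crash events driven by senescent-cell load.

    Each individual's SR trajectory X(t) modulates the proliferation
    rate of their tissue circuit; a collapse is recorded at the first
    age where D falls below ``threshold_criterion`` times the baseline
    steady state.  The crash ages aggregate to an incidence curve
    (collapsed individuals leave the risk pool).
    """
    ss = steady_state(circuit, X=0.0)
    if ss is None or not is_homeostatic(circuit):
        raise ValueError("circuit is not homeostatic at X = 0")
    s_star, d_star = ss
    crit = threshold_criterion * d_star

    rng = np.random.default_rng(seed)
    steps = int(round(horizon / dt))
    x = np.zeros(n)
    S = np.full(n, s_star)
    D = np.full(n, d_star)
    ages = np.full(n, np.nan)
    pending = np.ones(n, dtype=bool)
    sq = np.sqrt(2.0 * sr.epsilon * dt)
    sp, dp, sq_sign, dq_sign = circuit.feedback_signs
    K = circuit.half_sat
    t = 0.0
    for k in range(1, steps + 1):
        x += (sr.eta * t - sr.beta * x / (sr.kappa + x)) * dt
        x += sq * rng.standard_normal(n)
        np.maximum(x, 0.0, out=x)
        p = circuit.p_max * circuit.g_x(x) * _response(S, sp, K) * _response(D, dp, K)
        q = circuit.q0 * _response(S, sq_sign, K) * _response(D, dq_sign, K)
        S += (p - q - circuit.r1) * S * dt
        D += (q * S - circuit.r2 * D) * dt
        np.maximum(S, 0.0, out=S)
        np.maximum(D, 0.0, out=D)
        t = k * dt
        hit = pending & (D < crit)
        if hit.any():
            ages[hit] = t
            pending[hit] = False
    sample = FirstPassageSample(threshold=crit, ages=ages, horizon=horizon, seed=seed)
    return empirical_hazard(sample, bin_width=bin_width)
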