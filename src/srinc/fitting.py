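"""Fitting incidence tables with the two- and three-parameter models.

The fit minimizes weighted least squares between the observed and model
incidence on the linear rate scale.  When case counts and person-years
are available, weights are the inverse squared 95% CI half-widths
(floored to avoid a few ultra-precise points dominating); otherwise the
weights are uniform.  The global stage is a coarse multi-start grid in
(Xc, log10 s[, sigma]); the best grid cells are then refined with a
bounded trust-region least-squares solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .curves import IncidenceCurve
from .incidence_model import (
    DEFAULT_CONSTANTS,
    DiseaseModel,
    RegressionConstants,
    incidence_2p,
    incidence_3p,
    log_survival,
)

__all__ = [
    "FitResult",
    "mean_log_slope",
    "classify_age_related",
    "r_squared",
    "fit_2p",
    "fit_3p",
]

#: slope thresholds (per year) for the age-relatedness classes
MILD_SLOPE = 0.03
STRONG_SLOPE = 0.07

XC_GRID_STEP = 0.5
LOG10_S_GRID = np.arange(-5.0, 0.01, 0.25)
SIGMA_GRID = np.arange(0.0, 5.01, 0.5)
N_REFINE_STARTS = 5


@dataclass(frozen=True)
class FitResult:
    """Outcome of a model fit to an incidence table."""

    model: DiseaseModel
    r_squared: float
    loss: float
    converged: bool
    n_points: int
    model_kind: str  # "two-parameter" | "three-parameter"


def mean_log_slope(
    curve: IncidenceCurve, age_min: float = 30.0, age_max: float = 80.0
) -> float:
    """Average exponential slope of the incidence curve: the OLS slope
    of ln(incidence) against age over points with positive incidence in
    [age_min, age_max], per year."""
    m = (
        (curve.ages >= age_min)
        & (curve.ages <= age_max)
        & np.isfinite(curve.incidence)
        & (curve.incidence > 0)
    )
    k = int(m.sum())
    if k < 3:
        raise ValueError(
            f"need at least 3 points with positive incidence in "
            f"[{age_min}, {age_max}] years, found {k}"
        )
    slope, _ = np.polyfit(curve.ages[m], np.log(curve.incidence[m]), 1)
    return float(slope)


def classify_age_related(slope: float) -> str:
    """Classify a mean log-slope: 'not' (< 3%/yr), 'mild' (3-7%/yr) or
    'strong' (>= 7%/yr).  Class edges are closed on the left."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if slope >= STRONG_SLOPE:
        return "strong"
    if slope >= MILD_SLOPE:
        return "mild"
    return "not"


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on the linear
    incidence scale."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and predicted must be equal-length 1-d, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values are all identical (zero total variance)")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _weights(curve: IncidenceCurve) -> np.ndarray:
    """Inverse squared 95% CI half-widths when counts are present, with a
    floor of 5% relative precision per point (a systematic-error floor that
    stops a few ultra-precise low-incidence bins from dominating), else
    uniform."""
    if curve.has_counts:
        hw = curve.ci_halfwidth()
        floor = np.maximum(0.05 * curve.incidence, 1e-4 * np.nanmax(curve.incidence))
        with np.errstate(divide="ignore"):
            w = 1.0 / np.maximum(hw, floor) ** 2
        w[~np.isfinite(w)] = 0.0
        return w
    return np.ones(len(curve))


def _model_grid_incidence(ages, Xc, sigma, s_vec, c: RegressionConstants):
    """Incidence for one (Xc, sigma) and a vector of s, shape (n_s, n_ages)."""
    if sigma == 0.0:
        A = np.exp(c.A0 + c.A1 * Xc)
        b = np.exp(c.b0 + c.b1 * Xc)
        a = c.a0 + c.a1 * Xc
        h = (A / b) * expit(a * ages + np.log(b))
        cumh = (A / (a * b)) * (
            np.logaddexp(0.0, np.log(b) + a * ages) - np.logaddexp(0.0, np.log(b))
        )
        num = h * np.exp(-cumh)
        den = np.exp(-cumh)
    else:
        from .incidence_model import _threshold_quadrature

        nodes, w = _threshold_quadrature(Xc, sigma)
        A = np.exp(c.A0 + c.A1 * nodes)[:, None]
        b = np.exp(c.b0 + c.b1 * nodes)[:, None]
        a = (c.a0 + c.a1 * nodes)[:, None]
        ln_b = np.log(b)
        h = (A / b) * expit(a * ages[None, :] + ln_b)
        cumh = (A / (a * b)) * (
            np.logaddexp(0.0, ln_b + a * ages[None, :]) - np.logaddexp(0.0, ln_b)
        )
        Ss = np.exp(-cumh)
        num = np.sum(w[:, None] * h * Ss, axis=0)
        den = np.sum(w[:, None] * Ss, axis=0)
    Sd = np.exp(log_survival(ages, c.death_hazard))
    s_col = s_vec[:, None]
    return s_col * num[None, :] / (s_col * den[None, :] + (1.0 - s_col) * Sd[None, :])


def _grid_stage(ages, obs, w, sigmas, c, xc_max):
    xc_grid = np.arange(5.0, xc_max + 1e-9, XC_GRID_STEP)
    s_vec = 10.0 ** LOG10_S_GRID
    cells = []
    for sigma in sigmas:
        for Xc in xc_grid:
            inc = _model_grid_incidence(ages, Xc, sigma, s_vec, c)
            loss = np.sum(w[None, :] * (inc - obs[None, :]) ** 2, axis=1)
            j = int(np.argmin(loss))
            cells.append((float(loss[j]), Xc, float(s_vec[j]), float(sigma)))
    cells.sort(key=lambda cell: cell[0])
    return cells


def _refine(start, ages, obs, w, c, xc_max, fit_sigma):
    _, Xc0, s0, sig0 = start
    sw = np.sqrt(w)

    def residuals(p):
        Xc, ln_s = p[0], p[1]
        sigma = p[2] if fit_sigma else sig0
        inc = _model_grid_incidence(ages, Xc, sigma, np.array([np.exp(ln_s)]), c)[0]
        return sw * (inc - obs)

    if fit_sigma:
        p0 = [Xc0, np.log(s0), sig0]
        lb, ub = [0.5, np.log(1e-7), 0.0], [xc_max, 0.0, SIGMA_GRID[-1]]
    else:
        p0 = [Xc0, np.log(s0)]
        lb, ub = [0.5, np.log(1e-7)], [xc_max, 0.0]
    res = least_squares(residuals, p0, bounds=(lb, ub), method="trf", xtol=1e-12)
    return res


def _fit(curve, constants, sigmas, fit_sigma, allow_super_death_threshold, kind,
         weighted=True):
    c = constants
    cur = curve.dropna()
    ages, obs = cur.ages, cur.incidence
    w = _weights(cur) if weighted else np.ones(len(cur))
    xc_max = 25.0 if allow_super_death_threshold else c.Xdeath
    cells = _grid_stage(ages, obs, w, sigmas, c, xc_max)

    best, best_loss = None, np.inf
    any_ok = False
    for start in cells[:N_REFINE_STARTS]:
        try:
            res = _refine(start, ages, obs, w, c, xc_max, fit_sigma)
        except Exception:
            continue
        any_ok = any_ok or res.success
        loss = 2.0 * res.cost
        if loss < best_loss:
            best, best_loss = res, loss

    if best is None:
        model = DiseaseModel(Xc_mean=cells[0][1], s=cells[0][2], sigma=cells[0][3],
                             constants=c)
        pred = (incidence_3p if model.sigma > 0 else incidence_2p)(ages, model, c)
        try:
            r2 = r_squared(obs, np.asarray(pred))
        except ValueError:
            r2 = float("-inf")
        return FitResult(model, r2, cells[0][0], False, len(ages), kind)

    def safe_r2(observed, predicted):
        # a perfectly flat observed curve has no variance to explain;
        # report the worst possible score rather than erroring out
        try:
            return r_squared(observed, predicted)
        except ValueError:
            return float("-inf")

    Xc = float(best.x[0])
    s = float(np.exp(best.x[1]))
    sigma = float(best.x[2]) if fit_sigma else 0.0
    import warnings

    with warnings.catch_warnings():
        if allow_super_death_threshold:
            warnings.simplefilter("ignore")
        model = DiseaseModel(Xc_mean=Xc, s=s, sigma=sigma, constants=c)
    pred = np.asarray((incidence_3p if sigma > 0 else incidence_2p)(ages, model, c))
    return FitResult(
        model=model,
        r_squared=safe_r2(obs, pred),
        loss=float(best_loss),
        converged=bool(any_ok),
        n_points=len(ages),
        model_kind=kind,
    )


def fit_2p(
    curve: IncidenceCurve,
    constants: RegressionConstants = DEFAULT_CONSTANTS,
    allow_super_death_threshold: bool = False,
    weighted: bool = True,
) -> FitResult:
    """Fit the two-parameter model (Xc, s).

    Deterministic: coarse grid over Xc in [5, Xdeath] (or [5, 25] when
    thresholds above the death threshold are explicitly allowed, the
    dementia-like regime) and log10 s in [-5, 0], refined from the best
    grid cells.
    """
    if len(curve.dropna()) < 4:
        raise ValueError("fit_2p needs at least 4 incidence points")
    return _fit(curve, constants, [0.0], False, allow_super_death_threshold,
                "two-parameter", weighted=weighted)


def fit_3p(
    curve: IncidenceCurve,
    constants: RegressionConstants = DEFAULT_CONSTANTS,
    allow_super_death_threshold: bool = False,
    weighted: bool = True,
) -> FitResult:
    """Fit the three-parameter model (Xc_mean, sigma, s).

    The sigma = 0 boundary contains the two-parameter model, so the
    refined loss is never materially worse than the fit_2p loss.
    """
    if len(curve.dropna()) < 5:
        raise ValueError("fit_3p needs at least 5 incidence points")
    return _fit(curve, constants, SIGMA_GRID, True, allow_super_death_threshold,
                "three-parameter", weighted=weighted)
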