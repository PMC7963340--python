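"""Saturated-removal (SR) dynamics of senescent-cell abundance.

The senescent-cell level X of an individual follows the SR stochastic
differential equation

    dX = (eta*t - beta*X/(kappa + X)) dt + sqrt(2*epsilon) dW,

with production rising linearly in age and removal that saturates in X,
so a high senescent-cell load slows its own clearance.  Disease onset
and death are first passages of X across thresholds.  Integration is
Euler-Maruyama with X clamped to 0 after each step (reflecting-at-zero
in the simplest sense), which keeps abundances non-negative.

Human values of the SR rates are not fixed a priori here; they are
obtained by :func:`calibrate_sr_parameters`, which matches simulated
first-passage distributions across a ladder of thresholds to the
closed-form hazards of :mod:`srinc.incidence_model`, anchored by the
convention that X is of order 1 in young adults.  The calibrated values
ship as the package default (``srinc/data/sr_params.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import minimize

from .curves import IncidenceCurve
from .incidence_model import (
    DEFAULT_CONSTANTS,
    RegressionConstants,
    hazard_params_from_threshold,
    log_survival,
)

__all__ = [
    "SRParameters",
    "Trajectory",
    "FirstPassageSample",
    "CalibrationResult",
    "simulate_trajectory",
    "first_passage_times",
    "first_crossing_ages",
    "empirical_hazard",
    "calibrate_sr_parameters",
    "default_sr_parameters",
]


@dataclass(frozen=True)
class SRParameters:
    """Rates of the SR equation.

    eta : production-rate slope (X-units / year^2)
    beta : maximal removal rate (X-units / year)
    kappa : removal half-saturation (X-units)
    epsilon : noise intensity (X-units^2 / year)
    """

    eta: float
    beta: float
    kappa: float
    epsilon: float

    def __post_init__(self) -> None:
        # eta = 0 / epsilon = 0 are admitted as deterministic limits
        for name in ("eta", "epsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"SR parameter {name} must be non-negative")
        for name in ("beta", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SR parameter {name} must be strictly positive")


@dataclass(frozen=True)
class Trajectory:
    """A single simulated senescent-cell path.

    ``events`` lists (age, fraction_of_sensitive_removed) senolytic
    applications, empty for untreated paths.
    """

    times: np.ndarray
    values: np.ndarray
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("senescent-cell abundance must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FirstPassageSample:
    """Per-individual first-crossing ages of one threshold.

    ``ages`` holds the crossing age in years, NaN where the path never
    reached the threshold before ``horizon`` (censored).
    """

    threshold: float
    ages: np.ndarray
    horizon: float
    seed: int

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "ages", ages)
        crossed = ages[np.isfinite(ages)]
        if np.any(crossed > self.horizon + 1e-9):
            raise ValueError("crossing ages cannot exceed the horizon")

    @property
    def n(self) -> int:
        return len(self.ages)

    @property
    def n_crossed(self) -> int:
        return int(np.isfinite(self.ages).sum())


def _check_grid(dt: float, horizon: float) -> int:
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    return int(round(horizon / dt))


def simulate_trajectory(
    params: SRParameters,
    horizon: float,
    dt: float = 0.01,
    seed: int = 0,
    schedule=None,
    x0: float = 0.0,
) -> Trajectory:
    """Integrate one SR path by Euler-Maruyama.

    With a :class:`~srinc.treatment.TreatmentSchedule`, production is
    split into drug-sensitive and insensitive compartments and the
    sensitive one is multiplied by (1 - kill_fraction) at each
    application age (see :mod:`srinc.treatment`); the returned values
    are the total X.
    """
    steps = _check_grid(dt, horizon)
    rng = np.random.default_rng(seed)
    times = dt * np.arange(steps + 1)

    f = 0.0 if schedule is None else schedule.sensitive_fraction
    xs = x0 * f  # sensitive compartment
    xi = x0 * (1.0 - f)
    app_steps: dict[int, float] = {}
    events: list[tuple[float, float]] = []
    if schedule is not None:
        for age in schedule.application_ages(horizon):
            app_steps[int(round(age / dt))] = schedule.kill_fraction

    sq_s = np.sqrt(2.0 * params.epsilon * f * dt)
    sq_i = np.sqrt(2.0 * params.epsilon * (1.0 - f) * dt)
    values = np.empty(steps + 1)
    values[0] = xs + xi
    for k in range(steps):
        t = times[k]
        total = xs + xi
        removal = params.beta / (params.kappa + total)
        z = rng.standard_normal(2)
        xs = max(xs + (f * params.eta * t - removal * xs) * dt + sq_s * z[0], 0.0)
        xi = max(
            xi + ((1.0 - f) * params.eta * t - removal * xi) * dt + sq_i * z[1], 0.0
        )
        if k + 1 in app_steps:
            kill = app_steps[k + 1]
            xs *= 1.0 - kill
            events.append((times[k + 1], kill))
        values[k + 1] = xs + xi
    return Trajectory(times=times, values=values, events=events)


def first_crossing_ages(
    params: SRParameters,
    thresholds: np.ndarray,
    n: int,
    dt: float,
    horizon: float,
    rng: np.random.Generator,
    x0: float = 0.0,
    mean_ages: np.ndarray | None = None,
):
    """Vectorized first-crossing ages for ``n`` SR paths.

    ``thresholds`` is either shape (k,) — shared thresholds, result
    (k, n) — or shape (k, n) with per-individual thresholds (np.inf
    for "never").  Optionally also returns the sample-mean X at
    ``mean_ages`` (used by the calibration anchor).

    Crossings are detected on the step grid, so a reported age is the
    first grid time with X >= threshold.
    """
    steps = _check_grid(dt, horizon)
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim == 1:
        thr = thr[:, None]
    thr = np.broadcast_to(thr, (thr.shape[0], n))

    x = np.full(n, float(x0))
    ages = np.full(thr.shape, np.nan)
    hit0 = x[None, :] >= thr
    ages[hit0] = 0.0
    pending = ~hit0

    sq = np.sqrt(2.0 * params.epsilon * dt)
    mean_steps = {}
    if mean_ages is not None:
        mean_steps = {int(round(a / dt)): i for i, a in enumerate(mean_ages)}
    mean_x = np.full(len(mean_steps), np.nan)
    if 0 in mean_steps:
        mean_x[mean_steps[0]] = x.mean()

    t = 0.0
    for k in range(1, steps + 1):
        x += (params.eta * t - params.beta * x / (params.kappa + x)) * dt
        x += sq * rng.standard_normal(n)
        np.maximum(x, 0.0, out=x)
        t = k * dt
        hit = pending & (x[None, :] >= thr)
        if hit.any():
            ages[hit] = t
            pending &= ~hit
        if k in mean_steps:
            mean_x[mean_steps[k]] = x.mean()
    if mean_ages is not None:
        return ages, mean_x
    return ages


def first_passage_times(
    params: SRParameters,
    threshold: float,
    n: int,
    dt: float = 0.01,
    horizon: float = 110.0,
    seed: int = 0,
) -> FirstPassageSample:
    """First-passage ages of ``n`` independent SR paths across one
    threshold, censored (NaN) at the horizon."""
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    ages = first_crossing_ages(params, np.array([threshold]), n, dt, horizon, rng)[0]
    return FirstPassageSample(threshold=threshold, ages=ages, horizon=horizon, seed=seed)


def empirical_hazard(sample: FirstPassageSample, bin_width: float = 1.0) -> IncidenceCurve:
    """Empirical crossing hazard: crossings per bin over at-risk
    person-years (individuals leave the risk set at crossing)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if sample.n == 0:
        raise ValueError("empty first-passage sample")
    edges = np.arange(0.0, sample.horizon + bin_width * 0.5, bin_width)
    if edges[-1] < sample.horizon:
        edges = np.append(edges, sample.horizon)
    exit_ages = np.where(np.isfinite(sample.ages), sample.ages, sample.horizon)
    cases, _ = np.histogram(sample.ages[np.isfinite(sample.ages)], bins=edges)
    py = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        py[i] = np.clip(exit_ages - edges[i], 0.0, edges[i + 1] - edges[i]).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(py > 0, cases / py, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return IncidenceCurve(
        ages=centers, incidence=rate, cases=cases.astype(float), person_years=py
    )


@dataclass(frozen=True)
class CalibrationResult:
    params: SRParameters
    loss: float
    converged: bool
    n_evaluations: int


#: age grid on which first-passage CDFs are compared during calibration
_CAL_AGES = np.arange(20.0, 111.0, 2.0)
#: ages over which the young-adult level anchor <X> ~ 1 is averaged
_ANCHOR_AGES = np.arange(10.0, 31.0, 5.0)
_ANCHOR_WEIGHT = 5.0


def analytic_crossing_cdf(
    Xc: float, ages: np.ndarray, constants: RegressionConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Closed-form first-passage CDF 1 - S(t | Xc) for a threshold."""
    hp = hazard_params_from_threshold(Xc, constants)
    return 1.0 - np.exp(log_survival(ages, hp))


def calibrate_sr_parameters(
    constants: RegressionConstants = DEFAULT_CONSTANTS,
    thresholds=(12.0, 13.0, 14.0, 15.0, 16.0, 17.0),
    n: int = 2000,
    seed: int = 0,
    dt: float = 0.02,
    horizon: float = 110.0,
    initial: SRParameters | None = None,
    target_cdfs: np.ndarray | None = None,
    maxiter: int = 300,
    anchor_weight: float = _ANCHOR_WEIGHT,
) -> CalibrationResult:
    """Fit SR rates so simulated first-passage hazards match targets.

    For each threshold the empirical crossing CDF of ``n`` simulated
    paths is compared (sum of squares on :data:`_CAL_AGES`) against
    ``target_cdfs`` — by default the closed-form CDFs
    ``1 - S(t | Xc)`` — and the young-adult mean level is anchored at
    X = 1.  Optimization is Nelder-Mead in log-parameter space with
    common random numbers (the same seed re-used at every evaluation),
    which makes the objective deterministic and the result reproducible.

    A non-converged optimizer is reported through the ``converged``
    flag, never silently.
    """
    thr = np.asarray(thresholds, dtype=float)
    if len(np.unique(thr)) < 3:
        raise ValueError("calibration needs at least 3 distinct thresholds")
    if np.any(thr <= 0) or np.any(thr > constants.Xdeath):
        raise ValueError("thresholds must lie in (0, Xdeath]")

    if target_cdfs is None:
        target_cdfs = np.stack([analytic_crossing_cdf(x, _CAL_AGES, constants) for x in thr])
    target_cdfs = np.asarray(target_cdfs, dtype=float)

    if initial is None:
        initial = SRParameters(eta=0.009, beta=0.28, kappa=0.5, epsilon=1.0)

    n_eval = 0

    # variance-stabilized weights (binomial variance + a floor at the
    # n-path resolution limit) keep the hazard tails informative
    var = target_cdfs * (1.0 - target_cdfs) + 5.0 / n

    def loss_fn(log_p: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        p = SRParameters(*np.exp(log_p))
        rng = np.random.default_rng(seed)  # common random numbers
        ages, mean_x = first_crossing_ages(
            p, thr, n, dt, horizon, rng, mean_ages=_ANCHOR_AGES
        )
        # empirical CDF of crossing ages on the comparison grid
        emp = np.stack(
            [np.mean(np.nan_to_num(a, nan=np.inf)[:, None] <= _CAL_AGES[None, :], axis=0)
             for a in ages]
        )
        sse = float(np.mean((emp - target_cdfs) ** 2 / var))
        anchor = anchor_weight * float((np.nanmean(mean_x) - 1.0) ** 2)
        return sse + anchor

    x0 = np.log([initial.eta, initial.beta, initial.kappa, initial.epsilon])
    res = minimize(
        loss_fn,
        x0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 2e-4, "fatol": 1e-6, "adaptive": True},
    )
    params = SRParameters(*np.exp(res.x))
    return CalibrationResult(
        params=params, loss=float(res.fun), converged=bool(res.success), n_evaluations=n_eval
    )


def default_sr_parameters() -> SRParameters:
    """The calibrated SR rates shipped with the package."""
    text = resources.files("srinc").joinpath("data/sr_params.yaml").read_text()
    doc = yaml.safe_load(text)
    p = doc["sr_parameters"]
    return SRParameters(
        eta=float(p["eta"]),
        beta=float(p["beta"]),
        kappa=float(p["kappa"]),
        epsilon=float(p["epsilon"]),
    )
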