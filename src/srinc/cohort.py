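"""Individual-level synthetic cohorts under the threshold-mixture model.

Each simulated person is susceptible with probability ``s``; a
susceptible person carries a disease threshold (fixed ``Xc`` or a
truncated-normal draw) and develops the disease when their
senescent-cell level first crosses it.  Onset ages are generated either
by simulating the SR stochastic process directly (``mode="sde"``) or by
inverse-CDF sampling from the closed-form onset survival
(``mode="closed-form"``).  Death follows the threshold-17 hazard.

The closed-form model keeps susceptibles in the at-risk pool until
onset (it neglects their death beforehand); the cohort generator
mirrors that accounting — a susceptible's death age is drawn
conditional on falling after onset, and in SDE mode onset (at
Xc <= 17) necessarily precedes death (at 17) on the same trajectory —
so that aggregated cohort incidence is an unbiased Monte-Carlo estimate
of the closed-form curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curves import IncidenceCurve
from .incidence_model import (
    DiseaseModel,
    HazardParameters,
    hazard_params_from_threshold,
    log_survival,
)
from .sr_dynamics import SRParameters, first_crossing_ages, default_sr_parameters

__all__ = ["CohortSpec", "EventTable", "simulate_cohort", "aggregate_incidence", "make_fixture"]

MODES = ("sde", "closed-form")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort."""

    n: int
    model: DiseaseModel
    mode: str = "closed-form"
    horizon: float = 110.0
    seed: int = 0
    dt: float = 0.01
    sr: SRParameters | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be at least 1")
        if not 0 < self.horizon <= 110:
            raise ValueError("horizon must be in (0, 110] years")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def sr_params(self) -> SRParameters:
        return self.sr if self.sr is not None else default_sr_parameters()


@dataclass(frozen=True)
class EventTable:
    """Per-individual outcomes of a cohort simulation.

    ``onset_age`` and ``death_age`` are NaN when the event did not occur
    before the horizon.  Onset never falls after death.
    """

    susceptible: np.ndarray
    threshold: np.ndarray
    onset_age: np.ndarray
    death_age: np.ndarray
    horizon: float
    spec: CohortSpec | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        n = len(self.susceptible)
        for name in ("threshold", "onset_age", "death_age"):
            if len(getattr(self, name)) != n:
                raise ValueError("all per-individual arrays must share a length")
        both = np.isfinite(self.onset_age) & np.isfinite(self.death_age)
        if np.any(self.onset_age[both] > self.death_age[both] + 1e-9):
            raise ValueError("onset must precede death")

    @property
    def n(self) -> int:
        return len(self.susceptible)

    @property
    def n_onsets(self) -> int:
        return int(np.isfinite(self.onset_age).sum())

    def exit_ages(self) -> np.ndarray:
        """Age at which each individual leaves the at-risk pool
        (onset, death or the horizon, whichever is first)."""
        exit_age = np.full(self.n, self.horizon)
        d = np.isfinite(self.death_age)
        exit_age[d] = np.minimum(exit_age[d], self.death_age[d])
        o = np.isfinite(self.onset_age)
        exit_age[o] = np.minimum(exit_age[o], self.onset_age[o])
        return exit_age


def _sample_thresholds(model: DiseaseModel, size: int, rng: np.random.Generator) -> np.ndarray:
    if model.sigma == 0.0:
        return np.full(size, model.Xc_mean)
    # rejection below 0; negligible mass for realistic (Xc_mean, sigma)
    out = rng.normal(model.Xc_mean, model.sigma, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(model.Xc_mean, model.sigma, int(bad.sum()))
        bad = out <= 0
    return out


def _invert_survival(hp_A, hp_b, hp_a, target_cumhaz):
    """Solve cumulative_hazard(t) = target for t, vectorized over
    per-individual hazard parameters (requires a > 0)."""
    L0 = np.logaddexp(0.0, np.log(hp_b))
    L = L0 + target_cumhaz * hp_a * hp_b / hp_A
    # b e^{at} = e^L - 1  ->  t = (log(expm1(L)) - log b) / a
    with np.errstate(over="ignore"):
        t = (np.log(np.expm1(L)) - np.log(hp_b)) / hp_a
    return t


def _sample_event_ages(hp_arrays, u, horizon):
    """Inverse-CDF ages from survival S(t); NaN where S(horizon) > u."""
    A, b, a = hp_arrays
    t = _invert_survival(A, b, a, -np.log(u))
    return np.where(t <= horizon, t, np.nan)


def _hp_arrays(thresholds: np.ndarray, constants) -> tuple:
    A = np.exp(constants.A0 + constants.A1 * thresholds)
    b = np.exp(constants.b0 + constants.b1 * thresholds)
    a = constants.a0 + constants.a1 * thresholds
    if np.any(a <= 0):
        raise ValueError("closed-form sampling requires hazard slope a > 0 "
                         "(thresholds above ~2.1 X-units)")
    return A, b, a


def simulate_cohort(spec: CohortSpec) -> EventTable:
    """Simulate a cohort and return its event table (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    c = model.constants
    n = spec.n

    susceptible = rng.random(n) < model.s
    n_s = int(susceptible.sum())
    threshold = np.full(n, np.nan)
    threshold[susceptible] = _sample_thresholds(model, n_s, rng)

    onset = np.full(n, np.nan)
    death = np.full(n, np.nan)

    if spec.mode == "closed-form":
        dh = c.death_hazard
        if n_s:
            hp = _hp_arrays(threshold[susceptible], c)
            onset_s = _sample_event_ages(hp, rng.random(n_s), spec.horizon)
            onset[susceptible] = onset_s
            # death conditional on death >= onset (where onset occurred)
            t0 = np.nan_to_num(onset_s, nan=0.0)
            ch0 = -log_survival(t0, dh)
            death_s = _invert_survival(dh.A, dh.b, dh.a, ch0 - np.log(rng.random(n_s)))
            death[susceptible] = np.where(death_s <= spec.horizon, death_s, np.nan)
        n_r = n - n_s
        if n_r:
            death_r = _invert_survival(dh.A, dh.b, dh.a, -np.log(rng.random(n_r)))
            death[~susceptible] = np.where(death_r <= spec.horizon, death_r, np.nan)
    else:  # sde
        sr = spec.sr_params()
        onset_thr = np.where(susceptible, threshold, np.inf)
        thr = np.vstack([onset_thr, np.full(n, c.Xdeath)])
        ages = first_crossing_ages(sr, thr, n, spec.dt, spec.horizon, rng)
        onset, death = ages[0], ages[1]
        # a threshold draw above Xdeath can be reached only after death
        late = np.isfinite(onset) & np.isfinite(death) & (onset > death)
        onset[late] = np.nan

    return EventTable(
        susceptible=susceptible,
        threshold=threshold,
        onset_age=onset,
        death_age=death,
        horizon=spec.horizon,
        spec=spec,
    )


def aggregate_incidence(events: EventTable, bin_width: float = 1.0) -> IncidenceCurve:
    """Aggregate an event table to an incidence curve.

    Per age bin: cases = onsets in the bin; person_years = at-risk time
    of individuals alive and disease-free during the bin; incidence =
    cases / person_years, NaN (missing, not zero) where no person-years
    accrued.
    """
    if events.n == 0:
        raise ValueError("empty event table")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(0.0, events.horizon + 0.5 * bin_width, bin_width)
    if edges[-1] < events.horizon:
        edges = np.append(edges, events.horizon)
    exit_ages = events.exit_ages()
    onsets = events.onset_age[np.isfinite(events.onset_age)]
    cases, _ = np.histogram(onsets, bins=edges)
    py = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        py[i] = np.clip(exit_ages - edges[i], 0.0, edges[i + 1] - edges[i]).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(py > 0, cases / py, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return IncidenceCurve(
        ages=centers, incidence=rate, cases=cases.astype(float), person_years=py
    )


def make_fixture(
    name: str,
    spec: CohortSpec,
    noise: float = 0.0,
    directory: str | Path = ".",
    bin_width: float = 1.0,
    overwrite: bool = False,
) -> Path:
    """Write a deterministic incidence-curve CSV fixture.

    ``noise`` adds seeded multiplicative lognormal noise (relative sd)
    to the rates, in which case the count columns are dropped because
    the rate/count identity no longer holds.
    """
    from .io import write_incidence_csv

    path = Path(directory) / f"{name}.csv"
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    curve = aggregate_incidence(simulate_cohort(spec), bin_width=bin_width).dropna()
    if noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF1D0]))
        factor = np.exp(rng.normal(0.0, noise, len(curve)) - 0.5 * noise**2)
        curve = IncidenceCurve(ages=curve.ages, incidence=curve.incidence * factor)
    write_incidence_csv(curve, path)
    return path
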