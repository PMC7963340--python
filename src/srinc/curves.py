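"""The incidence-table container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IncidenceCurve"]


@dataclass(frozen=True)
class IncidenceCurve:
    """Incidence rates per person-year on a grid of ages.

    ``ages`` are bin-center ages in years (strictly increasing);
    ``incidence`` is new cases per person-year at risk.  When the
    underlying counts are known, ``cases`` and ``person_years`` are
    carried along and must satisfy incidence = cases/person_years; the
    counts give binomial error bars (95% CI via the normal
    approximation to the Poisson rate).
    """

    ages: np.ndarray
    incidence: np.ndarray
    cases: np.ndarray | None = None
    person_years: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "incidence", np.asarray(self.incidence, dtype=float))
        if self.ages.shape != self.incidence.shape or self.ages.ndim != 1:
            raise ValueError("ages and incidence must be 1-d arrays of equal length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        finite = np.isfinite(self.incidence)
        if np.any(self.incidence[finite] < 0):
            raise ValueError("incidence rates must be non-negative")
        for name in ("cases", "person_years"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != self.ages.shape:
                    raise ValueError(f"{name} must match the age grid")
        if self.cases is not None and self.person_years is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = self.cases / self.person_years
            ok = np.isfinite(ratio) & np.isfinite(self.incidence)
            if not np.allclose(ratio[ok], self.incidence[ok], atol=1e-9, rtol=1e-9):
                raise ValueError("incidence must equal cases/person_years")

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def has_counts(self) -> bool:
        return self.cases is not None and self.person_years is not None

    def ci_halfwidth(self) -> np.ndarray:
        """95% CI half-width of each rate (normal approx. to the Poisson
        count); requires counts."""
        if not self.has_counts:
            raise ValueError("confidence intervals require cases and person_years")
        with np.errstate(invalid="ignore", divide="ignore"):
            # zero-case bins carry the one-count resolution limit, not zero width
            return 1.96 * np.sqrt(np.maximum(self.cases, 1.0)) / self.person_years

    def dropna(self) -> "IncidenceCurve":
        """Curve restricted to bins with a finite incidence value."""
        keep = np.isfinite(self.incidence)
        return IncidenceCurve(
            ages=self.ages[keep],
            incidence=self.incidence[keep],
            cases=None if self.cases is None else self.cases[keep],
            person_years=None if self.person_years is None else self.person_years[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"age": self.ages, "incidence": self.incidence}
        if self.cases is not None:
            data["cases"] = self.cases
        if self.person_years is not None:
            data["person_years"] = self.person_years
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceCurve":
        return cls(
            ages=df["age"].to_numpy(dtype=float),
            incidence=df["incidence"].to_numpy(dtype=float),
            cases=df["cases"].to_numpy(dtype=float) if "cases" in df else None,
            person_years=(
                df["person_years"].to_numpy(dtype=float) if "person_years" in df else None
            ),
        )
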