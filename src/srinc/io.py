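"""Readers, writers and run configuration.

Incidence tables are comma-separated UTF-8 text with a mandatory
header: columns ``age``, ``incidence`` and optionally ``cases`` and
``person_years``.  Rates are always per person-year.  Every CLI output
gets a JSON metadata sidecar (parameters, seed, package version)
sufficient to regenerate it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import IncidenceCurve
from .incidence_model import DEFAULT_CONSTANTS, RegressionConstants
from .sr_dynamics import SRParameters, default_sr_parameters

__all__ = ["RunConfig", "read_incidence_csv", "write_incidence_csv", "write_sidecar",
           "load_config", "save_config"]

_REQUIRED = ("age", "incidence")
_OPTIONAL = ("cases", "person_years")


def read_incidence_csv(path: str | Path) -> IncidenceCurve:
    """Read and validate an incidence table.

    Errors name the offending row (1-based, excluding the header) and
    column: missing columns, non-numeric cells, duplicate or
    non-increasing ages, negative rates, and count/rate mismatches are
    all rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    cols = list(_REQUIRED) + [c for c in _OPTIONAL if c in df.columns]
    for col in cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path.name}: non-numeric value in column {col!r}, row {row}"
            )
        df[col] = numeric
    ages = df["age"].to_numpy(dtype=float)
    dup = np.where(np.diff(ages) == 0)[0]
    if dup.size:
        raise ValueError(
            f"{path.name}: duplicate age in column 'age', row {int(dup[0]) + 2}"
        )
    if np.any(np.diff(ages) < 0):
        row = int(np.where(np.diff(ages) < 0)[0][0]) + 2
        raise ValueError(f"{path.name}: ages must be strictly increasing (row {row})")
    try:
        return IncidenceCurve.from_frame(df)
    except ValueError as err:
        raise ValueError(f"{path.name}: {err}") from err


def write_incidence_csv(curve: IncidenceCurve, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curve.to_frame().to_csv(path, index=False, encoding="utf-8")
    return path


def write_sidecar(path: str | Path, **metadata) -> Path:
    """Write ``<output>.meta.json`` next to an output file."""
    from importlib.metadata import version

    out = Path(str(path) + ".meta.json")
    try:
        ver = version("srinc")
    except Exception:
        ver = "unknown"
    payload = {"srinc_version": ver, **metadata}
    out.write_text(json.dumps(payload, indent=2, default=str), encoding="utf-8")
    return out


@dataclass(frozen=True)
class RunConfig:
    """Package-level defaults: regression constants, SR rates and
    simulation granularity."""

    constants: RegressionConstants = field(default_factory=RegressionConstants)
    sr: SRParameters | None = None
    dt: float = 0.01
    horizon: float = 110.0
    bin_width: float = 1.0
    seed: int = 0
    output_dir: Path = Path(".")

    def sr_params(self) -> SRParameters:
        return self.sr if self.sr is not None else default_sr_parameters()


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    constants = RegressionConstants(**doc.get("constants", {}))
    sr = SRParameters(**doc["sr_parameters"]) if "sr_parameters" in doc else None
    defaults = doc.get("defaults", {})
    return RunConfig(
        constants=constants,
        sr=sr,
        dt=float(defaults.get("dt", 0.01)),
        horizon=float(defaults.get("horizon", 110.0)),
        bin_width=float(defaults.get("bin_width", 1.0)),
        seed=int(defaults.get("seed", 0)),
        output_dir=Path(defaults.get("output_dir", ".")),
    )


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "constants": asdict(config.constants),
        "defaults": {
            "dt": config.dt,
            "horizon": config.horizon,
            "bin_width": config.bin_width,
            "seed": config.seed,
            "output_dir": str(config.output_dir),
        },
    }
    if config.sr is not None:
        doc["sr_parameters"] = asdict(config.sr)
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path
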