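"""Readers, writers and the run-configuration schema.

CSV dialects (headers are mandatory and checked):

* dissolution:  ``time_h, released_mg``
* plasma:       ``time_h, conc_mg_per_L``
* pH program:   ``time_h, pH``
* trajectory:   tidy ``time_h, compartment, amount_mg, concentration_mg_per_L``

Configuration files are YAML (or JSON, a YAML subset) with strict schemas:
unknown keys are errors, the physiology block must contain exactly the 22
named parameters, and every key name embeds its unit.  A mis-specified
physiology silently falling back to defaults would corrupt a calibration,
so nothing here defaults silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ivivc import PlasmaDataset
from .pbpk import PARAMETER_NAMES, DoseEvent, PBPKTrajectory, PhysiologySpec
from .protocol import PHProgram
from .release import DissolutionProfile, ReleaseModel

__all__ = [
    "DataFormatError",
    "ConfigError",
    "RunConfig",
    "read_timeseries_csv",
    "write_dissolution_csv",
    "write_plasma_csv",
    "write_ph_program_csv",
    "write_fitted_curve_csv",
    "write_trajectory_csv",
    "load_config",
    "CONFIG_PHYSIOLOGY_KEYS",
]


class DataFormatError(ValueError):
    """Malformed input table; the message names the offending row/column."""


class ConfigError(ValueError):
    """Invalid run configuration; the message lists every problem found."""


_DIALECTS = {
    "dissolution": ("time_h", "released_mg"),
    "plasma": ("time_h", "conc_mg_per_L"),
    "ph_program": ("time_h", "pH"),
}

# config keys carry units; mapped onto the bare PhysiologySpec field names
CONFIG_PHYSIOLOGY_KEYS = {
    "V_gics_L": "V_gics",
    "V_liver_L": "V_liver",
    "V_plasma_L": "V_plasma",
    "V_tissues_L": "V_tissues",
    "V_lumen_stomach_L": "V_lumen_stomach",
    "V_lumen_si_L": "V_lumen_si",
    "V_lumen_li_L": "V_lumen_li",
    "Q_gics_L_per_h": "Q_gics",
    "Q_portal_L_per_h": "Q_portal",
    "Q_hepatic_out_L_per_h": "Q_hepatic_out",
    "Q_tissues_L_per_h": "Q_tissues",
    "k_gastric_per_h": "k_gastric",
    "k_si_transit_per_h": "k_si_transit",
    "k_li_transit_per_h": "k_li_transit",
    "PA_stomach_L_per_h": "PA_stomach",
    "PA_si_L_per_h": "PA_si",
    "PA_li_L_per_h": "PA_li",
    "CL_hepatic_L_per_h": "CL_hepatic",
    "CL_renal_L_per_h": "CL_renal",
    "F_unbound_factor": "F_unbound_factor",
    "t_form_gastric_h": "t_form_gastric",
    "t_form_si_h": "t_form_si",
}
assert set(CONFIG_PHYSIOLOGY_KEYS.values()) == set(PARAMETER_NAMES)


def _read_two_column(path: str | Path, columns: tuple[str, str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"{path}: file does not exist")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"found {list(df.columns)}"
        )
    df = df[list(columns)]
    for col in columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        if bad:
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise DataFormatError(f"{path}: non-numeric value in column {col!r} at row(s) {rows}")
    df = df.astype(float).sort_values(columns[0], kind="stable").reset_index(drop=True)
    dup = df.index[df[columns[0]].duplicated()].tolist()
    if dup:
        rows = ", ".join(str(i + 2) for i in dup[:5])
        raise DataFormatError(f"{path}: duplicated {columns[0]} value at sorted row(s) {rows}")
    return df


def read_timeseries_csv(
    path: str | Path,
    kind: str,
    *,
    label: str = "",
    dose_content_mg: float = 100.0,
    dose: DoseEvent | None = None,
    interpolation: str = "linear",
):
    """Read one of the three timeseries dialects into its typed object.

    Rows are normalized by time; duplicated times are rejected with the row
    number.  ``kind='plasma'`` needs the administered :class:`DoseEvent` to
    build a full :class:`PlasmaDataset` (pass ``dose=None`` to get a bare
    (times, concentrations) tuple).
    """
    if kind not in _DIALECTS:
        raise ValueError(f"kind must be one of {sorted(_DIALECTS)}")
    df = _read_two_column(path, _DIALECTS[kind])
    t = df.iloc[:, 0].to_numpy()
    v = df.iloc[:, 1].to_numpy()
    if kind == "dissolution":
        return DissolutionProfile(
            times=t, cumulative_released=v, label=label, dose_content_mg=dose_content_mg
        )
    if kind == "plasma":
        if dose is None:
            return t, v
        return PlasmaDataset(
            times=t, concentrations=v, formulation_label=label, dose=dose
        )
    return PHProgram(
        breakpoints=tuple(zip(t.tolist(), v.tolist())), interpolation=interpolation
    )


def write_dissolution_csv(path: str | Path, profile: DissolutionProfile) -> None:
    pd.DataFrame(
        {"time_h": profile.times, "released_mg": profile.cumulative_released}
    ).to_csv(path, index=False)


def write_plasma_csv(path: str | Path, dataset: PlasmaDataset) -> None:
    pd.DataFrame(
        {"time_h": dataset.times, "conc_mg_per_L": dataset.concentrations}
    ).to_csv(path, index=False)


def write_ph_program_csv(path: str | Path, program: PHProgram) -> None:
    t = [b[0] for b in program.breakpoints]
    ph = [b[1] for b in program.breakpoints]
    pd.DataFrame({"time_h": t, "pH": ph}).to_csv(path, index=False)


def write_fitted_curve_csv(
    path: str | Path, model: ReleaseModel, t_grid: np.ndarray
) -> None:
    """Smooth fitted release curve sampled on a configurable grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    pd.DataFrame(
        {
            "time_h": t_grid,
            "released_mg": model.cumulative(t_grid),
            "rate_mg_per_h": model.rate(t_grid),
        }
    ).to_csv(path, index=False)


def write_trajectory_csv(path: str | Path, trajectory: PBPKTrajectory) -> None:
    """Tidy long-format trajectory: one row per (time, compartment)."""
    from .pbpk import COMPARTMENTS

    perfused = {"gics", "liver", "plasma", "tissues"}
    rows = []
    for name in COMPARTMENTS:
        conc = (
            trajectory.concentration(name)
            if name in perfused
            else np.full_like(trajectory.times, np.nan)
        )
        rows.append(
            pd.DataFrame(
                {
                    "time_h": trajectory.times,
                    "compartment": name,
                    "amount_mg": trajectory.amount(name),
                    "concentration_mg_per_L": conc,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level run configuration."""

    physiology: PhysiologySpec
    doses: dict[str, DoseEvent] = field(default_factory=dict)
    input_paths: dict[str, str] = field(default_factory=dict)
    free_parameters: tuple[str, ...] = ()
    protocol: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"


_TOP_LEVEL_KEYS = {
    "physiology",
    "doses",
    "inputs",
    "free_parameters",
    "protocol",
    "seed",
    "output_dir",
    "log_level",
}

_DOSE_KEYS = {"route", "amount_mg", "start_h", "duration_h", "release"}
_RELEASE_KEYS = {"form", "M_inf_mg", "tau_h", "beta", "t_lag_h"}


def _parse_physiology(block: dict, problems: list[str]) -> PhysiologySpec | None:
    if not isinstance(block, dict):
        problems.append("physiology: must be a mapping")
        return None
    missing = sorted(set(CONFIG_PHYSIOLOGY_KEYS) - set(block))
    extra = sorted(set(block) - set(CONFIG_PHYSIOLOGY_KEYS))
    if missing:
        problems.append(f"physiology: missing parameter(s): {', '.join(missing)}")
    if extra:
        problems.append(f"physiology: unknown parameter(s): {', '.join(extra)}")
    if missing or extra:
        return None
    values = {}
    for key, name in CONFIG_PHYSIOLOGY_KEYS.items():
        v = block[key]
        if not isinstance(v, (int, float)) or isinstance(v, bool) or not math.isfinite(v):
            problems.append(f"physiology.{key}: must be a finite number, got {v!r}")
            return None
        values[name] = float(v)
    try:
        return PhysiologySpec.from_dict(values)
    except ValueError as exc:
        problems.append(f"physiology: {exc}")
        return None


def _parse_dose(name: str, block: dict, problems: list[str]) -> DoseEvent | None:
    if not isinstance(block, dict):
        problems.append(f"doses.{name}: must be a mapping")
        return None
    extra = sorted(set(block) - _DOSE_KEYS)
    if extra:
        problems.append(f"doses.{name}: unknown key(s): {', '.join(extra)}")
        return None
    release = None
    if "release" in block:
        rel = block["release"]
        rextra = sorted(set(rel) - _RELEASE_KEYS)
        if rextra:
            problems.append(f"doses.{name}.release: unknown key(s): {', '.join(rextra)}")
            return None
        try:
            release = ReleaseModel(
                form=rel.get("form", "weibull"),
                m_inf=rel["M_inf_mg"],
                tau=rel["tau_h"],
                beta=rel.get("beta", 1.0),
                t_lag=rel.get("t_lag_h", 0.0),
            )
        except (KeyError, ValueError) as exc:
            problems.append(f"doses.{name}.release: {exc}")
            return None
    try:
        return DoseEvent(
            route=block.get("route", "oral"),
            amount_mg=block.get("amount_mg", 0.0),
            start_h=block.get("start_h", 0.0),
            duration_h=block.get("duration_h"),
            release_model=release,
        )
    except ValueError as exc:
        problems.append(f"doses.{name}: {exc}")
        return None


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML/JSON run configuration.

    Every problem found is reported in one exception message; nothing is
    silently defaulted except the documented optional keys.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"{path}: file does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    problems: list[str] = []
    extra = sorted(set(raw) - _TOP_LEVEL_KEYS)
    if extra:
        problems.append(f"unknown top-level key(s): {', '.join(extra)}")
    if "physiology" not in raw:
        problems.append("missing required block: physiology")
        physiology = None
    else:
        physiology = _parse_physiology(raw["physiology"], problems)

    doses: dict[str, DoseEvent] = {}
    for name, block in (raw.get("doses") or {}).items():
        d = _parse_dose(name, block, problems)
        if d is not None:
            doses[name] = d

    free = tuple(raw.get("free_parameters") or ())
    unknown_free = sorted(set(free) - set(PARAMETER_NAMES))
    if unknown_free:
        problems.append(f"free_parameters: unknown name(s): {', '.join(unknown_free)}")

    inputs = raw.get("inputs") or {}
    if not isinstance(inputs, dict):
        problems.append("inputs: must be a mapping of name -> path")
        inputs = {}

    if problems:
        raise ConfigError(f"{path}: " + "; ".join(problems))
    assert physiology is not None
    return RunConfig(
        physiology=physiology,
        doses=doses,
        input_paths={k: str(v) for k, v in inputs.items()},
        free_parameters=free,
        protocol=raw.get("protocol") or {},
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
    )
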