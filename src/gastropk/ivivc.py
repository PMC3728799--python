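"""Calibrate-once, predict-without-refitting IVIVC workflow.

The workflow mirrors how a physiologically based model earns Level-A IVIVC
status: (1) fit each formulation's in-vitro release profile (see
:mod:`gastropk.release`); (2) calibrate a small set of free physiology
parameters against the plasma concentration curve of *one* formulation;
(3) predict the plasma curves of the remaining formulations with the
calibrated parameters frozen — no further optimization — and compare
Cmax/AUC prediction errors against the observed data.

Also provides standard non-compartmental analysis (NCA): Cmax/Tmax from the
discrete maximum, AUC by the linear-up/log-down trapezoid, and terminal
extrapolation via a log-linear lambda_z fit.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .pbpk import PARAMETER_NAMES, DoseEvent, PBPKTrajectory, PhysiologySpec, simulate

__all__ = [
    "PlasmaDataset",
    "CalibrationResult",
    "PKMetrics",
    "IdentifiabilityError",
    "FrozenParameterError",
    "calibrate",
    "predict",
    "nca_metrics",
    "prediction_errors",
]

# The splanchnic flows are constrained equal; calibrating any one of them
# moves all three together.
_FLOW_GROUP = ("Q_gics", "Q_portal", "Q_hepatic_out")

DEFAULT_FREE_PARAMETERS = ("PA_si", "CL_hepatic", "Q_tissues", "F_unbound_factor")


class IdentifiabilityError(ValueError):
    """More free parameters than data points."""


class FrozenParameterError(RuntimeError):
    """Calibrated parameters were mutated between calibrate and predict."""


@dataclass(frozen=True)
class PlasmaDataset:
    """Observed plasma concentration-time data for one formulation."""

    times: np.ndarray  # h
    concentrations: np.ndarray  # mg/L
    formulation_label: str
    dose: DoseEvent

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


def _fingerprint(physiology: PhysiologySpec) -> str:
    payload = json.dumps(physiology.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class CalibrationResult:
    """Outcome of :func:`calibrate`; input contract of :func:`predict`."""

    fitted: dict[str, float]
    fixed: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    objective: float
    convergence_report: dict
    physiology: PhysiologySpec
    dataset_label: str
    _frozen_fingerprint: str = field(repr=False, default="")

    def __post_init__(self) -> None:
        covered = set(self.fitted) | set(self.fixed)
        if covered != set(PARAMETER_NAMES) or (set(self.fitted) & set(self.fixed)):
            raise ValueError("fitted and fixed must partition the 22 parameters exactly")
        if not self._frozen_fingerprint:
            self._frozen_fingerprint = _fingerprint(self.physiology)


def _apply_free(
    template: PhysiologySpec, names: tuple[str, ...], values: np.ndarray
) -> PhysiologySpec:
    changes: dict[str, float] = {}
    for name, value in zip(names, values):
        if name in _FLOW_GROUP:
            for n in _FLOW_GROUP:
                changes[n] = float(value)
        else:
            changes[name] = float(value)
    return template.replace(**changes)


def _start_grid(
    bounds: list[tuple[float, float]], per_dim: int = 5, cap: int = 32
) -> np.ndarray:
    """Deterministic log-spaced multi-start grid, strided down to <= cap."""
    axes = [np.geomspace(lo, hi, per_dim) for lo, hi in bounds]
    full = np.array(list(itertools.product(*axes)))
    if len(full) <= cap:
        return full
    stride = int(math.ceil(len(full) / cap))
    return full[::stride][:cap]


def calibrate(
    dataset: PlasmaDataset,
    physiology_template: PhysiologySpec,
    free_parameter_names: list[str] = list(DEFAULT_FREE_PARAMETERS),
    *,
    bounds: dict[str, tuple[float, float]] | None = None,
    conc_floor_fraction: float = 0.01,
    n_local: int = 3,
    sim_rtol: float = 1e-8,
    li_residence_h: float = 24.0,
) -> CalibrationResult:
    """Bounded weighted least squares of free parameters to one plasma curve.

    The objective is sum_i w_i * (C_model(t_i) - C_obs(t_i))^2 with relative
    weights w_i = 1/max(C_obs_i, floor)^2, floor = ``conc_floor_fraction``
    of the observed Cmax (plasma curves span about an order of magnitude;
    relative weighting keeps the tail informative without letting
    near-zero samples blow up).

    Multi-start is deterministic: 5 log-spaced values per free dimension,
    the factorial grid strided down to at most 32 start points; every start
    is scored with one simulation and local optimization runs from the
    ``n_local`` best.  Default bounds are a factor of 10 either side of the
    template value.
    """
    names = tuple(free_parameter_names)
    if not names:
        raise ValueError("free parameter set must be non-empty")
    unknown = sorted(set(names) - set(PARAMETER_NAMES))
    if unknown:
        raise ValueError(f"unknown free parameters: {', '.join(unknown)}")
    if len(set(names) & set(_FLOW_GROUP)) > 1:
        raise ValueError(
            "the splanchnic flows are one constrained group; free at most one of "
            + ", ".join(_FLOW_GROUP)
        )
    if len(names) >= len(dataset):
        raise IdentifiabilityError(
            f"{len(names)} free parameters but only {len(dataset)} data points"
        )
    if len(dataset) < 5:
        raise ValueError("calibration needs at least 5 plasma samples")

    template_values = physiology_template.to_dict()
    bnds: list[tuple[float, float]] = []
    for name in names:
        if bounds and name in bounds:
            lo, hi = bounds[name]
        else:
            v = template_values[name]
            if v <= 0:
                raise ValueError(
                    f"cannot derive default bounds for {name} = 0; pass bounds explicitly"
                )
            lo, hi = v / 10.0, v * 10.0
        if not (0 < lo < hi):
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        bnds.append((lo, hi))

    c_obs = dataset.concentrations
    floor = conc_floor_fraction * float(np.max(c_obs))
    w = 1.0 / np.maximum(c_obs, floor)

    t_grid = dataset.times
    if t_grid[0] > dataset.dose.start_h:
        t_grid = np.concatenate([[dataset.dose.start_h], t_grid])
        obs_mask = np.ones(len(t_grid), dtype=bool)
        obs_mask[0] = False
    else:
        obs_mask = np.ones(len(t_grid), dtype=bool)

    n_sim = 0

    def residuals(theta_log: np.ndarray) -> np.ndarray:
        nonlocal n_sim
        phys = _apply_free(physiology_template, names, 10.0**theta_log)
        traj = simulate(
            phys,
            dataset.dose,
            t_grid,
            rtol=sim_rtol,
            li_residence_h=li_residence_h,
        )
        n_sim += 1
        return w * (traj.plasma_concentration[obs_mask] - c_obs)

    starts = _start_grid(bnds)
    scores = [float(np.sum(residuals(np.log10(s)) ** 2)) for s in starts]
    order = np.argsort(scores)[: max(1, n_local)]

    log_lo = np.log10([b[0] for b in bnds])
    log_hi = np.log10([b[1] for b in bnds])
    best = None
    reports = []
    for idx in order:
        sol = least_squares(
            residuals,
            np.log10(starts[idx]),
            bounds=(log_lo, log_hi),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        cost = float(np.sum(sol.fun**2))
        reports.append(
            {"start": starts[idx].tolist(), "objective": cost, "status": sol.status}
        )
        if best is None or cost < best[0]:
            best = (cost, sol)
    assert best is not None
    cost, sol = best
    if sol.status <= 0:
        raise RuntimeError(f"calibration did not converge: {sol.message}")

    fitted_values = 10.0**sol.x
    calibrated = _apply_free(physiology_template, names, fitted_values)
    fitted = {n: float(v) for n, v in zip(names, fitted_values)}
    # constrained flow partners count as fitted too, so fitted+fixed covers 22
    for n in names:
        if n in _FLOW_GROUP:
            for partner in _FLOW_GROUP:
                fitted[partner] = float(getattr(calibrated, partner))
    fixed = {
        n: float(getattr(calibrated, n)) for n in PARAMETER_NAMES if n not in fitted
    }
    return CalibrationResult(
        fitted=fitted,
        fixed=fixed,
        bounds={n: b for n, b in zip(names, bnds)},
        objective=cost,
        convergence_report={
            "n_starts_screened": len(starts),
            "n_local_fits": len(order),
            "n_simulations": n_sim,
            "termination": sol.message,
            "starts": reports,
        },
        physiology=calibrated,
        dataset_label=dataset.formulation_label,
    )


def predict(
    calibration: CalibrationResult,
    new_dose: DoseEvent,
    t_grid: np.ndarray,
    *,
    extrapolate: bool = True,
    li_residence_h: float = 24.0,
) -> tuple[PBPKTrajectory, "PKMetrics"]:
    """Simulate a new formulation with the calibrated parameters frozen.

    Any mutation of the calibrated physiology between :func:`calibrate` and
    :func:`predict` violates the no-refitting contract and raises
    :class:`FrozenParameterError`.
    """
    if _fingerprint(calibration.physiology) != calibration._frozen_fingerprint:
        raise FrozenParameterError(
            "calibrated physiology was modified after calibration; "
            "prediction requires the frozen parameter set"
        )
    traj = simulate(
        calibration.physiology, new_dose, t_grid, li_residence_h=li_residence_h
    )
    metrics = nca_metrics(traj.times, traj.plasma_concentration, extrapolate=extrapolate)
    return traj, metrics


@dataclass(frozen=True)
class PKMetrics:
    """Non-compartmental summary of one concentration-time curve."""

    cmax: float  # mg/L
    tmax: float  # h
    auc_0_last: float  # mg*h/L
    auc_0_inf: float  # mg*h/L (nan when extrapolation refused/not requested)
    lambda_z: float  # 1/h (nan when not estimable)
    extrapolated_fraction: float
    extrapolation_refused: bool = False
    prediction_error_cmax_pct: float | None = None
    prediction_error_auc_pct: float | None = None


def _auc_trapezoid(t: np.ndarray, c: np.ndarray, method: str) -> float:
    if method == "linear":
        return float(np.trapezoid(c, t))
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c2 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * 0.5 * (c1 + c2)
    return auc


def nca_metrics(
    times: np.ndarray,
    concentrations: np.ndarray,
    *,
    extrapolate: bool = False,
    max_extrapolated_fraction: float = 0.20,
    min_terminal_points: int = 3,
    auc_method: str = "lin_up_log_down",
) -> PKMetrics:
    """Non-compartmental analysis of a concentration-time curve.

    AUC(0-last) uses the linear-up/log-down trapezoid by default
    (``auc_method="linear"`` selects the plain linear trapezoid).  When
    ``extrapolate`` is set, lambda_z comes from a log-linear regression on
    the terminal descending points after Tmax (at least
    ``min_terminal_points``) and AUC(0-inf) = AUC(0-last) + C_last/lambda_z;
    the result is flagged refused when the extrapolated tail would exceed
    ``max_extrapolated_fraction`` of AUC(0-inf) or no descending terminal
    phase exists.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or len(t) < 3:
        raise ValueError("need >= 3 (time, concentration) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")

    if auc_method not in ("lin_up_log_down", "linear"):
        raise ValueError("auc_method must be 'lin_up_log_down' or 'linear'")
    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])
    auc_last = _auc_trapezoid(t, c, auc_method)

    if cmax == 0.0:
        return PKMetrics(0.0, tmax, 0.0, 0.0, math.nan, 0.0, True)

    lambda_z = math.nan
    auc_inf = math.nan
    frac = math.nan
    refused = False
    if extrapolate:
        tail = np.nonzero((np.arange(len(t)) > i_max) & (c > 0))[0]
        if len(tail) >= min_terminal_points:
            tt, cc = t[tail], np.log(c[tail])
            slope, _ = np.polyfit(tt, cc, 1)
            if slope < 0:
                lambda_z = -float(slope)
                c_last = float(c[tail[-1]])
                auc_inf = _auc_trapezoid(t[: tail[-1] + 1], c[: tail[-1] + 1], auc_method)
                auc_inf += c_last / lambda_z
                frac = (c_last / lambda_z) / auc_inf
                if frac > max_extrapolated_fraction:
                    refused = True
                    auc_inf = math.nan
            else:
                refused = True
        else:
            refused = True
        if refused and math.isnan(lambda_z):
            lambda_z = math.nan
    return PKMetrics(
        cmax=cmax,
        tmax=tmax,
        auc_0_last=auc_last,
        auc_0_inf=auc_inf,
        lambda_z=lambda_z,
        extrapolated_fraction=frac,
        extrapolation_refused=refused,
    )


def prediction_errors(predicted: PKMetrics, observed: PKMetrics) -> PKMetrics:
    """Attach percent prediction errors (predicted vs observed) to a result."""
    pe_cmax = 100.0 * (predicted.cmax - observed.cmax) / observed.cmax
    auc_p = predicted.auc_0_inf if not math.isnan(predicted.auc_0_inf) else predicted.auc_0_last
    auc_o = observed.auc_0_inf if not math.isnan(observed.auc_0_inf) else observed.auc_0_last
    pe_auc = 100.0 * (auc_p - auc_o) / auc_o
    return PKMetrics(
        cmax=predicted.cmax,
        tmax=predicted.tmax,
        auc_0_last=predicted.auc_0_last,
        auc_0_inf=predicted.auc_0_inf,
        lambda_z=predicted.lambda_z,
        extrapolated_fraction=predicted.extrapolated_fraction,
        extrapolation_refused=predicted.extrapolation_refused,
        prediction_error_cmax_pct=pe_cmax,
        prediction_error_auc_pct=pe_auc,
    )
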