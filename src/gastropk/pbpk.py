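"""Seven-compartment physiologically based pharmacokinetic (PBPK) model.

The body is represented as seven perfectly mixed compartments (the CSTR
assumption): three gastrointestinal lumen volumes (stomach, small intestine,
large intestine), the gastrointestinal circulatory system ("gi.c.s", the
splanchnic blood draining the gut wall), the liver, the plasma (blood plus
well-perfused organs), and a lumped scarcely perfused tissues compartment.
Drug crosses the gut wall and the tissue capillary walls by passive
diffusion: flux = PA * (concentration difference), with PA a
permeability-area product in L/h.

Circulation follows the physiological splanchnic route
plasma -> gi.c.s -> liver (portal vein) -> plasma; flow balance
(Q_gics = Q_portal = Q_hepatic_out) keeps the gi.c.s and liver volumes
constant and is enforced at construction.  Elimination is split into a
first-order hepatic metabolic clearance (acting on liver concentration,
which also produces the oral first-pass effect) and a renal clearance from
plasma.  Either may be zero.

Dissolved drug moves down the lumen chain by first-order transit
(k * amount); the *intact dosage form* — the release source — moves by timed
windows instead (gastric emptying at 2 h by default, matching the enteric
test protocol, then small-intestine and large-intestine residence).  An oral
dose therefore releases drug into whichever lumen the form currently
occupies; an IV dose enters plasma directly, as a bolus or a constant-rate
infusion.

Units are fixed throughout: mg, L, h; concentrations mg/L.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .release import ReleaseModel, release_rate

__all__ = [
    "PhysiologySpec",
    "DoseEvent",
    "PBPKState",
    "PBPKTrajectory",
    "PARAMETER_NAMES",
    "COMPARTMENTS",
    "N_COMPARTMENTS",
    "rhs",
    "simulate",
    "dosage_form_transit_times",
    "SolverError",
]

COMPARTMENTS = (
    "stomach_lumen",
    "si_lumen",
    "li_lumen",
    "gics",
    "liver",
    "plasma",
    "tissues",
)
N_COMPARTMENTS = len(COMPARTMENTS)

# augmented state: 7 compartments + dosage-form reservoir + 3 cumulative sinks
_IDX_UNRELEASED = 7
_IDX_MET = 8
_IDX_REN = 9
_IDX_FEC = 10
_N_STATES = 11

_NEG_TOL = 1e-9  # mg; solver-tolerance slack on non-negativity

PARAMETER_NAMES = (
    "V_gics",
    "V_liver",
    "V_plasma",
    "V_tissues",
    "V_lumen_stomach",
    "V_lumen_si",
    "V_lumen_li",
    "Q_gics",
    "Q_portal",
    "Q_hepatic_out",
    "Q_tissues",
    "k_gastric",
    "k_si_transit",
    "k_li_transit",
    "PA_stomach",
    "PA_si",
    "PA_li",
    "CL_hepatic",
    "CL_renal",
    "F_unbound_factor",
    "t_form_gastric",
    "t_form_si",
)


class SolverError(RuntimeError):
    """ODE integration failed."""


@dataclass(frozen=True)
class PhysiologySpec:
    """The model's 22 scalar parameters.

    Volumes (L): four distribution volumes (gi.c.s, liver, plasma, tissues)
    and three lumen fluid volumes.  Flows (L/h): splanchnic perfusion
    Q_gics, portal flow Q_portal, hepatic outflow Q_hepatic_out (all three
    must be equal — inflow = outflow for gi.c.s and liver) and the
    plasma-tissue exchange flow Q_tissues.  Transit constants (1/h) empty
    dissolved drug down the lumen chain.  PA_* (L/h) are permeability-area
    products for passive diffusion across the gut wall.  CL_hepatic and
    CL_renal (L/h) are first-order clearances.  F_unbound_factor lumps
    tissue partitioning/binding: at distribution equilibrium
    C_tissues = F * C_plasma.  t_form_gastric and t_form_si (h) are the
    timed-window residences of the intact dosage form in stomach and small
    intestine.
    """

    V_gics: float
    V_liver: float
    V_plasma: float
    V_tissues: float
    V_lumen_stomach: float
    V_lumen_si: float
    V_lumen_li: float
    Q_gics: float
    Q_portal: float
    Q_hepatic_out: float
    Q_tissues: float
    k_gastric: float
    k_si_transit: float
    k_li_transit: float
    PA_stomach: float
    PA_si: float
    PA_li: float
    CL_hepatic: float
    CL_renal: float
    F_unbound_factor: float
    t_form_gastric: float = 2.0
    t_form_si: float = 3.0

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not self.V_plasma > 0:
            raise ValueError("V_plasma must be > 0")
        if not math.isclose(self.Q_portal, self.Q_gics, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                "flow balance violated: Q_portal must equal Q_gics "
                f"({self.Q_portal} != {self.Q_gics})"
            )
        if not math.isclose(self.Q_hepatic_out, self.Q_portal, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                "flow balance violated: Q_hepatic_out must equal Q_portal "
                f"({self.Q_hepatic_out} != {self.Q_portal})"
            )
        lumen_vols = (self.V_lumen_stomach, self.V_lumen_si, self.V_lumen_li)
        for pa, vol, which in zip(
            (self.PA_stomach, self.PA_si, self.PA_li), lumen_vols, ("stomach", "si", "li")
        ):
            if pa > 0 and vol == 0:
                raise ValueError(f"PA_{which} > 0 requires V_lumen_{which} > 0")
        for q_or_cl, vol, which in (
            (self.Q_gics, self.V_gics, "gics"),
            (self.Q_portal + self.CL_hepatic, self.V_liver, "liver"),
            (self.Q_tissues, self.V_tissues, "tissues"),
        ):
            if q_or_cl > 0 and vol == 0:
                raise ValueError(f"flows through {which} require V_{which} > 0")

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAMETER_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "PhysiologySpec":
        missing = sorted(set(PARAMETER_NAMES) - set(d))
        extra = sorted(set(d) - set(PARAMETER_NAMES))
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"missing parameters: {', '.join(missing)}")
            if extra:
                parts.append(f"unknown parameters: {', '.join(extra)}")
            raise ValueError("; ".join(parts))
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **changes) -> "PhysiologySpec":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class DoseEvent:
    """One administration: IV bolus, IV constant-rate infusion, or oral.

    An oral dose carries the fitted release model of its dosage form; the
    released drug enters the lumen in which the intact form currently
    resides.  The release model's M_inf may not exceed the labelled amount.
    """

    route: str  # iv_bolus | iv_infusion | oral
    amount_mg: float
    start_h: float = 0.0
    duration_h: float | None = None
    release_model: ReleaseModel | None = None

    def __post_init__(self) -> None:
        if self.route not in ("iv_bolus", "iv_infusion", "oral"):
            raise ValueError(f"unknown route {self.route!r}")
        if not self.amount_mg > 0:
            raise ValueError("amount_mg must be > 0")
        if self.route == "iv_infusion":
            if self.duration_h is None or not self.duration_h > 0:
                raise ValueError("iv_infusion requires duration_h > 0")
        if self.route == "oral":
            if self.release_model is None:
                raise ValueError("oral dose requires a release_model")
            if self.release_model.m_inf > self.amount_mg * (1 + 1e-9):
                raise ValueError("release model M_inf exceeds the dose amount")


@dataclass(frozen=True)
class PBPKState:
    """State snapshot: compartment amounts plus bookkeeping (all mg)."""

    amounts: np.ndarray  # ordered as COMPARTMENTS
    unreleased: float
    dosage_form_location: str  # stomach | si | li | exited
    eliminated_metabolic: float
    eliminated_renal: float
    excreted_fecal: float

    @property
    def total(self) -> float:
        return (
            float(np.sum(self.amounts))
            + self.unreleased
            + self.eliminated_metabolic
            + self.eliminated_renal
            + self.excreted_fecal
        )


def dosage_form_transit_times(
    physiology: PhysiologySpec, li_residence_h: float = 24.0
) -> tuple[float, float, float]:
    """Absolute times (h after ingestion) at which the intact form moves on.

    Returns (gastric emptying, small-intestine exit, large-intestine exit).
    Defaults — 2 h gastric residence (the enteric protocol's "after two
    hours"), 3 h small-intestine and 24 h large-intestine residence — give
    switches at 2, 5 and 29 h.  Only the intact dosage form obeys these
    windows; dissolved drug always moves by the first-order k's.
    """
    t1 = physiology.t_form_gastric
    t2 = t1 + physiology.t_form_si
    t3 = t2 + li_residence_h
    return (t1, t2, t3)


def _form_location(t_since_dose: float, switches: tuple[float, float, float]) -> str:
    if t_since_dose < switches[0]:
        return "stomach"
    if t_since_dose < switches[1]:
        return "si"
    if t_since_dose < switches[2]:
        return "li"
    return "exited"


def _lumen_conc(amount: float, volume: float) -> float:
    return amount / volume if volume > 0 else 0.0


def _rhs_core(
    t: float,
    y: np.ndarray,
    p: PhysiologySpec,
    dose: DoseEvent,
    location: str,
    infusing: bool,
) -> np.ndarray:
    """Derivative with the dosage-form location and infusion state fixed.

    The algebraic sum of all 11 derivatives (compartments, reservoir,
    sinks) is identically zero: mass only moves, it is never created.
    """
    d = np.zeros(_N_STATES)
    c_st = _lumen_conc(y[0], p.V_lumen_stomach)
    c_si = _lumen_conc(y[1], p.V_lumen_si)
    c_li = _lumen_conc(y[2], p.V_lumen_li)
    c_g = y[3] / p.V_gics if p.V_gics > 0 else 0.0
    c_l = y[4] / p.V_liver if p.V_liver > 0 else 0.0
    c_p = y[5] / p.V_plasma
    c_t = y[6] / p.V_tissues if p.V_tissues > 0 else 0.0

    rel = 0.0
    if dose.route == "oral" and location != "exited" and y[_IDX_UNRELEASED] > 0:
        rel = release_rate(dose.release_model, max(t - dose.start_h, 0.0))
    iv = dose.amount_mg / dose.duration_h if infusing else 0.0

    j_st = p.PA_stomach * (c_st - c_g)
    j_si = p.PA_si * (c_si - c_g)
    j_li = p.PA_li * (c_li - c_g)
    tr_g = p.k_gastric * y[0]
    tr_si = p.k_si_transit * y[1]
    tr_li = p.k_li_transit * y[2]
    f_tis = p.Q_tissues * (c_p - c_t / p.F_unbound_factor) if p.Q_tissues > 0 else 0.0

    d[0] = (rel if location == "stomach" else 0.0) - tr_g - j_st
    d[1] = (rel if location == "si" else 0.0) + tr_g - tr_si - j_si
    d[2] = (rel if location == "li" else 0.0) + tr_si - tr_li - j_li
    d[3] = j_st + j_si + j_li + p.Q_gics * c_p - p.Q_portal * c_g
    d[4] = p.Q_portal * c_g - p.Q_hepatic_out * c_l - p.CL_hepatic * c_l
    d[5] = (
        p.Q_hepatic_out * c_l
        - p.Q_gics * c_p
        - f_tis
        - p.CL_renal * c_p
        + iv
    )
    d[6] = f_tis
    d[_IDX_UNRELEASED] = -rel - iv if (rel or iv) else 0.0
    d[_IDX_MET] = p.CL_hepatic * c_l
    d[_IDX_REN] = p.CL_renal * c_p
    d[_IDX_FEC] = tr_li
    return d


def rhs(
    t: float,
    state: np.ndarray,
    physiology: PhysiologySpec,
    dose: DoseEvent,
    li_residence_h: float = 24.0,
) -> np.ndarray:
    """Mass-balance derivatives at time t for the 11-entry augmented state.

    State layout: 7 compartment amounts (order :data:`COMPARTMENTS`), then
    the dosage-form reservoir (unreleased / undelivered mass), then the
    cumulative metabolic, renal and fecal sinks.  All entries in mg.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (_N_STATES,):
        raise ValueError(f"state must have {_N_STATES} entries, got shape {y.shape}")
    if np.any(y[:N_COMPARTMENTS] < -_NEG_TOL):
        raise ValueError("negative compartment amount beyond solver tolerance")
    location = "exited"
    infusing = False
    if dose.route == "oral":
        switches = dosage_form_transit_times(physiology, li_residence_h)
        location = _form_location(t - dose.start_h, switches)
    elif dose.route == "iv_infusion":
        infusing = dose.start_h <= t < dose.start_h + dose.duration_h
    return _rhs_core(t, y, physiology, dose, location, infusing)


@dataclass(frozen=True)
class PBPKTrajectory:
    """Solver output on the requested time grid."""

    times: np.ndarray
    amounts: np.ndarray  # (n_times, 11)
    physiology: PhysiologySpec
    dose: DoseEvent
    li_residence_h: float = 24.0

    @property
    def compartment_amounts(self) -> np.ndarray:
        """(n_times, 7) drug amount per compartment, mg."""
        return self.amounts[:, :N_COMPARTMENTS]

    def amount(self, compartment: str) -> np.ndarray:
        return self.amounts[:, COMPARTMENTS.index(compartment)]

    def concentration(self, compartment: str) -> np.ndarray:
        """Concentration (mg/L) in a perfused compartment."""
        volumes = {
            "gics": self.physiology.V_gics,
            "liver": self.physiology.V_liver,
            "plasma": self.physiology.V_plasma,
            "tissues": self.physiology.V_tissues,
        }
        if compartment not in volumes:
            raise ValueError(f"no distribution volume for {compartment!r}")
        v = volumes[compartment]
        if v == 0:
            return np.zeros_like(self.times)
        return self.amount(compartment) / v

    @property
    def plasma_concentration(self) -> np.ndarray:
        return self.concentration("plasma")

    def state(self, i: int) -> PBPKState:
        t = self.times[i]
        location = "exited"
        if self.dose.route == "oral":
            switches = dosage_form_transit_times(self.physiology, self.li_residence_h)
            location = _form_location(t - self.dose.start_h, switches)
        return PBPKState(
            amounts=self.amounts[i, :N_COMPARTMENTS].copy(),
            unreleased=float(self.amounts[i, _IDX_UNRELEASED]),
            dosage_form_location=location,
            eliminated_metabolic=float(self.amounts[i, _IDX_MET]),
            eliminated_renal=float(self.amounts[i, _IDX_REN]),
            excreted_fecal=float(self.amounts[i, _IDX_FEC]),
        )

    def mass_balance_error(self) -> np.ndarray:
        """Relative deviation of total accounted mass from the mobile dose.

        For oral doses the mobile mass is the release model's M_inf (an
        unreleasable fraction amount - M_inf never enters the body); for IV
        doses it is the administered amount.  Zero before the dose.
        """
        mobile = (
            self.dose.release_model.m_inf
            if self.dose.route == "oral"
            else self.dose.amount_mg
        )
        total = self.amounts.sum(axis=1)
        expected = np.where(self.times >= self.dose.start_h - 1e-12, mobile, 0.0)
        return (total - expected) / mobile


def simulate(
    physiology: PhysiologySpec,
    dose: DoseEvent,
    t_grid: np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    li_residence_h: float = 24.0,
    method: str = "LSODA",
) -> PBPKTrajectory:
    """Integrate the model over ``t_grid`` (hours).

    Integration is split at every derivative discontinuity — dose start,
    dosage-form location switches, infusion end — so the stiff-capable
    solver never steps across a kink.  Absolute tolerance in mg.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if t_grid[0] > dose.start_h:
        raise ValueError("t_grid must start at or before the dose start")

    t0, t_end = float(t_grid[0]), float(t_grid[-1])
    breaks = {dose.start_h}
    if dose.route == "oral":
        for s in dosage_form_transit_times(physiology, li_residence_h):
            breaks.add(dose.start_h + s)
    elif dose.route == "iv_infusion":
        breaks.add(dose.start_h + dose.duration_h)
    edges = [t0] + sorted(b for b in breaks if t0 < b < t_end) + [t_end]

    y = np.zeros(_N_STATES)
    out = np.empty((len(t_grid), _N_STATES))
    written = np.zeros(len(t_grid), dtype=bool)

    def store(mask: np.ndarray, values: np.ndarray) -> None:
        out[mask] = values
        written[mask] = True

    for a, b in zip(edges, edges[1:]):
        mask = (t_grid >= a - 1e-12) & (t_grid <= b + 1e-12) & ~written
        if math.isclose(a, dose.start_h, rel_tol=0, abs_tol=1e-12):
            if dose.route == "iv_bolus":
                y[5] += dose.amount_mg
            elif dose.route == "oral":
                y[_IDX_UNRELEASED] += dose.release_model.m_inf
            elif dose.route == "iv_infusion":
                y[_IDX_UNRELEASED] += dose.amount_mg
        t_mid = 0.5 * (a + b)
        location = "exited"
        infusing = False
        if dose.route == "oral" and t_mid >= dose.start_h:
            switches = dosage_form_transit_times(physiology, li_residence_h)
            location = _form_location(t_mid - dose.start_h, switches)
        elif dose.route == "iv_infusion":
            infusing = dose.start_h <= t_mid < dose.start_h + dose.duration_h
        t_eval = t_grid[mask]
        sol = solve_ivp(
            _rhs_core,
            (a, b),
            y,
            method=method,
            t_eval=t_eval if len(t_eval) else None,
            rtol=rtol,
            atol=atol,
            args=(physiology, dose, location, infusing),
        )
        if not sol.success:
            raise SolverError(f"integration failed on [{a}, {b}]: {sol.message}")
        if len(t_eval):
            store(mask, sol.y.T)
        y = sol.y[:, -1] if sol.y.shape[1] else y
        # ensure we continue from the segment endpoint, not the last t_eval
        if len(t_eval) == 0 or not math.isclose(t_eval[-1], b, rel_tol=0, abs_tol=1e-12):
            sol_end = solve_ivp(
                _rhs_core,
                (t_eval[-1] if len(t_eval) else a, b),
                y,
                method=method,
                rtol=rtol,
                atol=atol,
                args=(physiology, dose, location, infusing),
            )
            if not sol_end.success:
                raise SolverError(f"integration failed on [{a}, {b}]: {sol_end.message}")
            y = sol_end.y[:, -1]

    if not written.all():
        raise SolverError("internal error: some grid points were not evaluated")
    out[:, :N_COMPARTMENTS] = np.where(
        (out[:, :N_COMPARTMENTS] < 0) & (out[:, :N_COMPARTMENTS] > -_NEG_TOL),
        0.0,
        out[:, :N_COMPARTMENTS],
    )
    return PBPKTrajectory(
        times=t_grid,
        amounts=out,
        physiology=physiology,
        dose=dose,
        li_residence_h=li_residence_h,
    )
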