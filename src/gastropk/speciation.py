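"""Equilibrium acid/base chemistry of dissolution media.

The two-stage enteric dissolution test is defined chemically: an acid stage
(0.1 M hydrochloric acid) followed by a buffer stage made by adding tribasic
sodium phosphate.  This module computes the equilibrium pH of such media by
solving the full charge balance over every dissolved form (H+, OH-, spectator
counterions, and all protonation states of polyprotic buffers), either with
ideal (unit activity coefficient) chemistry or with the Davies activity
correction at a self-consistently solved ionic strength.

Conventions: concentrations in mol/L, volumes in liters.  The water
autoionization product Kw = 1e-14 enters every balance.  Only strong
acids/bases and one polyprotic buffer family are supported; this is a
dissolution-test tool, not a general geochemical speciation code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml
from scipy.optimize import brentq

__all__ = [
    "SpeciesDef",
    "SpeciesRegistry",
    "MediumComposition",
    "PHResult",
    "InfeasibleMediumError",
    "ConvergenceError",
    "TitrationDirectionError",
    "default_registry",
    "compute_ph",
    "mix",
    "titrant_volume_for_target_ph",
]

KW = 1e-14
DAVIES_A = 0.509
DAVIES_LINEAR = 0.3
H_BRACKET = (1e-14, 10.0)  # mol/L


class InfeasibleMediumError(ValueError):
    """No root of the charge balance inside the H+ bracket."""


class ConvergenceError(RuntimeError):
    """Ionic-strength self-consistency loop failed to converge."""


class TitrationDirectionError(ValueError):
    """Target pH lies on the wrong side of the current pH for the titrant."""


@dataclass(frozen=True)
class SpeciesDef:
    """One entry of the species registry.

    ``counterion_charge`` is the total spectator-ion charge delivered per
    formula unit: +3 for Na3PO4 (three sodium ions), -1 for HCl (chloride).
    ``pka`` lists the stepwise acid dissociation constants of the fully
    protonated parent acid; strong species carry an empty list.
    """

    name: str
    type: str  # strong_acid | strong_base | polyprotic_acid_salt
    pka: tuple[float, ...] = ()
    charge_fully_protonated: int = 0
    counterion_charge: int = 0
    form_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in ("strong_acid", "strong_base", "polyprotic_acid_salt"):
            raise ValueError(f"unknown species type {self.type!r} for {self.name!r}")
        if self.type in ("strong_acid", "strong_base") and self.pka:
            raise ValueError(f"strong species {self.name!r} must have an empty pKa list")
        if any(b <= a for a, b in zip(self.pka, self.pka[1:])):
            raise ValueError(f"pKa list of {self.name!r} must be strictly increasing")
        if self.type == "polyprotic_acid_salt" and not self.pka:
            raise ValueError(f"polyprotic species {self.name!r} needs at least one pKa")

    @property
    def n_protons(self) -> int:
        return len(self.pka)


class SpeciesRegistry:
    """Lookup table name -> SpeciesDef, loadable from a YAML file."""

    def __init__(self, species: dict[str, SpeciesDef]):
        self._species = dict(species)

    def __getitem__(self, name: str) -> SpeciesDef:
        try:
            return self._species[name]
        except KeyError:
            raise KeyError(
                f"species {name!r} not in registry (known: {sorted(self._species)})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._species

    def names(self) -> list[str]:
        return sorted(self._species)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "SpeciesRegistry":
        out = {}
        for name, entry in raw["species"].items():
            out[name] = SpeciesDef(
                name=name,
                type=entry["type"],
                pka=tuple(entry.get("pKa", ())),
                charge_fully_protonated=entry.get("charge_fully_protonated", 0),
                counterion_charge=entry.get("counterion_charge", 0),
                form_names=tuple(entry.get("form_names", ())),
            )
        return cls(out)


def default_registry() -> SpeciesRegistry:
    """Registry bundled with the package (HCl, NaOH, sodium phosphates)."""
    ref = resources.files("gastropk.data").joinpath("species.yaml")
    raw = yaml.safe_load(ref.read_text())
    return SpeciesRegistry._from_mapping(raw)


@dataclass(frozen=True)
class MediumComposition:
    """A stirred dissolution medium: volume plus total analytical concentrations.

    ``totals`` maps registry species names to total (analytical) molarity —
    e.g. 0.1 M HCl regardless of dissociation state.  Temperature is carried
    for bookkeeping only; equilibrium constants are 25 degC values.
    """

    volume_l: float
    totals: dict[str, float] = field(default_factory=dict)
    temperature_c: float = 37.0
    registry: SpeciesRegistry = field(default_factory=default_registry, compare=False)

    def __post_init__(self) -> None:
        if not (self.volume_l > 0 and math.isfinite(self.volume_l)):
            raise ValueError(f"volume must be a positive finite number, got {self.volume_l}")
        for name, conc in self.totals.items():
            if not (math.isfinite(conc) and conc >= 0):
                raise ValueError(f"total concentration of {name!r} must be finite and >= 0")
            self.registry[name]  # raises for unknown species

    def moles(self, name: str) -> float:
        return self.totals.get(name, 0.0) * self.volume_l


@dataclass(frozen=True)
class PHResult:
    """Solved equilibrium state of a medium."""

    ph: float
    mode: str
    ionic_strength: float
    speciation: dict[str, float]
    charge_balance_residual: float


def _davies_log10_gamma(z: int, ionic_strength: float) -> float:
    if z == 0 or ionic_strength <= 0:
        return 0.0
    s = math.sqrt(ionic_strength)
    return -DAVIES_A * z * z * (s / (1.0 + s) - DAVIES_LINEAR * ionic_strength)


def _gamma(z: int, ionic_strength: float, mode: str) -> float:
    if mode == "ideal":
        return 1.0
    return 10.0 ** _davies_log10_gamma(z, ionic_strength)


def _polyprotic_fractions(
    sp: SpeciesDef, a_h: float, ionic_strength: float, mode: str
) -> list[float]:
    """Mole fractions of the protonation forms, most protonated first.

    Successive deprotonation ratios use mixed constants: Ka_j relates the H+
    *activity* to the *concentrations* of the conjugate pair through the
    Davies activity coefficients of the two forms.
    """
    z0 = sp.charge_fully_protonated
    terms = [1.0]
    running = 1.0
    for j, pka in enumerate(sp.pka, start=1):
        ka = 10.0 ** (-pka)
        g_prev = _gamma(z0 - (j - 1), ionic_strength, mode)
        g_next = _gamma(z0 - j, ionic_strength, mode)
        running *= ka * g_prev / (a_h * g_next)
        terms.append(running)
    total = math.fsum(terms)
    return [t / total for t in terms]


def _speciate(
    medium: MediumComposition, h_conc: float, ionic_strength: float, mode: str
) -> tuple[dict[str, float], float, float]:
    """Full speciation at a trial [H+].

    Returns (concentration map, charge-balance residual in mol/L, ionic
    strength of this speciation).
    """
    g1 = _gamma(1, ionic_strength, mode)
    a_h = g1 * h_conc
    oh_conc = KW / (a_h * g1)  # a_OH = Kw / a_H, [OH-] = a_OH / gamma_1

    conc: dict[str, float] = {"H+": h_conc, "OH-": oh_conc}
    residual = h_conc - oh_conc
    ionic = h_conc + oh_conc  # running sum of z^2 * c (both ions are +/-1)

    for name, total in medium.totals.items():
        if total == 0.0:
            continue
        sp = medium.registry[name]
        zc = sp.counterion_charge
        if zc != 0:
            ion = "Na+" if zc > 0 else "Cl-"
            per_ion = abs(zc) * total
            conc[ion] = conc.get(ion, 0.0) + per_ion
            residual += zc * total
            ionic += per_ion * (1 if zc > 0 else 1)  # counterions are monovalent
        if sp.type == "polyprotic_acid_salt":
            fracs = _polyprotic_fractions(sp, a_h, ionic_strength, mode)
            z0 = sp.charge_fully_protonated
            for j, frac in enumerate(fracs):
                c = frac * total
                z = z0 - j
                form = sp.form_names[j] if sp.form_names else f"{name}:H{sp.n_protons - j}"
                conc[form] = conc.get(form, 0.0) + c
                residual += z * c
                ionic += z * z * c
    return conc, residual, 0.5 * ionic


def _solve_h(medium: MediumComposition, ionic_strength: float, mode: str) -> float:
    """Root of the charge balance in [H+], on the fixed bracket (1e-14, 10)."""

    def f(log_h: float) -> float:
        return _speciate(medium, 10.0**log_h, ionic_strength, mode)[1]

    lo, hi = math.log10(H_BRACKET[0]), math.log10(H_BRACKET[1])
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return 10.0**lo
    if f_hi == 0.0:
        return 10.0**hi
    if f_lo * f_hi > 0:
        raise InfeasibleMediumError(
            "charge balance has no root for [H+] in (1e-14, 10) mol/L; "
            "medium is outside the solver's domain"
        )
    log_h = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)
    h = 10.0**log_h
    # Newton polish on the residual in [H+] (numerical derivative).
    for _ in range(2):
        r = _speciate(medium, h, ionic_strength, mode)[1]
        dh = max(1e-9 * h, 1e-300)
        r2 = _speciate(medium, h + dh, ionic_strength, mode)[1]
        slope = (r2 - r) / dh
        if slope == 0.0:
            break
        step = r / slope
        if not math.isfinite(step) or abs(step) >= h:
            break
        h -= step
    return h


def compute_ph(
    medium: MediumComposition,
    mode: str,
    *,
    max_iter: int = 80,
    ionic_strength_tol: float = 1e-12,
) -> PHResult:
    """Equilibrium pH of a medium.

    Parameters
    ----------
    medium
        Volume and total analytical concentrations of registry species.
    mode
        ``"ideal"`` — unit activity coefficients, pH = -log10 [H+];
        ``"davies"`` — Davies activity coefficients (A = 0.509, linear term
        0.3·I) on every charged form, ionic strength solved self-consistently
        by fixed-point iteration, pH = -log10 a(H+).  The mode must be given
        explicitly: the nominal "pH 1.0" of 0.1 M HCl is an ideal-scale
        value, while buffer-stage targets like 6.8 require the activity
        correction.
    """
    if mode not in ("ideal", "davies"):
        raise ValueError(f"mode must be 'ideal' or 'davies', got {mode!r}")

    ionic = 0.0
    h = _solve_h(medium, ionic, mode)
    if mode == "davies":
        for _ in range(max_iter):
            _, _, ionic_new = _speciate(medium, h, ionic, mode)
            if abs(ionic_new - ionic) <= ionic_strength_tol:
                ionic = ionic_new
                break
            ionic = ionic_new
            h = _solve_h(medium, ionic, mode)
        else:
            raise ConvergenceError(
                f"ionic-strength iteration did not converge in {max_iter} steps"
            )
    conc, residual, ionic_final = _speciate(medium, h, ionic, mode)
    a_h = _gamma(1, ionic, mode) * h
    return PHResult(
        ph=-math.log10(a_h if mode == "davies" else h),
        mode=mode,
        ionic_strength=ionic_final if mode == "ideal" else ionic,
        speciation=conc,
        charge_balance_residual=residual,
    )


def mix(media: list[MediumComposition]) -> MediumComposition:
    """Volume-additive mixing; conserves moles of every species exactly."""
    if not media:
        raise ValueError("mix() needs at least one medium")
    registry = media[0].registry
    volume = math.fsum(m.volume_l for m in media)
    names = sorted({n for m in media for n in m.totals})
    totals = {
        n: math.fsum(m.moles(n) for m in media) / volume for n in names
    }
    temperature = math.fsum(m.temperature_c * m.volume_l for m in media) / volume
    return MediumComposition(
        volume_l=volume, totals=totals, temperature_c=temperature, registry=registry
    )


def _aliquot(medium: MediumComposition, volume_l: float) -> MediumComposition:
    return replace(medium, volume_l=volume_l)


def titrant_volume_for_target_ph(
    medium: MediumComposition,
    titrant: MediumComposition,
    target_ph: float,
    mode: str,
    *,
    ph_tol: float = 0.01,
    max_volume_l: float = 10.0,
) -> float:
    """Smallest titrant volume bringing the medium to ``target_ph``.

    The titrant must be a single strong acid or strong base; the pH response
    to its volume is then monotone, and the volume is found by bisection.
    Raises :class:`TitrationDirectionError` when the target lies on the wrong
    side of the current pH for the titrant's direction.
    """
    t_species = [n for n, c in titrant.totals.items() if c > 0]
    if len(t_species) != 1 or titrant.registry[t_species[0]].type not in (
        "strong_acid",
        "strong_base",
    ):
        raise ValueError("titrant must contain exactly one strong acid or strong base")
    is_base = titrant.registry[t_species[0]].type == "strong_base"

    ph0 = compute_ph(medium, mode).ph
    if abs(ph0 - target_ph) <= ph_tol:
        return 0.0
    if (target_ph > ph0) != is_base:
        direction = "base" if is_base else "acid"
        raise TitrationDirectionError(
            f"target pH {target_ph} is unreachable from pH {ph0:.3f} with a strong {direction}"
        )

    def ph_at(v: float) -> float:
        return compute_ph(mix([medium, _aliquot(titrant, v)]), mode).ph

    # expand to bracket the target
    hi = 1e-3
    while (ph_at(hi) < target_ph) == is_base:
        hi *= 2.0
        if hi > max_volume_l:
            raise InfeasibleMediumError(
                f"target pH {target_ph} not reached within {max_volume_l} L of titrant"
            )
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        ph_mid = ph_at(mid)
        if abs(ph_mid - target_ph) <= ph_tol and (hi - lo) <= max(1e-9, 1e-6 * hi):
            return mid
        if (ph_mid < target_ph) == is_base:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
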