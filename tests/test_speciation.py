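"""Charge-balance pH solver: closed forms, brute-force oracle, invariants."""

import math

import numpy as np
import pytest

from gastropk.speciation import (
    InfeasibleMediumError,
    MediumComposition,
    SpeciesDef,
    TitrationDirectionError,
    compute_ph,
    default_registry,
    mix,
    titrant_volume_for_target_ph,
)

REG = default_registry()

PKA = (2.148, 7.198, 12.35)
KW = 1e-14


def medium(volume, **totals):
    return MediumComposition(volume_l=volume, totals=totals, registry=REG)


# ---------------------------------------------------------------------------
# independent brute-force oracle: grid scan + bisection on the charge balance
# ---------------------------------------------------------------------------


def _oracle_gamma(z, ionic):
    if z == 0 or ionic <= 0:
        return 1.0
    s = math.sqrt(ionic)
    return 10.0 ** (-0.509 * z * z * (s / (1.0 + s) - 0.3 * ionic))


def _oracle_residual_and_ionic(ph, totals, ionic, davies):
    g1 = _oracle_gamma(1, ionic) if davies else 1.0
    a_h = 10.0**-ph
    h = a_h / g1 if davies else a_h
    oh = KW / a_h / g1 if davies else KW / a_h
    residual = h - oh
    ionic_sum = h + oh
    na = totals.get("NaOH", 0.0) + 3 * totals.get("Na3PO4", 0.0)
    na += 2 * totals.get("Na2HPO4", 0.0) + totals.get("NaH2PO4", 0.0)
    cl = totals.get("HCl", 0.0)
    residual += na - cl
    ionic_sum += na + cl
    p_total = (
        totals.get("Na3PO4", 0.0)
        + totals.get("Na2HPO4", 0.0)
        + totals.get("NaH2PO4", 0.0)
    )
    if p_total > 0:
        # explicit cumulative-product speciation of H3PO4
        terms = [1.0]
        for j, pka in enumerate(PKA, start=1):
            g_prev = _oracle_gamma(-(j - 1), ionic) if davies else 1.0
            g_next = _oracle_gamma(-j, ionic) if davies else 1.0
            terms.append(terms[-1] * 10.0**-pka * g_prev / (a_h * g_next))
        denom = sum(terms)
        for j, term in enumerate(terms):
            c = p_total * term / denom
            residual += -j * c
            ionic_sum += j * j * c
    return residual, 0.5 * ionic_sum


def oracle_ph(totals, davies):
    """Grid scan at 0.01 pH then bisection, with fixed-point ionic strength."""
    ionic = 0.0
    ph = None
    for _ in range(60):
        grid = np.arange(0.0, 14.0, 0.01)
        res = [_oracle_residual_and_ionic(p, totals, ionic, davies)[0] for p in grid]
        idx = next(i for i in range(len(res) - 1) if res[i] * res[i + 1] <= 0)
        lo, hi = grid[idx], grid[idx + 1]
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if (
                _oracle_residual_and_ionic(lo, totals, ionic, davies)[0]
                * _oracle_residual_and_ionic(mid, totals, ionic, davies)[0]
                <= 0
            ):
                hi = mid
            else:
                lo = mid
        ph_new = 0.5 * (lo + hi)
        _, ionic_new = _oracle_residual_and_ionic(ph_new, totals, ionic, davies)
        if not davies or (ph is not None and abs(ph_new - ph) < 1e-10):
            ph = ph_new
            break
        ph, ionic = ph_new, ionic_new
    return ph


# ---------------------------------------------------------------------------
# closed forms and printed protocol values
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("c", [1e-4, 1e-3, 1e-2, 0.1, 1.0])
def test_strong_acid_ideal_ph_is_minus_log10_c(c):
    """Strong-acid pH follows the closed form including water autoionization.

    [H+] = (c + sqrt(c^2 + 4 Kw))/2; the nominal -log10(c) is exact to about
    4e-7 pH at the dilute end of the range and machine-exact above 1e-2 M.
    """
    ph = compute_ph(medium(1.0, HCl=c), "ideal").ph
    exact = -math.log10((c + math.sqrt(c * c + 4e-14)) / 2.0)
    assert ph == pytest.approx(exact, abs=1e-9)
    assert ph == pytest.approx(-math.log10(c), abs=1e-6)


def test_pure_water_is_neutral():
    assert compute_ph(medium(1.0), "ideal").ph == pytest.approx(7.0, abs=1e-9)


def test_acid_stage_nominal_ph():
    assert compute_ph(medium(0.75, HCl=0.1), "ideal").ph == pytest.approx(1.0, abs=1e-9)


def test_buffer_stage_ph_davies_is_6_8():
    """Mixing the acid stage with tribasic phosphate gives pH 6.8.

    Ideal chemistry puts the equimolar H2PO4-/HPO4-2 buffer at pKa2 = 7.198;
    the Davies correction at the mixture's ionic strength (~0.18 mol/L)
    lowers it to about 6.8, the value the two-stage protocol targets.
    """
    post_mix = mix([medium(0.750, HCl=0.1), medium(0.250, Na3PO4=0.2)])
    ideal = compute_ph(post_mix, "ideal")
    davies = compute_ph(post_mix, "davies")
    assert ideal.ph == pytest.approx(7.198, abs=0.01)
    assert davies.ph == pytest.approx(6.8, abs=0.1)
    assert 0.1 < davies.ionic_strength < 0.3


# ---------------------------------------------------------------------------
# mixing
# ---------------------------------------------------------------------------


def test_mix_usp_stage_transition_dilution():
    m = mix([medium(0.750, HCl=0.1), medium(0.250, Na3PO4=0.2)])
    assert m.volume_l == pytest.approx(1.000)
    assert m.totals["HCl"] == pytest.approx(0.075)
    assert m.totals["Na3PO4"] == pytest.approx(0.050)


def test_mix_single_medium_is_identity():
    m = medium(0.5, HCl=0.01, NaOH=0.002)
    out = mix([m])
    assert out.volume_l == m.volume_l
    assert out.totals == pytest.approx(m.totals)


def test_mix_equal_aliquots_doubles_volume_keeps_concentrations():
    m = medium(0.3, Na3PO4=0.05)
    out = mix([m, m])
    assert out.volume_l == pytest.approx(0.6)
    assert out.totals["Na3PO4"] == pytest.approx(0.05)


def test_mix_conserves_moles():
    a, b = medium(0.2, HCl=0.3), medium(0.7, HCl=0.01, NaOH=0.1)
    out = mix([a, b])
    for name in ("HCl", "NaOH"):
        assert out.moles(name) == pytest.approx(a.moles(name) + b.moles(name), rel=1e-14)


def test_mix_empty_list_rejected():
    with pytest.raises(ValueError):
        mix([])


# ---------------------------------------------------------------------------
# solver invariants and oracle equivalence
# ---------------------------------------------------------------------------


def _random_media(n, seed=20):
    rng = np.random.default_rng(seed)
    media = []
    for _ in range(n):
        totals = {}
        for name in ("HCl", "NaOH", "Na3PO4"):
            if rng.random() < 0.7:
                totals[name] = 10.0 ** rng.uniform(-4, -0.7)
        media.append(totals)
    return media


@pytest.mark.parametrize("mode", ["ideal", "davies"])
def test_solver_matches_bruteforce_oracle(mode):
    """100 randomized media agree with grid-scan+bisection within 1e-6 pH."""
    for totals in _random_media(100):
        got = compute_ph(medium(1.0, **totals), mode).ph
        want = oracle_ph(totals, davies=(mode == "davies"))
        assert got == pytest.approx(want, abs=1e-6), totals


@pytest.mark.parametrize("mode", ["ideal", "davies"])
def test_charge_balance_residual_below_1e_10(mode):
    for totals in _random_media(30, seed=21):
        res = compute_ph(medium(1.0, **totals), mode)
        assert abs(res.charge_balance_residual) <= 1e-10


def test_phosphate_forms_sum_to_total():
    res = compute_ph(medium(1.0, Na3PO4=0.05, HCl=0.075), "davies")
    forms = ("H3PO4", "H2PO4-", "HPO4-2", "PO4-3")
    assert sum(res.speciation[f] for f in forms) == pytest.approx(0.05, rel=1e-8)


def test_davies_and_ideal_agree_in_dilute_limit():
    for totals in _random_media(20, seed=22):
        dilute = {k: min(v, 1e-4) for k, v in totals.items()}
        ideal = compute_ph(medium(1.0, **dilute), "ideal").ph
        davies = compute_ph(medium(1.0, **dilute), "davies").ph
        assert abs(ideal - davies) <= 0.02


def test_infeasible_medium_raises():
    with pytest.raises(InfeasibleMediumError):
        compute_ph(medium(1.0, HCl=20.0), "ideal")


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------


def test_titrant_volume_zero_when_already_at_target():
    m = medium(0.5, HCl=0.001)
    ph0 = compute_ph(m, "ideal").ph
    titrant = medium(1.0, NaOH=2.0)
    assert titrant_volume_for_target_ph(m, titrant, ph0, "ideal") == 0.0


def test_titrant_volume_matches_microliter_scan():
    """Bisection agrees with an independent 1 uL brute-force scan."""
    m = medium(0.5, HCl=0.001)
    titrant = medium(1.0, NaOH=2.0)
    v = titrant_volume_for_target_ph(m, titrant, 7.0, "ideal")
    scan = np.arange(0.0, 5e-4, 1e-6)
    errs = [
        abs(compute_ph(medium(0.5 + s, HCl=0.0005 / (0.5 + s), NaOH=2.0 * s / (0.5 + s)), "ideal").ph - 7.0)
        for s in scan
    ]
    v_scan = scan[int(np.argmin(errs))]
    assert v == pytest.approx(v_scan, abs=2e-6)
    # and the target is actually met
    final = mix([m, MediumComposition(v, {"NaOH": 2.0}, registry=REG)])
    assert compute_ph(final, "ideal").ph == pytest.approx(7.0, abs=0.01)


def test_titrant_volume_monotone_in_target():
    m = medium(0.5, HCl=0.001)
    titrant = medium(1.0, NaOH=2.0)
    vols = [
        titrant_volume_for_target_ph(m, titrant, ph, "ideal", ph_tol=1e-4)
        for ph in (5.0, 6.0, 7.0, 8.0)
    ]
    assert all(b > a for a, b in zip(vols, vols[1:]))


def test_titrant_wrong_direction_raises():
    m = medium(0.5, HCl=0.001)
    with pytest.raises(TitrationDirectionError):
        titrant_volume_for_target_ph(m, medium(1.0, HCl=2.0), 7.0, "ideal")


# ---------------------------------------------------------------------------
# species registry validation
# ---------------------------------------------------------------------------


def test_species_pka_must_increase():
    with pytest.raises(ValueError):
        SpeciesDef(name="bad", type="polyprotic_acid_salt", pka=(7.0, 2.0))


def test_strong_species_reject_pka():
    with pytest.raises(ValueError):
        SpeciesDef(name="bad", type="strong_acid", pka=(3.0,))


def test_mode_must_be_explicit():
    with pytest.raises(ValueError):
        compute_ph(medium(1.0, HCl=0.01), "auto")
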