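# Methods

This note records the model equations, assumptions, parameter meanings,
numerical choices and limitations behind `gastropk`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Medium chemistry

A dissolution medium is a volume plus total analytical concentrations of
registry species: strong acids (HCl), strong bases (NaOH), and salts of one
polyprotic buffer family (phosphoric acid as Na₃PO₄ / Na₂HPO₄ / NaH₂PO₄).
Equilibrium pH is the root of the charge balance

  [H⁺] − [OH⁻] + Σ z_counterion·C_total + Σ_j z_j·[form_j] = 0

with water autoionization (Kw = 10⁻¹⁴) in every balance and phosphate
speciation from the stepwise constants pKa = 2.148, 7.198, 12.35 (standard
25 °C values, stored in the auditable registry `data/species.yaml`;
temperature is carried on media but not used in the equilibria).

Two modes are exposed because protocol pH labels are not all on one
convention: the acid stage of the two-stage enteric test is quoted as
pH 1.0, the ideal value for 0.1 M HCl, while its buffer stage is quoted as
6.8, which an ideal calculation cannot produce (the equimolar
H₂PO₄⁻/HPO₄²⁻ mixture sits at pKa₂ = 7.198). In *davies* mode every
charged form gets log₁₀γ_z = −A z²(√I/(1+√I) − 0.3 I) with A = 0.509, the
ionic strength is solved by fixed-point iteration (tolerance 10⁻¹², max 80
iterations), and pH = −log₁₀ a_H. At the buffer stage's I ≈ 0.18 mol/L the
correction lowers the pH from 7.198 to ≈ 6.83 — inside the compendial
6.8 ± 0.1. Protocol presets pin the mode per stage.

Numerics: the H⁺ root is bracketed on (10⁻¹⁴, 10) mol/L, solved by Brent's
method on log₁₀[H⁺] (a bracketed bisection-class method) and polished with
two Newton steps; returned speciations close the charge balance to
≤ 10⁻¹⁰ mol/L (observed ~10⁻¹⁴). Titration volumes are found by bisection
on the monotone pH(v) map with a doubling bracket search; the default
target tolerance is 0.01 pH.

The Davies form is empirical and credible to I ≈ 0.5 mol/L; media beyond
that, CO₂ uptake, and ionic-strength-dependent solubility are out of scope.

## 2. Release kinetics

Cumulative release is fitted in mass units (mg), not fraction, with the
labelled drug content carried separately, so the PBPK mass balances stay in
one unit system. The primary form is the Weibull curve
M(t) = M∞(1 − exp(−((t−t_lag)/τ)^β)): it nests first-order release (β = 1)
and fits the sigmoid profiles of coated/extended-release tablets. A capped
zero-order ramp (constant rate M∞/τ until exhaustion) covers constant-rate
systems. The lag time exists for coated forms but defaults to 0 and is only
freed on request.

Fitting is nonlinear least squares (scipy `least_squares`, bounds
M∞ ∈ (0, 1.2·dose], τ > 0, β ∈ (0.2, 5]) from five deterministic starts
around an empirical time scale (first time to half the observed plateau);
the best residual sum of squares wins, and AICc
(n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)) drives model selection with ties going
to fewer parameters. There is no randomness anywhere in fitting. Degenerate
inputs — all-zero profiles, or cumulative drops larger than the 5%
noise allowance — raise a fit error rather than returning a vacuous model.

Rates are analytic derivatives (for β < 1 the rate has an integrable
singularity at t_lag⁺, evaluated safely); tests verify by quadrature that
the rate integrates back to the cumulative within 10⁻⁶ relative.

## 3. The compartment model

Seven perfectly mixed compartments (continuous-stirred-reactor assumption):
stomach lumen, small-intestine (SI) lumen, large-intestine (LI) lumen,
gastrointestinal circulatory system (gi.c.s — the splanchnic blood draining
the gut wall), liver, plasma (blood plus well-perfused organs), and a
lumped poorly perfused tissues pool. All membrane transport is passive
diffusion: flux = PA·(C_donor − C_acceptor) with PA a permeability–area
product (L/h).

The flux laws, per compartment (amounts in mg, C = amount/volume):

* lumen chain: release source r(t) into the lumen hosting the dosage form;
  first-order transit k_gastric, k_si_transit, k_li_transit down the chain;
  LI transit exits to a cumulative fecal sink; PA_stomach/PA_si/PA_li
  exchange with gi.c.s.
* circulation: plasma → gi.c.s at Q_gics·C_plasma; gi.c.s → liver (portal)
  at Q_portal·C_gics; liver → plasma at Q_hepatic_out·C_liver. Flow balance
  Q_gics = Q_portal = Q_hepatic_out is enforced at construction so the
  gi.c.s and liver volumes stay constant. This portal-only topology is the
  physiological splanchnic route; a direct gi.c.s ↔ plasma shunt is a
  deliberate non-feature.
* disposition: tissue exchange Q_tissues·(C_plasma − C_tissues/F) where the
  partition/binding lumping factor F sets the equilibrium ratio
  C_tissues = F·C_plasma; hepatic metabolic sink CL_hepatic·C_liver (this
  placement produces the oral first-pass effect mechanistically); renal
  sink CL_renal·C_plasma. Either clearance may be zero.

The parameterization has exactly 22 scalars: 4 distribution volumes, 3
lumen volumes, 4 flows, 3 transit constants, 3 permeability–area products,
2 clearances, 1 partition factor, and 2 dosage-form residence times. The
intact dosage form — the release source — moves by *timed windows* rather
than first-order transit: gastric emptying at t_form_gastric (default 2 h,
matching the enteric protocol's acid-stage duration), SI exit after
t_form_si (default 3 h), LI exit after a configurable residence (default
24 h, kept as a function argument). Dissolved drug always moves by the
first-order constants; only the monolithic form obeys the windows. This
dual representation reflects that a tablet is a discrete object while
dissolved drug is well mixed.

Dosing: IV bolus (initial condition on plasma), IV infusion (constant rate
over a window, with the undelivered remainder tracked), oral (release-model
driven). For oral doses the mobile mass is the release model's M∞ ≤ dose;
any unreleasable remainder never enters the body and is excluded from the
balance.

Numerics: stiff-capable LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰ mg; integration is
split at every derivative discontinuity (dose start, window switches,
infusion end) so the solver never steps across a kink. The augmented state
(7 compartments + reservoir + 3 cumulative sinks) has an identically zero
derivative sum, making global mass conservation the primary correctness
surface; trajectories close the balance to ~10⁻¹⁵ relative in practice
(asserted at 10⁻⁶ in tests). Units are fixed: mg, L, h, mg/L.

Out of scope by design: enterohepatic recirculation, saturable metabolism,
active transporters, inter-individual variability distributions.

## 4. Calibration and prediction (IVIVC)

`calibrate()` minimizes Σ w_i(C_model(t_i) − C_obs(t_i))² with relative
weights w_i = 1/max(C_obs,i, floor)², floor = 1% of observed Cmax — plasma
curves span roughly an order of magnitude, so unweighted least squares
would fit only the peak. The free set is an explicit input; the default
four (PA_si, CL_hepatic, Q_tissues, F_unbound_factor) are the
absorption/disposition parameters least constrained by prior physiology.
Freeing any splanchnic flow moves all three together (they are one
constrained group). Parameters are optimized in log space under bounds
(default: a factor of 10 either side of the template).

Multi-start is deterministic: 5 log-spaced values per free dimension, the
factorial grid strided down to at most 32 start points; every start is
scored with one simulation, and bounded local least-squares runs from the
3 best. Guards: more free parameters than observations is an
identifiability error; fewer than 5 samples is rejected.

`predict()` enforces the no-refitting contract: the calibrated physiology
is fingerprinted (SHA-256 of its 22 values) at calibration time and any
mutation before prediction raises an error.

NCA follows standard practice: Cmax/Tmax from the discrete maximum;
AUC(0–last) by linear-up/log-down trapezoid (a plain linear mode exists and
is the one that is additive across curves); λ_z by log-linear regression on
the ≥3 positive descending points after Tmax; AUC(0–∞) = AUC(0–last) +
C_last/λ_z, refused (flagged, AUC_inf = NaN) when the extrapolated tail
exceeds 20% of the total or no descending phase exists.

The ±15% Cmax/AUC acceptance band used in tests mirrors common Level-A
IVIVC practice; it is a configurable convention of this package, not a
measured constant.

## 5. Dissolution protocols

*Two-stage enteric test*: 2 h in 750 mL 0.1 M HCl (pH reported on the
ideal/nominal scale: 1.0), then 250 mL of 0.2 M Na₃PO₄ is mixed in
(volumes add; moles conserve exactly) and the buffer stage runs at the
Davies-mode pH (≈6.83). Release accrues per stage through the same
release-schedule objects used everywhere else, so the stage chemistry and
the speciation solver share one code path.

*pH-programmed test*: the vessel starts as 500 mL of buffer at pH 4.8.
The composition of that starting buffer is not specified by the protocol
literature; this package's stand-in — 0.05 M NaH₂PO₄ trimmed with strong
titrant to Davies-mode pH 4.80 — is an explicit assumption, and the
fed-stomach program itself (4.8 drifting to ~2.2 over 2 h, then rising to
6.8 in 30 min) is a synthetic, parameterized fixture emulating published
in-vivo profiles that exist only as figures.

The controller is a discrete PI law on the pH error at a 30 s interval,
with one non-standard but necessary ingredient: the control signal (in pH
units) is converted to titrant moles through an online estimate of the
vessel's buffer capacity (mol/pH), learned from each interval's
dose/response and exponentially smoothed (bounds 2·10⁻⁵–0.5 mol/pH).
Phosphate media have ~100-fold less buffer capacity near pH 4.5–5 than near
the pKa's; a fixed mol/pH gain oscillates in the weak region or lags in the
strong one, while the capacity-scheduled gain (kp = 0.7 of the error closed
per interval, ki = 0.5 h⁻¹, anti-windup while the 3 mL/interval pump limit
saturates) tracks the whole program. Acid and base are never dosed in the
same interval; a run saturated for more than half its intervals is flagged
unreachable. Defaults were tuned on the 4.8 → 6.8 step-response and are
stored in `PIControllerConfig`.

pH-gated release (`PHGatedRelease`) idealizes an enteric coat as a clock
that only runs above a threshold pH. It reproduces the qualitative failure
mode of interest — zero release in the pH-1.0 acid stage, early leakage
under a fed-stomach program whose gastric phase sits above the gate — but
it is not a mechanistic coating model (no dissolution/erosion kinetics of
the polymer itself, no partial opening).

## 6. Synthetic studies

The generator emulates the study design the workflow needs: three
formulations of one 100 mg drug differing only in release rate (Weibull,
β = 1.4, τ = 1.5/3/6 h — time-to-50% strictly ordered fast < medium <
slow), dissolution sampled at 12 points to 16 h, plasma at 16 points to
24 h, and multiplicative log-normal noise (σ = 0.05 by default) applied
per point; dissolution curves are then clipped to 1.05·M∞ and made
non-decreasing by cumulative maximum, as reported cumulative data are.

The ground-truth physiology is a round adult parameterization: 12 L
plasma+well-perfused volume, 30 L tissue pool (F = 8 — extensive tissue
partitioning), splanchnic flow 60 L/h, SI permeability–area 4 L/h,
CL_hepatic 40 L/h (high extraction, strong first pass, as for
calcium-channel blockers), CL_renal 2 L/h. These values are a plausible
synthetic subject, not any real drug's published parameters.

All randomness flows from one mandatory integer seed through per-purpose
child streams, so datasets are bit-reproducible. What passing tests show is
therefore internal consistency — the workflow recovers parameters and
predicts formulations *under the model's own assumptions plus realistic
noise* — not agreement with any real subject; real data add model error,
inter-occasion variability and sparser sampling that the generator does not
emulate.

## 7. Problem sizes and determinism

The test suite and acceptance script run at desk scale by choice: pH oracle
comparisons over 100 randomized media, 50-profile fit-recovery benchmarks,
one 4-parameter calibration (≈35 screened starts + 3 local fits, a few
hundred ODE solves) shared across tests via a session fixture, and
controller runs of ≤10 simulated hours at 30 s resolution. Every stochastic
step is seeded; `scripts/acceptance.py --seed N` drives the synthetic study
from N and computes the reported chemistry values deterministically.
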