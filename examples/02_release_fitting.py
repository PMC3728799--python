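"""Fitting parametric release models to noisy dissolution data.

Generates the synthetic fast/medium/slow dissolution triplet (100 mg
tablets, 5% multiplicative noise), fits a Weibull model to each profile,
and compares candidate functional forms by AICc.  The fitted tau (time
scale) should recover the generating values 1.5 / 3 / 6 h; the smooth
fitted curve is what the PBPK model consumes as its oral input.
"""

from gastropk import default_study, fit_release, generate_dissolution, select_model

study = default_study(seed=7)
profiles = generate_dissolution(study)

print("label   true_tau  fitted_tau  fitted_beta  AICc")
for label in ("fast", "medium", "slow"):
    truth = study.release_triplet[label]
    fit = fit_release(profiles[label], "weibull")
    print(
        f"{label:<7} {truth.tau:7.2f} {fit.tau:10.2f} {fit.beta:11.2f} {fit.aicc:7.1f}"
    )

chosen = select_model(profiles["medium"], ["weibull", "first_order", "zero_order_capped"])
print(f"\nbest form for 'medium' by AICc: {chosen.form}")
print(f"released at t = tau: {chosen.cumulative(chosen.tau):.1f} mg "
      f"(Weibull puts 63.2% of M_inf at tau when beta gives no lag)")
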