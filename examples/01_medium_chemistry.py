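"""Chemistry of the two-stage enteric dissolution test.

Builds the acid-stage medium (750 mL of 0.1 M HCl), mixes in the buffer
concentrate (250 mL of 0.2 M tribasic sodium phosphate), and solves the
charge balance for the pH of both stages.  The ideal/Davies contrast
matters: the acid-stage label "pH 1.0" is a nominal (ideal) value, while
the buffer stage only reaches its 6.8 target once activity coefficients at
the mixture's ionic strength (~0.18 mol/L) are accounted for.
"""

from gastropk import MediumComposition, compute_ph, default_registry, mix, titrant_volume_for_target_ph

reg = default_registry()

acid_stage = MediumComposition(volume_l=0.750, totals={"HCl": 0.1}, registry=reg)
print(f"acid stage  (ideal):  pH = {compute_ph(acid_stage, 'ideal').ph:.3f}")

concentrate = MediumComposition(volume_l=0.250, totals={"Na3PO4": 0.2}, registry=reg)
buffer_stage = mix([acid_stage, concentrate])
ideal = compute_ph(buffer_stage, "ideal")
davies = compute_ph(buffer_stage, "davies")
print(f"buffer stage (ideal):  pH = {ideal.ph:.3f}   <- equimolar H2PO4-/HPO4-2, i.e. pKa2")
print(f"buffer stage (Davies): pH = {davies.ph:.3f}   at I = {davies.ionic_strength:.3f} mol/L")
print(f"charge-balance residual: {davies.charge_balance_residual:.2e} mol/L")

# How much 2 M NaOH would a pump need to push a dilute acid to neutrality?
dilute = MediumComposition(volume_l=0.5, totals={"HCl": 0.001}, registry=reg)
naoh = MediumComposition(volume_l=1.0, totals={"NaOH": 2.0}, registry=reg)
v = titrant_volume_for_target_ph(dilute, naoh, target_ph=7.0, mode="ideal")
print(f"2 M NaOH to bring 0.5 L of 1 mM HCl to pH 7: {v * 1e6:.0f} uL")
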