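# Default species registry for dissolution-medium chemistry.
#
# pKa values are standard 25 degC thermodynamic constants (phosphoric acid:
# 2.148, 7.198, 12.35).  `counterion_charge` is the total charge contributed
# by the spectator counterions of one formula unit (e.g. 3 Na+ for tribasic
# sodium phosphate); for a strong acid it is the charge of the fully
# dissociated conjugate base itself (Cl- for HCl).
species:
  HCl:
    type: strong_acid
    pKa: []
    charge_fully_protonated: 0
    counterion_charge: -1
  NaOH:
    type: strong_base
    pKa: []
    charge_fully_protonated: 0
    counterion_charge: 1
  Na3PO4:
    type: polyprotic_acid_salt
    pKa: [2.148, 7.198, 12.35]
    charge_fully_protonated: 0
    counterion_charge: 3
    form_names: [H3PO4, H2PO4-, HPO4-2, PO4-3]
  Na2HPO4:
    type: polyprotic_acid_salt
    pKa: [2.148, 7.198, 12.35]
    charge_fully_protonated: 0
    counterion_charge: 2
    form_names: [H3PO4, H2PO4-, HPO4-2, PO4-3]
  NaH2PO4:
    type: polyprotic_acid_salt
    pKa: [2.148, 7.198, 12.35]
    charge_fully_protonated: 0
    counterion_charge: 1
    form_names: [H3PO4, H2PO4-, HPO4-2, PO4-3]
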