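"""Supporting assay calculations: uptake, transport efficiency, metabolite
fractions, and delta-Ct knockdown.

All four are small deterministic conversions used when validating screen
hits mechanistically (e.g. why one nucleoside analog outperforms another).
"""

import screenkit as sk

# radiotracer uptake: DPM -> pmol per mg protein via specific activity
assay = sk.TracerAssay(dpm=33300, specific_activity=15.0, protein=1.0,
                       exposure_time=5.0, concentration=1.0)
uptake = sk.protein_normalized_uptake(assay)
print(f"uptake: {uptake:.2f} pmol/mg (33300 DPM at 15 Ci/mmol in 1 mg protein)")

# clearance-style transport efficiency falls as the dose escalates
rate = lambda conc_um: 100.0 * conc_um / (5.0 + conc_um)  # saturable carrier
for conc in (1.0, 10.0, 100.0):
    eff = sk.transport_efficiency(rate(conc) / 5.0, conc)  # rate per 5 min window
    print(f"  at {conc:>5.0f} uM: efficiency = {eff:6.2f} uL/min/mg")
print("falling efficiency: dose escalation cannot rescue poor transport")

# HPLC metabolite fractionation: the triphosphate dominates accumulation
panel = sk.MetabolitePanel(("parent", "mono-P", "di-P", "tri-P"),
                           (10.0, 5.0, 5.0, 80.0))
fractions = sk.metabolite_fractions(panel)
print(f"triphosphate fraction of intracellular drug: {fractions['tri-P']:.0%}")

# delta-Ct: a ddCt of 1.12 cycles is a 54% knockdown
out = sk.delta_ct_expression(ct_target=21.12, ct_reference=20.0, calibrator_delta=0.0)
print(f"siRNA knockdown: {out['knockdown_pct']:.0f}% "
      f"(fold change {out['fold_change']:.2f} vs control)")
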