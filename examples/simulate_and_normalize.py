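"""Simulate a small viability screen and score it against plate controls.

Builds a two-cell-line plate set for one compound with known 4PL truth,
log10-normalizes the luminescence, anchors each well to its plate's DMSO
(negative) and cycloheximide (positive) controls, and prints the per-plate
Z'-factor plus median percent inhibition at each tested dose.
"""

import screenkit as sk

truth = sk.GroundTruthCompound(
    "example_drug",
    {
        "CHRF288-11": (-1.2, 100.0, 0.0, 5e-8),  # potent: EC50 50 nM
        "U937": (-1.2, 100.0, 0.0, 2e-6),        # weaker: EC50 2 uM
    },
)
config = sk.SimulationConfig(noise_sigma=0.05, seed=1)
design = sk.DoseDesign.ten_point(replicates=3)

plate_table, _ = sk.simulate_plate_set([truth], config, design)
scored = sk.normalize_plates(plate_table)

for plate_id, plate in plate_table.groupby("plate_id"):
    qc = sk.plate_qc(plate)
    print(f"{plate_id}: Z' = {qc.z_prime:.3f} ({'PASS' if qc.passed else 'FAIL'})")

samples = scored[scored.role == "sample"]
summary = samples.pivot_table(index="concentration_M", columns="cell_line",
                              values="pct_inhibition", aggfunc="median")
print("\nmedian % inhibition by dose (0 = DMSO control, 100 = full kill):")
print(summary.round(1).to_string())
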