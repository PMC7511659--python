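"""Quantify ddPCR droplet counts and derive a limit of quantification.

Converts positive-droplet counts to copies per microgram of input RNA via
the Poisson occupancy estimator, normalizes to the ACT2 reference, then
calibrates an LoQ from a simulated dilution series.
"""

import pandas as pd

import circquant as cq

# one target measured in three biological replicates, ~20,000 droplets each
assays = pd.DataFrame(
    {
        "target": ["5:1106879-1107381"] * 3,
        "organ": ["leaf"] * 3,
        "replicate": [1, 2, 3],
        "n_pos": [1813, 1650, 1930],
        "n_total": [20000, 19500, 20400],
    }
)
quant = cq.quantify_droplets(assays)
print(quant[["replicate", "n_pos", "lambda_", "cp_per_ug"]].round(4))
# lambda is copies per droplet; cp_per_ug scales it by droplet volume,
# reaction volume and the RNA mass one reaction represents (defaults:
# 0.85 nL, 20 uL, 0.05 ug).

marker = pd.DataFrame(
    {
        "target": cq.MARKER_GENE_ID,
        "organ": "leaf",
        "replicate": [1, 1, 1, 1],
        "technical_rep": [1, 2, 3, 4],
        "cp_per_ug": [21000.0, 20000.0, 19500.0, 20500.0],
    }
)
rel = cq.marker_normalize(quant[quant.replicate == 1], marker)
print("\nrelative to ACT2:", rel["rel_to_marker"].round(4).tolist())

# LoQ from a simulated dilution panel (10..300 cp/ug, 8 replicates each):
panel = cq.simulate_dilution_panel(cq.SimConfig(seed=0))
q = cq.quantify_droplets(panel)
loq = cq.loq_from_replicates(q[["target", "organ", "replicate", "cp_per_ug"]])
print(f"\nLoQ: {loq.threshold_cp_per_ug:g} cp/ug  ({loq.rule})")
# Below this concentration replicate scatter reaches the mean (CV >= 1),
# so single measurements are not quantitative.
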