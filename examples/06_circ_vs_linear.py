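"""Compare circular and linear transcript accumulation.

Simulates circRNA truth plus linear-counterpart abundances with a target
raw-scale correlation of 0.46, then measures the correlation and flags
circles enriched at least 1.5-fold over their host transcript.
"""

import circquant as cq

cfg = cq.SimConfig(seed=0, n_circ_total=2600, fraction_reproducible=0.05,
                   planted_per_organ=0)
truth = cq.generate_truth(cfg)
linear = cq.simulate_linear(truth)
mapping = {c: g for c, g in truth.parent_gene.items() if g is not None}

subset = truth.true_cp.iloc[:127]  # an analysis-set-sized cohort
res = cq.circ_linear_analysis(subset, linear, mapping)
print(f"overall Pearson r (circ vs linear): {res.r_overall:.2f}")
print("per organ:", {o: round(r, 2) for o, r in res.r_per_organ.items()})
# A weak overall correlation means circle abundance is not a simple
# consequence of host-gene expression.

enriched = res.pairs[res.pairs["enriched"]]
print(f"\n{len(enriched)} circRNAs at >=1.5x their linear counterpart "
      f"in at least one sample type; {res.n_excluded} had no detected "
      f"linear partner (intergenic or silent host).")
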