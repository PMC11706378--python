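"""Robustness sweep over a World Bank-style governance indicator.

The same sliding-cutoff procedure runs on the -2.5..2.5 governance scale
(step 0.1 by default; a coarser grid here for speed). In the synthetic
panel governance is income-linked, as are the composite scores, so
governance cutoffs partition countries similarly to score cutoffs.
"""

from ghsdid import SweepGrid, SyntheticTruth, generate_panel, sweep_governance

truth = SyntheticTruth(seed=1)
panel, _ = generate_panel(truth)
gov = panel.attributes.set_index("iso3")["gov_effectiveness"]

result = sweep_governance(panel, gov, grid=SweepGrid(-1.5, 1.5, 0.25),
                          score_id="gov_effectiveness")
frame = result.to_frame()
cols = ["cutoff", "gate_status", "n_treated", "avg_est", "avg_lo", "avg_hi", "pretrend_p"]
print(frame[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"\nminimum qualifying governance cutoff: {result.min_qualifying_cutoff}")
print("\nGovernance proxies the same underlying capacity, so a protective effect"
      "\nappears once the cutoff isolates the high-capacity countries.")
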