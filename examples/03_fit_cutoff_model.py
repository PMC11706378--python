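"""Fit the doubly-robust event-study DiD at a single score cutoff.

Assigns treatment at score >= 57, fits yearly post-period ATTs (base year
2019), placebo pre-period ATTs (rolling one-year base), the pooled
2020-2022 effect, and the joint parallel pre-trend test, then renders the
results the way the field's tables report them: estimate (95% CI) with an
asterisk when the interval excludes zero.
"""

from ghsdid import (
    SyntheticTruth,
    assign_treatment,
    estimate_did,
    generate_panel,
    percentile_of_cutoff,
    render_tables,
)

truth = SyntheticTruth(seed=1)
panel, hierarchy = generate_panel(truth)
scores = hierarchy.score("overall")

cutoff = 57.0
assignment = assign_treatment(scores, cutoff)
fit = estimate_did(panel, assignment)

_, pct = percentile_of_cutoff(scores, cutoff)
_, text = render_tables({"overall": fit}, cutoffs={"overall": (cutoff, pct)})
print(text)
print("Planted effects were (0.74, 1.23, 0.76); each yearly ATT estimates one of"
      "\nthem in percentage points of coverage, and the average row is their mean."
      f"\nParallel pre-trend p = {fit.pretrend_p:.2f} (>= 0.05 supports the design).")
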