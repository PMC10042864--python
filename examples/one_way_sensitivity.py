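"""One-way sensitivity analyses and the referral threshold.

Replays the published one-way battery: each row sweeps one model quantity
across its range (strategy-shared quantities move in lockstep for both
strategies) and reports either the dominant strategy or the parameter
value where the AI/ECP preference flips.
"""

from carevl import base_case, one_way_sa
from carevl.analysis import TABLE2_ROWS

params = base_case()

print(f"{'analysis':55s} {'range':12s} result")
for row in TABLE2_ROWS:
    res = one_way_sa(row.param_names, 101, params,
                     value_range=(row.low, row.high))
    if res.dominant:
        verdict = f"{res.dominant} dominates"
    else:
        verdict = "threshold at " + ", ".join(f"{t:.2f}" for t in res.thresholds)
    print(f"{row.label:55s} ({row.low:g}, {row.high:g})   {verdict}")

print("\nA threshold means the preferred (lowest-vision-loss) strategy "
      "switches at that parameter value; 'ai dominates' means AI is "
      "preferred across the entire swept range.")
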