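"""Compare water-transfer policies against the suitable-depth baseline.

Runs the full management catalogue — raising or lowering the water depth by
0.1/0.3/0.5/0.8 m over spring, summer, fall or the whole season — and prints
the worst percent loss of each carbon stock per scenario.
"""

from reedcarbon import seasonal_catalogue

results, summary = seasonal_catalogue()

whole = summary[(summary["window"] == "whole") & (summary["direction"] == "raise")]
print("whole-season raises (loss grows with the offset):")
print(
    whole[["offset_m", "max_loss_pac_pct", "max_loss_pbc_pct"]]
    .sort_values("offset_m")
    .to_string(index=False)
)

spring = next(r for r in results if r.name == "spring_raise_0.5m")
fall = next(r for r in results if r.name == "fall_raise_0.5m")
print(
    f"\nspring +0.5 m: worst aboveground change {spring.min_pct_pac:.1f}%, "
    f"end-of-season {spring.daily['pct_pac'].iloc[-1]:.2f}% (recovers)"
)
print(
    f"fall   +0.5 m: worst aboveground change {fall.min_pct_pac:.1f}%, "
    f"end-of-season {fall.daily['pct_pac'].iloc[-1]:.2f}% (does not recover)"
)
# max_loss_*_pct is the most negative daily percent change vs the baseline
# run at the suitable growth depth; spring interventions are forgiven once
# the depth returns to optimum, fall interventions are not.
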