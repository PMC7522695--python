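"""One-way sensitivity: where does the cost-effectiveness decision flip?

Sweeps the one-time gene-testing cost and the exon 9 prevalence, printing
the ICER grid and the break-even value found by bisection on the net
monetary benefit at the $100,000/QALY willingness-to-pay threshold.
"""

import warnings

from gistcea import default_parameters, generate_fixture_trials, one_way

warnings.simplefilter("ignore")
params = default_parameters(emit_warnings=False)
curves = generate_fixture_trials(seed=17)

grid = one_way("cost_tgt", 0.0, 10_000.0, 6, params, curves)
print("ICER vs one-time testing cost:")
for v, icer in zip(grid.values, grid.icers):
    print(f"  ${v:>8,.0f} -> {'cost-saving' if icer != icer else f'${icer:,.0f}/QALY'}")
print(f"testing stays cost-effective up to ${grid.threshold:,.0f}\n")

grid = one_way("prevalence_exon9", 0.02, 0.40, 6, params, curves)
print("ICER vs exon 9 prevalence (exon 11/other renormalised):")
for v, icer in zip(grid.values, grid.icers):
    label = "cost-saving" if icer != icer else f"${icer:,.0f}/QALY"
    print(f"  {100 * v:>5.1f}% -> {label}")
print(f"testing stays cost-effective above a prevalence of "
      f"{100 * grid.threshold:.1f}%")
# Below that prevalence too few patients benefit from tailored dosing to
# repay the universal testing cost.
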