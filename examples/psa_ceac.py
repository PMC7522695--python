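"""Probabilistic sensitivity analysis and acceptability curve.

Jointly samples all uncertain costs (gamma), adverse-event probabilities and
utilities (beta) plus per-curve hazard multipliers, re-runs the cohort model
10,000 times, and reports the probability that gene-test-directed dosing is
cost-effective across willingness-to-pay thresholds.
"""

import warnings

import numpy as np

from gistcea import default_parameters, generate_fixture_trials, psa, sd_fraction_sweep

warnings.simplefilter("ignore")
params = default_parameters(emit_warnings=False)
curves = generate_fixture_trials(seed=17)

res = psa(params, curves, n_iter=10_000, seed=1)
print(f"P(cost-effective at ${res.wtp:,.0f}/QALY) = {100 * res.ce_probability:.1f}%")
print(f"mean incremental cost ${res.delta_cost.mean():,.0f}, "
      f"mean incremental QALYs {res.delta_qaly.mean():.4f}")

print("\nCost-effectiveness acceptability curve (selected thresholds):")
for wtp in [25_000, 50_000, 100_000, 150_000, 200_000]:
    i = int(np.searchsorted(res.ceac_wtp, wtp))
    print(f"  WTP ${wtp:>7,} -> {100 * res.ceac_probability[i]:>5.1f}%")

print("\nSensitivity of the PSA to the assumed SD fraction:")
print(sd_fraction_sweep([0.1, 0.2, 0.4], params, curves,
                        n_iter=2000, seed=2).to_string(index=False))
# A stable CE probability across SD assumptions indicates the decision is not
# an artefact of the 20%-of-mean spread convention.
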