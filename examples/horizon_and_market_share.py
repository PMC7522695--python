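"""Horizon and imatinib market-share scenario analyses.

The incremental cost of gene-directed dosing is front-loaded while the QALY
gain accrues over time, so the ICER falls as the horizon lengthens.  The
imatinib price enters through a brand/generic market-share mix; the two
extremes bracket the base case.
"""

import warnings

from gistcea import default_parameters, generate_fixture_trials
from gistcea.sensitivity import horizon_sweep, market_share_scenario, scenario_parameters

warnings.simplefilter("ignore")
params = default_parameters(emit_warnings=False)
curves = generate_fixture_trials(seed=17)

print("ICER by model horizon:")
for _, row in horizon_sweep([3, 5, 10, 15], params, curves).iterrows():
    print(f"  {int(row['horizon_years']):>2} years "
          f"({int(row['n_cycles'])} cycles) -> ${row['icer']:>10,.0f}/QALY")

print("\nImatinib market-share scenarios:")
for share, label in [(0.0, "all brand-name"), (0.5, "base 50/50 mix"),
                     (1.0, "all generic")]:
    b = market_share_scenario(share, params, curves)
    cost_400 = scenario_parameters(share, params).cost_imatinib400_year.mean
    print(f"  {label:<15} imatinib 400 mg ${cost_400:>7,.0f}/yr"
          f"  ICER ${b.icer:>9,.0f}/QALY ({b.decision})")
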