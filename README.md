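# gistcea

A Markov cohort cost-effectiveness model for **genotype-directed first-line
imatinib dosing in metastatic gastrointestinal stromal tumor (GIST)**, built
for health-economics and biostatistics users who want a tested, scriptable
replication of the decision problem rather than a point-and-click model.

## The question

Metastatic GIST is usually driven by *KIT* variants. Tumors with *KIT*
exon 11 variants respond well to standard 400 mg imatinib, but the 10–15% of
patients with *KIT* exon 9 variants need 800 mg for comparable
progression-free survival (PFS); overall survival (OS) is equivalent across
doses. A one-time targeted gene test (TGT) before first-line therapy lets
exon 9 carriers start on the high dose. Is paying for universal testing
worth the QALYs it buys?

## The model

Two strategies are propagated as deterministic cohorts over a 10-year
horizon in 2-month cycles (60 cycles), from a US payer perspective in 2019
dollars:

* **Empirical** — all genotypes: imatinib 400 mg → imatinib 800 mg →
  sunitinib → best supportive care (BSC) → dead.
* **TGT** — every patient pays the one-time test; exon 9 carriers skip
  straight to 800 mg (800 mg → sunitinib → BSC → dead), all others follow
  the empirical sequence.

Per-cycle transition probabilities come from survival curves via
`p_i = 1 − S(t_{i+1})/S(t_i)`, with progression separated from death by
rate subtraction (`r_prog = max(0, r_PFS − r_OS)` under constant hazards
within a cycle). Each treatment line runs on its own PFS clock
(time-in-state); death follows model time on the genotype's first-line OS
schedule, switched after month 36 to a constant long-term monthly death
probability. Costs and utilities (0.935 metastatic, −0.12 per progression,
0.577 in BSC) accrue on beginning-of-cycle occupancy, discounted at 3%/year.
The decision quantity is the incremental cost-effectiveness ratio
ICER = ΔC/ΔQ against a $100,000/QALY willingness-to-pay, with all decision
logic routed through net monetary benefit (NMB = WTP·Q − C).

The published trial curves behind the original analysis were digitized from
two randomized trials and are not public, so `gistcea.survival` generates
**synthetic trial curves** (seeded, exponential by default) that encode the
trials' qualitative structure — exon 9 does better on 800 mg for PFS, OS is
dose-equivalent — and the package accepts real digitized point series in
their place. Numbers below are therefore properties of the packaged
synthetic study conditions, not the published estimates.

## Configuration

Ledgers load from YAML/JSON/mappings via `load_parameters`; a document may
set `use_defaults: true` and override only the fields it names. Each
uncertain entry is a mapping `{mean, ci_low, ci_high, distribution,
sd_override, sd_rule}`. `dump_parameters(default_parameters())` emits the
full packaged base-case ledger as YAML to inspect or edit.

## Worked example

```python
from gistcea import base_case, default_parameters, generate_fixture_trials

params = default_parameters()          # the published cost/utility ledger
curves = generate_fixture_trials(seed=17)
bundle = base_case(params, curves)
print(bundle.delta_cost, bundle.delta_qaly, bundle.icer)
```

Running `python examples/base_case.py` prints:

```
Empirical imatinib : cost $   343,980   QALYs 3.744
TGT-directed       : cost $   345,421   QALYs 3.771
Incremental        : cost $     1,441   QALYs 0.0262
ICER               : $54,973 per QALY (cost-effective at $100,000/QALY)
```

Testing costs $2,919 per patient but buys 0.026 QALYs on average (all of it
in the exon 9 subgroup, which avoids early progression on an inadequate
dose), so the strategy is cost-effective under these study conditions. The
other scripts in `examples/` walk through the survival fixtures, one-way
break-even searches, horizon and market-share scenarios, and the
probabilistic sensitivity analysis with its acceptability curve.

## Layout

| Module | Contents |
|---|---|
| `gistcea.config` | parameter ledger (`ModelParameters`), validation, YAML/JSON/CSV I/O |
| `gistcea.survival` | survival curves, rate↔probability conversion, decomposition, long-term extension, synthetic trial generator, parametric fitting |
| `gistcea.markov` | strategy arms, cohort propagation, cost/QALY accrual, base case |
| `gistcea.economics` | ICER, NMB, dominance classification, WTP decisions |
| `gistcea.sensitivity` | one-way grids with bisection thresholds, horizon and market-share scenarios, method-of-moments distributions, PSA + CEAC |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
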