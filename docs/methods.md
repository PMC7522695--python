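# Methods

This note documents the model implemented in `gistcea`: its structure and
assumptions, the parameter ledger, what the synthetic survival generator
does and does not emulate, the numerical choices, and the limitations a
user should keep in mind before trusting any number it prints.

## Decision problem and state space

The model compares two first-line strategies for metastatic GIST from a US
payer perspective: empirical imatinib 400 mg for everyone, versus a
one-time targeted gene test (TGT) with *KIT* exon 9 carriers started
directly on imatinib 800 mg. Three genomic subpopulations are modelled —
*KIT* exon 11, *KIT* exon 9, and "other" — with base prevalences 0.67,
0.15 and 0.18. The exon 9 base prevalence is back-derived from the
published sensitivity statement that the break-even prevalence (11.7%) sits
3.3 percentage points below the base case; all three shares are
config-exposed.

Each strategy × genotype pathway is a chain of health states:

    LINE1 → LINE2 → (LINE3 →) BSC → DEAD

where each active line carries a drug (empirical sequence
400 mg → 800 mg → sunitinib for all genotypes; TGT/exon 9 sequence
800 mg → sunitinib), BSC is best supportive care with no drug, and DEAD is
absorbing. Dose escalation and the transition into BSC both count as
progression events: they incur the one-time progression cost (during the
first three model years) and, for escalation between active lines, the
0.12 utility decrement. BSC uses its own absolute utility (0.577) rather
than a subtraction.

Cycles are 2 months (the standard reassessment interval); the base horizon
is 10 years (60 cycles). The cohort starts entirely in LINE1.

## Transition probabilities

Survival inputs are point series S(t) per genotype × drug × endpoint (PFS,
OS), interpolated piecewise-linearly on the survival scale. Per-cycle event
probabilities are conditional: `p_i = 1 − S(t_{i+1})/S(t_i)`.

PFS events include deaths, so progression-only probabilities are obtained
by rate subtraction under a constant-hazard-within-cycle assumption:
convert both schedules to monthly rates (`r = −ln(1−p)/T`), take
`r_prog = max(0, r_PFS − r_OS)`, convert back. Cycles where the OS hazard
exceeds the PFS hazard (possible with noisy digitized inputs) are clamped
to zero progression with a warning.

Two clocks coexist: **progression uses time-in-state** (a second-line PFS
curve is measured from second-line start in its source trial), while
**death uses model time** on the genotype's *first-line* drug's OS
schedule, for every state including BSC. The decomposition aligns each
drug's PFS schedule with the death schedule by cycle index; this mixes the
two clocks for later lines and is an acknowledged approximation — the
exact joint distribution is unidentifiable from marginal KM curves anyway.

From month 36 the death schedule switches to a constant per-cycle
probability derived from a constant monthly death probability
(`rate_to_prob(prob_to_rate(p_month), cycle_months)`), emulating
registry-style conditional mortality once trial follow-up runs out. The
registry value behind the original analysis is not public; the packaged
default (0.012/month) is a synthetic fixture value, config-exposed as
`longterm_monthly_death_prob`. The extension applies to OS only; PFS
curves carry their own tails.

## Synthetic trial curves

`generate_fixture_trials(seed)` produces the survival inputs the original
analysis digitized from two trials (first-line imatinib by genotype and
dose; second-line sunitinib). Defaults are exponential with per-month
hazards set from the source trials' published medians (λ = ln2/median):

| curve | λ/month | ~median (mo) |
|---|---|---|
| PFS exon 11, im400 / im800 | 0.028 / 0.030 | 25 / 23 |
| PFS exon 9, im400 / im800 | 0.115 / 0.053 | 6 / 13 |
| PFS other, im400 / im800 | 0.058 / 0.058 | 12 |
| PFS sunitinib, exon 11 / exon 9 / other | 0.135 / 0.036 / 0.115 | 5 / 19 / 6 |
| OS exon 11 / exon 9 / other (both imatinib doses) | 0.0115 / 0.0231 / 0.0173 | 60 / 30 / 40 |

A validator enforces the qualitative ordering these must encode: exon 9
progresses more slowly on 800 mg than 400 mg; exon 11 on 400 mg has the
lowest first-line progression hazard; OS is identical across imatinib
doses within a genotype. Optional seeded noise perturbs log-survival
(multiplicative on S, keeping S > 0 so log-scale fitting stays well posed),
after which the series is re-monotonized with a running minimum.

What the fixtures do **not** emulate: digitization step artefacts,
censoring-driven tail instability, non-proportional or non-constant
hazards, crossover between dose arms, and any correlation between PFS and
OS errors. Tests passing on these fixtures therefore certify the engine's
arithmetic and the pipeline's behaviour under clean inputs — not the
published trial-derived estimates. On these fixtures the base-case ICER is
≈ $55,000/QALY, not the published $92,100; the package accepts real
digitized 2-column CSV curves wherever fixtures are used.

One fixture-structural consequence worth flagging: here the empirical
exon 9 pathway accrues *more* imatinib spend than the TGT pathway, so the
decision never flips with the imatinib price (there is no imatinib-cost
break-even, and cheaper generic imatinib *raises* the ICER slightly). With
the published curves the direction was the opposite. Both are internally
consistent; which one obtains depends on how long each arm survives on
each drug.

## Costs, utilities and accrual

The ledger reproduces the published table: annual costs for imatinib
400 mg ($57,690, a 50/50 brand/generic weighted mean), 800 mg (exactly
2×), sunitinib ($86,726), BSC ($9,403) and drug-class "other medical"
costs; one-time costs for the test ($2,919), adverse events ($296
imatinib / $160 sunitinib) and progression ($46,548, first 3 years only);
monthly adverse-event probabilities (0.033 / 0.065 / 0.031); utilities
0.935 (metastatic), −0.12 per progression, 0.577 (BSC), 0 (dead). Both
published adverse-event cost means sit outside their own printed CIs; they
are loaded verbatim and flagged with a warning rather than repaired —
`sd_override` exists for users who want a coherent spread.

The brand/generic split is not printed in the source; defaults are
symmetric in ratio about the mean (generic 2/3×, brand 4/3×), satisfy the
weighted-mean constraint exactly, and are config-exposed. Market-share
scenarios recompute the 400 mg cost from these two prices and keep
800 mg = 2×.

Accrual is on beginning-of-cycle occupancy with discounting at cycle start
(`(1.03)^(−t_years)`) and **no half-cycle correction** — the common
default of the modelling software this replicates; switching would be a
localized change in `accrue`. Per cycle: drug + other-medical + BSC costs
proportional to occupancy and time; expected adverse-event cost
(occupancy × per-cycle AE probability × one-time AE cost — cost only, no
disutility, no discontinuation); progression cost on the cycle's
progression flow inside the 36-month window; the test cost once at cycle 0
for every TGT patient, including those whose management is unchanged.
QALYs weight occupancy by line utility (0.935 − k·0.12 for the k-th line,
clamped at 0 with a warning), 0.577 in BSC, scaled by cycle length.

The ICER is computed from unrounded totals. On the published *rounded*
totals (469,106/4.88 vs 478,619/4.98) the increments are $9,513 and 0.10
but the ratio is $95,130 — the published $92,100 used unrounded internals;
the test suite pins this distinction.

## Sensitivity machinery

**One-way grids** re-run the deterministic model over a parameter grid and
locate the decision flip by bisection on the NMB difference (tolerance $1).
When the varied parameter does not touch transition schedules (all costs,
utilities, AE probabilities, prevalences), cohort traces are computed once
and reused — exact, since such parameters enter only the accrual step.
Linked parameters keep the grid meaningful: the 400 mg imatinib cost drags
the 800 mg cost (2×) and both prices proportionally; exon 9 prevalence
renormalises the other two shares proportionally; exon 11 prevalence
trades only against "other" (so it provably cannot move the ICER — both
genotypes are managed identically under both strategies).

**Horizon sweeps** truncate/extend the run (each horizon must be a whole
number of cycles; fixture curves cover 180 months, enough for 15 years).

**PSA.** Each iteration draws every uncertain ledger entry: costs from
gamma, adverse-event probabilities and utilities from beta (the decrement
is sampled as a beta on its magnitude, sign reapplied), parameterized by
method of moments. SDs are 20% of the mean for costs and utilities
(config: `sd_fraction`) and CI-derived (width/3.92) for the event
probabilities, overridable per entry. Survival-curve uncertainty — for
which the source gives no distributional form — is induced by one
2×Beta(mean 1, SD = `sd_fraction`) multiplier per curve applied to its
per-cycle probabilities and clamped to [0, 1]; it is switchable off
(`hazard_uncertainty=False`). All sampling families have bounded support,
so the resample-on-infeasible path is a safeguard rather than a working
branch; an infeasible beta SD (possible at `sd_fraction` = 0.4 for the
0.935 utility) is capped at 99% of the feasibility limit with a warning,
while `moment_match` itself raises. The cohort propagation is vectorized
across iterations (identical arithmetic to the single-run path, which a
zero-spread degeneracy test enforces), making 10,000 iterations a
seconds-scale computation; the desk default is 10,000 iterations
(CE-probability SE < 0.5%), with any count available by argument. The
CEAC is evaluated on a $0–200,000 grid in $1,000 steps.

## Numerical choices and degenerate inputs

* `p = 1` has no finite rate → explicit error; negative rates rejected.
* A curve reaching S = 0 at a cycle boundary with later cycles still
  demanded raises a degenerate-denominator error.
* Schedules are validated so progression + death cannot exceed 1 in any
  cycle (conservatively, max + max); violations raise rather than silently
  losing mass. Row sums of every trace are conserved to 1e-9 by
  construction and asserted in tests.
* Exponential fitting is least squares of −ln S on t through the origin;
  Weibull fits ln(−ln S) on ln t. Flat curves yield rate 0 with a warning.
* Thresholds: bisection stops at |ΔNMB| ≤ $1 or a relative interval of
  1e-9; a dense-grid cross-check in the test suite agrees within one
  10,000-point grid step.
* All randomness flows through `numpy.random.default_rng(seed)` with a
  fixed draw order, so fixture generation and PSA runs are bit-reproducible.

## Problem sizes used in the shipped analyses

Deterministic analyses run the full 60-cycle horizon (90 cycles at
15 years). The packaged acceptance run uses 10,000 PSA iterations per
scenario and 31-point one-way grids with bisection refinement; the
parameter-recovery suite uses 20 seeds at 5% log-survival noise. These are
the package's desk-scale defaults; every size is an argument.

## Limitations

* Cohort (not individual) simulation: no treatment discontinuation, dose
  reduction, or regorafenib third-line option, matching the scope of the
  source analysis.
* The two-clock structure (per-state PFS, model-time OS) cannot represent
  survival benefits that depend on the sequence actually received.
* BSC retains the model-time death schedule; in reality post-progression
  mortality is higher. BSC carries no drug-era "other medical" costs and
  no adverse events.
* Synthetic curves are exponential by default; real digitized curves with
  strongly non-constant hazards will exercise the interpolation and
  decomposition differently (the machinery accepts them; the defaults do
  not emulate them).
* Costs are 2019 USD by contract; no inflation adjustment or currency
  conversion is performed.
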