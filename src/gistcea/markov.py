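"""Cohort state-transition engine.

Two strategies are compared over a 10-year horizon in 2-month cycles:

* **EMPIRICAL** — every genotype starts 400 mg imatinib, escalates to 800 mg
  at first progression, switches to sunitinib at the second, and moves to
  best supportive care (BSC) at the third.
* **TGT** — a one-time gene test is charged for every patient; *KIT* exon 9
  carriers start 800 mg imatinib directly (sequence 800 mg → sunitinib →
  BSC), all other genotypes follow the empirical sequence.

Each treatment line keeps its own progression clock (time-in-state indexes
that drug's PFS schedule, as second-line trial curves are measured from
second-line start), while death follows model time on the genotype's
first-line OS schedule.  DEAD is absorbing; BSC transitions only to DEAD.

Costs and QALYs accrue on beginning-of-cycle occupancy with discounting at
cycle start and no half-cycle correction.  Dose escalation and the move into
BSC each count as progression events (utility decrement, and the one-time
progression cost during the first three model years).  Adverse events carry
cost but no disutility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import economics
from .config import ModelParameters, ResultBundle, config_hash
from .survival import (
    SurvivalCurve,
    decompose_pfs,
    extend_longterm,
    km_to_cycle_probs,
    prob_to_rate,
    rate_to_prob,
)

__all__ = [
    "STRATEGIES",
    "EMPIRICAL_SEQUENCE",
    "LineState",
    "StrategyArm",
    "CohortTrace",
    "ArmAccrual",
    "StrategyResult",
    "ScheduleError",
    "treatment_sequence",
    "build_arm",
    "run_cohort",
    "accrue",
    "line_utilities",
    "simulate_strategy",
    "cohorts",
    "evaluate_strategies",
    "base_case",
]

STRATEGIES = ("EMPIRICAL", "TGT")
EMPIRICAL_SEQUENCE = ("imatinib400", "imatinib800", "sunitinib")

#: months after model start during which the progression cost applies
PROGRESSION_COST_WINDOW_MONTHS = 36.0

_DRUG_FAMILY = {"imatinib400": "imatinib", "imatinib800": "imatinib",
                "sunitinib": "sunitinib"}
_AE_PROB_FIELD = {"imatinib400": "p_ae_imatinib400_month",
                  "imatinib800": "p_ae_imatinib800_month",
                  "sunitinib": "p_ae_sunitinib_month"}
_DRUG_COST_FIELD = {"imatinib400": "cost_imatinib400_year",
                    "imatinib800": "cost_imatinib800_year",
                    "sunitinib": "cost_sunitinib_year"}


class ScheduleError(ValueError):
    """Per-cycle probabilities are jointly invalid (p_prog + p_death > 1)."""


@dataclass(frozen=True)
class LineState:
    """An active treatment line; ``index`` is the number of progressions a
    patient has experienced on entering it."""

    index: int
    drug: str


@dataclass
class StrategyArm:
    """One strategy × genotype pathway with its transition schedules.

    ``p_prog[j, a]`` is the progression probability for line ``j`` in its
    ``a``-th cycle *in state* (per-state clock); ``p_death[i]`` is the death
    probability in model cycle ``i`` (first-line OS schedule with long-term
    extension).  ``p_ae_cycle[j]`` is the base-case per-cycle adverse-event
    probability for line ``j``'s drug.
    """

    strategy: str
    genotype: str
    lines: tuple[LineState, ...]
    tgt_cost_applies: bool
    p_prog: np.ndarray
    p_death: np.ndarray
    p_ae_cycle: np.ndarray
    cycle_months: float

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_cycles(self) -> int:
        return self.p_death.shape[-1]

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(f"LINE{st.index + 1}({st.drug})" for st in self.lines) + ("BSC", "DEAD")


def treatment_sequence(strategy: str, genotype: str) -> tuple[str, ...]:
    """Ordered drug sequence for one strategy × genotype."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "TGT" and genotype == "exon9":
        return ("imatinib800", "sunitinib")
    return EMPIRICAL_SEQUENCE


def build_arm(
    strategy: str,
    genotype: str,
    params: ModelParameters,
    curves: Mapping[tuple[str, str, str], SurvivalCurve],
    n_cycles: int | None = None,
) -> StrategyArm:
    """Assemble an arm's per-cycle transition schedules from survival curves.

    Progression probabilities come from each line drug's PFS curve with the
    death hazard subtracted (rate decomposition); death probabilities come
    from the first-line drug's OS curve, switched to the constant long-term
    monthly death probability from month 36.
    """
    from .config import ConfigurationError

    seq = treatment_sequence(strategy, genotype)
    cm = params.cycle_length_months
    if n_cycles is None:
        n_cycles = params.n_cycles

    def _curve(drug: str, endpoint: str) -> SurvivalCurve:
        key = (genotype, drug, endpoint)
        if key not in curves:
            raise ConfigurationError(f"no survival curve supplied for {key}")
        return curves[key]

    os_probs = km_to_cycle_probs(_curve(seq[0], "OS"), cm, n_cycles)
    p_death = extend_longterm(os_probs, params.longterm_monthly_death_prob, cm)

    p_prog = np.empty((len(seq), n_cycles))
    for j, drug in enumerate(seq):
        pfs = km_to_cycle_probs(_curve(drug, "PFS"), cm, n_cycles)
        p_prog[j], _ = decompose_pfs(pfs, p_death, cm)

    p_ae_cycle = np.array([
        rate_to_prob(prob_to_rate(getattr(params, _AE_PROB_FIELD[d]).mean, 1.0), cm)
        for d in seq
    ])
    arm = StrategyArm(
        strategy=strategy,
        genotype=genotype,
        lines=tuple(LineState(j, d) for j, d in enumerate(seq)),
        tgt_cost_applies=(strategy == "TGT"),
        p_prog=p_prog,
        p_death=p_death,
        p_ae_cycle=p_ae_cycle,
        cycle_months=cm,
    )
    _check_joint(arm.p_prog, arm.p_death)
    return arm


def _check_joint(p_prog: np.ndarray, p_death: np.ndarray) -> None:
    worst = float(np.max(p_prog)) + float(np.max(p_death))
    if worst > 1.0 + 1e-12:
        raise ScheduleError(
            f"progression + death probability can reach {worst:.4f} > 1 in a cycle"
        )


# ----------------------------------------------------------------------
def _propagate(p_prog: np.ndarray, p_death: np.ndarray, n_cycles: int):
    """Forward cohort propagation; supports leading batch axes.

    ``p_prog``: (..., L, n_cycles) age-indexed; ``p_death``: (..., n_cycles)
    model-time indexed.  Returns per-cycle line occupancies, BSC and DEAD
    occupancies (at cycle starts 0..n), and progression / death flows during
    each cycle.  Within a cycle, death and progression compete directly via
    the jointly adjusted probabilities.
    """
    L = p_prog.shape[-2]
    batch = np.broadcast_shapes(p_prog.shape[:-2], p_death.shape[:-1])
    pp = np.broadcast_to(p_prog, batch + (L, n_cycles))
    pdth = np.broadcast_to(p_death, batch + (n_cycles,))
    _check_joint(pp, pdth)

    n_ages = n_cycles + 1
    # occupancy by (line, time-in-state); whole cohort starts line 1, age 0
    A = np.zeros(batch + (L, n_ages))
    A[..., 0, 0] = 1.0
    bsc = np.zeros(batch)
    dead = np.zeros(batch)

    occ_line = np.zeros(batch + (n_cycles + 1, L))
    occ_bsc = np.zeros(batch + (n_cycles + 1,))
    occ_dead = np.zeros(batch + (n_cycles + 1,))
    prog_flow = np.zeros(batch + (n_cycles,))
    death_flow = np.zeros(batch + (n_cycles,))
    occ_line[..., 0, :] = A.sum(axis=-1)

    pp_pad = np.concatenate([pp, np.zeros(batch + (L, 1))], axis=-1)
    for i in range(n_cycles):
        pdi = pdth[..., i][..., None, None]
        die = A * pdi
        flow = A * pp_pad
        stay = A - die - flow

        new_A = np.zeros_like(A)
        new_A[..., :, 1:] = stay[..., :, :-1]
        line_flow = flow.sum(axis=-1)           # (..., L)
        new_A[..., 1:, 0] += line_flow[..., :-1]
        to_bsc = line_flow[..., -1]

        bsc_die = bsc * pdth[..., i]
        dead = dead + die.sum(axis=(-1, -2)) + bsc_die
        bsc = bsc - bsc_die + to_bsc
        A = new_A

        occ_line[..., i + 1, :] = A.sum(axis=-1)
        occ_bsc[..., i + 1] = bsc
        occ_dead[..., i + 1] = dead
        prog_flow[..., i] = line_flow.sum(axis=-1)
        death_flow[..., i] = die.sum(axis=(-1, -2)) + bsc_die
    return occ_line, occ_bsc, occ_dead, prog_flow, death_flow


@dataclass
class CohortTrace:
    """Cycle-indexed state occupancy and event flows for one arm."""

    arm: StrategyArm
    occupancy: np.ndarray        # (n_cycles+1, L+2): lines…, BSC, DEAD
    prog_flow: np.ndarray        # (n_cycles,) progression transitions in cycle i
    death_flow: np.ndarray       # (n_cycles,)
    ae_expectation: np.ndarray   # (n_cycles,) expected AE events (base-case p_ae)

    @property
    def n_cycles(self) -> int:
        return len(self.prog_flow)

    @property
    def state_labels(self) -> tuple[str, ...]:
        return self.arm.state_labels

    def row_sums(self) -> np.ndarray:
        return self.occupancy.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.state_labels))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        for name, arr in (("progression_flow", self.prog_flow),
                          ("death_flow", self.death_flow),
                          ("ae_expectation", self.ae_expectation)):
            df[name] = np.concatenate([arr, [np.nan]])
        return df


def run_cohort(arm: StrategyArm, n_cycles: int | None = None) -> CohortTrace:
    """Deterministic forward propagation of the cohort occupancy vector."""
    if n_cycles is None:
        n_cycles = arm.n_cycles
    if n_cycles > arm.n_cycles:
        raise ScheduleError(
            f"arm schedules cover {arm.n_cycles} cycles; asked for {n_cycles}"
        )
    occ_line, occ_bsc, occ_dead, prog_flow, death_flow = _propagate(
        arm.p_prog[:, :n_cycles], arm.p_death[:n_cycles], n_cycles
    )
    occupancy = np.column_stack([occ_line, occ_bsc, occ_dead])
    ae = occ_line[:n_cycles] @ arm.p_ae_cycle
    return CohortTrace(arm=arm, occupancy=occupancy, prog_flow=prog_flow,
                       death_flow=death_flow, ae_expectation=ae)


# ----------------------------------------------------------------------
# accrual
# ----------------------------------------------------------------------
def line_utilities(arm: StrategyArm, params: ModelParameters,
                   u_metastatic=None, u_decrement=None):
    """Per-line health utilities: metastatic utility minus one decrement per
    progression already experienced, clamped at 0.  Accepts scalar or
    array-valued overrides (used by the PSA)."""
    u_met = params.utility_metastatic.mean if u_metastatic is None else u_metastatic
    u_dec = params.utility_progression_decrement.mean if u_decrement is None else u_decrement
    out = []
    clamped = False
    for st in arm.lines:
        u = np.asarray(u_met + st.index * u_dec)
        if np.any(u < 0):
            clamped = True
        out.append(np.maximum(u, 0.0))
    if clamped:
        warnings.warn("negative line utility clamped at 0", stacklevel=2)
    return out


def _line_cost_rates(arm: StrategyArm, params: ModelParameters,
                     overrides: Mapping[str, np.ndarray] | None = None):
    """Per-line cost per unit occupancy per cycle (drug + other-medical +
    expected adverse-event cost).  ``overrides`` may replace any ledger mean
    with per-iteration arrays (PSA)."""
    ov = overrides or {}

    def val(name: str):
        if name in ov:
            return ov[name]
        return getattr(params, name).mean

    cm = arm.cycle_months
    per_cycle = cm / 12.0
    rates = []
    for st in arm.lines:
        fam = _DRUG_FAMILY[st.drug]
        drug_cost = val(_DRUG_COST_FIELD[st.drug])
        other = val(f"cost_other_medical_{fam}_year")
        c_ae = val(f"cost_ae_{fam}")
        p_ae_month = val(_AE_PROB_FIELD[st.drug])
        p_ae_cycle = -np.expm1(np.log1p(-np.asarray(p_ae_month)) * cm)
        rates.append((drug_cost + other) * per_cycle + p_ae_cycle * c_ae)
    return rates


def discount_factors(params: ModelParameters, n_cycles: int) -> np.ndarray:
    """Discount factor at each cycle start, ``(1+r)^(−t_years)``."""
    t_years = np.arange(n_cycles) * params.cycle_length_months / 12.0
    return (1.0 + params.discount_rate_annual) ** (-t_years)


@dataclass
class ArmAccrual:
    """Discounted totals and the per-cycle ledger for one arm."""

    cost_total: float
    qaly_total: float
    cost_total_undiscounted: float
    qaly_total_undiscounted: float
    ledger: pd.DataFrame | None


def accrue(trace: CohortTrace, arm: StrategyArm, params: ModelParameters,
           ledger: bool = True) -> ArmAccrual:
    """Accrue discounted costs and QALYs on beginning-of-cycle occupancy.

    Per cycle: drug / other-medical / BSC costs proportional to occupancy;
    expected adverse-event cost; the one-time progression cost on this
    cycle's progression flow while the cycle starts inside the first three
    model years; the one-time gene-testing cost at cycle 0 for TGT arms.
    QALYs weight occupancy by per-line utilities, the BSC utility, and 0 for
    DEAD, scaled to years per cycle.
    """
    n = trace.n_cycles
    cm = arm.cycle_months
    L = arm.n_lines
    occ_line = trace.occupancy[:n, :L]
    occ_bsc = trace.occupancy[:n, L]
    df = discount_factors(params, n)
    starts_months = np.arange(n) * cm

    rates = _line_cost_rates(arm, params)
    cost_drug_om_ae = occ_line @ np.asarray(rates)
    cost_bsc = occ_bsc * params.cost_bsc_year.mean * cm / 12.0
    in_window = starts_months < PROGRESSION_COST_WINDOW_MONTHS - 1e-9
    cost_prog = trace.prog_flow * params.cost_progression.mean * in_window
    cost_tgt = np.zeros(n)
    if arm.tgt_cost_applies:
        cost_tgt[0] = params.cost_tgt.mean
    cost_cycle = cost_drug_om_ae + cost_bsc + cost_prog + cost_tgt

    utils = np.asarray(line_utilities(arm, params), dtype=float)
    qaly_cycle = (occ_line @ utils + occ_bsc * params.utility_bsc) * cm / 12.0

    ledger_df = None
    if ledger:
        ledger_df = pd.DataFrame({
            "cycle": np.arange(n),
            "time_years": starts_months / 12.0,
            "discount_factor": df,
            "cost_drug_om_ae": cost_drug_om_ae,
            "cost_bsc": cost_bsc,
            "cost_progression": cost_prog,
            "cost_tgt": cost_tgt,
            "cost_undiscounted": cost_cycle,
            "cost_discounted": cost_cycle * df,
            "qaly_undiscounted": qaly_cycle,
            "qaly_discounted": qaly_cycle * df,
        })
    return ArmAccrual(
        cost_total=float(cost_cycle @ df),
        qaly_total=float(qaly_cycle @ df),
        cost_total_undiscounted=float(cost_cycle.sum()),
        qaly_total_undiscounted=float(qaly_cycle.sum()),
        ledger=ledger_df,
    )


# ----------------------------------------------------------------------
@dataclass
class GenotypeResult:
    genotype: str
    arm: StrategyArm
    trace: CohortTrace
    accrual: ArmAccrual

    @property
    def cost(self) -> float:
        return self.accrual.cost_total

    @property
    def qaly(self) -> float:
        return self.accrual.qaly_total


@dataclass
class StrategyResult:
    """Prevalence-weighted discounted totals with per-genotype breakdown."""

    strategy: str
    cost: float
    qaly: float
    per_genotype: dict[str, GenotypeResult]


def cohorts(
    params: ModelParameters,
    curves: Mapping[tuple[str, str, str], SurvivalCurve],
    n_cycles: int | None = None,
) -> dict[tuple[str, str], tuple[StrategyArm, CohortTrace]]:
    """Build and run every strategy × genotype arm once.

    TGT arms for genotypes whose sequence matches the empirical one reuse
    the empirical cohort trace (the pathways are state-for-state identical;
    only the one-time testing cost differs).
    """
    from .survival import GENOTYPES

    out: dict[tuple[str, str], tuple[StrategyArm, CohortTrace]] = {}
    for genotype in GENOTYPES:
        arm_e = build_arm("EMPIRICAL", genotype, params, curves, n_cycles)
        trace_e = run_cohort(arm_e)
        out[("EMPIRICAL", genotype)] = (arm_e, trace_e)
        arm_t = build_arm("TGT", genotype, params, curves, n_cycles)
        if treatment_sequence("TGT", genotype) == treatment_sequence("EMPIRICAL", genotype):
            trace_t = CohortTrace(arm=arm_t, occupancy=trace_e.occupancy,
                                  prog_flow=trace_e.prog_flow,
                                  death_flow=trace_e.death_flow,
                                  ae_expectation=trace_e.ae_expectation)
        else:
            trace_t = run_cohort(arm_t)
        out[("TGT", genotype)] = (arm_t, trace_t)
    return out


def _strategy_result(strategy: str, params: ModelParameters, cohort_map) -> StrategyResult:
    from .survival import GENOTYPES

    prev = {"exon9": params.prevalence_exon9, "exon11": params.prevalence_exon11,
            "other": params.prevalence_other}
    per: dict[str, GenotypeResult] = {}
    cost = 0.0
    qaly = 0.0
    for genotype in GENOTYPES:
        arm, trace = cohort_map[(strategy, genotype)]
        acc = accrue(trace, arm, params, ledger=False)
        per[genotype] = GenotypeResult(genotype, arm, trace, acc)
        cost += prev[genotype] * acc.cost_total
        qaly += prev[genotype] * acc.qaly_total
    return StrategyResult(strategy=strategy, cost=cost, qaly=qaly, per_genotype=per)


def simulate_strategy(
    strategy: str,
    params: ModelParameters,
    curves: Mapping[tuple[str, str, str], SurvivalCurve],
    n_cycles: int | None = None,
    cohort_map=None,
) -> StrategyResult:
    """Run the three genotype arms of one strategy and weight by prevalence."""
    if cohort_map is None:
        cohort_map = cohorts(params, curves, n_cycles)
    return _strategy_result(strategy, params, cohort_map)


def evaluate_strategies(
    params: ModelParameters,
    curves: Mapping[tuple[str, str, str], SurvivalCurve],
    n_cycles: int | None = None,
    cohort_map=None,
) -> tuple[StrategyResult, StrategyResult]:
    """Both strategies on shared cohort runs: (EMPIRICAL, TGT)."""
    if cohort_map is None:
        cohort_map = cohorts(params, curves, n_cycles)
    return (_strategy_result("EMPIRICAL", params, cohort_map),
            _strategy_result("TGT", params, cohort_map))


def base_case(
    params: ModelParameters,
    curves: Mapping[tuple[str, str, str], SurvivalCurve],
    n_cycles: int | None = None,
) -> ResultBundle:
    """Full deterministic run of both strategies, packaged as a ResultBundle."""
    emp, tgt = evaluate_strategies(params, curves, n_cycles)
    inc = economics.icer((emp.cost, emp.qaly), (tgt.cost, tgt.qaly),
                         wtp=params.wtp_per_qaly)
    decision = "cost-effective" if economics.cost_effective(inc) else "not cost-effective"
    return ResultBundle(
        cost_empirical=emp.cost,
        qaly_empirical=emp.qaly,
        cost_tgt=tgt.cost,
        qaly_tgt=tgt.qaly,
        delta_cost=inc.delta_cost,
        delta_qaly=inc.delta_qaly,
        icer=inc.icer,
        dominance=inc.dominance,
        decision=decision,
        wtp_per_qaly=params.wtp_per_qaly,
        provenance={
            "config_sha256": config_hash(params),
            "seed": params.rng_seed,
            "horizon_years": params.horizon_years,
            "n_cycles": params.n_cycles if n_cycles is None else n_cycles,
        },
    )
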