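"""One-way, scenario, horizon and probabilistic sensitivity analyses.

One-way analyses re-run the full deterministic model over a grid of a single
parameter and locate the willingness-to-pay break-even point by bisection on
the net-monetary-benefit difference.  The probabilistic sensitivity analysis
(PSA) jointly samples every uncertain ledger entry — gamma for costs, beta
for probabilities and utilities, parameterized by method of moments — plus an
optional per-curve hazard multiplier that propagates survival-curve
uncertainty, and summarises the Monte-Carlo cloud as a cost-effectiveness
probability and acceptability curve (CEAC).

Linked parameters: varying the annual 400 mg imatinib cost rescales the
800 mg cost (always 2×) and the brand/generic prices proportionally; varying
the exon 9 prevalence renormalises the exon 11 / other shares
proportionally; varying the exon 11 prevalence is absorbed entirely by the
"other" share (exon 9 fixed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import economics, markov
from .config import ConfigurationError, ModelParameters, ResultBundle
from .markov import _line_cost_rates, discount_factors, line_utilities
from .survival import GENOTYPES, SurvivalCurve

__all__ = [
    "AddressingError",
    "ParameterizationError",
    "PSAError",
    "OneWayGrid",
    "PSAResult",
    "get_param",
    "set_param",
    "nmb_difference",
    "one_way",
    "horizon_sweep",
    "market_share_scenario",
    "moment_match",
    "sample_distribution",
    "psa",
    "sd_fraction_sweep",
]


class AddressingError(ConfigurationError):
    """A parameter path does not address a scalar in the ledger."""


class ParameterizationError(ValueError):
    """Requested moments are infeasible for the distribution family."""


class PSAError(RuntimeError):
    """Probabilistic sensitivity analysis failed (resample cap exceeded)."""


#: parameters whose change invalidates cached cohort traces
SCHEDULE_PATHS = frozenset({
    "longterm_monthly_death_prob", "cycle_length_months", "horizon_years",
})


# ----------------------------------------------------------------------
# parameter addressing
# ----------------------------------------------------------------------
def _normalize(path: str) -> str:
    from .config import _UNCERTAIN_FIELDS

    if path in _UNCERTAIN_FIELDS:
        return path + ".mean"
    return path


def get_param(params: ModelParameters, path: str) -> float:
    path = _normalize(path)
    obj = params
    for part in path.split("."):
        if not hasattr(obj, part):
            raise AddressingError(f"parameter path {path!r} does not exist")
        obj = getattr(obj, part)
    if not isinstance(obj, (int, float)):
        raise AddressingError(f"parameter path {path!r} does not address a scalar")
    return float(obj)


def set_param(params: ModelParameters, path: str, value: float) -> ModelParameters:
    """Return a copy of the ledger with one scalar changed.

    Applies the documented linked-parameter rules (imatinib price structure,
    prevalence renormalisation) so the result is internally consistent.
    """
    path = _normalize(path)
    old = get_param(params, path)
    p = params.copy()

    if path == "cost_imatinib400_year.mean":
        if old <= 0:
            raise AddressingError("cannot rescale a zero imatinib cost")
        factor = value / old
        p.cost_imatinib400_year.mean = value
        p.cost_imatinib800_year.mean = 2.0 * value
        p.price_brand_imatinib400_year *= factor
        p.price_generic_imatinib400_year *= factor
        return p
    if path == "prevalence_exon9":
        rest_old = 1.0 - old
        if rest_old <= 0:
            raise AddressingError("cannot renormalise: exon 9 prevalence is 1")
        scale = (1.0 - value) / rest_old
        p.prevalence_exon9 = value
        p.prevalence_exon11 *= scale
        p.prevalence_other *= scale
        return p
    if path == "prevalence_exon11":
        p.prevalence_exon11 = value
        p.prevalence_other = 1.0 - p.prevalence_exon9 - value
        return p

    parts = path.split(".")
    obj = p
    for part in parts[:-1]:
        obj = getattr(obj, part)
    if not hasattr(obj, parts[-1]):
        raise AddressingError(f"parameter path {path!r} does not exist")
    setattr(obj, parts[-1], value)
    return p


# ----------------------------------------------------------------------
# one-way / threshold
# ----------------------------------------------------------------------
def nmb_difference(params: ModelParameters,
                   curves: Mapping[tuple[str, str, str], SurvivalCurve],
                   wtp: float | None = None,
                   cohort_map=None) -> float:
    """TGT-minus-EMPIRICAL net-monetary-benefit difference at WTP."""
    if wtp is None:
        wtp = params.wtp_per_qaly
    emp, tgt = markov.evaluate_strategies(params, curves, cohort_map=cohort_map)
    return economics.nmb((tgt.cost, tgt.qaly), wtp) - economics.nmb((emp.cost, emp.qaly), wtp)


@dataclass
class OneWayGrid:
    """Result of a one-way sensitivity analysis over one parameter."""

    param_path: str
    values: np.ndarray
    icers: np.ndarray
    nmb_differences: np.ndarray
    threshold: float | None
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "icer": self.icers,
                             "nmb_difference": self.nmb_differences})


def one_way(param_path: str, lo: float, hi: float, n_points: int,
            params: ModelParameters,
            curves: Mapping[tuple[str, str, str], SurvivalCurve],
            wtp: float | None = None,
            nmb_tolerance: float = 1.0) -> OneWayGrid:
    """Deterministic model over a strictly increasing grid of one parameter.

    Records the ICER at every grid value and, when the cost-effectiveness
    decision flips inside the range, the break-even parameter value found by
    bisection on the NMB difference (|ΔNMB| ≤ ``nmb_tolerance`` dollars).
    Cohort traces are reused across the grid whenever the parameter does not
    affect transition schedules (exact, since costs, utilities, AE
    probabilities and prevalences enter only the accrual step).
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    path = _normalize(param_path)
    get_param(params, path)  # raises AddressingError early
    if wtp is None:
        wtp = params.wtp_per_qaly
    reuse = path.split(".")[0] not in SCHEDULE_PATHS
    base_cohorts = markov.cohorts(params, curves) if reuse else None

    def g(v: float) -> tuple[float, float | None]:
        p2 = set_param(params, path, v)
        emp, tgt = markov.evaluate_strategies(p2, curves, cohort_map=base_cohorts)
        inc = economics.icer((emp.cost, emp.qaly), (tgt.cost, tgt.qaly))
        dnmb = wtp * inc.delta_qaly - inc.delta_cost
        return dnmb, inc.icer

    values = np.linspace(lo, hi, n_points)
    icers = np.empty(n_points)
    dnmbs = np.empty(n_points)
    for i, v in enumerate(values):
        dnmbs[i], ic = g(v)
        icers[i] = np.nan if ic is None else ic

    threshold = None
    sign = np.sign(dnmbs)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(flips) > 0:
        a, b = float(values[flips[0]]), float(values[flips[0] + 1])
        ga, _ = g(a)
        for _ in range(200):
            mid = 0.5 * (a + b)
            gm, _ = g(mid)
            if abs(gm) <= nmb_tolerance or (b - a) < 1e-9 * max(1.0, abs(hi - lo)):
                threshold = mid
                break
            if np.sign(gm) == np.sign(ga):
                a, ga = mid, gm
            else:
                b = mid
        else:  # pragma: no cover
            threshold = 0.5 * (a + b)
    elif sign[0] == 0:
        threshold = float(values[0])
    return OneWayGrid(param_path=path, values=values, icers=icers,
                      nmb_differences=dnmbs, threshold=threshold, wtp=wtp)


def horizon_sweep(years_list, params: ModelParameters,
                  curves: Mapping[tuple[str, str, str], SurvivalCurve]) -> pd.DataFrame:
    """Re-run the model truncated/extended to each horizon; one row each."""
    rows = []
    for years in years_list:
        n = years * 12.0 / params.cycle_length_months
        if n < 1 or abs(n - round(n)) > 1e-9:
            raise ValueError(f"horizon {years} years is not a whole number of cycles")
        p2 = params.copy()
        p2.horizon_years = float(years)
        emp, tgt = markov.evaluate_strategies(p2, curves)
        inc = economics.icer((emp.cost, emp.qaly), (tgt.cost, tgt.qaly))
        rows.append({"horizon_years": years, "n_cycles": int(round(n)),
                     "delta_cost": inc.delta_cost, "delta_qaly": inc.delta_qaly,
                     "icer": np.nan if inc.icer is None else inc.icer})
    return pd.DataFrame(rows)


def market_share_scenario(share_generic: float, params: ModelParameters,
                          curves: Mapping[tuple[str, str, str], SurvivalCurve]) -> ResultBundle:
    """Recompute imatinib costs for a generic-market share and re-run."""
    if not 0.0 <= share_generic <= 1.0:
        raise ValueError("share must lie in [0, 1]")
    p2 = scenario_parameters(share_generic, params)
    return markov.base_case(p2, curves)


def scenario_parameters(share_generic: float, params: ModelParameters) -> ModelParameters:
    """Ledger with imatinib costs recomputed from brand/generic prices."""
    p2 = params.copy()
    p2.market_share_generic = float(share_generic)
    weighted = p2.imatinib400_weighted_price()
    p2.cost_imatinib400_year.mean = weighted
    p2.cost_imatinib800_year.mean = 2.0 * weighted
    return p2


# ----------------------------------------------------------------------
# distributions
# ----------------------------------------------------------------------
def moment_match(family: str, mean: float, sd: float) -> dict[str, float]:
    """Method-of-moments distribution parameters.

    gamma: shape = (mean/sd)², scale = sd²/mean.
    beta:  ν = mean(1−mean)/sd² − 1, α = mean·ν, β = (1−mean)·ν.
    ``sd = 0`` degenerates to a point mass at the mean.
    """
    if sd < 0:
        raise ParameterizationError("sd must be >= 0")
    if sd == 0.0:
        return {"family": "fixed", "value": mean}
    if family == "gamma":
        if mean <= 0:
            raise ParameterizationError("gamma requires mean > 0 (or sd = 0)")
        return {"family": "gamma", "shape": (mean / sd) ** 2, "scale": sd * sd / mean}
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ParameterizationError("beta requires mean in (0, 1)")
        if sd * sd >= mean * (1.0 - mean):
            raise ParameterizationError(
                f"beta infeasible: sd²={sd*sd:.6g} >= mean(1−mean)={mean*(1-mean):.6g}"
            )
        nu = mean * (1.0 - mean) / (sd * sd) - 1.0
        return {"family": "beta", "alpha": mean * nu, "beta": (1.0 - mean) * nu}
    raise ParameterizationError(f"unknown family {family!r}")


def sample_distribution(rng: np.random.Generator, spec: Mapping[str, float],
                        size: int) -> np.ndarray:
    """Draw from a moment-matched spec (``fixed`` returns the point mass)."""
    fam = spec["family"]
    if fam == "fixed":
        return np.full(size, float(spec["value"]))
    if fam == "gamma":
        return rng.gamma(spec["shape"], spec["scale"], size)
    if fam == "beta":
        return rng.beta(spec["alpha"], spec["beta"], size)
    raise ParameterizationError(f"unknown family {fam!r}")


#: ledger entries jointly sampled in the PSA, in draw order
_PSA_COST_FIELDS = (
    "cost_tgt", "cost_imatinib400_year", "cost_imatinib800_year",
    "cost_sunitinib_year", "cost_bsc_year",
    "cost_other_medical_imatinib_year", "cost_other_medical_sunitinib_year",
    "cost_ae_imatinib", "cost_ae_sunitinib", "cost_progression",
)
_PSA_PROB_FIELDS = (
    "p_ae_imatinib400_month", "p_ae_imatinib800_month", "p_ae_sunitinib_month",
)


def _feasible_beta_sd(mean: float, sd: float) -> float:
    limit = 0.99 * np.sqrt(mean * (1.0 - mean))
    if sd > limit:
        warnings.warn(
            f"beta sd {sd:.4g} infeasible for mean {mean:.4g}; capped at {limit:.4g}",
            stacklevel=3,
        )
        return float(limit)
    return sd


def _draw_field(rng, uv, sdf: float, n: int) -> np.ndarray:
    mean = abs(uv.mean)
    sd = uv.sd(sdf) if uv.distribution != "fixed" else 0.0
    if uv.distribution == "beta" and sd > 0:
        sd = _feasible_beta_sd(mean, sd)
    if sd == 0.0 or mean == 0.0:
        return np.full(n, mean)
    return sample_distribution(rng, moment_match(uv.distribution, mean, sd), n)


@dataclass
class PSAResult:
    """Monte-Carlo cloud with its cost-effectiveness summary."""

    n_iter: int
    seed: int
    wtp: float
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    cost_empirical: np.ndarray
    qaly_empirical: np.ndarray
    cost_tgt: np.ndarray
    qaly_tgt: np.ndarray
    ce_probability: float
    ceac_wtp: np.ndarray
    ceac_probability: np.ndarray
    clamped_fraction: float
    sd_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly,
            "cost_empirical": self.cost_empirical, "qaly_empirical": self.qaly_empirical,
            "cost_tgt": self.cost_tgt, "qaly_tgt": self.qaly_tgt,
        })

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.ceac_wtp,
                             "probability_cost_effective": self.ceac_probability})


def psa(params: ModelParameters,
        curves: Mapping[tuple[str, str, str], SurvivalCurve],
        n_iter: int | None = None,
        seed: int | None = None,
        wtp_grid: np.ndarray | None = None,
        sd_fraction: float | None = None,
        hazard_uncertainty: bool = True) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Every iteration draws all uncertain costs (gamma), adverse-event
    probabilities (beta, CI-derived SD), and utilities (beta on magnitude,
    20%-of-mean SD by default), plus — when ``hazard_uncertainty`` — one
    2×Beta multiplier (mean 1, SD = ``sd_fraction``) per survival schedule
    applied to its per-cycle probabilities and clamped to [0, 1].  The
    deterministic cohort model is then re-run and incrementals recorded.
    Fully reproducible for a fixed seed.
    """
    if n_iter is None:
        n_iter = params.psa_iterations
    if seed is None:
        seed = params.rng_seed
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    sdf = params.sd_fraction if sd_fraction is None else sd_fraction
    wtp = params.wtp_per_qaly
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 200_001.0, 1000.0)
    rng = np.random.default_rng(seed)
    cm = params.cycle_length_months
    n_cycles = params.n_cycles

    # ---- parameter draws (fixed order for determinism) ----
    pv: dict[str, np.ndarray] = {}
    for name in _PSA_COST_FIELDS + _PSA_PROB_FIELDS:
        pv[name] = _draw_field(rng, getattr(params, name), sdf, n_iter)
    pv["utility_metastatic"] = _draw_field(rng, params.utility_metastatic, sdf, n_iter)
    dec_mag = _draw_field(rng, params.utility_progression_decrement, sdf, n_iter)
    pv["utility_progression_decrement"] = -dec_mag

    # ---- hazard multipliers, one per survival schedule ----
    arm_keys = [("EMPIRICAL", g) for g in GENOTYPES] + [("TGT", "exon9")]
    arms = {k: markov.build_arm(k[0], k[1], params, curves) for k in arm_keys}
    mult_keys: set[tuple[str, str, str]] = set()
    if hazard_uncertainty:
        for (strategy, genotype), arm in arms.items():
            seq = [st.drug for st in arm.lines]
            mult_keys.add((genotype, seq[0], "OS"))
            for drug in seq:
                mult_keys.add((genotype, drug, "PFS"))
    multipliers: dict[tuple[str, str, str], np.ndarray] = {}
    if hazard_uncertainty and sdf > 0:
        spec = moment_match("beta", 0.5, sdf / 2.0)
        for key in sorted(mult_keys):
            multipliers[key] = 2.0 * sample_distribution(rng, spec, n_iter)
    else:
        for key in sorted(mult_keys):
            multipliers[key] = np.ones(n_iter)

    # ---- run each unique arm, batched over iterations ----
    df = discount_factors(params, n_cycles)
    window = (np.arange(n_cycles) * cm) < markov.PROGRESSION_COST_WINDOW_MONTHS - 1e-9
    df_window = df * window
    clamped = 0
    total_probs = 0

    def arm_totals(arm: markov.StrategyArm) -> tuple[np.ndarray, np.ndarray]:
        nonlocal clamped, total_probs
        seq = [st.drug for st in arm.lines]
        if hazard_uncertainty:
            m_prog = np.stack([multipliers[(arm.genotype, d, "PFS")] for d in seq], axis=1)
            pp = arm.p_prog[None, :, :] * m_prog[:, :, None]
            pdth = arm.p_death[None, :] * multipliers[(arm.genotype, seq[0], "OS")][:, None]
            clamped += int(np.sum(pp > 1.0)) + int(np.sum(pdth > 1.0))
            total_probs += pp.size + pdth.size
            pp = np.clip(pp, 0.0, 1.0)
            pdth = np.clip(pdth, 0.0, 1.0)
        else:
            pp = arm.p_prog[None, :, :]
            pdth = arm.p_death[None, :]
            total_probs += pp.size + pdth.size
        occ_line, occ_bsc, _, prog_flow, _ = markov._propagate(pp, pdth, n_cycles)
        D_occ = np.einsum("i,nij->nj", df, occ_line[:, :n_cycles, :])
        D_bsc = occ_bsc[:, :n_cycles] @ df
        D_prog = prog_flow @ df_window

        rates = _line_cost_rates(arm, params, overrides=pv)
        cost = sum(D_occ[:, j] * rates[j] for j in range(arm.n_lines))
        cost = cost + D_bsc * pv["cost_bsc_year"] * cm / 12.0
        cost = cost + D_prog * pv["cost_progression"]
        if arm.tgt_cost_applies:
            cost = cost + pv["cost_tgt"]
        utils = line_utilities(arm, params,
                               u_metastatic=pv["utility_metastatic"],
                               u_decrement=pv["utility_progression_decrement"])
        qaly = sum(D_occ[:, j] * utils[j] for j in range(arm.n_lines))
        qaly = (qaly + D_bsc * params.utility_bsc) * cm / 12.0
        return np.asarray(cost, float), np.asarray(qaly, float)

    totals = {k: arm_totals(arm) for k, arm in arms.items()}
    prev = {"exon9": params.prevalence_exon9, "exon11": params.prevalence_exon11,
            "other": params.prevalence_other}
    cost_emp = sum(prev[g] * totals[("EMPIRICAL", g)][0] for g in GENOTYPES)
    qaly_emp = sum(prev[g] * totals[("EMPIRICAL", g)][1] for g in GENOTYPES)
    # TGT arms for exon 11 / other share the empirical pathway plus the test cost
    cost_tgt = prev["exon9"] * totals[("TGT", "exon9")][0]
    qaly_tgt = prev["exon9"] * totals[("TGT", "exon9")][1]
    for g in ("exon11", "other"):
        cost_tgt = cost_tgt + prev[g] * (totals[("EMPIRICAL", g)][0] + pv["cost_tgt"])
        qaly_tgt = qaly_tgt + prev[g] * totals[("EMPIRICAL", g)][1]

    delta_cost = cost_tgt - cost_emp
    delta_qaly = qaly_tgt - qaly_emp
    if not (np.all(np.isfinite(delta_cost)) and np.all(np.isfinite(delta_qaly))):
        raise PSAError("non-finite incrementals in PSA draw")
    ce = float(np.mean(wtp * delta_qaly - delta_cost >= 0.0))
    ceac = np.array([float(np.mean(w * delta_qaly - delta_cost >= 0.0)) for w in wtp_grid])
    return PSAResult(
        n_iter=n_iter, seed=seed, wtp=wtp,
        delta_cost=delta_cost, delta_qaly=delta_qaly,
        cost_empirical=cost_emp, qaly_empirical=qaly_emp,
        cost_tgt=cost_tgt, qaly_tgt=qaly_tgt,
        ce_probability=ce, ceac_wtp=np.asarray(wtp_grid, float),
        ceac_probability=ceac,
        clamped_fraction=clamped / max(total_probs, 1),
        sd_fraction=sdf,
    )


def sd_fraction_sweep(fractions, params: ModelParameters,
                      curves: Mapping[tuple[str, str, str], SurvivalCurve],
                      n_iter: int | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """CE probability at the base WTP for several assumed SD fractions."""
    rows = []
    for f in fractions:
        res = psa(params, curves, n_iter=n_iter, seed=seed, sd_fraction=f)
        rows.append({"sd_fraction": f, "ce_probability": res.ce_probability})
    return pd.DataFrame(rows)
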