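"""Survival inputs and their conversion to per-cycle transition probabilities.

The engine consumes progression-free survival (PFS) and overall survival (OS)
curves per genotype × drug.  The published model digitized these from two
source trials; those point series are not public, so this module also ships a
seeded synthetic-trial generator whose exponential hazards encode the trials'
qualitative structure:

* *KIT* exon 9 disease progresses more slowly on 800 mg imatinib than on
  400 mg (the dose–response that genotype-directed dosing exploits);
* exon 11 disease on 400 mg has the lowest progression hazard of any
  genotype on first-line imatinib;
* OS is equivalent across imatinib doses within a genotype;
* beyond month 36 the death hazard is replaced by a constant long-term
  monthly death probability (registry-style conditional mortality).

Conversions use the standard constant-hazard-within-cycle identities
``r = −ln(1−p)/T`` and ``p = 1 − exp(−rT)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ENDPOINTS",
    "GENOTYPES",
    "DRUGS",
    "SurvivalCurve",
    "ParametricSurvival",
    "SurvivalError",
    "CoverageError",
    "AlignmentError",
    "FixtureSpecError",
    "prob_to_rate",
    "rate_to_prob",
    "km_to_cycle_probs",
    "decompose_pfs",
    "extend_longterm",
    "fit_parametric",
    "default_trial_spec",
    "generate_fixture_trials",
    "write_curve_csv",
    "read_curve_csv",
]

ENDPOINTS = ("PFS", "OS")
GENOTYPES = ("exon11", "exon9", "other")
DRUGS = ("imatinib400", "imatinib800", "sunitinib")


class SurvivalError(ValueError):
    """Invalid survival input."""


class CoverageError(SurvivalError):
    """Curve does not cover the requested horizon."""


class AlignmentError(SurvivalError):
    """Schedules are not on the same cycle grid."""


class FixtureSpecError(SurvivalError):
    """Fixture specification violates the required qualitative ordering."""


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SurvivalCurve:
    """A digitized or generated survival function as a point series.

    ``times`` are months, strictly increasing and starting at 0;
    ``survival`` are fractions with ``survival[0] == 1``, monotone
    non-increasing.  Evaluation between points is piecewise linear on the
    survival scale.
    """

    endpoint: str
    genotype: str
    drug: str
    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if self.endpoint not in ENDPOINTS:
            raise SurvivalError(f"unknown endpoint {self.endpoint!r}")
        if self.genotype not in GENOTYPES:
            raise SurvivalError(f"unknown genotype {self.genotype!r}")
        if self.drug not in DRUGS:
            raise SurvivalError(f"unknown drug {self.drug!r}")
        if t.ndim != 1 or s.ndim != 1 or len(t) != len(s):
            raise SurvivalError("times and survival must be 1-D and equal length")
        if len(t) < 2:
            raise SurvivalError("a curve needs at least two points")
        if t[0] != 0.0:
            raise SurvivalError("first time point must be 0")
        if np.any(np.diff(t) <= 0):
            raise SurvivalError("times must be strictly increasing")
        if s[0] != 1.0:
            raise SurvivalError("survival at time 0 must be 1")
        if np.any(np.diff(s) > 1e-12):
            raise SurvivalError("survival must be monotone non-increasing")
        if np.any(s < -1e-12) or np.any(s > 1.0 + 1e-12):
            raise SurvivalError("survival fractions must lie in [0, 1]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.genotype, self.drug, self.endpoint)

    def evaluate(self, t) -> np.ndarray:
        """S(t) by monotone piecewise-linear interpolation."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.times[-1]):
            raise CoverageError(
                f"curve {self.key} covers [0, {self.times[-1]}] months; asked for "
                f"t in [{t.min()}, {t.max()}]"
            )
        return np.interp(t, self.times, self.survival)


@dataclass(frozen=True)
class ParametricSurvival:
    """Exponential or Weibull survival, ``S(t) = exp(−(λ t)^k)`` (k = 1 for
    exponential).  ``rate`` is per month."""

    family: str
    rate: float
    shape: float = 1.0

    def __post_init__(self):
        if self.family not in ("exponential", "weibull"):
            raise SurvivalError(f"unknown family {self.family!r}")
        if self.rate < 0:
            raise SurvivalError("rate must be >= 0")
        if self.shape <= 0:
            raise SurvivalError("shape must be > 0")
        if self.family == "exponential" and self.shape != 1.0:
            raise SurvivalError("exponential family requires shape == 1")

    def cumulative_hazard(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.rate * t) ** self.shape

    def survival(self, t) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(t))


# ----------------------------------------------------------------------
def prob_to_rate(p: float, period_months: float = 1.0) -> float:
    """Event rate per month implied by probability ``p`` over ``period_months``."""
    if not 0.0 <= p < 1.0:
        raise SurvivalError(f"probability must lie in [0, 1); got {p!r}"
                            + (" (rate is infinite at p = 1)" if p == 1.0 else ""))
    if period_months <= 0:
        raise SurvivalError("period must be > 0")
    return -math.log1p(-p) / period_months


def rate_to_prob(r: float, period_months: float) -> float:
    """Event probability over ``period_months`` at constant monthly rate ``r``."""
    if r < 0:
        raise SurvivalError(f"rate must be >= 0; got {r!r}")
    if period_months < 0:
        raise SurvivalError("period must be >= 0")
    return -math.expm1(-r * period_months)


def km_to_cycle_probs(curve: SurvivalCurve, cycle_months: float, n_cycles: int) -> np.ndarray:
    """Per-cycle event probabilities from a survival curve.

    For cycle ``i``, ``p_i = 1 − S(t_{i+1}) / S(t_i)`` with cycle boundaries
    ``t_i = i × cycle_months`` and S interpolated linearly between digitized
    points.
    """
    if cycle_months <= 0 or n_cycles < 1:
        raise SurvivalError("cycle_months must be > 0 and n_cycles >= 1")
    bounds = np.arange(n_cycles + 1, dtype=float) * cycle_months
    if bounds[-1] > curve.times[-1] + 1e-9:
        raise CoverageError(
            f"curve {curve.key} ends at {curve.times[-1]} months but "
            f"{n_cycles} cycles of {cycle_months} months need {bounds[-1]}"
        )
    s = np.interp(np.minimum(bounds, curve.times[-1]), curve.times, curve.survival)
    if np.any(s[:-1] <= 0.0):
        first = int(np.argmax(s[:-1] <= 0.0))
        raise SurvivalError(
            f"curve {curve.key}: S = 0 at cycle boundary {first} with later cycles "
            "still demanded (degenerate denominator)"
        )
    p = 1.0 - s[1:] / s[:-1]
    return np.clip(p, 0.0, 1.0)


def decompose_pfs(pfs_cycle_probs: np.ndarray, os_cycle_probs: np.ndarray,
                  cycle_months: float) -> tuple[np.ndarray, np.ndarray]:
    """Split PFS event probabilities into progression-only and death.

    PFS events include death, so per cycle both schedules are converted to
    constant-within-cycle rates and the progression rate is the excess
    ``max(0, r_pfs − r_os)``; the death probability passes through unchanged.
    Cycles where the OS hazard exceeds the PFS hazard are clamped to zero
    progression with a warning (digitization noise in real inputs).
    """
    pfs = np.asarray(pfs_cycle_probs, dtype=float)
    osp = np.asarray(os_cycle_probs, dtype=float)
    if pfs.shape != osp.shape:
        raise AlignmentError(
            f"PFS and OS schedules are misaligned: {pfs.shape} vs {osp.shape}"
        )
    with np.errstate(divide="ignore"):
        r_pfs = -np.log1p(-pfs) / cycle_months
        r_os = -np.log1p(-osp) / cycle_months
    excess = r_pfs - r_os
    if np.any(excess < -1e-12):
        warnings.warn(
            "OS hazard exceeds PFS hazard in %d cycle(s); progression clamped to 0"
            % int(np.sum(excess < -1e-12)),
            stacklevel=2,
        )
    r_prog = np.maximum(0.0, excess)
    p_prog = -np.expm1(-r_prog * cycle_months)
    return p_prog, osp.copy()


def extend_longterm(os_cycle_probs: np.ndarray, longterm_monthly_death_prob: float,
                    cycle_months: float, switch_month: float = 36.0) -> np.ndarray:
    """Replace the death schedule from ``switch_month`` on with a constant
    per-cycle probability derived from a constant monthly death probability."""
    osp = np.asarray(os_cycle_probs, dtype=float).copy()
    n_cycles = len(osp)
    starts = np.arange(n_cycles) * cycle_months
    mask = starts >= switch_month - 1e-9
    if not mask.any():
        warnings.warn("switch_month is beyond the horizon; extension is a no-op",
                      stacklevel=2)
        return osp
    monthly_rate = prob_to_rate(longterm_monthly_death_prob, 1.0)
    osp[mask] = rate_to_prob(monthly_rate, cycle_months)
    return osp


# ----------------------------------------------------------------------
def fit_parametric(curve: SurvivalCurve, family: str = "exponential") -> ParametricSurvival:
    """Least-squares fit on the log-survival scale.

    Exponential: regress ``−ln S`` on ``t`` through the origin.
    Weibull: regress ``ln(−ln S)`` on ``ln t`` (slope = shape).
    Points with ``S <= 0`` (or ``S >= 1`` for the Weibull log-log transform)
    are excluded.
    """
    t = curve.times
    s = curve.survival
    keep = (t > 0) & (s > 0)
    if keep.sum() < 3:
        raise SurvivalError("need at least 3 points with t > 0 and survival > 0")
    t, s = t[keep], s[keep]
    logs = np.log(s)
    if family == "exponential":
        if np.all(logs == 0.0):
            warnings.warn("flat curve: fitted exponential rate is 0", stacklevel=2)
            return ParametricSurvival("exponential", 0.0)
        lam = -(t @ logs) / (t @ t)
        return ParametricSurvival("exponential", max(0.0, float(lam)))
    if family == "weibull":
        ok = logs < 0
        if ok.sum() < 3:
            warnings.warn("flat curve: fitted Weibull rate is 0", stacklevel=2)
            return ParametricSurvival("weibull", 0.0, 1.0)
        x = np.log(t[ok])
        y = np.log(-logs[ok])
        k, c = np.polyfit(x, y, 1)
        return ParametricSurvival("weibull", float(np.exp(c / k)), float(k))
    raise SurvivalError(f"unknown family {family!r}")


# ----------------------------------------------------------------------
def default_trial_spec() -> dict[tuple[str, str, str], ParametricSurvival]:
    """Synthetic stand-ins for the two source trials (exponential hazards,
    per month), keyed ``(genotype, drug, endpoint)``.

    Rates are set from the source trials' published median PFS/OS at
    realistic orders of magnitude (λ = ln 2 / median): first-line imatinib
    medians of roughly 24 (exon 11), 6→13 (exon 9, 400→800 mg) and 12 months
    (other); second-line sunitinib strongly favouring exon 9.  OS rates are
    identical across imatinib doses within each genotype.
    """
    E = lambda r: ParametricSurvival("exponential", r)  # noqa: E731
    spec: dict[tuple[str, str, str], ParametricSurvival] = {
        # --- PFS, imatinib (first-line trial) ---
        ("exon11", "imatinib400", "PFS"): E(0.028),
        ("exon11", "imatinib800", "PFS"): E(0.030),
        ("exon9", "imatinib400", "PFS"): E(0.115),
        ("exon9", "imatinib800", "PFS"): E(0.053),
        ("other", "imatinib400", "PFS"): E(0.058),
        ("other", "imatinib800", "PFS"): E(0.058),
        # --- PFS, sunitinib (second-line trial) ---
        ("exon11", "sunitinib", "PFS"): E(0.135),
        ("exon9", "sunitinib", "PFS"): E(0.036),
        ("other", "sunitinib", "PFS"): E(0.115),
        # --- OS, imatinib (equal across doses within genotype) ---
        ("exon11", "imatinib400", "OS"): E(0.0115),
        ("exon11", "imatinib800", "OS"): E(0.0115),
        ("exon9", "imatinib400", "OS"): E(0.0231),
        ("exon9", "imatinib800", "OS"): E(0.0231),
        ("other", "imatinib400", "OS"): E(0.0173),
        ("other", "imatinib800", "OS"): E(0.0173),
        # --- OS, sunitinib (independent trial; not used by the engine, which
        #     keeps each arm on its first-line OS schedule) ---
        ("exon11", "sunitinib", "OS"): E(0.0347),
        ("exon9", "sunitinib", "OS"): E(0.0257),
        ("other", "sunitinib", "OS"): E(0.030),
    }
    return spec


def validate_trial_spec(spec: Mapping[tuple[str, str, str], ParametricSurvival]) -> None:
    """Enforce the qualitative ordering the synthetic trials must encode."""
    def H(genotype, drug, endpoint, t=12.0):
        try:
            return float(spec[(genotype, drug, endpoint)].cumulative_hazard(t))
        except KeyError:
            raise FixtureSpecError(f"missing spec entry {(genotype, drug, endpoint)}")

    problems = []
    if not H("exon9", "imatinib800", "PFS") < H("exon9", "imatinib400", "PFS"):
        problems.append("exon 9 PFS hazard on imatinib 800 must be below imatinib 400")
    h11 = H("exon11", "imatinib400", "PFS")
    for g in ("exon9", "other"):
        if h11 > H(g, "imatinib400", "PFS") + 1e-12:
            problems.append(f"exon 11 PFS hazard on imatinib 400 must be the lowest "
                            f"of all genotypes (violated by {g})")
    for g in GENOTYPES:
        a = spec.get((g, "imatinib400", "OS"))
        b = spec.get((g, "imatinib800", "OS"))
        if a is None or b is None:
            problems.append(f"missing OS spec for {g} imatinib")
        elif abs(a.rate - b.rate) > 1e-12 or abs(a.shape - b.shape) > 1e-12:
            problems.append(f"OS must be equivalent across imatinib doses for {g}")
    if problems:
        raise FixtureSpecError("; ".join(problems))


def generate_fixture_trials(
    seed: int,
    spec: Mapping[tuple[str, str, str], ParametricSurvival] | None = None,
    noise_sd: float = 0.0,
    t_max_months: float = 180.0,
    step_months: float = 1.0,
) -> dict[tuple[str, str, str], SurvivalCurve]:
    """Generate the synthetic trial point series on a monthly grid.

    ``noise_sd`` perturbs log-survival with seeded Gaussian noise
    (multiplicative on the survival scale, so S stays positive); the series
    is then re-monotonized with a running minimum and clipped to [0, 1].
    Deterministic for a fixed seed.
    """
    if spec is None:
        spec = default_trial_spec()
    validate_trial_spec(spec)
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max_months + step_months / 2, step_months)
    curves: dict[tuple[str, str, str], SurvivalCurve] = {}
    for key in sorted(spec):
        genotype, drug, endpoint = key
        s = spec[key].survival(t)
        if noise_sd > 0:
            logs = np.log(s)
            logs[1:] = logs[1:] + rng.normal(0.0, noise_sd, size=len(t) - 1)
            s = np.exp(logs)
        s = np.minimum(np.minimum.accumulate(np.clip(s, 0.0, 1.0)), 1.0)
        s[0] = 1.0
        curves[key] = SurvivalCurve(endpoint=endpoint, genotype=genotype, drug=drug,
                                    times=t, survival=s)
    return curves


# ----------------------------------------------------------------------
def write_curve_csv(curve: SurvivalCurve, path: str | Path) -> None:
    pd.DataFrame({"time_months": curve.times, "survival": curve.survival}).to_csv(
        path, index=False
    )


def read_curve_csv(path: str | Path, endpoint: str, genotype: str, drug: str) -> SurvivalCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    return SurvivalCurve(endpoint=endpoint, genotype=genotype, drug=drug,
                         times=df["time_months"].to_numpy(),
                         survival=df["survival"].to_numpy())
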