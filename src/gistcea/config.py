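"""Model-parameter ledger, validation, and configuration / results I/O.

The ledger holds every base-case input of the cost-effectiveness model — costs
(2019 US dollars, payer perspective), monthly adverse-event probabilities,
health utilities, genotype prevalences and the economic settings — each with a
95% CI and a sampling-distribution family for probabilistic sensitivity
analysis.  Costs are modelled with gamma distributions; probabilities and
utilities with beta distributions.

Two published adverse-event cost estimates have means lying outside their own
printed confidence intervals.  They are loaded verbatim and flagged with a
:class:`CIConsistencyWarning` rather than silently repaired; ``sd_override``
lets a user supply a coherent spread.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GAMMA",
    "BETA",
    "FIXED",
    "UncertainValue",
    "ModelParameters",
    "ResultBundle",
    "ConfigurationError",
    "ValidationError",
    "CIConsistencyWarning",
    "default_parameters",
    "load_parameters",
    "dump_parameters",
    "config_hash",
    "write_bundle_json",
    "read_bundle_json",
    "write_trace_csv",
    "read_trace_csv",
]

GAMMA = "gamma"
BETA = "beta"
FIXED = "fixed"

#: two-sided 97.5% normal quantile used when an SD is derived from a 95% CI
_Z95 = 1.959963984540054


class ConfigurationError(ValueError):
    """A configuration document is missing or mis-addresses a field."""


class ValidationError(ValueError):
    """One or more ledger invariants are violated.

    ``violations`` lists every failed check, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("parameter validation failed:\n  - " + "\n  - ".join(violations))


class CIConsistencyWarning(UserWarning):
    """A mean lies outside its own printed 95% CI (loadable, but flagged)."""


@dataclass
class UncertainValue:
    """A scalar input with an uncertainty specification.

    ``sd_rule`` selects how the PSA standard deviation is derived when
    ``sd_override`` is absent: ``"fraction"`` uses ``sd_fraction × |mean|``
    (the rule for costs and utilities); ``"ci"`` uses the normal-theory
    width ``(ci_high − ci_low) / (2 × 1.96)`` (used for event probabilities,
    whose spreads come from the source trials).
    """

    mean: float
    ci_low: float | None = None
    ci_high: float | None = None
    distribution: str = FIXED
    sd_override: float | None = None
    sd_rule: str = "fraction"

    @property
    def ci_consistent(self) -> bool:
        if self.ci_low is None or self.ci_high is None:
            return True
        return self.ci_low <= self.mean <= self.ci_high

    def sd(self, sd_fraction: float) -> float:
        """Standard deviation used when sampling this value in the PSA."""
        if self.sd_override is not None:
            return float(self.sd_override)
        if self.sd_rule == "ci":
            if self.ci_low is None or self.ci_high is None:
                raise ConfigurationError(
                    "sd_rule='ci' requires both CI bounds (mean=%r)" % self.mean
                )
            return (self.ci_high - self.ci_low) / (2.0 * _Z95)
        if self.sd_rule == "fraction":
            return sd_fraction * abs(self.mean)
        raise ConfigurationError(f"unknown sd_rule {self.sd_rule!r}")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"mean": self.mean, "distribution": self.distribution}
        if self.ci_low is not None:
            d["ci_low"] = self.ci_low
        if self.ci_high is not None:
            d["ci_high"] = self.ci_high
        if self.sd_override is not None:
            d["sd_override"] = self.sd_override
        if self.sd_rule != "fraction":
            d["sd_rule"] = self.sd_rule
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any] | float) -> "UncertainValue":
        if isinstance(d, (int, float)):
            return cls(mean=float(d))
        allowed = {"mean", "ci_low", "ci_high", "distribution", "sd_override", "sd_rule"}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigurationError(f"unknown UncertainValue keys: {sorted(unknown)}")
        if "mean" not in d:
            raise ConfigurationError("UncertainValue mapping requires 'mean'")
        return cls(
            mean=float(d["mean"]),
            ci_low=None if d.get("ci_low") is None else float(d["ci_low"]),
            ci_high=None if d.get("ci_high") is None else float(d["ci_high"]),
            distribution=d.get("distribution", FIXED),
            sd_override=None if d.get("sd_override") is None else float(d["sd_override"]),
            sd_rule=d.get("sd_rule", "fraction"),
        )


# fields stored as UncertainValue; everything else is a plain scalar
_UNCERTAIN_FIELDS = (
    "cost_tgt",
    "cost_imatinib400_year",
    "cost_imatinib800_year",
    "cost_sunitinib_year",
    "cost_bsc_year",
    "cost_other_medical_imatinib_year",
    "cost_other_medical_sunitinib_year",
    "cost_ae_imatinib",
    "cost_ae_sunitinib",
    "cost_progression",
    "p_ae_imatinib400_month",
    "p_ae_imatinib800_month",
    "p_ae_sunitinib_month",
    "utility_metastatic",
    "utility_progression_decrement",
)


@dataclass
class ModelParameters:
    """The full model-input ledger.

    Costs are per year unless named otherwise (``cost_tgt``, the adverse-event
    costs and ``cost_progression`` are one-time amounts).  Adverse-event
    probabilities are per month.  ``utility_progression_decrement`` is stored
    with its sign (negative).
    """

    # --- costs ($) ---
    cost_tgt: UncertainValue
    cost_imatinib400_year: UncertainValue
    cost_imatinib800_year: UncertainValue
    cost_sunitinib_year: UncertainValue
    cost_bsc_year: UncertainValue
    cost_other_medical_imatinib_year: UncertainValue
    cost_other_medical_sunitinib_year: UncertainValue
    cost_ae_imatinib: UncertainValue
    cost_ae_sunitinib: UncertainValue
    cost_progression: UncertainValue
    # --- probabilities (per month) ---
    p_ae_imatinib400_month: UncertainValue
    p_ae_imatinib800_month: UncertainValue
    p_ae_sunitinib_month: UncertainValue
    # --- utilities ---
    utility_metastatic: UncertainValue
    utility_progression_decrement: UncertainValue
    utility_bsc: float
    utility_dead: float
    # --- population ---
    prevalence_exon9: float
    prevalence_exon11: float
    prevalence_other: float
    # --- imatinib market ---
    market_share_generic: float
    price_brand_imatinib400_year: float
    price_generic_imatinib400_year: float
    # --- economic settings ---
    discount_rate_annual: float
    cycle_length_months: float
    horizon_years: float
    wtp_per_qaly: float
    # --- long-term mortality (synthetic fixture default; see docs) ---
    longterm_monthly_death_prob: float
    # --- PSA settings ---
    sd_fraction: float
    psa_iterations: int
    rng_seed: int

    # ------------------------------------------------------------------
    @property
    def n_cycles(self) -> int:
        n = self.horizon_years * 12.0 / self.cycle_length_months
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                [f"cycle_length_months={self.cycle_length_months} does not divide "
                 f"the {self.horizon_years}-year horizon into whole cycles"]
            )
        return int(round(n))

    def imatinib400_weighted_price(self, share_generic: float | None = None) -> float:
        """Market-share-weighted annual price of 400 mg imatinib."""
        s = self.market_share_generic if share_generic is None else share_generic
        return s * self.price_generic_imatinib400_year + (1.0 - s) * self.price_brand_imatinib400_year

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    # ------------------------------------------------------------------
    def validate(self, emit_warnings: bool = True) -> list[str]:
        """Check every ledger invariant; raise :class:`ValidationError` listing
        all violations.  Returns the list of (non-fatal) flags."""
        v: list[str] = []
        flags: list[str] = []

        prev_sum = self.prevalence_exon9 + self.prevalence_exon11 + self.prevalence_other
        if abs(prev_sum - 1.0) > 1e-9:
            v.append(f"genotype prevalences sum to {prev_sum!r}, expected 1")
        for name in ("prevalence_exon9", "prevalence_exon11", "prevalence_other",
                     "market_share_generic", "longterm_monthly_death_prob"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                v.append(f"{name}={x!r} outside [0, 1]")
        for name in ("p_ae_imatinib400_month", "p_ae_imatinib800_month", "p_ae_sunitinib_month"):
            uv = getattr(self, name)
            if not (0.0 <= uv.mean <= 1.0):
                v.append(f"{name}.mean={uv.mean!r} outside [0, 1]")
        if self.discount_rate_annual < 0:
            v.append("discount_rate_annual must be >= 0")
        if self.cycle_length_months <= 0 or self.horizon_years <= 0:
            v.append("cycle_length_months and horizon_years must be > 0")
        else:
            n = self.horizon_years * 12.0 / self.cycle_length_months
            if abs(n - round(n)) > 1e-9:
                v.append("cycle length must divide the horizon into a whole number of cycles")
        if self.psa_iterations < 1:
            v.append("psa_iterations must be >= 1")
        if not (0.0 <= self.utility_bsc <= 1.0):
            v.append(f"utility_bsc={self.utility_bsc!r} outside [0, 1]")

        w = self.imatinib400_weighted_price()
        if abs(w - self.cost_imatinib400_year.mean) > 1.0:
            v.append(
                f"market-share-weighted imatinib price {w:.2f} does not reproduce "
                f"cost_imatinib400_year {self.cost_imatinib400_year.mean:.2f} within $1"
            )

        for name in _UNCERTAIN_FIELDS:
            uv: UncertainValue = getattr(self, name)
            if uv.distribution not in (GAMMA, BETA, FIXED):
                v.append(f"{name}: unknown distribution {uv.distribution!r}")
            if uv.distribution == GAMMA and uv.mean < 0:
                v.append(f"{name}: gamma distribution requires a non-negative mean")
            if uv.distribution == BETA and not (0.0 <= abs(uv.mean) <= 1.0):
                v.append(f"{name}: beta distribution requires |mean| in [0, 1]")
            if not uv.ci_consistent:
                flag = (f"{name}: mean {uv.mean} lies outside its printed 95% CI "
                        f"({uv.ci_low} to {uv.ci_high}); loaded verbatim")
                flags.append(flag)
                if emit_warnings:
                    warnings.warn(flag, CIConsistencyWarning, stacklevel=2)

        if v:
            raise ValidationError(v)
        return flags

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in fields(self):
            val = getattr(self, f.name)
            out[f.name] = val.to_dict() if isinstance(val, UncertainValue) else val
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParameters":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigurationError(f"unknown parameter fields: {sorted(unknown)}")
        missing = names - set(d)
        if missing:
            raise ConfigurationError(f"missing parameter fields: {sorted(missing)}")
        kwargs: dict[str, Any] = {}
        for f in fields(cls):
            raw = d[f.name]
            if f.name in _UNCERTAIN_FIELDS:
                kwargs[f.name] = raw if isinstance(raw, UncertainValue) else UncertainValue.from_dict(raw)
            elif f.name == "psa_iterations" or f.name == "rng_seed":
                kwargs[f.name] = int(raw)
            else:
                kwargs[f.name] = float(raw)
        return cls(**kwargs)


# ----------------------------------------------------------------------
def default_parameters(emit_warnings: bool = True) -> ModelParameters:
    """The packaged base-case ledger.

    Costs are 2019 US dollars.  The adverse-event cost rows reproduce the
    published means verbatim even though both lie outside their printed CIs
    (a :class:`CIConsistencyWarning` is emitted).  The long-term monthly
    death probability is a synthetic fixture default — the registry-derived
    value behind the published model is not public — and should be replaced
    for any real analysis.
    """
    uv = UncertainValue
    p = ModelParameters(
        cost_tgt=uv(2919.0, 1903.0, 4150.0, GAMMA),
        cost_imatinib400_year=uv(57690.0, 38064.0, 85446.0, GAMMA),
        cost_imatinib800_year=uv(115380.0, 76128.0, 170892.0, GAMMA),
        cost_sunitinib_year=uv(86726.0, 51516.0, 114756.0, GAMMA),
        cost_bsc_year=uv(9403.0, 5856.0, 13194.0, GAMMA),
        cost_other_medical_imatinib_year=uv(2315.0, 1500.0, 3252.0, GAMMA),
        cost_other_medical_sunitinib_year=uv(3344.0, 2178.0, 4704.0, GAMMA),
        cost_ae_imatinib=uv(296.0, 1164.0, 2526.0, GAMMA),
        cost_ae_sunitinib=uv(160.0, 612.0, 1392.0, GAMMA),
        cost_progression=uv(46548.0, 29754.0, 66636.0, GAMMA),
        p_ae_imatinib400_month=uv(0.033, 0.021, 0.047, BETA, sd_rule="ci"),
        p_ae_imatinib800_month=uv(0.065, 0.042, 0.094, BETA, sd_rule="ci"),
        p_ae_sunitinib_month=uv(0.031, 0.020, 0.043, BETA, sd_rule="ci"),
        utility_metastatic=uv(0.935, 0.82, 1.0, BETA),
        utility_progression_decrement=uv(-0.12, -0.15, -0.08, BETA),
        utility_bsc=0.577,
        utility_dead=0.0,
        prevalence_exon9=0.15,
        prevalence_exon11=0.67,
        prevalence_other=0.18,
        market_share_generic=0.50,
        price_brand_imatinib400_year=76920.0,
        price_generic_imatinib400_year=38460.0,
        discount_rate_annual=0.03,
        cycle_length_months=2.0,
        horizon_years=10.0,
        wtp_per_qaly=100_000.0,
        longterm_monthly_death_prob=0.012,
        sd_fraction=0.20,
        psa_iterations=10_000,
        rng_seed=12345,
    )
    p.validate(emit_warnings=emit_warnings)
    return p


def load_parameters(source: None | str | Path | Mapping[str, Any] = None,
                    emit_warnings: bool = True) -> ModelParameters:
    """Load a validated ledger from YAML text, a file path, or a mapping.

    A document may set ``use_defaults: true`` to start from the packaged
    base case and override only the fields it names; otherwise every field is
    required and a missing one raises :class:`ConfigurationError` naming it.
    ``None`` returns the packaged defaults.
    """
    if source is None:
        return default_parameters(emit_warnings=emit_warnings)
    if isinstance(source, Mapping):
        doc: dict[str, Any] = dict(source)
    else:
        text = None
        if isinstance(source, Path) or (isinstance(source, str) and os.path.exists(str(source))):
            text = Path(source).read_text()
        elif isinstance(source, str):
            text = source
        loaded = yaml.safe_load(text)
        if not isinstance(loaded, Mapping):
            raise ConfigurationError("configuration document must be a mapping")
        doc = dict(loaded)

    use_defaults = bool(doc.pop("use_defaults", False))
    if use_defaults:
        base = default_parameters(emit_warnings=False).to_dict()
        for key, val in doc.items():
            if key in _UNCERTAIN_FIELDS and isinstance(val, Mapping):
                merged = dict(base[key])
                merged.update(val)
                base[key] = merged
            else:
                base[key] = val
        doc = base
    params = ModelParameters.from_dict(doc)
    params.validate(emit_warnings=emit_warnings)
    return params


def dump_parameters(params: ModelParameters) -> str:
    """Serialise the ledger to YAML (round-trips through :func:`load_parameters`)."""
    return yaml.safe_dump(params.to_dict(), sort_keys=False)


def config_hash(params: ModelParameters) -> str:
    """SHA-256 of the canonical JSON form of the ledger (provenance tag)."""
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ----------------------------------------------------------------------
@dataclass
class ResultBundle:
    """Discounted per-strategy totals, incrementals and the WTP decision."""

    cost_empirical: float
    qaly_empirical: float
    cost_tgt: float
    qaly_tgt: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str | None
    decision: str
    wtp_per_qaly: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ResultBundle":
        return cls(**d)


def write_bundle_json(bundle: ResultBundle, path: str | Path) -> None:
    Path(path).write_text(json.dumps(bundle.to_dict(), indent=2) + "\n")


def read_bundle_json(path: str | Path) -> ResultBundle:
    return ResultBundle.from_dict(json.loads(Path(path).read_text()))


def bundle_to_frame(bundle: ResultBundle) -> pd.DataFrame:
    """Two strategy rows plus one incremental row (stable column order)."""
    rows = [
        {"row": "EMPIRICAL", "cost": bundle.cost_empirical, "qaly": bundle.qaly_empirical,
         "icer": np.nan},
        {"row": "TGT", "cost": bundle.cost_tgt, "qaly": bundle.qaly_tgt, "icer": np.nan},
        {"row": "incremental", "cost": bundle.delta_cost, "qaly": bundle.delta_qaly,
         "icer": np.nan if bundle.icer is None else bundle.icer},
    ]
    return pd.DataFrame(rows, columns=["row", "cost", "qaly", "icer"])


def write_trace_csv(trace, path: str | Path) -> None:
    """One row per cycle (cycle 0..N), full float precision."""
    trace.to_frame().to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps the written full-precision floats bit-exact
    return pd.read_csv(path, float_precision="round_trip")
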