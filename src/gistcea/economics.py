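"""Incremental cost-effectiveness arithmetic.

The decision quantity is the incremental cost-effectiveness ratio
ICER = ΔC / ΔQ between two strategies (comparator minus reference), judged
against a willingness-to-pay (WTP) threshold.  All decision logic routes
through net monetary benefit, NMB = WTP × QALY − cost, whose difference is
sign-robust where the ICER is not (dominance, ΔQ = 0); the ICER itself is
reported for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["IncrementalResult", "nmb", "icer", "cost_effective"]


def _cq(totals) -> tuple[float, float]:
    if hasattr(totals, "cost") and hasattr(totals, "qaly"):
        return float(totals.cost), float(totals.qaly)
    cost, qaly = totals
    return float(cost), float(qaly)


@dataclass
class IncrementalResult:
    """Comparator-vs-reference incrementals.

    ``icer`` is ``None`` when ΔQ = 0 or when a dominance flag applies;
    ``dominance`` is one of ``None``, ``"comparator dominates"`` (cheaper and
    more effective), ``"comparator dominated"``, ``"equivalent"`` or
    ``"cost difference only"`` (ΔQ = 0, ΔC ≠ 0).
    """

    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str | None
    wtp: float | None = None
    nmb_reference: float | None = None
    nmb_comparator: float | None = None


def nmb(totals, wtp: float) -> float:
    """Net monetary benefit, ``wtp × QALY − cost``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    cost, qaly = _cq(totals)
    return wtp * qaly - cost


def icer(reference, comparator, wtp: float | None = None) -> IncrementalResult:
    """Incremental cost, incremental QALYs and their ratio.

    ``reference`` and ``comparator`` are ``(cost, qaly)`` pairs or objects
    with ``cost`` / ``qaly`` attributes, on unrounded discounted totals.
    Dominance is classified before any division; ΔQ = 0 yields a
    "cost difference only" (or "equivalent") result rather than an exception.
    """
    ref_c, ref_q = _cq(reference)
    cmp_c, cmp_q = _cq(comparator)
    dc = cmp_c - ref_c
    dq = cmp_q - ref_q

    dominance: str | None = None
    ratio: float | None = None
    if dq == 0.0 and dc == 0.0:
        dominance = "equivalent"
    elif dq == 0.0:
        dominance = "cost difference only"
    elif dq > 0.0 and dc < 0.0:
        dominance = "comparator dominates"
    elif dq < 0.0 and dc > 0.0:
        dominance = "comparator dominated"
    else:
        ratio = dc / dq

    nmb_ref = nmb_cmp = None
    if wtp is not None:
        nmb_ref = nmb((ref_c, ref_q), wtp)
        nmb_cmp = nmb((cmp_c, cmp_q), wtp)
    return IncrementalResult(delta_cost=dc, delta_qaly=dq, icer=ratio,
                             dominance=dominance, wtp=wtp,
                             nmb_reference=nmb_ref, nmb_comparator=nmb_cmp)


def cost_effective(result: IncrementalResult, wtp: float | None = None) -> bool:
    """Is the comparator cost-effective at WTP?  Decided on NMB difference,
    which coincides with ``ICER ≤ WTP`` whenever ΔQ > 0."""
    if wtp is None:
        wtp = result.wtp
    if wtp is None:
        raise ValueError("a willingness-to-pay threshold is required")
    dnmb = wtp * result.delta_qaly - result.delta_cost
    return bool(dnmb >= 0.0)
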