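"""Survival representations, probability conversions and fixture generation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gistcea import survival as sv
from gistcea.survival import (
    AlignmentError,
    CoverageError,
    FixtureSpecError,
    ParametricSurvival,
    SurvivalCurve,
    SurvivalError,
    decompose_pfs,
    default_trial_spec,
    extend_longterm,
    fit_parametric,
    generate_fixture_trials,
    km_to_cycle_probs,
    prob_to_rate,
    rate_to_prob,
)


# ----------------------------------------------------------------------
# rate <-> probability
# ----------------------------------------------------------------------
@pytest.mark.parametrize("p,T,expected", [
    (0.033, 1.0, 0.0335560),   # monthly adverse-event probability -> rate
    (0.0, 1.0, 0.0),
    (0.5, 2.0, math.log(2) / 2),
])
def test_prob_to_rate_closed_forms(p, T, expected):
    assert prob_to_rate(p, T) == pytest.approx(expected, abs=1e-6)


def test_rate_to_prob_closed_form():
    # 1 - exp(-0.033556 * 2)
    assert rate_to_prob(0.033556, 2.0) == pytest.approx(0.0649095, abs=1e-6)
    assert rate_to_prob(0.0, 17.0) == 0.0


def test_conversion_domain_errors():
    with pytest.raises(SurvivalError, match="infinite"):
        prob_to_rate(1.0)
    with pytest.raises(SurvivalError):
        prob_to_rate(-0.1)
    with pytest.raises(SurvivalError):
        rate_to_prob(-0.01, 1.0)


@settings(derandomize=True, max_examples=200)
@given(p=st.floats(min_value=0.0, max_value=0.999999),
       T=st.floats(min_value=1e-3, max_value=120.0))
def test_prob_rate_round_trip(p, T):
    assert rate_to_prob(prob_to_rate(p, T), T) == pytest.approx(p, abs=1e-12)


def test_rate_to_prob_monotone_in_rate_and_period():
    rates = np.linspace(0.0, 0.5, 20)
    probs = [rate_to_prob(r, 2.0) for r in rates]
    assert np.all(np.diff(probs) > 0)
    periods = np.linspace(0.1, 24, 20)
    probs_t = [rate_to_prob(0.05, T) for T in periods]
    assert np.all(np.diff(probs_t) > 0)


# ----------------------------------------------------------------------
# curve -> per-cycle probabilities
# ----------------------------------------------------------------------
def _exp_curve(rate, t_max=120.0, **kw):
    t = np.arange(0.0, t_max + 0.5)
    defaults = dict(endpoint="PFS", genotype="exon11", drug="imatinib400")
    defaults.update(kw)
    return SurvivalCurve(times=t, survival=np.exp(-rate * t), **defaults)


def test_km_exponential_gives_constant_memoryless_schedule():
    p = km_to_cycle_probs(_exp_curve(0.1), 2.0, 60)
    np.testing.assert_allclose(p, 1 - math.exp(-0.2), rtol=1e-12)
    assert p[0] == pytest.approx(0.18127, abs=1e-5)


def test_km_constant_curve_gives_zero_probs():
    t = np.arange(0.0, 121.0)
    c = SurvivalCurve(endpoint="OS", genotype="other", drug="sunitinib",
                      times=t, survival=np.ones_like(t))
    assert np.all(km_to_cycle_probs(c, 2.0, 60) == 0.0)


def test_km_strictly_decreasing_curve_gives_positive_probs(curves):
    for curve in curves.values():
        p = km_to_cycle_probs(curve, 2.0, 60)
        assert np.all(p > 0)
        assert np.all(p <= 1)


def test_km_coverage_error():
    with pytest.raises(CoverageError):
        km_to_cycle_probs(_exp_curve(0.1, t_max=30.0), 2.0, 60)


def test_survival_reconstruction_from_schedule(curves):
    """prod(1 - p_i) reproduces the curve at cycle boundaries to 1e-9."""
    cm, n = 2.0, 60
    for key in [("exon11", "imatinib400", "PFS"), ("exon9", "sunitinib", "OS"),
                ("other", "imatinib800", "PFS")]:
        curve = curves[key]
        p = km_to_cycle_probs(curve, cm, n)
        s_rebuilt = np.cumprod(1.0 - p)
        bounds = np.arange(1, n + 1) * cm
        np.testing.assert_allclose(s_rebuilt, curve.evaluate(bounds), atol=1e-9)


def test_curve_invariants_enforced():
    t = np.arange(0.0, 10.0)
    with pytest.raises(SurvivalError):  # not monotone
        SurvivalCurve("PFS", "exon11", "imatinib400", t,
                      np.array([1, .9, .95, .8, .7, .6, .5, .4, .3, .2]))
    with pytest.raises(SurvivalError):  # S(0) != 1
        SurvivalCurve("PFS", "exon11", "imatinib400", t, np.linspace(0.9, 0.1, 10))


# ----------------------------------------------------------------------
# decomposition and long-term extension
# ----------------------------------------------------------------------
def test_decompose_rate_subtraction_closed_form():
    cm = 2.0
    pfs = np.full(5, rate_to_prob(0.10, cm))
    osp = np.full(5, rate_to_prob(0.03, cm))
    p_prog, p_death = decompose_pfs(pfs, osp, cm)
    np.testing.assert_allclose(p_prog, 1 - math.exp(-0.14), rtol=1e-10)
    assert p_prog[0] == pytest.approx(0.13064, abs=1e-5)
    np.testing.assert_array_equal(p_death, osp)  # death passes through


def test_decompose_identical_curves_gives_zero_progression():
    p = np.full(10, 0.1)
    p_prog, _ = decompose_pfs(p, p.copy(), 2.0)
    np.testing.assert_allclose(p_prog, 0.0, atol=1e-15)


def test_decompose_clamps_with_warning():
    pfs = np.full(4, 0.05)
    osp = np.full(4, 0.20)  # OS hazard exceeds PFS hazard
    with pytest.warns(UserWarning, match="clamped"):
        p_prog, _ = decompose_pfs(pfs, osp, 2.0)
    assert np.all(p_prog == 0.0)


def test_decompose_misaligned_grids():
    with pytest.raises(AlignmentError):
        decompose_pfs(np.zeros(5), np.zeros(6), 2.0)


def test_decompose_recombination_recovers_pfs_hazard(curves):
    """Where no clamping occurs, r_prog + r_death reproduces the PFS hazard."""
    cm = 2.0
    pfs = km_to_cycle_probs(curves[("exon9", "imatinib800", "PFS")], cm, 60)
    osp = km_to_cycle_probs(curves[("exon9", "imatinib800", "OS")], cm, 60)
    p_prog, p_death = decompose_pfs(pfs, osp, cm)
    r_recombined = (-np.log1p(-p_prog) - np.log1p(-p_death)) / cm
    r_pfs = -np.log1p(-pfs) / cm
    np.testing.assert_allclose(r_recombined, r_pfs, rtol=1e-10)


def test_extend_longterm_constant_tail():
    osp = np.full(60, 0.005)
    ext = extend_longterm(osp, 0.01, cycle_months=2.0, switch_month=36.0)
    np.testing.assert_array_equal(ext[:18], osp[:18])       # pre-switch unchanged
    assert ext[18] == pytest.approx(0.019900, abs=1e-6)      # 1 - 0.99^2
    assert np.all(ext[18:] == ext[18])


def test_extend_longterm_zero_prob_flattens_survival():
    osp = np.full(60, 0.01)
    ext = extend_longterm(osp, 0.0, cycle_months=2.0)
    s = np.cumprod(1 - ext)
    assert np.all(s[18:] == s[17])  # survival flat after month 36


def test_extend_longterm_no_jump_in_survival():
    """The splice changes the hazard, not the occupancy: S is continuous."""
    osp = np.full(60, 0.03)
    ext = extend_longterm(osp, 0.012, cycle_months=2.0)
    s = np.cumprod(1 - np.concatenate([[0.0], ext]))
    assert np.all(np.diff(s) <= 0)
    assert s[18] == pytest.approx(np.prod(1 - osp[:18]), rel=1e-12)


def test_extend_longterm_switch_beyond_horizon_warns():
    osp = np.full(12, 0.01)  # 24 months
    with pytest.warns(UserWarning, match="no-op"):
        out = extend_longterm(osp, 0.02, cycle_months=2.0, switch_month=24.0 + 1.0)
    np.testing.assert_array_equal(out, osp)


# ----------------------------------------------------------------------
# fixture generation and parametric fitting
# ----------------------------------------------------------------------
def test_fixture_generation_deterministic_for_fixed_seed():
    a = generate_fixture_trials(seed=17, noise_sd=0.02)
    b = generate_fixture_trials(seed=17, noise_sd=0.02)
    assert set(a) == set(b)
    for key in a:
        np.testing.assert_array_equal(a[key].survival, b[key].survival)
    c = generate_fixture_trials(seed=18, noise_sd=0.02)
    assert any(not np.array_equal(a[k].survival, c[k].survival) for k in a)


def test_fixture_noiseless_matches_parametric_exactly(curves):
    spec = default_trial_spec()
    for key, curve in curves.items():
        np.testing.assert_allclose(curve.survival, spec[key].survival(curve.times),
                                   atol=1e-15)


def test_fixture_spec_ordering_violations_rejected():
    spec = default_trial_spec()
    bad = dict(spec)
    # high-dose imatinib must beat low-dose on exon 9 PFS
    bad[("exon9", "imatinib800", "PFS")] = ParametricSurvival("exponential", 0.2)
    with pytest.raises(FixtureSpecError, match="exon 9"):
        generate_fixture_trials(seed=1, spec=bad)
    bad = dict(spec)
    # OS must be equivalent across imatinib doses within genotype
    bad[("exon11", "imatinib800", "OS")] = ParametricSurvival("exponential", 0.05)
    with pytest.raises(FixtureSpecError, match="equivalent"):
        generate_fixture_trials(seed=1, spec=bad)


def test_fit_exponential_recovers_rate_exactly():
    fit = fit_parametric(_exp_curve(0.05), "exponential")
    assert fit.rate == pytest.approx(0.05, abs=1e-9)


def test_fit_weibull_on_exponential_data_gives_unit_shape():
    fit = fit_parametric(_exp_curve(0.05), "weibull")
    assert fit.shape == pytest.approx(1.0, abs=1e-6)
    assert fit.rate == pytest.approx(0.05, rel=1e-6)


def test_fit_flat_curve_returns_zero_rate_with_warning():
    t = np.arange(0.0, 20.0)
    c = SurvivalCurve("PFS", "exon11", "imatinib400", t, np.ones_like(t))
    with pytest.warns(UserWarning, match="flat"):
        fit = fit_parametric(c, "exponential")
    assert fit.rate == 0.0


def test_noiseless_fixture_fit_recovers_generating_rate():
    curves = generate_fixture_trials(seed=23, noise_sd=0.0)
    spec = default_trial_spec()
    key = ("exon11", "imatinib400", "PFS")
    fit = fit_parametric(curves[key], "exponential")
    assert fit.rate == pytest.approx(spec[key].rate, abs=1e-6)


@pytest.mark.parametrize("seed", [101, 202, 303])
def test_noisy_fixture_fit_recovers_rate_within_tolerance(seed):
    curves = generate_fixture_trials(seed=seed, noise_sd=0.05)
    spec = default_trial_spec()
    for key in [("exon9", "imatinib400", "PFS"), ("exon11", "imatinib400", "OS")]:
        fit = fit_parametric(curves[key], "exponential")
        assert fit.rate == pytest.approx(spec[key].rate, rel=0.05)


def test_curve_csv_round_trip(tmp_path, curves):
    key = ("exon9", "imatinib800", "PFS")
    path = tmp_path / "curve.csv"
    sv.write_curve_csv(curves[key], path)
    back = sv.read_curve_csv(path, "PFS", "exon9", "imatinib800")
    np.testing.assert_array_equal(back.times, curves[key].times)
    np.testing.assert_array_equal(back.survival, curves[key].survival)
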