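"""One-way / scenario / horizon sweeps and the probabilistic analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gistcea import markov
from gistcea.sensitivity import (
    AddressingError,
    ParameterizationError,
    get_param,
    horizon_sweep,
    market_share_scenario,
    moment_match,
    nmb_difference,
    one_way,
    psa,
    sample_distribution,
    sd_fraction_sweep,
    set_param,
)


# ----------------------------------------------------------------------
# parameter addressing and linked rules
# ----------------------------------------------------------------------
def test_get_set_scalar_paths(params):
    assert get_param(params, "cost_tgt.mean") == 2919.0
    assert get_param(params, "cost_tgt") == 2919.0  # bare name resolves to mean
    p2 = set_param(params, "wtp_per_qaly", 50_000.0)
    assert p2.wtp_per_qaly == 50_000.0
    assert params.wtp_per_qaly == 100_000.0  # original untouched


def test_invalid_path_raises_addressing_error(params):
    with pytest.raises(AddressingError):
        get_param(params, "cost_of_nothing")
    with pytest.raises(AddressingError):
        set_param(params, "cost_tgt.nonsense", 1.0)


def test_imatinib_cost_link_preserves_price_structure(params):
    p2 = set_param(params, "cost_imatinib400_year", 69_924.0)
    assert p2.cost_imatinib800_year.mean == pytest.approx(2 * 69_924.0)
    assert p2.imatinib400_weighted_price() == pytest.approx(69_924.0, abs=1.0)
    p2.validate(emit_warnings=False)


def test_prevalence_links_keep_simplex(params):
    p2 = set_param(params, "prevalence_exon9", 0.117)
    total = p2.prevalence_exon9 + p2.prevalence_exon11 + p2.prevalence_other
    assert total == pytest.approx(1.0, abs=1e-12)
    # exon11:other ratio preserved
    assert p2.prevalence_exon11 / p2.prevalence_other == pytest.approx(0.67 / 0.18)
    p3 = set_param(params, "prevalence_exon11", 0.5)
    assert p3.prevalence_exon9 == params.prevalence_exon9
    assert p3.prevalence_other == pytest.approx(1.0 - 0.15 - 0.5)


# ----------------------------------------------------------------------
# one-way grids and thresholds
# ----------------------------------------------------------------------
def test_icer_affine_increasing_in_tgt_cost(params, curves):
    # range kept above the point where TGT becomes cost-saving (no ratio there)
    grid = one_way("cost_tgt", 2000.0, 6000.0, 9, params, curves)
    d = np.diff(grid.icers)
    assert np.all(d > 0)
    assert np.allclose(d, d[0], rtol=1e-6)  # affine: constant slope
    emp, tgt = markov.evaluate_strategies(params, curves)
    dq = tgt.qaly - emp.qaly
    slope = d[0] / (grid.values[1] - grid.values[0])
    assert slope == pytest.approx(1.0 / dq, rel=1e-6)


def test_parameter_touching_only_shared_pathways_gives_flat_grid(params, curves):
    """Exon 11 prevalence trades against 'other' only; both genotypes follow
    identical sequences in both strategies, so the ICER cannot move."""
    grid = one_way("prevalence_exon11", 0.30, 0.70, 5, params, curves)
    assert np.allclose(grid.icers, grid.icers[0], rtol=1e-9)
    assert grid.threshold is None


def test_threshold_satisfies_nmb_tolerance(params, curves):
    grid = one_way("cost_tgt", 0.0, 30_000.0, 31, params, curves)
    assert grid.threshold is not None
    p2 = set_param(params, "cost_tgt", grid.threshold)
    assert abs(nmb_difference(p2, curves)) <= 1.0


def test_threshold_none_when_no_flip(params, curves):
    grid = one_way("cost_tgt", 0.0, 1000.0, 5, params, curves)
    assert grid.threshold is None


def test_one_way_requires_increasing_range(params, curves):
    with pytest.raises(ValueError):
        one_way("cost_tgt", 10.0, 10.0, 3, params, curves)


# ----------------------------------------------------------------------
# scenarios and horizons
# ----------------------------------------------------------------------
def test_market_share_base_reproduces_base_case(params, curves):
    bundle = market_share_scenario(0.5, params, curves)
    base = markov.base_case(params, curves)
    assert bundle.cost_empirical == pytest.approx(base.cost_empirical, rel=1e-12)
    assert bundle.icer == pytest.approx(base.icer, rel=1e-12)


def test_market_share_extremes_use_single_price(params, curves):
    from gistcea.sensitivity import scenario_parameters

    all_generic = scenario_parameters(1.0, params)
    assert all_generic.cost_imatinib400_year.mean == params.price_generic_imatinib400_year
    all_brand = scenario_parameters(0.0, params)
    assert all_brand.cost_imatinib400_year.mean == params.price_brand_imatinib400_year


def test_horizon_sweep_consistency_with_base(params, curves):
    df = horizon_sweep([10], params, curves)
    base = markov.base_case(params, curves)
    assert df["icer"].iloc[0] == base.icer  # bit-for-bit


def test_horizon_must_be_whole_cycles(params, curves):
    with pytest.raises(ValueError):
        horizon_sweep([2.5 / 12], params, curves)


# ----------------------------------------------------------------------
# distributions
# ----------------------------------------------------------------------
def test_moment_match_gamma_closed_form():
    spec = moment_match("gamma", 2919.0, 583.8)  # sd = 20% of mean
    assert spec["shape"] == pytest.approx(25.0, rel=1e-12)
    assert spec["scale"] == pytest.approx(116.76, rel=1e-12)


def test_moment_match_degenerates_at_zero_sd():
    assert moment_match("gamma", 10.0, 0.0) == {"family": "fixed", "value": 10.0}


def test_moment_match_beta_feasibility():
    with pytest.raises(ParameterizationError):
        moment_match("beta", 0.5, 0.6)
    with pytest.raises(ParameterizationError):
        moment_match("beta", 1.2, 0.1)


@settings(derandomize=True, max_examples=200)
@given(mean=st.floats(0.01, 0.99), frac=st.floats(0.01, 0.9))
def test_moment_match_beta_round_trip(mean, frac):
    sd = frac * np.sqrt(mean * (1 - mean))
    spec = moment_match("beta", mean, sd)
    a, b = spec["alpha"], spec["beta"]
    m = a / (a + b)
    v = a * b / ((a + b) ** 2 * (a + b + 1))
    assert m == pytest.approx(mean, abs=1e-12)
    assert np.sqrt(v) == pytest.approx(sd, abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(mean=st.floats(1.0, 1e5), frac=st.floats(0.05, 1.5))
def test_moment_match_gamma_round_trip(mean, frac):
    sd = frac * mean
    spec = moment_match("gamma", mean, sd)
    assert spec["shape"] * spec["scale"] == pytest.approx(mean, rel=1e-12)
    assert np.sqrt(spec["shape"]) * spec["scale"] == pytest.approx(sd, rel=1e-12)


def test_sampled_moments_converge():
    rng = np.random.default_rng(7)
    n = 1_000_000
    for family, mean, sd in [("gamma", 2919.0, 583.8), ("beta", 0.065, 0.0133)]:
        x = sample_distribution(rng, moment_match(family, mean, sd), n)
        se = sd / np.sqrt(n)
        assert abs(x.mean() - mean) < 3 * se


# ----------------------------------------------------------------------
# probabilistic sensitivity analysis
# ----------------------------------------------------------------------
def test_psa_reproducible_for_fixed_seed(params, curves):
    a = psa(params, curves, n_iter=300, seed=42)
    b = psa(params, curves, n_iter=300, seed=42)
    np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
    np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)
    assert a.ce_probability == b.ce_probability
    c = psa(params, curves, n_iter=300, seed=43)
    assert not np.array_equal(a.delta_cost, c.delta_cost)


def test_psa_degenerate_collapses_to_base_case(params, curves):
    p = params.copy()
    for name in ("p_ae_imatinib400_month", "p_ae_imatinib800_month",
                 "p_ae_sunitinib_month"):
        getattr(p, name).sd_override = 0.0
    res = psa(p, curves, n_iter=50, seed=5, sd_fraction=0.0,
              hazard_uncertainty=False)
    base = markov.base_case(p, curves)
    np.testing.assert_allclose(res.delta_cost, base.delta_cost, rtol=1e-9)
    np.testing.assert_allclose(res.delta_qaly, base.delta_qaly, rtol=1e-9)
    deterministic_ce = base.decision == "cost-effective"
    assert res.ce_probability == (1.0 if deterministic_ce else 0.0)


def test_ceac_at_zero_wtp_counts_cost_savings(params, curves):
    res = psa(params, curves, n_iter=500, seed=9)
    direct = float(np.mean(res.delta_cost <= 0.0))
    assert res.ceac_probability[0] == pytest.approx(direct, abs=1e-12)
    assert res.ceac_wtp[0] == 0.0
    assert np.all((res.ceac_probability >= 0) & (res.ceac_probability <= 1))


def test_psa_cloud_shapes_and_summary(params, curves):
    res = psa(params, curves, n_iter=200, seed=11)
    assert res.delta_cost.shape == (200,)
    assert 0.0 <= res.ce_probability <= 1.0
    df = res.to_frame()
    assert len(df) == 200
    ce_direct = float(np.mean(res.wtp * res.delta_qaly - res.delta_cost >= 0))
    assert res.ce_probability == pytest.approx(ce_direct, abs=1e-12)


def test_sd_fraction_sweep(params, curves):
    with pytest.warns(UserWarning, match="capped"):
        df = sd_fraction_sweep([0.1, 0.2, 0.4], params, curves,
                               n_iter=200, seed=3)
    assert list(df["sd_fraction"]) == [0.1, 0.2, 0.4]
    assert df["ce_probability"].between(0, 1).all()
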