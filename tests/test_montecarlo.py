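"""Monte Carlo engine: oracle equivalence, convergence, determinism, reporting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhdrisk import (
    ANY_HARM,
    DistributionSpec,
    ValidationError,
    chain_probability,
    credibility_interval,
    format_reciprocal,
    round_sig,
    run_simulation,
    to_reciprocal,
)
from rhdrisk.montecarlo import NO_EVENTS, draw_event_samples
from tests.conftest import make_chain_config, make_single_event_config, quantile_oracle


def test_point_mass_inputs_reproduce_analytic_product_exactly():
    """With degenerate inputs every iteration equals the chain product and the
    credibility interval has zero width."""
    cfg = make_chain_config([0.5, 0.2, 0.1])
    est = run_simulation(cfg, "pop", iterations=200, seed=1)
    analytic = chain_probability(cfg, "harm")
    assert np.all(est["harm"].samples == analytic)
    # sample mean agrees to within pairwise-summation rounding (1 ulp)
    assert est["harm"].mean_probability == pytest.approx(analytic, rel=1e-14)
    assert est["harm"].ci_low_probability == est["harm"].ci_high_probability == analytic
    assert est[ANY_HARM].mean_probability == pytest.approx(analytic, rel=1e-14)


def test_uniform_single_event_mean_and_quantiles():
    """A one-event chain driven by U(0,1): mean 0.5 and 95% CI ~ (0.025, 0.975)."""
    n = 100_000
    cfg = make_single_event_config(DistributionSpec("N1", "uniform", (0.0, 1.0)))
    est = run_simulation(cfg, "pop", iterations=n, seed=9)["harm"]
    se = math.sqrt(1.0 / 12.0 / n)
    assert abs(est.mean_probability - 0.5) < 3 * se
    assert est.ci_low_probability == pytest.approx(0.025, abs=0.005)
    assert est.ci_high_probability == pytest.approx(0.975, abs=0.005)


def test_same_seed_same_config_is_bit_identical(default_cfg):
    a = run_simulation(default_cfg, "all_recipients", seed=42)
    b = run_simulation(default_cfg, "all_recipients", seed=42)
    for hid in a:
        assert np.array_equal(a[hid].samples, b[hid].samples)
        assert a[hid].summary() == b[hid].summary()
    c = run_simulation(default_cfg, "all_recipients", seed=43)
    assert not np.array_equal(a["hdfn"].samples, c["hdfn"].samples)


def test_substream_independence_across_inputs(default_cfg):
    """Re-parametrising one input leaves every other input's draws unchanged."""
    from rhdrisk import conditional_fix

    base = draw_event_samples(default_cfg, "all_recipients", 500, seed=3)
    altered = conditional_fix(default_cfg, "N7", 0.5)
    after = draw_event_samples(altered, "all_recipients", 500, seed=3)
    for eid in base:
        if default_cfg.events[eid].input_ref == "N7":
            continue
        assert np.array_equal(base[eid], after[eid]), eid


def test_any_harm_is_capped_additive_combination(default_cfg):
    est = run_simulation(default_cfg, "dneg_females_cbp", iterations=400, seed=5)
    summed = sum(est[h].samples for h in default_cfg.harms)
    assert np.array_equal(est[ANY_HARM].samples, np.minimum(1.0, summed))
    assert est[ANY_HARM].mean_probability >= max(
        est[h].mean_probability for h in default_cfg.harms
    )


def test_unknown_population_rejected(default_cfg):
    with pytest.raises(ValidationError, match="nowhere"):
        run_simulation(default_cfg, "nowhere")


class TestCredibilityInterval:
    def test_constant_samples_collapse(self):
        assert credibility_interval([3.0] * 10, 0.95) == (3.0, 3.0)

    def test_matches_sort_based_oracle_on_1_to_1000(self):
        xs = np.arange(1, 1001, dtype=float)
        lo, hi = credibility_interval(xs, 0.95)
        assert lo == pytest.approx(quantile_oracle(xs, 0.025))
        assert hi == pytest.approx(quantile_oracle(xs, 0.975))

    @settings(max_examples=50, derandomize=True)
    @given(
        xs=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
        level=st.floats(0.0, 0.99),
    )
    def test_matches_oracle_for_arbitrary_samples(self, xs, level):
        lo, hi = credibility_interval(xs, level)
        tail = (1 - level) / 2
        assert lo == pytest.approx(quantile_oracle(xs, tail), abs=1e-6)
        assert hi == pytest.approx(quantile_oracle(xs, 1 - tail), abs=1e-6)
        assert lo <= hi

    def test_level_zero_collapses_to_median(self):
        xs = [1.0, 2.0, 10.0]
        assert credibility_interval(xs, 0.0) == (2.0, 2.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            credibility_interval([], 0.95)


class TestReciprocalForm:
    def test_basic_arithmetic(self):
        assert to_reciprocal(0.002) == pytest.approx(500)
        assert to_reciprocal(1.0) == 1.0

    def test_two_sig_fig_display_of_summed_risk(self):
        """The reciprocal of the all-recipient summed risk rounds to 1.4e4."""
        p = 1 / 27000 + 1 / 850000 + 1 / 29000
        assert p == pytest.approx(7.2696e-5, rel=1e-4)
        assert round_sig(to_reciprocal(p)) == 1.4e4

    def test_zero_probability_is_a_sentinel_not_an_error(self):
        assert math.isinf(to_reciprocal(0.0))
        assert format_reciprocal(0.0) == NO_EVENTS

    def test_display_formatting(self):
        assert format_reciprocal(0.002) == "1 in 500"
        with pytest.raises(ValidationError):
            to_reciprocal(-0.1)


def test_round_sig():
    assert round_sig(4.855) == 4.9
    assert round_sig(13762.3) == 14000
    assert round_sig(0.0) == 0.0
    assert round_sig(522.8, 3) == 523


def test_risk_estimate_reciprocal_ci_is_sorted_ascending(default_cfg):
    est = run_simulation(default_cfg, "all_recipients", iterations=500, seed=2)
    for e in est.values():
        lo_n, hi_n = e.reciprocal_ci
        assert lo_n <= hi_n
        assert lo_n == pytest.approx(1.0 / e.ci_high_probability)
        assert hi_n == pytest.approx(1.0 / e.ci_low_probability)
        assert len(e.samples) == 500
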