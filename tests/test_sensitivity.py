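"""Sobol first-order indices: closed-form toy models, a brute-force
double-loop oracle, and scatter export."""

import numpy as np
import pytest

from rhdrisk import (
    DistributionSpec,
    ValidationError,
    all_first_order_indices,
    first_order_index,
    pick_freeze_first_order,
    scatter_export,
)
from rhdrisk.distributions import substream
from tests.conftest import make_chain_config, make_single_event_config

U01 = lambda name: DistributionSpec(name, "uniform", (0.0, 1.0))  # noqa: E731


def double_loop_index(dists, func, index, outer=256, inner=2048, seed=0):
    """Independent brute-force estimate of Var(E[Y|X_i]) / Var(Y).

    Outer loop over fixed values of input ``index``; inner loop re-samples all
    other inputs and averages the output.  Slow but assumption-free.
    """
    rng = np.random.default_rng([seed, 101])
    cond_means = np.empty(outer)
    for j in range(outer):
        xi = dists[index].sample(rng)
        cols = []
        for i, d in enumerate(dists):
            if i == index:
                cols.append(np.full(inner, xi))
            else:
                cols.append(np.asarray(d.sample(rng, inner)))
        cond_means[j] = func(np.column_stack(cols)).mean()
    big = np.column_stack(
        [np.asarray(d.sample(rng, outer * inner)) for d in dists]
    )
    return np.var(cond_means) / np.var(func(big))


def _replicated(dists, func, index, n=2**13, seeds=range(5)):
    return np.array(
        [pick_freeze_first_order(dists, func, index, n=n, seed=s) for s in seeds]
    )


class TestLinearToyModel:
    """Y = N1 + 2*N2 with independent U(0,1) inputs: S1 = 1/5, S2 = 4/5."""

    def test_closed_form_recovery_within_replication_noise(self):
        dists = [U01("u1"), U01("u2")]
        func = lambda X: X[:, 0] + 2.0 * X[:, 1]  # noqa: E731
        for index, truth in [(0, 0.2), (1, 0.8)]:
            est = _replicated(dists, func, index)
            sd = est.std(ddof=1)
            assert abs(est.mean() - truth) < 3 * max(sd, 1e-3)

    def test_indices_sum_to_one_for_additive_model(self):
        dists = [U01("u1"), U01("u2")]
        func = lambda X: X[:, 0] + 2.0 * X[:, 1]  # noqa: E731
        s = sum(
            pick_freeze_first_order(dists, func, i, n=2**14, seed=3) for i in (0, 1)
        )
        assert s == pytest.approx(1.0, abs=0.05)


def test_pick_freeze_matches_double_loop_oracle_on_product_model():
    """Two-input multiplicative model Y = N1*N2 with unequal uncertainty."""
    dists = [
        DistributionSpec("n1", "uniform", (0.1, 0.9)),
        DistributionSpec("n2", "beta", (2.0, 5.0)),
    ]
    func = lambda X: X[:, 0] * X[:, 1]  # noqa: E731
    for index in (0, 1):
        pf = _replicated(dists, func, index)
        oracle = double_loop_index(dists, func, index)
        sd = pf.std(ddof=1)
        assert abs(pf.mean() - oracle) < 3 * max(sd, 0.02)


def test_point_mass_input_has_zero_index():
    cfg = make_chain_config([0.5, 0.2])  # all point masses -> zero variance too
    cfg.inputs["N1"] = DistributionSpec("N1", "uniform", (0.3, 0.7))
    res = first_order_index(cfg, "N2", output_id="harm", n=2**12, seed=0)
    assert res.s_index == 0.0


def test_single_input_chain_attributes_all_variance():
    cfg = make_single_event_config(DistributionSpec("N1", "uniform", (0.0, 1.0)))
    reps = np.array(
        [
            first_order_index(cfg, "N1", output_id="harm", n=2**13, seed=s).s_index_raw
            for s in range(5)
        ]
    )
    assert abs(reps.mean() - 1.0) < 3 * max(reps.std(ddof=1), 0.02)


def test_zero_output_variance_warns_and_returns_zero():
    cfg = make_chain_config([0.5, 0.2])
    with pytest.warns(UserWarning, match="variance"):
        res = first_order_index(cfg, "N1", output_id="harm", n=256, seed=0)
    assert res.s_index_raw == 0.0


def test_chain_model_indices_sum_to_at_most_one(default_cfg):
    results = all_first_order_indices(
        default_cfg, output_id="any_harm", population_id="all_recipients",
        n=2**12, seed=2,
    )
    total = sum(r.s_index_raw for r in results.values())
    assert total <= 1.0 + 0.1
    assert all(np.isfinite(r.s_index_raw) for r in results.values())


def test_unknown_ids_rejected(default_cfg):
    with pytest.raises(ValidationError, match="N99"):
        first_order_index(default_cfg, "N99")
    with pytest.raises(ValidationError, match="ghost_harm"):
        first_order_index(default_cfg, "N1", output_id="ghost_harm")
    with pytest.raises(ValidationError, match="N99"):
        scatter_export(default_cfg, "N99")


class TestScatterExport:
    def test_single_event_chain_lies_on_identity_line(self):
        cfg = make_single_event_config(DistributionSpec("N1", "uniform", (0.0, 1.0)))
        pairs = scatter_export(cfg, "N1", output_id="harm", iterations=500, seed=3)
        assert pairs.shape == (500, 2)
        assert np.array_equal(pairs[:, 0], pairs[:, 1])

    def test_point_mass_input_gives_constant_abscissae(self, default_cfg):
        from rhdrisk import conditional_fix

        cfg = conditional_fix(default_cfg, "N7", 0.2)
        pairs = scatter_export(cfg, "N7", iterations=100, seed=3)
        assert np.all(pairs[:, 0] == 0.2)

    def test_pairs_match_simulation_draws_bit_exactly(self, default_cfg):
        from rhdrisk import run_simulation

        pairs1 = scatter_export(
            default_cfg, "N7", output_id="hdfn",
            population_id="all_recipients", iterations=400, seed=7,
        )
        pairs2 = scatter_export(
            default_cfg, "N7", output_id="hdfn",
            population_id="all_recipients", iterations=400, seed=7,
        )
        assert np.array_equal(pairs1, pairs2)
        est = run_simulation(default_cfg, "all_recipients", iterations=400, seed=7)
        assert np.array_equal(pairs1[:, 1], est["hdfn"].samples)
        draws = default_cfg.inputs["N7"].sample(substream(7, "input", "N7"), 400)
        assert np.array_equal(pairs1[:, 0], draws)

    def test_conditioning_on_an_input_shifts_the_output(self, default_cfg):
        """Fixing the alloimmunization input at a high vs low value shifts the
        conditional risk distribution, the reading behind the scatterplot."""
        from rhdrisk import conditional_fix, run_simulation

        low = conditional_fix(default_cfg, "N7", 0.10)
        high = conditional_fix(default_cfg, "N7", 0.40)
        m_low = run_simulation(low, "dneg_females_cbp", iterations=2000, seed=1)
        m_high = run_simulation(high, "dneg_females_cbp", iterations=2000, seed=1)
        assert (
            m_high["any_harm"].mean_probability
            > 2 * m_low["any_harm"].mean_probability
        )
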