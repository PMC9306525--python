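import numpy as np
import pytest

from rhdrisk import (
    DistributionSpec,
    EventNode,
    HarmDefinition,
    ModelConfig,
    MonteCarloConfig,
    PopulationSpec,
    default_config,
)


def make_chain_config(probabilities, harm_id="harm", population_id="pop", **mc_kwargs):
    """A single-harm config whose events are point masses at `probabilities`."""
    inputs, events, chain = {}, {}, []
    for i, p in enumerate(probabilities, start=1):
        iid, eid = f"N{i}", f"X{i}"
        inputs[iid] = DistributionSpec(iid, "point", (float(p),))
        events[eid] = EventNode(eid, f"event {i}", iid)
        chain.append(eid)
    return ModelConfig(
        inputs=inputs,
        events=events,
        harms={harm_id: HarmDefinition(harm_id, "test harm", tuple(chain))},
        populations={population_id: PopulationSpec(population_id, "test", 83.0, 67_000_000)},
        mc=MonteCarloConfig(**{"iterations": 1000, "seed": 7, **mc_kwargs}),
    )


def make_single_event_config(spec: DistributionSpec, **mc_kwargs):
    """A one-event chain driven by an arbitrary input distribution."""
    return ModelConfig(
        inputs={spec.input_id: spec},
        events={"X1": EventNode("X1", "event", spec.input_id)},
        harms={"harm": HarmDefinition("harm", "test harm", ("X1",))},
        populations={"pop": PopulationSpec("pop", "test", 83.0, 67_000_000)},
        mc=MonteCarloConfig(**{"iterations": 1000, "seed": 7, **mc_kwargs}),
    )


def quantile_oracle(samples, q):
    """Brute-force linear-interpolation quantile from sorted order statistics."""
    xs = sorted(float(v) for v in samples)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def product_sample_variance(moments):
    """Variance of a product of independent inputs from per-input (mean, var)."""
    second = 1.0
    mean_sq = 1.0
    for m, v in moments:
        second *= v + m * m
        mean_sq *= m * m
    return second - mean_sq


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()
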