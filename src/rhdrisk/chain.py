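"""Analytic evaluation of the event chain.

A harm occurs only if every contingent event in its chain occurs, so with
fixed per-event conditional probabilities the per-transfusion harm probability
is simply the product along the chain.  The overall "any harm" risk is the
*sum* of the per-harm probabilities (capped at 1): at the probability scales
of interest (1e-5 .. 1e-3 per transfusion) the additive form and the exact
union 1 - prod(1 - p_i) differ by far less than display precision; the exact
union is available behind ``method="union"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .config import ModelConfig
from .distributions import DistributionSpec, ValidationError

__all__ = [
    "ChainEvaluation",
    "PolicyMix",
    "chain_probability",
    "evaluate_chain",
    "analytic_chain_mean",
    "combined_risk",
    "apply_policy_mix",
    "conditional_fix",
]


@dataclass(frozen=True)
class ChainEvaluation:
    """Per-event probabilities and the resulting per-transfusion harm probability."""

    harm_id: str
    per_event_probabilities: dict[str, float]
    harm_probability: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "harm_id": self.harm_id,
                "per_event_probabilities": self.per_event_probabilities,
                "harm_probability": self.harm_probability,
            }
        )


@dataclass(frozen=True)
class PolicyMix:
    """Fraction of prehospital transfusion episodes served with D-positive units.

    The base case is exclusive D-positive use (``dpos_fraction = 1``); a 50:50
    mix with D-negative units halves every exposure-driven risk.
    """

    dpos_fraction: float

    def __post_init__(self):
        if not (0.0 <= self.dpos_fraction <= 1.0):
            raise ValidationError(
                f"dpos_fraction {self.dpos_fraction} outside [0, 1]"
            )


def _resolve_event_probability(
    config: ModelConfig,
    event_id: str,
    fixed: Mapping[str, float],
    population_id: str | None,
) -> float:
    if event_id in fixed:
        p = float(fixed[event_id])
    else:
        spec = config.event_distribution(event_id, population_id)
        if spec.family != "point":
            raise ValidationError(
                f"no probability given for event {event_id!r} and its input "
                f"({spec.input_id!r}, family {spec.family!r}) is not a point mass",
                event_id,
            )
        p = spec.params[0]
    if not (0.0 <= p <= 1.0):
        raise ValidationError(
            f"event {event_id!r}: probability {p} outside [0, 1]", event_id
        )
    return p


def evaluate_chain(
    config: ModelConfig,
    harm_id: str,
    fixed_probabilities: Mapping[str, float] | None = None,
    population_id: str | None = None,
) -> ChainEvaluation:
    """Evaluate one harm chain with fixed per-event probabilities.

    Probabilities come from ``fixed_probabilities`` where given, otherwise
    from point-mass inputs (after population overrides).  An event with
    neither is an error naming the event.
    """
    if harm_id not in config.harms:
        raise ValidationError(f"unknown harm {harm_id!r}", harm_id)
    fixed = fixed_probabilities or {}
    per_event: dict[str, float] = {}
    prob = 1.0
    for eid in config.harms[harm_id].chain:
        p = _resolve_event_probability(config, eid, fixed, population_id)
        per_event[eid] = p
        prob *= p
    return ChainEvaluation(harm_id, per_event, prob)


def chain_probability(
    config: ModelConfig,
    harm_id: str,
    fixed_probabilities: Mapping[str, float] | None = None,
    population_id: str | None = None,
) -> float:
    """Per-transfusion probability of one harm: product along its chain."""
    return evaluate_chain(config, harm_id, fixed_probabilities, population_id).harm_probability


def analytic_chain_mean(
    config: ModelConfig, harm_id: str, population_id: str | None = None
) -> float:
    """Expected harm probability under input uncertainty.

    Because inputs are sampled independently, the mean of the product is the
    product of the per-event input means.  This is the analytic ground truth
    the Monte Carlo mean must converge to.
    """
    if harm_id not in config.harms:
        raise ValidationError(f"unknown harm {harm_id!r}", harm_id)
    prob = 1.0
    for eid in config.harms[harm_id].chain:
        prob *= config.event_distribution(eid, population_id).mean()
    return prob


def combined_risk(
    harm_probabilities: Iterable[float], method: str = "additive"
) -> float:
    """Probability that any of several harms occurs.

    ``additive`` (default) sums the per-harm probabilities and caps at 1;
    ``union`` computes the exact 1 - prod(1 - p_i).  For risks of order 1e-3
    or smaller the two differ by < 1e-5.
    """
    probs = [float(p) for p in harm_probabilities]
    if not probs:
        raise ValidationError("combined_risk of an empty collection")
    for p in probs:
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"harm probability {p} outside [0, 1]")
    if method == "additive":
        return min(1.0, sum(probs))
    if method == "union":
        q = 1.0
        for p in probs:
            q *= 1.0 - p
        return 1.0 - q
    raise ValidationError(f"unknown combination method {method!r}")


def apply_policy_mix(harm_probability: float, mix: PolicyMix) -> float:
    """Scale a per-episode harm probability by the D-positive issue fraction.

    Exposure scales linearly at the transfusion-episode level; unit counts
    within an episode are not modelled.
    """
    if not (0.0 <= harm_probability <= 1.0):
        raise ValidationError(f"harm probability {harm_probability} outside [0, 1]")
    return harm_probability * mix.dpos_fraction


def conditional_fix(
    config: ModelConfig, input_id: str, fixed_value: float
) -> ModelConfig:
    """Return a config with one input replaced by a point mass at ``fixed_value``.

    This is the conditioning operation behind scatterplot sensitivity reading
    ("if the alloimmunization risk were exactly v ..."): all other inputs keep
    their distributions, so a Monte Carlo run on the result is the conditional
    risk distribution given that input value.
    """
    if input_id not in config.inputs:
        raise ValidationError(f"unknown input {input_id!r}", input_id)
    old = config.inputs[input_id]
    new = DistributionSpec(
        input_id=input_id,
        family="point",
        params=(float(fixed_value),),
        description=old.description,
        source_note=f"fixed at {fixed_value} (was {old.family}{old.params})",
    )
    inputs = dict(config.inputs)
    inputs[input_id] = new
    return replace(config, inputs=inputs)
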