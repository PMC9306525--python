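"""Monte Carlo propagation of input uncertainty through the event chain.

Each iteration draws one value per model input from its distribution, then
evaluates every harm chain (product along the chain) and the additive "any
harm" combination.  The sample of per-iteration harm probabilities summarises
the uncertainty: its mean is the point estimate and its equal-tailed empirical
quantiles form the credibility interval.  Results are reported both as
probabilities and in reciprocal "one event per N transfusions" form, with
2-significant-figure display rounding; raw values are always retained.

Sampling uses one root seed with per-input substreams, so every input's draws
are independent of which other inputs exist or which families they use, and
the same seed with the same config is bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .distributions import ValidationError, substream

__all__ = [
    "ANY_HARM",
    "RiskEstimate",
    "round_sig",
    "to_reciprocal",
    "format_reciprocal",
    "credibility_interval",
    "draw_event_samples",
    "run_simulation",
]

#: harm_id used for the additive combination of all harms
ANY_HARM = "any_harm"

#: display sentinel for a zero probability
NO_EVENTS = "no events expected"


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention of the tables)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def to_reciprocal(p: float) -> float:
    """Convert a per-transfusion probability to "one event per N transfusions".

    A zero probability maps to ``inf`` (rendered as "no events expected"),
    not a division error.
    """
    if p < 0:
        raise ValidationError(f"probability {p} is negative")
    return math.inf if p == 0 else 1.0 / p


def format_reciprocal(p: float, sig: int = 2) -> str:
    """Human-readable reciprocal form, e.g. ``0.002`` -> ``"1 in 500"``."""
    r = to_reciprocal(p)
    if math.isinf(r):
        return NO_EVENTS
    r = round_sig(r, sig)
    return f"1 in {r:g}"


def credibility_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed empirical interval of a Monte Carlo output sample.

    Quantiles at ``(1-level)/2`` and ``1-(1-level)/2``, linear interpolation
    between order statistics.  ``level -> 0`` collapses to the median.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValidationError("credibility interval of an empty sample")
    if not (0.0 <= level <= 1.0):
        raise ValidationError(f"ci level {level} outside [0, 1]")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [tail, 1.0 - tail], method="linear")
    return float(lo), float(hi)


@dataclass(eq=False)
class RiskEstimate:
    """Monte Carlo summary of one harm's per-transfusion risk in one population."""

    harm_id: str
    population_id: str
    samples: np.ndarray
    ci_level: float = 0.95
    mean_probability: float = field(init=False)
    ci_low_probability: float = field(init=False)
    ci_high_probability: float = field(init=False)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValidationError("RiskEstimate with no samples")
        self.mean_probability = float(self.samples.mean())
        self.ci_low_probability, self.ci_high_probability = credibility_interval(
            self.samples, self.ci_level
        )

    @property
    def iterations(self) -> int:
        return int(self.samples.size)

    @property
    def reciprocal_mean(self) -> float:
        return to_reciprocal(self.mean_probability)

    @property
    def reciprocal_ci(self) -> tuple[float, float]:
        """Reciprocal interval, sorted ascending (best case first)."""
        pair = (to_reciprocal(self.ci_high_probability),
                to_reciprocal(self.ci_low_probability))
        return (min(pair), max(pair))

    def summary(self, sig: int = 2) -> dict:
        """JSON-ready summary with both raw and display-rounded values."""
        lo, hi = self.reciprocal_ci
        return {
            "harm_id": self.harm_id,
            "population_id": self.population_id,
            "iterations": self.iterations,
            "ci_level": self.ci_level,
            "mean_probability": self.mean_probability,
            "ci_probability": [self.ci_low_probability, self.ci_high_probability],
            "reciprocal_mean": None if math.isinf(self.reciprocal_mean) else self.reciprocal_mean,
            "reciprocal_ci": [None if math.isinf(v) else v for v in (lo, hi)],
            "display": {
                "one_in": format_reciprocal(self.mean_probability, sig),
                "ci": [
                    NO_EVENTS if math.isinf(v) else round_sig(v, sig)
                    for v in (lo, hi)
                ],
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.summary(), **kwargs)


def draw_event_samples(
    config: ModelConfig,
    population_id: str,
    iterations: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Per-event probability draws, shape ``(iterations,)`` per event.

    Each input is drawn from its own substream keyed by ``input_id``;
    population overrides draw from a substream keyed by population and event,
    leaving base-input streams untouched.
    """
    if population_id not in config.populations:
        raise ValidationError(f"unknown population {population_id!r}", population_id)
    input_draws: dict[str, np.ndarray] = {}
    event_draws: dict[str, np.ndarray] = {}
    for eid in sorted(config.events):
        ev = config.events[eid]
        if population_id in ev.population_overrides:
            spec = ev.population_overrides[population_id]
            rng = substream(seed, "override", population_id, eid)
            event_draws[eid] = np.asarray(spec.sample(rng, iterations), dtype=float)
        else:
            ref = ev.input_ref
            if ref not in input_draws:
                rng = substream(seed, "input", ref)
                input_draws[ref] = np.asarray(
                    config.inputs[ref].sample(rng, iterations), dtype=float
                )
            event_draws[eid] = input_draws[ref]
    return event_draws


def run_simulation(
    config: ModelConfig,
    population_id: str,
    iterations: int | None = None,
    seed: int | None = None,
) -> dict[str, RiskEstimate]:
    """Run the Monte Carlo model for one population.

    Returns one :class:`RiskEstimate` per harm plus the additive ``any_harm``
    combination.  With all inputs point masses every sample equals the
    analytic chain product exactly.
    """
    iterations = config.mc.iterations if iterations is None else int(iterations)
    seed = config.mc.seed if seed is None else int(seed)
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    event_draws = draw_event_samples(config, population_id, iterations, seed)

    estimates: dict[str, RiskEstimate] = {}
    harm_samples = []
    for hid in config.harms:
        prob = np.ones(iterations)
        for eid in config.harms[hid].chain:
            prob = prob * event_draws[eid]
        harm_samples.append(prob)
        estimates[hid] = RiskEstimate(hid, population_id, prob, config.mc.ci_level)

    # per-iteration additive combination, same convention as chain.combined_risk
    any_harm = np.minimum(1.0, np.sum(harm_samples, axis=0))
    estimates[ANY_HARM] = RiskEstimate(ANY_HARM, population_id, any_harm, config.mc.ci_level)
    return estimates
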