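"""Synthetic scenario generation with analytic ground truth.

The published input distributions for the chain model live in supplementary
material that the package does not ship.  For testing and demonstration this
module generates configurations whose ground truth is known in closed form:
event chains with random admissible distribution parameters whose *means* are
constructed exactly, so the analytic harm probability (product of means,
valid by independence) is available for parameter-recovery checks.

``paper_shaped_scenario`` emits a scenario with the same shape as the shipped
default model — 14 events, three harms sharing chain prefixes, two
populations with subgroup overrides — scaled so the per-harm reciprocal risks
land in the realistic 1e4..1e6 "one in N transfusions" range, which exercises
the small-probability regime the real model lives in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chain import analytic_chain_mean, combined_risk
from .config import (
    EventNode,
    HarmDefinition,
    LifeYearsConfig,
    ModelConfig,
    MonteCarloConfig,
    PopulationSpec,
)
from .distributions import FAMILIES, DistributionSpec, ValidationError, substream
from .montecarlo import ANY_HARM

__all__ = ["ScenarioTruth", "generate_scenario", "paper_shaped_scenario"]


@dataclass(frozen=True)
class ScenarioTruth:
    """A generated config together with its closed-form ground truth."""

    config: ModelConfig
    #: (harm_id, population_id) -> analytic mean per-transfusion probability
    analytic_probability: dict[tuple[str, str], float]
    #: input_id -> (closed-form mean, closed-form variance)
    input_moments: dict[str, tuple[float, float]]

    def analytic_reciprocal(self, harm_id: str, population_id: str) -> float:
        p = self.analytic_probability[(harm_id, population_id)]
        return float("inf") if p == 0 else 1.0 / p


def _spec_with_mean(
    input_id: str, family: str, mean: float, rng: np.random.Generator
) -> DistributionSpec:
    """A distribution of the given family whose closed-form mean is exactly ``mean``."""
    if not (0.0 < mean < 1.0):
        raise ValidationError(f"cannot target mean {mean} in (0, 1)", input_id)
    if family == "point":
        return DistributionSpec(input_id, "point", (mean,))
    if family == "uniform":
        half = min(mean, 1.0 - mean) * rng.uniform(0.1, 0.9)
        return DistributionSpec(input_id, "uniform", (mean - half, mean + half))
    if family == "triangular":
        half = min(mean, 1.0 - mean) * rng.uniform(0.1, 0.9)
        return DistributionSpec(input_id, "triangular", (mean - half, mean, mean + half))
    if family == "beta":
        conc = rng.uniform(2.0, 50.0)
        return DistributionSpec(input_id, "beta", (conc * mean, conc * (1.0 - mean)))
    if family == "log_uniform":
        # mean of log-uniform on [a, ra] is a(r-1)/ln r; solve for a given r
        r = rng.uniform(1.5, 5.0)
        a = mean * np.log(r) / (r - 1.0)
        if a * r > 1.0:  # keep support inside the unit interval
            r = 1.0 + (1.0 - mean) / mean * 0.5 if mean < 1 else 1.0
            a = mean * np.log(r) / (r - 1.0) if r > 1 else mean
        return DistributionSpec(input_id, "log_uniform", (a, a * r))
    raise ValidationError(f"unknown family {family!r}", input_id)


def _truth(config: ModelConfig) -> ScenarioTruth:
    analytic: dict[tuple[str, str], float] = {}
    for pop in config.populations:
        per_harm = [
            analytic_chain_mean(config, hid, pop) for hid in config.harms
        ]
        for hid, p in zip(config.harms, per_harm):
            analytic[(hid, pop)] = p
        analytic[(ANY_HARM, pop)] = combined_risk(per_harm)
    moments = {
        iid: (spec.mean(), spec.variance()) for iid, spec in config.inputs.items()
    }
    return ScenarioTruth(config, analytic, moments)


def generate_scenario(
    seed: int,
    n_events: int = 5,
    families: Sequence[str] = FAMILIES,
    target_risk_scale: float = 1e-4,
) -> ScenarioTruth:
    """Random single-harm chain whose analytic risk is exactly ``target_risk_scale``.

    Per-event means are ``target ** w_i`` with Dirichlet-distributed exponents
    summing to 1, so the product of means equals the target exactly while the
    split across events varies with the seed.  Deterministic given ``seed``.
    """
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    if not (0.0 < target_risk_scale <= 1.0):
        raise ValidationError(
            f"target_risk_scale {target_risk_scale} outside (0, 1]"
        )
    bad = [f for f in families if f not in FAMILIES]
    if bad or not families:
        raise ValidationError(f"unknown families {bad!r}" if bad else "no families given")
    rng = substream(seed, "scenario", str(n_events), repr(float(target_risk_scale)))

    if target_risk_scale == 1.0:
        means = np.ones(n_events)
    else:
        weights = rng.dirichlet(np.ones(n_events))
        means = np.asarray(target_risk_scale) ** weights
    inputs, events = {}, {}
    chain = []
    for i, m in enumerate(means, start=1):
        iid, eid = f"N{i}", f"X{i}"
        fam = families[rng.integers(0, len(families))]
        if m >= 1.0:
            spec = DistributionSpec(iid, "point", (1.0,))
        else:
            spec = _spec_with_mean(iid, fam, float(m), rng)
        inputs[iid] = spec
        events[eid] = EventNode(eid, f"synthetic event {i}", iid)
        chain.append(eid)
    config = ModelConfig(
        inputs=inputs,
        events=events,
        harms={"harm": HarmDefinition("harm", "synthetic harm", tuple(chain))},
        populations={
            "all_recipients": PopulationSpec(
                "all_recipients", "synthetic population", 83.0, 67_000_000, 1.0
            )
        },
        life_years=LifeYearsConfig(),
        mc=MonteCarloConfig(iterations=1000, seed=int(seed) & 0x7FFFFFFF),
    )
    return _truth(config)


#: per-event mean targets of the paper-shaped structure (before jitter);
#: chosen so all-recipient reciprocals land near 1e4 / 1e5 / 1e4
_SHAPE_MEANS = {
    "X1": 0.15, "X2": 0.10, "X3": 0.01, "X4": 0.30, "X5": 0.10,
    "X6": 0.70, "X7": 0.20, "X8": 0.10, "X9": 0.15, "X10": 0.20,
    "X11": 0.10, "X12": 0.30, "X13": 0.60, "X14": 0.08,
}

_SHAPE_CHAINS = {
    "htr_index": ("X1", "X3", "X4", "X5"),
    "htr_future": ("X1", "X6", "X7", "X8", "X9", "X10", "X11"),
    "hdfn": ("X1", "X2", "X6", "X7", "X12", "X13", "X14"),
}

_SHAPE_LABELS = {
    "htr_index": "HTR at index D-positive transfusion (major morbidity/mortality)",
    "htr_future": "HTR at a future transfusion (major morbidity/mortality)",
    "hdfn": "HDFN death or lifelong disability in a future pregnancy",
}


def paper_shaped_scenario(seed: int = 0) -> ScenarioTruth:
    """Scenario with the full published model *shape* and realistic risk scales.

    14 events, three harms sharing the chain prefix, and two populations: all
    recipients and D-negative females of childbearing potential, the latter
    via overrides that fix the two subgroup-defining events at probability 1.
    Families are drawn per input; means are jittered around the shape targets
    (so parameters are not the published ones) while remaining known exactly.
    """
    rng = substream(seed, "paper_shaped")
    jitter_families = ("uniform", "triangular", "beta")
    inputs, events = {}, {}
    for i, (eid, m0) in enumerate(_SHAPE_MEANS.items(), start=1):
        iid = f"N{i}"
        mean = float(np.clip(m0 * rng.uniform(0.85, 1.15), 1e-6, 0.95))
        fam = jitter_families[rng.integers(0, len(jitter_families))]
        inputs[iid] = _spec_with_mean(iid, fam, mean, rng)
        overrides = {}
        if eid in ("X1", "X2"):
            overrides["dneg_females_cbp"] = DistributionSpec(
                f"{eid}@dneg_females_cbp", "point", (1.0,)
            )
        events[eid] = EventNode(eid, f"synthetic event {eid}", iid, overrides)
    harms = {
        hid: HarmDefinition(hid, _SHAPE_LABELS[hid], chain)
        for hid, chain in _SHAPE_CHAINS.items()
    }
    populations = {
        "all_recipients": PopulationSpec(
            "all_recipients", "all prehospital trauma recipients",
            83.0, 67_000_000, 1.0,
        ),
        "dneg_females_cbp": PopulationSpec(
            "dneg_females_cbp", "D-negative females of childbearing potential",
            83.0, 67_000_000, 0.017982,
        ),
    }
    config = ModelConfig(
        inputs=inputs,
        events=events,
        harms=harms,
        populations=populations,
        life_years=LifeYearsConfig(),
        mc=MonteCarloConfig(iterations=1000, seed=int(seed) & 0x7FFFFFFF),
    )
    return _truth(config)
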