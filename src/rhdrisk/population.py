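"""Population and time scaling: annual transfusion counts and years-to-event.

The per-transfusion risks become policy-relevant once scaled by how many
prehospital transfusion episodes occur per year.  With an incidence of major
traumatic haemorrhage of ``i`` per million per year and a national population
``P``, a population receiving a fraction ``f`` of those episodes sees

    annual = i * (P / 1e6) * f          episodes / year

and a harm occurring once per ``N`` transfusions is first expected after

    years = N / annual.

Both the mean and the credibility-interval endpoints transform this way
(the map is monotone decreasing in probability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import ModelConfig, PopulationSpec
from .distributions import ValidationError
from .montecarlo import RiskEstimate, round_sig, to_reciprocal

__all__ = ["AnnualProjection", "annual_transfusions", "years_to_event", "project"]


def annual_transfusions(
    incidence_per_million: float, population_size: float, subgroup_fraction: float = 1.0
) -> float:
    """Annual transfusion episodes: incidence x population/1e6 x fraction."""
    if incidence_per_million < 0 or population_size < 0:
        raise ValidationError("incidence and population size must be non-negative")
    if not (0.0 <= subgroup_fraction <= 1.0):
        raise ValidationError(f"subgroup_fraction {subgroup_fraction} outside [0, 1]")
    return incidence_per_million * (population_size / 1e6) * subgroup_fraction


def years_to_event(risk_reciprocal: float, annual: float) -> float:
    """Expected years until one event: (transfusions per event) / (transfusions per year)."""
    if annual <= 0:
        raise ValidationError("annual transfusion count must be positive")
    return risk_reciprocal / annual


@dataclass(frozen=True)
class AnnualProjection:
    """Years to first event for one harm in one population (mean + CI)."""

    harm_id: str
    population_id: str
    annual_transfusions: float
    years_mean: float
    years_ci: tuple[float, float]

    def to_dict(self, sig: int = 2) -> dict:
        def _disp(v):
            return None if math.isinf(v) else round_sig(v, sig)

        return {
            "harm_id": self.harm_id,
            "population_id": self.population_id,
            "annual_transfusions": self.annual_transfusions,
            "years_mean": None if math.isinf(self.years_mean) else self.years_mean,
            "years_ci": [None if math.isinf(v) else v for v in self.years_ci],
            "display": {
                "years": _disp(self.years_mean),
                "ci": [_disp(v) for v in self.years_ci],
            },
        }


def project(estimate: RiskEstimate, population: PopulationSpec) -> AnnualProjection:
    """Convert a per-transfusion risk estimate to years-to-first-event."""
    annual = population.annual_transfusions
    lo_n, hi_n = estimate.reciprocal_ci
    return AnnualProjection(
        harm_id=estimate.harm_id,
        population_id=population.population_id,
        annual_transfusions=annual,
        years_mean=years_to_event(estimate.reciprocal_mean, annual),
        years_ci=(years_to_event(lo_n, annual), years_to_event(hi_n, annual)),
    )


def project_all(
    estimates: dict[str, RiskEstimate], config: ModelConfig, population_id: str
) -> dict[str, AnnualProjection]:
    pop = config.populations[population_id]
    return {hid: project(est, pop) for hid, est in estimates.items()}
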