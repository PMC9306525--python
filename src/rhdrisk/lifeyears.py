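"""Life-years trade-off: survival benefit of whole blood vs. future HDFN harm.

For D-negative females of childbearing potential, transfusing D-positive
whole blood trades an immediate survival benefit against the risk of a future
HDFN death or lifelong disability, costed at a fixed number of life-years
(default 83, undiscounted life expectancy at birth).

Per transfused patient, an absolute survival improvement of ``s`` percentage
points gains ``(s/100) * L_surv`` life-years in expectation, where ``L_surv``
is the life-years lived by an averted trauma death; a per-transfusion HDFN
probability ``p`` loses ``p * L_hdfn`` life-years.  Both ``p`` (from the
Monte Carlo output sample) and ``L_surv`` (a configured distribution) are
uncertain, so the comparison is bootstrapped: the break-even benefit is the
smallest grid value of ``s`` for which life-years gained exceed life-years
lost in at least 95% of replicates.  Population scaling cancels because both
sides are per transfused patient in the same subgroup.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .config import LifeYearsConfig
from .distributions import ValidationError, substream

__all__ = [
    "TradeoffResult",
    "expected_life_years_lost",
    "tradeoff_bootstrap",
    "closed_form_break_even",
]


def expected_life_years_lost(hdfn_probability: float, years_per_event: float) -> float:
    """Expected life-years lost per transfusion: probability x years per event."""
    if hdfn_probability < 0 or years_per_event < 0:
        raise ValidationError("inputs must be non-negative")
    return hdfn_probability * years_per_event


@dataclass(frozen=True)
class TradeoffResult:
    """Break-even scan: P(gained > lost) along a grid of survival benefits.

    ``break_even_benefit`` is the smallest grid percentage whose probability
    reaches ``confidence_level``; ``None`` means "not reached" on this grid.
    """

    grid: tuple[float, ...]
    probabilities: tuple[float, ...]
    confidence_level: float
    break_even_benefit: float | None

    @property
    def reached(self) -> bool:
        return self.break_even_benefit is not None

    def to_dict(self) -> dict:
        return {
            "grid_percent": list(self.grid),
            "probability_gained_exceeds_lost": list(self.probabilities),
            "confidence_level": self.confidence_level,
            "break_even_benefit_percent": self.break_even_benefit,
            "reached": self.reached,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def tradeoff_bootstrap(
    hdfn_samples,
    cfg: LifeYearsConfig,
    seed: int = 0,
    confidence_level: float = 0.95,
) -> TradeoffResult:
    """Bootstrap the break-even survival benefit.

    Each replicate resamples one HDFN per-transfusion probability from the
    Monte Carlo output sample (with replacement) and one survivor life-years
    value from its distribution; a single set of replicates is scanned across
    the whole grid, which makes the exceedance probability non-decreasing in
    the benefit by construction.  Deterministic given ``seed``.
    """
    p = np.asarray(hdfn_samples, dtype=float)
    if p.size == 0:
        raise ValidationError("tradeoff_bootstrap needs a non-empty HDFN sample")
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("HDFN samples must be probabilities in [0, 1]")
    if not (0.0 < confidence_level < 1.0):
        raise ValidationError(f"confidence_level {confidence_level} outside (0, 1)")

    n = cfg.bootstrap_samples
    rng_idx = substream(seed, "tradeoff", "resample")
    rng_ly = substream(seed, "tradeoff", "survivor_life_years")
    hdfn = p[rng_idx.integers(0, p.size, size=n)]
    survivor_years = np.asarray(cfg.survivor_life_years.sample(rng_ly, n), dtype=float)

    lost = hdfn * cfg.life_years_lost_per_hdfn_event
    grid = cfg.survival_benefit_grid
    probabilities = tuple(
        float(np.mean((g / 100.0) * survivor_years > lost)) for g in grid
    )

    break_even = None
    for g, prob in zip(grid, probabilities):
        if prob >= confidence_level:
            break_even = float(g)
            break
    return TradeoffResult(
        grid=tuple(float(g) for g in grid),
        probabilities=probabilities,
        confidence_level=confidence_level,
        break_even_benefit=break_even,
    )


def closed_form_break_even(
    hdfn_probability: float, years_per_event: float, survivor_life_years: float
) -> float:
    """Degenerate-input break-even in percent: 100 * p * L_hdfn / L_surv.

    With all three quantities fixed, gained exceeds lost exactly when the
    benefit passes this value; the bootstrap must reproduce it on any grid
    fine enough to resolve it.
    """
    if survivor_life_years <= 0:
        return math.inf
    return 100.0 * expected_life_years_lost(hdfn_probability, years_per_event) / survivor_life_years
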