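"""Variance-based sensitivity analysis of the chain model.

Two complementary views of how input uncertainty drives output uncertainty:

* **Scatterplots** — per-iteration pairs (input draw, output draw) under the
  same substream seeding as the Monte Carlo run, exported for plotting.
* **First-order Sobol indices** — ``S_i = Var(E[Y | N_i]) / Var(Y)``, the
  expected fractional reduction in output variance if input ``N_i`` were
  known exactly.  Estimated by the pick-freeze (Saltelli) scheme: two
  independent input sample matrices ``A`` and ``B`` and, per input, a hybrid
  matrix ``A`` with that input's column taken from ``B``; then

      S_i ~= mean(Y_B * (Y_ABi - Y_A)) / Var(Y).

Inputs are independent by design, so for an additive model the indices sum to
~1 and for the multiplicative chain they sum to at most ~1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import ModelConfig
from .distributions import DistributionSpec, ValidationError, substream
from .montecarlo import ANY_HARM, run_simulation

__all__ = [
    "SensitivityResult",
    "pick_freeze_first_order",
    "first_order_index",
    "all_first_order_indices",
    "scatter_export",
]


@dataclass(frozen=True)
class SensitivityResult:
    """First-order index for one input (raw and clipped-for-display)."""

    input_id: str
    output_id: str
    population_id: str
    s_index_raw: float
    estimator: str = "pick-freeze"
    n: int = 0
    seed: int = 0
    scatter: np.ndarray | None = field(default=None, compare=False, repr=False)

    @property
    def s_index(self) -> float:
        """Raw estimate clipped to [0, 1] for display; estimator noise can
        push the raw value slightly outside."""
        return float(min(1.0, max(0.0, self.s_index_raw)))

    def to_dict(self) -> dict:
        return {
            "input_id": self.input_id,
            "output_id": self.output_id,
            "population_id": self.population_id,
            "s_index": self.s_index,
            "s_index_raw": self.s_index_raw,
            "estimator": self.estimator,
            "n": self.n,
            "seed": self.seed,
        }


def pick_freeze_first_order(
    dists: Sequence[DistributionSpec],
    func: Callable[[np.ndarray], np.ndarray],
    index: int,
    n: int = 2**14,
    seed: int = 0,
) -> float:
    """Generic pick-freeze first-order index of input ``index`` for ``func``.

    ``func`` maps an ``(n, k)`` matrix of input draws to ``n`` outputs.
    Matrices ``A`` and ``B`` are sampled from per-input substreams, so the
    estimate is deterministic given ``seed``.  Returns the raw (unclipped)
    estimate; if the output variance is zero the index is defined as 0.
    """
    k = len(dists)
    if not (0 <= index < k):
        raise ValidationError(f"input index {index} out of range for {k} inputs")
    A = np.column_stack(
        [np.asarray(d.sample(substream(seed, "pf", "A", d.input_id, str(j)), n))
         for j, d in enumerate(dists)]
    )
    B = np.column_stack(
        [np.asarray(d.sample(substream(seed, "pf", "B", d.input_id, str(j)), n))
         for j, d in enumerate(dists)]
    )
    AB = A.copy()
    AB[:, index] = B[:, index]
    y_a, y_b, y_ab = func(A), func(B), func(AB)
    var = np.var(np.concatenate([y_a, y_b]))
    # a constant output can yield var ~ eps^2 instead of exactly 0
    if var <= 1e-24:
        warnings.warn("output variance is zero; sensitivity index defined as 0")
        return 0.0
    return float(np.mean(y_b * (y_ab - y_a)) / var)


# -- wiring the chain model into the generic estimator ----------------------


def _model_columns(
    config: ModelConfig, population_id: str
) -> tuple[list[DistributionSpec], dict[str, int], dict[str, str]]:
    """Column layout for the sampled input vector of one population.

    One column per referenced input, plus one per population-override
    (overrides are population-level constants/distributions, not shared model
    inputs).  Returns (column specs, event -> column index, input -> column key).
    """
    specs: list[DistributionSpec] = []
    col_of_key: dict[str, int] = {}
    event_col: dict[str, int] = {}
    for eid in sorted(config.events):
        ev = config.events[eid]
        if population_id in ev.population_overrides:
            key = f"override:{population_id}:{eid}"
            spec = ev.population_overrides[population_id]
        else:
            key = f"input:{ev.input_ref}"
            spec = config.inputs[ev.input_ref]
        if key not in col_of_key:
            col_of_key[key] = len(specs)
            specs.append(spec)
        event_col[eid] = col_of_key[key]
    return specs, event_col, col_of_key


def _output_function(
    config: ModelConfig, output_id: str, event_col: dict[str, int]
) -> Callable[[np.ndarray], np.ndarray]:
    if output_id != ANY_HARM and output_id not in config.harms:
        raise ValidationError(f"unknown output {output_id!r}", output_id)

    def func(X: np.ndarray) -> np.ndarray:
        if output_id == ANY_HARM:
            total = np.zeros(X.shape[0])
            for hid in config.harms:
                prob = np.ones(X.shape[0])
                for eid in config.harms[hid].chain:
                    prob = prob * X[:, event_col[eid]]
                total += prob
            return np.minimum(1.0, total)
        prob = np.ones(X.shape[0])
        for eid in config.harms[output_id].chain:
            prob = prob * X[:, event_col[eid]]
        return prob

    return func


def first_order_index(
    config: ModelConfig,
    input_id: str,
    output_id: str = ANY_HARM,
    population_id: str | None = None,
    n: int = 2**14,
    seed: int = 0,
) -> SensitivityResult:
    """First-order Sobol index of one model input for one output.

    ``output_id`` is a harm id or ``"any_harm"``; ``population_id`` defaults
    to the first configured population.
    """
    if input_id not in config.inputs:
        raise ValidationError(f"unknown input {input_id!r}", input_id)
    if population_id is None:
        population_id = next(iter(sorted(config.populations)))
    specs, event_col, col_of_key = _model_columns(config, population_id)
    func = _output_function(config, output_id, event_col)
    key = f"input:{input_id}"
    if key not in col_of_key:
        # input not referenced by any event active in this population
        raw = 0.0
    else:
        raw = pick_freeze_first_order(specs, func, col_of_key[key], n=n, seed=seed)
    return SensitivityResult(
        input_id=input_id,
        output_id=output_id,
        population_id=population_id,
        s_index_raw=raw,
        n=n,
        seed=seed,
    )


def all_first_order_indices(
    config: ModelConfig,
    output_id: str = ANY_HARM,
    population_id: str | None = None,
    n: int = 2**14,
    seed: int = 0,
) -> dict[str, SensitivityResult]:
    return {
        iid: first_order_index(config, iid, output_id, population_id, n, seed)
        for iid in sorted(config.inputs)
    }


def scatter_export(
    config: ModelConfig,
    input_id: str,
    output_id: str = ANY_HARM,
    population_id: str | None = None,
    iterations: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Per-iteration (input draw, output draw) pairs, shape ``(iterations, 2)``.

    Uses the same substream seeding as :func:`~rhdrisk.montecarlo.run_simulation`,
    so the pairs are exactly the draws of a simulation run with that seed.
    """
    if input_id not in config.inputs:
        raise ValidationError(f"unknown input {input_id!r}", input_id)
    if population_id is None:
        population_id = next(iter(sorted(config.populations)))
    iterations = config.mc.iterations if iterations is None else int(iterations)
    seed = config.mc.seed if seed is None else int(seed)
    x = np.asarray(
        config.inputs[input_id].sample(substream(seed, "input", input_id), iterations),
        dtype=float,
    )
    estimates = run_simulation(config, population_id, iterations=iterations, seed=seed)
    if output_id not in estimates:
        raise ValidationError(f"unknown output {output_id!r}", output_id)
    y = estimates[output_id].samples
    return np.column_stack([x, y])


def scatter_to_csv(pairs: np.ndarray, path, input_id: str, output_id: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "iteration": np.arange(len(pairs)),
            f"input_{input_id}": pairs[:, 0],
            f"output_{output_id}": pairs[:, 1],
        }
    ).to_csv(path, index=False)


def indices_to_json(results: dict[str, SensitivityResult], **kwargs) -> str:
    return json.dumps({k: v.to_dict() for k, v in sorted(results.items())}, **kwargs)
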