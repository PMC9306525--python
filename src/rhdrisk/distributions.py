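"""Bounded probability distributions used as model inputs.

Every input to the event-chain model is a conditional probability (or a
proportion), so the canonical support is the unit interval.  Uncertainty about
each input is expressed by giving it a distribution rather than a point value;
the Monte Carlo engine draws one value per input per iteration.  The life-years
trade-off additionally needs distributions over non-negative quantities
(life-years gained per survivor), which reuse the same families with a relaxed
support.

Five families are supported:

``point``        a degenerate mass at ``p``
``uniform``      uniform on ``[a, b]``
``triangular``   triangular with minimum ``a``, mode ``m``, maximum ``b``
``beta``         Beta(alpha, beta), natural for probabilities
``log_uniform``  log-uniform (reciprocal) on ``[a, b]``, ``a > 0`` — suited to
                 inputs uncertain over orders of magnitude

Each family exposes its closed-form mean and variance so that analytic ground
truth (product of means along a chain, by independence) is always available.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "ValidationError",
    "substream",
    "sample_input",
]

FAMILIES = ("point", "uniform", "triangular", "beta", "log_uniform")

#: number of parameters each family takes
_ARITY = {"point": 1, "uniform": 2, "triangular": 3, "beta": 2, "log_uniform": 2}


class ValidationError(ValueError):
    """A configuration element violates an invariant.

    Carries the identifier of the offending element so callers (and error
    messages) can name it.
    """

    def __init__(self, message: str, offending_id: str | None = None):
        super().__init__(message)
        self.offending_id = offending_id


def substream(seed: int, *keys: str) -> np.random.Generator:
    """Return an independent generator derived from ``(seed, *keys)``.

    Substreams are derived by hashing the string keys, so each model input owns
    its own stream: adding, removing or re-parametrising one input never
    perturbs the draws of any other.  The derivation is stable across runs and
    platforms (SHA-256, not Python's salted ``hash``).
    """
    digest = hashlib.sha256("\x1f".join(keys).encode("utf-8")).digest()
    entropy = [int(seed) & 0xFFFFFFFF] + list(
        int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)
    )
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class DistributionSpec:
    """One model input: a named, bounded probability distribution.

    Parameters
    ----------
    input_id : str
        Stable identifier (conventionally ``N1``..``N14`` for the shipped
        chain, but any string is accepted).
    family : str
        One of :data:`FAMILIES`.
    params : tuple of float
        Family-specific parameters, see module docstring.
    description, source_note : str
        Free text; ``source_note`` records the provenance of the value.
    support : str
        ``"unit"`` (default) restricts samples to ``[0, 1]``;
        ``"nonnegative"`` only requires them to be ``>= 0`` (used for
        life-years inputs, never for chain probabilities).
    """

    input_id: str
    family: str
    params: tuple[float, ...]
    description: str = ""
    source_note: str = ""
    support: str = field(default="unit")

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        fam, p = self.family, self.params
        if fam not in FAMILIES:
            raise ValidationError(
                f"input {self.input_id!r}: unknown family {fam!r} "
                f"(expected one of {FAMILIES})",
                self.input_id,
            )
        if len(p) != _ARITY[fam]:
            raise ValidationError(
                f"input {self.input_id!r}: family {fam!r} takes "
                f"{_ARITY[fam]} parameter(s), got {len(p)}",
                self.input_id,
            )
        if self.support not in ("unit", "nonnegative"):
            raise ValidationError(
                f"input {self.input_id!r}: unknown support {self.support!r}",
                self.input_id,
            )
        upper = 1.0 if self.support == "unit" else math.inf

        def _in_range(x: float, name: str, low: float = 0.0):
            if not (low <= x <= upper):
                raise ValidationError(
                    f"input {self.input_id!r}: parameter {name}={x} outside "
                    f"[{low}, {upper}]",
                    self.input_id,
                )

        if fam == "point":
            _in_range(p[0], "p")
        elif fam == "uniform":
            a, b = p
            _in_range(a, "a")
            _in_range(b, "b")
            if a > b:
                raise ValidationError(
                    f"input {self.input_id!r}: uniform requires a <= b, "
                    f"got a={a}, b={b}",
                    self.input_id,
                )
        elif fam == "triangular":
            a, m, b = p
            _in_range(a, "a")
            _in_range(b, "b")
            if not (a <= m <= b):
                raise ValidationError(
                    f"input {self.input_id!r}: triangular requires a <= m <= b, "
                    f"got a={a}, m={m}, b={b}",
                    self.input_id,
                )
        elif fam == "beta":
            alpha, beta = p
            if alpha <= 0 or beta <= 0:
                raise ValidationError(
                    f"input {self.input_id!r}: beta requires alpha > 0 and "
                    f"beta > 0, got alpha={alpha}, beta={beta}",
                    self.input_id,
                )
        elif fam == "log_uniform":
            a, b = p
            if not (0 < a <= b <= upper):
                raise ValidationError(
                    f"input {self.input_id!r}: log_uniform requires "
                    f"0 < a <= b <= {upper}, got a={a}, b={b}",
                    self.input_id,
                )

    # -- sampling -----------------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        """Draw ``size`` values (a scalar if ``size`` is None)."""
        fam, p = self.family, self.params
        if fam == "point":
            out = np.full(size, p[0]) if size is not None else p[0]
        elif fam == "uniform":
            a, b = p
            out = rng.uniform(a, b, size) if a < b else (
                np.full(size, a) if size is not None else a
            )
        elif fam == "triangular":
            a, m, b = p
            out = rng.triangular(a, m, b, size) if a < b else (
                np.full(size, a) if size is not None else a
            )
        elif fam == "beta":
            out = rng.beta(p[0], p[1], size)
        else:  # log_uniform
            a, b = p
            if a < b:
                out = np.exp(rng.uniform(math.log(a), math.log(b), size))
            else:
                out = np.full(size, a) if size is not None else a
        if self.support == "unit":
            # guards against float round-off at the edges only
            out = np.clip(out, 0.0, 1.0)
            if size is None:
                out = float(out)
        return out

    # -- closed-form moments ------------------------------------------------

    def mean(self) -> float:
        fam, p = self.family, self.params
        if fam == "point":
            return p[0]
        if fam == "uniform":
            return (p[0] + p[1]) / 2.0
        if fam == "triangular":
            return (p[0] + p[1] + p[2]) / 3.0
        if fam == "beta":
            return p[0] / (p[0] + p[1])
        a, b = p  # log_uniform
        return a if a == b else (b - a) / (math.log(b) - math.log(a))

    def variance(self) -> float:
        fam, p = self.family, self.params
        if fam == "point":
            return 0.0
        if fam == "uniform":
            return (p[1] - p[0]) ** 2 / 12.0
        if fam == "triangular":
            a, m, b = p
            return (a * a + m * m + b * b - a * m - a * b - m * b) / 18.0
        if fam == "beta":
            alpha, beta = p
            s = alpha + beta
            return alpha * beta / (s * s * (s + 1.0))
        a, b = p  # log_uniform
        if a == b:
            return 0.0
        second = (b * b - a * a) / (2.0 * (math.log(b) - math.log(a)))
        return second - self.mean() ** 2

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = {"input_id": self.input_id, "family": self.family, "params": list(self.params)}
        if self.description:
            d["description"] = self.description
        if self.source_note:
            d["source_note"] = self.source_note
        if self.support != "unit":
            d["support"] = self.support
        return d

    @classmethod
    def from_dict(cls, d: dict, default_id: str = "") -> "DistributionSpec":
        try:
            return cls(
                input_id=str(d.get("input_id", default_id)),
                family=str(d["family"]),
                params=tuple(d["params"]),
                description=str(d.get("description", "")),
                source_note=str(d.get("source_note", "")),
                support=str(d.get("support", "unit")),
            )
        except KeyError as exc:
            raise ValidationError(
                f"input {d.get('input_id', default_id)!r}: missing field {exc}",
                str(d.get("input_id", default_id)),
            ) from exc


def sample_input(
    spec: DistributionSpec, rng: np.random.Generator, size: int | None = None
) -> np.ndarray | float:
    """Draw from a model-input distribution (functional alias of ``spec.sample``)."""
    return spec.sample(rng, size)
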