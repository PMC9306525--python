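"""Model configuration: events, harms, populations, and their distributional inputs.

The model is an event tree: each harm is reached through an ordered chain of
contingent events (``X1``..``X14`` in the shipped default), each event carrying
a conditional probability given all upstream events.  The conditional
probabilities are uncertain, so each event references a
:class:`~rhdrisk.distributions.DistributionSpec` (``N1``..``N14``).

Two recipient populations are modelled: all prehospital trauma recipients, and
the highest-risk subgroup of D-negative females of childbearing potential
(CBP, under 50).  Rather than duplicating the chain, events may carry
*population overrides*: for the subgroup, "recipient is D-negative" and
"recipient is a female of CBP" are fixed at probability 1.

Configurations are plain YAML documents (schema version 1); ``load_config`` /
``write_config`` round-trip losslessly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import yaml

from .distributions import DistributionSpec, ValidationError

__all__ = [
    "SCHEMA_VERSION",
    "EventNode",
    "HarmDefinition",
    "PopulationSpec",
    "MonteCarloConfig",
    "LifeYearsConfig",
    "ModelConfig",
    "ValidationError",
    "load_config",
    "loads_config",
    "write_config",
    "dumps_config",
    "default_config",
    "default_config_path",
]

SCHEMA_VERSION = 1

#: the three harms of the shipped model
STANDARD_HARMS = ("htr_index", "htr_future", "hdfn")


@dataclass(frozen=True)
class EventNode:
    """One contingent event in the chain.

    ``input_ref`` names the :class:`DistributionSpec` giving the event's
    conditional probability.  ``population_overrides`` maps a population id to
    a replacement distribution for that population (e.g. a point mass at 1 for
    an event that defines the subgroup).
    """

    event_id: str
    label: str
    input_ref: str
    population_overrides: dict[str, DistributionSpec] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"event_id": self.event_id, "label": self.label, "input_ref": self.input_ref}
        if self.population_overrides:
            d["population_overrides"] = {
                pop: {k: v for k, v in spec.to_dict().items() if k != "input_id"}
                for pop, spec in sorted(self.population_overrides.items())
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EventNode":
        eid = str(d.get("event_id", ""))
        if not eid:
            raise ValidationError("event with missing event_id", eid)
        overrides = {}
        for pop, od in (d.get("population_overrides") or {}).items():
            overrides[str(pop)] = DistributionSpec.from_dict(
                dict(od), default_id=f"{eid}@{pop}"
            )
        return cls(
            event_id=eid,
            label=str(d.get("label", "")),
            input_ref=str(d.get("input_ref", "")),
            population_overrides=overrides,
        )


@dataclass(frozen=True)
class HarmDefinition:
    """A harm and the ordered chain of events (root first) that produces it."""

    harm_id: str
    label: str
    chain: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "chain", tuple(str(e) for e in self.chain))
        if not self.chain:
            raise ValidationError(f"harm {self.harm_id!r}: empty chain", self.harm_id)
        if len(set(self.chain)) != len(self.chain):
            raise ValidationError(
                f"harm {self.harm_id!r}: duplicate event ids in chain", self.harm_id
            )

    def to_dict(self) -> dict:
        return {"harm_id": self.harm_id, "label": self.label, "chain": list(self.chain)}

    @classmethod
    def from_dict(cls, d: dict) -> "HarmDefinition":
        return cls(
            harm_id=str(d.get("harm_id", "")),
            label=str(d.get("label", "")),
            chain=tuple(d.get("chain") or ()),
        )


@dataclass(frozen=True)
class PopulationSpec:
    """A recipient population and how its annual transfusion count is derived.

    annual count = incidence_per_million_per_year * population_size / 1e6
                   * subgroup_fraction
    """

    population_id: str
    label: str
    incidence_per_million_per_year: float
    population_size: int
    subgroup_fraction: float = 1.0

    def __post_init__(self):
        if self.incidence_per_million_per_year < 0:
            raise ValidationError(
                f"population {self.population_id!r}: negative incidence",
                self.population_id,
            )
        if self.population_size <= 0:
            raise ValidationError(
                f"population {self.population_id!r}: population_size must be positive",
                self.population_id,
            )
        if not (0.0 <= self.subgroup_fraction <= 1.0):
            raise ValidationError(
                f"population {self.population_id!r}: subgroup_fraction "
                f"{self.subgroup_fraction} outside [0, 1]",
                self.population_id,
            )

    @property
    def annual_transfusions(self) -> float:
        return (
            self.incidence_per_million_per_year
            * (self.population_size / 1e6)
            * self.subgroup_fraction
        )

    def to_dict(self) -> dict:
        return {
            "population_id": self.population_id,
            "label": self.label,
            "incidence_per_million_per_year": self.incidence_per_million_per_year,
            "population_size": self.population_size,
            "subgroup_fraction": self.subgroup_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        return cls(
            population_id=str(d.get("population_id", "")),
            label=str(d.get("label", "")),
            incidence_per_million_per_year=float(
                d.get("incidence_per_million_per_year", 0.0)
            ),
            population_size=int(d.get("population_size", 1)),
            subgroup_fraction=float(d.get("subgroup_fraction", 1.0)),
        )


@dataclass(frozen=True)
class MonteCarloConfig:
    iterations: int = 1000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self):
        if self.iterations < 1:
            raise ValidationError("mc.iterations must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValidationError("mc.ci_level must be in (0, 1)")

    def to_dict(self) -> dict:
        return {"iterations": self.iterations, "seed": self.seed, "ci_level": self.ci_level}

    @classmethod
    def from_dict(cls, d: dict) -> "MonteCarloConfig":
        return cls(
            iterations=int(d.get("iterations", 1000)),
            seed=int(d.get("seed", 0)),
            ci_level=float(d.get("ci_level", 0.95)),
        )


@dataclass(frozen=True)
class LifeYearsConfig:
    """Inputs of the life-years trade-off.

    A fatal or permanently disabling HDFN event is costed at
    ``life_years_lost_per_hdfn_event`` (83 years: UK life expectancy at
    birth, undiscounted).  ``survivor_life_years`` is a distribution over the
    life-years gained per trauma death averted.  ``survival_benefit_grid`` is
    the grid of absolute percentage-point improvements in survival scanned for
    the break-even point.
    """

    life_years_lost_per_hdfn_event: float = 83.0
    bootstrap_samples: int = 10_000
    survivor_life_years: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(
            "survivor_life_years", "triangular", (20.0, 40.0, 60.0),
            support="nonnegative",
        )
    )
    survival_benefit_grid: tuple[float, ...] = tuple(
        round(0.005 * i, 9) for i in range(401)  # 0 .. 2% in 0.005% steps
    )

    def __post_init__(self):
        if self.life_years_lost_per_hdfn_event <= 0:
            raise ValidationError("life_years_lost_per_hdfn_event must be positive")
        if self.bootstrap_samples < 1:
            raise ValidationError("bootstrap_samples must be >= 1")
        grid = tuple(float(g) for g in self.survival_benefit_grid)
        if not grid or any(b < a for a, b in zip(grid, grid[1:])):
            raise ValidationError("survival_benefit_grid must be non-empty and ascending")
        object.__setattr__(self, "survival_benefit_grid", grid)

    def to_dict(self) -> dict:
        return {
            "life_years_lost_per_hdfn_event": self.life_years_lost_per_hdfn_event,
            "bootstrap_samples": self.bootstrap_samples,
            "survivor_life_years": self.survivor_life_years.to_dict(),
            "survival_benefit_grid": list(self.survival_benefit_grid),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LifeYearsConfig":
        kwargs: dict = {}
        if "life_years_lost_per_hdfn_event" in d:
            kwargs["life_years_lost_per_hdfn_event"] = float(
                d["life_years_lost_per_hdfn_event"]
            )
        if "bootstrap_samples" in d:
            kwargs["bootstrap_samples"] = int(d["bootstrap_samples"])
        if "survivor_life_years" in d:
            sd = dict(d["survivor_life_years"])
            sd.setdefault("support", "nonnegative")
            kwargs["survivor_life_years"] = DistributionSpec.from_dict(
                sd, default_id="survivor_life_years"
            )
        if "survival_benefit_grid" in d:
            g = d["survival_benefit_grid"]
            if isinstance(g, dict):
                start, stop, step = float(g["start"]), float(g["stop"]), float(g["step"])
                n = int(round((stop - start) / step))
                kwargs["survival_benefit_grid"] = tuple(
                    round(start + i * step, 9) for i in range(n + 1)
                )
            else:
                kwargs["survival_benefit_grid"] = tuple(float(x) for x in g)
        return cls(**kwargs)


@dataclass(frozen=True)
class ModelConfig:
    """A fully cross-referenced model: inputs, events, harms, populations."""

    inputs: dict[str, DistributionSpec]
    events: dict[str, EventNode]
    harms: dict[str, HarmDefinition]
    populations: dict[str, PopulationSpec]
    life_years: LifeYearsConfig = field(default_factory=LifeYearsConfig)
    mc: MonteCarloConfig = field(default_factory=MonteCarloConfig)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.harms:
            raise ValidationError("config declares no harms")
        for eid, ev in self.events.items():
            if ev.event_id != eid:
                raise ValidationError(f"event key {eid!r} != event_id {ev.event_id!r}", eid)
            if ev.input_ref not in self.inputs:
                raise ValidationError(
                    f"event {eid!r}: input_ref {ev.input_ref!r} does not resolve "
                    "to any declared input",
                    ev.input_ref,
                )
            for pop, spec in ev.population_overrides.items():
                if pop not in self.populations:
                    raise ValidationError(
                        f"event {eid!r}: override for unknown population {pop!r}", pop
                    )
                if spec.support != "unit":
                    raise ValidationError(
                        f"event {eid!r}: override for {pop!r} must have unit support",
                        eid,
                    )
        for hid, harm in self.harms.items():
            for eid in harm.chain:
                if eid not in self.events:
                    raise ValidationError(
                        f"harm {hid!r}: chain references unknown event {eid!r}", eid
                    )
        for spec in self.inputs.values():
            if spec.support != "unit":
                raise ValidationError(
                    f"input {spec.input_id!r}: chain inputs must have unit support",
                    spec.input_id,
                )

    # -- convenience --------------------------------------------------------

    def event_distribution(self, event_id: str, population_id: str | None = None
                           ) -> DistributionSpec:
        """The distribution in force for one event in one population."""
        ev = self.events[event_id]
        if population_id is not None and population_id in ev.population_overrides:
            return ev.population_overrides[population_id]
        return self.inputs[ev.input_ref]

    def with_mc(self, **changes) -> "ModelConfig":
        return replace(self, mc=replace(self.mc, **changes))

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "inputs": [self.inputs[k].to_dict() for k in sorted(self.inputs)],
            "events": [self.events[k].to_dict() for k in sorted(self.events)],
            "harms": [self.harms[k].to_dict() for k in sorted(self.harms)],
            "populations": [self.populations[k].to_dict() for k in sorted(self.populations)],
            "life_years": self.life_years.to_dict(),
            "mc": self.mc.to_dict(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelConfig":
        if not isinstance(doc, dict):
            raise ValidationError("config document must be a mapping")
        version = int(doc.get("schema_version", SCHEMA_VERSION))
        if version != SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported schema_version {version} (supported: {SCHEMA_VERSION})"
            )

        def _collect(kind: str, factory, key: str) -> dict:
            out: dict = {}
            for item in doc.get(kind) or []:
                obj = factory(dict(item))
                ident = getattr(obj, key)
                if ident in out:
                    raise ValidationError(f"duplicate {key} {ident!r}", ident)
                out[ident] = obj
            return out

        return cls(
            inputs=_collect("inputs", DistributionSpec.from_dict, "input_id"),
            events=_collect("events", EventNode.from_dict, "event_id"),
            harms=_collect("harms", HarmDefinition.from_dict, "harm_id"),
            populations=_collect("populations", PopulationSpec.from_dict, "population_id"),
            life_years=LifeYearsConfig.from_dict(doc.get("life_years") or {}),
            mc=MonteCarloConfig.from_dict(doc.get("mc") or {}),
            schema_version=version,
        )


# -- file I/O ---------------------------------------------------------------


def loads_config(text: str) -> ModelConfig:
    """Parse and validate a YAML config document from a string."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValidationError(f"config parse error: {exc}") from exc
    return ModelConfig.from_dict(doc)


def load_config(path) -> ModelConfig:
    """Load and validate a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_config(fh.read())


def dumps_config(config: ModelConfig) -> str:
    buf = io.StringIO()
    yaml.safe_dump(config.to_dict(), buf, sort_keys=False, default_flow_style=None)
    return buf.getvalue()


def write_config(config: ModelConfig, path) -> None:
    """Write a config as YAML; ``load_config`` of the result reproduces it."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_config(config))


def default_config_path():
    """Path of the shipped default (placeholder-valued) configuration."""
    from importlib.resources import files

    return files("rhdrisk").joinpath("data/default_config.yaml")


def default_config() -> ModelConfig:
    """The shipped 14-event, 3-harm, 2-population configuration.

    Its distribution parameters are placeholders with plausible magnitudes;
    reproducing published risk tables requires transcribing the original
    input distributions into a user config.
    """
    return loads_config(default_config_path().read_text(encoding="utf-8"))
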