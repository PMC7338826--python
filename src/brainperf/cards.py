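"""Descriptor cards for *in silico* neuron models and hardware architectures.

The performance engines in this package are composed over two kinds of
structured descriptors ("cards"):

* :class:`InSilicoModelCard` -- a hardware-agnostic description of a neuron
  model: integration timestep, minimum network delay, connectivity fan-in,
  per-neuron/per-connection state counts and an inventory of simulation
  kernels (:class:`KernelDescriptor`), each annotated with its work-item
  cost vector (in-core cycles, load/store cycles, bytes crossing each
  memory-hierarchy boundary, flop, exponentials).

* :class:`HardwareCard` -- an abstract machine: thread count, clock, SIMD
  width, cache hierarchy with per-boundary bandwidths, memory bandwidth,
  latency and memory-level parallelism, and LogGP network parameters.

Cards are stored as YAML files (a set is packaged under ``brainperf/data``)
and validated on load.  Per-kernel cycle and byte constants in the packaged
cards are calibrated fixtures: each card file annotates its provenance
(nominal hardware spec, published model parameter, or fitted constant).
"""

from __future__ import annotations

import math
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Phase",
    "WorkItem",
    "Locality",
    "SynapseFormalism",
    "Morphology",
    "KernelDescriptor",
    "InSilicoModelCard",
    "CacheLevel",
    "LogGPParams",
    "HardwareCard",
    "CardSet",
    "CardValidationError",
    "load_cards",
    "default_cards",
    "save_cards",
    "calibration_report",
]

#: tolerance used when checking that delta_min is an integer multiple of dt
COUPLING_RATIO_TOL = 1e-9


class CardValidationError(ValueError):
    """A card file violated the schema or a semantic invariant."""


class Phase(str, Enum):
    clock_driven = "clock_driven"
    event_driven = "event_driven"


class WorkItem(str, Enum):
    per_neuron = "per_neuron"
    per_compartment = "per_compartment"
    per_synapse_instance = "per_synapse_instance"
    per_ion_channel = "per_ion_channel"
    per_event = "per_event"


class Locality(str, Enum):
    streaming = "streaming"
    random = "random"


class SynapseFormalism(str, Enum):
    I_based = "I_based"
    G_based = "G_based"


class Morphology(str, Enum):
    point = "point"
    detailed = "detailed"


#: clock-driven kernel inventories implied by the two algorithm skeletons.
#: I-based point models only integrate the neuron ODEs and accumulate
#: post-synaptic currents; G-based models additionally assemble and solve a
#: linear system per neuron and advance synapse/channel state equations.
ALGORITHM_SKELETONS: dict[SynapseFormalism, frozenset[str]] = {
    SynapseFormalism.I_based: frozenset({"state_update", "current_update"}),
    SynapseFormalism.G_based: frozenset(
        {"state_update", "current_update", "linear_solve"}
    ),
}
EVENT_KERNEL_NAME = "spike_delivery"


class KernelDescriptor(BaseModel):
    """Cost vector of one simulation kernel, per work item.

    ``t_OL`` is the in-core execution time assuming operands are already in
    registers, expressed in *scalar-lane* cycles; engines divide by the
    hardware SIMD width.  ``t_nOL`` is the load/store issue time.
    ``bytes_algorithmic`` is the hand-countable load/store volume of the
    algorithm per work item (what a flop/byte audit would report); the
    three boundary fields give the traffic actually crossing each
    memory-hierarchy boundary under streaming access, which can exceed the
    algorithmic volume (write-allocate, cache-line granularity).  Event-driven kernels with random
    locality instead pay ``cache_lines_per_event`` full cache lines per
    event (the erratic activation order defeats prefetching).
    """

    name: str
    phase: Phase
    work_item: WorkItem
    items_per_neuron: float = Field(1.0, ge=0)
    t_OL: float = Field(0.0, ge=0)
    t_nOL: float = Field(0.0, ge=0)
    n_exp: float = Field(0.0, ge=0)
    flop: float = Field(0.0, ge=0)
    bytes_algorithmic: float = Field(0.0, ge=0)
    bytes_l1l2: float = Field(0.0, ge=0)
    bytes_l2l3: float = Field(0.0, ge=0)
    bytes_l3mem: float = Field(0.0, ge=0)
    locality: Locality = Locality.streaming
    cache_lines_per_event: int | None = None
    provenance: str | None = None

    @model_validator(mode="after")
    def _check_locality(self) -> "KernelDescriptor":
        if self.locality is Locality.random:
            if self.phase is not Phase.event_driven:
                raise ValueError(
                    f"kernel {self.name!r}: random locality requires an "
                    "event-driven phase"
                )
            if self.cache_lines_per_event is None or self.cache_lines_per_event < 1:
                raise ValueError(
                    f"kernel {self.name!r}: random locality requires "
                    "cache_lines_per_event >= 1"
                )
        return self


class InSilicoModelCard(BaseModel):
    """Hardware-agnostic description of a published neuron model."""

    name: str
    synapse_formalism: SynapseFormalism
    morphology: Morphology
    dt: float = Field(gt=0, description="integration timestep [s]")
    delta_min: float = Field(gt=0, description="minimum network delay [s]")
    fan_in: float = Field(ge=0, description="mean incoming connections per neuron")
    firing_rate_default: float = Field(ge=0, description="mean firing rate [Hz]")
    state_vars_per_neuron: float = Field(ge=0)
    params_per_neuron: float = Field(ge=0)
    vars_per_connection: float = Field(ge=0)
    bytes_per_state_var: float = Field(8.0, gt=0)
    vars_per_spike: float = Field(1.0, ge=0)
    bytes_per_spike_message: float = Field(8.0, gt=0)
    kernels: list[KernelDescriptor] = Field(default_factory=list)
    provenance: str | None = None

    @model_validator(mode="after")
    def _check_invariants(self) -> "InSilicoModelCard":
        if self.delta_min < self.dt:
            raise ValueError(
                f"model {self.name!r}: delta_min ({self.delta_min}) must be "
                f">= dt ({self.dt})"
            )
        ratio = self.delta_min / self.dt
        if abs(ratio - round(ratio)) > COUPLING_RATIO_TOL * max(1.0, ratio):
            raise ValueError(
                f"model {self.name!r}: coupling ratio delta_min/dt = {ratio} "
                "is not an integer; fractional synchronization windows are "
                "rejected rather than rounded"
            )
        if self.kernels:
            clock = {k.name for k in self.kernels if k.phase is Phase.clock_driven}
            skeleton = ALGORITHM_SKELETONS[self.synapse_formalism]
            if clock != skeleton:
                raise ValueError(
                    f"model {self.name!r}: clock-driven kernels {sorted(clock)} "
                    f"do not match the {self.synapse_formalism.value} algorithm "
                    f"skeleton {sorted(skeleton)}"
                )
        return self

    @property
    def coupling_ratio(self) -> int:
        """Timesteps between two global spike-exchange synchronizations."""
        return round(self.delta_min / self.dt)

    @property
    def clock_kernels(self) -> list[KernelDescriptor]:
        return [k for k in self.kernels if k.phase is Phase.clock_driven]

    @property
    def event_kernels(self) -> list[KernelDescriptor]:
        return [k for k in self.kernels if k.phase is Phase.event_driven]

    def memory_per_neuron(self, fan_in: float | None = None) -> float:
        """Resident bytes to represent one neuron and its incoming synapses."""
        k = self.fan_in if fan_in is None else fan_in
        vars_neuron = self.state_vars_per_neuron + self.params_per_neuron
        return (vars_neuron + k * self.vars_per_connection) * self.bytes_per_state_var


class CacheLevel(BaseModel):
    """One cache level; ``bandwidth`` is the bytes/cycle the boundary
    between this level and the next-closer one can sustain."""

    name: str
    size: float = Field(gt=0, description="capacity [bytes]")
    bandwidth: float = Field(gt=0, description="boundary bandwidth [bytes/cycle]")


class LogGPParams(BaseModel):
    """LogGP network parameters (seconds; G is seconds per byte)."""

    L: float = Field(ge=0)
    o: float = Field(ge=0)
    g: float = Field(ge=0)
    G: float = Field(ge=0)


class HardwareCard(BaseModel):
    name: str
    n_threads: int = Field(ge=1)
    clock: float = Field(gt=0, description="core clock [Hz]")
    simd_doubles: int = Field(ge=1, description="SIMD width in double lanes")
    exp_cycles: float = Field(gt=0, description="cycles per exponential per lane")
    cache_levels: list[CacheLevel]
    mem_bandwidth: float = Field(gt=0, description="main memory bandwidth [B/s]")
    mem_latency: float = Field(gt=0, description="main memory latency [cycles]")
    mlp: float = Field(ge=1, description="max outstanding memory requests")
    cache_line: float = Field(64.0, gt=0)
    net: LogGPParams
    provenance: str | None = None

    @model_validator(mode="after")
    def _check_hierarchy(self) -> "HardwareCard":
        sizes = [lvl.size for lvl in self.cache_levels]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError(
                f"hardware {self.name!r}: cache sizes must be strictly "
                f"increasing along the hierarchy, got {sizes}"
            )
        return self

    @property
    def mem_bandwidth_cycles(self) -> float:
        """Main memory bandwidth in bytes per core clock cycle."""
        return self.mem_bandwidth / self.clock

    @property
    def residency_levels(self) -> list[str]:
        return [lvl.name for lvl in self.cache_levels] + ["MEM"]

    @property
    def last_level_cache(self) -> CacheLevel:
        return self.cache_levels[-1]

    def cache_level(self, name: str) -> CacheLevel:
        for lvl in self.cache_levels:
            if lvl.name == name:
                return lvl
        raise KeyError(f"hardware {self.name!r} has no cache level {name!r}")


class CardSet(BaseModel):
    models: dict[str, InSilicoModelCard] = Field(default_factory=dict)
    hardware: dict[str, HardwareCard] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_names(self) -> "CardSet":
        for key, card in {**self.models, **self.hardware}.items():
            if key != card.name:
                raise ValueError(f"card registered as {key!r} is named {card.name!r}")
        return self

    def model(self, name: str) -> InSilicoModelCard:
        try:
            return self.models[name]
        except KeyError:
            raise KeyError(
                f"unknown model card {name!r}; available: {sorted(self.models)}"
            ) from None

    def hw(self, name: str) -> HardwareCard:
        try:
            return self.hardware[name]
        except KeyError:
            raise KeyError(
                f"unknown hardware card {name!r}; available: {sorted(self.hardware)}"
            ) from None


# ---------------------------------------------------------------------------
# loading / saving


def _load_one(path: Path) -> tuple[str, InSilicoModelCard | HardwareCard]:
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - parser detail
        raise CardValidationError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, Mapping) or "kind" not in raw:
        raise CardValidationError(f"{path}: card files need a top-level 'kind' key")
    kind = raw["kind"]
    body = {k: v for k, v in raw.items() if k != "kind"}
    try:
        if kind == "model":
            return "model", InSilicoModelCard(**body)
        if kind == "hardware":
            return "hardware", HardwareCard(**body)
    except ValueError as exc:
        raise CardValidationError(f"{path}: {exc}") from exc
    raise CardValidationError(f"{path}: unknown card kind {kind!r}")


def load_cards(paths: Iterable[str | Path]) -> CardSet:
    """Load and validate model/hardware cards from YAML files or directories.

    Raises :class:`CardValidationError` naming the offending file and field
    on any schema or invariant violation.
    """
    models: dict[str, InSilicoModelCard] = {}
    hardware: dict[str, HardwareCard] = {}
    files: list[Path] = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            files.extend(sorted(p.glob("**/*.yaml")))
        elif p.exists():
            files.append(p)
        else:
            raise CardValidationError(f"card path does not exist: {p}")
    for f in files:
        kind, card = _load_one(f)
        registry = models if kind == "model" else hardware
        if card.name in registry:
            raise CardValidationError(f"{f}: duplicate card name {card.name!r}")
        registry[card.name] = card
    return CardSet(models=models, hardware=hardware)


def default_cards() -> CardSet:
    """The packaged card set: three neuron models, five hardware variants."""
    root = resources.files("brainperf").joinpath("data")
    with resources.as_file(root) as data_dir:
        return load_cards([data_dir])


def save_cards(cards: CardSet, directory: str | Path) -> list[Path]:
    """Write every card in ``cards`` to ``directory`` as YAML; returns paths.

    ``save_cards`` then ``load_cards`` round-trips to an identical CardSet.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for kind, registry in [("model", cards.models), ("hardware", cards.hardware)]:
        for name, card in registry.items():
            payload = {"kind": kind, **card.model_dump(mode="json")}
            path = directory / f"{kind}_{name}.yaml"
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
            written.append(path)
    return written


# ---------------------------------------------------------------------------
# calibration report


def calibration_report(model: InSilicoModelCard, rate: float) -> pd.Series:
    """Aggregate a model's kernel inventory over one simulated second.

    Clock-driven kernels execute ``1/dt`` times; event-driven kernels fire
    ``fan_in * rate`` times (deterministic mean-rate accounting).  The data
    volume sums each kernel's ``bytes_algorithmic`` -- the hand-countable
    loads and stores the algorithm performs per work item, i.e. the useful
    payload rather than the (generally larger, fitted) traffic that
    actually crosses each hardware boundary.

    Returns a Series with, per neuron per simulated second: ``flop``,
    ``data_volume_bytes``, ``arithmetic_intensity`` [flop/B],
    ``memory_capacity_bytes`` (rate-independent resident footprint).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    steps = 1.0 / model.dt
    events = model.fan_in * rate
    flop = 0.0
    volume = 0.0
    for k in model.kernels:
        mult = steps if k.phase is Phase.clock_driven else events
        flop += mult * k.items_per_neuron * k.flop
        volume += mult * k.items_per_neuron * k.bytes_algorithmic
    intensity = flop / volume if volume > 0 else math.nan
    return pd.Series(
        {
            "flop": flop,
            "data_volume_bytes": volume,
            "arithmetic_intensity": intensity,
            "memory_capacity_bytes": model.memory_per_neuron(),
        },
        name=model.name,
    )
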