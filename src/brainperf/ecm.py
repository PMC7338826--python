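"""Execution-Cache-Memory (ECM) runtime model for streaming kernels.

The ECM model decomposes the serial runtime of a loop (per work item, in
core cycles) into an in-core part and a data part::

    t_core = t_OL / simd_doubles + n_exp * exp_cycles
    t_data = t_nOL + sum of boundary transfer times outside the residency
    t_serial = max(t_core, t_data)

Transfer times are the kernel's per-boundary byte counts divided by the
hardware boundary bandwidths.  In-core execution and data transfers are
assumed to overlap fully (the non-overlapping-transfers convention: t_nOL
is accounted on the data path).  A kernel is *core bound* if
``t_core > t_data`` and *data bound* otherwise.

Thread scaling is linear until a shared resource saturates; on the
architectures modelled here that resource is the memory interface, so

    throughput(n) = min(n / t_serial, 1 / t_mem)

and the saturation point is ``n_satur = ceil(t_serial / t_mem)``.

The loop-ordering optimization advances each neuron through all timesteps
of a minimum-delay window consecutively, so main-memory traffic is paid
only on the first of the ``r = delta_min/dt`` steps and the remaining
``r - 1`` stream from the last-level cache:
``t_mem_effective = t_mem / r`` (equivalently a 1/r : (r-1)/r blend of
memory and last-level-cache residency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from . import events as _events
from .cards import HardwareCard, InSilicoModelCard, KernelDescriptor, Locality, Phase

__all__ = [
    "Boundedness",
    "EcmPrediction",
    "KernelStepCost",
    "boundary_transfers",
    "ecm_serial",
    "saturation_point",
    "model_saturation_point",
    "thread_scaling",
    "loop_ordering_traffic",
    "bandwidth_utilization",
    "aggregate_step_cost",
    "UNBOUNDED",
]

#: sentinel returned when no memory traffic exists and saturation never occurs
UNBOUNDED = math.inf


class Boundedness(str, Enum):
    core_bound = "core_bound"
    data_bound = "data_bound"


def boundary_transfers(
    k: KernelDescriptor, hw: HardwareCard
) -> list[tuple[str, float]]:
    """Per-boundary transfer cycles for one work item, innermost first.

    The kernel's three byte fields describe a three-level hierarchy; on
    shallower hierarchies (e.g. a GPU-like card where compute units talk
    almost directly to device memory) only the innermost fields are used
    and the memory-boundary field always applies last.
    """
    names = [lvl.name for lvl in hw.cache_levels]
    inner_bytes = [k.bytes_l1l2, k.bytes_l2l3]
    out: list[tuple[str, float]] = []
    for i in range(len(names) - 1):
        if i >= len(inner_bytes):  # pragma: no cover - cards cap at 3 levels
            break
        bw = hw.cache_levels[i + 1].bandwidth
        out.append((f"{names[i]}{names[i + 1]}", inner_bytes[i] / bw))
    out.append((f"{names[-1]}Mem", k.bytes_l3mem / hw.mem_bandwidth_cycles))
    return out


def _residency_index(hw: HardwareCard, residency: str) -> int:
    """Number of boundary terms included for a given residency."""
    if residency == "MEM":
        return len(hw.cache_levels)
    for i, lvl in enumerate(hw.cache_levels):
        if lvl.name == residency:
            return i
    raise ValueError(
        f"unknown residency {residency!r}; choose from {hw.residency_levels}"
    )


@dataclass(frozen=True)
class EcmPrediction:
    """Serial ECM decomposition of one streaming kernel, cycles/work item."""

    kernel: str
    residency: str
    t_OL: float  # in-core, SIMD-scaled, excluding exponentials
    t_exp: float
    t_nOL: float
    transfers: dict[str, float] = field(default_factory=dict)  # included terms
    t_core: float = 0.0
    t_data: float = 0.0
    t_serial: float = 0.0
    t_mem: float = 0.0  # memory-boundary term (post loop-ordering), saturable
    bound: Boundedness = Boundedness.core_bound
    n_satur: float = UNBOUNDED

    @property
    def t_l1l2(self) -> float:
        return next((v for k, v in self.transfers.items() if k.startswith("L1")), 0.0)

    @property
    def t_l2l3(self) -> float:
        return next(
            (v for k, v in self.transfers.items()
             if k.startswith("L2") and not k.endswith("Mem")),
            0.0,
        )

    @property
    def t_l3mem(self) -> float:
        return next((v for k, v in self.transfers.items() if k.endswith("Mem")), 0.0)


def ecm_serial(
    k: KernelDescriptor,
    hw: HardwareCard,
    residency: str = "MEM",
    coupling_ratio: int = 1,
    loop_ordering: bool = False,
) -> EcmPrediction:
    """Serial ECM prediction for a streaming (clock-driven) kernel.

    ``residency`` names the memory-hierarchy level holding the working set;
    transfer terms for boundaries inside it cost nothing.  With
    ``loop_ordering`` and memory residency, the memory-boundary term is
    divided by ``coupling_ratio``.
    """
    if k.locality is not Locality.streaming or k.phase is Phase.event_driven:
        raise ValueError(
            f"kernel {k.name!r} is event-driven/random-access; use the event "
            "engine (brainperf.events) for spike delivery"
        )
    if coupling_ratio < 1:
        raise ValueError("coupling_ratio must be >= 1")
    idx = _residency_index(hw, residency)
    all_transfers = boundary_transfers(k, hw)
    included = dict(all_transfers[:idx])
    if residency == "MEM" and loop_ordering:
        mem_name = all_transfers[-1][0]
        included[mem_name] = included[mem_name] / coupling_ratio
    t_mem = included.get(all_transfers[-1][0], 0.0) if residency == "MEM" else 0.0
    t_ol = k.t_OL / hw.simd_doubles
    t_exp = k.n_exp * hw.exp_cycles
    t_core = t_ol + t_exp
    t_data = k.t_nOL + sum(included.values())
    t_serial = max(t_core, t_data)
    return EcmPrediction(
        kernel=k.name,
        residency=residency,
        t_OL=t_ol,
        t_exp=t_exp,
        t_nOL=k.t_nOL,
        transfers=included,
        t_core=t_core,
        t_data=t_data,
        t_serial=t_serial,
        t_mem=t_mem,
        bound=Boundedness.core_bound if t_core > t_data else Boundedness.data_bound,
        n_satur=saturation_point(t_serial, t_mem),
    )


def saturation_point(t_serial: float, t_mem: float) -> float:
    """Thread count at which the memory interface saturates.

    ``ceil(t_serial / t_mem)``; the unbounded sentinel (``math.inf``) when
    there is no memory traffic.
    """
    if t_mem <= 0:
        return UNBOUNDED
    return float(math.ceil(t_serial / t_mem))


def thread_scaling(pred: EcmPrediction, hw: HardwareCard, n: int) -> float:
    """Effective cycles per work item at ``n`` threads.

    Linear speedup of the serial time until the shared memory bandwidth
    bound ``t_mem`` is reached: ``1 / min(n/t_serial, 1/t_mem)``.
    """
    if not 1 <= n <= hw.n_threads:
        raise ValueError(f"n must be in [1, {hw.n_threads}]")
    per_thread = pred.t_serial / n
    return max(per_thread, pred.t_mem)


def loop_ordering_traffic(
    model: InSilicoModelCard,
    hw: HardwareCard,
    use_optimization: bool,
    coupling_ratio: int | None = None,
) -> dict[str, float]:
    """Effective per-timestep ``t_data`` of each clock-driven kernel.

    Without the optimization every timestep pays full main-memory traffic;
    with it the memory term is amortized over the ``r`` steps of a
    minimum-delay window (data fetched from memory only on the first step,
    from the last-level cache afterwards).
    """
    r = model.coupling_ratio if coupling_ratio is None else coupling_ratio
    out = {}
    for k in model.clock_kernels:
        pred = ecm_serial(
            k, hw, residency="MEM", coupling_ratio=r, loop_ordering=use_optimization
        )
        out[k.name] = pred.t_data
    return out


# ---------------------------------------------------------------------------
# model-level aggregation

#: hardware-feature labels used in runtime attributions
FEATURES = (
    "CPU",
    "exp",
    "T_load",
    "L1L2",
    "L2L3",
    "MemBW",
    "MLP_latency",
    "NetLatency",
    "NetBandwidth",
)


@dataclass(frozen=True)
class KernelStepCost:
    """Per-neuron per-timestep cost of one kernel at a thread count."""

    name: str
    phase: Phase
    cycles: float  # effective cycles per neuron-step at n threads
    serial_cycles: float  # at one thread
    mem_cycles: float  # DRAM cycles per neuron-step at full bandwidth
    saturated: bool
    features: dict[str, float] = field(default_factory=dict)  # sums to `cycles`


def _clock_step_cost(
    k: KernelDescriptor,
    hw: HardwareCard,
    n_threads: int,
    residency: str,
    loop_ordering: bool,
    r: int,
) -> KernelStepCost:
    pred = ecm_serial(
        k, hw, residency=residency, coupling_ratio=r, loop_ordering=loop_ordering
    )
    items = k.items_per_neuron
    serial = pred.t_serial * items
    t_mem_item = pred.t_mem if residency == "MEM" else 0.0
    mem = t_mem_item * items
    per_item = max(pred.t_serial / n_threads, t_mem_item)
    cycles = per_item * items
    saturated = t_mem_item > 0 and t_mem_item >= pred.t_serial / n_threads
    features: dict[str, float]
    if saturated:
        features = {"MemBW": cycles}
    elif pred.bound is Boundedness.core_bound:
        tot = pred.t_core
        features = {
            "CPU": cycles * pred.t_OL / tot,
            "exp": cycles * pred.t_exp / tot,
        }
    elif pred.t_data > 0:
        tot = pred.t_data
        features = {"T_load": cycles * pred.t_nOL / tot}
        for bname, t in pred.transfers.items():
            label = "MemBW" if bname.endswith("Mem") else bname
            features[label] = features.get(label, 0.0) + cycles * t / tot
    else:  # zero-cost kernel: nothing to attribute
        features = {}
    return KernelStepCost(
        name=k.name,
        phase=Phase.clock_driven,
        cycles=cycles,
        serial_cycles=serial,
        mem_cycles=mem,
        saturated=saturated,
        features=features,
    )


def _event_step_cost(
    model: InSilicoModelCard,
    hw: HardwareCard,
    rate: float,
    n_threads: int,
    residency: str,
) -> KernelStepCost:
    k = _events.event_kernel(model)
    cost = _events.event_cost(model, hw, rate, n_threads=n_threads, residency=residency)
    ev = cost.events_per_neuron_step
    serial = (
        _events.event_cost(model, hw, rate, 1, residency).t_event * ev
    )
    mem = cost.t_bandwidth * ev if residency == "MEM" else 0.0
    cycles = cost.t_event * ev
    saturated = residency == "MEM" and cost.binding is _events.Binding.bandwidth
    if saturated:
        features = {"MemBW": cycles}
    elif cost.binding is _events.Binding.mlp_latency:
        features = {"MLP_latency": cycles}
    elif residency != "MEM" and cost.t_bandwidth >= cost.t_core:
        # optimistic in-cache delivery: charge the boundary feeding that level
        label = {0: "T_load", 1: "L1L2", 2: "L2L3"}[_residency_index(hw, residency)]
        features = {label: cycles}
    else:
        tot = cost.t_core or 1.0
        t_ol = k.t_OL / hw.simd_doubles
        features = {
            "CPU": cycles * t_ol / tot,
            "exp": cycles * (k.n_exp * hw.exp_cycles) / tot,
        }
    return KernelStepCost(
        name=k.name,
        phase=Phase.event_driven,
        cycles=cycles,
        serial_cycles=serial,
        mem_cycles=mem,
        saturated=saturated,
        features=features,
    )


def aggregate_step_cost(
    model: InSilicoModelCard,
    hw: HardwareCard,
    rate: float | None = None,
    n_threads: int = 1,
    residency: str = "MEM",
    loop_ordering: bool = False,
    coupling_ratio: int | None = None,
) -> list[KernelStepCost]:
    """Per-kernel cost of advancing one neuron by one timestep.

    The workhorse behind every composite scenario: clock-driven kernels go
    through the ECM path (with residency/loop-ordering), the spike-delivery
    kernel through the event path (never helped by loop ordering).
    """
    f = model.firing_rate_default if rate is None else rate
    r = model.coupling_ratio if coupling_ratio is None else coupling_ratio
    out = [
        _clock_step_cost(k, hw, n_threads, residency, loop_ordering, r)
        for k in model.clock_kernels
    ]
    if model.event_kernels:
        out.append(_event_step_cost(model, hw, f, n_threads, residency))
    return out


def model_saturation_point(
    model: InSilicoModelCard,
    hw: HardwareCard,
    rate: float | None = None,
    loop_ordering: bool = False,
    coupling_ratio: int | None = None,
) -> float:
    """Saturation thread count of the whole model (duty-cycle weighted).

    Computed on the aggregate of all kernels: the ratio of total serial
    cycles per neuron-step to total memory-boundary cycles per neuron-step.
    """
    costs = aggregate_step_cost(
        model,
        hw,
        rate=rate,
        n_threads=1,
        residency="MEM",
        loop_ordering=loop_ordering,
        coupling_ratio=coupling_ratio,
    )
    t_serial = sum(c.serial_cycles for c in costs)
    t_mem = sum(c.mem_cycles for c in costs)
    return saturation_point(t_serial, t_mem)


def bandwidth_utilization(
    model: InSilicoModelCard,
    hw: HardwareCard,
    n_threads: int,
    rate: float | None = None,
    loop_ordering: bool = False,
    coupling_ratio: int | None = None,
) -> float:
    """Fraction of main-memory bandwidth consumed at ``n_threads`` threads.

    Each thread demands memory traffic at a rate ``t_mem / t_serial`` of
    the full bandwidth; the aggregate is capped at 1.
    """
    if n_threads < 1:
        raise ValueError("n_threads must be >= 1")
    costs = aggregate_step_cost(
        model,
        hw,
        rate=rate,
        n_threads=1,
        residency="MEM",
        loop_ordering=loop_ordering,
        coupling_ratio=coupling_ratio,
    )
    t_serial = sum(c.serial_cycles for c in costs)
    t_mem = sum(c.mem_cycles for c in costs)
    if t_serial <= 0 or t_mem <= 0:
        return 0.0
    return min(1.0, n_threads * t_mem / t_serial)
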