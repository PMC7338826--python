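"""Runtime model of the event-driven spike-delivery kernel.

Spike delivery integrates arriving synaptic events into postsynaptic state.
Its memory access pattern is random: the activation order of synapses is
unpredictable, so each event touches ``cache_lines_per_event`` full cache
lines that, in the worst case, must come from main memory.  Because events
are independent, the processor can keep several such requests in flight;
the per-event cost is therefore bounded below by three candidate terms

* latency / memory-level parallelism: ``lines * mem_latency / mlp``,
* the bandwidth floor: ``lines * cache_line / (memory bytes per cycle)``,
* the in-core integration work ``t_core`` (for conductance-based synapses
  this includes the short-term-plasticity update with its exponentials;
  for current-based synapses it is a weighted counter increment),

and the model takes their maximum.  With ``n`` threads the latency and core
paths scale linearly while the bandwidth floor is shared.  An optimistic
in-cache variant charges the lines to a cache level's boundary bandwidth
instead (used for cache-residency scenarios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .cards import (
    EVENT_KERNEL_NAME,
    HardwareCard,
    InSilicoModelCard,
    KernelDescriptor,
    Phase,
)

__all__ = [
    "Binding",
    "EventCost",
    "event_rate",
    "event_kernel",
    "event_cost",
    "spike_delivery_time",
]


class Binding(str, Enum):
    mlp_latency = "mlp_latency"
    bandwidth = "bandwidth"
    core = "core"


@dataclass(frozen=True)
class EventCost:
    """Per-event cost decomposition, cycles."""

    events_per_neuron_step: float
    lines_per_event: int
    t_latency: float
    t_bandwidth: float
    t_core: float
    t_event: float
    binding: Binding

    @property
    def cycles_per_neuron_step(self) -> float:
        return self.events_per_neuron_step * self.t_event


def event_rate(model: InSilicoModelCard, rate: float) -> float:
    """Mean synaptic events per neuron per timestep: ``K * rate * dt``."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return model.fan_in * rate * model.dt


def event_kernel(model: InSilicoModelCard) -> KernelDescriptor:
    for k in model.kernels:
        if k.phase is Phase.event_driven:
            return k
    raise ValueError(
        f"model {model.name!r} has no event-driven kernel "
        f"(expected {EVENT_KERNEL_NAME!r})"
    )


def _core_time(k: KernelDescriptor, hw: HardwareCard) -> float:
    return k.t_OL / hw.simd_doubles + k.n_exp * hw.exp_cycles


def event_cost(
    model: InSilicoModelCard,
    hw: HardwareCard,
    rate: float,
    n_threads: int = 1,
    residency: str = "MEM",
) -> EventCost:
    """Cost of spike delivery per event at ``n_threads`` threads.

    ``residency='MEM'`` is the default worst case (nothing cacheable); a
    cache level name gives the optimistic in-cache variant where the lines
    are charged to that level's boundary bandwidth and the DRAM latency
    does not apply.
    """
    if not 1 <= n_threads <= hw.n_threads:
        raise ValueError(f"n_threads must be in [1, {hw.n_threads}]")
    k = event_kernel(model)
    lines = k.cache_lines_per_event or 1
    line_bytes = lines * hw.cache_line
    t_core = _core_time(k, hw)
    if residency == "MEM":
        t_lat = lines * hw.mem_latency / hw.mlp
        # latency and core paths are private to a thread; the memory
        # bandwidth is the shared floor
        t_bw = line_bytes / hw.mem_bandwidth_cycles
        t_event = max(max(t_lat, t_core) / n_threads, t_bw)
    else:
        t_lat = 0.0
        t_bw = line_bytes / hw.cache_level(residency).bandwidth
        t_event = max(t_core, t_bw) / n_threads
    if residency == "MEM" and t_bw >= max(t_lat, t_core) / n_threads:
        binding = Binding.bandwidth  # shared floor binds (ties included)
    elif residency != "MEM" and t_bw >= t_core:
        binding = Binding.bandwidth
    elif t_lat >= t_core:
        binding = Binding.mlp_latency
    else:
        binding = Binding.core
    return EventCost(
        events_per_neuron_step=event_rate(model, rate),
        lines_per_event=lines,
        t_latency=t_lat,
        t_bandwidth=t_bw,
        t_core=t_core,
        t_event=t_event,
        binding=binding,
    )


def spike_delivery_time(
    model: InSilicoModelCard,
    hw: HardwareCard,
    rate: float,
    n_threads: int = 1,
    residency: str = "MEM",
) -> float:
    """Cycles per neuron per timestep spent delivering spikes.

    Unaffected by the loop-ordering optimization: event data is presumed
    evicted between reuses regardless of the synchronization window.
    """
    cost = event_cost(model, hw, rate, n_threads=n_threads, residency=residency)
    return cost.cycles_per_neuron_step
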