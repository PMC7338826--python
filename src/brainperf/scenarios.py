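"""Composite performance scenarios: serial, shared-memory, distributed.

Performance is reported in simulated seconds per wallclock second, either
per neuron (single-node profiles: how fast can one neuron's worth of work
be advanced when the node is filled with neurons) or for the whole network
(distributed runs: how much biological time the full simulation advances
per wall second).  Every result carries a breakdown of runtime into
simulation kernels and into hardware features, with the dominant feature
as the bottleneck label.

Attribution is winner-take-all per kernel (only the path that wins the
ECM/event max() contributes) and proportional within the winning path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from . import ecm as _ecm
from . import netcomm as _net
from .cards import HardwareCard, InSilicoModelCard, Phase

__all__ = [
    "ScenarioResult",
    "ScalingMode",
    "serial_profile",
    "saturated_throughput",
    "shared_memory_profile",
    "distributed_performance",
    "bottleneck_attribution",
    "bottleneck_grid",
]

_SUM_TOL = 1e-6


class ScalingMode(str, Enum):
    memory_constrained = "memory_constrained"  # weak scaling
    constant_problem = "constant_problem"  # strong scaling


@dataclass(frozen=True)
class ScenarioResult:
    performance: float  # simulated seconds per wallclock second
    unit: str  # "per_neuron" | "network"
    kernel_breakdown: dict[str, float] = field(default_factory=dict)
    feature_breakdown: dict[str, float] = field(default_factory=dict)
    bottleneck: str = ""
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, frac in (
            ("kernel", self.kernel_breakdown),
            ("feature", self.feature_breakdown),
        ):
            if frac and abs(sum(frac.values()) - 1.0) > _SUM_TOL:
                raise ValueError(f"{name} fractions must sum to 1, got {frac}")


def _finalize(
    perf: float,
    unit: str,
    kernel_cycles: dict[str, float],
    feature_cycles: dict[str, float],
    config: dict,
) -> ScenarioResult:
    total = sum(kernel_cycles.values())
    ftotal = sum(feature_cycles.values())
    if total <= 0 or ftotal <= 0:
        raise ValueError("degenerate configuration: zero total runtime")
    features = {k: v / ftotal for k, v in feature_cycles.items() if v > 0}
    return ScenarioResult(
        performance=perf,
        unit=unit,
        kernel_breakdown={k: v / total for k, v in kernel_cycles.items() if v > 0},
        feature_breakdown=features,
        bottleneck=max(features, key=lambda k: features[k]),
        config=config,
    )


def _node_costs(
    model: InSilicoModelCard,
    hw: HardwareCard,
    rate: float | None,
    n_threads: int,
    residency: str,
    loop_ordering: bool,
):
    costs = _ecm.aggregate_step_cost(
        model,
        hw,
        rate=rate,
        n_threads=n_threads,
        residency=residency,
        loop_ordering=loop_ordering,
    )
    kernel_cycles = {c.name: c.cycles for c in costs}
    feature_cycles: dict[str, float] = {}
    for c in costs:
        for feat, cy in c.features.items():
            feature_cycles[feat] = feature_cycles.get(feat, 0.0) + cy
    return costs, kernel_cycles, feature_cycles


def serial_profile(
    model: InSilicoModelCard, hw: HardwareCard, rate: float | None = None
) -> ScenarioResult:
    """Single-thread, memory-resident performance of one neuron.

    Sums all clock-driven kernels over the ``1/dt`` steps of a simulated
    second plus event costs at the firing rate; no loop ordering.
    """
    costs, kcy, fcy = _node_costs(model, hw, rate, 1, "MEM", False)
    cycles_per_step = sum(c.cycles for c in costs)
    if cycles_per_step <= 0:
        raise ValueError(
            f"model {model.name!r} has no runtime cost at this rate; the "
            "serial profile is undefined"
        )
    wall_per_sim_s = cycles_per_step / (model.dt * hw.clock)
    return _finalize(
        1.0 / wall_per_sim_s,
        "per_neuron",
        kcy,
        fcy,
        {"model": model.name, "hardware": hw.name, "rate": rate, "threads": 1},
    )


def saturated_throughput(
    model: InSilicoModelCard, hw: HardwareCard, rate: float | None = None
) -> float:
    """Per-neuron performance assuming memory bandwidth is fully saturated.

    The theoretical shared-memory ceiling without loop ordering: all DRAM
    traffic (streaming plus event cache lines) runs at full bandwidth and
    nothing else costs time: ``dt / (bytes per neuron-step / bandwidth)``.
    Returns the unbounded sentinel for a model with no memory traffic.
    """
    costs = _ecm.aggregate_step_cost(model, hw, rate=rate, n_threads=1)
    mem_cycles = sum(c.mem_cycles for c in costs)
    if mem_cycles <= 0:
        return _ecm.UNBOUNDED
    return model.dt * hw.clock / mem_cycles


def shared_memory_profile(
    model: InSilicoModelCard,
    hw: HardwareCard,
    n_threads: int | None = None,
    residency: str = "MEM",
    loop_ordering: bool = True,
    rate: float | None = None,
) -> ScenarioResult:
    """Per-neuron performance on one node at ``n_threads`` threads.

    Kernels scale linearly in threads up to the shared memory-bandwidth
    floor (memory residency only); cache residencies assume the working
    set is served from that level.
    """
    n = hw.n_threads if n_threads is None else n_threads
    if not 1 <= n <= hw.n_threads:
        raise ValueError(f"n_threads must be in [1, {hw.n_threads}]")
    costs, kcy, fcy = _node_costs(model, hw, rate, n, residency, loop_ordering)
    cycles_per_step = sum(c.cycles for c in costs)
    perf = model.dt * hw.clock / cycles_per_step
    return _finalize(
        perf,
        "per_neuron",
        kcy,
        fcy,
        {
            "model": model.name,
            "hardware": hw.name,
            "rate": rate,
            "threads": n,
            "residency": residency,
            "loop_ordering": loop_ordering,
        },
    )


def distributed_performance(
    model: InSilicoModelCard,
    hw: HardwareCard,
    total_neurons: float,
    ranks: int,
    mode: ScalingMode | str = ScalingMode.memory_constrained,
    rate: float | None = None,
    unit: str = "network",
    collective: str = "ring",
) -> ScenarioResult:
    """Whole-network performance of ``total_neurons`` over ``ranks`` ranks.

    Each rank advances its ``N/P`` neurons through one minimum-delay window
    (``r`` timesteps, all node threads, loop ordering, memory residency),
    then all ranks exchange spikes via a blocking collective.  Shared-memory
    parallelism is exhausted before distributed parallelism, so every rank
    always uses the full node.  Configurations with fewer neurons than
    ranks would require splitting single neurons and are rejected.
    """
    mode = ScalingMode(mode)
    if ranks < 1:
        raise ValueError("ranks must be >= 1")
    if total_neurons < ranks:
        raise ValueError(
            f"{total_neurons} neurons over {ranks} ranks would require "
            "sub-neuron splitting, which is unsupported"
        )
    f = model.firing_rate_default if rate is None else rate
    local = total_neurons / ranks
    costs, kcy, fcy = _node_costs(model, hw, f, hw.n_threads, "MEM", True)
    cycles_per_step = sum(c.cycles for c in costs)
    r = model.coupling_ratio
    compute_s = r * cycles_per_step * local / hw.clock
    m = _net.spike_message_size(model, local, f)
    comms = _net.COLLECTIVE_POLICIES[collective](ranks, m, hw.net)
    window = compute_s + comms.total
    perf_network = model.delta_min / window
    # express kernel/feature cycles and comms on a common (seconds) scale
    kernel_s = {k: v * r * local / hw.clock for k, v in kcy.items()}
    feature_s = {k: v * r * local / hw.clock for k, v in fcy.items()}
    if comms.total > 0:
        kernel_s["spike_exchange"] = comms.total
        feature_s["NetLatency"] = feature_s.get("NetLatency", 0.0) + comms.latency_term
        feature_s["NetBandwidth"] = (
            feature_s.get("NetBandwidth", 0.0) + comms.bandwidth_term
        )
    perf = perf_network * total_neurons if unit == "per_neuron" else perf_network
    return _finalize(
        perf,
        unit,
        kernel_s,
        feature_s,
        {
            "model": model.name,
            "hardware": hw.name,
            "total_neurons": total_neurons,
            "ranks": ranks,
            "mode": mode.value,
            "rate": f,
            "collective": collective,
        },
    )


def bottleneck_attribution(
    model: InSilicoModelCard,
    hw: HardwareCard,
    total_neurons: float,
    ranks: int,
    rate: float | None = None,
) -> tuple[str, dict[str, float]]:
    """Dominant hardware feature and full feature breakdown for a config."""
    res = distributed_performance(model, hw, total_neurons, ranks, rate=rate)
    return res.bottleneck, res.feature_breakdown


def bottleneck_grid(
    model: InSilicoModelCard,
    hw: HardwareCard,
    neuron_counts,
    rank_counts,
    rate: float | None = None,
):
    """Map of (total_neurons, ranks) -> dominant-bottleneck label.

    Infeasible configurations (sub-neuron splitting) are labelled
    ``"unsupported"``, mirroring the greyed-out regions of a design-space
    map.
    """
    grid: dict[tuple[float, int], str] = {}
    for n in neuron_counts:
        for p in rank_counts:
            if n < p:
                grid[(n, p)] = "unsupported"
            else:
                grid[(n, p)] = bottleneck_attribution(model, hw, n, p, rate=rate)[0]
    return grid
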