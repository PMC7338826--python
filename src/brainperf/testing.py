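"""Toy generators and brute-force oracles for validating the engines.

Everything here is deliberately simple and self-contained: the oracles
re-derive costs by explicit enumeration (no code shared with the engines
they check), and the toy generators produce random but invariant-respecting
kernels and cards so that the engines can be exercised without any of the
calibrated packaged cards.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .cards import (
    CacheLevel,
    HardwareCard,
    InSilicoModelCard,
    KernelDescriptor,
    Locality,
    LogGPParams,
    Phase,
    WorkItem,
)

__all__ = [
    "ToySpec",
    "random_kernel",
    "toy_hardware",
    "toy_model",
    "oracle_cycle_account",
    "oracle_ring_sim",
    "oracle_serialized_event_time",
]


@dataclass(frozen=True)
class ToySpec:
    """Reproducible recipe for random toy kernels."""

    seed: int = 0
    cycles_range: tuple[float, float] = (0.0, 50.0)
    bytes_range: tuple[float, float] = (0.0, 512.0)
    flop_range: tuple[float, float] = (0.0, 100.0)
    exp_range: tuple[float, float] = (0.0, 4.0)
    p_event: float = 0.0  # probability a draw is an event-driven kernel


def random_kernel(spec: ToySpec, index: int = 0) -> KernelDescriptor:
    """Draw one invariant-respecting kernel; same (seed, index) -> same kernel."""
    rng = random.Random(f"{spec.seed}:{index}")
    event = rng.random() < spec.p_event
    common = dict(
        items_per_neuron=rng.choice([1, 1, 2, 10, 100]),
        t_OL=rng.uniform(*spec.cycles_range),
        t_nOL=rng.uniform(*spec.cycles_range),
        n_exp=rng.uniform(*spec.exp_range),
        flop=rng.uniform(*spec.flop_range),
        bytes_l1l2=rng.uniform(*spec.bytes_range),
        bytes_l2l3=rng.uniform(*spec.bytes_range),
        bytes_l3mem=rng.uniform(*spec.bytes_range),
    )
    if event:
        return KernelDescriptor(
            name="spike_delivery",
            phase=Phase.event_driven,
            work_item=WorkItem.per_event,
            locality=Locality.random,
            cache_lines_per_event=rng.randint(1, 4),
            **common,
        )
    return KernelDescriptor(
        name=f"toy_{index}",
        phase=Phase.clock_driven,
        work_item=WorkItem.per_neuron,
        locality=Locality.streaming,
        **common,
    )


def toy_hardware(
    seed: int = 0,
    n_threads: int = 8,
    simd_doubles: int = 4,
    n_cache_levels: int = 3,
) -> HardwareCard:
    rng = random.Random(f"hw:{seed}")
    sizes = sorted(rng.sample(range(15, 26), n_cache_levels))
    levels = [
        CacheLevel(
            name=f"L{i + 1}",
            size=2.0**s,
            bandwidth=rng.uniform(8, 64),
        )
        for i, s in enumerate(sizes)
    ]
    return HardwareCard(
        name=f"toy_hw_{seed}",
        n_threads=n_threads,
        clock=rng.uniform(1e9, 3e9),
        simd_doubles=simd_doubles,
        exp_cycles=rng.uniform(2, 20),
        cache_levels=levels,
        mem_bandwidth=rng.uniform(2e10, 2e11),
        mem_latency=rng.uniform(100, 400),
        mlp=rng.randint(1, 16),
        net=LogGPParams(L=1e-6, o=5e-7, g=1e-7, G=1e-11),
    )


def toy_model(
    seed: int = 0,
    with_event: bool = True,
    dt: float = 1e-4,
    coupling_ratio: int = 5,
    fan_in: float = 1000.0,
) -> InSilicoModelCard:
    """A G-based point-model card with random kernel costs."""
    spec = ToySpec(seed=seed)
    # the full G-based skeleton, so card validation passes
    names = ["state_update", "current_update", "linear_solve"]
    kernels = []
    for i, name in enumerate(names):
        k = random_kernel(spec, index=i)
        kernels.append(k.model_copy(update={"name": name}))
    if with_event:
        ev = random_kernel(ToySpec(seed=seed, p_event=1.0), index=99)
        kernels.append(ev)
    return InSilicoModelCard(
        name="toy_model",
        synapse_formalism="G_based",
        morphology="point",
        dt=dt,
        delta_min=dt * coupling_ratio,
        fan_in=fan_in,
        firing_rate_default=1.0,
        state_vars_per_neuron=10,
        params_per_neuron=20,
        vars_per_connection=2,
        kernels=kernels,
    )


# ---------------------------------------------------------------------------
# oracles (independent code paths, used only in tests)


def oracle_cycle_account(
    k: KernelDescriptor, hw: HardwareCard, residency: str = "MEM"
) -> float:
    """Brute-force serial cycle count for a streaming kernel.

    Walks the hierarchy outwards, explicitly accumulating each boundary's
    transfer cycles until the residency level is reached, then applies the
    overlap rule.  Independent twin of the ECM engine's ``ecm_serial``.
    """
    core = k.t_OL / hw.simd_doubles + k.n_exp * hw.exp_cycles
    data = k.t_nOL
    names = [lvl.name for lvl in hw.cache_levels]
    # enumerate boundaries one by one, innermost first
    per_boundary = []
    if len(names) >= 2:
        per_boundary.append(("inner0", k.bytes_l1l2 / hw.cache_levels[1].bandwidth))
    if len(names) >= 3:
        per_boundary.append(("inner1", k.bytes_l2l3 / hw.cache_levels[2].bandwidth))
    per_boundary.append(("mem", k.bytes_l3mem / (hw.mem_bandwidth / hw.clock)))
    if residency == "MEM":
        n_included = len(per_boundary)
    else:
        n_included = names.index(residency)
    for _, cycles in per_boundary[:n_included]:
        data = data + cycles
    if core > data:
        return core
    return data


def oracle_ring_sim(P: int, m: float, net: LogGPParams) -> float:
    """Discrete simulation of a ring Allgather: P-1 neighbour exchanges.

    Every rank sends its current chunk to the next rank each step; steps
    are synchronous, so the collective finishes after P-1 steps each
    costing one overhead, the wire latency, the per-byte gap for m bytes,
    and the receive overhead.
    """
    clock = 0.0
    for _step in range(P - 1):
        send_done = net.o
        arrival = send_done + net.L + m * net.G
        recv_done = arrival + net.o
        clock += recv_done
    return clock


def oracle_serialized_event_time(lines: int, hw: HardwareCard) -> float:
    """Naive fully-serialized cost of one event: latency per line, no MLP."""
    total = 0.0
    for _ in range(lines):
        total += hw.mem_latency
    return total
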