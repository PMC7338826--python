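"""LogGP cost model for the bulk-synchronous spike-exchange step.

Once per minimum network delay every rank must learn all spikes emitted
anywhere in the network; state-of-the-art simulators implement this with a
blocking Allgather, most commonly the ring algorithm.  In LogGP terms a
ring Allgather over ``P`` ranks performs ``P - 1`` neighbour exchanges of
each rank's ``m``-byte spike buffer, giving

    latency term   (P - 1) * (L + 2 o)      (send + receive overhead)
    bandwidth term (P - 1) * m * G

The bandwidth term is algorithm independent (the same total data moves for
any dissemination order); the latency term is what distinguishes
algorithms, e.g. recursive doubling pays it only ``ceil(log2 P)`` times.
CPU/network overlap is ignored (conservative serial addition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .cards import InSilicoModelCard, LogGPParams

__all__ = [
    "CommsCost",
    "spike_message_size",
    "allgather_ring_time",
    "allgather_recursive_doubling_time",
    "COLLECTIVE_POLICIES",
]


@dataclass(frozen=True)
class CommsCost:
    latency_term: float  # seconds
    bandwidth_term: float  # seconds
    message_bytes_per_rank: float

    @property
    def total(self) -> float:
        return self.latency_term + self.bandwidth_term


def spike_message_size(
    model: InSilicoModelCard, neurons_per_rank: float, rate: float
) -> float:
    """Bytes each rank contributes per exchange.

    All spikes of the rank's neurons during one minimum-delay window:
    ``neurons_per_rank * rate * delta_min * bytes_per_spike_message``
    (spike emission is assumed homogeneous across ranks).
    """
    if neurons_per_rank < 0 or rate < 0:
        raise ValueError("neurons_per_rank and rate must be >= 0")
    return neurons_per_rank * rate * model.delta_min * model.bytes_per_spike_message


def allgather_ring_time(P: int, m: float, net: LogGPParams) -> CommsCost:
    """Ring-algorithm Allgather cost; ``P = 1`` exchanges nothing."""
    if P < 1:
        raise ValueError("P must be >= 1")
    steps = P - 1
    return CommsCost(
        latency_term=steps * (net.L + 2 * net.o),
        bandwidth_term=steps * m * net.G,
        message_bytes_per_rank=m,
    )


def allgather_recursive_doubling_time(P: int, m: float, net: LogGPParams) -> CommsCost:
    """Recursive-doubling variant: logarithmic latency, same bandwidth."""
    if P < 1:
        raise ValueError("P must be >= 1")
    stages = math.ceil(math.log2(P)) if P > 1 else 0
    return CommsCost(
        latency_term=stages * (net.L + 2 * net.o),
        bandwidth_term=(P - 1) * m * net.G,
        message_bytes_per_rank=m,
    )


COLLECTIVE_POLICIES: dict[str, Callable[[int, float, LogGPParams], CommsCost]] = {
    "ring": allgather_ring_time,
    "recursive_doubling": allgather_recursive_doubling_time,
}
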