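"""Parameter-sensitivity sweeps: firing rate, minimum delay, fan-in, memory.

The firing-frequency and minimum-delay sweeps average feature breakdowns
over an ensemble of randomly sampled simulation configurations (number of
neurons, number of ranks) drawn log-uniformly over a design-space grid,
with a fixed seed for reproducibility.  The fan-in sweeps are closed-form
memory accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import scenarios as _scn
from .cards import HardwareCard, InSilicoModelCard
from .metrics import coupling_ratio

__all__ = [
    "ConfigSampler",
    "SweepResult",
    "frequency_sweep",
    "delay_sweep",
    "fanin_capacity",
    "connection_table_memory",
    "local_connection_probability",
]


@dataclass(frozen=True)
class ConfigSampler:
    """Log-uniform sampler of (total_neurons, ranks) configurations."""

    n_configs: int = 100
    seed: int = 0
    neurons_range: tuple[float, float] = (1e4, 1e9)
    ranks_range: tuple[float, float] = (1, 1e4)

    def draw(self) -> list[tuple[float, int]]:
        rng = np.random.default_rng(self.seed)
        out: list[tuple[float, int]] = []
        while len(out) < self.n_configs:
            n = 10 ** rng.uniform(*np.log10(self.neurons_range))
            p = int(round(10 ** rng.uniform(*np.log10(self.ranks_range))))
            p = max(p, 1)
            if n >= p:  # skip sub-neuron-splitting configurations
                out.append((n, p))
        return out


@dataclass(frozen=True)
class SweepResult:
    axis_name: str
    axis_values: list[float]
    results: list[dict] = field(default_factory=list)  # one per axis value
    mean_feature_breakdown: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.axis_values
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("axis values must be strictly increasing")
        if len(self.results) != len(vals):
            raise ValueError("one result per axis value required")


def _mean_breakdown(breakdowns: list[dict[str, float]]) -> dict[str, float]:
    keys = sorted({k for b in breakdowns for k in b})
    n = len(breakdowns)
    return {k: sum(b.get(k, 0.0) for b in breakdowns) / n for k in keys}


def frequency_sweep(
    model: InSilicoModelCard,
    hw: HardwareCard,
    rates,
    sampler: ConfigSampler | None = None,
) -> SweepResult:
    """Mean feature breakdown per firing rate over sampled configurations."""
    rates = [float(r) for r in rates]
    if any(r <= 0 for r in rates):
        raise ValueError("rates must be > 0")
    sampler = sampler or ConfigSampler()
    configs = sampler.draw()
    results, means = [], []
    for f in rates:
        bds = [
            _scn.distributed_performance(model, hw, n, p, rate=f).feature_breakdown
            for n, p in configs
        ]
        means.append(_mean_breakdown(bds))
        results.append({"rate": f, "n_configs": len(bds)})
    return SweepResult("firing_rate", rates, results, means)


def delay_sweep(
    model: InSilicoModelCard,
    hw: HardwareCard,
    delta_min_values,
    sampler: ConfigSampler | None = None,
) -> SweepResult:
    """Sweep the minimum network delay (integer multiples of the timestep).

    Each value re-derives the coupling ratio and hence the loop-ordering
    amortization and the communication frequency; the total operation count
    per simulated second is unchanged.
    """
    values = [float(d) for d in delta_min_values]
    variants = []
    for d in values:
        coupling_ratio(d, model.dt)  # raises on non-multiples
        variants.append(model.model_copy(update={"delta_min": d}))
    sampler = sampler or ConfigSampler()
    configs = sampler.draw()
    results, means = [], []
    for d, variant in zip(values, variants):
        bds = [
            _scn.distributed_performance(variant, hw, n, p).feature_breakdown
            for n, p in configs
        ]
        means.append(_mean_breakdown(bds))
        results.append(
            {"delta_min": d, "coupling_ratio": variant.coupling_ratio,
             "n_configs": len(bds)}
        )
    return SweepResult("delta_min", values, results, means)


def fanin_capacity(
    model: InSilicoModelCard,
    fan_in_values,
    budget: float = 1e9,
) -> SweepResult:
    """Neurons fitting in a memory budget vs fan-in, normalized to K=10.

    The per-neuron footprint is affine in the fan-in ``K`` with slope
    ``vars_per_connection * bytes_per_state_var``.
    """
    values = [float(k) for k in fan_in_values]
    if any(k < 0 for k in values):
        raise ValueError("fan-in must be >= 0")
    anchor = budget / model.memory_per_neuron(fan_in=10)
    results = []
    for k in values:
        n = budget / model.memory_per_neuron(fan_in=k)
        results.append({"fan_in": k, "neurons": n, "normalized": n / anchor})
    return SweepResult("fan_in", values, results, [])


def local_connection_probability(total_neurons: float, ranks: int, fan_in: float) -> float:
    """Probability that a global source neuron has >= 1 local target.

    Under uniform random connectivity each of the rank's ``N/P`` neurons
    picks a given source with probability ``K/(N-1)``, so
    ``p = 1 - (1 - K/(N-1))**(N/P)``.  ``K >= N`` is clamped (with every
    neuron connected to every other, all sources are local).
    """
    if not total_neurons >= ranks >= 1:
        raise ValueError("need total_neurons >= ranks >= 1")
    if total_neurons <= 1:
        return 1.0
    k = min(fan_in, total_neurons - 1)
    local = total_neurons / ranks
    return 1.0 - (1.0 - k / (total_neurons - 1)) ** local


def connection_table_memory(
    total_neurons: float,
    ranks: int,
    fan_in: float,
    entry_bytes: float = 8.0,
) -> float:
    """Bytes per rank for the source-presence connection table.

    Each rank must be able to decide, for any of the ``N`` global source
    neurons, whether it has local postsynaptic targets; only sources that
    do need an entry: ``N * entry_bytes * p_local``.
    """
    if fan_in < 0:
        raise ValueError("fan_in must be >= 0")
    if fan_in == 0:
        return 0.0
    if fan_in >= total_neurons:
        import warnings

        warnings.warn(
            f"fan_in {fan_in} >= total_neurons {total_neurons}; clamping",
            stacklevel=2,
        )
    p = local_connection_probability(total_neurons, ranks, fan_in)
    return total_neurons * entry_bytes * p
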