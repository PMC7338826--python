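"""Hardware-agnostic descriptive metrics of an *in silico* model.

These metrics are computable from the model card alone and take the same
value on any machine: the coupling ratio (timesteps per global
synchronization), the sequential compressibility limit (iterations per
simulated second), the iteration compressibility limits (state variables
updated per timestep, clock- and event-driven), the information carried by
a connection per delay period, and the unit-size (memory footprint)
breakdown.

Event counts use deterministic mean-rate accounting: a neuron with fan-in
``K`` whose afferents fire at ``f`` Hz integrates ``K * f * dt`` synaptic
events per timestep on average.  No stochastic sampling is performed, which
mirrors the deterministic synaptic-release variant the engines model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cards import COUPLING_RATIO_TOL, InSilicoModelCard

__all__ = ["MetricsReport", "coupling_ratio", "hardware_agnostic_metrics"]


def coupling_ratio(delta_min: float, dt: float) -> int:
    """Number of timesteps between two global synchronization points.

    ``delta_min / dt`` must be a positive integer (within 1e-9 relative
    tolerance); fractional ratios raise ``ValueError`` because the bulk
    synchronous window must contain a whole number of steps.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if delta_min < dt:
        raise ValueError("delta_min must be >= dt")
    ratio = delta_min / dt
    if abs(ratio - round(ratio)) > COUPLING_RATIO_TOL * max(1.0, ratio):
        raise ValueError(f"delta_min/dt = {ratio} is not an integer")
    return round(ratio)


@dataclass(frozen=True)
class MetricsReport:
    coupling_ratio: int
    sequential_compressibility: float  # iterations per simulated second
    iteration_compressibility_clock: float  # state vars updated per dt
    iteration_compressibility_event: float  # mean events per neuron per dt
    info_per_connection: float  # variables per connection per delta_min
    unit_size: dict[str, float] = field(default_factory=dict)


def hardware_agnostic_metrics(
    model: InSilicoModelCard, rate: float | None = None
) -> MetricsReport:
    """Compute the descriptive metrics of ``model`` at firing rate ``rate``.

    ``rate`` defaults to the card's published firing rate.  No hardware
    argument exists by construction: every field depends on the model alone.
    """
    f = model.firing_rate_default if rate is None else rate
    if f < 0:
        raise ValueError("rate must be >= 0")
    return MetricsReport(
        coupling_ratio=coupling_ratio(model.delta_min, model.dt),
        sequential_compressibility=1.0 / model.dt,
        iteration_compressibility_clock=model.state_vars_per_neuron,
        iteration_compressibility_event=model.fan_in * f * model.dt,
        info_per_connection=f * model.delta_min * model.vars_per_spike,
        unit_size={
            "vars_per_neuron": model.state_vars_per_neuron + model.params_per_neuron,
            "vars_per_connection": model.vars_per_connection,
            "connections_per_neuron": model.fan_in,
        },
    )
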