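# Methods

## Scope and model structure

brainperf is a grey-box analytical performance model for cellular-level
simulations of brain tissue.  It predicts — without executing any neural
simulation — how fast a spiking-network simulation advances biological time
on a given machine, and which hardware resource limits it.  The prediction
is composed from three engines over two kinds of descriptor cards:

1. an **Execution-Cache-Memory (ECM)** engine for the clock-driven,
   streaming kernels (state integration, current accumulation, linear
   solves);
2. an **event engine** for the spike-delivery kernel, whose random access
   pattern is governed by memory latency and memory-level parallelism
   (MLP) rather than streaming bandwidth;
3. a **LogGP** engine for the bulk-synchronous collective spike exchange.

All simulations modelled here follow the bulk synchronous parallel pattern:
`r = delta_min / dt` integration timesteps (the *coupling ratio*) between
two global spike exchanges, where `delta_min` is the network's minimum
synaptic delay.  Asynchronous, variable-timestep and axon-resolving schemes
are out of scope, as are event-queue bookkeeping, stochastic synaptic
release (the modelled codes use a deterministic mean-rate variant),
long-term plasticity, and energy modelling.

## Serial ECM model

For each streaming kernel, per work item (a neuron, compartment, synapse
instance or channel):

    t_core  = t_OL / simd_doubles + n_exp * exp_cycles
    t_data  = t_nOL + sum over boundaries outside the residency of
              bytes_boundary / bandwidth_boundary
    t       = max(t_core, t_data)

`t_OL` is stored in the card as scalar-lane in-core cycles; dividing by the
SIMD width assumes perfect vectorization, which is also how the strawman
cards scale instruction throughput across architectures.  Exponentials are
priced separately because their cost dominates conductance-based synapse
updates and depends strongly on the hardware's math library/SFU.  The
overlap convention is the standard non-overlapping-transfers one: `t_nOL`
(load/store issue) sits on the data path, and in-core work overlaps all
data movement.  A kernel is *core bound* when `t_core > t_data`.

`residency` names the hierarchy level assumed to hold the working set; it
truncates the boundary sum.  Cache-residency numbers deliberately ignore
whether the working set actually fits (the interesting question is what the
hardware could sustain if it did).

The ECM model is a full-throughput model: latency effects for streaming
kernels, prefetcher/TLB details, cache associativity and NUMA are not
modelled.

## Thread scaling and saturation

Performance scales linearly in threads until a shared resource — on all
cards modelled here, the memory interface — saturates:

    throughput(n) = min(n / t_serial, 1 / t_mem)
    n_satur       = ceil(t_serial / t_mem)

where `t_mem` is the memory-boundary transfer time.  For a whole model the
saturation point is computed on the duty-cycle-weighted aggregate: total
serial cycles per neuron-step over total memory cycles per neuron-step,
including the event kernel's cache-line traffic.  The formula is exposed as
a small function so alternative policies can be plugged in.  Bandwidth
utilization at `n` threads is `min(1, n * t_mem / t_serial)` on the same
aggregate.  Whether the pre-saturation slope should scale `t_nOL` as well
is ambiguous; we scale the whole serial time and note that the choice only
affects the shape between 1 thread and saturation, not the ceiling.

## Loop ordering

State-of-the-art simulators advance each neuron through all `r` timesteps
of a minimum-delay window consecutively, so main memory is touched only on
the window's first step and the remaining `r - 1` stream from the
last-level cache:

    t_mem_effective = t_mem / r

equivalently a `1/r : (r-1)/r` blend of memory and last-level-cache
residency.  This is a conservative assumption (last-level-cache residency
is assumed even when the working set exceeds the cache; no partial-fit
modelling).  The event kernel is never helped by loop ordering: its
accesses are assumed uncacheable between events.

## Spike delivery

Per event, `lines` full cache lines (64 B each) must be fetched in
unpredictable order.  Three candidate bounds compete:

    t_lat  = lines * mem_latency / mlp        (independent requests overlap)
    t_bw   = lines * cache_line / (bytes per cycle of memory bandwidth)
    t_core = in-core integration work (heavy for conductance-based synapses
             with short-term plasticity; a counter increment for
             current-based ones)

    t_event = max(t_lat, t_bw, t_core)

With `n` threads the latency and core paths scale as `1/n` (per-thread MLP
is assumed independent) while `t_bw` is the shared floor.  The naive fully
serialized model (`lines * latency` per event) is retained only as a test
oracle: it strictly upper-bounds the prediction whenever `mlp > 1`.  An
optimistic in-cache variant charges the lines to a cache level's boundary
bandwidth with no DRAM latency; it serves the cache-residency scenarios and
is knowingly generous to the current-based model.

Event counts use deterministic mean-rate accounting: `K * f * dt` events
per neuron per step for fan-in `K` and rate `f`.  No Poisson sampling is
performed anywhere in the package.

## Spike exchange

Each exchange is a blocking ring Allgather of each rank's spike buffer,
`m = neurons_per_rank * f * delta_min * bytes_per_spike_message` bytes
(homogeneous emission across ranks):

    T = (P - 1) * (L + 2 o)  +  (P - 1) * m * G

The overhead `o` is charged twice per ring step (send + receive); a
recursive-doubling variant with a `ceil(log2 P)` latency factor is included
for comparison, and both are registered in a pluggable policy table.  The
bandwidth term is algorithm independent.  CPU/network overlap is ignored
(conservative serial addition).  Per window the node compute time
(`r` steps at full threads, loop ordering, memory residency) and the
exchange time add; whole-network performance is `delta_min / T_window`.
Configurations with fewer neurons than ranks would require splitting single
neurons across ranks and are rejected.

## Bottleneck attribution

Runtime is attributed winner-take-all per kernel: only the path that wins
the `max()` contributes, proportionally among its components — CPU vs
exponentials on the core path; load issue, per-boundary transfers and
memory bandwidth on the data path; MLP/latency or memory bandwidth for
events; network latency vs network bandwidth for the exchange.  Fractions
sum to one and the bottleneck label is the argmax.  This reproduces stacked
breakdowns most simply; a saturated kernel is attributed entirely to memory
bandwidth.

## Cards and calibration

Model cards are hardware-agnostic: timestep, minimum delay, fan-in,
variable counts, and a kernel inventory with per-work-item cost vectors.
Two byte accountings coexist deliberately: `bytes_algorithmic` is the
hand-countable load/store volume of the algorithm (what a flop/byte audit
reports and what `calibration_report` sums), while the per-boundary fields
are the traffic the hardware actually moves, which can exceed the
algorithmic volume (write-allocate stores, cache-line granularity on
indexed accesses) or fall below it (temporal reuse).  No single number can
serve both roles consistently across the three packaged models.

Hardware cards record nominal, publicly specified quantities (thread count,
clock, SIMD width, cache sizes, 64 B lines) directly; quantities that
normally require microbenchmarks (sustained bandwidth, boundary bandwidths,
latency, MLP, exponential throughput) are *fitted*: a least-squares
calibration harness adjusted them, together with the per-kernel cycle/byte
constants, so that the engines reproduce the published per-neuron audits
and runtime predictions for all three models simultaneously; every card
value is annotated `[nominal]`, `[published]`, `[hand count]` or
`[fitted]`.  The engines, not the constants, are the artifact: the
`calibrate` CLI subcommand re-derives every calibrated quantity from the
cards at run time and flags agreement to two significant figures.

Two calibration observations worth recording: the published per-neuron
data volumes are mutually inconsistent with the saturated throughputs under
any single memory bandwidth, which is what forces the dual byte accounting
above; and the Simplified model's serial, saturated and L3-speedup values
are simultaneously reproducible only if its state-update kernel is core
bound at L3 residency — the packaged card encodes exactly that structure.
The GPU-like card fits a higher per-SM MLP (17.4) than the CPU value
rather than carrying the CPU value over, since a GPU streaming
multiprocessor sustains far more outstanding loads than a CPU core.

Card-level choices: the coupling ratio must be an exact integer (fractional
windows are rejected, not rounded); spike messages default to 8 bytes
(source id plus discretized time); the detailed model's per-neuron item
counts are means over a strongly variable population; its minimum delay is
not printed in the source material and is set to 4 timesteps, flagged
fitted.

## Sweeps

The firing-rate and minimum-delay sweeps average feature breakdowns over an
ensemble of (total neurons, ranks) configurations drawn log-uniformly
(neurons 1e4-1e9, ranks 1-1e4 by default; the sampling distribution is this
package's choice) with a caller-supplied seed; sweeps are deterministic
given (seed, axis).  Minimum-delay values must be integer multiples of the
model's timestep.  Fan-in capacity is closed form: the per-neuron footprint
is affine in `K` with slope `vars_per_connection * bytes_per_state_var`,
normalized at `K = 10`.  The connection table models a presence test over
all `N` global sources; a source needs an entry with probability
`p_local = 1 - (1 - K/(N-1))**(N/P)` under uniform random connectivity.
Both the entry model and `p_local` are this package's concretization of a
verbal description and are pluggable.

## Numerical and degenerate-input choices

Integer coupling-ratio checks use a 1e-9 relative tolerance.  Zero memory
traffic yields an unbounded saturation sentinel (`inf`) rather than an
error; an all-zero-cost model makes the serial profile undefined and
raises.  Breakdown fractions are validated to sum to 1 within 1e-6.  Ties
at the bandwidth floor are labelled bandwidth bound (the floor is the
binding constraint at and beyond saturation).  `K >= N` in the connection
table is clamped with a warning.

## What the toy generators do and do not emulate

`brainperf.testing` draws random kernels and hardware within broad
physical ranges so that engine algebra can be verified against independent
brute-force oracles (explicit boundary enumeration; a discrete ring-step
simulator) without touching any calibrated card.  Passing those tests
establishes that the engines compute their stated formulas exactly and
that scaling shapes (monotone thread scaling, saturation plateaus,
linearities) hold for arbitrary inputs — it does not establish that the
formulas describe any real machine.  The fidelity claim rests on the
calibrated cards reproducing the published measurements-derived audit, and
inherits that audit's precision (two significant figures).

## Known limitations

* Constants in the packaged cards are a calibrated joint solution, not
  per-kernel microbenchmark measurements; individual kernel splits are not
  identifiable from the published aggregates and should not be
  over-interpreted.
* The in-cache spike-delivery variant is optimistic; cache-residency
  speedups for the current-based model are upper bounds.
* No load-imbalance modelling (homogeneous partitioning), no
  alltoall/point-to-point/asynchronous exchange schemes, no power model.
* Shallow hierarchies (2-level cards) skip the mid-hierarchy byte field;
  kernels calibrated on a 3-level card lose that term there by design.
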