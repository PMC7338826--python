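# brainperf

Analytical performance models for cellular-level brain tissue simulations.

Simulating networks of biological neurons — from current-based
integrate-and-fire point neurons up to morphologically detailed,
conductance-based reconstructions — is limited by very different hardware
resources depending on the modelling abstraction: streaming memory
bandwidth, memory latency and memory-level parallelism, in-core arithmetic
and exponential throughput, or collective-communication latency.  brainperf
predicts, without running a simulation, how many seconds of biological time
a given (neuron model, machine, configuration) advances per wallclock
second, and attributes the runtime to hardware features, so that
computational neuroscientists, simulator developers and hardware designers
can explore co-design questions quantitatively.

It is aimed at anyone asking questions like: *how much slower is a detailed
neuron than a point neuron, and why?  How many threads until memory
bandwidth saturates?  When does network latency dominate a distributed
run?  What would a GPU-class memory system buy?*

## The model

Everything is closed-form, composed from descriptor **cards**:

* **Clock-driven kernels** (state integration, current accumulation,
  linear solves) use the Execution-Cache-Memory model.  Per work item,
  with data resident at some hierarchy level,

      t_core   = t_OL / simd + n_exp · c_exp
      t_data   = t_nOL + Σ bytes_boundary / bw_boundary
      t_serial = max(t_core, t_data)

  Threads scale performance linearly until the shared memory interface
  saturates at `n_satur = ⌈t_serial / t_mem⌉`; the loop-ordering
  optimization (advancing each neuron through all `r = δ_min/Δt` steps of
  a synchronization window consecutively) divides the memory term by the
  coupling ratio `r`.

* **Spike delivery** (event-driven, random access) costs, per event,
  `max(lines·latency/MLP, lines·64 B/BW, t_core)` — latency hidden by
  memory-level parallelism, a shared bandwidth floor, and the postsynaptic
  integration work (heavy for conductance-based synapses with short-term
  plasticity).

* **Spike exchange** is a ring Allgather in LogGP terms:
  `(P−1)(L + 2o) + (P−1)·m·G` for `P` ranks exchanging `m`-byte spike
  buffers once per minimum network delay.

Three packaged model cards cover the abstraction spectrum — `brunel`
(I-based point network, coupling ratio 15), `simplified` (G-based
generalized integrate-and-fire reduction, coupling ratio 1) and
`reconstructed` (G-based morphologically detailed microcircuit neuron) —
alongside hardware cards for a Skylake-class reference server (AVX-512 and
SSE variants), a KNL-like manycore, an AMD-Naples-like server and a
GPU-like strawman.  Nominal card values are public specifications;
microbenchmark-grade constants are calibrated fixtures (see
`docs/methods.md`).

## Worked example

Full-node prediction for the point-neuron network on the reference CPU
(18 threads, loop ordering, data streaming from DRAM):

    $ brainperf scenario shared brunel
    {
      "performance": 52004.72870013962,
      "unit": "per_neuron",
      "bottleneck": "MemBW",
      "kernel_breakdown": {
        "state_update": 0.0796,
        "current_update": 0.0883,
        "spike_delivery": 0.8321
      },
      "feature_breakdown": {
        "T_load": 0.0188, "L1L2": 0.0539, "L2L3": 0.0862, "MemBW": 0.8410
      }
    }

Read: one node advances each neuron ~5.2·10⁴ simulated seconds per
wallclock second; 83% of the time goes to delivering spikes, and the
dominant hardware feature is memory bandwidth — event cache lines keep
streaming from DRAM no matter how long the synchronization window is,
which is also why this model's saturation point stays below 17 threads at
any coupling ratio (`brainperf ecm brunel skx_avx512 --loop-ordering`
prints the per-kernel decomposition and the saturation estimate).

The same library calls are available in Python:

    >>> from brainperf import default_cards, shared_memory_profile
    >>> cards = default_cards()
    >>> res = shared_memory_profile(cards.model("brunel"), cards.hw("skx_avx512"))
    >>> round(res.performance), res.bottleneck
    (52005, 'MemBW')

`brainperf calibrate` audits every packaged card against the published
per-neuron workload audit and runtime predictions it was calibrated to
reproduce, flagging agreement to two significant figures:

    $ brainperf calibrate --format csv | head -4
    ,model,quantity,computed,reference,matches_2sf
    0,brunel,flop,230000.0,230000.0,True
    1,brunel,data_volume_bytes,1000000.0,1000000.0,True
    2,brunel,arithmetic_intensity,0.23,0.23,True

Other entry points: `brainperf metrics` (hardware-agnostic model metrics),
`brainperf comms` (LogGP exchange cost), `brainperf scenario
serial|shared|distributed|bottleneck-map`, `brainperf sweep
frequency|delay|fanin|conntable`, and `brainperf run config.yaml` for
reproducible scenario files.

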