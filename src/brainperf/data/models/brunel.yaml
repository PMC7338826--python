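kind: model
name: brunel
provenance: >-
  Randomly connected balanced network of current-based integrate-and-fire
  point neurons (large-scale NEST-style configuration).  dt, delta_min,
  fan-in and firing rate are published model parameters; per-neuron and
  per-connection variable counts are hand counts; kernel cycle and
  boundary-byte constants are fitted so that the engines reproduce the
  published flop/traffic audit and runtime predictions on the reference
  hardware.
synapse_formalism: I_based
morphology: point
dt: 1.0e-4            # 0.1 ms  [published]
delta_min: 1.5e-3     # 1.5 ms -> coupling ratio 15  [published]
fan_in: 10000         # [published]
firing_rate_default: 1.0   # Hz  [benchmark condition]
state_vars_per_neuron: 10      # [hand count]
params_per_neuron: 40          # [hand count]
vars_per_connection: 3.37      # mean incl. bookkeeping share  [fitted]
bytes_per_state_var: 8.0
vars_per_spike: 1.0
bytes_per_spike_message: 8.0   # source id + discretized time  [assumed]
kernels:
  - name: state_update           # IAF membrane/synapse ODE propagators
    phase: clock_driven
    work_item: per_neuron
    items_per_neuron: 1
    t_OL: 7.2        # scalar-lane cycles  [fitted]
    t_nOL: 0.8       # [fitted]
    n_exp: 0.0
    flop: 16.0       # [hand count]
    bytes_algorithmic: 40.0    # [hand count]
    bytes_l1l2: 84.0           # [fitted]
    bytes_l2l3: 20.0           # [fitted]
    bytes_l3mem: 180.0         # [fitted]
    locality: streaming
  - name: current_update         # total post-synaptic current accumulation
    phase: clock_driven
    work_item: per_neuron
    items_per_neuron: 1
    t_OL: 6.4        # [fitted]
    t_nOL: 0.7       # [fitted]
    n_exp: 0.0
    flop: 6.0        # [hand count]
    bytes_algorithmic: 30.0    # [hand count]
    bytes_l1l2: 79.0           # [fitted]
    bytes_l2l3: 26.0           # [fitted]
    bytes_l3mem: 192.0         # [fitted]
    locality: streaming
  - name: spike_delivery         # weighted counter increment per event
    phase: event_driven
    work_item: per_event
    items_per_neuron: 1
    t_OL: 4.0        # [fitted]
    t_nOL: 0.0
    n_exp: 0.0
    flop: 1.0        # [hand count]
    bytes_algorithmic: 30.0    # useful payload per event  [hand count]
    cache_lines_per_event: 2   # synapse object + target accumulator [fitted]
    locality: random
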