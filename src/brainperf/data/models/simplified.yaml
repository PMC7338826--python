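kind: model
name: simplified
provenance: >-
  Generalized integrate-and-fire point-neuron reduction of the detailed
  microcircuit, retaining conductance-based synapses with short-term
  plasticity but lumping synapse instances into shared receptor pools
  (hence the sub-unit vars_per_connection).  Coupling ratio is 1 by
  construction (delta_min = dt).  Kernel constants fitted as for the other
  cards.
synapse_formalism: G_based
morphology: point
dt: 2.5e-5            # 0.025 ms  [published]
delta_min: 2.5e-5     # coupling ratio 1  [published]
fan_in: 4000          # [published scale]
firing_rate_default: 1.0
state_vars_per_neuron: 60      # lumped receptor + GIF state  [hand count]
params_per_neuron: 190         # [hand count]
vars_per_connection: 0.25      # amortized over lumped receptors  [fitted]
bytes_per_state_var: 8.0
vars_per_spike: 1.0
bytes_per_spike_message: 8.0
kernels:
  - name: state_update           # receptor/GIF state advance (exponentials)
    phase: clock_driven
    work_item: per_neuron
    items_per_neuron: 1
    t_OL: 520.0      # [fitted]
    t_nOL: 14.0      # [fitted]
    n_exp: 4.0       # [hand count]
    flop: 230.0      # [hand count]
    bytes_algorithmic: 1400.0  # [hand count]
    bytes_l1l2: 600.0          # [fitted]
    bytes_l2l3: 255.0          # [fitted]
    bytes_l3mem: 840.0         # [fitted]
    locality: streaming
  - name: current_update         # receptor current contributions to the matrix
    phase: clock_driven
    work_item: per_neuron
    items_per_neuron: 1
    t_OL: 440.0      # [fitted]
    t_nOL: 14.0      # [fitted]
    n_exp: 0.0
    flop: 150.0      # [hand count]
    bytes_algorithmic: 1500.0  # [hand count]
    bytes_l1l2: 760.0          # [fitted]
    bytes_l2l3: 393.0          # [fitted]
    bytes_l3mem: 870.0         # [fitted]
    locality: streaming
  - name: linear_solve           # per-neuron voltage system solve
    phase: clock_driven
    work_item: per_neuron
    items_per_neuron: 1
    t_OL: 459.0      # [fitted]
    t_nOL: 40.0      # [fitted]
    n_exp: 0.0
    flop: 40.0       # [hand count]
    bytes_algorithmic: 345.0   # [hand count]
    bytes_l1l2: 775.0          # [fitted]
    bytes_l2l3: 270.0          # [fitted]
    bytes_l3mem: 800.0         # [fitted]
    locality: streaming
  - name: spike_delivery         # quantal STP update per event (exponentials)
    phase: event_driven
    work_item: per_event
    items_per_neuron: 1
    t_OL: 256.0      # [fitted]
    t_nOL: 0.0
    n_exp: 3.0       # [hand count]
    flop: 50.0       # [hand count]
    bytes_algorithmic: 50.0    # [hand count]
    cache_lines_per_event: 2   # [fitted]
    locality: random
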