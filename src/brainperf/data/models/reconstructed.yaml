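kind: model
name: reconstructed
provenance: >-
  Morphologically detailed neocortical microcircuit neuron with
  conductance-based, short-term-plastic synapses.  Per-neuron item counts
  (synapse instances, ion-channel states, compartments) vary strongly
  across reconstructed cells; the card stores means only.  The coupling
  ratio is not printed in the source material; dt 0.025 ms with a 0.1 ms
  minimum delay (ratio 4) is used, flagged fitted.  Kernel constants
  fitted as for the other cards.
synapse_formalism: G_based
morphology: detailed
dt: 2.5e-5            # 0.025 ms  [published]
delta_min: 1.0e-4     # coupling ratio 4  [fitted]
fan_in: 10000         # mean synapses per neuron  [published scale]
firing_rate_default: 1.0
state_vars_per_neuron: 60000     # compartments + channel states  [mean, hand count]
params_per_neuron: 102500        # [mean, hand count]
vars_per_connection: 20          # STP synapse state + params  [hand count]
bytes_per_state_var: 8.0
vars_per_spike: 1.0
bytes_per_spike_message: 8.0
kernels:
  - name: state_update           # synapse/channel state advance (exponentials)
    phase: clock_driven
    work_item: per_synapse_instance
    items_per_neuron: 12500      # synapses + channel blocks  [mean]
    t_OL: 28.0       # [fitted]
    t_nOL: 1.0       # [fitted]
    n_exp: 0.72      # per item  [fitted]
    flop: 8.2        # [hand count]
    bytes_algorithmic: 40.0    # [hand count]
    bytes_l1l2: 20.0           # [fitted]
    bytes_l2l3: 10.0           # [fitted]
    bytes_l3mem: 2.7           # [fitted]
    locality: streaming
  - name: current_update         # conductance contributions to the matrix
    phase: clock_driven
    work_item: per_synapse_instance
    items_per_neuron: 12500
    t_OL: 18.0       # [fitted]
    t_nOL: 0.33      # [fitted]
    n_exp: 0.0
    flop: 8.0        # [hand count]
    bytes_algorithmic: 20.0    # [hand count]
    bytes_l1l2: 14.0           # [fitted]
    bytes_l2l3: 4.5            # [fitted]
    bytes_l3mem: 90.5          # [fitted]
    locality: streaming
  - name: linear_solve           # Hines solve over the compartment tree
    phase: clock_driven
    work_item: per_compartment
    items_per_neuron: 700        # [mean]
    t_OL: 26.3       # [fitted]
    t_nOL: 1.65      # [fitted]
    n_exp: 0.0
    flop: 14.3       # [hand count]
    bytes_algorithmic: 35.714285  # [hand count]
    bytes_l1l2: 51.5           # [fitted]
    bytes_l2l3: 354.0          # [fitted]
    bytes_l3mem: 19.2          # [fitted]
    locality: streaming
  - name: spike_delivery         # quantal STP update per event
    phase: event_driven
    work_item: per_event
    items_per_neuron: 1
    t_OL: 100.0      # [fitted]
    t_nOL: 0.0
    n_exp: 2.0       # [hand count]
    flop: 60.0       # [hand count]
    bytes_algorithmic: 64.0    # [hand count]
    cache_lines_per_event: 2   # [fitted]
    locality: random
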