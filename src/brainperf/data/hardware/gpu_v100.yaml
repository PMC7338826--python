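kind: hardware
name: gpu_v100
provenance: >-
  Strawman GPU (Volta-like): streaming multiprocessors treated as
  shared-memory threads with 32-double-wide SIMD, connected almost
  directly to device memory (shallow cache hierarchy).  SM count, clock
  and SIMD width are nominal; sustained device bandwidth, per-SM MLP and
  exp throughput fitted within nominal envelopes.
n_threads: 80          # streaming multiprocessors  [nominal]
clock: 1.38e9          # [nominal]
simd_doubles: 32       # warp of doubles  [nominal]
exp_cycles: 3.0        # special-function units  [fitted]
cache_levels:
  - {name: L1, size: 131072, bandwidth: 200.0}
  - {name: L2, size: 6291456, bandwidth: 38.0}
mem_bandwidth: 6.63e11 # B/s HBM2 sustained  [fitted]
mem_latency: 194.0     # cycles, carried over from reference
mlp: 17.4              # per-SM outstanding requests  [fitted]
cache_line: 64.0
net: {L: 1.1e-6, o: 1.2e-6, g: 1.0e-7, G: 8.0e-11}
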