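kind: hardware
name: naples
provenance: >-
  Strawman multicore server (AMD-Naples-like): more cores than the
  reference but narrower (AVX2) vectors and a flatter cache hierarchy.
  Core count, clock and SIMD width nominal; latency/MLP carried over from
  the reference; bandwidth fitted within the nominal 8-channel envelope.
n_threads: 24          # one socket  [nominal]
clock: 2.2e9           # [nominal]
simd_doubles: 4        # AVX2  [nominal]
exp_cycles: 8.0        # exp throughput scales with vector width  [fitted]
cache_levels:
  - {name: L1, size: 32768, bandwidth: 200.0}
  - {name: L2, size: 524288, bandwidth: 38.0}
  - {name: L3, size: 8388608, bandwidth: 6.7}
mem_bandwidth: 1.2e11  # B/s sustained  [fitted]
mem_latency: 194.0
mlp: 8.8
cache_line: 64.0
net: {L: 1.1e-6, o: 1.2e-6, g: 1.0e-7, G: 8.0e-11}
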