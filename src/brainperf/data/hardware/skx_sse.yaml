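kind: hardware
name: skx_sse
provenance: >-
  The reference Skylake-class CPU restricted to 128-bit SSE vectors
  (2 double lanes); all other constants identical to skx_avx512.  Used to
  study how vectorization moves kernels between core- and data-bound.
n_threads: 18
clock: 2.3e9
simd_doubles: 2        # SSE  [nominal]
exp_cycles: 16.0       # exp throughput scales with vector width  [fitted]
cache_levels:
  - {name: L1, size: 32768, bandwidth: 200.0}
  - {name: L2, size: 1048576, bandwidth: 38.0}
  - {name: L3, size: 25952256, bandwidth: 6.7}
mem_bandwidth: 8.0e10
mem_latency: 194.0
mlp: 8.8
cache_line: 64.0
net: {L: 1.1e-6, o: 1.2e-6, g: 1.0e-7, G: 8.0e-11}
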