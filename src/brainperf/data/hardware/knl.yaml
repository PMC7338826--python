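kind: hardware
name: knl
provenance: >-
  Strawman manycore (Knights-Landing-like): 64 cores at low clock with
  AVX-512 and high-bandwidth on-package memory (only the HBM is modelled).
  Parallelism, clock, SIMD width and cache structure are nominal; memory
  latency (in cycles) and MLP are carried over from the reference card;
  sustained HBM bandwidth fitted within the nominal envelope.
n_threads: 64          # [nominal]
clock: 1.4e9           # [nominal]
simd_doubles: 8        # AVX-512  [nominal]
exp_cycles: 4.0
cache_levels:
  - {name: L1, size: 32768, bandwidth: 200.0}
  - {name: L2, size: 524288, bandwidth: 38.0}
mem_bandwidth: 3.45e11 # B/s HBM sustained  [fitted]
mem_latency: 194.0     # carried over from reference
mlp: 8.8               # carried over from reference
cache_line: 64.0
net: {L: 1.1e-6, o: 1.2e-6, g: 1.0e-7, G: 8.0e-11}
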