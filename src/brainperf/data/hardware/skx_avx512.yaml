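kind: hardware
name: skx_avx512
provenance: >-
  Reference server CPU: 18-core Skylake-class Xeon with AVX-512, one
  socket.  Thread count, clock, SIMD width, cache sizes and the 64 B line
  are nominal public specifications; boundary bandwidths, sustained memory
  bandwidth, latency and memory-level parallelism are fitted by the
  calibration harness.  Network: 100 Gb/s-class Infiniband fabric with a
  vendor MPI; LogGP constants are representative values for such fabrics.
n_threads: 18          # [nominal]
clock: 2.3e9           # Hz  [nominal]
simd_doubles: 8        # AVX-512  [nominal]
exp_cycles: 4.0        # vectorized exp, cycles/element  [fitted]
cache_levels:
  - {name: L1, size: 32768, bandwidth: 200.0}      # bandwidth [fitted]
  - {name: L2, size: 1048576, bandwidth: 38.0}     # [fitted]
  - {name: L3, size: 25952256, bandwidth: 6.7}     # [fitted]
mem_bandwidth: 8.0e10  # B/s sustained  [fitted]
mem_latency: 194.0     # cycles  [fitted]
mlp: 8.8               # outstanding requests  [fitted]
cache_line: 64.0       # [nominal]
net: {L: 1.1e-6, o: 1.2e-6, g: 1.0e-7, G: 8.0e-11}
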