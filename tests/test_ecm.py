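"""ECM engine: serial decomposition, thread scaling, loop ordering."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainperf import ecm_serial, saturation_point, thread_scaling
from brainperf.cards import CacheLevel, HardwareCard, LogGPParams, KernelDescriptor
from brainperf.ecm import (
    Boundedness,
    bandwidth_utilization,
    loop_ordering_traffic,
    model_saturation_point,
)
from brainperf.testing import ToySpec, oracle_cycle_account, random_kernel, toy_hardware


def _hand_hw(n_threads=8):
    """Hierarchy engineered so a (16, 16, 24)-byte kernel costs (4, 4, 6)."""
    return HardwareCard(
        name="hand", n_threads=n_threads, clock=1e9, simd_doubles=1,
        exp_cycles=1.0,
        cache_levels=[
            CacheLevel(name="L1", size=2**15, bandwidth=8),
            CacheLevel(name="L2", size=2**20, bandwidth=4),
            CacheLevel(name="L3", size=2**24, bandwidth=4),
        ],
        mem_bandwidth=4e9, mem_latency=100, mlp=4,
        net=LogGPParams(L=0, o=0, g=0, G=0),
    )


def _hand_kernel():
    return KernelDescriptor(
        name="state_update", phase="clock_driven", work_item="per_neuron",
        t_OL=8, t_nOL=4, bytes_l1l2=16, bytes_l2l3=16, bytes_l3mem=24,
    )


def test_serial_decomposition_by_hand():
    """t_OL=8, t_nOL=4, transfers (4,4,6): memory-resident -> data bound 18,
    L1-resident -> core bound 8."""
    hw, k = _hand_hw(), _hand_kernel()
    mem = ecm_serial(k, hw, residency="MEM")
    assert mem.t_data == pytest.approx(18)
    assert mem.t_serial == pytest.approx(18)
    assert mem.bound is Boundedness.data_bound
    l1 = ecm_serial(k, hw, residency="L1")
    assert l1.t_data == pytest.approx(4)
    assert l1.t_serial == pytest.approx(8)
    assert l1.bound is Boundedness.core_bound


def test_t_data_monotone_in_residency():
    hw, k = _hand_hw(), _hand_kernel()
    times = [ecm_serial(k, hw, residency=r).t_data for r in ("L1", "L2", "L3", "MEM")]
    assert times == sorted(times)


def test_event_kernel_rejected():
    hw = _hand_hw()
    ev = random_kernel(ToySpec(seed=0, p_event=1.0), index=1)
    with pytest.raises(ValueError, match="event"):
        ecm_serial(ev, hw)


@settings(deadline=None, max_examples=150)
@given(seed=st.integers(0, 10**6), idx=st.integers(0, 10),
       res=st.sampled_from(["L1", "L2", "L3", "MEM"]))
def test_matches_brute_force_oracle(seed, idx, res):
    """ecm_serial agrees exactly with the independent cycle-accounting oracle
    on randomized kernels and hardware."""
    k = random_kernel(ToySpec(seed=seed), index=idx)
    hw = toy_hardware(seed=seed % 17)
    assert ecm_serial(k, hw, residency=res).t_serial == pytest.approx(
        oracle_cycle_account(k, hw, res), rel=1e-12
    )


def test_saturation_point_arithmetic():
    assert saturation_point(18, 6) == 3
    assert saturation_point(18, 0) == math.inf  # no traffic, never saturates


def test_thread_scaling_shape():
    """1/n scaling up to the saturation point, then a flat bandwidth floor."""
    hw = toy_hardware(seed=2, n_threads=64)
    k = random_kernel(ToySpec(seed=2), index=0)
    pred = ecm_serial(k, hw, residency="MEM")
    times = [thread_scaling(pred, hw, n) for n in range(1, 65)]
    assert times[0] == pytest.approx(pred.t_serial)
    assert all(a >= b - 1e-12 for a, b in zip(times, times[1:]))  # non-increasing
    if pred.n_satur <= 64:
        n_sat = int(pred.n_satur)
        for n in range(n_sat, 65):
            assert times[n - 1] == pytest.approx(pred.t_mem)
        # strictly 1/n before saturation
        for n in range(1, n_sat):
            assert times[n - 1] == pytest.approx(pred.t_serial / n)


def test_simd_scaling_touches_only_the_core_path(skx, brunel):
    """Widening vector registers improves t_core and leaves t_data unchanged."""
    wide = skx
    narrow = skx.model_copy(update={"simd_doubles": 2, "name": "narrow"})
    for k in brunel.clock_kernels:
        pw, pn = ecm_serial(k, wide), ecm_serial(k, narrow)
        assert pn.t_data == pytest.approx(pw.t_data)
        assert pn.t_OL == pytest.approx(pw.t_OL * wide.simd_doubles / 2)


def test_loop_ordering_identity_and_limit(simplified, brunel, skx):
    """A one-step window gains nothing; an infinite window reduces the
    memory term to last-level-cache residency."""
    # the point-neuron reduction has coupling ratio 1: optimized == naive
    assert loop_ordering_traffic(simplified, skx, True) == pytest.approx(
        loop_ordering_traffic(simplified, skx, False)
    )
    big = loop_ordering_traffic(brunel, skx, True, coupling_ratio=10**9)
    for k in brunel.clock_kernels:
        l3 = ecm_serial(k, skx, residency="L3").t_data
        assert big[k.name] == pytest.approx(l3, rel=1e-6)


def test_saturation_vs_coupling_ratio_bounded_for_current_based(brunel, skx):
    """With loop ordering, the I-based model's saturation point grows with
    the coupling ratio but stays below ~17 threads: the event-driven spike
    delivery keeps paying full memory traffic."""
    ratios = [1, 2, 3, 5, 10, 15, 25, 50, 100, 1000]
    nsat = [
        model_saturation_point(brunel, skx, loop_ordering=True, coupling_ratio=r)
        for r in ratios
    ]
    assert all(b >= a for a, b in zip(nsat, nsat[1:]))  # non-decreasing
    assert max(nsat) <= 17


def test_saturation_near_linear_in_ratio_for_conductance_based(
    simplified, reconstructed, skx
):
    """G-based models: saturation point is nearly proportional to the
    coupling ratio (their event traffic is a tiny fraction)."""
    ratios = [1, 2, 4, 8, 16]
    for model in (simplified, reconstructed):
        nsat = [
            model_saturation_point(model, skx, loop_ordering=True, coupling_ratio=r)
            for r in ratios
        ]
        slope = [n / r for n, r in zip(nsat, ratios)]
        assert max(slope) / min(slope) < 1.5  # near-linear
        assert all(b >= a for a, b in zip(nsat, nsat[1:]))


def test_bandwidth_saturates_well_before_full_node(cards, skx):
    """All three reference models cross 90% bandwidth utilization well
    before the 18 available threads when data streams from memory."""
    for model in cards.models.values():
        util = [bandwidth_utilization(model, skx, n) for n in range(1, 19)]
        assert all(b >= a for a, b in zip(util, util[1:]))
        crossing = next(n for n, u in zip(range(1, 19), util) if u >= 0.9)
        assert crossing < 18
        assert util[-1] == 1.0
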