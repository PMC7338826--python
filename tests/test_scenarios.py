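"""Composite scenarios: serial/shared/distributed predictions and attribution."""

import math

import pytest

from brainperf import (
    bottleneck_attribution,
    bottleneck_grid,
    distributed_performance,
    saturated_throughput,
    serial_profile,
    shared_memory_profile,
)
from brainperf.scenarios import ScenarioResult
from brainperf.testing import toy_model


def test_breakdown_fractions_sum_to_one(cards, skx):
    for model in cards.models.values():
        for res in (
            serial_profile(model, skx),
            shared_memory_profile(model, skx),
            distributed_performance(model, skx, 1e6, 8),
        ):
            assert sum(res.kernel_breakdown.values()) == pytest.approx(1.0, abs=1e-9)
            assert sum(res.feature_breakdown.values()) == pytest.approx(1.0, abs=1e-9)
            assert res.performance > 0
            assert res.bottleneck in res.feature_breakdown


def test_inconsistent_fractions_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        ScenarioResult(performance=1.0, unit="per_neuron",
                       feature_breakdown={"CPU": 0.7, "MemBW": 0.6})


def test_degenerate_zero_cost_model_raises(skx):
    m = toy_model(seed=21, with_event=False)
    zeroed = [
        k.model_copy(update={
            "t_OL": 0.0, "t_nOL": 0.0, "n_exp": 0.0,
            "bytes_l1l2": 0.0, "bytes_l2l3": 0.0, "bytes_l3mem": 0.0,
        })
        for k in m.kernels
    ]
    with pytest.raises(ValueError, match="serial profile is undefined"):
        serial_profile(m.model_copy(update={"kernels": zeroed}), skx, rate=0.0)


def test_saturated_throughput_properties(brunel, skx):
    base = saturated_throughput(brunel, skx)
    doubled = skx.model_copy(update={"mem_bandwidth": 2 * skx.mem_bandwidth})
    assert saturated_throughput(brunel, doubled) == pytest.approx(2 * base)
    m = toy_model(seed=22, with_event=False)
    no_traffic = [k.model_copy(update={"bytes_l3mem": 0.0}) for k in m.kernels]
    assert saturated_throughput(m.model_copy(update={"kernels": no_traffic}), skx) \
        == math.inf


def test_saturated_equals_full_node_when_coupling_ratio_is_one(simplified, skx):
    """The point-neuron reduction synchronizes every step, so loop ordering
    buys nothing and its full-node performance sits exactly on the
    bandwidth ceiling (computed via two independent code paths)."""
    sat = saturated_throughput(simplified, skx)
    full = shared_memory_profile(simplified, skx).performance
    assert full == pytest.approx(sat, rel=1e-12)


def test_single_thread_l1_profile_reduces_to_serial_composition(brunel, skx):
    """shared_memory_profile at 1 thread, L1-resident, is the plain sum of
    per-kernel serial ECM/event predictions."""
    from brainperf.ecm import aggregate_step_cost

    res = shared_memory_profile(brunel, skx, n_threads=1, residency="L1",
                                loop_ordering=False)
    cycles = sum(c.cycles for c in aggregate_step_cost(
        brunel, skx, n_threads=1, residency="L1"))
    assert res.performance == pytest.approx(brunel.dt * skx.clock / cycles)


def test_single_rank_distributed_equals_shared_memory(brunel, skx):
    n = 2e5
    dist = distributed_performance(brunel, skx, n, 1, unit="per_neuron")
    shared = shared_memory_profile(brunel, skx)
    assert dist.performance == pytest.approx(shared.performance, rel=1e-12)


def test_sub_neuron_splitting_rejected(brunel, skx):
    with pytest.raises(ValueError, match="sub-neuron splitting"):
        distributed_performance(brunel, skx, 10, 100)


def test_weak_scaling_flat_then_latency_degraded(brunel, skx):
    """At 1e5 neurons/rank the network performance is constant over small
    clusters and only sags once the linear-in-P latency term matters."""
    ranks = [1, 4, 16]
    perfs = [
        distributed_performance(brunel, skx, 1e5 * p, p).performance
        for p in ranks
    ]
    assert max(perfs) / min(perfs) < 1.03
    huge = distributed_performance(brunel, skx, 1e5 * 65536, 65536).performance
    assert huge < 0.5 * perfs[0]


def test_strong_scaling_has_an_interior_optimum(brunel, skx):
    """Constant problem size: performance rises with ranks, peaks, then is
    dragged down by collective latency."""
    ranks = [2**i for i in range(0, 17)]
    perfs = [
        distributed_performance(brunel, skx, 1e6, p,
                                mode="constant_problem").performance
        for p in ranks
    ]
    best = perfs.index(max(perfs))
    assert 0 < best < len(ranks) - 1
    assert perfs[-1] < max(perfs)


def test_network_latency_dominates_large_clusters(cards, skx):
    for model in cards.models.values():
        label, _ = bottleneck_attribution(model, skx, 2**22, 2**14)
        assert label == "NetLatency"


def test_network_bandwidth_never_dominates(cards, skx):
    grid_n = [1e4, 1e6, 1e8]
    grid_p = [1, 16, 256, 4096, 65536]
    for model in cards.models.values():
        grid = bottleneck_grid(model, skx, grid_n, grid_p)
        assert "NetBandwidth" not in set(grid.values())
        assert grid[(1e4, 65536)] == "unsupported"  # sub-neuron splitting


def test_simplified_single_rank_is_pure_memory_bandwidth(simplified, skx):
    """Coupling ratio 1 leaves every kernel pinned to the bandwidth ceiling:
    the breakdown attributes ~100% to MemBW."""
    _, features = bottleneck_attribution(simplified, skx, 1e6, 1)
    assert features["MemBW"] == pytest.approx(1.0, abs=1e-6)


def test_serial_performance_ratio_spans_four_orders(brunel, reconstructed, skx):
    """Point current-based vs morphologically detailed conductance-based:
    ~1e4x per-neuron serial performance gap on the reference card."""
    ratio = (serial_profile(brunel, skx).performance
             / serial_profile(reconstructed, skx).performance)
    assert ratio == pytest.approx(1e4, rel=0.1)


def test_removing_a_zero_share_feature_changes_nothing(brunel, skx):
    res = shared_memory_profile(brunel, skx)
    assert all(v > 0 for v in res.feature_breakdown.values())
    again = shared_memory_profile(brunel, skx)
    assert again.performance == res.performance
    assert again.feature_breakdown == res.feature_breakdown
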