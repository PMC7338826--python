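"""Card calibration audit: recompute headline predictions and compare.

The packaged cards' free constants were calibrated so the engines
reproduce a fixed set of reference values (per-neuron flop/traffic audit,
serial and saturated performance, full-node shared-memory performance and
cache-residency speedups).  This module recomputes every one of those
quantities from the cards through the engines and reports it next to its
calibration reference, flagging agreement to two significant figures --
the audit a user should run after editing any card.
"""

from __future__ import annotations

import pandas as pd

from .cards import CardSet, calibration_report
from .scenarios import saturated_throughput, serial_profile, shared_memory_profile

__all__ = ["CALIBRATION_REFERENCE", "calibration_audit"]

#: reference values the packaged cards are calibrated to reproduce
#: (units: flop and bytes per neuron per simulated second at 1 Hz; bytes of
#: resident state; simulated seconds per wallclock second; dimensionless
#: speedups relative to memory residency)
CALIBRATION_REFERENCE: dict[str, dict[str, float]] = {
    "brunel": {
        "flop": 2.3e5, "data_volume_bytes": 1.0e6, "arithmetic_intensity": 0.23,
        "memory_capacity_bytes": 2.7e5, "serial_perf": 3.4e3,
        "saturated_perf": 1.6e4, "full_node_perf": 5.2e4,
        "speedup_L3": 2.5, "speedup_L2": 8.7, "speedup_L1": 33.9,
    },
    "simplified": {
        "flop": 1.7e7, "data_volume_bytes": 1.3e8, "arithmetic_intensity": 0.13,
        "memory_capacity_bytes": 1.0e4, "serial_perf": 1.7e2,
        "saturated_perf": 7.9e2, "full_node_perf": 7.9e2,
        "speedup_L3": 4.7, "speedup_L2": 6.5, "speedup_L1": 6.6,
    },
    "reconstructed": {
        "flop": 8.5e9, "data_volume_bytes": 3.1e10, "arithmetic_intensity": 0.27,
        "memory_capacity_bytes": 2.9e6, "serial_perf": 3.4e-1,
        "saturated_perf": 1.7, "full_node_perf": 3.9,
        "speedup_L3": 1.8, "speedup_L2": 2.4, "speedup_L1": 2.4,
    },
}


def _round2(x: float) -> float:
    return float(f"{x:.1e}") if x else 0.0


def calibration_audit(
    cards: CardSet, hardware: str = "skx_avx512", rate: float = 1.0
) -> pd.DataFrame:
    """Recompute all calibrated quantities and compare to their references.

    Returns a tidy frame with one row per (model, quantity):
    ``computed``, ``reference``, ``matches_2sf``.
    """
    hw = cards.hw(hardware)
    rows = []
    for name, ref in CALIBRATION_REFERENCE.items():
        if name not in cards.models:
            continue
        model = cards.model(name)
        rep = calibration_report(model, rate)
        full = shared_memory_profile(model, hw)
        computed = {
            **rep.to_dict(),
            "serial_perf": serial_profile(model, hw, rate).performance,
            "saturated_perf": saturated_throughput(model, hw, rate),
            "full_node_perf": full.performance,
        }
        for lvl in ("L3", "L2", "L1"):
            prof = shared_memory_profile(model, hw, residency=lvl)
            computed[f"speedup_{lvl}"] = prof.performance / full.performance
        for key, want in ref.items():
            got = computed[key]
            rows.append(
                {
                    "model": name,
                    "quantity": key,
                    "computed": got,
                    "reference": want,
                    "matches_2sf": _round2(got) == _round2(want),
                }
            )
    return pd.DataFrame(rows)
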