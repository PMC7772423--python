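"""Drug-condition tail-current ratios for the 4-AP / NS-1643 sequence.

Cells are recorded sequentially in Tyrode, 3 mM 4-AP, and 4-AP + 30 uM
NS-1643.  4-AP blocks Kv11 channels while potentiating Kv12; NS-1643 then
blocks the Kv12 component.  In Kv12-dominant (mock-like) cells the 4-AP
tail ratio stays near 1 (potentiation compensates the Kv11 block) and
NS-1643 nearly abolishes the tail; in Kv12-poor (cln1-like) cells 4-AP
already suppresses the tail.  For the instantaneous, stateless drug model
used by the simulator the tail ratio equals the conductance algebra
(sum_f g_f s_f) / (sum_f g_f) over the families' tail shares, with s_f the
family's drug scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SweepRecording
from .tails import tail_amplitude, tail_peak_latency

__all__ = ["ConditionTailSet", "tail_ratio", "sequential_condition_table", "condition_tails"]

CONDITIONS = ("tyrode", "ap4", "ap4_ns1643")
_DRUG_TO_CONDITION = {"none": "tyrode", "ap4": "ap4", "ap4_ns1643": "ap4_ns1643"}


@dataclass
class ConditionTailSet:
    """Tail amplitudes (pA/pF) per drug condition for one cell."""

    cell_id: str
    day: int
    genotype: str
    tails: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond in self.tails:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        if "tyrode" not in self.tails:
            raise ValueError("the tyrode entry is mandatory")


def condition_tails(
    sweeps: dict[str, SweepRecording], cm: float, window_ms: float = 20.0
) -> ConditionTailSet:
    """Measure +70 mV-step tails across drug conditions at a fixed latency.

    The peak latency is located on the drug-free sweep so the same window
    is applied across the sequence; tails are measured relative to the
    late-tail baseline so a fully blocked cell reads zero (leak excluded).
    """
    by_cond = {_DRUG_TO_CONDITION[s.drug]: s for s in sweeps.values()}
    if "tyrode" not in by_cond:
        raise ValueError("a drug-free (tyrode) sweep is required")
    ref = by_cond["tyrode"]
    latency = tail_peak_latency(ref)
    tails = {
        cond: tail_amplitude(s, cm, latency, window_ms, subtract_baseline=True)
        for cond, s in by_cond.items()
    }
    return ConditionTailSet(
        cell_id=ref.cell_id, day=ref.day, genotype=ref.genotype, tails=tails
    )


def tail_ratio(
    tail_set: ConditionTailSet,
    num: str = "ap4",
    den: str = "tyrode",
    resolution_floor: float = 1e-6,
) -> float:
    """Ratio of tail amplitudes between two conditions (NaN when undefined)."""
    for cond in (num, den):
        if cond not in tail_set.tails:
            raise KeyError(f"condition {cond!r} missing for cell {tail_set.cell_id}")
    d = tail_set.tails[den]
    if abs(d) < resolution_floor:
        return float("nan")
    return tail_set.tails[num] / d


def sequential_condition_table(cells: list[ConditionTailSet]) -> pd.DataFrame:
    """Long-format table of per-cell tails normalised to the Tyrode value.

    Cells missing any of the three conditions are excluded (logged on the
    returned frame's ``attrs['excluded']``).  Columns: cell, genotype,
    condition, value — ready for a two-way repeated-measures ANOVA with
    between-factor genotype and within-factor condition.
    """
    rows = []
    excluded = []
    for c in cells:
        if any(cond not in c.tails for cond in CONDITIONS):
            excluded.append(c.cell_id)
            continue
        tyr = c.tails["tyrode"]
        for cond in CONDITIONS:
            rows.append(
                {
                    "cell": c.cell_id,
                    "genotype": c.genotype,
                    "condition": cond,
                    "value": c.tails[cond] / tyr if tyr != 0 else float("nan"),
                }
            )
    df = pd.DataFrame(rows, columns=["cell", "genotype", "condition", "value"])
    df.attrs["excluded"] = excluded
    return df
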