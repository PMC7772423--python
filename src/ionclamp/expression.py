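"""FPKM fold-change computation and differential-expression calling.

Works on per-gene FPKM tables for two conditions (A = mock, B = the
CLN1-overexpressing condition).  log2FC = log2(FPKM_B / FPKM_A); a gene is
called differentially expressed when |log2FC| >= 1 and the FDR q-value
<= 0.05, both thresholds inclusive.  q-values are consumed, not computed:
FDR control belongs to the upstream RNA-seq pipeline.  The packaged
channel-DEG table (13 VGCC/VGKC subunit genes with printed FPKM pairs,
log2FC and q) ships as a fixture for desk-scale verification; it carries
both the printed log2FC and the value recomputed from the rounded FPKMs so
rounding and logic errors stay distinguishable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionRecord",
    "log2_fold_change",
    "call_degs",
    "family_summary",
    "load_channel_deg_table",
]

#: Families counted as potassium channels (Kv plus two-pore and inward rectifiers).
POTASSIUM_FAMILIES = ("VGKC-Kv", "K2P", "Kir")
VGCC_FAMILIES = ("VGCC-aux-a2d", "VGCC-aux-gamma")


@dataclass
class ExpressionRecord:
    """One gene's expression pair with derived fold change and DEG flag."""

    gene: str
    alias: str
    family: str
    fpkm_a: float
    fpkm_b: float
    log2fc: float
    q: float
    is_deg: bool


def log2_fold_change(fpkm_a: float, fpkm_b: float, pseudocount: float = 0.0) -> float:
    """log2(FPKM_B / FPKM_A), B the overexpressing condition.

    Zero or negative FPKM yields NaN (undefined fold change) unless a
    pseudocount is configured.
    """
    a = fpkm_a + pseudocount
    b = fpkm_b + pseudocount
    if a <= 0 or b <= 0:
        return float("nan")
    return math.log2(b / a)


def call_degs(
    table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Flag differentially expressed genes: |log2FC| >= 1 and q <= 0.05.

    Thresholds are inclusive.  Requires ``fpkm_a``, ``fpkm_b`` and ``q``
    columns; adds/overwrites ``log2fc`` and ``is_deg``.  Rows with an
    undefined fold change are never flagged.
    """
    if "q" not in table.columns:
        raise ValueError("table must provide a 'q' column")
    out = table.copy()
    out["log2fc"] = [
        log2_fold_change(a, b, pseudocount) for a, b in zip(out["fpkm_a"], out["fpkm_b"])
    ]
    lfc = out["log2fc"].to_numpy()
    q = out["q"].to_numpy()
    with np.errstate(invalid="ignore"):
        out["is_deg"] = (np.abs(lfc) >= lfc_threshold) & (q <= q_threshold) & np.isfinite(lfc)
    return out


def family_summary(table: pd.DataFrame) -> dict[str, int]:
    """DEG counts by family and super-group.

    Returns per-family counts plus ``potassium_total`` (Kv + K2P + Kir),
    ``kv`` and ``vgcc_related``.
    """
    if len(table) == 0 or "is_deg" not in table.columns:
        degs = table.iloc[0:0] if len(table) == 0 else table[table["is_deg"]]
    else:
        degs = table[table["is_deg"]]
    counts: dict[str, int] = {}
    if len(degs):
        counts.update(degs.groupby("family").size().to_dict())
    counts["potassium_total"] = int(sum(counts.get(f, 0) for f in POTASSIUM_FAMILIES))
    counts["kv"] = int(counts.get("VGKC-Kv", 0))
    counts["vgcc_related"] = int(sum(counts.get(f, 0) for f in VGCC_FAMILIES))
    return counts


def load_channel_deg_table() -> pd.DataFrame:
    """The packaged 13-gene VGCC/VGKC channel-DEG table.

    Columns: family, gene, alias, name, fpkm_mock, fpkm_cln1,
    log2fc_printed, q, plus recomputed ``log2fc`` and the ``is_deg`` flag
    (mock is condition A, the overexpressing line condition B).
    """
    with resources.files("ionclamp.data").joinpath("channel_degs.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t")
    table = raw.rename(columns={"fpkm_mock": "fpkm_a", "fpkm_cln1": "fpkm_b"})
    table = call_degs(table)
    table = table.rename(columns={"fpkm_a": "fpkm_mock", "fpkm_b": "fpkm_cln1"})
    return table
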