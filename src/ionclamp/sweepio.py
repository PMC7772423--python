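"""Plain-text sweep files and expression-table IO.

Sweep dialect: '#'-prefixed ``key=value`` header lines followed by two
tab-separated columns (time_ms, current_pA).  Mandatory keys: cell_id,
genotype, day, solution, drug, sampling_khz, filter_khz, n_sweep_avg,
protocol.  The protocol is serialised as comma-separated segments
``kind:v_start:v_end:duration_ms``.  Floats are written at 6 significant
digits (documented relative loss below 1e-5).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import call_degs
from .simulate import ProtocolSpec, Segment, SweepRecording

__all__ = ["read_sweep_file", "write_sweep_file", "read_expression_table", "SweepParseError"]

MANDATORY_KEYS = (
    "cell_id", "genotype", "day", "solution", "drug",
    "sampling_khz", "filter_khz", "n_sweep_avg", "protocol",
)


class SweepParseError(ValueError):
    """Malformed sweep file; the message names the offending key or line."""


def _protocol_to_str(p: ProtocolSpec) -> str:
    return ",".join(
        f"{s.kind}:{s.v_start:g}:{s.v_end:g}:{s.duration:g}" for s in p.segments
    )


def _protocol_from_str(text: str, sampling_khz: float, filter_khz: float,
                       n_avg: int, name: str = "protocol") -> ProtocolSpec:
    segments = []
    for part in text.split(","):
        fields = part.split(":")
        if len(fields) != 4:
            raise SweepParseError(f"malformed protocol segment {part!r}")
        kind, v0, v1, dur = fields
        segments.append(Segment(kind, float(v0), float(v1), float(dur)))
    return ProtocolSpec(
        segments=tuple(segments), sampling_khz=sampling_khz,
        filter_khz=filter_khz, n_sweep_avg=n_avg, name=name,
    )


def write_sweep_file(rec: SweepRecording, path: str | Path) -> Path:
    """Write a sweep in the text dialect; header key order is fixed."""
    path = Path(path)
    lines = [
        f"# cell_id={rec.cell_id}",
        f"# genotype={rec.genotype}",
        f"# day={rec.day}",
        f"# solution={rec.solution}",
        f"# drug={rec.drug}",
        f"# sampling_khz={rec.protocol.sampling_khz:g}",
        f"# filter_khz={rec.protocol.filter_khz:g}",
        f"# n_sweep_avg={rec.protocol.n_sweep_avg}",
        f"# protocol={_protocol_to_str(rec.protocol)}",
        f"# protocol_name={rec.protocol.name}",
    ]
    if rec.cm_pf is not None:
        lines.append(f"# cm_pf={rec.cm_pf:.6g}")
    body = io.StringIO()
    # time at full precision (the uniform-grid check must survive long
    # recordings); currents at 6 significant digits (documented loss bound)
    np.savetxt(
        body, np.column_stack([rec.time, rec.current]),
        fmt=["%.10g", "%.6g"], delimiter="\t",
    )
    path.write_text("\n".join(lines) + "\n" + body.getvalue())
    return path


def read_sweep_file(path: str | Path) -> SweepRecording:
    """Parse a sweep file, validating the header and the time grid."""
    path = Path(path)
    header: dict[str, str] = {}
    body_start = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body_start += 1
            entry = line[1:].strip()
            if "=" not in entry:
                raise SweepParseError(f"malformed header line: {line.strip()!r}")
            key, value = entry.split("=", 1)
            header[key.strip()] = value.strip()
    for key in MANDATORY_KEYS:
        if key not in header:
            raise SweepParseError(f"missing mandatory header key '{key}'")
    data = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["time_ms", "current_pA"],
        dtype=float, engine="c",
    )
    if data.shape[1] != 2:
        raise SweepParseError("body must have exactly 2 columns")
    time = data["time_ms"].to_numpy()
    fs = float(header["sampling_khz"])
    if len(time) > 1:
        dt = np.diff(time)
        if np.any(dt <= 0) or not np.allclose(dt, 1.0 / fs, rtol=1e-4, atol=1e-6):
            raise SweepParseError("non-uniform time grid")
    protocol = _protocol_from_str(
        header["protocol"], fs, float(header["filter_khz"]),
        int(header["n_sweep_avg"]), header.get("protocol_name", "protocol"),
    )
    # rebuild the exactly uniform grid (same construction as the simulator)
    time = np.arange(len(time)) * (1.0 / fs)
    return SweepRecording(
        time=time,
        current=data["current_pA"].to_numpy(),
        protocol=protocol,
        solution=header["solution"],
        drug=header["drug"],
        cell_id=header["cell_id"],
        genotype=header["genotype"],
        day=int(header["day"]),
        cm_pf=float(header["cm_pf"]) if "cm_pf" in header else None,
    )


def read_expression_table(path: str | Path, warn_tolerance: float = 0.01) -> pd.DataFrame:
    """Read a TSV expression table and recompute fold changes.

    Requires ``gene``, ``fpkm_a``, ``fpkm_b`` and ``q`` columns (the
    ``fpkm_mock`` / ``fpkm_cln1`` aliases are accepted).  Recomputes log2fc
    and flags DEGs; if the file carries its own log2fc column the recomputed
    values are cross-checked and discrepancies beyond ``warn_tolerance``
    collected under ``attrs['log2fc_mismatches']``.
    """
    table = pd.read_csv(path, sep="\t")
    if len(table) == 0:
        return table
    table = table.rename(columns={"fpkm_mock": "fpkm_a", "fpkm_cln1": "fpkm_b"})
    for col in ("gene", "fpkm_a", "fpkm_b", "q"):
        if col not in table.columns:
            raise SweepParseError(f"expression table missing column '{col}'")
    for col in ("fpkm_a", "fpkm_b", "q"):
        bad = pd.to_numeric(table[col], errors="coerce").isna() & table[col].notna()
        if bad.any():
            raise SweepParseError(
                f"malformed numeric value in column '{col}', rows {list(table.index[bad])}"
            )
        table[col] = pd.to_numeric(table[col])
    provided = table["log2fc"].copy() if "log2fc" in table.columns else None
    table = call_degs(table)
    if provided is not None:
        delta = (table["log2fc"] - provided).abs()
        table.attrs["log2fc_mismatches"] = list(table.loc[delta > warn_tolerance, "gene"])
    return table
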