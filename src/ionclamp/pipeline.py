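"""End-to-end pipeline driver: simulate, analyse, and summarise.

Runs the full analysis chain on a simulated population — passive membrane
properties, ramp I-V in both charge carriers, tail activation with
Boltzmann fits, the drug sequence, calcium imaging, the channel-DEG table
and the group statistics — writing one TSV/JSON per stage plus a summary
report.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression, imaging, passive, pharm, rampiv, simulate, stats, tails

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("ionclamp")


@dataclass
class RunConfig:
    """Pipeline configuration; ``seed`` is mandatory for simulation runs."""

    seed: int
    out_dir: str = "ionclamp_out"
    n_mock: int = 15
    n_cln1: int = 15
    day_range: tuple[int, int] = (3, 10)
    n_mock_rois: int = 132
    n_cln1_rois: int = 40
    stages: tuple[str, ...] = (
        "passive", "ramp", "tails", "pharm", "imaging", "degs", "stats",
    )
    lfc_threshold: float = 1.0
    q_threshold: float = 0.05
    fit_range: tuple[float, float] = (-90.0, -40.0)
    search_range: tuple[float, float] = (-30.0, 40.0)
    population: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ValueError("config must provide a seed")
        for key in ("day_range", "stages", "fit_range", "search_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _summaries(df: pd.DataFrame, column: str) -> dict:
    out = {}
    for genotype, sub in df.groupby("genotype"):
        x = sub[column].dropna().to_numpy()
        out[genotype] = {
            "mean": float(np.mean(x)),
            "sem": float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else None,
            "n": int(len(x)),
        }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary report dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    rng_seed = config.seed

    protocols = []
    if "passive" in config.stages:
        protocols.append("capacitance")
    if "ramp" in config.stages:
        protocols += ["ramp_ca", "ramp_ba"]
    if "tails" in config.stages:
        protocols.append("tails")
    if "pharm" in config.stages:
        protocols.append("pharm")

    cells = []
    if protocols:
        log.info("simulating %d+%d cells: %s", config.n_mock, config.n_cln1, protocols)
        try:
            cells = simulate.simulate_population(
                config.population, config.n_mock, config.n_cln1,
                config.day_range, rng_seed, protocols,
            )
        except Exception as err:
            raise RuntimeError(f"stage 'simulate' failed: {err}") from err

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as err:
            raise RuntimeError(f"stage '{name}' failed: {err}") from err

    per_cell = pd.DataFrame(
        {
            "cell_id": [c.truth.params.cell_id for c in cells],
            "genotype": [c.truth.params.genotype for c in cells],
            "day": [c.truth.params.day for c in cells],
            "true_cm": [c.truth.cm for c in cells],
        }
    )

    if "passive" in config.stages:
        def _passive():
            rows = []
            for c in cells:
                est = passive.passive_estimate(c.sweeps["capacitance"])
                rows.append(
                    {
                        "cell_id": c.truth.params.cell_id,
                        "cm": est.cm, "rm": est.rm, "g": est.g,
                        "g_density": est.g_density,
                        "holding_density": est.holding_density,
                        "delta_q": est.delta_q, "delta_v": est.delta_v,
                    }
                )
            df = per_cell.merge(pd.DataFrame(rows), on="cell_id")
            df.to_csv(out_dir / "passive.tsv", sep="\t", index=False)
            report["passive"] = {
                "cm_pf": _summaries(df, "cm"),
                "g_density_ps_per_pf": _summaries(df, "g_density"),
                "holding_pa_per_pf": _summaries(df, "holding_density"),
            }
            return df
        passive_df = run_stage("passive", _passive)
        cm_lookup = dict(zip(passive_df["cell_id"], passive_df["cm"]))
    else:
        cm_lookup = {c.truth.params.cell_id: c.truth.cm for c in cells}

    if "ramp" in config.stages:
        def _ramp():
            rows = []
            for c in cells:
                for key, solution in (("ramp_ca", "tyrode_ca"), ("ramp_ba", "ba_tea")):
                    sweep = c.sweeps[key]
                    sweep.cm_pf = cm_lookup[c.truth.params.cell_id]
                    iv = rampiv.net_inward_current(
                        sweep, fit_range=config.fit_range, search_range=config.search_range
                    )
                    rows.append(
                        {
                            "cell_id": c.truth.params.cell_id,
                            "solution": solution,
                            "net_peak": iv.net_peak,
                            "peak_voltage": iv.peak_voltage,
                            "no_deflection": iv.no_deflection,
                        }
                    )
            df = per_cell.merge(pd.DataFrame(rows), on="cell_id")
            df.to_csv(out_dir / "ramp_iv.tsv", sep="\t", index=False)
            report["ramp"] = {
                sol: _summaries(df[df["solution"] == sol], "net_peak")
                for sol in ("tyrode_ca", "ba_tea")
            }
            return df
        ramp_df = run_stage("ramp", _ramp)

    if "tails" in config.stages:
        def _tails():
            rows = []
            for c in cells:
                cm = cm_lookup[c.truth.params.cell_id]
                curve = tails.activation_curve(c.sweeps["tails"], cm)
                fa = tails.fractional_activation(curve)
                fit = tails.fit_boltzmann(curve.activating_v, fa)
                rows.append(
                    {
                        "cell_id": c.truth.params.cell_id,
                        "v_half": fit.v_half, "slope_s": fit.slope_s,
                        "tail_max": curve.i_max, "converged": fit.converged,
                    }
                )
            df = per_cell.merge(pd.DataFrame(rows), on="cell_id")
            df.to_csv(out_dir / "tail_activation.tsv", sep="\t", index=False)
            report["tails"] = {
                "v_half_mv": _summaries(df, "v_half"),
                "slope_mv": _summaries(df, "slope_s"),
            }
            return df
        tails_df = run_stage("tails", _tails)

    if "pharm" in config.stages:
        def _pharm():
            sets = []
            for c in cells:
                cm = cm_lookup[c.truth.params.cell_id]
                sets.append(pharm.condition_tails(c.sweeps["pharm"], cm))
            long = pharm.sequential_condition_table(sets)
            long.to_csv(out_dir / "pharm_conditions.tsv", sep="\t", index=False)
            ratios = pd.DataFrame(
                {
                    "cell_id": [s.cell_id for s in sets],
                    "genotype": [s.genotype for s in sets],
                    "day": [s.day for s in sets],
                    "ratio_4ap": [pharm.tail_ratio(s, "ap4", "tyrode") for s in sets],
                    "ratio_ns": [pharm.tail_ratio(s, "ap4_ns1643", "tyrode") for s in sets],
                }
            )
            ratios.to_csv(out_dir / "pharm_ratios.tsv", sep="\t", index=False)
            report["pharm"] = {
                "ratio_4ap": _summaries(ratios, "ratio_4ap"),
                "ratio_ns": _summaries(ratios, "ratio_ns"),
            }
            return long, ratios
        pharm_long, pharm_ratios = run_stage("pharm", _pharm)

    if "imaging" in config.stages:
        def _imaging():
            traces = simulate.simulate_fluorescence_traces(
                config.n_mock_rois, config.n_cln1_rois, seed=rng_seed + 1
            )
            df = pd.DataFrame(
                {
                    "roi_id": [t.roi_id for t in traces],
                    "genotype": [t.genotype for t in traces],
                    "day": [t.day for t in traces],
                    "df_f0": [imaging.delta_f_over_f0(t) for t in traces],
                    "true_amplitude": [t.true_amplitude for t in traces],
                }
            )
            df.to_csv(out_dir / "imaging.tsv", sep="\t", index=False)
            report["imaging"] = {"df_f0": _summaries(df, "df_f0")}
            return df
        imaging_df = run_stage("imaging", _imaging)

    if "degs" in config.stages:
        def _degs():
            table = expression.load_channel_deg_table()
            table.to_csv(out_dir / "channel_degs.tsv", sep="\t", index=False)
            counts = expression.family_summary(table)
            report["degs"] = {
                "n_rows": int(len(table)),
                "n_flagged": int(table["is_deg"].sum()),
                "family_counts": counts,
                "table": table[
                    ["family", "gene", "fpkm_mock", "fpkm_cln1", "log2fc_printed", "log2fc", "q"]
                ].to_dict(orient="records"),
            }
            return table
        run_stage("degs", _degs)

    if "stats" in config.stages and "passive" in config.stages:
        def _stats():
            mock = passive_df[passive_df["genotype"] == "mock"]["cm"].to_numpy()
            cln1 = passive_df[passive_df["genotype"] == "cln1"]["cm"].to_numpy()
            tests = {
                "cm_mann_whitney": stats.mann_whitney(mock, cln1),
                "cm_shapiro_gate": stats.shapiro_gate(mock, cln1),
            }
            if "ramp" in config.stages:
                ba = ramp_df[ramp_df["solution"] == "ba_tea"]
                tests["ramp_ba_pooled_t"] = stats.pooled_t_raw(
                    ba[ba["genotype"] == "mock"]["net_peak"],
                    ba[ba["genotype"] == "cln1"]["net_peak"],
                )
            if "imaging" in config.stages:
                tests["imaging_pooled_t"] = stats.pooled_t_raw(
                    imaging_df[imaging_df["genotype"] == "mock"]["df_f0"],
                    imaging_df[imaging_df["genotype"] == "cln1"]["df_f0"],
                )
            if "pharm" in config.stages:
                tests["pharm_rm_anova"] = stats.rm_anova_two_way(pharm_long)
            def as_dict(res):
                if isinstance(res, dict):
                    return {k: as_dict(v) for k, v in res.items()}
                return {
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "method": res.method,
                }
            report["stats"] = {name: as_dict(res) for name, res in tests.items()}
        run_stage("stats", _stats)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
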