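"""Orchestration: simulate -> analyze -> report as one reproducible run.

A run is parameterized by a single config (YAML/JSON or constructed in
code) carrying one global seed.  The seed fans out to per-modality seeds
through ``numpy.random.SeedSequence.spawn`` in a fixed modality order
(cm, syph, fusion, em), so any modality can be re-run independently and an
identical config + seed reproduces byte-identical result files.

The default demo config simulates a control condition and an
endocytosis-blocked condition side by side and reports the group
comparisons (mean +/- s.e.m., t-test, stars) for the headline statistics.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as eqio
from .capacitance import analyze_recording
from .em import aggregate_densities, profile_densities
from .errors import InvalidConfigError, StageError
from .fusion import analyze_spot, detect_pre_close, summarize_cell
from .groupstats import t_test
from .protocols import get_protocol
from .synthetic import (
    CmGroundTruth, EMGroundTruth, SpotGroundTruth, SypHGroundTruth,
    simulate_cm_recording, simulate_em_tables, simulate_spot_trace,
    simulate_syph_experiment, truth_dict,
)
from .syph import compute_syph_rate_decay_n

log = logging.getLogger("endoquant.pipeline")

MODALITY_ORDER = ("cm", "syph", "fusion", "em")

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Fully-resolved configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "endoquant_run"
    modalities: tuple = MODALITY_ORDER
    # capacitance: per-condition generator parameters
    cm_protocol: str = "depol_20ms"
    cm_n_cells: int = 6
    cm_conditions: dict = field(default_factory=lambda: {
        "ctrl": {"jump_fF": 531.0, "tau_s": 10.2, "noise_sd_fF": 10.0},
        "nsf_block": {"jump_fF": 420.0, "tau_s": 35.0, "noise_sd_fF": 10.0},
    })
    # SypH
    syph_n_experiments: int = 4
    syph_n_boutons: int = 10
    syph_conditions: dict = field(default_factory=lambda: {
        "ctrl": {"peak_dff_percent": 161.0, "rate": 3.9, "noise_sd_percent": 3.0},
        "nsf_block": {"peak_dff_percent": 100.0, "rate": 1.0, "noise_sd_percent": 3.0},
    })
    # fusion spots
    fusion_n_cells: int = 4
    fusion_n_spots: int = 8
    fusion_n_pre_spots: int = 5
    fusion_noise_sd: float = 5.0
    fusion_conditions: dict = field(default_factory=lambda: {
        "ctrl": {"p_close": 0.5, "p_stay": 0.3, "p_shrink": 0.2,
                 "p_pre_close": 0.6, "ffn_release_tau_s": 2.0},
        "nsf_block": {"p_close": 0.15, "p_stay": 0.6, "p_shrink": 0.25,
                      "p_pre_close": 0.2, "ffn_release_tau_s": 4.0},
    })
    # EM
    em_n_profiles: int = 40
    em_timepoints: tuple = ("rest", "0min", "3min", "10min")
    em_conditions: dict = field(default_factory=lambda: {
        "ctrl": {"hrp_rates": {"rest": 0.2, "0min": 1.2, "3min": 1.8, "10min": 2.0},
                 "bulk_rates": {"rest": 0.05, "0min": 0.6, "3min": 0.4, "10min": 0.2}},
        "nsf_block": {"hrp_rates": {"rest": 0.2, "0min": 0.5, "3min": 0.7, "10min": 0.8},
                      "bulk_rates": {"rest": 0.05, "0min": 0.2, "3min": 0.15,
                                     "10min": 0.1}},
    })

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise InvalidConfigError(f"config file {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["modalities"] = list(self.modalities)
        d["em_timepoints"] = list(self.em_timepoints)
        d["version"] = __version__
        return d


def modality_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    """Fixed-order fan-out of the global seed to one child per modality."""
    children = np.random.SeedSequence(seed).spawn(len(MODALITY_ORDER))
    return dict(zip(MODALITY_ORDER, children))


# ---------------------------------------------------------------------------
# stages


def _stage_cm(cfg: RunConfig, ss: np.random.SeedSequence, out: Path) -> pd.DataFrame:
    protocol = get_protocol(cfg.cm_protocol)
    recs = []
    child = iter(ss.spawn(len(cfg.cm_conditions) * cfg.cm_n_cells))
    for cond, params in cfg.cm_conditions.items():
        for i in range(cfg.cm_n_cells):
            truth = CmGroundTruth(decay_model="mono", **params)
            recs.append(simulate_cm_recording(
                truth, protocol, seed=np.random.default_rng(next(child)),
                cell_id=f"{cond}_cell{i:02d}", condition=cond,
            ))
    eqio.write_cm_csv(recs, out / "cm_traces.csv")
    eqio.write_json(
        {cond: params for cond, params in cfg.cm_conditions.items()},
        out / "cm_truth.json",
    )
    kins = [analyze_recording(rec, model="mono") for rec in recs]
    df = eqio.cm_kinetics_to_frame(kins)
    df.to_csv(out / "cm_kinetics.csv", index=False, float_format=eqio.FLOAT_FORMAT)
    return df


def _stage_syph(cfg: RunConfig, ss: np.random.SeedSequence, out: Path) -> pd.DataFrame:
    exps = []
    child = iter(ss.spawn(len(cfg.syph_conditions) * cfg.syph_n_experiments))
    for cond, params in cfg.syph_conditions.items():
        for i in range(cfg.syph_n_experiments):
            truth = SypHGroundTruth(
                peak_dff_percent=params["peak_dff_percent"],
                decay=("linear", params["rate"]),
                n_boutons=cfg.syph_n_boutons,
                noise_sd_percent=params["noise_sd_percent"],
            )
            exps.append(simulate_syph_experiment(
                truth, seed=np.random.default_rng(next(child)),
                experiment_id=f"{cond}_exp{i:02d}", condition=cond,
            ))
    eqio.write_syph_csv(exps, out / "syph_traces.csv")
    rows = []
    for exp in exps:
        kin = compute_syph_rate_decay_n(exp)
        rows.append({
            "experiment_id": kin.experiment_id, "condition": kin.condition,
            "dff_percent": kin.dff_percent,
            "rate_decay_n_percent_per_s": kin.rate_decay_n_percent_per_s,
            "tau_s": kin.tau_s, "n_boutons": kin.n_boutons,
            "flagged": kin.flagged,
        })
    df = pd.DataFrame(rows)
    df.to_csv(out / "syph_kinetics.csv", index=False, float_format=eqio.FLOAT_FORMAT)
    return df


def _stage_fusion(cfg: RunConfig, ss: np.random.SeedSequence, out: Path) -> pd.DataFrame:
    traces = []
    cells = []
    n_cells_total = len(cfg.fusion_conditions) * cfg.fusion_n_cells
    child = iter(ss.spawn(n_cells_total))
    for cond, params in cfg.fusion_conditions.items():
        probs = np.array([params["p_close"], params["p_stay"], params["p_shrink"]])
        probs = probs / probs.sum()
        for c in range(cfg.fusion_n_cells):
            rng = np.random.default_rng(next(child))
            cell_id = f"{cond}_cell{c:02d}"
            cell_traces = []
            for s in range(cfg.fusion_n_spots):
                mode = rng.choice(
                    ["close_fusion", "stay_fusion", "shrink_fusion"], p=probs)
                truth = SpotGroundTruth(
                    mode=str(mode), noise_sd=cfg.fusion_noise_sd,
                    ffn_release_tau_s=params["ffn_release_tau_s"],
                    closure_time_s=float(rng.uniform(0.5, 8.0)),
                )
                cell_traces.append(simulate_spot_trace(
                    truth, seed=rng, spot_id=f"{cell_id}_s{s:02d}",
                    cell_id=cell_id))
            for s in range(cfg.fusion_n_pre_spots):
                mode = "pre_close" if rng.random() < params["p_pre_close"] else "no_close"
                truth = SpotGroundTruth(
                    mode=mode, noise_sd=cfg.fusion_noise_sd,
                    closure_time_s=float(rng.uniform(0.5, 8.0)),
                )
                cell_traces.append(simulate_spot_trace(
                    truth, seed=rng, spot_id=f"{cell_id}_pre{s:02d}",
                    cell_id=cell_id))
            traces.extend(cell_traces)
            events = [ev for tr in cell_traces if tr.spot_kind == "fusion_candidate"
                      and (ev := analyze_spot(tr)) is not None]
            pre = [detect_pre_close(tr) for tr in cell_traces
                   if tr.spot_kind == "pre_spot"]
            cells.append((summarize_cell(cell_id, events, pre), cond))
    eqio.write_spots_csv(traces, out / "fusion_spots.csv")
    events_df = eqio.fusion_events_to_frame(
        [ev for summary, _ in cells for ev in summary.events])
    events_df.to_csv(out / "fusion_events.csv", index=False,
                     float_format=eqio.FLOAT_FORMAT)
    cells_df = eqio.cell_summaries_to_frame([s for s, _ in cells])
    cells_df["condition"] = [cond for _, cond in cells]
    cells_df.to_csv(out / "fusion_cells.csv", index=False,
                    float_format=eqio.FLOAT_FORMAT)
    return cells_df


def _stage_em(cfg: RunConfig, ss: np.random.SeedSequence, out: Path) -> pd.DataFrame:
    tables = []
    n = len(cfg.em_conditions) * len(cfg.em_timepoints)
    child = iter(ss.spawn(n))
    for cond, params in cfg.em_conditions.items():
        for tp in cfg.em_timepoints:
            truth = EMGroundTruth(
                condition=cond, timepoint=tp, n_profiles=cfg.em_n_profiles,
                hrp_pos_rate_per_um2=params["hrp_rates"][tp],
                bulk_rate_per_um2=params["bulk_rates"][tp],
            )
            tables.append(simulate_em_tables(
                truth, seed=np.random.default_rng(next(child))))
    table = eqio.concat_em_tables(tables)
    eqio.write_em_csv(table, out / "em_vesicles.csv", out / "em_profiles.csv")
    per_profile = profile_densities(table)
    per_profile.to_csv(out / "em_densities.csv", index=False,
                       float_format=eqio.FLOAT_FORMAT)
    agg = aggregate_densities(per_profile)
    agg.to_csv(out / "em_aggregates.csv", index=False,
               float_format=eqio.FLOAT_FORMAT)
    return per_profile


def _stage_report(cfg: RunConfig, out: Path, results: dict) -> None:
    comparisons = []

    def compare(metric, df, col, cond_col="condition"):
        conds = list(dict.fromkeys(df[cond_col]))
        if len(conds) < 2:
            return
        a, b = conds[0], conds[1]
        va = df.loc[df[cond_col] == a, col].dropna()
        vb = df.loc[df[cond_col] == b, col].dropna()
        if len(va) < 2 or len(vb) < 2:
            return
        comparisons.append(t_test(va, vb, metric=metric, label_a=a, label_b=b))

    if "cm" in results:
        compare("cm_rate_decay_n_per_s", results["cm"], "rate_decay_n_per_s")
        compare("cm_delta_cm_peak_fF", results["cm"], "delta_cm_peak_fF")
    if "syph" in results:
        compare("syph_rate_decay_n_percent_per_s", results["syph"],
                "rate_decay_n_percent_per_s")
        compare("syph_dff_percent", results["syph"], "dff_percent")
    if "fusion" in results:
        kept = results["fusion"][~results["fusion"]["excluded"]]
        compare("prob_close_fusion", kept, "prob_close_fusion")
        compare("prob_pre_close", kept, "prob_pre_close")
        compare("mean_t_ffn_s", kept, "mean_t_ffn_s")
    if "em" in results:
        compare("em_hrp_density_per_um2", results["em"], "hrp_density_per_um2")
        compare("em_bulk_area_per_um2", results["em"], "bulk_area_per_um2")

    df = pd.DataFrame([dataclasses.asdict(c) for c in comparisons])
    df.to_csv(out / "report_comparisons.csv", index=False,
              float_format=eqio.FLOAT_FORMAT)
    eqio.write_json([dataclasses.asdict(c) for c in comparisons],
                    out / "report_comparisons.json")


STAGES = {
    "cm": _stage_cm,
    "syph": _stage_syph,
    "fusion": _stage_fusion,
    "em": _stage_em,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured stage; returns the per-modality result frames.

    Each stage writes its inputs (simulated CSVs + ground-truth sidecars)
    and outputs under the run directory before the next stage starts; a
    stage failure raises StageError and leaves earlier outputs in place.
    The fully-resolved config is written beside the outputs.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    eqio.write_json(cfg.to_dict(), out / "run_config.json")
    seeds = modality_seeds(cfg.seed)
    results: dict[str, pd.DataFrame] = {}
    for name in MODALITY_ORDER:
        if name not in cfg.modalities:
            continue
        log.info("stage %s: start", name)
        try:
            results[name] = STAGES[name](cfg, seeds[name], out)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(name, str(exc)) from exc
        log.info("stage %s: done", name)
    try:
        _stage_report(cfg, out, results)
    except Exception as exc:  # noqa: BLE001
        raise StageError("report", str(exc)) from exc
    return results
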