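"""CSV/JSON readers and writers for every modality.

Trace CSVs use a long format (recording_id, channel, time_s, value, masked);
fusion-spot CSVs are wide per frame (cell_id, spot_id, spot_kind, time_s,
f_ph, f_655, f_ffn, size_nm); EM data are two typed tables (vesicles and
profiles).  Ground truth travels in a JSON sidecar.  Floats are written with
a fixed format so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .capacitance import CmKinetics, CmRecording
from .em import EMProfileTable
from .errors import InvalidConfigError
from .fusion import CellFusionSummary, FusionEvent, SpotTrace
from .protocols import get_protocol
from .syph import SypHExperiment

FLOAT_FORMAT = "%.9g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# capacitance traces (long format)


def cm_recordings_to_frame(recs: Iterable[CmRecording]) -> pd.DataFrame:
    rows = []
    for rec in recs:
        for channel, values in (("cm_fF", rec.cm_fF), ("ica_pA", rec.ica_pA)):
            if values is None:
                continue
            rows.append(pd.DataFrame({
                "recording_id": rec.cell_id,
                "condition": rec.condition,
                "protocol": rec.protocol.name,
                "stim_onset_s": rec.protocol.onset_s,
                "channel": channel,
                "time_s": rec.time_s,
                "value": values,
                "masked": rec.artifact_mask if channel == "cm_fF" else False,
            }))
    return pd.concat(rows, ignore_index=True)


def write_cm_csv(recs: Iterable[CmRecording], path) -> None:
    _write_csv(cm_recordings_to_frame(recs), Path(path))


def read_cm_csv(path) -> list[CmRecording]:
    df = pd.read_csv(path)
    recs = []
    for rid, g in df.groupby("recording_id", sort=False):
        cm = g[g["channel"] == "cm_fF"].sort_values("time_s")
        if cm.empty:
            raise InvalidConfigError(f"recording {rid!r} has no cm_fF channel")
        ica = g[g["channel"] == "ica_pA"].sort_values("time_s")
        protocol = get_protocol(str(cm["protocol"].iloc[0]),
                                onset_s=float(cm["stim_onset_s"].iloc[0]))
        recs.append(CmRecording(
            time_s=cm["time_s"].to_numpy(),
            cm_fF=cm["value"].to_numpy(),
            artifact_mask=cm["masked"].to_numpy(dtype=bool),
            protocol=protocol,
            ica_pA=ica["value"].to_numpy() if len(ica) else None,
            cell_id=str(rid),
            condition=str(cm["condition"].iloc[0]),
        ))
    return recs


def cm_kinetics_to_frame(kins: Iterable[CmKinetics]) -> pd.DataFrame:
    rows = []
    for k in kins:
        rows.append({
            "cell_id": k.cell_id, "condition": k.condition, "protocol": k.protocol,
            "delta_cm_peak_fF": k.delta_cm_peak_fF, "fit_model": k.fit.model,
            "tau_s": k.fit.tau_s, "tau1_s": k.fit.tau1_s, "tau2_s": k.fit.tau2_s,
            "weight1": k.fit.weight1,
            "rate_decay_fF_per_s": k.rate_decay_fF_per_s,
            "rate_decay_n_per_s": k.rate_decay_n_per_s,
            "total_decay_fraction": k.total_decay_fraction,
            "first_second_retrieval": k.first_second_retrieval,
            "mode": k.mode,
            "ica_peak_pA": k.ica.peak_pA, "ica_bin": k.ica.bin,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SypH traces


def syph_to_frame(exps: Iterable[SypHExperiment]) -> pd.DataFrame:
    rows = []
    for exp in exps:
        for b in range(exp.n_boutons):
            rows.append(pd.DataFrame({
                "experiment_id": exp.experiment_id,
                "condition": exp.condition,
                "bouton_id": f"{exp.experiment_id}_b{b:03d}",
                "stim_onset_s": exp.stim_onset_s,
                "stim_end_s": exp.stim_end_s,
                "time_s": exp.time_s,
                "f_percent": exp.bouton_f[b],
            }))
    return pd.concat(rows, ignore_index=True)


def write_syph_csv(exps: Iterable[SypHExperiment], path) -> None:
    _write_csv(syph_to_frame(exps), Path(path))


def read_syph_csv(path) -> list[SypHExperiment]:
    df = pd.read_csv(path)
    exps = []
    for eid, g in df.groupby("experiment_id", sort=False):
        boutons = []
        time = None
        for _, gb in g.groupby("bouton_id", sort=False):
            gb = gb.sort_values("time_s")
            time = gb["time_s"].to_numpy()
            boutons.append(gb["f_percent"].to_numpy())
        exps.append(SypHExperiment(
            time_s=time, bouton_f=np.vstack(boutons),
            stim_onset_s=float(g["stim_onset_s"].iloc[0]),
            stim_end_s=float(g["stim_end_s"].iloc[0]),
            experiment_id=str(eid), condition=str(g["condition"].iloc[0]),
        ))
    return exps


# ---------------------------------------------------------------------------
# fusion spots (wide per-frame format)


def spots_to_frame(traces: Iterable[SpotTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "cell_id": tr.cell_id, "spot_id": tr.spot_id,
            "spot_kind": tr.spot_kind, "time_s": tr.time_s,
            "f_ph": tr.f_ph, "f_655": tr.f_655,
            "f_ffn": tr.f_ffn if tr.f_ffn is not None else np.nan,
            "size_nm": tr.size_nm if tr.size_nm is not None else np.nan,
        }))
    return pd.concat(rows, ignore_index=True)


def write_spots_csv(traces: Iterable[SpotTrace], path) -> None:
    _write_csv(spots_to_frame(traces), Path(path))


def read_spots_csv(path) -> list[SpotTrace]:
    df = pd.read_csv(path)
    traces = []
    for (cell, spot), g in df.groupby(["cell_id", "spot_id"], sort=False):
        g = g.sort_values("time_s")
        ffn = g["f_ffn"].to_numpy()
        size = g["size_nm"].to_numpy()
        traces.append(SpotTrace(
            spot_id=str(spot), cell_id=str(cell),
            time_s=g["time_s"].to_numpy(),
            f_ph=g["f_ph"].to_numpy(), f_655=g["f_655"].to_numpy(),
            f_ffn=None if np.all(np.isnan(ffn)) else ffn,
            size_nm=None if np.all(np.isnan(size)) else size,
            spot_kind=str(g["spot_kind"].iloc[0]),
        ))
    return traces


def fusion_events_to_frame(events: Iterable[FusionEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": e.cell_id, "spot_id": e.spot_id, "onset_s": e.onset_s,
        "mode": e.mode, "closure_time_s": e.closure_time_s,
        "t_ffn_s": e.t_ffn_s, "t_ffn_censored": e.t_ffn_censored,
        "censored": e.censored,
    } for e in events])


def cell_summaries_to_frame(cells: Iterable[CellFusionSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": c.cell_id, "n_fusion_events": c.n_fusion_events,
        "n_close": c.n_close, "n_stay": c.n_stay, "n_shrink": c.n_shrink,
        "n_ambiguous": c.n_ambiguous, "prob_close_fusion": c.prob_close_fusion,
        "n_pre_spots": c.n_pre_spots, "n_pre_closed": c.n_pre_closed,
        "prob_pre_close": c.prob_pre_close, "mean_t_ffn_s": c.mean_t_ffn_s,
        "excluded": c.excluded,
    } for c in cells])


# ---------------------------------------------------------------------------
# EM tables


def write_em_csv(table: EMProfileTable, vesicles_path, profiles_path) -> None:
    _write_csv(table.vesicles, Path(vesicles_path))
    _write_csv(table.profiles, Path(profiles_path))


def read_em_csv(vesicles_path, profiles_path) -> EMProfileTable:
    return EMProfileTable(
        vesicles=pd.read_csv(vesicles_path),
        profiles=pd.read_csv(profiles_path),
    )


def concat_em_tables(tables: Iterable[EMProfileTable]) -> EMProfileTable:
    tables = list(tables)
    return EMProfileTable(
        vesicles=pd.concat([t.vesicles for t in tables], ignore_index=True),
        profiles=pd.concat([t.profiles for t in tables], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# JSON sidecars


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
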