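"""Pipeline orchestration: simulate -> behavior -> photometry -> report.

Each stage reads only the file dialects, writes delimited tables (and
figures in the report stage), and logs exclusions.  A full run is a pure
function of (config, seed): rerunning with the same config reproduces
every numeric output bit-for-bit, which the manifest's config hash lets a
caller assert.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import ContactIntervals, merge_contacts, session_summary
from .config import RunConfig
from .io import (
    FLOAT_FMT,
    read_events_table,
    read_manifest,
    read_photometry,
    write_manifest,
)
from .photometry import (
    EventList,
    align_events,
    animal_mean_trace,
    area_under_curve,
    build_heatmap,
    detrend_isosbestic,
    extract_peri_event,
    qc_session,
    zscore_peri_event,
)
from .stats import permutation_group_test, summarize_group_time
from .synthetic import TASK_STIMULI, default_profiles, generate_cohort

log = logging.getLogger(__name__)

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_behavior",
    "stage_photometry",
    "stage_report",
    "StageError",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return str(path)


def stage_simulate(config: RunConfig) -> dict:
    try:
        return generate_cohort(
            profiles=default_profiles(),
            n_per_genotype=config.n_per_genotype,
            config=config.sim,
            out_dir=config.input_dir,
            tasks=config.tasks,
            conditions=config.conditions,
            force=True,
        )
    except Exception as e:  # noqa: BLE001 - stage-tag every failure
        raise StageError("simulate", str(e)) from e


def stage_behavior(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-session behavioral summaries from the events tables.

    Returns (sessions, minutes): one row per session with totals, and the
    long-format per-minute table (investigation time per stimulus and the
    preference score).
    """
    in_dir = Path(config.input_dir)
    if not in_dir.exists():
        raise StageError("behavior", f"input dir {in_dir} does not exist")
    meta = pd.read_csv(in_dir / "metadata.csv", dtype={"animal_id": str})
    sess_rows, min_rows = [], []
    for ev_file in sorted((in_dir / "events").glob("*.csv")):
        try:
            sessions = read_events_table(ev_file)
        except Exception as e:
            raise StageError("behavior", str(e)) from e
        for (animal, session_id, task, cond), contacts in sessions.items():
            stims = TASK_STIMULI[task]
            for s in stims:  # sessions where a stimulus was never contacted
                contacts.setdefault(s, ContactIntervals(s, np.empty((0, 2))))
            rec = session_summary(
                contacts,
                session_len=config.sim.session_len,
                max_gap=config.merge_gap_s,
                bin_s=config.bin_s,
            )
            g = meta.loc[meta.session_id == session_id, "genotype"]
            genotype = g.iloc[0] if len(g) else ""
            a, b = rec["stimuli"]
            row = {
                "animal_id": animal, "session_id": session_id, "task": task,
                "condition": cond, "genotype": genotype,
                "n_transitions": rec["n_transitions"],
            }
            for s in (a, b):
                cat = rec[s]["categories"]
                row.update({
                    f"{s}_time_s": rec[s]["total_time_s"],
                    f"{s}_contact_s": rec[s]["contact_time_s"],
                    f"{s}_n_bouts": rec[s]["n_bouts"],
                    **{f"{s}_{c}_count": cat[c]["count"] for c in cat},
                    **{f"{s}_{c}_time_s": cat[c]["time_s"] for c in cat},
                })
            sess_rows.append(row)
            for m in range(len(rec["preference"])):
                min_rows.append({
                    "animal_id": animal, "session_id": session_id, "task": task,
                    "condition": cond, "genotype": genotype, "minute": m + 1,
                    f"{a}_time_s": rec[a]["minute_time_s"][m],
                    f"{b}_time_s": rec[b]["minute_time_s"][m],
                    "preference_s": rec["preference"][m],
                    "transitions": rec["transition_rate"][m],
                })
    sessions_df = pd.DataFrame(sess_rows).sort_values("session_id").reset_index(drop=True)
    minutes_df = pd.DataFrame(min_rows).sort_values(["session_id", "minute"]).reset_index(drop=True)
    return sessions_df, minutes_df


def stage_photometry(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Detrend, align, z-score and summarize every session's photometry.

    Returns (auc table, qc table, heatmaps keyed by (task, condition,
    stimulus)).  Event onsets are merged-bout onsets mapped onto the
    photometry clock with the session's recorded offset.
    """
    in_dir = Path(config.input_dir)
    if not in_dir.exists():
        raise StageError("photometry", f"input dir {in_dir} does not exist")
    meta = pd.read_csv(in_dir / "metadata.csv", dtype={"animal_id": str})
    auc_rows, qc_rows, responses = [], [], []
    trace_rows = []
    for _, m in meta.iterrows():
        sid = m.session_id
        try:
            trace = read_photometry(in_dir / "photometry" / f"{sid}.csv")
            trace = detrend_isosbestic(trace)
            qc = qc_session(trace, stimulus_intro_time=m.get("clock_offset", 0.0),
                            drift_thresh=config.qc_drift_thresh,
                            snr_thresh=config.qc_snr_thresh)
            qc_rows.append({"session_id": sid, **qc})
            if config.apply_qc_exclusion and qc["pass"] is False:
                log.info("QC excluded session %s", sid)
                continue
            contacts = read_events_table(in_dir / "events" / f"{sid}.csv")
            if not contacts:
                continue
            (_, per_stim), = contacts.items()
            bouts = [b for s in per_stim for b in merge_contacts(per_stim[s], config.merge_gap_s)]
            bouts.sort(key=lambda b: b.start)
            if not bouts:
                continue
            events = EventList(
                onsets=np.array([b.start for b in bouts]),
                offsets=np.array([b.end for b in bouts]),
                labels=np.array([b.stimulus for b in bouts], dtype=object),
            )
            events = align_events(events, trace,
                                  clock_offset=m.get("clock_offset", 0.0))
            mat = extract_peri_event(
                trace, events, config.peri_window, config.peri_bin_s,
                exclude_cross_stimulus=config.exclude_cross_stimulus_overlap,
            )
            mat = zscore_peri_event(mat)
            if config.exclude_overlapping_baselines:
                mat = dataclasses.replace(mat, kept=mat.kept & ~mat.baseline_overlap)
            for stim, resp in animal_mean_trace(
                mat, animal_id=m.animal_id, genotype=m.genotype
            ).items():
                auc = area_under_curve(resp, config.auc_interval)
                auc_rows.append({
                    "animal_id": m.animal_id, "session_id": sid, "task": m.task,
                    "condition": m.condition, "genotype": m.genotype,
                    "stimulus": stim, "n_events": resp.n_events, "auc": auc,
                    "n_excluded_window": mat.n_excluded_window,
                    "n_dropped_align": events.n_dropped,
                })
                responses.append((m.task, m.condition, resp))
                trace_rows.extend(
                    {"session_id": sid, "task": m.task, "condition": m.condition,
                     "genotype": m.genotype, "animal_id": m.animal_id,
                     "stimulus": stim, "t": c, "zdff": v}
                    for c, v in zip(resp.centers, resp.mean_trace)
                )
        except StageError:
            raise
        except Exception as e:
            raise StageError("photometry", f"session {sid}: {e}") from e
    heatmaps = {}
    for (task, cond) in sorted({(t, c) for t, c, _ in responses}):
        for stim in TASK_STIMULI[task]:
            sel = [r for t, c, r in responses
                   if t == task and c == cond and r.stimulus == stim]
            if sel:
                heatmaps[(task, cond, stim)] = build_heatmap(sel)
    auc_df = pd.DataFrame(auc_rows).sort_values(["session_id", "stimulus"]).reset_index(drop=True)
    qc_df = pd.DataFrame(qc_rows).sort_values("session_id").reset_index(drop=True)
    traces_df = pd.DataFrame(trace_rows)
    return auc_df, qc_df, {"heatmaps": heatmaps, "traces": traces_df}


def stage_report(config: RunConfig, sessions: pd.DataFrame, minutes: pd.DataFrame,
                 auc: pd.DataFrame, out_dir: Path) -> list[dict]:
    """Group summaries and permutation tests, plus figures."""
    from . import plots

    files = []
    rows = []
    for task in config.tasks:
        for cond in config.conditions:
            a, b = TASK_STIMULI[task]
            sel_min = minutes[(minutes.task == task) & (minutes.condition == cond)]
            sel_auc = auc[(auc.task == task) & (auc.condition == cond)] if len(auc) else auc
            for minute, grp in sel_min.groupby("minute"):
                by_g = {g: d["preference_s"].to_numpy() for g, d in grp.groupby("genotype")}
                if len(by_g) >= 2 and all(v.size >= 2 for v in by_g.values()):
                    r = permutation_group_test(by_g, config.n_perm, seed=config.seed)
                    rows.append({"task": task, "condition": cond,
                                 "metric": "preference_s", "bin": minute,
                                 "statistic": r.statistic, "p": r.p_value,
                                 "n_perm": r.n_perm, "effect": r.effect_size})
            for stim in (a, b):
                if len(sel_auc):
                    by_g = {g: d["auc"].to_numpy()
                            for g, d in sel_auc[sel_auc.stimulus == stim].groupby("genotype")}
                    by_g = {g: v for g, v in by_g.items() if v.size >= 2}
                    if len(by_g) >= 2:
                        r = permutation_group_test(by_g, config.n_perm, seed=config.seed)
                        rows.append({"task": task, "condition": cond,
                                     "metric": f"auc_{stim}", "bin": "total",
                                     "statistic": r.statistic, "p": r.p_value,
                                     "n_perm": r.n_perm, "effect": r.effect_size})
    tests_df = pd.DataFrame(rows)
    files.append({"path": _write(tests_df, out_dir / "report_tests.csv"), "role": "report"})

    # long-format cohort table + group mean/SEM summaries
    long = minutes.melt(
        id_vars=["animal_id", "genotype", "task", "condition", "minute"],
        value_vars=["preference_s"], var_name="metric", value_name="value",
    ).rename(columns={"minute": "bin"})
    summaries = []
    for task in config.tasks:
        for cond in config.conditions:
            try:
                s = summarize_group_time(long, "preference_s", task, cond)
            except ValueError:
                continue
            s.insert(0, "condition", cond)
            s.insert(0, "task", task)
            summaries.append(s)
    if summaries:
        files.append({
            "path": _write(pd.concat(summaries, ignore_index=True),
                           out_dir / "report_group_preference.csv"),
            "role": "report",
        })
    for name, fig_path in plots.render_all(config, minutes, auc, out_dir):
        files.append({"path": str(fig_path), "role": "figure"})
    return files


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write the run manifest.

    Any stage failure aborts with a stage-tagged error and, if outputs were
    already produced, marks the manifest invalid.  Numeric outputs are
    deterministic under a fixed config and seed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[dict] = []

    cohort_manifest = stage_simulate(config)
    files.append({"path": str(Path(config.input_dir) / "manifest.json"),
                  "role": "cohort_manifest", "seed": config.sim.seed})

    try:
        sessions, minutes = stage_behavior(config)
    except StageError:
        raise
    files.append({"path": _write(sessions, out_dir / "behavior_sessions.csv"),
                  "role": "behavior"})
    files.append({"path": _write(minutes, out_dir / "behavior_minutes.csv"),
                  "role": "behavior"})

    auc, qc, extras = stage_photometry(config)
    files.append({"path": _write(auc, out_dir / "photometry_auc.csv"),
                  "role": "photometry"})
    files.append({"path": _write(qc, out_dir / "photometry_qc.csv"),
                  "role": "photometry"})
    if len(extras["traces"]):
        files.append({"path": _write(extras["traces"], out_dir / "photometry_traces.csv"),
                      "role": "photometry"})
    from . import plots

    bin_centers = (np.arange(
        int(round((config.peri_window[1] - config.peri_window[0]) / config.peri_bin_s))
    ) + 0.5) * config.peri_bin_s + config.peri_window[0]
    for (task, cond, stim), (mat, meta) in extras["heatmaps"].items():
        hm = pd.DataFrame(mat)
        hm.insert(0, "animal_id", [r["animal_id"] for r in meta])
        hm.insert(1, "genotype", [r["genotype"] for r in meta])
        tag = f"{task}_{cond.replace('+', '-')}_{stim}"
        files.append({"path": _write(hm, out_dir / f"heatmap_{tag}.csv"),
                      "role": "heatmap"})
        fig_path = out_dir / f"fig_heatmap_{tag}.png"
        plots.heatmap_figure(mat, bin_centers, fig_path, title=f"{task} / {stim}")
        files.append({"path": str(fig_path), "role": "figure"})

    try:
        files += stage_report(config, sessions, minutes, auc, out_dir)
    except StageError:
        raise
    except Exception as e:
        raise StageError("report", str(e)) from e

    import time

    return write_manifest(
        out_dir / "manifest.json", files, config.to_dict(), __version__,
        extra={"created": time.strftime("%Y-%m-%dT%H:%M:%S"),
               "cohort_config_hash": cohort_manifest["config_hash"]},
    )
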