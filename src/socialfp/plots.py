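"""Report figures: investigation curves, preference bars, peri-event traces, heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .synthetic import TASK_STIMULI

GENOTYPE_COLORS = {"WT": "#1f77b4", "HET": "#ff7f0e", "KO": "#d62728"}


def minute_curves(minutes: pd.DataFrame, task: str, cond: str, path) -> None:
    """Per-minute group-mean investigation time (± SEM) for both stimuli."""
    a, b = TASK_STIMULI[task]
    sel = minutes[(minutes.task == task) & (minutes.condition == cond)]
    genos = [g for g in ("WT", "HET", "KO") if g in set(sel.genotype)]
    fig, axes = plt.subplots(1, max(len(genos), 1), figsize=(3.2 * max(len(genos), 1), 3),
                             sharey=True, squeeze=False)
    for ax, g in zip(axes[0], genos):
        d = sel[sel.genotype == g]
        for stim, style in ((a, "-o"), (b, "--s")):
            grp = d.groupby("minute")[f"{stim}_time_s"]
            m, sem = grp.mean(), grp.sem()
            ax.errorbar(m.index, m, yerr=sem, fmt=style, label=stim, capsize=2)
        ax.set_title(g)
        ax.set_xlabel("minute")
    axes[0][0].set_ylabel("investigation time (s)")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.suptitle(f"{task} / {cond}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def preference_bars(minutes: pd.DataFrame, task: str, cond: str, path) -> None:
    sel = minutes[(minutes.task == task) & (minutes.condition == cond)]
    fig, ax = plt.subplots(figsize=(4.5, 3))
    genos = [g for g in ("WT", "HET", "KO") if g in set(sel.genotype)]
    width = 0.8 / max(len(genos), 1)
    for i, g in enumerate(genos):
        d = sel[sel.genotype == g].groupby("minute")["preference_s"]
        ax.bar(d.mean().index + (i - (len(genos) - 1) / 2) * width, d.mean(),
               width=width, yerr=d.sem(), capsize=2, label=g,
               color=GENOTYPE_COLORS.get(g))
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("minute")
    ax.set_ylabel("preference (s)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def peri_event_traces(traces: pd.DataFrame, task: str, cond: str, stim: str, path) -> None:
    """Group-mean ± SEM event-aligned zdF/F."""
    sel = traces[(traces.task == task) & (traces.condition == cond)
                 & (traces.stimulus == stim)]
    fig, ax = plt.subplots(figsize=(4.5, 3))
    for g, d in sel.groupby("genotype"):
        per_animal = d.pivot_table(index="animal_id", columns="t", values="zdff")
        t = per_animal.columns.to_numpy(dtype=float)
        m = per_animal.mean(axis=0).to_numpy()
        sem = per_animal.sem(axis=0).to_numpy()
        ax.plot(t, m, label=f"{g} (n={len(per_animal)})", color=GENOTYPE_COLORS.get(g))
        ax.fill_between(t, m - sem, m + sem, alpha=0.25, color=GENOTYPE_COLORS.get(g))
    ax.axvline(0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("time from bout onset (s)")
    ax.set_ylabel("zdF/F")
    ax.set_title(f"{task} / {stim}", fontsize=9)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def heatmap_figure(mat: np.ndarray, centers: np.ndarray, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 0.25 * max(mat.shape[0], 4) + 1.2))
    im = ax.imshow(mat, aspect="auto", cmap="viridis",
                   extent=[centers[0], centers[-1], mat.shape[0], 0])
    ax.set_xlabel("time from bout onset (s)")
    ax.set_ylabel("animal")
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="zdF/F")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_all(config, minutes: pd.DataFrame, auc: pd.DataFrame, out_dir):
    """Render the standard report figures; returns (name, path) pairs."""
    out_dir = Path(out_dir)
    done = []
    traces_path = out_dir / "photometry_traces.csv"
    traces = pd.read_csv(traces_path) if traces_path.exists() else pd.DataFrame()
    for task in config.tasks:
        for cond in config.conditions:
            tag = f"{task}_{cond.replace('+', '-')}"
            if len(minutes):
                p = out_dir / f"fig_minutes_{tag}.png"
                minute_curves(minutes, task, cond, p)
                done.append(("minutes", p))
                p = out_dir / f"fig_preference_{tag}.png"
                preference_bars(minutes, task, cond, p)
                done.append(("preference", p))
            if len(traces):
                for stim in TASK_STIMULI[task]:
                    p = out_dir / f"fig_peri_{tag}_{stim}.png"
                    peri_event_traces(traces, task, cond, stim, p)
                    done.append(("peri", p))
    return done
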