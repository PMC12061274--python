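"""In-memory simulation-study helpers shared by the acceptance checks.

These run the package's own analysis path (simulate -> detrend -> align ->
peri-event -> z-score -> AUC) without touching disk, so that cohort-scale
recovery studies stay fast.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from socialfp import (
    EventList,
    PhotometryTrace,
    SimConfig,
    align_events,
    animal_mean_trace,
    area_under_curve,
    detrend_isosbestic,
    extract_peri_event,
    merge_contacts,
    simulate_session,
    zscore_peri_event,
)


def analyze_session_aucs(profile, cfg: SimConfig, stimuli=("social", "empty")):
    """Simulate one animal-session and return its per-stimulus z-AUC."""
    contacts, (t, s465, s405), truth = simulate_session(profile, cfg, stimuli)
    trace = PhotometryTrace(t=t, s465=s465, s405=s405, fs=cfg.fs_photo)
    trace = detrend_isosbestic(trace)
    bouts = [b for s in stimuli for b in merge_contacts(contacts[s])]
    bouts.sort(key=lambda b: b.start)
    if not bouts:
        return {}, truth
    events = EventList(
        onsets=np.array([b.start for b in bouts]),
        offsets=np.array([b.end for b in bouts]),
        labels=np.array([b.stimulus for b in bouts], dtype=object),
    )
    events = align_events(events, trace, clock_offset=cfg.clock_offset)
    mat = zscore_peri_event(extract_peri_event(trace, events))
    return {
        stim: area_under_curve(resp)
        for stim, resp in animal_mean_trace(mat).items()
    }, truth


def cohort_aucs(profiles, n_per_genotype: int, base_seed: int,
                stimuli=("social", "food"), **cfg_overrides):
    """Per-genotype arrays of animal social/food z-AUCs for one cohort."""
    out = {g: {s: [] for s in stimuli} for g in profiles}
    for gi, (g, prof) in enumerate(sorted(profiles.items())):
        for i in range(n_per_genotype):
            cfg = SimConfig(seed=base_seed + 97 * gi + i, **cfg_overrides)
            aucs, _ = analyze_session_aucs(prof, cfg, stimuli)
            for s in stimuli:
                if s in aucs:
                    out[g][s].append(aucs[s])
    return {
        g: {s: np.asarray(v) for s, v in d.items()} for g, d in out.items()
    }


def zeroed_amplitude_profile(profile):
    """Genotype profile with every transient amplitude exactly 0 (no
    between-animal amplitude variation either)."""
    return dataclasses.replace(
        profile,
        transient_amp={s: 0.0 for s in profile.transient_amp},
        transient_amp_sd=0.0,
    )
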