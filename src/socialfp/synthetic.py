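"""Synthetic two-stimulus sessions with recorded ground truth.

Generates cohorts whose statistical structure matches what the analysis
assumes about the real task:

* **Behavior** — an alternating-renewal bout process.  Bout onsets are drawn
  per minute at a genotype- and stimulus-specific realized rate, bout
  lengths from a log-normal, and the two stimuli never overlap (the animal
  is at one compartment at a time).  Wild-type-like profiles habituate
  (high social rate in minute 1, low thereafter); knockout-like profiles
  sustain high investigation for all five minutes.
* **Photometry** — a two-channel fluorescence trace.  The 465 nm signal
  carries an exponentially bleaching baseline, a shared low-frequency
  motion artifact, event-locked calcium transients (double-exponential
  kernel, peak-normalized) whose amplitude depends on genotype and
  stimulus, and white noise.  The 405 nm isosbestic control carries the
  same bleach and motion (scaled) but no transients, so regressing it onto
  the signal channel removes both nuisance terms.

Every random draw flows from a single seed via ``numpy`` ``SeedSequence``
spawning, so a cohort is a pure function of (profiles, config, seed).  The
generator writes a ground-truth table (realized per-bout amplitudes, bout
schedules, per-session seeds) that the analysis stages never read; recovery
tests compare analysis output against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .behavior import ContactIntervals

__all__ = [
    "GenotypeProfile",
    "SimConfig",
    "SyntheticGroundTruth",
    "default_profiles",
    "transient_kernel",
    "simulate_behavior_session",
    "simulate_photometry_trace",
    "simulate_session",
    "TASK_STIMULI",
]

#: stimulus pair presented in each task
TASK_STIMULI = {
    "social_vs_empty": ("social", "empty"),
    "object_vs_empty": ("object", "empty"),
    "social_vs_food": ("social", "food"),
    "object_vs_food": ("object", "food"),
}

GENOTYPES = ("WT", "HET", "KO")


@dataclass(frozen=True)
class GenotypeProfile:
    """Hidden behavioral and neural parameters of one genotype.

    Parameters
    ----------
    label
        Genotype tag, one of ``WT | HET | KO``.
    bout_rate_per_min
        Per stimulus, a 5-vector of expected (realized) bout-initiation
        rates, events/min, one entry per minute of the 5-min session.
    bout_mean_dur
        Per stimulus, mean bout duration in seconds (log-normal mean).
    transient_amp
        Per stimulus, event-locked transient amplitude in peak dF/F units.
    transient_amp_sd
        Between-animal s.d. of the amplitude (truncated at zero).
    """

    label: str
    bout_rate_per_min: dict[str, np.ndarray]
    bout_mean_dur: dict[str, float]
    transient_amp: dict[str, float]
    transient_amp_sd: float = 0.3

    def __post_init__(self):
        rates = {
            s: np.asarray(r, dtype=float) for s, r in self.bout_rate_per_min.items()
        }
        object.__setattr__(self, "bout_rate_per_min", rates)
        for s, r in rates.items():
            if np.any(r < 0) or not np.all(np.isfinite(r)):
                raise ValueError(f"{self.label}/{s}: rates must be finite and >= 0")
        for s, d in self.bout_mean_dur.items():
            if not d > 0:
                raise ValueError(f"{self.label}/{s}: mean duration must be positive")
        for s, a in self.transient_amp.items():
            if a < 0 or not np.isfinite(a):
                raise ValueError(f"{self.label}/{s}: amplitude must be finite and >= 0")

    def restrict(self, stimuli: tuple[str, ...]) -> "GenotypeProfile":
        """Profile narrowed to the stimuli actually presented in a task."""
        return GenotypeProfile(
            self.label,
            {s: self.bout_rate_per_min[s] for s in stimuli},
            {s: self.bout_mean_dur[s] for s in stimuli},
            {s: self.transient_amp.get(s, 0.0) for s in stimuli},
            self.transient_amp_sd,
        )


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    Times are seconds; rates Hz.  ``session_len`` must divide into 60 s
    bins.  ``pre_s`` seconds of stimulus-free recording precede t = 0 on
    the photometry clock (baseline-stability QC needs >= 60 s).
    ``clock_offset`` shifts the photometry clock relative to the behavioral
    clock to exercise event alignment.
    """

    seed: int = 0
    session_len: float = 300.0
    fs_video: float = 15.0
    fs_photo: float = 100.0
    pre_s: float = 60.0
    baseline_465: float = 100.0
    ctrl_gain: float = 0.8          # 405-channel gain on the shared terms
    bleach_tau: float = 1800.0
    motion_sd: float = 2.0          # a.u., shared across channels
    motion_cutoff_hz: float = 1.0   # low-pass corner of the motion process
    noise_sd: float = 1.0           # a.u., per channel, white
    kernel_rise: float = 0.2
    kernel_decay: float = 1.0
    lognorm_sigma: float = 0.5      # bout-duration log-normal shape
    refractory_s: float = 0.6       # dead time after each bout
    clock_offset: float = 0.0

    def __post_init__(self):
        if self.fs_video <= 0 or self.fs_photo <= 0 or self.session_len <= 0:
            raise ValueError("sampling rates and session length must be positive")
        if not (self.kernel_decay > self.kernel_rise > 0):
            raise ValueError("require kernel_decay > kernel_rise > 0")
        if self.session_len % 60.0 != 0.0:
            raise ValueError("session_len must divide into 60 s bins")
        for name in ("baseline_465", "bleach_tau"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("motion_sd", "noise_sd"):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass
class SyntheticGroundTruth:
    """Hidden parameters realized for one session, never read by analysis."""

    seed: int
    bouts: list[dict] = field(default_factory=list)   # stimulus, start, end, amp
    amp_by_stimulus: dict[str, float] = field(default_factory=dict)


def default_profiles() -> dict[str, GenotypeProfile]:
    """Genotype defaults encoding the study's qualitative structure.

    WT: strong social investigation in minute 1 that collapses to the
    empty-compartment level from minute 2 on (within-session habituation);
    social transient amplitude 2.0.  HET: partial habituation, amplitude
    0.5.  KO: sustained high social investigation, amplitude 0.0.  Food
    responses (amplitude 1.0) do not differ by genotype.
    """
    return {
        "WT": GenotypeProfile(
            "WT",
            bout_rate_per_min={
                "social": [6.0, 1.5, 1.5, 1.5, 1.5],
                "empty": [1.5] * 5,
                "object": [5.0, 1.5, 1.0, 1.0, 1.0],
                "food": [2.5] * 5,
            },
            bout_mean_dur={"social": 8.0, "empty": 8.0, "object": 6.0, "food": 4.0},
            transient_amp={"social": 2.0, "empty": 0.0, "object": 0.5, "food": 1.0},
        ),
        "HET": GenotypeProfile(
            "HET",
            bout_rate_per_min={
                "social": [5.0, 4.0, 3.5, 3.0, 3.0],
                "empty": [1.0] * 5,
                "object": [5.0, 1.5, 1.0, 1.0, 1.0],
                "food": [2.5] * 5,
            },
            bout_mean_dur={"social": 8.0, "empty": 4.0, "object": 6.0, "food": 4.0},
            transient_amp={"social": 0.5, "empty": 0.0, "object": 0.5, "food": 1.0},
        ),
        "KO": GenotypeProfile(
            "KO",
            bout_rate_per_min={
                "social": [5.0] * 5,
                "empty": [1.0] * 5,
                "object": [5.0, 4.0, 4.0, 4.0, 4.0],
                "food": [2.5] * 5,
            },
            bout_mean_dur={"social": 9.0, "empty": 3.0, "object": 6.0, "food": 4.0},
            transient_amp={"social": 0.0, "empty": 0.0, "object": 0.5, "food": 1.0},
        ),
    }


def transient_kernel(config: SimConfig, t: np.ndarray) -> np.ndarray:
    """Peak-normalized difference-of-exponentials calcium kernel.

    ``K(t) = (exp(-t/decay) - exp(-t/rise)) / K_max`` for t >= 0, else 0.
    The analytic peak sits at ``t* = ln(decay/rise) * rise*decay /
    (decay - rise)``.
    """
    r, d = config.kernel_rise, config.kernel_decay
    t_peak = np.log(d / r) * r * d / (d - r)
    peak = np.exp(-t_peak / d) - np.exp(-t_peak / r)
    k = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / d) - np.exp(-np.clip(t, 0, None) / r), 0.0)
    return k / peak


def _feasibility(profile: GenotypeProfile, config: SimConfig) -> np.ndarray:
    """Expected free-time fraction per minute; raises if the schedule is infeasible."""
    n_min = int(config.session_len // 60)
    occ = np.zeros(n_min)
    busy = np.zeros(n_min)
    for s, rates in profile.bout_rate_per_min.items():
        if len(rates) != n_min:
            raise ValueError(f"{s}: need one rate per minute ({n_min})")
        d = profile.bout_mean_dur[s]
        if np.any(rates * d > 60.0):
            raise ValueError(
                f"{profile.label}/{s}: rate x mean duration exceeds 60 s occupancy per minute"
            )
        occ += rates * d
        busy += rates * (d + config.refractory_s)
    if np.any(occ > 60.0):
        raise ValueError(f"{profile.label}: total occupancy exceeds 60 s per minute")
    return np.clip(1.0 - busy / 60.0, 0.02, None)


def simulate_behavior_session(
    profile: GenotypeProfile,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, ContactIntervals], SyntheticGroundTruth]:
    """Draw one session's bout schedule for all stimuli in the profile.

    Candidate onsets are drawn per minute from a Poisson process at the
    profile rate divided by the expected free-time fraction; candidates
    arriving while the animal is occupied are discarded, so the *realized*
    bout rate approximates the profile rate and bouts never overlap across
    stimuli.  Durations are log-normal with the profile mean; a short
    refractory period separates consecutive bouts so that merged bouts
    coincide with generated bouts.  Output times are quantized to the video
    frame grid (1/fs_video).
    """
    free = _feasibility(profile, config)
    n_min = int(config.session_len // 60)
    fs = config.fs_video
    sigma = config.lognorm_sigma
    candidates: list[tuple[float, str]] = []
    for s, rates in profile.bout_rate_per_min.items():
        for m in range(n_min):
            lam = rates[m] / free[m]
            n = rng.poisson(lam)
            for onset in rng.uniform(60.0 * m, 60.0 * (m + 1), n):
                candidates.append((onset, s))
    candidates.sort()
    schedule: dict[str, list[tuple[float, float]]] = {
        s: [] for s in profile.bout_rate_per_min
    }
    truth = SyntheticGroundTruth(seed=config.seed)
    t_free = 0.0
    for onset, s in candidates:
        if onset < t_free:
            continue
        mu = np.log(profile.bout_mean_dur[s]) - sigma**2 / 2.0
        dur = rng.lognormal(mu, sigma)
        end = min(onset + dur, config.session_len)
        q0 = round(onset * fs) / fs
        q1 = round(end * fs) / fs
        if q1 <= q0:
            continue
        schedule[s].append((q0, q1))
        truth.bouts.append({"stimulus": s, "start": q0, "end": q1})
        t_free = end + config.refractory_s
    contacts = {
        s: ContactIntervals(s, np.asarray(iv, dtype=float).reshape(-1, 2))
        for s, iv in schedule.items()
    }
    return contacts, truth


def simulate_photometry_trace(
    bouts: list[dict],
    amp_by_stimulus: dict[str, float],
    config: SimConfig,
    rng: np.random.Generator,
):
    """Synthesize the two-channel trace for one session's bout schedule.

    465 nm: ``B * exp(-t/tau) * (1 + sum_i amp_i * K(t - onset_i)) +
    motion(t) + noise``; 405 nm: ``gain * (B * exp(-t/tau) + motion(t)) +
    independent noise``.  The motion artifact is a low-pass-filtered
    Gaussian process shared across channels, which is exactly the nuisance
    structure the isosbestic regression removes.  Transient amplitudes are
    peak dF/F units (the kernel is peak-normalized).

    Returns ``(t, s465, s405, realized)`` where ``realized`` lists each
    bout's amplitude.  Times run from ``-pre_s`` to ``session_len`` on the
    behavioral clock plus ``clock_offset``.
    """
    for s, a in amp_by_stimulus.items():
        if a < 0 or not np.isfinite(a):
            raise ValueError(f"{s}: transient amplitude must be finite and >= 0")
    for name in ("bleach_tau", "motion_sd", "noise_sd", "baseline_465"):
        if not np.isfinite(getattr(config, name)):
            raise ValueError(f"non-finite config value: {name}")
    fs = config.fs_photo
    n = int(round((config.session_len + config.pre_s) * fs))
    t = (np.arange(n) / fs) - config.pre_s + config.clock_offset
    t_behav = t - config.clock_offset
    bleach = config.baseline_465 * np.exp(-(t_behav + config.pre_s) / config.bleach_tau)

    # shared motion: white noise smoothed to the configured corner frequency
    if config.motion_sd > 0:
        sigma_samp = fs / (2.0 * np.pi * config.motion_cutoff_hz)
        m = gaussian_filter1d(rng.standard_normal(n), sigma_samp, mode="reflect")
        sd = m.std()
        motion = m * (config.motion_sd / sd) if sd > 0 else np.zeros(n)
    else:
        motion = np.zeros(n)

    transient = np.zeros(n)
    realized = []
    support = int(round((6.0 * config.kernel_decay + 1.0) * fs))
    for b in bouts:
        onset = b["start"]
        if not (0.0 <= onset < config.session_len):
            raise ValueError(f"bout onset {onset} outside [0, session_len)")
        amp = amp_by_stimulus.get(b["stimulus"], 0.0)
        realized.append({**b, "amp": amp})
        if amp == 0.0:
            continue
        i0 = int(np.ceil((onset + config.pre_s) * fs))
        i1 = min(i0 + support, n)
        tk = t_behav[i0:i1] - onset
        transient[i0:i1] += amp * transient_kernel(config, tk)

    s465 = bleach * (1.0 + transient) + motion
    s405 = config.ctrl_gain * (bleach + motion)
    if config.noise_sd > 0:
        s465 = s465 + rng.normal(0.0, config.noise_sd, n)
        s405 = s405 + rng.normal(0.0, config.noise_sd, n)
    np.clip(s465, 1e-6, None, out=s465)
    np.clip(s405, 1e-6, None, out=s405)
    return t, s465, s405, realized


def realized_amplitudes(
    profile: GenotypeProfile, stimuli: tuple[str, ...], rng: np.random.Generator
) -> dict[str, float]:
    """Per-animal transient amplitudes: normal around the profile mean, floored at 0."""
    return {
        s: float(max(0.0, rng.normal(profile.transient_amp.get(s, 0.0),
                                     profile.transient_amp_sd)))
        for s in stimuli
    }


def simulate_session(
    profile: GenotypeProfile,
    config: SimConfig,
    stimuli: tuple[str, ...] = ("social", "empty"),
):
    """One animal-session: behavior plus photometry, from ``config.seed``.

    Returns ``(contacts, trace_tuple, truth)`` where ``trace_tuple`` is
    ``(t, s465, s405)`` and ``truth`` records the bout schedule and the
    realized per-stimulus amplitudes.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_b, rng_a, rng_p = (np.random.default_rng(s) for s in ss.spawn(3))
    prof = profile.restrict(stimuli)
    contacts, truth = simulate_behavior_session(prof, config, rng_b)
    amps = realized_amplitudes(prof, stimuli, rng_a)
    t, s465, s405, realized = simulate_photometry_trace(
        truth.bouts, amps, config, rng_p
    )
    truth.amp_by_stimulus = amps
    truth.bouts = realized
    return contacts, (t, s465, s405), truth


def generate_cohort(
    profiles: dict[str, GenotypeProfile] | None = None,
    n_per_genotype: dict[str, int] | int | None = None,
    config: SimConfig = SimConfig(),
    out_dir=None,
    tasks: tuple[str, ...] = ("social_vs_empty",),
    conditions: tuple[str, ...] = ("satiety+none",),
    force: bool = False,
) -> dict:
    """Simulate a cohort and write it as an on-disk dataset.

    One session per animal per (task, condition).  Cohort sizes default to
    the photometry cohort of the study design (WT 10, HET 12, KO 9).  The
    dataset comprises per-session event tables and photometry traces, a
    metadata table, a ground-truth table (never read by analysis stages)
    and a manifest listing every file with its per-session seed.  Refuses
    to overwrite a non-empty output directory unless ``force``.
    """
    import dataclasses as _dc
    from pathlib import Path

    import pandas as pd

    from . import __version__
    from .io import write_events_table, write_manifest, write_photometry

    if profiles is None:
        profiles = default_profiles()
    if n_per_genotype is None:
        n_per_genotype = {"WT": 10, "HET": 12, "KO": 9}
    if isinstance(n_per_genotype, int):
        n_per_genotype = {g: n_per_genotype for g in profiles}
    if any(n < 1 for n in n_per_genotype.values()):
        raise ValueError("n_per_genotype must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    (out / "events").mkdir(parents=True, exist_ok=True)
    (out / "photometry").mkdir(exist_ok=True)

    sessions = [
        (g, i, task, cond)
        for g in sorted(n_per_genotype)
        for i in range(n_per_genotype[g])
        for task in tasks
        for cond in conditions
    ]
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(sessions))
    files, meta_rows, truth_rows = [], [], []
    for (g, i, task, cond), child in zip(sessions, children):
        animal = f"{g}{i + 1:02d}"
        session_id = f"{animal}_{task}_{cond}"
        seed = int(child.generate_state(1)[0] % (2**31))
        cfg = dataclasses.replace(config, seed=seed)
        stimuli = TASK_STIMULI[task]
        contacts, (t, s465, s405), truth = simulate_session(
            profiles[g], cfg, stimuli
        )
        ev = pd.DataFrame(
            [
                {
                    "animal_id": animal, "session_id": session_id, "task": task,
                    "condition": cond, "stimulus": s,
                    "start_s": a, "end_s": b,
                }
                for s in stimuli
                for a, b in contacts[s].intervals
            ]
        )
        ev_path = out / "events" / f"{session_id}.csv"
        ph_path = out / "photometry" / f"{session_id}.csv"
        if ev.empty:
            ev = pd.DataFrame(columns=[
                "animal_id", "session_id", "task", "condition",
                "stimulus", "start_s", "end_s",
            ])
        write_events_table(ev_path, ev)
        write_photometry(ph_path, t, s465, s405)
        files.append({"path": str(ev_path.relative_to(out)), "role": "events", "seed": seed})
        files.append({"path": str(ph_path.relative_to(out)), "role": "photometry", "seed": seed})
        meta_rows.append(
            {"animal_id": animal, "session_id": session_id, "genotype": g,
             "task": task, "condition": cond, "seed": seed,
             "clock_offset": config.clock_offset}
        )
        for b in truth.bouts:
            truth_rows.append(
                {"animal_id": animal, "session_id": session_id, "stimulus": b["stimulus"],
                 "start_s": b["start"], "end_s": b["end"], "amp": b["amp"]}
            )
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False, float_format="%.17g")
    files.append({"path": "metadata.csv", "role": "metadata", "seed": config.seed})
    files.append({"path": "ground_truth.csv", "role": "ground_truth", "seed": config.seed})
    cfg_dict = _dc.asdict(config)
    cfg_dict["n_per_genotype"] = n_per_genotype
    cfg_dict["tasks"] = list(tasks)
    cfg_dict["conditions"] = list(conditions)
    return write_manifest(out / "manifest.json", files, cfg_dict, __version__)
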