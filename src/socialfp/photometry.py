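"""Event-aligned fiber-photometry processing.

The raw recording has two channels: a calcium-dependent signal (465 nm
excitation) and a calcium-independent isosbestic control (405 nm).  The
control sees the same photobleaching and motion artifacts but no calcium
transients, so an ordinary least-squares fit of the control onto the signal
yields the nuisance component; the fractional residual is dF/F.

dF/F is then aligned to behavioral events (bout onsets), averaged into
0.1 s bins over a window from 2 s before to 5 s after each onset, and
z-scored within each event against its own 2 s pre-onset baseline (zdF/F).
Per-animal responses are the event-averaged traces; the scalar summary is
the area under the averaged z-score curve over the post-onset interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

__all__ = [
    "PhotometryTrace",
    "EventList",
    "PeriEventMatrix",
    "AnimalResponse",
    "detrend_isosbestic",
    "align_events",
    "extract_peri_event",
    "zscore_peri_event",
    "animal_mean_trace",
    "area_under_curve",
    "qc_session",
    "build_heatmap",
]


class PhotometryError(ValueError):
    pass


@dataclass(frozen=True)
class PhotometryTrace:
    """Time-aligned two-channel trace; ``dff`` is populated by detrending."""

    t: np.ndarray
    s465: np.ndarray
    s405: np.ndarray
    fs: float
    dff: np.ndarray | None = None
    fit_coef: tuple[float, float] | None = None  # (slope a, intercept b) of a*s405+b

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        for name in ("t", "s465", "s405"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.s465.shape != t.shape or self.s405.shape != t.shape:
            raise PhotometryError("channel/time length mismatch")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise PhotometryError("time vector not strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-6 / self.fs:
                raise PhotometryError("non-uniform sampling")
        if not (np.all(np.isfinite(self.s465)) and np.all(np.isfinite(self.s405))):
            raise PhotometryError("non-finite fluorescence")


@dataclass(frozen=True)
class EventList:
    """Bout onsets/offsets with stimulus labels, on some clock."""

    onsets: np.ndarray
    offsets: np.ndarray
    labels: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        on = np.asarray(self.onsets, dtype=float)
        off = np.asarray(self.offsets, dtype=float)
        lab = np.asarray(self.labels, dtype=object)
        if not (on.shape == off.shape == lab.shape):
            raise ValueError("onsets/offsets/labels length mismatch")
        if on.size and np.any(np.diff(on) < 0):
            raise ValueError("onsets must be sorted")
        if np.any(off <= on):
            raise ValueError("each onset must precede its offset")
        for name, v in (("onsets", on), ("offsets", off), ("labels", lab)):
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class PeriEventMatrix:
    """events x time-bins matrix around bout onsets.

    ``values`` holds binned dF/F (or zdF/F after :func:`zscore_peri_event`);
    ``centers`` are bin centers; baseline columns are those with center < 0.
    ``kept`` flags rows that survive exclusion (degenerate baselines);
    ``baseline_overlap`` flags events with another same-stimulus onset
    inside their baseline (kept by default).
    """

    values: np.ndarray
    centers: np.ndarray
    labels: np.ndarray
    onsets: np.ndarray
    kept: np.ndarray
    baseline_overlap: np.ndarray
    cross_stimulus_overlap: np.ndarray | None = None
    n_excluded_window: int = 0
    zscored: bool = False

    @property
    def baseline_cols(self) -> np.ndarray:
        return self.centers < 0.0


@dataclass(frozen=True)
class AnimalResponse:
    """Event-averaged zdF/F trace for one animal and stimulus."""

    stimulus: str
    mean_trace: np.ndarray
    centers: np.ndarray
    n_events: int
    animal_id: str = ""
    genotype: str = ""


def detrend_isosbestic(trace: PhotometryTrace) -> PhotometryTrace:
    """Fit the 405 control onto the 465 signal; dF/F is the fractional residual.

    Least-squares affine fit ``c = a*s405 + b`` minimizing ``||s465 - c||^2``,
    then ``dff = (s465 - c) / c``.  The fitted control estimates bleaching
    plus motion; dividing by it converts the residual (the calcium-dependent
    part) to a fractional change.
    """
    if trace.t.size < 2:
        raise PhotometryError("need at least 2 samples to detrend")
    x = trace.s405
    if np.ptp(x) < 1e-12:
        raise PhotometryError("constant 405 channel: degenerate regressor")
    a, b = np.polyfit(x, trace.s465, 1)
    c = a * x + b
    if np.any(c <= 0):
        raise PhotometryError("fitted control crosses zero; division unsafe")
    return replace(trace, dff=(trace.s465 - c) / c, fit_coef=(float(a), float(b)))


def align_events(
    events: EventList,
    trace: PhotometryTrace,
    clock_offset: float = 0.0,
    clock_scale: float = 1.0,
) -> EventList:
    """Map event times onto the photometry clock: ``t' = scale*t + offset``.

    Events mapped outside the recorded trace are dropped and counted in
    ``n_dropped``; if all events fall outside, an error is raised.
    """
    if clock_scale <= 0:
        raise ValueError("clock_scale must be positive")
    on = clock_scale * events.onsets + clock_offset
    off = clock_scale * events.offsets + clock_offset
    inside = (on >= trace.t[0]) & (on <= trace.t[-1])
    if events.onsets.size and not inside.any():
        raise PhotometryError("all events fall outside the recorded trace")
    return EventList(
        on[inside], off[inside], events.labels[inside],
        n_dropped=int((~inside).sum()),
    )


def extract_peri_event(
    trace: PhotometryTrace,
    events: EventList,
    window: tuple[float, float] = (-2.0, 5.0),
    bin_s: float = 0.1,
    exclude_cross_stimulus: bool = True,
) -> PeriEventMatrix:
    """Bin dF/F into ``bin_s`` bins over ``window`` around each onset.

    Each bin averages the raw samples whose time falls in
    ``[onset + edge, onset + edge + bin_s)`` (anti-aliased resampling by
    within-bin averaging).  Onsets whose window extends beyond the trace
    are excluded and counted.  Onsets with another same-stimulus onset
    inside their baseline are flagged but kept.

    An event whose peri-event span contains a bout onset of the *other*
    stimulus mixes responses of different types (e.g. a food-aligned
    window that catches the onset of the next social bout); such events
    are marked not-kept by default (``exclude_cross_stimulus``) so they do
    not bias per-animal averages toward the other stimulus's response.
    """
    if trace.dff is None:
        raise PhotometryError("dff not populated; run detrend_isosbestic first")
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + np.arange(n_bins + 1) * bin_s
    centers = edges[:-1] + bin_s / 2.0
    per_bin = max(1, int(round(bin_s * trace.fs)))

    rows, labs, ons, overlap, cross = [], [], [], [], []
    n_excl = 0
    t0, fs = trace.t[0], trace.fs
    n = trace.t.size
    for onset, label in zip(events.onsets, events.labels):
        i0 = int(np.ceil((onset + lo - t0) * fs - 1e-9))
        i1 = i0 + n_bins * per_bin
        if i0 < 0 or i1 > n:
            n_excl += 1
            continue
        seg = trace.dff[i0:i1].reshape(n_bins, per_bin)
        rows.append(seg.mean(axis=1))
        labs.append(label)
        ons.append(onset)
        same = events.onsets[(events.labels == label) & (events.onsets != onset)]
        overlap.append(bool(np.any((same > onset + lo) & (same < onset))))
        other = events.onsets[events.labels != label]
        cross.append(bool(np.any((other >= onset + lo) & (other < onset + hi))))
    values = np.asarray(rows, dtype=float).reshape(len(rows), n_bins)
    cross = np.asarray(cross, dtype=bool)
    kept = ~cross if exclude_cross_stimulus else np.ones(len(rows), dtype=bool)
    return PeriEventMatrix(
        values=values,
        centers=centers,
        labels=np.asarray(labs, dtype=object),
        onsets=np.asarray(ons, dtype=float),
        kept=kept,
        baseline_overlap=np.asarray(overlap, dtype=bool),
        cross_stimulus_overlap=cross,
        n_excluded_window=n_excl,
    )


def zscore_peri_event(matrix: PeriEventMatrix, eps: float = 1e-9) -> PeriEventMatrix:
    """z-score each row against its own pre-onset baseline bins.

    ``z = (x - mean(baseline)) / sd(baseline)`` with the n-1 denominator.
    Rows whose baseline s.d. falls below ``eps`` carry no usable noise
    estimate; they are flagged and excluded from averaging rather than
    clipped.
    """
    base = matrix.values[:, matrix.baseline_cols]
    if base.shape[1] < 2:
        raise ValueError("need >= 2 baseline bins per row")
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=1, keepdims=True)
    kept = matrix.kept & (sd[:, 0] >= eps)
    sd_safe = np.where(sd < eps, 1.0, sd)
    return replace(matrix, values=(matrix.values - mu) / sd_safe, kept=kept, zscored=True)


def animal_mean_trace(
    matrix: PeriEventMatrix, animal_id: str = "", genotype: str = ""
) -> dict[str, AnimalResponse]:
    """Bin-wise mean across kept events, per stimulus.

    A stimulus with zero kept events yields no record — animals that never
    engaged a stimulus are simply absent, as in the per-animal heatmaps.
    """
    out: dict[str, AnimalResponse] = {}
    for stim in dict.fromkeys(matrix.labels[matrix.kept]):
        sel = matrix.kept & (matrix.labels == stim)
        out[str(stim)] = AnimalResponse(
            stimulus=str(stim),
            mean_trace=matrix.values[sel].mean(axis=0),
            centers=matrix.centers,
            n_events=int(sel.sum()),
            animal_id=animal_id,
            genotype=genotype,
        )
    return out


def area_under_curve(
    response: AnimalResponse, interval: tuple[float, float] = (0.0, 5.0)
) -> float:
    """Trapezoidal AUC of the mean z-trace over ``interval`` (z*s).

    Bin centers are the abscissae; the trace is extended constantly to the
    interval endpoints so that a constant trace of height h over [0, T]
    integrates to exactly h*T.
    """
    lo, hi = interval
    c = response.centers
    half = (c[1] - c[0]) / 2.0
    if lo < c[0] - half - 1e-9 or hi > c[-1] + half + 1e-9:
        raise ValueError("AUC interval outside the peri-event window")
    sel = (c >= lo) & (c <= hi)
    x = c[sel]
    y = response.mean_trace[sel]
    if x.size == 0:
        raise ValueError("AUC interval contains no bins")
    xs = np.concatenate([[lo], x, [hi]])
    ys = np.concatenate([[y[0]], y, [y[-1]]])
    return float(np.trapezoid(ys, xs))


def qc_session(
    trace: PhotometryTrace,
    stimulus_intro_time: float = 0.0,
    drift_thresh: float = 0.01,
    snr_thresh: float = 3.0,
) -> dict:
    """Session quality control: baseline stability and signal-to-noise.

    * stability — |Theil-Sen slope| of dF/F over the pre-stimulus period,
      in dF/F per minute, must stay below ``drift_thresh``;
    * SNR — 95th percentile of |dF/F - median| over the whole session,
      divided by the median absolute deviation; must reach ``snr_thresh``
      (a trace with real transients has a heavy positive tail relative to
      its noise floor, a flat one does not).

    A missing pre-period (< 60 s before the stimulus) yields an incomplete
    record rather than a verdict.
    """
    if trace.dff is None:
        raise PhotometryError("dff not populated; run detrend_isosbestic first")
    pre = trace.t < stimulus_intro_time
    rec: dict = {"complete": bool((stimulus_intro_time - trace.t[0]) >= 60.0 and pre.sum() >= 10)}
    dff = trace.dff
    dev = np.abs(dff - np.median(dff))
    mad = np.median(dev)
    snr = float(np.percentile(dev, 95) / mad) if mad > 0 else np.inf
    rec["snr"] = snr
    rec["snr_pass"] = bool(snr >= snr_thresh)
    if rec["complete"]:
        # decimate the pre-period for the Theil-Sen fit; full fs is O(n^2)
        tp, yp = trace.t[pre], dff[pre]
        step = max(1, tp.size // 600)
        slope = sps.theilslopes(yp[::step], tp[::step])[0] * 60.0  # per minute
        rec["drift_per_min"] = float(slope)
        rec["stability_pass"] = bool(abs(slope) < drift_thresh)
        rec["pass"] = rec["stability_pass"] and rec["snr_pass"]
    else:
        rec["drift_per_min"] = np.nan
        rec["stability_pass"] = None
        rec["pass"] = None
    return rec


GENOTYPE_ORDER = ("WT", "HET", "KO")


def build_heatmap(responses: list[AnimalResponse]) -> tuple[np.ndarray, list[dict]]:
    """Stack per-animal mean traces into an animals x bins matrix.

    Rows are ordered by genotype (WT, HET, KO) then animal id, so the
    matrix is a deterministic function of the response set regardless of
    input order.  Returns the matrix and per-row metadata.
    """
    if not responses:
        return np.empty((0, 0)), []
    centers = responses[0].centers
    for r in responses:
        if r.centers.shape != centers.shape or not np.allclose(r.centers, centers):
            raise ValueError("inconsistent bin structure across responses")

    def key(r: AnimalResponse):
        g = GENOTYPE_ORDER.index(r.genotype) if r.genotype in GENOTYPE_ORDER else 99
        return (g, r.animal_id, r.stimulus)

    ordered = sorted(responses, key=key)
    mat = np.vstack([r.mean_trace for r in ordered])
    meta = [
        {"animal_id": r.animal_id, "genotype": r.genotype,
         "stimulus": r.stimulus, "n_events": r.n_events}
        for r in ordered
    ]
    return mat, meta
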