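"""Investigation-bout analytics for two-stimulus preference sessions.

A session presents a subject rat with two stimulus compartments (e.g. a
confined juvenile vs. an empty chamber) for five minutes.  An automated
tracker emits, per stimulus, the raw intervals during which the subject was
in active contact with the compartment.  This module turns those intervals
into the behavioral readouts of the task:

* merged investigation *bouts* (contacts separated by gaps shorter than
  0.5 s count as one bout),
* investigation time binned at one minute,
* per-minute *preference scores* (time at stimulus A minus time at B),
* bout-length categories (short < 6 s, mid 6-19 s, long > 19 s),
* *transitions* — onsets of bouts at a different stimulus than the previous
  bout — and their per-minute rate,
* the distribution of switch intervals (gap between leaving one stimulus
  and contacting the other).

All times are seconds on a 0-based session clock; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactIntervals",
    "Bout",
    "MinuteBins",
    "merge_contacts",
    "bin_investigation_time",
    "preference_score",
    "categorize_bouts",
    "detect_transitions",
    "transition_rate",
    "shift_interval_histogram",
    "session_summary",
    "STIMULI",
    "CATEGORY_EDGES",
]

#: stimulus vocabulary used across the package
STIMULI = ("social", "empty", "object", "food")

#: bout-length category edges (s): short [0, 6), mid [6, 19], long (19, inf)
CATEGORY_EDGES = (6.0, 19.0)


class IntervalError(ValueError):
    """Raised for malformed contact intervals (unsorted, overlapping, empty)."""


@dataclass(frozen=True)
class ContactIntervals:
    """Raw tracker output for one stimulus: sorted half-open contact intervals."""

    stimulus: str
    intervals: np.ndarray  # shape (n, 2), float seconds

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "intervals", iv)
        self.validate()

    def validate(self, session_len: float | None = None) -> None:
        iv = self.intervals
        if iv.size == 0:
            return
        if not np.all(np.isfinite(iv)):
            raise IntervalError(f"{self.stimulus}: non-finite interval bounds")
        if np.any(iv[:, 1] <= iv[:, 0]):
            raise IntervalError(f"{self.stimulus}: end <= start")
        if np.any(iv[0, 0] < 0):
            raise IntervalError(f"{self.stimulus}: negative start time")
        if np.any(np.diff(iv[:, 0]) < 0):
            raise IntervalError(f"{self.stimulus}: intervals not sorted by start")
        if np.any(iv[1:, 0] < iv[:-1, 1]):
            raise IntervalError(f"{self.stimulus}: overlapping intervals")
        if session_len is not None and np.any(iv[:, 1] > session_len):
            raise IntervalError(f"{self.stimulus}: interval exceeds session length")

    @property
    def total_contact(self) -> float:
        if self.intervals.size == 0:
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))


@dataclass(frozen=True)
class Bout:
    """A merged investigation episode.

    ``duration`` is the merged span (end - start), sub-gap pauses included;
    ``contact_time`` is the summed raw contact inside the span.
    """

    stimulus: str
    start: float
    end: float
    contact_time: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def category(self) -> str:
        lo, hi = CATEGORY_EDGES
        if self.duration < lo:
            return "short"
        if self.duration <= hi:
            return "mid"
        return "long"


@dataclass(frozen=True)
class MinuteBins:
    """Binned investigation time for one stimulus."""

    stimulus: str
    edges: np.ndarray        # len n_bins + 1
    time_s: np.ndarray       # len n_bins, seconds of investigation per bin
    total_s: float = field(default=0.0)

    @property
    def bin_s(self) -> float:
        return float(self.edges[1] - self.edges[0])


def merge_contacts(raw: ContactIntervals, max_gap: float = 0.5) -> list[Bout]:
    """Fuse contacts separated by gaps strictly shorter than ``max_gap``.

    The tracker breaks a single investigation episode into several contacts
    when the snout briefly leaves the chamber wall; gaps of less than 0.5 s
    are treated as part of the same bout.  A gap of exactly ``max_gap`` does
    NOT merge (strict inequality).
    """
    raw.validate()
    iv = raw.intervals
    if iv.size == 0:
        return []
    bouts: list[Bout] = []
    cur_start, cur_end = iv[0]
    contact = cur_end - cur_start
    for start, end in iv[1:]:
        if start - cur_end < max_gap:
            cur_end = end
            contact += end - start
        else:
            bouts.append(Bout(raw.stimulus, float(cur_start), float(cur_end), float(contact)))
            cur_start, cur_end = start, end
            contact = end - start
    bouts.append(Bout(raw.stimulus, float(cur_start), float(cur_end), float(contact)))
    return bouts


def bin_investigation_time(
    bouts: list[Bout], bin_s: float = 60.0, session_len: float = 300.0
) -> MinuteBins:
    """Investigation time per time bin; bouts spanning an edge are split.

    Time is additive, so a bout crossing a bin edge contributes its overlap
    to each bin.  Bin sums plus the session total are returned; the total
    equals the summed bout durations for bouts inside the session.
    """
    if bin_s <= 0:
        raise ValueError("bin size must be positive")
    n_bins = int(np.ceil(session_len / bin_s))
    edges = np.arange(n_bins + 1, dtype=float) * bin_s
    edges[-1] = min(edges[-1], session_len)  # last bin may be partial
    time_s = np.zeros(n_bins)
    stim = bouts[0].stimulus if bouts else ""
    for b in bouts:
        if b.start < 0 or b.end > session_len + 1e-9:
            raise ValueError(f"bout [{b.start}, {b.end}) outside session [0, {session_len})")
        lo = np.maximum(b.start, edges[:-1])
        hi = np.minimum(b.end, edges[1:])
        time_s += np.clip(hi - lo, 0.0, None)
    return MinuteBins(stim, edges, time_s, total_s=float(time_s.sum()))


def preference_score(bins_a: MinuteBins, bins_b: MinuteBins) -> np.ndarray:
    """Signed per-bin preference: investigation time at A minus at B (s)."""
    if bins_a.edges.shape != bins_b.edges.shape or not np.allclose(
        bins_a.edges, bins_b.edges
    ):
        raise ValueError("mismatched bin structure")
    return bins_a.time_s - bins_b.time_s


def categorize_bouts(
    bouts: list[Bout], edges: tuple[float, float] = CATEGORY_EDGES
) -> dict[str, dict[str, float]]:
    """Count and sum bout durations by length category.

    Categories: short ``[0, edges[0])``, mid ``[edges[0], edges[1]]``, long
    ``(edges[1], inf)``.  Every bout falls in exactly one category.
    """
    lo, hi = edges
    if not lo < hi:
        raise ValueError("category edges must be strictly increasing")
    out = {c: {"count": 0, "time_s": 0.0} for c in ("short", "mid", "long")}
    for b in bouts:
        d = b.duration
        c = "short" if d < lo else ("mid" if d <= hi else "long")
        out[c]["count"] += 1
        out[c]["time_s"] += d
    return out


def detect_transitions(bouts_a: list[Bout], bouts_b: list[Bout]) -> list[float]:
    """Onset times of bouts at a different stimulus than the previous bout.

    The session's first bout is not a transition.  Bouts across the two
    stimuli must not overlap (the animal is at one compartment at a time).
    """
    merged = sorted(bouts_a + bouts_b, key=lambda b: b.start)
    for prev, nxt in zip(merged, merged[1:]):
        if nxt.start < prev.end - 1e-9:
            raise IntervalError(
                f"bouts overlap across stimuli at t={nxt.start:.3f}"
            )
    out = []
    for prev, nxt in zip(merged, merged[1:]):
        if nxt.stimulus != prev.stimulus:
            out.append(nxt.start)
    return out


def transition_rate(
    transitions: list[float], bin_s: float = 60.0, session_len: float = 300.0
) -> np.ndarray:
    """Histogram of transition times at ``bin_s`` bins (counts per bin)."""
    n_bins = int(np.ceil(session_len / bin_s))
    edges = np.arange(n_bins + 1, dtype=float) * bin_s
    counts, _ = np.histogram(np.asarray(transitions, dtype=float), bins=edges)
    return counts.astype(int)


def shift_interval_histogram(
    bouts_a: list[Bout],
    bouts_b: list[Bout],
    duration_bins: np.ndarray | None = None,
) -> dict:
    """Distribution of intervals between bouts where the animal switched stimulus.

    For every consecutive bout pair (chronological, both stimuli pooled)
    whose stimuli differ, the interval is ``next.start - prev.end``.
    Returns counts per duration bin and percentages (summing to 100 when at
    least one switch interval exists; flagged undefined otherwise).
    """
    if duration_bins is None:
        duration_bins = np.concatenate([np.arange(0.0, 10.5, 0.5), [np.inf]])
    duration_bins = np.asarray(duration_bins, dtype=float)
    merged = sorted(bouts_a + bouts_b, key=lambda b: b.start)
    intervals = [
        nxt.start - prev.end
        for prev, nxt in zip(merged, merged[1:])
        if nxt.stimulus != prev.stimulus
    ]
    counts, _ = np.histogram(np.asarray(intervals, dtype=float), bins=duration_bins)
    n = counts.sum()
    return {
        "edges": duration_bins,
        "counts": counts.astype(int),
        "percent": counts * 100.0 / n if n else np.full(counts.shape, np.nan),
        "n_intervals": int(n),
        "defined": bool(n),
        "intervals": np.asarray(intervals, dtype=float),
    }


def session_summary(
    contacts: dict[str, ContactIntervals],
    session_len: float = 300.0,
    max_gap: float = 0.5,
    bin_s: float = 60.0,
) -> dict:
    """One flat record of all per-session behavioral metrics.

    ``contacts`` maps the two stimulus labels to their raw intervals.  The
    record is invariant to the order in which stimuli are supplied: the
    preference score is reported for the pair sorted by the package-wide
    stimulus vocabulary (social before empty/object/food, etc.).
    """
    stims = sorted(contacts, key=lambda s: STIMULI.index(s) if s in STIMULI else 99)
    if len(stims) != 2:
        raise ValueError("a session has exactly two stimuli")
    bouts = {s: merge_contacts(contacts[s], max_gap) for s in stims}
    bins = {s: bin_investigation_time(bouts[s], bin_s, session_len) for s in stims}
    trans = detect_transitions(bouts[stims[0]], bouts[stims[1]])
    rec: dict = {
        "stimuli": tuple(stims),
        "n_transitions": len(trans),
        "transition_rate": transition_rate(trans, bin_s, session_len),
        "preference": preference_score(bins[stims[0]], bins[stims[1]]),
        "shift_intervals": shift_interval_histogram(bouts[stims[0]], bouts[stims[1]]),
    }
    for s in stims:
        cat = categorize_bouts(bouts[s])
        rec[s] = {
            "total_time_s": bins[s].total_s,
            "contact_time_s": contacts[s].total_contact,
            "n_bouts": len(bouts[s]),
            "minute_time_s": bins[s].time_s,
            "categories": cat,
        }
    return rec
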