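"""Independent brute-force oracles for the interval algebra.

Everything here works on the video frame grid (15 fps): contact is a
boolean per frame, merging is gap-filling on the frame sequence, binning
is frame counting.  These implementations share no code with the package
and are deliberately naive; the tests assert exact agreement on
frame-quantized input.
"""

from __future__ import annotations

import numpy as np

FS = 15.0


def intervals_to_frames(intervals: np.ndarray, n_frames: int) -> np.ndarray:
    """Mark the frames covered by half-open frame-aligned intervals."""
    occ = np.zeros(n_frames, dtype=bool)
    for a, b in np.asarray(intervals, dtype=float).reshape(-1, 2):
        occ[int(round(a * FS)):int(round(b * FS))] = True
    return occ


def frames_to_intervals(occ: np.ndarray) -> np.ndarray:
    """Extract runs of True as half-open [start, end) intervals in seconds."""
    padded = np.concatenate([[False], occ, [False]])
    edges = np.flatnonzero(np.diff(padded.view(np.int8)))
    return edges.reshape(-1, 2) / FS


def merge_oracle(intervals: np.ndarray, n_frames: int, max_gap: float = 0.5) -> np.ndarray:
    """Frame-dilation merge: fill gaps strictly shorter than max_gap."""
    occ = intervals_to_frames(intervals, n_frames)
    runs = frames_to_intervals(occ)
    out = occ.copy()
    for (_, end), (start, _) in zip(runs, runs[1:]):
        gap_frames = int(round((start - end) * FS))
        if gap_frames / FS < max_gap:
            out[int(round(end * FS)):int(round(start * FS))] = True
    return frames_to_intervals(out)


def bin_oracle(intervals: np.ndarray, n_frames: int, bin_s: float = 60.0) -> np.ndarray:
    """Per-bin investigation time by counting frames (exact at 15 fps, 60 s bins)."""
    occ = intervals_to_frames(intervals, n_frames)
    per_bin = int(round(bin_s * FS))
    n_bins = int(np.ceil(n_frames / per_bin))
    return np.array(
        [occ[i * per_bin:(i + 1) * per_bin].sum() / FS for i in range(n_bins)]
    )


def transitions_oracle(merged_a: np.ndarray, merged_b: np.ndarray) -> np.ndarray:
    """Scan merged bouts chronologically; onsets where the stimulus changes."""
    events = [(float(a), "A") for a, _ in merged_a] + [(float(a), "B") for a, _ in merged_b]
    events.sort()
    out, prev = [], None
    for t, s in events:
        if prev is not None and s != prev:
            out.append(t)
        prev = s
    return np.asarray(out)


def random_session(rng: np.random.Generator, session_len: float = 300.0):
    """Random frame-quantized two-stimulus session (raw tracker-style contacts).

    Alternating away / at-stimulus segments with geometric lengths.  Gaps
    between contacts of the *same* stimulus are often shorter than 0.5 s
    (the case the merge rule exists for); away-time before switching to the
    *other* stimulus is at least 8 frames (>= 0.5 s), since a tracker
    cannot register the animal at the far compartment inside a sub-0.5 s
    gap.  Returns (intervals_a, intervals_b, n_frames).
    """
    n_frames = int(round(session_len * FS))
    state_seq = np.zeros(n_frames, dtype=np.int8)
    f = 0
    last = 0
    while f < n_frames:
        stim = int(rng.integers(1, 3)) if (last == 0 or rng.random() < 0.4) else last
        away = 1 + rng.geometric(0.25)
        if stim != last and last != 0:
            away = max(away, 8)
        f += away
        length = 1 + rng.geometric(0.05)
        state_seq[f:f + length] = stim
        f += length
        last = stim
    a = frames_to_intervals(state_seq == 1)
    b = frames_to_intervals(state_seq == 2)
    return a, b, n_frames
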