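"""Debouncing and 4-level gait-phase coding of foot-switch channels.

Mechanical switch bounce shows up as isolated samples (or very short
runs) toggling around a contact transition.  Because gait phases last
~100-500 ms while bounce artifacts last a few milliseconds, removing
every constant run shorter than a threshold (default 20 ms) cleans the
channels without touching genuine phase transitions.  The filter is
offline ("anti-causal"): it looks at future samples and introduces no
systematic lag.

The cleaned channels are then mapped sample-by-sample onto the 4-phase
foot-floor contact alphabet:

====  ==========================  ===========================
code  switch state (heel, mets)   gait phase
====  ==========================  ===========================
H     heel only                   heel contact
F     heel + >=1 metatarsal       flat-foot contact
P     >=1 metatarsal, no heel     push-off
S     no switch closed            swing
====  ==========================  ===========================
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .io_formats import SwitchRecording

__all__ = [
    "PhaseSignal",
    "PHASES",
    "DEFAULT_DEBOUNCE_S",
    "debounce",
    "encode_phases",
    "remove_short_phases",
    "to_phase_signal",
    "run_length_encode",
]

PHASES = ("H", "F", "P", "S")
DEFAULT_DEBOUNCE_S = 0.020

# index = heel*4 + met1*2 + met5
_PHASE_TABLE = np.array(["S", "P", "P", "P", "H", "F", "F", "F"])


@dataclass
class PhaseSignal:
    """Per-sample gait-phase labels over the alphabet {H, F, P, S}."""

    labels: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U1")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        bad = ~np.isin(self.labels, PHASES)
        if bad.any():
            raise ValueError(f"labels outside {PHASES}: {set(self.labels[bad])}")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def run_length_encode(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal constant runs of ``x`` as ``(values, starts, lengths)``."""
    x = np.asarray(x)
    if len(x) == 0:
        return x[:0], np.empty(0, int), np.empty(0, int)
    change = np.flatnonzero(x[1:] != x[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [len(x)])))
    return x[starts], starts, lengths


def _min_samples(min_run_s: float, fs: float) -> int:
    # a run is removed iff its duration is strictly shorter than min_run_s
    return int(np.ceil(min_run_s * fs - 1e-9))


def _merge_short_runs(x: np.ndarray, min_samples: int) -> np.ndarray:
    """Iteratively absorb interior sub-threshold runs into the preceding run.

    The shortest interior run is merged first (earliest on ties); merged
    neighbours with equal values coalesce, and the grown run is
    re-examined.  Runs touching either signal boundary are never removed.
    Implemented on the run-length encoding with a lazy heap, O(R log R).
    """
    if min_samples <= 1:
        return np.asarray(x).copy()
    vals, starts, lens = run_length_encode(x)
    m = len(vals)
    if m <= 2:
        return np.asarray(x).copy()
    val = list(vals)
    ln = [int(v) for v in lens]
    start = [int(v) for v in starts]
    prv = list(range(-1, m - 1))
    nxt = list(range(1, m + 1))
    nxt[-1] = -1
    alive = [True] * m
    heap = [
        (ln[i], start[i], i) for i in range(1, m - 1) if ln[i] < min_samples
    ]
    heapq.heapify(heap)
    while heap:
        length, _, i = heapq.heappop(heap)
        if not alive[i] or ln[i] != length:
            continue
        p, q = prv[i], nxt[i]
        if p == -1 or q == -1:  # boundary runs are kept
            continue
        alive[i] = False
        ln[p] += ln[i]
        nxt[p] = q
        prv[q] = p
        if val[q] == val[p]:
            alive[q] = False
            ln[p] += ln[q]
            r = nxt[q]
            nxt[p] = r
            if r != -1:
                prv[r] = p
        if prv[p] != -1 and nxt[p] != -1 and ln[p] < min_samples:
            heapq.heappush(heap, (ln[p], start[p], p))
    out_vals, out_lens = [], []
    i = 0
    while i != -1:
        out_vals.append(val[i])
        out_lens.append(ln[i])
        i = nxt[i]
    return np.repeat(np.asarray(out_vals, dtype=vals.dtype), out_lens)


def debounce(rec: SwitchRecording, min_run_s: float = DEFAULT_DEBOUNCE_S) -> SwitchRecording:
    """Remove sub-threshold constant runs from each switch channel.

    After filtering, no interior maximal run is strictly shorter than
    ``min_run_s``; runs touching a recording boundary are kept.  The
    operator is idempotent and shifts no transition by more than
    ``min_run_s``.
    """
    if min_run_s < 0:
        raise ValueError("min_run_s must be nonnegative")
    if min_run_s >= rec.duration:
        raise ValueError(
            f"min_run_s ({min_run_s}s) must be shorter than the recording "
            f"({rec.duration}s)"
        )
    ms = _min_samples(min_run_s, rec.sampling_rate)
    return SwitchRecording(
        subject_id=rec.subject_id,
        side=rec.side,
        sampling_rate=rec.sampling_rate,
        heel=_merge_short_runs(rec.heel, ms),
        met1=_merge_short_runs(rec.met1, ms),
        met5=_merge_short_runs(rec.met5, ms),
    )


def encode_phases(rec: SwitchRecording) -> PhaseSignal:
    """Map each sample's (heel, met1, met5) state to a gait-phase label.

    The mapping is total over all 8 switch states; it assumes the
    recording has already been debounced but does not enforce it.
    """
    idx = rec.heel.astype(np.intp) * 4 + rec.met1.astype(np.intp) * 2 + rec.met5
    return PhaseSignal(labels=_PHASE_TABLE[idx], sampling_rate=rec.sampling_rate)


def remove_short_phases(
    sig: PhaseSignal, min_run_s: float = DEFAULT_DEBOUNCE_S
) -> PhaseSignal:
    """Second debouncing pass on the 4-level phase signal.

    Bounce at a phase boundary can survive channel-level filtering as a
    1-2 sample spurious phase (two channels toggling near-simultaneously);
    this removes any interior phase run shorter than ``min_run_s``.
    """
    if min_run_s >= sig.duration:
        raise ValueError("min_run_s must be shorter than the signal")
    ms = _min_samples(min_run_s, sig.sampling_rate)
    return PhaseSignal(
        labels=_merge_short_runs(sig.labels, ms), sampling_rate=sig.sampling_rate
    )


def to_phase_signal(
    rec: SwitchRecording,
    debounce_s: float = DEFAULT_DEBOUNCE_S,
    phase_pass: bool = True,
) -> PhaseSignal:
    """Full preprocessing: channel debounce, phase coding, phase debounce."""
    sig = encode_phases(debounce(rec, debounce_s))
    if phase_pass:
        sig = remove_short_phases(sig, debounce_s)
    return sig
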