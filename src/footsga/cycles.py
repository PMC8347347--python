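"""Gait-cycle segmentation and foot-floor contact classification.

A gait cycle opens at a contact onset -- any swing-to-contact transition
(S -> H, F or P) -- and closes at the next onset.  Opening at any contact
(rather than heel strike only) is required to capture pathological
cycles that begin with a forefoot (PFPS, PS) or flat-foot (FPS) strike.
Partial segments before the first and after the last onset are
discarded; implausibly long "cycles" (default > 3 s, typically standing
pauses) are set aside and counted separately.

A cycle's class label is its run-length-encoded phase string; the single
physiological class is ``HFPS`` (heel contact, flat-foot contact,
push-off, swing) and every other label is atypical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationTrack
from .preprocess import PhaseSignal, run_length_encode

__all__ = [
    "GaitCycle",
    "TYPICAL_LABEL",
    "segment_cycles",
    "classify_cycle",
    "tag_regions",
]

logger = logging.getLogger(__name__)

TYPICAL_LABEL = "HFPS"
DEFAULT_MAX_CYCLE_S = 3.0


@dataclass
class GaitCycle:
    """One segmented gait cycle.

    ``phase_runs`` is the run-length encoding of the cycle's phase signal
    as ``(phase, duration_s)`` pairs; by construction no two adjacent
    phases are equal and the durations sum to ``end_s - start_s``.
    """

    start_s: float
    end_s: float
    phase_runs: list[tuple[str, float]]
    region: str = "unknown"

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("cycle must have end_s > start_s")
        if not self.phase_runs:
            raise ValueError("cycle must contain at least one phase run")
        seq = [p for p, _ in self.phase_runs]
        if any(a == b for a, b in zip(seq, seq[1:])):
            raise ValueError("phase_runs must not contain equal adjacent phases")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    @property
    def phase_seq(self) -> str:
        return "".join(p for p, _ in self.phase_runs)

    @property
    def class_label(self) -> str:
        return self.phase_seq

    @property
    def is_typical(self) -> bool:
        return self.phase_seq == TYPICAL_LABEL


def classify_cycle(cycle: GaitCycle) -> tuple[bool, str]:
    """Return ``(is_typical, class_label)`` for a segmented cycle."""
    label = cycle.phase_seq
    return label == TYPICAL_LABEL, label


def segment_cycles(
    sig: PhaseSignal,
    max_cycle_s: float = DEFAULT_MAX_CYCLE_S,
    with_discarded: bool = False,
):
    """Split a phase signal into gait cycles at contact onsets.

    Returns the list of complete cycles (onset to next onset); with
    ``with_discarded=True`` also returns the over-length segments that
    were excluded as pauses.
    """
    lab = sig.labels
    fs = sig.sampling_rate
    contact = lab != "S"
    onsets = np.flatnonzero(contact[1:] & ~contact[:-1]) + 1
    cycles: list[GaitCycle] = []
    discarded: list[GaitCycle] = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        vals, _, lens = run_length_encode(lab[a:b])
        cyc = GaitCycle(
            start_s=a / fs,
            end_s=b / fs,
            phase_runs=[(str(v), int(n) / fs) for v, n in zip(vals, lens)],
        )
        if cyc.duration > max_cycle_s:
            discarded.append(cyc)
        else:
            cycles.append(cyc)
    if discarded:
        logger.info(
            "discarded %d over-length segment(s) (> %.1f s) as pauses",
            len(discarded),
            max_cycle_s,
        )
    if with_discarded:
        return cycles, discarded
    return cycles


def tag_regions(
    cycles: list[GaitCycle], track: AnnotationTrack | None
) -> list[GaitCycle]:
    """Assign each cycle the region containing its onset (in place).

    A cycle belongs to the straight/turn interval containing its start;
    onsets outside every interval (or with no annotation track) are
    tagged ``unknown``.
    """
    for c in cycles:
        c.region = track.region_at(c.start_s) if track is not None else "unknown"
    return cycles
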