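"""Spatio-temporal gait parameters and atypical-cycle statistics.

Per subject and side this module computes: the share of typical (HFPS)
and atypical cycles, per-class percentages, the straight/turn split of
atypical cycles, gait-phase durations in percent of the gait cycle
(%GC, typical cycles only), cadence (strides/min), bilateral double
support (%GC) and the straight-walkway speed.  The speed-normalized
atypical percentage Atyp = %atypical / speed (%, per m/s) is the main
derived biomarker.

All percentages use the total number of cycles of that side (straight
plus turns) as denominator, so the straight and turn atypical
percentages add up to the side's total atypical percentage whenever the
annotations cover every onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cycles import GaitCycle
from .io_formats import AnnotationTrack, SubjectMeta
from .preprocess import PHASES, PhaseSignal

__all__ = [
    "SideSummary",
    "SubjectResult",
    "CohortTable",
    "phase_durations_pct",
    "cadence",
    "double_support_pct",
    "walking_speed",
    "atyp_normalized",
    "summarize_side",
]


@dataclass
class SideSummary:
    """Aggregate gait parameters for one subject-side."""

    n_cycles: int
    pct_typical: float
    pct_atypical: float
    phase_pct: dict[str, float]
    class_pct: dict[str, float]
    region_atypical_pct: dict[str, float]
    cadence: float
    cadence_mode: str = "full"
    double_support_pct: float = math.nan
    n_discarded: int = 0

    def to_row(self) -> dict:
        row = {
            "n_cycles": self.n_cycles,
            "pct_typical": self.pct_typical,
            "pct_atypical": self.pct_atypical,
            "cadence": self.cadence,
            "cadence_mode": self.cadence_mode,
            "double_support_pct": self.double_support_pct,
            "atypical_straight_pct": self.region_atypical_pct.get("straight", 0.0),
            "atypical_turn_pct": self.region_atypical_pct.get("turn", 0.0),
            "atypical_unknown_pct": self.region_atypical_pct.get("unknown", 0.0),
            "n_discarded": self.n_discarded,
        }
        for ph in PHASES:
            row[f"phase_{ph}_pct"] = self.phase_pct.get(ph, math.nan)
        return row


@dataclass
class SubjectResult:
    """Per-subject results: side summaries keyed by role, speed, Atyp."""

    meta: SubjectMeta
    sides: dict[str, SideSummary]
    speed: float
    atyp_norm: float

    @property
    def subject_id(self) -> str:
        return self.meta.subject_id


@dataclass
class CohortTable:
    """Cohort summary tables (means +/- SD per group-side, with p-values)."""

    parameters: pd.DataFrame = field(default_factory=pd.DataFrame)
    regions: pd.DataFrame = field(default_factory=pd.DataFrame)


def phase_durations_pct(cycle: GaitCycle) -> dict[str, float]:
    """H/F/P/S durations of a typical cycle in % of cycle duration."""
    if not cycle.is_typical:
        raise ValueError(
            f"phase durations in %GC are defined for typical (HFPS) cycles, "
            f"got {cycle.class_label!r}"
        )
    total = cycle.duration
    return {ph: 100.0 * dur / total for ph, dur in cycle.phase_runs}


def cadence(cycles, recording_duration_s: float) -> float:
    """Gait cycles (strides) per minute over the given duration."""
    if recording_duration_s <= 0:
        raise ValueError("recording duration must be positive")
    n = cycles if isinstance(cycles, (int, np.integer)) else len(cycles)
    return n / (recording_duration_s / 60.0)


def double_support_pct(
    left: PhaseSignal,
    right: PhaseSignal,
    cycles: list[GaitCycle],
    mode: str = "total",
) -> float:
    """Mean double-support duration per cycle, in %GC.

    ``total`` counts every sample of the cycle where both feet are in
    contact (neither side in swing); ``initial`` counts only the
    double-support period that starts at the cycle's own contact onset
    (the loading-response double support).
    """
    if mode not in ("total", "initial"):
        raise ValueError("mode must be 'total' or 'initial'")
    if left.sampling_rate != right.sampling_rate or left.n_samples != right.n_samples:
        raise ValueError("left and right phase signals must share the time base")
    if not cycles:
        return math.nan
    fs = left.sampling_rate
    both = (left.labels != "S") & (right.labels != "S")
    vals = []
    for c in cycles:
        a = int(round(c.start_s * fs))
        b = int(round(c.end_s * fs))
        window = both[a:b]
        if len(window) == 0:
            continue
        if mode == "total":
            frac = window.mean()
        else:
            n0 = np.argmin(window) if not window.all() else len(window)
            frac = (n0 if window[0] else 0) / len(window)
        vals.append(100.0 * frac)
    return float(np.mean(vals)) if vals else math.nan


def walking_speed(track: AnnotationTrack) -> float:
    """Straight-walkway speed: total distance over total passage time.

    Pools all timed passages (n * path length / summed durations) rather
    than averaging per-passage speeds.
    """
    if not track.passages:
        raise ValueError("no timed passages: cannot estimate walking speed")
    total_time = sum(e - s for s, e in track.passages)
    return len(track.passages) * track.path_length_m / total_time


def atyp_normalized(pct_atypical: float, speed: float) -> float:
    """Atyp: percentage of atypical cycles divided by walking speed."""
    if speed <= 0:
        raise ValueError("speed must be positive")
    return pct_atypical / speed


def summarize_side(
    cycles: list[GaitCycle],
    track: AnnotationTrack | None,
    recording_duration_s: float,
    cadence_mode: str = "full",
    n_discarded: int = 0,
) -> SideSummary:
    """Aggregate segmented, classified, region-tagged cycles for one side.

    ``cadence_mode='full'`` divides the cycle count by the whole
    recording; ``'straight'`` restricts to straight-region cycles over
    the summed straight-interval time.
    """
    n = len(cycles)
    if n == 0:
        return SideSummary(
            n_cycles=0,
            pct_typical=math.nan,
            pct_atypical=math.nan,
            phase_pct={},
            class_pct={},
            region_atypical_pct={},
            cadence=0.0,
            cadence_mode=cadence_mode,
            n_discarded=n_discarded,
        )
    typical = [c for c in cycles if c.is_typical]
    atypical = [c for c in cycles if not c.is_typical]
    pct_typical = 100.0 * len(typical) / n
    pct_atypical = 100.0 * len(atypical) / n

    phase_pct: dict[str, float] = {}
    if typical:
        per_cycle = [phase_durations_pct(c) for c in typical]
        phase_pct = {
            ph: float(np.mean([d[ph] for d in per_cycle])) for ph in PHASES
        }

    class_pct: dict[str, float] = {}
    for c in atypical:
        class_pct[c.class_label] = class_pct.get(c.class_label, 0.0) + 100.0 / n

    region_pct: dict[str, float] = {"straight": 0.0, "turn": 0.0}
    for c in atypical:
        region_pct[c.region] = region_pct.get(c.region, 0.0) + 100.0 / n
    if region_pct.get("unknown") == 0.0:
        region_pct.pop("unknown", None)

    if cadence_mode == "straight":
        if track is None:
            raise ValueError("straight cadence mode requires annotations")
        straight_time = track.total_duration("straight")
        n_straight = sum(1 for c in cycles if c.region == "straight")
        cad = cadence(n_straight, straight_time)
    elif cadence_mode == "full":
        cad = cadence(n, recording_duration_s)
    else:
        raise ValueError("cadence_mode must be 'full' or 'straight'")

    return SideSummary(
        n_cycles=n,
        pct_typical=pct_typical,
        pct_atypical=pct_atypical,
        phase_pct=phase_pct,
        class_pct=class_pct,
        region_atypical_pct=region_pct,
        cadence=cad,
        cadence_mode=cadence_mode,
        n_discarded=n_discarded,
    )
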