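"""On-disk formats for foot-switch gait analysis.

Signals are stored as one CSV per subject-side with columns
``time_s, heel, met1, met5`` (binary channels sampled on a regular grid);
annotations as a CSV of half-open ``[start_s, end_s)`` intervals labelled
``straight``/``turn`` plus timed ``passage`` rows; cohort metadata and the
summary tables as plain CSV.  Everything round-trips through
:func:`read_switch_csv` / :func:`write_switch_csv` and friends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SwitchRecording",
    "AnnotationTrack",
    "SubjectMeta",
    "FormatError",
    "read_switch_csv",
    "write_switch_csv",
    "read_annotations",
    "write_annotations",
    "read_metadata",
    "write_metadata",
    "write_cohort_tables",
    "read_cohort_tables",
]

SIDES = ("left", "right")
GROUPS = ("PD", "control")
PD_ROLES = ("more_affected", "less_affected")
CONTROL_ROLES = ("dominant", "non_dominant")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the expected format."""


@dataclass
class SwitchRecording:
    """Binary heel / 1st-metatarsal / 5th-metatarsal channels for one side.

    Channels are sampled at ``sampling_rate`` Hz; a value of 1 means the
    switch is closed (that foot segment is on the ground).
    """

    subject_id: str
    side: str
    sampling_rate: float
    heel: np.ndarray
    met1: np.ndarray
    met5: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        self.heel = np.asarray(self.heel, dtype=np.int8)
        self.met1 = np.asarray(self.met1, dtype=np.int8)
        self.met5 = np.asarray(self.met5, dtype=np.int8)
        n = len(self.heel)
        if not (len(self.met1) == len(self.met5) == n):
            raise ValueError("heel, met1 and met5 must have equal length")
        if n == 0:
            raise ValueError("recording must contain at least one sample")
        for name in ("heel", "met1", "met5"):
            ch = getattr(self, name)
            if not np.isin(ch, (0, 1)).all():
                raise FormatError(f"channel {name} contains non-binary values")

    @property
    def n_samples(self) -> int:
        return len(self.heel)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate

    def channels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.heel, self.met1, self.met5


@dataclass
class AnnotationTrack:
    """Straight/turn intervals and timed straight passages for one walk.

    Intervals are half-open ``[start, end)`` in seconds from recording
    start.  ``passages`` are the manually timed straight-walkway
    traversals used for the speed estimate; each must lie inside a
    straight interval.  ``path_length_m`` is the straight-walkway length.
    """

    intervals: list[tuple[float, float, str]] = field(default_factory=list)
    passages: list[tuple[float, float]] = field(default_factory=list)
    path_length_m: float = 9.0

    def __post_init__(self) -> None:
        if not self.path_length_m > 0:
            raise ValueError("path_length_m must be positive")
        self.intervals = sorted(
            (float(s), float(e), str(lab)) for s, e, lab in self.intervals
        )
        self.passages = sorted((float(s), float(e)) for s, e in self.passages)
        prev_end = -np.inf
        for s, e, lab in self.intervals:
            if lab not in ("straight", "turn"):
                raise FormatError(f"unknown interval label {lab!r}")
            if not e > s:
                raise FormatError(f"interval ({s}, {e}) has start >= end")
            if s < prev_end - 1e-9:
                raise FormatError(f"interval starting at {s} overlaps the previous one")
            prev_end = e
        for s, e in self.passages:
            if not e > s:
                raise FormatError(f"passage ({s}, {e}) has start >= end")
            if not any(
                lab == "straight" and s >= is_ - 1e-9 and e <= ie + 1e-9
                for is_, ie, lab in self.intervals
            ):
                raise FormatError(
                    f"passage ({s}, {e}) does not lie within a straight interval"
                )

    def region_at(self, t: float) -> str:
        """Region label (``straight``/``turn``/``unknown``) containing time t."""
        for s, e, lab in self.intervals:
            if s <= t < e:
                return lab
        return "unknown"

    def total_duration(self, label: str) -> float:
        return float(sum(e - s for s, e, lab in self.intervals if lab == label))


@dataclass
class SubjectMeta:
    """Group membership, side roles and clinical scores for one subject."""

    subject_id: str
    group: str
    side_roles: dict[str, str]
    updrs3: float | None = None
    hoehn_yahr: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        expected = set(PD_ROLES) if self.group == "PD" else set(CONTROL_ROLES)
        if set(self.side_roles) != set(SIDES):
            raise ValueError("side_roles must map exactly 'left' and 'right'")
        if set(self.side_roles.values()) != expected:
            raise ValueError(
                f"{self.group} subject must have one side per role {sorted(expected)}"
            )
        if self.updrs3 is not None and self.updrs3 < 0:
            raise ValueError("updrs3 must be nonnegative")

    def side_of(self, role: str) -> str:
        for side, r in self.side_roles.items():
            if r == role:
                return side
        raise KeyError(role)


# ---------------------------------------------------------------------------
# switch signals


def read_switch_csv(
    path: str | Path, subject_id: str | None = None, side: str | None = None
) -> SwitchRecording:
    """Read a subject-side signal CSV and infer the sampling rate.

    The file must have header ``time_s,heel,met1,met5`` with a monotone,
    regular time grid (relative step jitter above 1% is rejected).  If
    ``subject_id``/``side`` are not given they are parsed from a filename
    of the form ``<subject>_<left|right>.csv``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["time_s", "heel", "met1", "met5"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"{path}: expected columns {required}, got {list(df.columns)}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer sampling rate")
    t = df["time_s"].to_numpy(float)
    steps = np.diff(t)
    step = float(np.median(steps))
    if step <= 0:
        raise FormatError(f"{path}: time_s must be strictly increasing")
    if np.any(np.abs(steps - step) > 0.01 * step):
        raise FormatError(f"{path}: irregular time step (beyond 1% tolerance)")
    for col in ("heel", "met1", "met5"):
        if not df[col].isin([0, 1]).all():
            raise FormatError(f"{path}: column {col} contains non-binary values")
    if subject_id is None or side is None:
        m = re.match(r"(?P<sid>.+)_(?P<side>left|right)$", path.stem)
        if m:
            subject_id = subject_id or m.group("sid")
            side = side or m.group("side")
        else:
            subject_id = subject_id or path.stem
            side = side or "left"
    return SwitchRecording(
        subject_id=subject_id,
        side=side,
        sampling_rate=1.0 / step,
        heel=df["heel"].to_numpy(),
        met1=df["met1"].to_numpy(),
        met5=df["met5"].to_numpy(),
    )


def write_switch_csv(rec: SwitchRecording, path: str | Path) -> None:
    t = np.arange(rec.n_samples) / rec.sampling_rate
    df = pd.DataFrame(
        {"time_s": t, "heel": rec.heel, "met1": rec.met1, "met5": rec.met5}
    )
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read an annotation CSV (rows ``start_s,end_s,label``).

    ``label`` is ``straight``, ``turn`` or ``passage``.  The walkway length
    is carried in a ``# path_length_m: <value>`` comment line.
    """
    path = Path(path)
    path_length = 9.0
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#"):
            m = re.search(r"path_length_m\s*[:=]\s*([\d.]+)", line)
            if m:
                path_length = float(m.group(1))
    from io import StringIO

    df = pd.read_csv(StringIO(text), comment="#")
    intervals: list[tuple[float, float, str]] = []
    passages: list[tuple[float, float]] = []
    for _, row in df.iterrows():
        lab = str(row["label"]).strip()
        if lab == "passage":
            passages.append((float(row["start_s"]), float(row["end_s"])))
        elif lab in ("straight", "turn"):
            intervals.append((float(row["start_s"]), float(row["end_s"]), lab))
        else:
            raise FormatError(f"{path}: unknown label {lab!r}")
    return AnnotationTrack(
        intervals=intervals, passages=passages, path_length_m=path_length
    )


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    rows = [
        {"start_s": s, "end_s": e, "label": lab} for s, e, lab in track.intervals
    ] + [{"start_s": s, "end_s": e, "label": "passage"} for s, e in track.passages]
    df = pd.DataFrame(rows, columns=["start_s", "end_s", "label"])
    with open(path, "w") as fh:
        fh.write(f"# path_length_m: {track.path_length_m}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# cohort metadata


def write_metadata(metas: list[SubjectMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        rows.append(
            {
                "subject_id": m.subject_id,
                "group": m.group,
                "left_role": m.side_roles["left"],
                "right_role": m.side_roles["right"],
                "updrs3": m.updrs3 if m.updrs3 is not None else "",
                "hoehn_yahr": m.hoehn_yahr if m.hoehn_yahr is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path: str | Path) -> list[SubjectMeta]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    metas = []
    for _, row in df.iterrows():
        updrs = row.get("updrs3")
        hy = row.get("hoehn_yahr")
        metas.append(
            SubjectMeta(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                side_roles={
                    "left": str(row["left_role"]),
                    "right": str(row["right_role"]),
                },
                updrs3=None if pd.isna(updrs) else float(updrs),
                hoehn_yahr=None if pd.isna(hy) else float(hy),
            )
        )
    return metas


# ---------------------------------------------------------------------------
# cohort result tables


def write_cohort_tables(table, out_dir: str | Path) -> list[Path]:
    """Write per-group summary tables (spatio-temporal + atypical regions).

    ``table`` is a :class:`footsga.gait_parameters.CohortTable`.  Two CSVs
    are produced: ``table_parameters.csv`` (speed, cadence, double support,
    cycle counts, phase durations, atypical percentage) and
    ``table_regions.csv`` (straight/turn atypical percentages).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if table.parameters.empty:
        raise ValueError("empty cohort: nothing to write")
    paths = []
    for name, df in (
        ("table_parameters.csv", table.parameters),
        ("table_regions.csv", table.regions),
    ):
        p = out_dir / name
        df.to_csv(p, index=True, float_format="%.4f")
        paths.append(p)
    return paths


def read_cohort_tables(out_dir: str | Path):
    from .gait_parameters import CohortTable

    out_dir = Path(out_dir)
    return CohortTable(
        parameters=pd.read_csv(out_dir / "table_parameters.csv", index_col=0),
        regions=pd.read_csv(out_dir / "table_regions.csv", index_col=0),
    )
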