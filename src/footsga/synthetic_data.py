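"""Synthetic foot-switch cohorts with known ground truth.

The generator emulates the acquisition protocol the analysis assumes:
each subject walks back and forth over a 9-m straight walkway for about
5 minutes, alternating straight segments (duration = path length /
speed) and ~2-s U-turns.  Both feet carry heel / 1st- / 5th-metatarsal
switches sampled at 2 kHz.  Every gait cycle is assigned a foot-floor
contact class (HFPS or an atypical class: PFPS, PS, FPS, HFHFPS,
"other") drawn from a region- and side-role-specific mixture, realized
as phase runs from a Dirichlet-jittered phase-fraction profile, and
converted back to switch channels that satisfy the 4-phase truth table
at every sample.  Switch-bounce noise is injected as sub-threshold
toggles; the right foot is phase-shifted by half a stride so that
double support emerges from the overlap of the two stance phases.

Atypicality is modelled as a subject-level trait with two strata: a
"mild" majority whose atypical-cycle rates are low and right-skewed
(lognormal), and a "severe" minority (default 40% of patients) with
high rates (truncated normal).  Stratum means are constrained so the
mixture reproduces the configured per-region group means.  A motor
score (UPDRS-III-like) is linked linearly to the speed-normalized
atypical percentage of the more-affected side, with noisier scores in
the mild stratum - in mildly impaired patients the motor score is
dominated by non-gait symptoms, in severely impaired ones it tracks
gait quality closely.

Every draw flows from one seed; the same seed reproduces the cohort
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationTrack,
    SubjectMeta,
    SwitchRecording,
    write_annotations,
    write_metadata,
    write_switch_csv,
)
from .preprocess import DEFAULT_DEBOUNCE_S, run_length_encode

__all__ = ["SynthConfig", "SubjectData", "CohortData", "generate_subject",
           "generate_cohort", "sample_cohort_truth"]

ATYPICAL_CLASSES = ("PFPS", "PS", "FPS", "HFHFPS", "other")


def _default_phase_profiles():
    # typical-cycle phase durations (H, F, P, S) in %GC per group-side
    return {
        ("PD", "more_affected"): (9.6, 20.3, 25.5, 44.6),
        ("PD", "less_affected"): (9.1, 22.2, 24.7, 44.0),
        ("control", "dominant"): (7.1, 25.0, 24.4, 43.4),
        ("control", "non_dominant"): (9.9, 24.9, 22.8, 42.3),
    }


def _default_class_shares():
    # share of each atypical class among a side's atypical cycles
    return {
        ("PD", "more_affected"): {
            "PFPS": 0.264, "PS": 0.240, "FPS": 0.223, "HFHFPS": 0.174, "other": 0.099,
        },
        ("PD", "less_affected"): {
            "PFPS": 0.374, "PS": 0.129, "FPS": 0.224, "HFHFPS": 0.174, "other": 0.099,
        },
        ("control", "dominant"): {
            "PFPS": 0.457, "PS": 0.049, "FPS": 0.222, "HFHFPS": 0.173, "other": 0.099,
        },
        ("control", "non_dominant"): {
            "PFPS": 0.307, "PS": 0.125, "FPS": 0.256, "HFHFPS": 0.199, "other": 0.113,
        },
    }


def _default_atypical_pct():
    """Per-stratum (mean, sd) of atypical cycles as % of ALL cycles.

    Keyed (group, role, region, stratum).  PD stratum means obey
    0.6 * mild + 0.4 * severe = group target.  Straight-walk atypicality
    is the severity marker (heavily concentrated in the severe stratum,
    matching its large group SD); turn atypicality is only mildly
    stratified (its group SD is small) and its severe-stratum mean is
    kept below the share of cycles spent turning, which bounds what any
    subject can physically express.
    """
    return {
        ("PD", "more_affected", "straight", "mild"): (1.5, 1.5),
        ("PD", "more_affected", "turn", "mild"): (5.5, 2.5),
        ("PD", "more_affected", "straight", "severe"): (28.5, 12.0),
        ("PD", "more_affected", "turn", "severe"): (20.5, 4.0),
        ("PD", "less_affected", "straight", "mild"): (0.8, 0.8),
        ("PD", "less_affected", "turn", "mild"): (5.0, 2.5),
        ("PD", "less_affected", "straight", "severe"): (10.8, 6.0),
        ("PD", "less_affected", "turn", "severe"): (19.25, 4.0),
        ("control", "dominant", "straight", "mild"): (2.0, 2.5),
        ("control", "dominant", "turn", "mild"): (6.1, 4.1),
        ("control", "non_dominant", "straight", "mild"): (2.5, 3.4),
        ("control", "non_dominant", "turn", "mild"): (6.3, 3.0),
    }


@dataclass
class SynthConfig:
    """All knobs of the synthetic cohort; defaults emulate the target study."""

    n_pd: int = 20
    n_control: int = 20
    recording_minutes: float = 5.0
    sampling_rate: float = 2000.0
    path_length_m: float = 9.0
    # self-selected straight-walk speed (m/s) per group
    speed_mean: dict = field(default_factory=lambda: {"PD": 1.01, "control": 1.08})
    speed_sd: dict = field(default_factory=lambda: {"PD": 0.25, "control": 0.17})
    # cadence (cycles/min) per group; stride period = 60 / cadence
    cadence_mean: dict = field(default_factory=lambda: {"PD": 55.7, "control": 54.6})
    cadence_sd: dict = field(default_factory=lambda: {"PD": 5.9, "control": 3.3})
    stride_cv: float = 0.03
    straight_jitter_cv: float = 0.03
    turn_duration_s: float = 3.0
    turn_duration_sd: float = 0.5
    phase_profiles: dict = field(default_factory=_default_phase_profiles)
    # between-subject spread of the phase profile (Dirichlet concentration
    # around the group profile; ~120 gives 3-4 %GC SD across subjects)
    subject_phase_concentration: float = 120.0
    # within-subject cycle-to-cycle spread around the subject profile
    phase_concentration: float = 300.0
    severe_fraction: float = 0.40
    # within-subject coupling of a control's atypicality across sides and
    # regions: a shared lognormal multiplier (mean 1) with this CV
    control_subject_cv: float = 0.70
    atypical_pct: dict = field(default_factory=_default_atypical_pct)
    class_shares: dict = field(default_factory=_default_class_shares)
    bounce_rate_hz: float = 2.0
    max_bounce_s: float = 0.015
    bounce_guard_s: float = DEFAULT_DEBOUNCE_S
    hard_noise: bool = False
    ds_phase_shift: float = 0.5
    pd_more_affected_right_frac: float = 0.45   # 9 of 20
    control_dominant_right_frac: float = 0.90   # 18 of 20
    updrs_intercept: float = 12.4
    updrs_slope: float = 0.2
    updrs_noise_sd: dict = field(
        default_factory=lambda: {"mild": 7.5, "severe": 2.0}
    )
    seed: int = 0

    def roles(self, group: str) -> tuple[str, str]:
        return (
            ("more_affected", "less_affected")
            if group == "PD"
            else ("dominant", "non_dominant")
        )


@dataclass
class SubjectData:
    meta: SubjectMeta
    left: SwitchRecording
    right: SwitchRecording
    track: AnnotationTrack
    cycles: pd.DataFrame          # injected per-cycle truth
    truth: dict                   # subject-level truth (speed, strata, rates)


@dataclass
class CohortData:
    subjects: list[SubjectData]
    metas: list[SubjectMeta]
    truth_subjects: pd.DataFrame
    truth_cycles: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sub in self.subjects:
            sid = sub.meta.subject_id
            write_switch_csv(sub.left, out_dir / f"{sid}_left.csv")
            write_switch_csv(sub.right, out_dir / f"{sid}_right.csv")
            write_annotations(sub.track, out_dir / f"{sid}_annotations.csv")
        write_metadata(self.metas, out_dir / "metadata.csv")
        self.truth_subjects.to_csv(out_dir / "truth_subjects.csv", index=False)
        self.truth_cycles.to_csv(out_dir / "truth_cycles.csv", index=False)


# ---------------------------------------------------------------------------
# elementary draws


def _lognormal(rng, mean, sd, size=None):
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if sd <= 0:
        return np.full(size, float(mean)) if size else float(mean)
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2), size)

def _trunc_normal(rng, mean, sd, lo=0.0):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lo:
            return x
    return lo


def _draw_pct(
    rng, mean_sd: tuple[float, float], stratum: str, subject_factor: float = 1.0,
    factor_cv: float = 0.0,
) -> float:
    """Severity component draw: lognormal (mild), truncated normal (severe).

    A subject-level multiplier (mean 1, CV ``factor_cv``) can couple a
    subject's components; the residual per-component CV is reduced so
    the marginal mean and SD still match ``mean_sd``.
    """
    mean, sd = mean_sd
    if stratum == "severe":
        return _trunc_normal(rng, mean, sd)
    if factor_cv > 0:
        cv = sd / mean
        cv_r = np.sqrt(max((1 + cv**2) / (1 + factor_cv**2) - 1.0, 0.0))
        return float(subject_factor * _lognormal(rng, mean, mean * cv_r))
    return float(_lognormal(rng, mean, sd))


# ---------------------------------------------------------------------------
# cycle realization


def _partition(m: int, weights) -> np.ndarray:
    """Split m samples into len(weights) integer runs (each >= 1 sample)."""
    w = np.asarray(weights, float)
    if m < len(w):
        raise ValueError("cycle too short for its phase sequence")
    edges = np.floor(np.cumsum(w / w.sum()) * m + 0.5).astype(int)
    edges[-1] = m
    lens = np.diff(np.concatenate(([0], edges)))
    while (lens < 1).any():
        lens[int(np.argmin(lens))] += 1
        lens[int(np.argmax(lens))] -= 1
    return lens


def _other_sequence(rng) -> str:
    """A random legal contact sequence != HFPS (contact phases then swing)."""
    while True:
        length = int(rng.integers(2, 6))
        seq = [str(rng.choice(["H", "F", "P"]))]
        while len(seq) < length:
            nxt = str(rng.choice(["H", "F", "P"]))
            if nxt != seq[-1]:
                seq.append(nxt)
        s = "".join(seq) + "S"
        if s != "HFPS":
            return s


def _realize_runs(label: str, fracs, rng) -> list[tuple[str, float]]:
    """Phase sequence of a class with fractions of the cycle per run.

    ``fracs`` are the typical-profile fractions (h, f, p, s); classes
    missing a phase redistribute its mass onto their own stance runs
    (e.g. PS puts the whole stance on the forefoot).
    """
    h, f, p, s = fracs
    if label == "HFPS":
        return [("H", h), ("F", f), ("P", p), ("S", s)]
    if label == "PFPS":
        return [("P", h), ("F", f), ("P", p), ("S", s)]
    if label == "PS":
        return [("P", h + f + p), ("S", s)]
    if label == "FPS":
        return [("F", h + f), ("P", p), ("S", s)]
    if label == "HFHFPS":
        return [("H", h / 2), ("F", f / 2), ("H", h / 2), ("F", f / 2),
                ("P", p), ("S", s)]
    # open-vocabulary class: random split of the stance mass
    stance_letters = label[:-1]
    k = len(stance_letters)
    split = rng.dirichlet(np.full(k, 5.0)) * (h + f + p)
    return [(ph, float(w)) for ph, w in zip(stance_letters, split)] + [("S", s)]


# ---------------------------------------------------------------------------
# per-subject synthesis


def _plan_segments(rng, cfg: SynthConfig, speed: float, total_s: float):
    segs = []
    t = 0.0
    lab = "straight"
    while t < total_s - 1e-9:
        if lab == "straight":
            nominal = cfg.path_length_m / speed
            dur = max(nominal * (1.0 + cfg.straight_jitter_cv * rng.standard_normal()),
                      0.5 * nominal)
        else:
            dur = max(rng.normal(cfg.turn_duration_s, cfg.turn_duration_sd), 0.8)
        end = min(t + dur, total_s)
        segs.append((t, end, lab, bool(end == t + dur)))
        t = end
        lab = "turn" if lab == "straight" else "straight"
    return segs


def _region_lookup(segs):
    starts = np.array([s for s, _, _, _ in segs])
    labels = [lab for _, _, lab, _ in segs]

    def lookup(t: float) -> str:
        i = int(np.searchsorted(starts, t, side="right")) - 1
        return labels[max(i, 0)]

    return lookup


def _gen_side_labels(rng, cfg, group, role, stratum, segs, stride_seq, t0,
                     total_s, fs, n_samples, subject_factor=1.0):
    """Phase-label array plus per-cycle truth rows for one side.

    ``stride_seq`` is the subject's shared stride-period sequence; both
    sides walk to the same rhythm (offset by the double-support phase
    shift) so stance overlap stays physiological instead of drifting.
    """
    region_of = _region_lookup(segs)
    share = {
        "straight": sum(e - s for s, e, lab, _ in segs if lab == "straight") / total_s,
    }
    share["turn"] = 1.0 - share["straight"]
    factor_cv = cfg.control_subject_cv if group == "control" else 0.0
    targets = {
        reg: _draw_pct(
            rng, cfg.atypical_pct[(group, role, reg, stratum)], stratum,
            subject_factor=subject_factor, factor_cv=factor_cv,
        )
        for reg in ("straight", "turn")
    }
    p_cond = {
        reg: float(np.clip((targets[reg] / 100.0) / max(share[reg], 0.02), 0.0, 0.95))
        for reg in ("straight", "turn")
    }
    shares = cfg.class_shares[(group, role)]
    class_names = list(shares)
    class_p = np.array([shares[c] for c in class_names], float)
    class_p /= class_p.sum()
    profile = np.asarray(cfg.phase_profiles[(group, role)], float)
    profile = profile / profile.sum()
    subj_profile = rng.dirichlet(cfg.subject_phase_concentration * profile)
    subj_profile = np.clip(subj_profile, 0.02, None)
    alpha = cfg.phase_concentration * subj_profile / subj_profile.sum()

    labels = np.full(n_samples, "S", dtype="<U1")
    rows = []
    t = t0
    for T_i in stride_seq:
        if t + T_i + 0.35 >= total_s:
            break
        region = region_of(t)
        if rng.random() < p_cond[region]:
            label = str(rng.choice(class_names, p=class_p))
            if label == "other":
                label = _other_sequence(rng)
        else:
            label = "HFPS"
        fracs = rng.dirichlet(alpha)
        runs = _realize_runs(label, fracs, rng)
        s0 = int(round(t * fs))
        s1 = int(round((t + T_i) * fs))
        lens = _partition(s1 - s0, [w for _, w in runs])
        pos = s0
        for (ph, _), ln in zip(runs, lens):
            labels[pos:pos + ln] = ph
            pos += ln
        rows.append({
            "start_s": s0 / fs, "end_s": s1 / fs, "class_label": label,
            "region": region, "is_typical": label == "HFPS",
        })
        t += T_i
    if rows:
        # closing contact so the final cycle has a terminating onset
        s_end = int(round(rows[-1]["end_s"] * fs))
        term = int(round(0.15 * fs))
        labels[s_end:min(s_end + term, n_samples)] = "H"
    return labels, rows, targets


_F_PATTERNS = [(1, 0), (0, 1), (1, 1)]
_F_PROBS = [0.4, 0.2, 0.4]
_P_PROBS = [0.3, 0.3, 0.4]


def _switches_from_phases(rng, labels: np.ndarray):
    """Switch channels consistent with the phase truth table at each sample."""
    n = len(labels)
    heel = np.zeros(n, np.int8)
    met1 = np.zeros(n, np.int8)
    met5 = np.zeros(n, np.int8)
    vals, starts, lens = run_length_encode(labels)
    for v, s, ln in zip(vals, starts, lens):
        sl = slice(s, s + ln)
        if v == "H":
            heel[sl] = 1
        elif v == "F":
            heel[sl] = 1
            m1, m5 = _F_PATTERNS[rng.choice(3, p=_F_PROBS)]
            met1[sl], met5[sl] = m1, m5
        elif v == "P":
            m1, m5 = _F_PATTERNS[rng.choice(3, p=_P_PROBS)]
            met1[sl], met5[sl] = m1, m5
    return heel, met1, met5


def _inject_bounce(rng, cfg, channels, labels, fs, total_s):
    """Flip short windows on random channels, clear of real transitions.

    In the default mode every artifact is strictly shorter than the
    debounce guard and at least one guard away from any phase
    transition and from other artifacts, so debouncing removes it
    exactly.  ``hard_noise`` drops those safeguards (robustness testing).
    """
    if cfg.bounce_rate_hz <= 0:
        return
    min_samples = int(np.ceil(cfg.bounce_guard_s * fs - 1e-9))
    if min_samples < 2 and not cfg.hard_noise:
        return
    n_ev = rng.poisson(cfg.bounce_rate_hz * total_s)
    if n_ev == 0:
        return
    starts_t = np.sort(rng.uniform(0.0, total_s, n_ev))
    durs_t = rng.uniform(1.0 / fs, max(cfg.max_bounce_s, 1.5 / fs), n_ev)
    chans = rng.integers(0, 3, n_ev)
    _, tr_starts, _ = run_length_encode(labels)
    trans_t = tr_starts[1:] / fs
    guard = cfg.bounce_guard_s
    last_end = -np.inf
    for u, d, ci in zip(starts_t, durs_t, chans):
        if not cfg.hard_noise:
            j = np.searchsorted(trans_t, u)
            near = min(
                (u - trans_t[j - 1]) if j > 0 else np.inf,
                (trans_t[j] - (u + d)) if j < len(trans_t) else np.inf,
            )
            if near < guard or u < guard or u + d > total_s - guard:
                continue
            if u - last_end < 2 * guard:
                continue
        a = int(round(u * fs))
        if cfg.hard_noise:
            ds = max(1, int(round(d * fs)))
        else:
            ds = int(np.clip(round(d * fs), 1, min_samples - 1))
        ch = channels[ci]
        ch[a:a + ds] ^= 1
        last_end = u + d


def generate_subject(
    cfg: SynthConfig,
    meta: SubjectMeta,
    rng: np.random.Generator | None = None,
    severe: bool = False,
) -> SubjectData:
    """Synthesize one subject's bilateral recording, annotations and truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    total_s = cfg.recording_minutes * 60.0
    n_samples = int(round(total_s * fs))
    group = meta.group
    stratum = "severe" if (group == "PD" and severe) else "mild"

    speed = max(rng.normal(cfg.speed_mean[group], cfg.speed_sd[group]), 0.4)
    cad = max(rng.normal(cfg.cadence_mean[group], cfg.cadence_sd[group]), 30.0)
    stride_s = 60.0 / cad
    segs = _plan_segments(rng, cfg, speed, total_s)
    t0 = 0.3 + rng.uniform(0.0, 0.2)
    t0_side = {"left": t0, "right": t0 + cfg.ds_phase_shift * stride_s}
    n_strides = int(np.ceil(total_s / (0.5 * stride_s))) + 2
    stride_seq = stride_s * np.maximum(
        1.0 + cfg.stride_cv * rng.standard_normal(n_strides), 0.5
    )

    subject_factor = (
        float(_lognormal(rng, 1.0, cfg.control_subject_cv))
        if (group == "control" and cfg.control_subject_cv > 0) else 1.0
    )
    recs, all_rows, side_targets = {}, [], {}
    for side in ("left", "right"):
        role = meta.side_roles[side]
        labels, rows, targets = _gen_side_labels(
            rng, cfg, group, role, stratum, segs, stride_seq,
            t0_side[side], total_s, fs, n_samples, subject_factor=subject_factor,
        )
        heel, met1, met5 = _switches_from_phases(rng, labels)
        _inject_bounce(rng, cfg, [heel, met1, met5], labels, fs, total_s)
        recs[side] = SwitchRecording(
            subject_id=meta.subject_id, side=side, sampling_rate=fs,
            heel=heel, met1=met1, met5=met5,
        )
        for r in rows:
            r["side"] = side
            r["role"] = role
        all_rows.extend(rows)
        side_targets[role] = targets

    track = AnnotationTrack(
        intervals=[(s, e, lab) for s, e, lab, _ in segs],
        passages=[(s, e) for s, e, lab, full in segs if lab == "straight" and full],
        path_length_m=cfg.path_length_m,
    )
    cyc = pd.DataFrame(all_rows)
    truth = {
        "subject_id": meta.subject_id,
        "group": group,
        "stratum": stratum,
        "speed": speed,
        "cadence": cad,
    }
    for role, targets in side_targets.items():
        sub = cyc[cyc["role"] == role]
        realized = 100.0 * (~sub["is_typical"]).mean() if len(sub) else np.nan
        truth[f"target_straight_pct_{role}"] = targets["straight"]
        truth[f"target_turn_pct_{role}"] = targets["turn"]
        truth[f"realized_atypical_pct_{role}"] = realized
        truth[f"n_cycles_{role}"] = len(sub)
    return SubjectData(
        meta=meta, left=recs["left"], right=recs["right"],
        track=track, cycles=cyc, truth=truth,
    )


# ---------------------------------------------------------------------------
# cohort


def _make_metas(cfg: SynthConfig, rng: np.random.Generator) -> tuple[list[SubjectMeta], np.ndarray]:
    metas = []
    k_right = int(round(cfg.pd_more_affected_right_frac * cfg.n_pd))
    right_first = rng.permutation(cfg.n_pd) < k_right
    for i in range(cfg.n_pd):
        major, minor = ("right", "left") if right_first[i] else ("left", "right")
        metas.append(SubjectMeta(
            subject_id=f"PD{i + 1:02d}", group="PD",
            side_roles={major: "more_affected", minor: "less_affected"},
        ))
    k_dom = int(round(cfg.control_dominant_right_frac * cfg.n_control))
    dom_right = rng.permutation(cfg.n_control) < k_dom
    for i in range(cfg.n_control):
        major, minor = ("right", "left") if dom_right[i] else ("left", "right")
        metas.append(SubjectMeta(
            subject_id=f"CT{i + 1:02d}", group="control",
            side_roles={major: "dominant", minor: "non_dominant"},
        ))
    k_sev = int(round(cfg.severe_fraction * cfg.n_pd))
    severe = rng.permutation(cfg.n_pd) < k_sev
    return metas, severe


def generate_cohort(
    cfg: SynthConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> CohortData:
    """Synthesize the full cohort; optionally write all CSV artifacts."""
    if cfg.n_pd + cfg.n_control == 0:
        raise ValueError("cohort must contain at least one subject")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    metas, severe = _make_metas(cfg, rng)
    child_rngs = rng.spawn(len(metas))
    subjects = []
    for i, (meta, srng) in enumerate(zip(metas, child_rngs)):
        is_severe = bool(severe[i]) if meta.group == "PD" else False
        sub = generate_subject(cfg, meta, rng=srng, severe=is_severe)
        if meta.group == "PD":
            atyp = sub.truth["realized_atypical_pct_more_affected"] / sub.truth["speed"]
            noise_sd = cfg.updrs_noise_sd[sub.truth["stratum"]]
            updrs = cfg.updrs_intercept + cfg.updrs_slope * atyp + rng.normal(0, noise_sd)
            meta.updrs3 = float(np.round(max(updrs, 0.0)))
            sub.truth["atyp_true"] = atyp
            sub.truth["updrs3"] = meta.updrs3
        subjects.append(sub)
    truth_subjects = pd.DataFrame([s.truth for s in subjects])
    truth_cycles = pd.concat(
        [s.cycles.assign(subject_id=s.meta.subject_id) for s in subjects],
        ignore_index=True,
    )
    cohort = CohortData(
        subjects=subjects, metas=metas,
        truth_subjects=truth_subjects, truth_cycles=truth_cycles,
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def sample_cohort_truth(cfg: SynthConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw subject-level truth only (no signal synthesis).

    Uses the same severity, speed and motor-score models as the full
    generator; per-side atypical percentages are the drawn stratum
    targets (straight + turn).  Intended for fast statistical
    calibration over many replicate cohorts.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k_sev = int(round(cfg.severe_fraction * cfg.n_pd))
    severe = rng.permutation(cfg.n_pd) < k_sev
    rows = []
    for group, n in (("PD", cfg.n_pd), ("control", cfg.n_control)):
        for i in range(n):
            stratum = "severe" if (group == "PD" and severe[i]) else "mild"
            speed = max(rng.normal(cfg.speed_mean[group], cfg.speed_sd[group]), 0.4)
            factor_cv = cfg.control_subject_cv if group == "control" else 0.0
            factor = (
                float(_lognormal(rng, 1.0, factor_cv)) if factor_cv > 0 else 1.0
            )
            row = {"group": group, "stratum": stratum, "speed": speed}
            for role in cfg.roles(group):
                total = sum(
                    _draw_pct(
                        rng, cfg.atypical_pct[(group, role, reg, stratum)], stratum,
                        subject_factor=factor, factor_cv=factor_cv,
                    )
                    for reg in ("straight", "turn")
                )
                row[f"pct_atypical_{role}"] = total
            if group == "PD":
                atyp = row["pct_atypical_more_affected"] / speed
                noise = cfg.updrs_noise_sd[stratum]
                row["atyp"] = atyp
                row["updrs3"] = max(
                    cfg.updrs_intercept + cfg.updrs_slope * atyp + rng.normal(0, noise),
                    0.0,
                )
            else:
                row["atyp"] = (
                    (row["pct_atypical_dominant"] + row["pct_atypical_non_dominant"]) / 2.0
                ) / speed
            rows.append(row)
    return pd.DataFrame(rows)
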