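import dataclasses

import numpy as np
import pandas as pd
import pytest

from footsga import (
    SynthConfig,
    analyze_subject_data,
    generate_cohort,
    generate_subject,
    sample_cohort_truth,
    segment_cycles,
)
from footsga.preprocess import encode_phases, to_phase_signal
from footsga.synthetic_data import _make_metas, _partition


def small_cfg(**kw):
    base = dict(n_pd=2, n_control=2, recording_minutes=0.6,
                sampling_rate=200.0, seed=3)
    base.update(kw)
    return SynthConfig(**base)


def one_subject(cfg, severe=False, subject=0):
    rng = np.random.default_rng(cfg.seed)
    metas, _ = _make_metas(cfg, rng)
    return generate_subject(cfg, metas[subject], rng=rng.spawn(1)[0], severe=severe)


def test_same_seed_reproduces_identical_files(tmp_path):
    cfg = small_cfg(n_pd=1, n_control=1)
    generate_cohort(cfg, out_dir=tmp_path / "a")
    generate_cohort(cfg, out_dir=tmp_path / "b")
    for name in ("PD01_left.csv", "CT01_right.csv", "PD01_annotations.csv",
                 "metadata.csv", "truth_cycles.csv"):
        assert (tmp_path / "a" / name).read_bytes() == \
               (tmp_path / "b" / name).read_bytes()


def test_noise_free_signal_encodes_to_injected_phases_exactly():
    """With zero bounce the raw channels already satisfy the truth table."""
    cfg = small_cfg(bounce_rate_hz=0.0)
    sub = one_subject(cfg, severe=True)
    for rec in (sub.left, sub.right):
        sig = encode_phases(rec)  # no debouncing at all
        cycles = segment_cycles(sig, max_cycle_s=3.0)
        truth = sub.cycles[sub.cycles["side"] == rec.side].reset_index(drop=True)
        assert len(cycles) == len(truth)
        assert [c.class_label for c in cycles] == truth["class_label"].tolist()
        starts = [c.start_s for c in cycles]
        assert starts == pytest.approx(truth["start_s"].tolist())


def test_bounce_noise_is_fully_removed_by_debouncing():
    """Sub-threshold bounce leaves end-to-end class recovery exact."""
    cfg = small_cfg(bounce_rate_hz=5.0, sampling_rate=500.0)
    sub = one_subject(cfg, severe=True)
    for rec in (sub.left, sub.right):
        raw_cycles = segment_cycles(encode_phases(rec))
        truth = sub.cycles[sub.cycles["side"] == rec.side]
        # bounce corrupts the raw stream for this check to be non-trivial
        sig = to_phase_signal(rec, cfg.bounce_guard_s)
        cycles = segment_cycles(sig)
        assert [c.class_label for c in cycles] == truth["class_label"].tolist()
    assert raw_cycles is not None


def test_class_share_recovery_within_binomial_bounds():
    """An injected forefoot-strike (PS) share is recovered at binomial accuracy."""
    from scipy.stats import binom

    share = 0.25
    cfg = small_cfg(
        n_pd=1, n_control=0, recording_minutes=5.0, sampling_rate=200.0,
        atypical_pct={
            (g, r, reg, s): (12.5, 0.0)
            for g in ("PD",) for r in ("more_affected", "less_affected")
            for reg in ("straight", "turn") for s in ("mild", "severe")
        },
        class_shares={
            (g, r): {"PS": 1.0}
            for g in ("PD",) for r in ("more_affected", "less_affected")
        },
    )
    sub = one_subject(cfg)
    res, cyc = analyze_subject_data(sub.left, sub.right, sub.track, sub.meta)
    n = len(cyc)
    k = (cyc["class_label"] == "PS").sum()
    assert (cyc["class_label"].isin(["HFPS", "PS"])).all()
    lo, hi = binom.ppf([0.005, 0.995], n, share)
    assert lo <= k <= hi


def test_recovered_rates_approach_injected_with_more_cycles():
    """|realized - injected| atypical rate shrinks as the walk lengthens."""
    errs = []
    for minutes in (0.6, 2.5, 10.0):
        cfg = small_cfg(
            n_pd=1, n_control=0, recording_minutes=minutes,
            atypical_pct={
                (g, r, reg, s): (10.0, 0.0)
                for g in ("PD",) for r in ("more_affected", "less_affected")
                for reg in ("straight", "turn") for s in ("mild", "severe")
            },
        )
        per_subject = []
        for seed in range(6):
            sub = one_subject(dataclasses.replace(cfg, seed=seed))
            for role in ("more_affected", "less_affected"):
                per_subject.append(
                    abs(sub.truth[f"realized_atypical_pct_{role}"] - 20.0)
                )
        errs.append(np.mean(per_subject))
    assert errs[-1] < errs[0]


def test_cycle_count_and_cadence_scale():
    """A 5-min walk yields a few hundred cycles per side, stride ~1.1 s."""
    cfg = small_cfg(n_pd=1, n_control=1, recording_minutes=5.0,
                    sampling_rate=200.0)
    sub = one_subject(cfg)
    for role in ("more_affected", "less_affected"):
        assert 180 <= sub.truth[f"n_cycles_{role}"] <= 380


def test_sampling_rate_invariance():
    """The same seed gives the same walk at 500 Hz and 1 kHz."""
    subs = {}
    for fs in (500.0, 1000.0):
        cfg = small_cfg(n_pd=1, n_control=0, recording_minutes=1.0,
                        sampling_rate=fs, bounce_rate_hz=0.0)
        sub = one_subject(cfg)
        res, _ = analyze_subject_data(sub.left, sub.right, sub.track, sub.meta)
        subs[fs] = (sub, res)
    a, ra = subs[500.0]
    b, rb = subs[1000.0]
    assert len(a.cycles) == len(b.cycles)
    assert a.cycles["class_label"].tolist() == b.cycles["class_label"].tolist()
    assert ra.speed == pytest.approx(rb.speed, rel=1e-6)
    for role in ra.sides:
        assert ra.sides[role].cadence == pytest.approx(rb.sides[role].cadence,
                                                       rel=1e-6)
        assert ra.sides[role].pct_atypical == pytest.approx(
            rb.sides[role].pct_atypical
        )


def test_side_role_assignment_fractions():
    cfg = SynthConfig(n_pd=20, n_control=20, seed=0)
    metas, severe = _make_metas(cfg, np.random.default_rng(0))
    pd_right = sum(
        1 for m in metas if m.group == "PD" and m.side_roles["right"] == "more_affected"
    )
    ctl_right = sum(
        1 for m in metas
        if m.group == "control" and m.side_roles["right"] == "dominant"
    )
    assert pd_right == 9
    assert ctl_right == 18
    assert severe.sum() == 8


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        generate_cohort(SynthConfig(n_pd=0, n_control=0))


def test_truth_only_sampler_matches_generator_moments():
    """The fast truth path reproduces the configured group-level rates."""
    cfg = SynthConfig()
    tr = pd.concat(
        [sample_cohort_truth(cfg, seed=s) for s in range(40)], ignore_index=True
    )
    pd_rows = tr[tr["group"] == "PD"]
    ctl = tr[tr["group"] == "control"]
    assert pd_rows["pct_atypical_more_affected"].mean() == pytest.approx(23.8, abs=1.5)
    assert pd_rows["pct_atypical_less_affected"].mean() == pytest.approx(15.5, abs=1.2)
    assert ctl["pct_atypical_dominant"].mean() == pytest.approx(8.1, abs=1.0)
    assert ctl["pct_atypical_non_dominant"].mean() == pytest.approx(8.8, abs=1.0)
    assert (tr[tr["group"] == "PD"]["updrs3"] >= 0).all()


def test_partition_gives_positive_runs_summing_to_total():
    lens = _partition(23, [0.05, 0.2, 0.25, 0.5])
    assert lens.sum() == 23 and (lens >= 1).all()
    lens = _partition(4, [0.001, 0.001, 0.001, 0.997])
    assert lens.sum() == 4 and (lens >= 1).all()
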