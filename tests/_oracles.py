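"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np


def rle(x):
    """Run-length encoding: list of (value, start, length)."""
    x = np.asarray(x)
    if len(x) == 0:
        return []
    starts = np.concatenate(([0], np.flatnonzero(x[1:] != x[:-1]) + 1))
    ends = np.concatenate((starts[1:], [len(x)]))
    return [(x[s], int(s), int(e - s)) for s, e in zip(starts, ends)]


def debounce_oracle(x, min_samples):
    """Fixpoint run-merge by repeated full re-scan.

    Each iteration finds the shortest interior run strictly shorter than
    ``min_samples`` (earliest on ties) and overwrites it with the value
    of the preceding run, until no such run remains.
    """
    x = np.asarray(x).copy()
    while True:
        runs = rle(x)
        candidates = [
            (length, start, k)
            for k, (_, start, length) in enumerate(runs)
            if 0 < k < len(runs) - 1 and length < min_samples
        ]
        if not candidates:
            return x
        _, start, k = min(candidates)
        prev_val = runs[k - 1][0]
        x[start:start + runs[k][2]] = prev_val


def anova_ss_oracle(values, group, side):
    """Cell-means sums of squares for a balanced two-way layout."""
    values = np.asarray(values, float)
    group = np.asarray(group)
    side = np.asarray(side)
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    ss_group = sum(
        (values[group == g]).size * (values[group == g].mean() - grand) ** 2
        for g in np.unique(group)
    )
    ss_side = sum(
        (values[side == s]).size * (values[side == s].mean() - grand) ** 2
        for s in np.unique(side)
    )
    ss_cells = 0.0
    ss_error = 0.0
    for g in np.unique(group):
        for s in np.unique(side):
            cell = values[(group == g) & (side == s)]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
            ss_error += ((cell - cell.mean()) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_side
    return {
        "group": ss_group,
        "side": ss_side,
        "interaction": ss_inter,
        "error": ss_error,
        "total": ss_total,
    }
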