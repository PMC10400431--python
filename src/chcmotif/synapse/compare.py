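"""Bootstrap comparison of SSE distributions between conditions.

Condition-level uncertainty is estimated by robust random sampling: in each
of ``n_rep`` repetitions one mouse's SSE distribution is drawn at random
from each condition, ``n_draw`` values are resampled with replacement from
each, and the normalized histograms are subtracted. The per-bin mean and
s.d. over repetitions summarize the distributional change; subgroup
(high/mid/low) proportion changes are obtained the same way.
"""

from __future__ import annotations

import warnings

import numpy as np


def _subgroup_props(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.array(
        [(values > hi).mean(), ((values >= lo) & (values <= hi)).mean(), (values < lo).mean()]
    )


def bootstrap_compare(
    dist_by_mouse_a: list,
    dist_by_mouse_b: list,
    n_draw: int = 3000,
    n_rep: int = 10,
    seed: int | np.random.Generator = 0,
    bin_edges: np.ndarray | None = None,
    subgroup_thresholds: tuple = (0.5, 1.5),
    min_values: int = 30,
) -> dict:
    """Compare two sets of per-mouse SSE distributions (condition A - B).

    Returns a dict with the histogram bin edges, the per-bin mean and s.d.
    of the A-B probability differences over repetitions, subgroup-
    proportion changes (high, mid, low), and per-mouse CDFs with condition
    means. Mice contributing fewer than ``min_values`` values are excluded
    with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def clean(dists, name):
        kept = [np.asarray(d, dtype=float) for d in dists]
        ok = [d[np.isfinite(d)] for d in kept]
        out = [d for d in ok if d.size >= min_values]
        if len(out) < len(ok):
            warnings.warn(f"excluded {len(ok) - len(out)} mice from {name} (< {min_values} values)",
                          stacklevel=2)
        if len(out) < 2:
            raise ValueError(f"need at least 2 usable mice in condition {name}")
        return out

    a = clean(dist_by_mouse_a, "A")
    b = clean(dist_by_mouse_b, "B")

    if bin_edges is None:
        hi = max(max(d.max() for d in a), max(d.max() for d in b))
        bin_edges = np.linspace(0.0, max(hi, 1e-9), 21)
    bin_edges = np.asarray(bin_edges, dtype=float)

    lo_thr, hi_thr = subgroup_thresholds
    diffs = np.empty((n_rep, bin_edges.size - 1))
    sub_diffs = np.empty((n_rep, 3))
    for rep in range(n_rep):
        da = a[rng.integers(len(a))]
        db = b[rng.integers(len(b))]
        sa = rng.choice(da, size=n_draw, replace=True)
        sb = rng.choice(db, size=n_draw, replace=True)
        ha = np.histogram(sa, bins=bin_edges)[0] / n_draw
        hb = np.histogram(sb, bins=bin_edges)[0] / n_draw
        diffs[rep] = ha - hb
        sub_diffs[rep] = _subgroup_props(sa, lo_thr, hi_thr) - _subgroup_props(sb, lo_thr, hi_thr)

    grid = np.sort(np.unique(np.concatenate(a + b)))

    def cdfs(dists):
        return np.vstack([np.searchsorted(np.sort(d), grid, side="right") / d.size for d in dists])

    cdf_a, cdf_b = cdfs(a), cdfs(b)
    return {
        "bin_edges": bin_edges,
        "diff_mean": diffs.mean(axis=0),
        "diff_sd": diffs.std(axis=0, ddof=1),
        "diff_reps": diffs,
        "subgroup_labels": ("high", "mid", "low"),
        "subgroup_diff_mean": sub_diffs.mean(axis=0),
        "subgroup_diff_sd": sub_diffs.std(axis=0, ddof=1),
        "subgroup_diff_reps": sub_diffs,
        "cdf_grid": grid,
        "cdf_a": cdf_a,
        "cdf_b": cdf_b,
        "cdf_a_mean": cdf_a.mean(axis=0),
        "cdf_b_mean": cdf_b.mean(axis=0),
    }
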