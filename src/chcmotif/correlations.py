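"""Pairwise activity correlations.

The coincident-event correlation for binary event trains i, j over N frames
is

    CI_ij = (E_i . E_j - N <E_i><E_j>) / (N sqrt(<E_i><E_j>))

with <E_i> the per-frame event probability n_i / N, so the numerator is the
observed minus the independence-expected coincidence count. Pearson
correlations of dF/F traces split by behavioral state, and CI as a function
of the pairwise preferred-direction difference, round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior import FrameStates
from .utils import circ_dist_deg

HIGH_CORR_THRESHOLD = 0.6


@dataclass
class PairwiseCorrMatrix:
    ci: np.ndarray  # symmetric, NaN diagonal and NaN for zero-event neurons
    n_frames: int
    sign_class: np.ndarray | None = None  # 'positive' / 'negative' / 'null' / ''
    n_excluded_zero_event: int = 0


@dataclass
class DeltaPdCurve:
    dpd_centers: np.ndarray
    mean_ci: np.ndarray
    n_pairs: np.ndarray
    normalized: bool = False


def _ci_from_counts(coinc: np.ndarray, p: np.ndarray, N: int) -> np.ndarray:
    expected = N * np.outer(p, p)
    denom = N * np.sqrt(np.outer(p, p))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (coinc - expected) / denom


def event_pairwise_correlation(
    events: np.ndarray,
    classify: bool = False,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> PairwiseCorrMatrix:
    """Coincident-event correlation matrix, optionally with bootstrap sign
    classification.

    A pair is positive/negative when the frame-resampling bootstrap
    confidence interval of its CI lies wholly above/below zero, and null
    otherwise. Neurons with zero events have undefined pairs (NaN).
    """
    E = np.atleast_2d(np.asarray(events)).astype(float)
    n, N = E.shape
    counts = E.sum(axis=1)
    p = counts / N
    ci = _ci_from_counts(E @ E.T, p, N)
    np.fill_diagonal(ci, np.nan)
    zero = counts == 0
    ci[zero, :] = np.nan
    ci[:, zero] = np.nan

    sign = None
    if classify:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
        boots = np.empty((n_boot, n, n))
        for b in range(n_boot):
            m = rng.multinomial(N, np.full(N, 1.0 / N)).astype(float)
            pb = (E @ m) / N
            boots[b] = _ci_from_counts((E * m) @ E.T, pb, N)
        lo = np.nanpercentile(boots, lo_q, axis=0)
        hi = np.nanpercentile(boots, hi_q, axis=0)
        sign = np.full((n, n), "null", dtype=object)
        sign[lo > 0] = "positive"
        sign[hi < 0] = "negative"
        sign[~np.isfinite(ci)] = ""
        sign = sign.astype(str)
    return PairwiseCorrMatrix(
        ci=ci, n_frames=N, sign_class=sign, n_excluded_zero_event=int(zero.sum())
    )


def pearson_by_state(
    dff_a: np.ndarray, dff_b: np.ndarray, states: FrameStates, min_frames: int = 100
) -> dict:
    """Pearson r of two traces computed separately on locomotion and rest
    frames; a state shorter than ``min_frames`` yields NaN."""
    out = {}
    for name, mask in (("locomotion", states.is_movement), ("rest", states.is_rest)):
        if mask.sum() < min_frames:
            out[name] = np.nan
            continue
        a, b = np.asarray(dff_a)[mask], np.asarray(dff_b)[mask]
        if np.std(a) == 0 or np.std(b) == 0:
            out[name] = np.nan
        else:
            out[name] = float(stats.pearsonr(a, b)[0])
    return out


def pairwise_pearson_by_state(
    dff_group_a: np.ndarray,
    dff_group_b: np.ndarray,
    states: FrameStates,
    min_frames: int = 100,
) -> dict:
    """All cross-group pairwise Pearson r by state (e.g. ChC x PyN pairs),
    with the fraction of high-correlation pairs (r > 0.6) and sign
    fractions per state."""
    A = np.atleast_2d(dff_group_a)
    B = np.atleast_2d(dff_group_b)
    res = {}
    for name, mask in (("locomotion", states.is_movement), ("rest", states.is_rest)):
        if mask.sum() < min_frames:
            res[name] = {"r": np.full((A.shape[0], B.shape[0]), np.nan)}
            continue
        a = A[:, mask] - A[:, mask].mean(axis=1, keepdims=True)
        b = B[:, mask] - B[:, mask].mean(axis=1, keepdims=True)
        sa = np.sqrt((a * a).sum(axis=1))
        sb = np.sqrt((b * b).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a @ b.T) / np.outer(sa, sb)
        finite = np.isfinite(r)
        res[name] = {
            "r": r,
            "frac_high": float((r[finite] > HIGH_CORR_THRESHOLD).mean()) if finite.any() else np.nan,
            "frac_positive": float((r[finite] > 0).mean()) if finite.any() else np.nan,
            "frac_negative": float((r[finite] < 0).mean()) if finite.any() else np.nan,
        }
    return res


def ci_by_delta_pd(
    ci_matrix: np.ndarray,
    pds: np.ndarray,
    bin_width: float = 30.0,
    reference_curve: np.ndarray | None = None,
) -> DeltaPdCurve:
    """Mean CI binned by the circular PD difference of each pair, optionally
    normalized bin-wise by a reference curve (e.g. an early session)."""
    ci = np.asarray(ci_matrix, dtype=float)
    pds = np.asarray(pds, dtype=float)
    n = pds.size
    n_bins = int(np.ceil(180.0 / bin_width))
    centers = (np.arange(n_bins) + 0.5) * bin_width
    sums = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        if not (np.isfinite(pds[i]) and np.isfinite(pds[j]) and np.isfinite(ci[i, j])):
            continue
        b = min(int(circ_dist_deg(pds[i], pds[j]) / bin_width), n_bins - 1)
        sums[b] += ci[i, j]
        cnt[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ci = np.where(cnt > 0, sums / cnt, np.nan)
    normalized = False
    if reference_curve is not None:
        ref = np.asarray(reference_curve, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_ci = np.where(ref != 0, mean_ci / ref, np.nan)
        normalized = True
    return DeltaPdCurve(dpd_centers=centers, mean_ci=mean_ci, n_pairs=cnt, normalized=normalized)
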