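"""Raw fluorescence to dF/F, binary calcium events, and population metrics.

The dF/F procedure mirrors standard two-photon ROI processing: a neuropil
annulus around each ROI supplies a background trace that is subtracted with
a 0.7 weight after both traces are baseline-normalized; the slowly varying
baseline F0 is a LOESS smooth of the raw trace plus a noise-calibrated
offset. Events are inferred by nonnegative sparse deconvolution under an
AR(2) calcium-kernel observation model and binarized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage as ndi
from scipy import signal, stats

from .behavior import FrameStates
from .utils import loess_smooth

logger = logging.getLogger(__name__)

NEUROPIL_WEIGHT = 0.7
NEUROPIL_INNER_UM = 0.3
NEUROPIL_OUTER_UM = 10.0
BASELINE_SPAN_FRAMES = 120
F0_FLOOR = 1e-6


@dataclass
class RoiSet:
    roi_masks: list  # boolean 2-D arrays, one per neuron
    neuropil_masks: list
    pixel_size_um: float
    flagged_empty: list | None = None  # neuron ids whose annulus emptied out


@dataclass
class DffSet:
    F: np.ndarray  # neurons x frames, raw
    F0: np.ndarray
    dff: np.ndarray
    background_dff: np.ndarray
    frame_rate: float


@dataclass
class EventRaster:
    events: np.ndarray  # binary, neurons x frames
    deconvolved: np.ndarray  # nonnegative amplitudes

    @property
    def n_neurons(self) -> int:
        return self.events.shape[0]


@dataclass
class MovementClassLabels:
    label: np.ndarray  # 'movement-positive' / 'movement-negative' / 'non-movement'
    p_value: np.ndarray


# ---------------------------------------------------------------------------
# neuropil masks


def build_neuropil_masks(
    roi_masks: list, pixel_size_um: float, movie: np.ndarray | None = None
) -> RoiSet:
    """Annulus masks 0.3-10 um outside each ROI, minus all neuronal ROIs and
    minus contaminated pixels.

    A pixel is contaminated when the difference between its time series and
    the ROI's mean trace shows an apparent calcium transient: at least three
    consecutive frames more than 3 s.d. (robust, MAD-based) above the
    difference's median.
    """
    any_roi = np.zeros_like(roi_masks[0], dtype=bool)
    for m in roi_masks:
        any_roi |= m
    neuropil = []
    flagged = []
    for i, m in enumerate(roi_masks):
        dist = ndi.distance_transform_edt(~m, sampling=pixel_size_um)
        ann = (dist > NEUROPIL_INNER_UM) & (dist <= NEUROPIL_OUTER_UM) & ~any_roi
        if movie is not None and ann.any():
            roi_trace = movie[:, m].mean(axis=1)
            pix = movie[:, ann]  # frames x n_pix
            diff = pix - roi_trace[:, None]
            med = np.median(diff, axis=0)
            sigma = 1.4826 * np.median(np.abs(diff - med), axis=0)
            hot = diff - med > 3.0 * sigma
            # transient = >= 3 consecutive supra-threshold frames
            if hot.shape[0] >= 3:
                sustained = (hot[:-2] & hot[1:-1] & hot[2:]).any(axis=0)
            else:
                sustained = hot.all(axis=0)
            keep = np.flatnonzero(ann.ravel())[~sustained]
            ann = np.zeros_like(ann)
            ann.ravel()[keep] = True
        if not ann.any():
            flagged.append(i)
            logger.warning("neuron %d: empty neuropil annulus after exclusions", i)
        neuropil.append(ann)
    return RoiSet(
        roi_masks=list(roi_masks),
        neuropil_masks=neuropil,
        pixel_size_um=pixel_size_um,
        flagged_empty=flagged,
    )


# ---------------------------------------------------------------------------
# baseline and dF/F


def estimate_baseline(F: np.ndarray, frame_rate: float | None = None) -> np.ndarray:
    """Time-varying baseline F0 of one or many fluorescence traces.

    Procedure: preliminary baseline = LOESS smooth of F with a 120-frame
    span; PreDF = F - PreF0; noise = s.d. of the residual of PreDF around
    its own LOESS smooth; offset = mean of the PreDF values within +/- 2x
    noise; F0 = PreF0 + offset, floored at a small positive epsilon.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    out = np.empty_like(F)
    for i, f in enumerate(F):
        if f.size <= BASELINE_SPAN_FRAMES:
            raise ValueError("trace must be longer than the 120-frame baseline span")
        pre_f0 = loess_smooth(f, BASELINE_SPAN_FRAMES)
        pre_df = f - pre_f0
        smooth_df = loess_smooth(pre_df, BASELINE_SPAN_FRAMES)
        noise = float(np.std(pre_df - smooth_df))
        if noise > 0:
            sel = np.abs(pre_df) <= 2.0 * noise
            offset = float(pre_df[sel].mean()) if sel.any() else 0.0
        else:
            offset = 0.0
        f0 = pre_f0 + offset
        if np.any(f0 <= 0):
            warnings.warn("nonpositive baseline floored at epsilon", stacklevel=2)
            f0 = np.maximum(f0, F0_FLOOR)
        out[i] = f0
    return out if np.asarray(F).ndim == 2 else out[0]


def compute_dff(
    F: np.ndarray,
    F0: np.ndarray,
    background_dff: np.ndarray | None = None,
    weight: float = NEUROPIL_WEIGHT,
) -> np.ndarray:
    """dF/F = (F - F0)/F0 - weight * background dF/F."""
    F = np.asarray(F, dtype=float)
    F0 = np.maximum(np.asarray(F0, dtype=float), F0_FLOOR)
    dff = (F - F0) / F0
    if background_dff is not None and weight != 0:
        dff = dff - weight * np.asarray(background_dff, dtype=float)
    return dff


def dff_pipeline(fluor, weight: float = NEUROPIL_WEIGHT) -> DffSet:
    """Full dF/F path on a FluorescenceSet: baselines for ROI and neuropil
    traces, background dF/F, weighted subtraction."""
    F = np.atleast_2d(fluor.F)
    F_np = np.atleast_2d(fluor.F_neuropil)
    F0 = estimate_baseline(F)
    F0_np = estimate_baseline(F_np)
    bg_dff = compute_dff(F_np, F0_np, None)
    dff = compute_dff(F, F0, bg_dff, weight)
    return DffSet(F=F, F0=F0, dff=dff, background_dff=bg_dff, frame_rate=fluor.frame_rate)


# ---------------------------------------------------------------------------
# event inference


def estimate_noise_sd(y: np.ndarray, frame_rate: float = 1.0) -> float:
    """Noise s.d. from the high-frequency half of the power spectrum."""
    n = y.size
    nperseg = min(256, n)
    freqs, pxx = signal.welch(y, nperseg=nperseg)
    sel = freqs >= 0.25
    return float(np.sqrt(np.mean(pxx[sel]) / 2.0)) if sel.any() else float(np.std(y))


def estimate_ar2(
    y: np.ndarray,
    noise_sd: float,
    frame_rate: float = 100.0,
    max_lag: int = 25,
    decay_bounds_s: tuple = (0.1, 2.5),
    rise_bounds_s: tuple = (0.03, 0.25),
) -> tuple[float, float] | None:
    """AR(2) coefficients from the trace autocovariance.

    Least-squares Yule-Walker over lags >= 2 only, so the noise-inflated
    lag-0 term never enters. The trace is first high-passed on a 1-s scale
    to strip slow event-rate autocorrelation (behavioral bouts), which
    would otherwise bias the kernel slow. None when the implied kernel is
    unstable, oscillatory (complex roots), or has implausible rise/decay
    time constants for a calcium indicator.
    """
    from scipy.ndimage import gaussian_filter1d

    y = y - gaussian_filter1d(np.asarray(y, dtype=float), frame_rate)
    n = y.size
    max_lag = min(max_lag, n // 4)
    if max_lag < 4:
        return None
    gamma = np.array([np.dot(y[: n - k], y[k:]) / n for k in range(max_lag + 1)])
    ks = np.arange(2, max_lag + 1)
    A = np.column_stack([gamma[ks - 1], gamma[ks - 2]])
    b = gamma[ks]
    try:
        (g1, g2), *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return None
    roots = np.roots([1.0, -g1, -g2])
    if np.any(np.abs(roots.imag) > 1e-10):
        return None
    roots = np.sort(roots.real)
    if np.any(roots <= 0) or np.any(roots >= 1):
        return None
    rise_s = -1.0 / (frame_rate * np.log(roots[0]))
    decay_s = -1.0 / (frame_rate * np.log(roots[1]))
    if not (decay_bounds_s[0] <= decay_s <= decay_bounds_s[1]):
        return None
    if not (rise_bounds_s[0] <= rise_s <= min(rise_bounds_s[1], decay_s)):
        return None
    return float(g1), float(g2)


@njit(cache=True)
def _cd_lasso_baseline(y, h, lam, max_sweeps=400, tol=1e-8):  # pragma: no cover - jitted
    """Nonnegative LASSO deconvolution with a jointly estimated scalar
    baseline: min_{s>=0,b} 0.5||conv(h,s) + b - y||^2 + lam 1's.

    Coordinate descent over event amplitudes with the intercept b as an
    extra (least-squares) coordinate, so the objective decreases
    monotonically. Returns (s, b).
    """
    T = y.size
    k = h.size
    h2 = 0.0
    for i in range(k):
        h2 += h[i] * h[i]
    s = np.zeros(T)
    r = y.copy()
    b = 0.0
    for _sweep in range(max_sweeps):
        rb = np.mean(r)
        if rb != 0.0:
            r -= rb
            b += rb
        maxdel = 0.0
        for j in range(T):
            m = k if j + k <= T else T - j
            c = 0.0
            for i in range(m):
                c += h[i] * r[j + i]
            anew = s[j] + (c - lam) / h2
            if anew < 0.0:
                anew = 0.0
            d = anew - s[j]
            if d != 0.0:
                for i in range(m):
                    r[j + i] -= d * h[i]
                s[j] = anew
                ad = abs(d)
                if ad > maxdel:
                    maxdel = ad
        if maxdel < tol:
            break
    return s, b


def estimate_decay_root(
    y: np.ndarray,
    frame_rate: float = 100.0,
    lags: tuple = (2, 10),
    decay_bounds_s: tuple = (0.1, 2.5),
) -> float | None:
    """Slow (decay) root of the calcium kernel from autocovariance ratios.

    The autocovariance tail decays geometrically with the slow root even
    when the fast (rise) root is buried in noise; estimated by a linear fit
    of log autocovariance over intermediate lags on the 1-s high-passed
    trace. None if outside plausible decay bounds.
    """
    from scipy.ndimage import gaussian_filter1d

    y = np.asarray(y, dtype=float)
    y = y - gaussian_filter1d(y, frame_rate)
    n = y.size
    k0, k1 = lags
    if n < 4 * k1:
        return None
    gamma = np.array([np.dot(y[: n - k], y[k:]) / n for k in range(k1 + 1)])
    g = gamma[k0 : k1 + 1]
    if np.any(g <= 0):
        return None
    slope = np.polyfit(np.arange(k0, k1 + 1), np.log(g), 1)[0]
    r = float(np.exp(slope))
    if not (0 < r < 1):
        return None
    decay_s = -1.0 / (frame_rate * np.log(r))
    if not (decay_bounds_s[0] <= decay_s <= decay_bounds_s[1]):
        return None
    return r


def _refine_ar_quiet(y: np.ndarray, event_frames: np.ndarray, b: float, halo: int = 3):
    """Re-estimate (g1, g2) from the AR recursion on quiet rows (frames
    with no event within ``halo`` frames, absorbing detection jitter),
    where y_t - b = g1 (y_{t-1} - b) + g2 (y_{t-2} - b) holds exactly in
    the noiseless limit. Returns (g1, g2, rms residual) or None."""
    T = y.size
    quiet = np.ones(T, dtype=bool)
    quiet[:2] = False
    for e in event_frames:
        quiet[max(0, e - halo) : e + halo + 1] = False
    rows = np.flatnonzero(quiet)
    rows = rows[rows >= 2]
    if rows.size < 50:
        return None
    yc = y - b
    g1 = g2 = c0 = np.nan
    resid = None
    # intercept absorbs any residual baseline error; one robustness pass
    # drops rows polluted by undetected events
    for _ in range(2):
        A = np.column_stack([yc[rows - 1], yc[rows - 2], np.ones(rows.size)])
        try:
            (g1, g2, c0), *_ = np.linalg.lstsq(A, yc[rows], rcond=None)
        except np.linalg.LinAlgError:
            return None
        resid = yc[rows] - A @ np.array([g1, g2, c0])
        mad = np.median(np.abs(resid - np.median(resid)))
        # floor the cutoff so dynamics-rich rows are never rejected en
        # masse when the flat majority drives the MAD to zero
        cutoff = max(6.0 * mad, 1e-3 * float(np.ptp(yc[rows])), 1e-12)
        good = np.abs(resid - np.median(resid)) <= cutoff
        if good.all() or good.sum() < 50:
            break
        rows = rows[good]
    roots = np.roots([1.0, -g1, -g2])
    if np.any(np.abs(roots.imag) > 1e-10):
        return None
    rr = roots.real
    if np.any(rr <= 0) or np.any(rr >= 1):
        return None
    return float(g1), float(g2), float(c0), float(np.sqrt(np.mean(resid**2)))


def infer_events(
    dff: np.ndarray,
    frame_rate: float = 100.0,
    default_rise_s: float = 0.1,
    default_decay_s: float = 1.0,
) -> EventRaster:
    """Binary calcium events by sparse nonnegative AR(2) deconvolution.

    Per neuron: estimate the AR(2) kernel from the trace autocovariance
    (falling back to a 0.1-s-rise / 1-s-decay kernel when the estimate is
    unstable), solve an L1-penalized nonnegative deconvolution with a
    jointly estimated baseline, merge deconvolved mass split across nearby
    frames into single events, and binarize. When the AR recursion on
    event-free frames shows the trace is essentially noiseless, the kernel
    is refined on those frames and events are recovered by exact
    AR-whitening inversion instead.
    """
    from .synthetic.population import ar2_coefficients  # no cycle at module load

    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    if not np.all(np.isfinite(dff)):
        raise ValueError("dff must be finite")
    n_neurons, T = dff.shape
    events = np.zeros((n_neurons, T), dtype=np.int8)
    amps = np.zeros((n_neurons, T))

    for i in range(n_neurons):
        y = dff[i]
        if not np.any(y != 0):
            continue
        scale = float(np.ptp(y))
        sn = estimate_noise_sd(y, frame_rate)
        ar = estimate_ar2(y, sn, frame_rate)
        if ar is None:
            # full AR(2) unidentifiable: combine the robustly estimable
            # decay root with the assumed rise, else fall back entirely
            r1 = estimate_decay_root(y, frame_rate)
            r2 = np.exp(-1.0 / (default_rise_s * frame_rate))
            if r1 is not None and r2 < r1:
                ar = (r1 + r2, -r1 * r2)
            else:
                logger.warning("neuron %d: unstable AR estimate, default kernel used", i)
                ar = ar2_coefficients(default_rise_s, default_decay_s, frame_rate)
        g1, g2 = ar
        klen = min(T, max(int(6.0 * default_decay_s * frame_rate), 100))

        def run_cd(h):
            h2 = float(h @ h)
            # mild penalty (1 sigma of the matched-filter scale); detection
            # is decided by the cluster-total significance threshold below
            lam = max(sn, 1e-6 * scale) * np.sqrt(h2)
            s, b = _cd_lasso_baseline(y.copy(), h, lam)
            # 4 sigma of the amplitude estimator, then a relative cut
            # against the typical event amplitude
            ef, ea = _events_from_mass(
                s, min_total=4.0 * max(sn, 1e-9 * scale) / np.sqrt(h2), merge_px=12
            )
            if ea.size:
                keep = ea > 0.25 * np.median(ea)
                ef, ea = ef[keep], ea[keep]
            return ef, ea, b

        h = np.empty(klen)
        h[0] = 1.0
        if klen > 1:
            h[1] = g1
        for k in range(2, klen):
            h[k] = g1 * h[k - 1] + g2 * h[k - 2]
        ef, ea, b = run_cd(h)
        # refine the kernel on quiet frames (exact AR recursion, immune to
        # the rate autocorrelation that biases Yule-Walker)
        refined = _refine_ar_quiet(y, ef, b) if ef.size else None
        if refined is not None and refined[3] < max(0.5 * sn, 1e-9 * scale):
            # near-noiseless: recover events by exact AR-whitening inversion
            g1r, g2r, c0 = refined[0], refined[1], refined[2]
            yc = y - b
            s_exact = np.empty(T)
            s_exact[0] = yc[0]
            s_exact[1] = yc[1] - g1r * yc[0]
            s_exact[2:] = yc[2:] - g1r * yc[1:-1] - g2r * yc[:-2]
            s_exact -= c0
            s_exact[:2] = 0.0  # boundary terms carry no event information
            s_exact[s_exact < 0] = 0.0
            big = s_exact[s_exact > 0.1 * s_exact.max()] if s_exact.max() > 0 else np.asarray([])
            ref_amp = float(np.median(big)) if big.size else 0.0
            # exact inversion needs no mass merging: one frame, one event
            ef = np.flatnonzero(s_exact > 0.3 * max(ref_amp, 1e-9))
            ea = s_exact[ef]
        events[i, ef] = 1
        amps[i, ef] = ea
    return EventRaster(events=events, deconvolved=amps)


def _robust_amp(s: np.ndarray) -> float:
    """Median positive deconvolved amplitude (0 when empty)."""
    pos = s[s > 1e-6]
    return float(np.median(pos)) if pos.size else 0.0


def _events_from_mass(s: np.ndarray, min_total: float, merge_px: int = 2):
    """Group deconvolved mass within ``merge_px`` frames; each group whose
    total exceeds ``min_total`` becomes one event at its peak frame."""
    active = s > 1e-6
    if not active.any():
        return np.asarray([], dtype=int), np.asarray([])
    grouped = ndi.binary_dilation(active, iterations=merge_px)
    labels, n_runs = ndi.label(grouped)
    frames = []
    totals = []
    for run in range(1, n_runs + 1):
        idx = np.flatnonzero((labels == run) & active)
        total = s[idx].sum()
        if total > min_total:
            frames.append(idx[np.argmax(s[idx])])
            totals.append(total)
    return np.asarray(frames, dtype=int), np.asarray(totals)


# ---------------------------------------------------------------------------
# movement-related classification and population metrics


def classify_movement_related(
    dff: np.ndarray, states: FrameStates, alpha: float = 0.05, min_state_s: float = 10.0, frame_rate: float = 100.0
) -> MovementClassLabels:
    """Two-sided rank-sum test of frame dF/F between movement and rest."""
    dff = np.atleast_2d(dff)
    mov, rest = states.is_movement, states.is_rest
    n = dff.shape[0]
    min_frames = int(min_state_s * frame_rate)
    if mov.sum() < min_frames or rest.sum() < min_frames:
        warnings.warn("a behavioral state is (nearly) absent; all neurons non-movement", stacklevel=2)
        return MovementClassLabels(
            label=np.array(["non-movement"] * n), p_value=np.full(n, np.nan)
        )
    labels = np.empty(n, dtype=object)
    pvals = np.empty(n)
    for i in range(n):
        stat, p = stats.ranksums(dff[i, mov], dff[i, rest])
        pvals[i] = p
        if p < alpha:
            labels[i] = "movement-positive" if stat > 0 else "movement-negative"
        else:
            labels[i] = "non-movement"
    return MovementClassLabels(label=labels.astype(str), p_value=pvals)


def onset_aligned_metrics(
    activity: np.ndarray, onsets: np.ndarray, window: tuple, frame_rate: float = 100.0
):
    """Movement-onset-triggered population metrics.

    Returns (aligned neurons x window, peak_time_s per neuron,
    (bin_times_s, max_activation_probability)); the probability is the
    fraction of neurons whose onset-triggered average peaks in each time
    bin and sums to 1.
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    onsets = np.asarray(onsets, dtype=int)
    pre, post = int(window[0]), int(window[1])
    T = activity.shape[1]
    valid = onsets[(onsets + pre >= 0) & (onsets + post <= T)]
    if valid.size == 0:
        return None
    w = post - pre
    aligned = np.zeros((activity.shape[0], w))
    for o in valid:
        aligned += activity[:, o + pre : o + post]
    aligned /= valid.size
    rel_t = (np.arange(pre, post)) / frame_rate
    peak_idx = np.argmax(aligned, axis=1)
    peak_times = rel_t[peak_idx]
    counts = np.bincount(peak_idx, minlength=w).astype(float)
    prob = counts / counts.sum()
    return aligned, peak_times, (rel_t, prob)


def coactivity(events: np.ndarray, states: FrameStates) -> dict:
    """Percent of neurons co-active per frame, averaged by behavioral state."""
    events = np.atleast_2d(events)
    pct = 100.0 * events.mean(axis=0)
    mov, rest = states.is_movement, states.is_rest
    return {
        "locomotion": float(pct[mov].mean()) if mov.any() else np.nan,
        "rest": float(pct[rest].mean()) if rest.any() else np.nan,
    }
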