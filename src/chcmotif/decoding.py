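"""Bayesian and population-vector decoding of movement direction.

The posterior over 72 five-degree MD bins at frame t is the product over
the neurons active at t of P(active_k | MD) P(MD) / P(active_k) — the
printed form, with the prior inside every factor — renormalized to sum to
one; the decoded direction is the maximum a posteriori bin center. A
population-vector readout (vector sum of active tuned neurons' PDs) is
provided as a model-free counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tuning import DirectionBins
from .utils import circ_dist_deg, wrap_deg, wrap_signed_deg


@dataclass
class PosteriorSeries:
    posterior: np.ndarray  # frames x n_bins, rows sum to 1 (NaN rows: no active neuron)
    map_md: np.ndarray  # decoded degrees per frame (NaN when undecodable)
    decode_error: np.ndarray  # signed, (-180, 180]
    prior: np.ndarray
    chance_level: float
    flagged: np.ndarray  # frames where the product vanished and the prior was used

    @property
    def abs_error(self) -> np.ndarray:
        return np.abs(self.decode_error)


@dataclass
class PopulationVector:
    pov_angle: np.ndarray  # degrees per frame (NaN when undefined)
    pov_magnitude: np.ndarray
    pov_error: np.ndarray  # signed circular difference to MD
    pd_alignment_errors: np.ndarray  # pooled |PD - MD| over active tuned neurons
    frac_decoded: float  # |error| < 22.5 deg
    frac_anti_decoded: float  # |error| > 157.5 deg
    n_skipped_zero_resultant: int = 0


def compute_prior(md: np.ndarray, bins: DirectionBins | None = None) -> np.ndarray:
    """P(MD): occupancy histogram over movement frames, summing to 1."""
    bins = bins or DirectionBins()
    idx = bins.index(md)
    ok = idx >= 0
    counts = np.bincount(idx[ok], minlength=bins.n_bins).astype(float)
    total = counts.sum()
    return counts / total if total > 0 else counts


def decode_posterior(
    events: np.ndarray,
    likelihoods: np.ndarray,
    prior: np.ndarray,
    md: np.ndarray | None = None,
    bins: DirectionBins | None = None,
    prior_mode: str = "per-neuron",
) -> PosteriorSeries:
    """MAP decoding of MD from binary population activity.

    Parameters
    ----------
    events : neurons x frames binary raster.
    likelihoods : neurons x n_bins matrix of P(active | MD_i); NaN bins are
        treated as uninformative for that neuron.
    prior : P(MD) per bin.
    md : optional actual MD per frame; enables the decode-error output.
    prior_mode : 'per-neuron' multiplies the prior inside each active
        neuron's factor (the printed form); 'single' applies it once.

    Frames with no active neuron are left undecoded (NaN). Frames whose
    factor product vanishes in every bin fall back to the prior and are
    flagged.
    """
    bins = bins or DirectionBins()
    events = np.atleast_2d(events)
    lik = np.asarray(likelihoods, dtype=float)
    n_neurons, n_frames = events.shape
    prior = np.asarray(prior, dtype=float)

    # floor the likelihood: a sampled zero should down-weight a bin, not
    # veto it with infinite evidence
    lik_floor = np.where(np.isfinite(lik), np.clip(lik, 1e-4, 1.0), np.nan)
    p_active = np.nansum(lik_floor * prior[None, :], axis=1)  # P(active_k) marginal
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lik = np.log(lik_floor)
        log_prior = np.log(prior)
        log_pa = np.log(p_active)

    # per-neuron factor in log space: log P(a_k|MD) + log P(MD) - log P(a_k)
    factors = log_lik - log_pa[:, None]
    if prior_mode == "per-neuron":
        factors = factors + log_prior[None, :]
    # missing likelihood bins contribute nothing for that neuron; -inf from
    # zero-prior bins becomes a large finite penalty so that inactive
    # neurons (weight 0) contribute exactly nothing in the matmul
    factors = np.where(np.isnan(factors), 0.0, factors)
    factors = np.where(np.isneginf(factors), -1e30, factors)

    ev = events.astype(float)
    log_post = ev.T @ factors  # frames x bins
    if prior_mode == "single":
        log_post = log_post + log_prior[None, :]

    n_active = ev.sum(axis=0)
    posterior = np.full((n_frames, bins.n_bins), np.nan)
    map_md = np.full(n_frames, np.nan)
    flagged = np.zeros(n_frames, dtype=bool)
    decodable = np.flatnonzero(n_active > 0)
    for t in decodable:
        row = log_post[t]
        finite = np.isfinite(row)
        if not finite.any():
            posterior[t] = prior
            flagged[t] = True
        else:
            w = np.zeros(bins.n_bins)
            m = row[finite].max()
            w[finite] = np.exp(row[finite] - m)
            posterior[t] = w / w.sum()
        map_md[t] = bins.centers[int(np.argmax(posterior[t]))]

    if md is not None:
        err = decoding_error(map_md, md)
    else:
        err = np.full(n_frames, np.nan)
    return PosteriorSeries(
        posterior=posterior,
        map_md=map_md,
        decode_error=err,
        prior=prior,
        chance_level=1.0 / bins.n_bins,
        flagged=flagged,
    )


def decoding_error(map_md: np.ndarray, md: np.ndarray) -> np.ndarray:
    """Signed circular difference decoded - actual, wrapped to (-180, 180]."""
    map_md = np.asarray(map_md, dtype=float)
    md = np.asarray(md, dtype=float)
    err = np.full(map_md.shape, np.nan)
    ok = np.isfinite(map_md) & np.isfinite(md)
    err[ok] = wrap_signed_deg(map_md[ok] - md[ok])
    return err


def posterior_vs_distance(
    posterior: np.ndarray, md: np.ndarray, bins: DirectionBins | None = None
):
    """Chance-normalized mean posterior mass vs circular distance from the
    actual MD. Returns (distance_centers, curve); the chance level is 1/72.
    """
    bins = bins or DirectionBins()
    md = np.asarray(md, dtype=float)
    ok = np.isfinite(md) & np.isfinite(posterior).all(axis=1)
    n_dist = bins.n_bins // 2 + 1
    sums = np.zeros(n_dist)
    counts = np.zeros(n_dist)
    centers = bins.centers
    for t in np.flatnonzero(ok):
        d = circ_dist_deg(centers, md[t])
        db = np.minimum(np.round(d / bins.bin_width).astype(int), n_dist - 1)
        sums += np.bincount(db, weights=posterior[t], minlength=n_dist)
        counts += np.bincount(db, minlength=n_dist)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_mass = np.where(counts > 0, sums / counts, np.nan)
    return np.arange(n_dist) * bins.bin_width, mean_mass / (1.0 / bins.n_bins)


def population_vector_decode(
    events: np.ndarray, pds: np.ndarray, md: np.ndarray
) -> PopulationVector:
    """Population-vector readout: the angle of the vector sum of unit
    vectors at the PDs of the neurons active in each frame.

    Only neurons with a finite PD (direction-tuned) contribute. Frames with
    no active tuned neuron are undefined; zero-resultant frames are skipped
    and counted. Fractions of decoded (|error| < 22.5 deg) and anti-decoded
    (|error| > 157.5 deg) frames are reported over the defined frames.
    """
    events = np.atleast_2d(events)
    pds = np.asarray(pds, dtype=float)
    tuned = np.isfinite(pds)
    ev = events[tuned].astype(float)
    ux = np.cos(np.deg2rad(pds[tuned]))
    uy = np.sin(np.deg2rad(pds[tuned]))
    sx = ux @ ev
    sy = uy @ ev
    mag = np.hypot(sx, sy)
    n_active = ev.sum(axis=0)

    angle = np.full(events.shape[1], np.nan)
    defined = (n_active > 0) & (mag > 1e-12)
    n_skipped = int(((n_active > 0) & ~defined).sum())
    angle[defined] = wrap_deg(np.rad2deg(np.arctan2(sy[defined], sx[defined])))

    md = np.asarray(md, dtype=float)
    err = np.full(events.shape[1], np.nan)
    ok = defined & np.isfinite(md)
    err[ok] = wrap_signed_deg(angle[ok] - md[ok])

    align = []
    for i in np.flatnonzero(tuned):
        frames = (events[i] > 0) & np.isfinite(md)
        align.append(circ_dist_deg(pds[i], md[frames]))
    align = np.concatenate(align) if align else np.asarray([])

    abs_err = np.abs(err[ok])
    n_def = abs_err.size
    return PopulationVector(
        pov_angle=angle,
        pov_magnitude=mag,
        pov_error=err,
        pd_alignment_errors=align,
        frac_decoded=float((abs_err < 22.5).mean()) if n_def else np.nan,
        frac_anti_decoded=float((abs_err > 157.5).mean()) if n_def else np.nan,
        n_skipped_zero_resultant=n_skipped,
    )
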