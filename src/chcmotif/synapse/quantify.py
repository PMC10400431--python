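"""Geometry, gephyrin puncta, and structural-efficacy parameters.

For each ChC-AIS contact the AIS and ChC channel intensities are projected
onto the fiber's lengthwise axis (the ROI extended 5 um past the AIS ends so
a cartridge overhanging the end is fully measured); profile lengths are read
at half of each profile's maximum. The presynaptic structural efficacy is

    PRE = (A_ChC-AIS / L_AIS) x (L_ChC-AIS / L_ChC)

and the postsynaptic one is POST = Z_ChC-AIS / Z_AIS, the ratio of summed
modified z-scores of gephyrin puncta inside the contact versus all puncta on
the AIS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from skimage.feature import peak_local_max

from .detect import (
    Contact,
    SegmentationConfig,
    classify_contacts,
    register_segments_3d,
    segment_planes,
)

logger = logging.getLogger(__name__)

PRE_HIGH, PRE_LOW = 1.5, 0.5
POST_HIGH, POST_LOW = 0.6, 0.1


@dataclass
class GephyrinPunctum:
    z: int
    y: float
    x: float
    amplitude: float
    z_score: float = np.nan
    ais_id: int | None = None
    in_contact: bool = False


# ---------------------------------------------------------------------------
# geometry


def _axis_profile(intensity: np.ndarray, planes: list, origin, direction,
                  s_min: float, s_max: float, halfwidth_px: float, step: float = 1.0):
    """Max-intensity profile along the axis within a corridor.

    Returns (s_positions, profile) with s in px from ``origin``.
    """
    ny, nx = intensity.shape[1:]
    ys, xs = np.mgrid[0:ny, 0:nx]
    rel_y = ys - origin[0]
    rel_x = xs - origin[1]
    s = rel_y * direction[0] + rel_x * direction[1]
    d = np.abs(-rel_y * direction[1] + rel_x * direction[0])
    corridor = (d <= halfwidth_px) & (s >= s_min) & (s <= s_max)
    img = np.max(intensity[planes], axis=0)
    edges = np.arange(s_min, s_max + step, step)
    centers = 0.5 * (edges[:-1] + edges[1:])
    prof = np.zeros(centers.size)
    sel = corridor & (img > 0)
    sv = s[sel]
    iv = img[sel]
    idx = np.clip(((sv - s_min) / step).astype(int), 0, centers.size - 1)
    np.maximum.at(prof, idx, iv)
    return centers, prof


def measure_geometry(
    contact: Contact,
    ais_channel: np.ndarray,
    chc_channel: np.ndarray,
    pixel_size_um: float,
    config: SegmentationConfig | None = None,
) -> dict | None:
    """L_AIS, L_ChC, L_ChC-AIS (half-max profile lengths, um) and the
    ChC-on-AIS mask area A (um^2). None for degenerate (<3 px) axes."""
    config = config or SegmentationConfig()
    ais = contact.ais
    if ais.proj_mask.sum() < 3 or ais.axis_dir is None:
        logger.warning("degenerate AIS axis; contact dropped")
        return None
    ext_px = config.roi_extension_um / pixel_size_um
    hw_px = config.corridor_halfwidth_um / pixel_size_um
    length_px = ais.length_um / pixel_size_um

    planes = ais.planes
    cart_planes = sorted({s.plane for c in contact.cartridges for s in c.segments}) or planes

    s_a, prof_ais = _axis_profile(
        ais_channel, planes, ais.axis_origin, ais.axis_dir, -ext_px, length_px + ext_px, hw_px
    )
    s_c, prof_chc = _axis_profile(
        chc_channel, cart_planes, ais.axis_origin, ais.axis_dir, -ext_px, length_px + ext_px, hw_px
    )

    def halfmax_support(prof):
        if prof.max() <= 0:
            return np.zeros(prof.size, dtype=bool)
        return prof >= 0.5 * prof.max()

    sup_a = halfmax_support(prof_ais)
    sup_c = halfmax_support(prof_chc)
    step_um = (s_a[1] - s_a[0]) * pixel_size_um if s_a.size > 1 else pixel_size_um
    l_ais = float(sup_a.sum()) * step_um
    l_chc = float(sup_c.sum()) * step_um
    l_on = float((sup_a & sup_c).sum()) * step_um
    a_um2 = float(contact.overlap_proj.sum()) * pixel_size_um**2
    return {
        "L_AIS_um": l_ais,
        "L_ChC_um": l_chc,
        "L_ChC_AIS_um": l_on,
        "A_um2": a_um2,
    }


def compute_pre_sse(geometry: dict) -> float:
    """PRE = (A / L_AIS) x (L_ChC-AIS / L_ChC); 0 when there is no cartridge."""
    if geometry["L_ChC_um"] == 0:
        return 0.0
    if geometry["L_AIS_um"] <= 0:
        raise ValueError("L_AIS must be positive")
    return (geometry["A_um2"] / geometry["L_AIS_um"]) * (
        geometry["L_ChC_AIS_um"] / geometry["L_ChC_um"]
    )


# ---------------------------------------------------------------------------
# gephyrin puncta


def _fit_gaussian_2d(patch: np.ndarray, sigma: float):
    """Fit amplitude, center and offset of an isotropic Gaussian with fixed
    sigma. Returns (y, x, amplitude) in patch coords or None on divergence."""
    r = patch.shape[0] // 2
    ys, xs = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]].astype(float)

    def model(p):
        y0, x0, amp, off = p
        return off + amp * np.exp(-((ys - y0) ** 2 + (xs - x0) ** 2) / (2 * sigma**2))

    p0 = [float(r), float(r), float(patch.max() - patch.min()), float(patch.min())]
    try:
        res = optimize.least_squares(
            lambda p: (model(p) - patch).ravel(), p0, max_nfev=200
        )
    except Exception:  # noqa: BLE001
        return None
    y0, x0, amp, off = res.x
    if not res.success or amp <= 0:
        return None
    if abs(y0 - r) > 3 or abs(x0 - r) > 3:
        return None
    return float(y0), float(x0), float(amp), float(off)


def _maybe_split_pair(patch: np.ndarray, fit, sigma: float, noise_sd: float = 0.0):
    """Split an elongated blob into two fixed-sigma kernels.

    Two puncta closer than the classical resolution limit merge into a
    single unimodal blob; an excess second moment along the principal axis
    reveals the pair, which is then refit as a two-kernel mixture. Only
    fires when the single-kernel fit leaves residual structure well above
    the noise, so isolated puncta are never split. Returns a list of
    (y, x, amplitude) in patch coordinates.
    """
    y0, x0, amp, off = fit
    ys, xs = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]].astype(float)
    single = off + amp * np.exp(-((ys - y0) ** 2 + (xs - x0) ** 2) / (2 * sigma**2))
    resid_rms = float(np.sqrt(np.mean((patch - single) ** 2)))
    if noise_sd > 0 and resid_rms <= 3.0 * noise_sd:
        return [(y0, x0, amp)]
    w = np.clip(patch - off, 0, None)
    tot = w.sum()
    if tot <= 0:
        return [(y0, x0, amp)]
    my, mx = (w * ys).sum() / tot, (w * xs).sum() / tot
    cyy = (w * (ys - my) ** 2).sum() / tot
    cxx = (w * (xs - mx) ** 2).sum() / tot
    cyx = (w * (ys - my) * (xs - mx)).sum() / tot
    cov = np.array([[cyy, cyx], [cyx, cxx]])
    lam, vec = np.linalg.eigh(cov)
    if lam[1] <= 1.35 * max(lam[0], 1e-9) or lam[1] <= 1.2 * sigma**2:
        return [(y0, x0, amp)]
    u = vec[:, 1]
    d = np.sqrt(max(lam[1] - sigma**2, 0.25))

    def model2(p):
        ya, xa, aa, yb, xb, ab, o = p
        g = o + aa * np.exp(-((ys - ya) ** 2 + (xs - xa) ** 2) / (2 * sigma**2))
        return g + ab * np.exp(-((ys - yb) ** 2 + (xs - xb) ** 2) / (2 * sigma**2))

    p0 = [my - d * u[0], mx - d * u[1], amp, my + d * u[0], mx + d * u[1], amp, off]
    try:
        res = optimize.least_squares(lambda p: (model2(p) - patch).ravel(), p0, max_nfev=300)
    except Exception:  # noqa: BLE001
        return [(y0, x0, amp)]
    ya, xa, aa, yb, xb, ab, _ = res.x
    if not res.success or aa <= 0 or ab <= 0 or np.hypot(ya - yb, xa - xb) < 1.0:
        return [(y0, x0, amp)]
    return [(float(ya), float(xa), float(aa)), (float(yb), float(xb), float(ab))]


def detect_gephyrin(
    channel: np.ndarray,
    sigma_px: float = 1.5,
    threshold_k_sd: float = 6.0,
    merge_lateral_px: float = 2.0,
) -> list[GephyrinPunctum]:
    """Gephyrin puncta by Gaussian fitting around local maxima, per plane.

    sigma is fixed at the microscope PSF scale (default 1.5 px); position
    and amplitude are free. Duplicates on adjacent planes closer than 2 px
    laterally are merged, keeping the brighter fit. Each punctum gets a
    modified z-score (amplitude - median) / s.d. over all detected puncta
    in the tile.
    """
    vol = channel if channel.ndim == 3 else channel[None]
    r = int(np.ceil(3 * sigma_px))
    puncta: list[GephyrinPunctum] = []
    for z in range(vol.shape[0]):
        plane = vol[z].astype(float)
        med = float(np.median(plane))
        # robust background scale: bright puncta must not inflate it
        sd = 1.4826 * float(np.median(np.abs(plane - med)))
        if sd == 0:
            sd = float(np.std(plane))  # constant background, e.g. noiseless fixtures
        if sd == 0:
            continue
        peaks = peak_local_max(
            plane, min_distance=2, threshold_abs=med + threshold_k_sd * sd, exclude_border=r
        )
        for py, px_ in peaks:
            patch = plane[py - r : py + r + 1, px_ - r : px_ + r + 1]
            fit = _fit_gaussian_2d(patch, sigma_px)
            if fit is None:
                continue
            for fy, fx, amp in _maybe_split_pair(patch, fit, sigma_px, noise_sd=sd):
                puncta.append(
                    GephyrinPunctum(z=z, y=py - r + fy, x=px_ - r + fx, amplitude=amp)
                )

    # merge duplicates across adjacent planes
    puncta.sort(key=lambda p: -p.amplitude)
    kept: list[GephyrinPunctum] = []
    for p in puncta:
        dup = any(
            abs(p.z - q.z) <= 1 and np.hypot(p.y - q.y, p.x - q.x) < merge_lateral_px
            for q in kept
        )
        if not dup:
            kept.append(p)

    if kept:
        amps = np.array([p.amplitude for p in kept])
        med, sd = float(np.median(amps)), float(np.std(amps))
        for p in kept:
            p.z_score = (p.amplitude - med) / sd if sd > 0 else 0.0
    return kept


def assign_puncta(puncta: list, contacts: list) -> None:
    """Associate each punctum with the AIS whose registered boundary
    contains its position, and flag it in-contact when it also falls inside
    the ChC-on-AIS boundary. Mutates the puncta in place."""
    for p in puncta:
        iy, ix = int(round(p.y)), int(round(p.x))
        for ais_id, c in enumerate(contacts):
            m = c.ais.proj_mask
            if 0 <= iy < m.shape[0] and 0 <= ix < m.shape[1] and m[iy, ix]:
                p.ais_id = ais_id
                p.in_contact = bool(c.overlap_proj[iy, ix])
                break


def compute_post_sse(contact_puncta: list) -> float:
    """POST = sum of z-scores of in-contact puncta over the sum for all
    AIS-associated puncta; 0 with no in-contact puncta, NaN when the signed
    z-scores cancel."""
    if not contact_puncta:
        return 0.0
    z_all = float(sum(p.z_score for p in contact_puncta))
    z_in = float(sum(p.z_score for p in contact_puncta if p.in_contact))
    if z_all == 0.0:
        logger.warning("Z_AIS sums to zero with puncta present; POST undefined")
        return np.nan
    return z_in / z_all


def classify_subgroups(pre_sse: float, post_sse: float) -> tuple[str, str]:
    """Subgroup labels with strict thresholds: high > 1.5 / > 0.6, low < 0.5
    / < 0.1 for Pre-/Post-SSE; boundary values fall in mid."""

    def lab(v, lo, hi):
        if not np.isfinite(v):
            return ""
        if v > hi:
            return "high"
        if v < lo:
            return "low"
        return "mid"

    return lab(pre_sse, PRE_LOW, PRE_HIGH), lab(post_sse, POST_LOW, POST_HIGH)


# ---------------------------------------------------------------------------
# full pipeline


def quantify_stack(stack, config: SegmentationConfig | None = None) -> pd.DataFrame:
    """Run the full detection/quantification pipeline on an ImageStack.

    Returns a contacts table with one row per detected AIS: geometry,
    PRE/POST, subgroup labels and the projected centroid for matching.
    """
    config = config or SegmentationConfig()
    px = stack.voxel_size_um[1]
    ais_planes = segment_planes(stack.channels["ais"], "ais", config)
    chc_planes = segment_planes(stack.channels["chc"], "chc", config)
    ais_objs = register_segments_3d(ais_planes, px, "ais", config)
    cart_objs = register_segments_3d(chc_planes, px, "chc", config)
    contacts = classify_contacts(ais_objs, cart_objs)

    puncta = detect_gephyrin(stack.channels["gephyrin"], config.puncta_sigma_px)
    assign_puncta(puncta, contacts)

    rows = []
    for ais_id, c in enumerate(contacts):
        cy, cx = c.ais.centroid
        row = {
            "ais_id": ais_id,
            "centroid_y": cy,
            "centroid_x": cx,
            "is_contact": c.is_contact,
            "L_AIS_um": np.nan,
            "L_ChC_um": np.nan,
            "L_ChC_AIS_um": np.nan,
            "A_um2": np.nan,
            "pre_sse": np.nan,
            "post_sse": np.nan,
            "subgroup_pre": "",
            "subgroup_post": "",
            "n_puncta": 0,
        }
        mine = [p for p in puncta if p.ais_id == ais_id]
        row["n_puncta"] = len(mine)
        if c.is_contact:
            geom = measure_geometry(
                c, stack.channels["ais"], stack.channels["chc"], px, config
            )
            if geom is not None:
                row.update(geom)
                row["pre_sse"] = compute_pre_sse(geom)
                row["post_sse"] = compute_post_sse(mine)
                row["subgroup_pre"], row["subgroup_post"] = classify_subgroups(
                    row["pre_sse"], row["post_sse"]
                )
        rows.append(row)
    return pd.DataFrame(rows)
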