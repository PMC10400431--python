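"""Three-channel volumetric stack simulator for ChC-AIS quantification.

Renders axon initial segments (AnkG channel) as straight fluorescent fibers,
chandelier-cell cartridges (TdTomato channel) as strings of boutons covering
a known fraction of selected AISs, and gephyrin puncta (antibody channel) as
2-D Gaussian spots along each AIS. The generative geometry is recorded so
the detection/quantification pipeline can be scored against exact
ground-truth Pre-SSE and Post-SSE values, which are computed with the same
formulas the pipeline uses, applied to the noiseless masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._truth import GroundTruth


@dataclass
class ImageStack:
    """Channel volumes (z, y, x) plus voxel calibration in microns."""

    channels: dict  # keys: 'gephyrin', 'chc', 'ais'
    voxel_size_um: tuple  # (z, y, x)

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape


@dataclass
class StackSimConfig:
    shape_px: tuple = (10, 1100, 1100)  # (z, y, x)
    voxel_size_um: tuple = (1.0, 0.15, 0.15)
    n_ais: int = 30
    ais_length_range_um: tuple = (12.0, 22.0)
    n_cartridge_fraction: float = 0.8
    cartridge_coverage_range: tuple = (0.3, 0.9)
    cartridge_overhang_um: float = 0.0  # cartridge extension past the AIS end
    puncta_per_ais_range: tuple = (4, 10)
    puncta_sigma_px: float = 1.5
    # dim gephyrin puncta scattered off-AIS (neuropil synapses); they anchor
    # the tile-wide z-score statistics below the AIS-associated amplitudes
    n_background_puncta: int = 400
    background_amp_range: tuple = (0.15, 0.6)  # x peak_intensity
    fiber_sigma_px: float = 3.0  # cross-section of the rendered AIS tube (~1 um FWHM)
    bouton_sigma_range_px: tuple = (2.0, 6.0)  # per-cartridge bouton size
    bouton_spacing_um: float = 1.0
    z_extent_planes: int = 3
    peak_intensity: float = 100.0
    snr: float = 10.0  # peak / background intensity ratio
    read_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.n_ais < 0:
            raise ValueError("n_ais must be >= 0")
        if not (0 <= self.n_cartridge_fraction <= 1):
            raise ValueError("n_cartridge_fraction must lie in [0, 1]")


def _stamp_gaussian(img: np.ndarray, y: float, x: float, sigma: float, amp: float):
    """Add an isotropic 2-D Gaussian to ``img`` in place (4-sigma support)."""
    r = int(np.ceil(4 * sigma))
    yy0, yy1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    xx0, xx1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0, y1 = max(yy0, 0), min(yy1, img.shape[0])
    x0, x1 = max(xx0, 0), min(xx1, img.shape[1])
    if y0 >= y1 or x0 >= x1:
        return
    ys = np.arange(y0, y1)[:, None]
    xs = np.arange(x0, x1)[None, :]
    img[y0:y1, x0:x1] += amp * np.exp(-((ys - y) ** 2 + (xs - x) ** 2) / (2 * sigma**2))


def _render_fiber(img, y0, x0, y1, x1, sigma, amp):
    """Render a tube as densely-spaced Gaussian cross-sections along a line,
    normalized so the ridge amplitude equals ``amp``."""
    length = np.hypot(y1 - y0, x1 - x0)
    step = 0.5
    n = max(2, int(np.ceil(length / step)))
    stamp_amp = amp * step / (sigma * np.sqrt(2.0 * np.pi))
    for f in np.linspace(0, 1, n):
        _stamp_gaussian(img, y0 + f * (y1 - y0), x0 + f * (x1 - x0), sigma, stamp_amp)


def simulate_synapse_stack(config: StackSimConfig) -> tuple[ImageStack, GroundTruth]:
    """Simulate one tile; returns the stack and its ground truth.

    AISs are laid out on a grid of non-overlapping cells, each a straight
    fiber at a random in-plane angle spanning a few consecutive z planes.
    Gephyrin puncta are placed uniformly along each AIS, so the fraction of
    puncta falling inside a cartridge scales with its coverage — coupling
    Pre-SSE and Post-SSE as in real tissue.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape_px
    vz, vy, vx = config.voxel_size_um
    if abs(vy - vx) > 1e-9:
        raise ValueError("anisotropic in-plane voxels are not supported")
    px = vx  # microns per in-plane pixel

    max_len_px = config.ais_length_range_um[1] / px
    cell = int(np.ceil(max_len_px)) + 30
    ncy, ncx = ny // cell, nx // cell
    if ncy * ncx < config.n_ais:
        raise ValueError("field too small for the requested number of AISs")
    cells = [(i, j) for i in range(ncy) for j in range(ncx)]
    rng.shuffle(cells)

    ais_sig = np.zeros((nz, ny, nx), dtype=np.float32)
    chc_sig = np.zeros((nz, ny, nx), dtype=np.float32)
    geph_sig = np.zeros((nz, ny, nx), dtype=np.float32)

    ais_records = []
    all_amps = []

    n_with_cart = int(round(config.n_cartridge_fraction * config.n_ais))
    has_cart = np.zeros(config.n_ais, dtype=bool)
    has_cart[:n_with_cart] = True
    rng.shuffle(has_cart)

    for idx in range(config.n_ais):
        ci, cj = cells[idx]
        cy = (ci + 0.5) * cell
        cx = (cj + 0.5) * cell
        length_um = rng.uniform(*config.ais_length_range_um)
        half_px = length_um / px / 2.0
        for attempt in range(100):
            ang = rng.uniform(0, np.pi)
            dy, dx = np.sin(ang) * half_px, np.cos(ang) * half_px
            y0, x0, y1, x1 = cy - dy, cx - dx, cy + dy, cx + dx
            if 5 <= min(y0, y1) and max(y0, y1) < ny - 5 and 5 <= min(x0, x1) and max(x0, x1) < nx - 5:
                break
        else:
            raise RuntimeError("could not place AIS inside the field after 100 attempts")

        ext = min(config.z_extent_planes, nz)
        z_max = nz - ext
        zc = int(rng.integers(min(1, z_max), z_max + 1))
        z_planes = list(range(zc, zc + ext))
        for z in z_planes:
            _render_fiber(ais_sig[z], y0, x0, y1, x1, config.fiber_sigma_px, config.peak_intensity)

        rec = {
            "center_yx": (cy, cx),
            "endpoints_px": (y0, x0, y1, x1),
            "angle_rad": ang,
            "length_um": length_um,
            "z_planes": z_planes,
            "has_cartridge": bool(has_cart[idx]),
            "coverage": np.nan,
            "cart_interval_um": None,
            "puncta": [],
        }

        cart_interval = None
        if has_cart[idx]:
            cov = rng.uniform(*config.cartridge_coverage_range)
            cart_len_um = cov * length_um + config.cartridge_overhang_um
            start_um = rng.uniform(0, max(1e-9, length_um - cov * length_um))
            rec["coverage"] = cov
            cart_interval = (start_um, start_um + cart_len_um)
            rec["cart_interval_um"] = cart_interval

        # gephyrin puncta along the AIS axis, in the central plane; spots are
        # kept >= 1 um apart and >= 1 um clear of cartridge boundaries so
        # ground-truth membership is unambiguous at rendering resolution
        n_p = int(rng.integers(config.puncta_per_ais_range[0], config.puncta_per_ais_range[1] + 1))
        zmid = z_planes[len(z_planes) // 2]
        positions: list[float] = []
        for _ in range(50 * n_p):
            if len(positions) == n_p:
                break
            pos = rng.uniform(0.05, 0.95) * length_um
            if any(abs(pos - q) < 1.0 for q in positions):
                continue
            if cart_interval is not None and (
                abs(pos - cart_interval[0]) < 1.0 or abs(pos - cart_interval[1]) < 1.0
            ):
                continue
            positions.append(pos)
        for pos in sorted(positions):
            f = pos / length_um
            py, qx = y0 + f * (y1 - y0), x0 + f * (x1 - x0)
            amp = config.peak_intensity * rng.uniform(0.5, 1.5)
            all_amps.append(amp)
            _stamp_gaussian(geph_sig[zmid], py, qx, config.puncta_sigma_px, amp)
            rec["puncta"].append({"pos_um": pos, "yx_px": (py, qx), "z": zmid, "amp": amp})

        if has_cart[idx]:
            start_um, _end = cart_interval
            cart_len_um = _end - start_um
            n_b = max(2, int(np.ceil(cart_len_um / config.bouton_spacing_um)))
            bsig = rng.uniform(*config.bouton_sigma_range_px)
            rec["bouton_sigma_px"] = bsig
            ux, uy = (x1 - x0) / (length_um / px), (y1 - y0) / (length_um / px)
            # slight lateral offset of the bouton string from the fiber axis
            oy, ox = ux, -uy
            for f in np.linspace(0, 1, n_b):
                pos_um = start_um + f * cart_len_um
                pos_px = pos_um / px
                by = y0 + uy * pos_px + 0.5 * oy
                bx = x0 + ux * pos_px + 0.5 * ox
                for z in z_planes:
                    _stamp_gaussian(chc_sig[z], by, bx, bsig, config.peak_intensity)
        ais_records.append(rec)

    # background gephyrin puncta away from every AIS
    endpoints = np.array([r["endpoints_px"] for r in ais_records]) if ais_records else None
    n_bg = 0
    attempts = 0
    while n_bg < config.n_background_puncta and attempts < 20 * config.n_background_puncta:
        attempts += 1
        by = rng.uniform(10, ny - 10)
        bx = rng.uniform(10, nx - 10)
        if endpoints is not None:
            p = np.array([by, bx])
            a = endpoints[:, :2]
            bvec = endpoints[:, 2:] - a
            tpar = np.clip(
                np.einsum("ij,ij->i", p - a, bvec) / np.maximum((bvec**2).sum(1), 1e-9), 0, 1
            )
            dmin = np.sqrt(((a + tpar[:, None] * bvec - p) ** 2).sum(1).min())
            if dmin < 15:
                continue
        amp = config.peak_intensity * rng.uniform(*config.background_amp_range)
        z = int(rng.integers(0, nz))
        _stamp_gaussian(geph_sig[z], by, bx, config.puncta_sigma_px, amp)
        all_amps.append(amp)
        n_bg += 1

    # ground-truth SSE from the noiseless masks, by the same formulas the
    # quantification pipeline applies (half-max masks, projected overlap area)
    amps = np.asarray(all_amps)
    med, sd = (np.median(amps), np.std(amps)) if amps.size else (0.0, 1.0)
    pre_true = np.full(config.n_ais, np.nan)
    post_true = np.full(config.n_ais, np.nan)
    half = 0.5 * config.peak_intensity
    ais_mask_proj = (ais_sig > half).any(axis=0)
    chc_mask_proj = (chc_sig > half).any(axis=0)
    from scipy import ndimage as ndi

    lab, n_lab = ndi.label(ais_mask_proj)
    for idx, rec in enumerate(ais_records):
        if not rec["has_cartridge"]:
            continue
        y0, x0, y1, x1 = rec["endpoints_px"]
        own = lab == lab[int(round((y0 + y1) / 2)), int(round((x0 + x1) / 2))]
        overlap = own & chc_mask_proj
        a_um2 = float(overlap.sum()) * px * px
        l_ais = rec["length_um"]
        c0, c1 = rec["cart_interval_um"]
        l_chc = c1 - c0
        l_on = min(c1, l_ais) - max(c0, 0.0)
        rec["A_um2_true"] = a_um2
        rec["L_chc_um_true"] = l_chc
        rec["L_chc_ais_um_true"] = l_on
        pre_true[idx] = (a_um2 / l_ais) * (l_on / l_chc)
        z_all = z_in = 0.0
        for p in rec["puncta"]:
            z = (p["amp"] - med) / sd if sd > 0 else 0.0
            p["z_score_true"] = z
            p["in_cartridge"] = c0 <= p["pos_um"] <= c1
            z_all += z
            z_in += z if p["in_cartridge"] else 0.0
        post_true[idx] = z_in / z_all if z_all != 0 else np.nan

    background = config.peak_intensity / config.snr
    channels = {}
    for name, sig in (("gephyrin", geph_sig), ("chc", chc_sig), ("ais", ais_sig)):
        img = rng.poisson(sig + background).astype(np.float32)
        img += rng.standard_normal(img.shape).astype(np.float32) * config.read_noise_sd
        channels[name] = np.clip(img, 0, None)

    stack = ImageStack(channels=channels, voxel_size_um=config.voxel_size_um)
    truth = GroundTruth(
        ais_geometry_true=ais_records,
        pre_sse_true=pre_true,
        post_sse_true=post_true,
    )
    return stack, truth
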