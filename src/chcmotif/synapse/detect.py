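"""Per-plane segmentation and 3-D registration of AIS fibers and ChC cartridges.

Each plane of the AnkG (AIS) and TdTomato (ChC) channels is binarized with a
local-mean adaptive threshold (sensitivity 0.08 / neighborhood 19 for AIS,
sensitivity 0 / neighborhood 15 for ChC), connected components become
candidate segments, segments are filtered on intensity, area and width, and
finally linked across adjacent planes by mask overlap into 3-D objects.
Only AISs longer than 10 um are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_local
from skimage.measure import label, regionprops


@dataclass
class SegmentationConfig:
    # adaptive-threshold parameters per role
    sensitivity: dict = field(default_factory=lambda: {"ais": 0.08, "chc": 0.0})
    neighborhood: dict = field(default_factory=lambda: {"ais": 19, "chc": 15})
    # candidate filters ("intensity, size and width"); numeric values are
    # package defaults, adjustable per dataset
    min_area_px: int = 10
    intensity_k_sd: float = 1.0  # min mean intensity = plane median + k * sd
    max_width_um: dict = field(default_factory=lambda: {"ais": 3.0, "chc": 4.0})
    min_ais_length_um: float = 10.0
    roi_extension_um: float = 5.0
    corridor_halfwidth_um: float = 1.5
    puncta_sigma_px: float = 1.5


@dataclass
class PlaneSegment:
    plane: int
    mask: np.ndarray  # boolean, full-plane
    area_px: int
    mean_intensity: float
    width_px: float


@dataclass
class Object3D:
    """A registered AIS fiber or ChC cartridge."""

    segments: list  # PlaneSegment members
    proj_mask: np.ndarray  # 2-D any-plane projection
    planes: list
    axis_origin: np.ndarray | None = None  # (y, x) px
    axis_dir: np.ndarray | None = None  # unit (y, x)
    length_um: float = np.nan

    @property
    def centroid(self) -> np.ndarray:
        ys, xs = np.nonzero(self.proj_mask)
        return np.array([ys.mean(), xs.mean()])


def segment_planes(
    channel: np.ndarray, role: str, config: SegmentationConfig | None = None
) -> list[list[PlaneSegment]]:
    """Candidate segments per plane of one channel.

    The adaptive threshold is ``local mean * (1 - sensitivity)`` over the
    role's neighborhood (bright-on-dark). Candidates below the area,
    intensity or width criteria are discarded.
    """
    config = config or SegmentationConfig()
    sens = config.sensitivity[role]
    block = config.neighborhood[role]
    if block % 2 == 0:
        block += 1
    out = []
    vol = channel[None] if channel.ndim == 2 else channel
    for z in range(vol.shape[0]):
        plane = vol[z].astype(float)
        segs = []
        if plane.max() > plane.min():
            local_mean = threshold_local(plane, block_size=block, method="mean")
            binary = plane > local_mean * (1.0 - sens)
            med = float(np.median(plane))
            sd_rob = 1.4826 * float(np.median(np.abs(plane - med)))
            # global noise floor: keeps background speckle from percolating
            # into one giant component that swallows real fibers
            binary &= plane > med + 2.0 * sd_rob
            sd = float(np.std(plane))
            min_int = med + config.intensity_k_sd * sd
            lab = label(binary, connectivity=2)
            for rp in regionprops(lab, intensity_image=plane):
                if rp.area < config.min_area_px:
                    continue
                if rp.intensity_mean < min_int:
                    continue
                m = np.zeros(plane.shape, dtype=bool)
                m[tuple(rp.coords.T)] = True
                segs.append(
                    PlaneSegment(
                        plane=z,
                        mask=m,
                        area_px=int(rp.area),
                        mean_intensity=float(rp.intensity_mean),
                        width_px=float(rp.axis_minor_length),
                    )
                )
        out.append(segs)
    return out


def _principal_axis(mask: np.ndarray):
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([ys, xs]).astype(float)
    c = pts.mean(axis=0)
    centered = pts - c
    cov = centered.T @ centered / len(pts)
    w, v = np.linalg.eigh(cov)
    u = v[:, np.argmax(w)]
    proj = centered @ u
    return c, u, float(proj.min()), float(proj.max())


def register_segments_3d(
    plane_segments: list,
    pixel_size_um: float,
    role: str = "ais",
    config: SegmentationConfig | None = None,
) -> list[Object3D]:
    """Link per-plane segments across adjacent planes by mask overlap
    (>= 1 px) into 3-D objects; apply the width filter and, for AISs, the
    10-um minimum length."""
    config = config or SegmentationConfig()
    max_w = config.max_width_um[role] / pixel_size_um

    flat = [(z, s) for z, segs in enumerate(plane_segments) for s in segs]
    n = len(flat)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_plane: dict[int, list[int]] = {}
    for i, (z, _) in enumerate(flat):
        by_plane.setdefault(z, []).append(i)
    for z in sorted(by_plane):
        for i in by_plane[z]:
            for j in by_plane.get(z + 1, []):
                if np.any(flat[i][1].mask & flat[j][1].mask):
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    objects = []
    shape = None
    for segs in plane_segments:
        if segs:
            shape = segs[0].mask.shape
            break
    if shape is None:
        return objects
    for members in groups.values():
        segs = [flat[i][1] for i in members]
        proj = np.zeros(shape, dtype=bool)
        for s in segs:
            proj |= s.mask
        c, u, lo, hi = _principal_axis(proj)
        length_um = (hi - lo) * pixel_size_um
        # width filter on the registered object: extent orthogonal to the axis
        ys, xs = np.nonzero(proj)
        ortho = (np.column_stack([ys, xs]) - c) @ np.array([-u[1], u[0]])
        if float(ortho.max() - ortho.min()) > max_w:
            continue
        if role == "ais" and length_um <= config.min_ais_length_um:
            continue
        objects.append(
            Object3D(
                segments=segs,
                proj_mask=proj,
                planes=sorted({s.plane for s in segs}),
                axis_origin=c + u * lo,
                axis_dir=u,
                length_um=length_um,
            )
        )
    return objects


@dataclass
class Contact:
    ais: Object3D
    cartridges: list  # overlapping Object3D cartridges
    overlap_proj: np.ndarray  # 2-D ChC-on-AIS mask
    is_contact: bool


def classify_contacts(ais_objects: list, cartridge_objects: list) -> list[Contact]:
    """Per AIS, overlay cartridges plane by plane; any co-localized area at
    all makes it a ChC-AIS contact."""
    contacts = []
    for ais in ais_objects:
        carts = []
        overlap = np.zeros_like(ais.proj_mask)
        ais_by_plane: dict[int, np.ndarray] = {}
        for s in ais.segments:
            if s.plane in ais_by_plane:
                ais_by_plane[s.plane] = ais_by_plane[s.plane] | s.mask
            else:
                ais_by_plane[s.plane] = s.mask
        for cart in cartridge_objects:
            hit = False
            for s in cart.segments:
                if s.plane in ais_by_plane:
                    ov = ais_by_plane[s.plane] & s.mask
                    if ov.any():
                        hit = True
                        overlap |= ov
            if hit:
                carts.append(cart)
        contacts.append(
            Contact(ais=ais, cartridges=carts, overlap_proj=overlap, is_contact=bool(carts))
        )
    return contacts
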