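"""ChC-AIS detection, geometry, SSE parameters and bootstrap comparison."""

import numpy as np
import pytest

from chcmotif.synapse.compare import bootstrap_compare
from chcmotif.synapse.detect import (
    Contact,
    Object3D,
    PlaneSegment,
    SegmentationConfig,
    classify_contacts,
    register_segments_3d,
    segment_planes,
)
from chcmotif.synapse.quantify import (
    GephyrinPunctum,
    assign_puncta,
    classify_subgroups,
    compute_post_sse,
    compute_pre_sse,
    detect_gephyrin,
    measure_geometry,
)
from chcmotif.synthetic.stack import StackSimConfig, _stamp_gaussian, simulate_synapse_stack


def make_object(mask, plane=0):
    seg = PlaneSegment(plane=plane, mask=mask, area_px=int(mask.sum()),
                       mean_intensity=1.0, width_px=3.0)
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([ys, xs]).astype(float)
    c = pts.mean(axis=0)
    cov = (pts - c).T @ (pts - c) / len(pts)
    w, v = np.linalg.eigh(cov)
    u = v[:, np.argmax(w)]
    proj = (pts - c) @ u
    return Object3D(
        segments=[seg], proj_mask=mask, planes=[plane],
        axis_origin=c + u * proj.min(), axis_dir=u,
        length_um=float(proj.max() - proj.min()),
    )


def post_fixture(all_inside):
    """One AIS with 5 puncta of arbitrary positive z-scores; inside or
    outside the ChC-on-AIS overlap mask."""
    ais = np.zeros((40, 80), dtype=bool)
    ais[18:22, 5:75] = True
    overlap = np.zeros_like(ais)
    overlap[18:22, 30:60] = True
    contact = Contact(ais=make_object(ais), cartridges=[object()], overlap_proj=overlap,
                      is_contact=True)
    xs = np.linspace(32, 58, 5) if all_inside else np.linspace(7, 27, 5)
    puncta = [
        GephyrinPunctum(z=0, y=20.0, x=float(x), amplitude=50 + 10 * i, z_score=0.5 + 0.3 * i)
        for i, x in enumerate(xs)
    ]
    assign_puncta(puncta, [contact])
    return [p for p in puncta if p.ais_id == 0]


class TestSegmentPlanes:
    def test_uniform_plane_no_segments(self):
        segs = segment_planes(np.full((64, 64), 7.0), "ais")
        assert segs[0] == []

    def test_single_bright_bar(self):
        img = np.full((64, 64), 5.0)
        img[30:33, 20:35] = 100.0
        segs = segment_planes(img, "ais")[0]
        assert len(segs) == 1
        ys, xs = np.nonzero(segs[0].mask)
        assert ys.min() >= 29 and ys.max() <= 33
        assert set(range(20, 35)) <= set(xs.tolist())

    def test_two_separated_bars(self):
        img = np.full((64, 64), 5.0)
        img[10:13, 5:25] = 100.0
        img[45:48, 30:55] = 100.0
        segs = segment_planes(img, "chc")[0]
        assert len(segs) == 2


class TestRegistration:
    def _fiber_planes(self, length_px, n_planes=5, shape=(64, 200)):
        vol = np.full((n_planes,) + shape, 5.0)
        vol[:, 30:33, 10 : 10 + length_px] = 100.0
        return segment_planes(vol, "ais")

    def test_straight_fiber_length(self):
        # 15 um at 1 um/px spanning 5 planes
        planes = self._fiber_planes(15)
        objs = register_segments_3d(planes, pixel_size_um=1.0, role="ais")
        assert len(objs) == 1
        assert objs[0].length_um == pytest.approx(15.0, rel=0.1)
        assert objs[0].planes == [0, 1, 2, 3, 4]

    def test_short_fiber_excluded_by_10um_filter(self):
        planes = self._fiber_planes(8)
        objs = register_segments_3d(planes, pixel_size_um=1.0, role="ais")
        assert objs == []

    def test_two_parallel_fibers_stay_separate(self):
        imgs = []
        for z in range(3):
            img = np.full((64, 200), 5.0)
            img[20:23, 10:40] = 100.0
            img[40:43, 10:40] = 100.0
            imgs.append(segment_planes(img, "ais")[0])
        objs = register_segments_3d(imgs, pixel_size_um=1.0, role="ais")
        assert len(objs) == 2


class TestContacts:
    def test_one_voxel_overlap_is_contact(self):
        ais = np.zeros((40, 40), dtype=bool)
        ais[20, 5:30] = True
        cart = np.zeros_like(ais)
        cart[20, 29] = True  # single shared voxel
        contacts = classify_contacts([make_object(ais)], [make_object(cart)])
        assert contacts[0].is_contact
        assert contacts[0].overlap_proj.sum() == 1

    def test_zero_overlap_not_contact(self):
        ais = np.zeros((40, 40), dtype=bool)
        ais[20, 5:30] = True
        cart = np.zeros_like(ais)
        cart[25, 5:30] = True
        contacts = classify_contacts([make_object(ais)], [make_object(cart)])
        assert not contacts[0].is_contact

    def test_generative_contact_fraction_recovered(self):
        cfg = StackSimConfig(n_ais=20, n_cartridge_fraction=0.5, snr=10, seed=9)
        _, truth = simulate_synapse_stack(cfg)
        frac = np.mean([r["has_cartridge"] for r in truth.ais_geometry_true])
        assert abs(frac - 0.5) <= 0.1


class TestGeometry:
    def _rect_stack(self, ais_len=133, cart_len=67, cart_start=0):
        # ~20 um AIS, ~10 um cartridge at 0.15 um/px
        ais_img = np.full((1, 60, 220), 2.0, dtype=float)
        chc_img = np.full((1, 60, 220), 2.0, dtype=float)
        ais_img[0, 28:32, 40 : 40 + ais_len] = 100.0
        chc_img[0, 28:32, 40 + cart_start : 40 + cart_start + cart_len] = 100.0
        ais_mask = ais_img[0] > 50
        chc_mask = chc_img[0] > 50
        contact = Contact(
            ais=make_object(ais_mask), cartridges=[make_object(chc_mask)],
            overlap_proj=ais_mask & chc_mask, is_contact=True,
        )
        return contact, ais_img, chc_img

    def test_rectangular_profiles(self):
        contact, ais_img, chc_img = self._rect_stack()
        geom = measure_geometry(contact, ais_img, chc_img, pixel_size_um=0.15)
        assert geom["L_AIS_um"] == pytest.approx(133 * 0.15, abs=0.3)
        assert geom["L_ChC_um"] == pytest.approx(67 * 0.15, abs=0.3)
        assert geom["L_ChC_AIS_um"] == pytest.approx(67 * 0.15, abs=0.3)

    def test_cartridge_half_off_the_end(self):
        contact, ais_img, chc_img = self._rect_stack(cart_start=100)
        # cartridge extends 34 px past the 133-px AIS end
        geom = measure_geometry(contact, ais_img, chc_img, pixel_size_um=0.15)
        assert geom["L_ChC_um"] == pytest.approx(67 * 0.15, abs=0.3)
        assert geom["L_ChC_AIS_um"] == pytest.approx(33 * 0.15, abs=0.45)

    def test_no_chc_signal(self):
        contact, ais_img, _ = self._rect_stack()
        blank = np.zeros_like(ais_img)
        contact.overlap_proj = np.zeros_like(contact.overlap_proj)
        geom = measure_geometry(contact, ais_img, blank, pixel_size_um=0.15)
        assert geom["L_ChC_um"] == 0.0 and geom["A_um2"] == 0.0


class TestPreSse:
    def test_formula_and_scale_law(self):
        g = {"A_um2": 30.0, "L_AIS_um": 20.0, "L_ChC_AIS_um": 8.0, "L_ChC_um": 8.0}
        assert compute_pre_sse(g) == pytest.approx(1.5)
        g["A_um2"] = 0.0
        assert compute_pre_sse(g) == 0.0
        g["A_um2"] = 30.0
        g["L_AIS_um"] = 10.0
        assert compute_pre_sse(g) == pytest.approx(3.0)

    def test_no_cartridge_convention(self):
        assert compute_pre_sse({"A_um2": 0, "L_AIS_um": 15, "L_ChC_AIS_um": 0, "L_ChC_um": 0}) == 0.0


class TestGephyrin:
    def test_single_spot_position_recovery(self):
        img = np.zeros((1, 64, 64), dtype=float)
        _stamp_gaussian(img[0], 30.3, 41.7, 1.5, 100.0)
        img += 1.0
        puncta = detect_gephyrin(img)
        assert len(puncta) == 1
        assert np.hypot(puncta[0].y - 30.3, puncta[0].x - 41.7) < 0.2

    def test_median_amplitude_gets_zero_zscore(self):
        img = np.zeros((1, 128, 64), dtype=float)
        amps = [50.0, 100.0, 150.0]
        for i, a in enumerate(amps):
            _stamp_gaussian(img[0], 20.0 + 40 * i, 30.0, 1.5, a)
        img += 1.0
        puncta = detect_gephyrin(img)
        assert len(puncta) == 3
        by_amp = sorted(puncta, key=lambda p: p.amplitude)
        assert by_amp[1].z_score == pytest.approx(0.0, abs=0.05)

    def test_pair_two_px_apart_resolved(self):
        rng = np.random.default_rng(0)
        img = np.zeros((1, 64, 64), dtype=float)
        _stamp_gaussian(img[0], 30.0, 30.0, 1.5, 200.0)
        _stamp_gaussian(img[0], 30.0, 32.0, 1.5, 200.0)
        img += rng.poisson(20.0, img.shape)
        puncta = detect_gephyrin(img, merge_lateral_px=1.5)
        assert len(puncta) >= 2


class TestPostSse:
    def test_all_puncta_inside_contact_gives_one(self):
        assert compute_post_sse(post_fixture(all_inside=True)) == pytest.approx(1.0)

    def test_no_puncta_inside_contact_gives_zero(self):
        assert compute_post_sse(post_fixture(all_inside=False)) == pytest.approx(0.0)

    def test_half_split(self):
        mine = post_fixture(all_inside=True)
        for p in mine:
            p.z_score = 1.0
        mine[0].in_contact = False
        mine[1].in_contact = False
        # 3 of 5 equal-z puncta inside
        assert compute_post_sse(mine) == pytest.approx(0.6)
        two = [p for p in mine[:2]]
        two[0].in_contact = True
        assert compute_post_sse(two) == pytest.approx(0.5)

    def test_cancellation_flagged_nan(self):
        mine = post_fixture(all_inside=True)
        mine[0].z_score, mine[1].z_score = 1.0, -1.0
        for p in mine[2:]:
            p.z_score = 0.0
        assert np.isnan(compute_post_sse(mine))

    def test_empty_is_zero(self):
        assert compute_post_sse([]) == 0.0


class TestSubgroups:
    @pytest.mark.parametrize(
        "pre,post,want",
        [
            (2.0, 0.7, ("high", "high")),
            (0.4, 0.05, ("low", "low")),
            (1.5, 0.6, ("mid", "mid")),  # boundaries are strict
            (1.0, 0.3, ("mid", "mid")),
        ],
    )
    def test_thresholds(self, pre, post, want):
        assert classify_subgroups(pre, post) == want

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(1)
        for pre, post in zip(rng.uniform(0, 3, 50), rng.uniform(0, 1.2, 50)):
            lp, lq = classify_subgroups(pre, post)
            assert lp in {"high", "mid", "low"} and lq in {"high", "mid", "low"}


class TestBootstrapCompare:
    def _mice(self, rng, n_mice=4, n=400, shift=False):
        out = []
        for _ in range(n_mice):
            x = np.clip(rng.gamma(2.0, 0.4, n), 0, 4)
            if shift:
                mid = (x >= 0.5) & (x <= 1.5)
                idx = np.flatnonzero(mid)
                pick = rng.choice(idx, int(0.1 * mid.sum()), replace=False)
                half = pick.size // 2
                x[pick[:half]] = rng.uniform(1.6, 3.0, half)
                x[pick[half:]] = rng.uniform(0.0, 0.45, pick.size - half)
            out.append(x)
        return out

    def test_null_identity(self):
        # literally the same per-mouse distributions in both conditions
        rng = np.random.default_rng(2)
        a = self._mice(rng, n=2000)
        b = [x.copy() for x in a]
        res = bootstrap_compare(a, b, seed=5)
        assert np.all(np.abs(res["diff_mean"]) <= 2 * res["diff_sd"] + 1e-12)

    def test_constructed_mid_to_extremes_shift_detected(self):
        rng = np.random.default_rng(3)
        b = self._mice(rng, n_mice=4, n=2000)
        a = self._mice(rng, n_mice=4, n=2000, shift=True)
        res = bootstrap_compare(a, b, seed=6)
        sub = res["subgroup_diff_reps"]  # high, mid, low columns
        good = np.sum((sub[:, 0] > 0) & (sub[:, 2] > 0))
        assert good >= 9

    def test_determinism(self):
        rng = np.random.default_rng(4)
        a, b = self._mice(rng), self._mice(rng)
        r1 = bootstrap_compare(a, b, seed=9)
        r2 = bootstrap_compare(a, b, seed=9)
        assert np.array_equal(r1["diff_reps"], r2["diff_reps"])

    def test_small_mouse_excluded_with_warning(self):
        rng = np.random.default_rng(5)
        a = self._mice(rng) + [np.array([0.1, 0.2])]
        b = self._mice(rng)
        with pytest.warns(UserWarning):
            bootstrap_compare(a, b, seed=10)


class TestEndToEndRecovery:
    def test_pre_post_coupling_in_recovered_values(self):
        """Coverage-coupled puncta placement makes recovered Pre- and
        Post-SSE positively rank-correlated."""
        from scipy.stats import spearmanr

        from chcmotif.synapse import quantify_stack

        stack, truth = simulate_synapse_stack(StackSimConfig(n_ais=20, snr=10, seed=13))
        df = quantify_stack(stack)
        sel = df.is_contact & np.isfinite(df.pre_sse) & np.isfinite(df.post_sse)
        rho = spearmanr(df.pre_sse[sel], df.post_sse[sel]).statistic
        assert rho > 0
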