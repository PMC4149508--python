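import numpy as np
import pytest

from radialnav.metrics import motion_error
from radialnav.motion_correct import correct_interleave
from radialnav.selfnav import (
    MotionTrace,
    ROIMask,
    extract_motion,
    make_ellipse_mask,
    masked_mse,
    register_translation,
    si_component,
    translate_image,
)
from radialnav.synthdata import make_motion_trace, make_phantom, simulate_acquisition
from radialnav.recon import SubImage, gridding_reconstruct
from radialnav.trajectory import make_interleaved_radial


class TestEllipseMask:
    def test_covering_ellipse_all_ones(self):
        mask = make_ellipse_mask(32, (16, 16), (100, 100))
        assert np.all(mask.grid == 1)

    def test_area_matches_analytic(self):
        mask = make_ellipse_mask(64, (32, 32), (10, 5))
        assert mask.grid.sum() == pytest.approx(np.pi * 10 * 5, rel=0.05)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            make_ellipse_mask(32, (500, 500), (2, 2))

    def test_values_binary(self):
        mask = make_ellipse_mask(32, (10, 12), (5, 7))
        assert set(np.unique(mask.grid)) <= {0, 1}

    def test_non_binary_grid_rejected(self):
        with pytest.raises(ValueError):
            ROIMask(grid=np.full((4, 4), 0.5), center=(2, 2), semiaxes=(1, 1))


class TestMaskedMse:
    def test_identical_zero(self):
        a = np.random.default_rng(0).standard_normal((16, 16))
        mask = make_ellipse_mask(16, (8, 8), (5, 5))
        assert masked_mse(a, a, mask) == 0.0

    def test_constant_offset(self):
        a = np.zeros((16, 16))
        mask = make_ellipse_mask(16, (8, 8), (5, 5))
        assert masked_mse(a, a + 2.0, mask) == pytest.approx(4.0)

    def test_differences_outside_mask_ignored(self):
        mask = make_ellipse_mask(16, (8, 8), (3, 3))
        a = np.zeros((16, 16))
        b = a.copy()
        b[~mask.indices] = 42.0
        assert masked_mse(a, b, mask) == 0.0

    def test_shape_mismatch_rejected(self):
        mask = make_ellipse_mask(16, (8, 8), (3, 3))
        with pytest.raises(ValueError):
            masked_mse(np.zeros((16, 16)), np.zeros((8, 8)), mask)


@pytest.fixture(scope="module")
def reg_setup():
    n = 96
    ph = make_phantom(n, 1.0, seed=2)
    mask = make_ellipse_mask(n, (n / 2, n / 2), (n / 3, n / 3))
    return ph.image, mask


class TestRegisterTranslation:
    def test_identity(self, reg_setup):
        img, mask = reg_setup
        dx, dy = register_translation(img, img, mask)
        assert abs(dx) < 0.05 and abs(dy) < 0.05

    def test_integer_circular_shift(self, reg_setup):
        img, mask = reg_setup
        moved = np.roll(np.roll(img, -2, axis=0), 3, axis=1)  # content (+3, -2)
        dx, dy = register_translation(moved, img, mask)
        assert dx == pytest.approx(3.0, abs=0.1)
        assert dy == pytest.approx(-2.0, abs=0.1)

    def test_integer_shift_matches_exhaustive_oracle(self, reg_setup):
        img, mask = reg_setup
        moved = np.roll(np.roll(img, 4, axis=0), -5, axis=1)  # content (-5, +4)
        dx, dy = register_translation(moved, img, mask)
        # oracle: exhaustive masked-MSE over all integer shifts
        best, best_c = None, np.inf
        for sx in range(-8, 9):
            for sy in range(-8, 9):
                shifted, valid = translate_image(moved, -sx, -sy)
                sel = mask.indices & valid
                c = np.mean((shifted[sel] - img[sel]) ** 2)
                if c < best_c:
                    best, best_c = (sx, sy), c
        assert best == (-5, 4)
        assert abs(dx - best[0]) <= 0.1 and abs(dy - best[1]) <= 0.1

    def test_subpixel_kspace_shift(self, reg_setup):
        _, mask = reg_setup
        n = 96
        traj = make_interleaved_radial(200, 1, n, 96.0)
        ph = make_phantom(n, 1.0, seed=2)
        static = simulate_acquisition(ph, traj, make_motion_trace(1, 0.0))
        # correcting for (-0.5, -1.25) displaces the content by (+0.5, +1.25)
        shifted = correct_interleave(static, 0, -0.5, -1.25)
        ref = gridding_reconstruct(static).pixels
        mov = gridding_reconstruct(shifted).pixels
        dx, dy = register_translation(mov, ref, mask)
        assert dx == pytest.approx(0.5, abs=0.25)
        assert dy == pytest.approx(1.25, abs=0.25)

    def test_antisymmetry(self, reg_setup):
        img, mask = reg_setup
        moved = np.roll(np.roll(img, 2, axis=0), 1, axis=1)
        d_ab = register_translation(moved, img, mask)
        d_ba = register_translation(img, moved, mask)
        assert abs(d_ab[0] + d_ba[0]) < 0.2
        assert abs(d_ab[1] + d_ba[1]) < 0.2

    def test_shape_mismatch_rejected(self, reg_setup):
        img, mask = reg_setup
        with pytest.raises(ValueError):
            register_translation(img[:-2], img, mask)


@pytest.fixture(scope="module")
def small_acq():
    n = 96
    traj = make_interleaved_radial(144, 8, n, 96.0)
    ph = make_phantom(n, 1.0, seed=3)
    truth = make_motion_trace(8, 7.0, seed=5, pixel_mm=1.0)
    data = simulate_acquisition(ph, traj, truth)
    subs = [gridding_reconstruct(data, m) for m in range(8)]
    mask = make_ellipse_mask(
        n, ph.registry["heart_center"], ph.registry["heart_semiaxes"]
    )
    return ph, truth, subs, mask


class TestExtractMotion:
    def test_identical_sub_images_zero_trace(self):
        sub = SubImage(
            pixels=make_phantom(64, 1.0, seed=1).image,
            interleave_id=0,
            method="LN",
            pixel_mm=1.0,
        )
        trace = extract_motion([sub] * 4, make_ellipse_mask(64, (32, 32), (20, 20)))
        assert np.allclose(trace.dx_mm, 0, atol=0.05)
        assert np.allclose(trace.dy_mm, 0, atol=0.05)
        assert trace.dx_mm[0] == 0.0 and trace.dy_mm[0] == 0.0

    def test_recovers_known_displacements(self, small_acq):
        ph, truth, subs, mask = small_acq
        trace = extract_motion(subs, mask, truth.reference_index)
        _, mean_mm, _, _ = motion_error(trace, truth)
        assert mean_mm <= 0.5  # pixels == mm here (1 mm pixels)

    def test_reference_invariance_up_to_offset(self, small_acq):
        ph, truth, subs, mask = small_acq
        t0 = extract_motion(subs, mask, 0)
        t3 = extract_motion(subs, mask, 3)
        off_x = t0.dx_mm - t3.dx_mm
        off_y = t0.dy_mm - t3.dy_mm
        assert np.ptp(off_x) < 0.4 and np.ptp(off_y) < 0.4

    def test_mask_excludes_asynchronous_confounder(self):
        n = 96
        traj = make_interleaved_radial(144, 8, n, 96.0)
        ph = make_phantom(n, 1.0, seed=3, with_confounder=True)
        truth = make_motion_trace(8, 7.0, seed=5, pixel_mm=1.0)
        conf_trace = make_motion_trace(8, 10.0, seed=99, pixel_mm=1.0, anisotropy=0.9)
        data = simulate_acquisition(ph, traj, truth, confounder_trace=conf_trace)
        subs = [gridding_reconstruct(data, m) for m in range(8)]
        heart = make_ellipse_mask(
            n, ph.registry["heart_center"], ph.registry["heart_semiaxes"]
        )
        whole = make_ellipse_mask(n, (n / 2, n / 2), (n, n))
        err_heart = motion_error(
            extract_motion(subs, heart, truth.reference_index), truth
        )[1]
        err_whole = motion_error(
            extract_motion(subs, whole, truth.reference_index), truth
        )[1]
        assert err_heart < err_whole

    def test_too_few_sub_images_rejected(self, small_acq):
        _, _, subs, mask = small_acq
        with pytest.raises(ValueError):
            extract_motion(subs[:1], mask)


class TestSiComponent:
    def test_zero_trace_zero_si(self):
        trace = MotionTrace(dx_mm=np.zeros(5), dy_mm=np.zeros(5), pixel_mm=1.0)
        assert np.all(si_component(trace, np.eye(3)) == 0)

    def test_slice_y_equals_patient_z(self):
        # orientation mapping patient (x,y,z) -> slice (x,z,-y): the slice
        # in-plane y axis coincides with patient z, so si == dy
        R = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, -1.0, 0]])
        trace = MotionTrace(
            dx_mm=np.array([0.0, 1.0]), dy_mm=np.array([0.0, 2.5]), pixel_mm=1.0
        )
        assert np.allclose(si_component(trace, R), trace.dy_mm)

    def test_inplane_rotation_maps_dx(self):
        # 90-degree in-plane rotation composed with the mapping above:
        # patient z now lies along the slice x axis (up to sign)
        Rz = np.array([[0.0, -1.0, 0], [1.0, 0, 0], [0, 0, 1.0]])
        Ry2z = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, -1.0, 0]])
        R = Rz @ Ry2z
        trace = MotionTrace(
            dx_mm=np.array([0.0, 3.0]), dy_mm=np.array([0.0, 0.0]), pixel_mm=1.0
        )
        si = si_component(trace, R)
        assert np.allclose(np.abs(si), trace.dx_mm)

    def test_non_orthonormal_rejected(self):
        trace = MotionTrace(dx_mm=np.zeros(3), dy_mm=np.zeros(3), pixel_mm=1.0)
        with pytest.raises(ValueError):
            si_component(trace, np.eye(3) * 2.0)


class TestMotionTrace:
    def test_reference_entry_validation(self):
        with pytest.raises(ValueError):
            MotionTrace(dx_mm=np.zeros(3), dy_mm=np.zeros(3), pixel_mm=1.0,
                        reference_index=5)

    def test_pixel_conversion(self):
        t = MotionTrace(dx_mm=np.array([2.0]), dy_mm=np.array([-3.0]), pixel_mm=2.0)
        assert t.dx_px[0] == 1.0 and t.dy_px[0] == -1.5

    def test_text_export_roundtrip(self, tmp_path):
        t = MotionTrace(
            dx_mm=np.array([0.0, 1.25]), dy_mm=np.array([0.0, -2.5]), pixel_mm=1.0
        )
        path = tmp_path / "trace.tsv"
        t.to_text(path)
        rows = np.loadtxt(path, skiprows=1)
        assert np.allclose(rows[:, 1], t.dx_mm)
        assert np.allclose(rows[:, 2], t.dy_mm)
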