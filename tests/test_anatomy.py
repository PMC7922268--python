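import numpy as np
import pytest

from kneegap.anatomy import (
    AnatomicalFrame,
    LandmarkSet,
    axis_fea,
    axis_pca,
    axis_tea,
    axis_wsl,
    build_frame,
    compute_hka,
    femoral_mechanical_axis,
    tibial_mechanical_axis,
)
from kneegap.cohort import KneeParams, generate_knee
from kneegap.pipeline import reference_axes


def make_landmarks(side="left", hip=(0, 0, 400), ankle=(0, 0, -400),
                   notch=(0, 0, 0), tib_center=(0, 0, -60),
                   med_epi=(-40, 0, -30), lat_epi=(40, 0, -30),
                   groove=(0, 18, -28)):
    return LandmarkSet(
        hip_center=hip, ankle_center=ankle, intercondylar_notch=notch,
        proximal_tibia_center=tib_center, medial_epicondylar_sulcus=med_epi,
        lateral_epicondyle=lat_epi, trochlear_groove_point=groove, side=side,
    )


class TestMechanicalAxes:
    def test_femoral_vertical(self):
        lm = make_landmarks()
        np.testing.assert_allclose(femoral_mechanical_axis(lm), (0, 0, 1))

    def test_femoral_normalized(self):
        lm = make_landmarks(hip=(0, 40, 398))
        v = np.array([0, 40, 398], float)
        np.testing.assert_allclose(femoral_mechanical_axis(lm), v / np.linalg.norm(v))

    def test_swapping_endpoints_negates(self):
        lm = make_landmarks(hip=(5, 10, 380))
        swapped = make_landmarks(hip=(0, 0, 0), notch=(5, 10, 380))
        np.testing.assert_allclose(
            femoral_mechanical_axis(lm), -femoral_mechanical_axis(swapped), atol=1e-12
        )

    def test_tibial_vertical(self):
        lm = make_landmarks(ankle=(0, 0, -360), tib_center=(0, 0, 0))
        np.testing.assert_allclose(tibial_mechanical_axis(lm), (0, 0, 1))

    def test_tilted_five_degrees(self):
        t = np.deg2rad(5)
        lm = make_landmarks(ankle=(360 * np.sin(t), 0, -60 - 360 * np.cos(t)))
        dot = np.dot(tibial_mechanical_axis(lm), femoral_mechanical_axis(lm))
        assert dot == pytest.approx(np.cos(t), abs=1e-12)

    def test_coincident_rejected(self):
        with pytest.raises(ValueError):
            make_landmarks(hip=(0, 0, 0))


class TestBuildFrame:
    def test_orthonormal_and_anterior_convention(self):
        # canonical left-knee layout; the right knee is its world-x mirror
        layouts = {
            "left": make_landmarks(side="left"),
            "right": make_landmarks(side="right", med_epi=(40, 0, -30), lat_epi=(-40, 0, -30)),
        }
        for side, lm in layouts.items():
            fr = build_frame(lm)
            for a, b in [(fr.x, fr.y), (fr.y, fr.z), (fr.x, fr.z)]:
                assert abs(np.dot(a, b)) < 1e-9
            for v in (fr.x, fr.y, fr.z):
                assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
            # x is lateral (epicondylar direction); y anterior for both sides
            assert np.dot(fr.x, lm.lateral_epicondyle - lm.medial_epicondylar_sulcus) > 0
            assert np.dot(fr.y, [0, 1, 0]) > 0

    def test_handedness_flips_with_side(self):
        lm_right = make_landmarks(side="right", med_epi=(40, 0, -30), lat_epi=(-40, 0, -30))
        assert build_frame(make_landmarks(side="left")).handedness == 1
        assert build_frame(lm_right).handedness == -1

    def test_gram_schmidt_vs_qr_oracle(self, rng):
        for _ in range(25):
            hip = rng.normal((0, 0, 400), 30)
            med = rng.normal((-40, 0, -30), 5)
            lat = rng.normal((40, 0, -30), 5)
            lm = make_landmarks(hip=hip, med_epi=med, lat_epi=lat)
            fr = build_frame(lm)
            z = femoral_mechanical_axis(lm)
            Q, _ = np.linalg.qr(np.column_stack([z, lat - med]))
            x_qr = Q[:, 1] * np.sign(np.dot(Q[:, 1], lat - med))
            np.testing.assert_allclose(fr.x, x_qr, atol=1e-9)

    def test_degenerate_epicondyles_rejected(self):
        with pytest.raises(ValueError):
            build_frame(make_landmarks(med_epi=(0, 0, -50), lat_epi=(0.1, 0, 50)))


class TestHKA:
    def test_identical_axes_zero(self):
        fr = build_frame(make_landmarks())
        assert compute_hka((0, 0, 1), (0, 0, 1), fr) == 0.0

    def test_antisymmetry(self):
        fr = build_frame(make_landmarks())
        t = np.deg2rad(6)
        tib = np.array([-np.sin(t), 0, np.cos(t)])
        tib_neg = np.array([np.sin(t), 0, np.cos(t)])
        h = compute_hka((0, 0, 1), tib, fr)
        assert h == pytest.approx(6.0, abs=1e-9)
        assert compute_hka((0, 0, 1), tib_neg, fr) == pytest.approx(-h, abs=1e-9)

    def test_generator_round_trip(self):
        m = generate_knee(KneeParams(hka_deg=8.2))
        fr = build_frame(m.landmarks)
        h = compute_hka(
            femoral_mechanical_axis(m.landmarks), tibial_mechanical_axis(m.landmarks), fr
        )
        assert h == pytest.approx(8.2, abs=1e-6)


class TestAxisTEA:
    def test_symmetric_equals_frame_x(self):
        lm = make_landmarks()
        fr = build_frame(lm)
        np.testing.assert_allclose(axis_tea(lm, fr).direction, fr.x, atol=1e-12)

    def test_z_perturbation_invariant(self, rng):
        lm = make_landmarks()
        fr = build_frame(lm)
        base = axis_tea(lm, fr).direction
        for _ in range(10):
            dz = rng.normal(scale=5.0)
            lm2 = make_landmarks(lat_epi=(40, 0, -30 + dz))
            np.testing.assert_allclose(axis_tea(lm2, fr).direction, base, atol=1e-12)


class TestAxisWSL:
    def test_ap_line_along_y_gives_x(self):
        lm = make_landmarks(groove=(0, 18, -28))
        fr = build_frame(lm)
        np.testing.assert_allclose(axis_wsl(lm, fr).direction, fr.x, atol=1e-12)

    def test_equivariance_under_rotation(self):
        fr = build_frame(make_landmarks())
        for tau in (-10, -3, 4, 12):
            t = np.deg2rad(tau)
            lm = make_landmarks(groove=(18 * np.sin(t), 18 * np.cos(t), -28))
            d = axis_wsl(lm, fr).direction
            expected = np.array([np.cos(t), -np.sin(t), 0.0])
            np.testing.assert_allclose(d, expected, atol=1e-9)

    def test_degenerate_ap_line_rejected(self):
        lm = make_landmarks(groove=(0, 0, -28))  # directly distal of the notch
        fr = build_frame(make_landmarks())
        with pytest.raises(ValueError):
            axis_wsl(lm, fr)


def _arc(center, radius, n=40, x=0.0):
    th = np.deg2rad(np.linspace(40, 100, n))
    return np.column_stack(
        [np.full(n, x), center[1] - radius * np.sin(th), center[2] - radius * np.cos(th)]
    )


class TestAxisPCA:
    def test_symmetric_condyles_exactly_three_degrees(self):
        lm = make_landmarks()
        fr = build_frame(lm)
        med = _arc((0, -8, -30), 20, x=-22)
        lat = _arc((0, -8, -30), 20, x=22)
        res = axis_pca(med, lat, fr)
        t = np.deg2rad(3)
        np.testing.assert_allclose(
            res.direction, np.array([np.cos(t), -np.sin(t), 0.0]), atol=1e-9
        )
        # lateral end posterior (external rotation)
        assert np.dot(res.direction, fr.y) < 0

    def test_angle_to_raw_is_exactly_rotation(self, rng):
        lm = make_landmarks()
        fr = build_frame(lm)
        for _ in range(10):
            dy = rng.normal(scale=2.0)
            med = _arc((0, -8 + dy, -30), 20 + rng.uniform(-2, 2), x=-22)
            lat = _arc((0, -8, -30), 20 + rng.uniform(-2, 2), x=22)
            res = axis_pca(med, lat, fr, external_rotation_deg=3.0)
            cosang = np.clip(np.dot(res.direction, res.diagnostics["raw_pca"]), -1, 1)
            assert np.degrees(np.arccos(cosang)) == pytest.approx(3.0, abs=1e-9)

    def test_mirror_symmetric_left_right(self):
        for asym in (0.0, 1.5):
            frames = {}
            for side in ("right", "left"):
                m = generate_knee(KneeParams(side=side, posterior_asym=asym))
                fr = build_frame(m.landmarks)
                res = reference_axes(m, fr)["PCA"]
                frames[side] = fr.dir_to_frame(res.direction)
            np.testing.assert_allclose(frames["right"], frames["left"], atol=1e-12)

    def test_empty_region_rejected(self):
        fr = build_frame(make_landmarks())
        with pytest.raises(ValueError):
            axis_pca(np.empty((0, 3)), _arc((0, -8, -30), 20), fr)


class TestAxisFEA:
    def test_exact_arcs_recover_centers(self):
        m = generate_knee(KneeParams(posterior_asym=1.0, wear_fem_lat=1.5))
        fr = build_frame(m.landmarks)
        res = reference_axes(m, fr)["FEA"]
        for comp in ("medial", "lateral"):
            c = fr.to_frame(res.diagnostics[f"center_{comp}"])
            np.testing.assert_allclose(c, m.truth[f"fea_center_{comp}"], atol=1e-6)
            assert res.diagnostics[f"circle_{comp}"].radius == pytest.approx(
                m.truth[f"fea_radius_{comp}"], abs=1e-6
            )

    def test_coaxial_equal_radius_parallel_to_tea(self):
        lm = make_landmarks()
        fr = build_frame(lm)
        med = _arc((0, -8, -30), 20, x=-22)
        lat = _arc((0, -8, -30), 20, x=22)
        res = axis_fea(med, lat, fr)
        np.testing.assert_allclose(res.direction, axis_tea(lm, fr).direction, atol=1e-9)

    def test_offset_centers_closed_form_angle(self):
        lm = make_landmarks()
        fr = build_frame(lm)
        med = _arc((0, -9, -30), 20, x=-22)  # centers offset 2 mm in y, 44 mm apart
        lat = _arc((0, -7, -30), 20, x=22)
        res = axis_fea(med, lat, fr)
        ang = np.degrees(
            np.arctan2(np.dot(res.direction, fr.y), np.dot(res.direction, fr.x))
        )
        assert ang == pytest.approx(np.degrees(np.arctan2(2, 44)), abs=1e-6)

    def test_too_few_points_rejected(self):
        fr = build_frame(make_landmarks())
        with pytest.raises(ValueError, match="medial"):
            axis_fea(_arc((0, -8, -30), 20, n=5, x=-22), _arc((0, -8, -30), 20, x=22), fr)


class TestReferenceAxisInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_unit_in_plane_lateral_positive(self, seed):
        rng = np.random.default_rng(seed)
        params = KneeParams(
            side=("left", "right")[seed % 2],
            hka_deg=float(rng.uniform(-10, 15)),
            posterior_asym=float(rng.uniform(-1, 2)),
            distal_asym=float(rng.uniform(-1, 1)),
            tea_rotation_deg=float(rng.uniform(-2, 4)),
            trochlea_rotation_deg=float(rng.uniform(-4, 4)),
            wear_fem_med=float(rng.uniform(0, 2.5)),
            wear_fem_lat=float(rng.uniform(0, 2.5)),
            seed=seed,
        )
        m = generate_knee(params)
        fr = build_frame(m.landmarks)
        for res in reference_axes(m, fr).values():
            assert np.linalg.norm(res.direction) == pytest.approx(1.0, abs=1e-9)
            assert abs(np.dot(res.direction, fr.z)) < 1e-9
            assert np.dot(res.direction, fr.x) > 0
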