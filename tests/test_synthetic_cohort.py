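import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lordquant as lq
from lordquant.errors import CapacityError, InvalidConfigError
from lordquant.quantification import area_of_atrophy, ez_width, foveal_thickness
from lordquant.registration import reprojection_error
from lordquant.synthetic_cohort import (
    CohortConfig,
    HingeParams,
    eye_noise_sd_for_target_r,
    generate_anatomy,
    hinge_mean,
    perturb_followup,
    render_atrophy_mask,
    simulate_hinge_series,
    synthesize_oct_scan,
)


class TestAnatomy:
    def test_same_seed_reproduces_anatomy(self):
        cfg = CohortConfig(n_patients=2, seed=4)
        a1 = generate_anatomy(cfg, 0, 0)
        a2 = generate_anatomy(cfg, 0, 0)
        assert a1 == a2

    def test_right_eye_onh_is_nasal(self):
        cfg = CohortConfig(n_patients=4, seed=4)
        for p in range(4):
            an = generate_anatomy(cfg, p, 0)
            assert an.laterality == "right"
            assert an.onh_xy[0] > an.fovea_xy[0]

    def test_left_eye_mirrors_to_right_format(self):
        cfg = CohortConfig(n_patients=2, seed=4)
        an = generate_anatomy(cfg, 0, 1)
        assert an.laterality == "left"
        assert an.onh_xy[0] < an.fovea_xy[0]  # temporal pre-flip
        from lordquant.imaging_io import mirror_x

        onh_flipped = mirror_x(an.onh_xy, cfg.image_size)
        fov_flipped = mirror_x(an.fovea_xy, cfg.image_size)
        assert onh_flipped[0] > fov_flipped[0]  # nasal after flip

    def test_fovea_disc_pixel_distance_matches_scale(self):
        cfg = CohortConfig(n_patients=1, seed=4)
        an = generate_anatomy(cfg, 0, 0)
        assert an.fovea_disc_um == pytest.approx(
            an.fovea_disc_px * an.pixel_scale, rel=1e-12
        )
        lo, hi = cfg.fovea_disc_distance_range
        assert lo <= an.fovea_disc_um <= hi

    def test_too_small_image_rejected(self):
        cfg = CohortConfig(n_patients=1, image_size=256, seed=4)
        with pytest.raises(InvalidConfigError):
            generate_anatomy(cfg, 0, 0)


class TestHingeSeries:
    def test_paper_arithmetic_ten_years_post_breakpoint(self):
        params = HingeParams(53.9, 0.0, 0.53, 2.0)
        rng = np.random.default_rng(0)
        val = simulate_hinge_series(params, [63.9], rng)
        assert val[0] == pytest.approx(2.0 + 5.3)

    def test_value_at_breakpoint_is_intercept(self):
        params = HingeParams(60.0, -1.0, 2.0, 7.5)
        rng = np.random.default_rng(0)
        assert simulate_hinge_series(params, [60.0], rng)[0] == pytest.approx(7.5)

    def test_zero_noise_finite_differences_match_slopes(self):
        params = HingeParams(55.0, 0.2, -0.7, 1.0)
        ages = np.arange(45.0, 65.0)
        vals = hinge_mean(params, ages)
        diffs = np.diff(vals)
        np.testing.assert_allclose(diffs[ages[1:] <= 55.0], 0.2)
        np.testing.assert_allclose(diffs[ages[:-1] >= 55.0], -0.7)

    def test_monte_carlo_sd_matches_variance_sum(self):
        params = HingeParams(55.0, 0.0, 0.0, 0.0, 0.4, 0.3, 0.5)
        rng = np.random.default_rng(1)
        draws = np.array(
            [simulate_hinge_series(params, [60.0], rng)[0] for _ in range(10_000)]
        )
        expected = math.sqrt(0.4**2 + 0.3**2 + 0.5**2)
        assert draws.std() == pytest.approx(expected, rel=0.05)

    @given(
        psi=st.floats(min_value=40.0, max_value=80.0),
        pre=st.floats(min_value=-1.0, max_value=1.0),
        post=st.floats(min_value=-1.0, max_value=1.0),
        intercept=st.floats(min_value=-10.0, max_value=10.0),
        age=st.floats(min_value=30.0, max_value=90.0),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_hinge_mean_piecewise_structure(self, psi, pre, post, intercept, age):
        params = HingeParams(psi, pre, post, intercept)
        v = float(hinge_mean(params, [age])[0])
        d = age - psi
        expected = intercept + (pre * d if d < 0 else post * d)
        assert v == pytest.approx(expected, rel=1e-12, abs=1e-12)
        assert float(hinge_mean(params, [psi])[0]) == pytest.approx(intercept)

    def test_interocular_noise_calibration_closed_form(self):
        traj = hinge_mean(HingeParams(53.9, 0, 0.53, 0), np.linspace(56, 66, 10))
        sd = eye_noise_sd_for_target_r(traj, 0.97)
        var_w = np.var(traj)
        r_implied = var_w / (var_w + sd**2)
        assert r_implied == pytest.approx(0.97, abs=1e-12)


class TestMasks:
    def anatomy(self):
        return lq.EyeAnatomy((150.0, 256.0), (370.0, 276.0), 21.0, "right")

    def test_zero_target_is_empty(self):
        rng = np.random.default_rng(0)
        assert render_atrophy_mask(self.anatomy(), 0.0, rng, (512, 512)).sum() == 0

    def test_realised_area_within_two_percent(self):
        an = self.anatomy()
        rng = np.random.default_rng(0)
        mask = render_atrophy_mask(an, 35.0, rng, (512, 512))
        area = mask.sum() * an.pixel_scale**2 / 1e6
        assert area == pytest.approx(35.0, rel=0.02)

    def test_masks_nested_across_targets(self):
        an = self.anatomy()
        masks = [
            render_atrophy_mask(an, t, np.random.default_rng(7), (512, 512))
            for t in (5.0, 20.0, 60.0)
        ]
        assert np.all(masks[0] <= masks[1]) and np.all(masks[1] <= masks[2])

    def test_growth_starts_temporal_of_fovea(self):
        an = self.anatomy()
        rng = np.random.default_rng(3)
        small = render_atrophy_mask(an, 3.0, rng, (512, 512))
        ys, xs = np.nonzero(small)
        assert xs.mean() < an.fovea_xy[0]  # early atrophy temporal

    def test_impossible_target_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(CapacityError):
            render_atrophy_mask(self.anatomy(), 1e5, rng, (512, 512))


class TestPerturbFollowup:
    def make_exam(self):
        an = self.anatomy = lq.EyeAnatomy((150.0, 256.0), (370.0, 276.0), 21.0, "right")
        rng = np.random.default_rng(2)
        mask = render_atrophy_mask(an, 10.0, rng, (512, 512))
        return lq.FAFExam(
            image=np.full((512, 512), 0.5, np.float32),
            atrophy_mask=mask,
            peripapillary_mask=None,
            anatomy=an,
            patient_id="P0",
            eye="OD",
            age_at_exam=60.0,
        )

    def test_zero_shift_plants_identity(self):
        exam = self.make_exam()
        warped, points, h = perturb_followup(exam, 0.0, np.random.default_rng(0))
        np.testing.assert_allclose(h.matrix, np.eye(3))
        np.testing.assert_array_equal(warped.atrophy_mask, exam.atrophy_mask)

    def test_points_satisfy_planted_homography_exactly(self):
        exam = self.make_exam()
        _, points, h = perturb_followup(exam, 10.0, np.random.default_rng(1))
        assert reprojection_error(points, h) < 1e-6

    def test_nine_points_noncollinear(self):
        exam = self.make_exam()
        _, points, _ = perturb_followup(exam, 10.0, np.random.default_rng(1), n_points=9)
        assert points.n == 9
        centred = points.base - points.base.mean(axis=0)
        assert np.linalg.matrix_rank(centred) == 2


class TestOCTSynthesis:
    def test_planted_ez_width_recovered_within_one_ascan(self):
        rng = np.random.default_rng(4)
        scan = synthesize_oct_scan(2400.0, 250.0, 90.0, rng, spacing_um=12.0)
        res = ez_width(scan)
        assert res.total_um == pytest.approx(2400.0, abs=2 * 12.0)

    def test_planted_thicknesses_exact(self):
        rng = np.random.default_rng(4)
        scan = synthesize_oct_scan(2400.0, 251.0, 93.5, rng)
        assert foveal_thickness(scan, "CRT") == pytest.approx(251.0)
        assert foveal_thickness(scan, "PR_RPE") == pytest.approx(93.5)


class TestCohort:
    def test_ledger_has_one_row_per_exam(self, small_cohort):
        assert len(small_cohort.ledger) == len(small_cohort.exams)
        assert small_cohort.ledger.exam_id.is_unique

    def test_eye_series_count(self, stats_cohort):
        cfg = stats_cohort.config
        n_series = stats_cohort.ledger.groupby(["patient_id", "eye"]).ngroups
        assert n_series == cfg.n_patients * cfg.eyes_per_patient

    def test_same_seed_gives_byte_identical_tables(self):
        cfg = CohortConfig(n_patients=3, seed=9)
        c1 = lq.generate_cohort(cfg, render_images=False)
        c2 = lq.generate_cohort(cfg, render_images=False)
        assert c1.ledger.to_csv(index=False) == c2.ledger.to_csv(index=False)
        assert c1.clinical.to_csv(index=False) == c2.clinical.to_csv(index=False)

    def test_no_atrophy_planted_before_age_fifty(self, stats_cohort):
        led = stats_cohort.ledger
        young = led[led.age_years < 50.0]
        if len(young):
            assert young["aa14_target_mm2"].max() <= 1.0

    def test_mask_area_agrees_with_ledger_within_two_percent(self, small_cohort):
        led = small_cohort.ledger.set_index("exam_id")
        for art in small_cohort.exams:
            if art.visit > 0:
                continue  # follow-ups are in the misaligned frame
            exam = art.exam
            target = led.loc[exam.exam_id, "aa14_target_mm2"]
            if target < 1.0:
                continue
            measured = area_of_atrophy(
                exam.atrophy_mask, exam.peripapillary_mask, exam.anatomy, 14.0
            ).aa_mm2
            assert measured == pytest.approx(target, rel=0.02)

    def test_masks_nested_across_visits(self, small_cohort):
        led = small_cohort.ledger
        baseline = {
            (a.exam.patient_id, a.exam.eye): a.exam for a in small_cohort.exams if a.visit == 0
        }
        # registered follow-up masks grow over the baseline mask footprint
        from lordquant.registration import register_exam

        for art in small_cohort.exams:
            if art.visit != 1:
                continue
            base = baseline[(art.exam.patient_id, art.exam.eye)]
            registered, _ = register_exam(art.exam, art.control_points)
            grown = registered.atrophy_mask.sum() >= 0.98 * base.atrophy_mask.sum()
            assert grown

    def test_planted_homography_recovered_from_emitted_points(self, small_cohort):
        from lordquant.registration import estimate_projective

        for art in small_cohort.exams:
            if art.visit == 0:
                continue
            h_est = estimate_projective(art.control_points)
            assert np.abs(h_est.matrix - art.planted_homography.matrix).max() < 1e-8
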