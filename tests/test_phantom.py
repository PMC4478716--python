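"""Analytic phantom: closed-form displacement/strain and cohort generation."""
import numpy as np
import pytest

from densestrain import phantom as ph


def _pt(geom, x, y):
    return geom.center + np.array([[x, y]], dtype=float)


class TestAnalyticDisplacement:
    def test_identity_deformation_gives_zero_displacement(self, sa_geom):
        deform = ph.DeformationParams()  # no contraction, no twist
        pts = _pt(sa_geom, 30.0, 0.0)
        u = ph.analytic_displacement(sa_geom, deform, pts)
        np.testing.assert_allclose(u, 0.0, atol=1e-12)

    def test_contraction_matches_closed_form_radial_inward(self, sa_geom, contraction):
        # r(30) = sqrt(900 - (625 - 484)) = sqrt(759); inward by 2.450 mm
        u = ph.analytic_displacement(sa_geom, contraction, _pt(sa_geom, 30.0, 0.0))
        expected = np.sqrt(900.0 - 141.0) - 30.0
        np.testing.assert_allclose(u, [[expected, 0.0]], atol=1e-12)
        assert abs(expected) == pytest.approx(2.450, abs=5e-4)

    def test_pure_twist_is_tangential_with_chord_length(self, sa_geom):
        deform = ph.DeformationParams(twist_deg=5.0)
        pts = np.stack([_pt(sa_geom, 28.0, 0.0)[0], _pt(sa_geom, 0.0, 33.0)[0]])
        u = ph.analytic_displacement(sa_geom, deform, pts)
        radial = (pts - sa_geom.center)
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        R = np.array([28.0, 33.0])
        chord = 2.0 * R * np.sin(np.radians(2.5))
        np.testing.assert_allclose(np.linalg.norm(u, axis=1), chord, rtol=1e-12)
        # tangential: tiny radial component (chord is a secant, not a tangent)
        assert np.all(np.abs(np.einsum("ij,ij->i", u, radial)) < 0.15 * chord)

    def test_point_outside_annulus_is_flagged_missing(self, sa_geom, contraction):
        u = ph.analytic_displacement(sa_geom, contraction, _pt(sa_geom, 40.0, 0.0))
        assert np.isnan(u).all()


class TestAnalyticStrain:
    def test_identity_and_rigid_twist_have_zero_strain(self, sa_geom):
        for deform in (ph.DeformationParams(), ph.DeformationParams(twist_deg=17.0)):
            s = ph.analytic_strain(sa_geom, deform, _pt(sa_geom, 30.0, 0.0))
            np.testing.assert_allclose(s["circumferential"], 0.0, atol=1e-9)
            np.testing.assert_allclose(s["radial_sa"], 0.0, atol=1e-9)

    def test_contraction_strain_closed_form(self, sa_geom, contraction):
        s = ph.analytic_strain(sa_geom, contraction, _pt(sa_geom, 30.0, 0.0))
        lam_c = np.sqrt(759.0) / 30.0
        assert s["circumferential"][0] == pytest.approx(100 * (lam_c**2 - 1) / 2, abs=1e-9)
        assert s["circumferential"][0] == pytest.approx(-7.8, abs=0.05)
        assert s["radial_sa"][0] == pytest.approx(100 * (1 / lam_c**2 - 1) / 2, abs=1e-9)
        assert s["radial_sa"][0] == pytest.approx(9.3, abs=0.05)

    def test_long_axis_strain_closed_form(self):
        geom = ph.PhantomGeometry("long-axis", view="two_chamber")
        lam = 0.9
        deform = ph.DeformationParams(longitudinal_stretch=lam)
        s = ph.analytic_strain(geom, deform, _pt(geom, 25.0, 10.0))
        assert s["longitudinal"][0] == pytest.approx(100 * (lam**2 - 1) / 2, abs=1e-9)
        assert s["radial_la"][0] == pytest.approx(100 * (lam**-2 - 1) / 2, abs=1e-9)

    def test_transition_zone_raises_but_nan_mode_flags(self, sa_geom):
        sector = ph.ScarSector(0.0, 60.0, contraction_scale=0.4, transition_deg=15.0)
        deform = ph.DeformationParams(endo_radius_deformed_mm=20.0, scar_sectors=(sector,))
        # point at 65 degrees: inside the cosine blending ramp
        ang = np.radians(65.0)
        pt = sa_geom.center + 30.0 * np.array([[np.cos(ang), np.sin(ang)]])
        with pytest.raises(ValueError, match="transition"):
            ph.analytic_strain(sa_geom, deform, pt)
        s = ph.analytic_strain(sa_geom, deform, pt, on_transition="nan")
        assert np.isnan(s["circumferential"]).all()

    def test_scar_core_strain_is_scaled_gradient(self, sa_geom):
        sector = ph.ScarSector(0.0, 90.0, contraction_scale=0.4, transition_deg=5.0)
        deform = ph.DeformationParams(endo_radius_deformed_mm=20.0, scar_sectors=(sector,))
        normal = ph.DeformationParams(endo_radius_deformed_mm=20.0)
        ang = np.radians(45.0)
        pt = sa_geom.center + 30.0 * np.array([[np.cos(ang), np.sin(ang)]])
        s_scar = ph.analytic_strain(sa_geom, deform, pt)
        s_norm = ph.analytic_strain(sa_geom, normal, pt)
        # reduced contraction: strictly smaller magnitude in the scar core
        assert abs(s_scar["circumferential"][0]) < abs(s_norm["circumferential"][0])
        assert abs(s_scar["radial_sa"][0]) < abs(s_norm["radial_sa"][0])


class TestAnalyticInvariants:
    def test_jacobian_determinant_one_without_scar(self, sa_geom, contraction):
        rng = np.random.default_rng(0)
        th = rng.uniform(0, 2 * np.pi, 200)
        R = rng.uniform(25.2, 34.8, 200)
        pts = sa_geom.center + np.stack([R * np.cos(th), R * np.sin(th)], axis=-1)
        F = ph.analytic_deformation_gradient(sa_geom, contraction, pts)
        np.testing.assert_allclose(np.linalg.det(F), 1.0, atol=1e-9)

    def test_circumferential_radial_stretches_are_reciprocal(self, sa_geom, contraction):
        R = np.linspace(25.5, 34.5, 30)
        pts = sa_geom.center + np.stack([R, np.zeros_like(R)], axis=-1)
        s = ph.analytic_strain(sa_geom, contraction, pts)
        lam_c = np.sqrt(1 + 2 * s["circumferential"] / 100.0)
        lam_r = np.sqrt(1 + 2 * s["radial_sa"] / 100.0)
        np.testing.assert_allclose(lam_c * lam_r, 1.0, atol=1e-12)

    @pytest.mark.parametrize("kind", ["short-axis", "long-axis"])
    def test_gradient_matches_finite_difference_of_displacement(self, kind):
        if kind == "short-axis":
            geom = ph.PhantomGeometry(kind, endo_radius_mm=25.0, epi_radius_mm=35.0)
            deform = ph.DeformationParams(
                endo_radius_deformed_mm=20.0, twist_deg=4.0,
                wall_motion_modes=(ph.WallMotionMode(0.4, 2, 30.0),))
            rng = np.random.default_rng(1)
            th = rng.uniform(0, 2 * np.pi, 100)
            R = rng.uniform(25.5, 34.5, 100)
            pts = geom.center + np.stack([R * np.cos(th), R * np.sin(th)], axis=-1)
        else:
            geom = ph.PhantomGeometry(kind, view="two_chamber")
            deform = ph.DeformationParams(longitudinal_stretch=0.87)
            rng = np.random.default_rng(1)
            x = rng.uniform(21, 29, 100) * rng.choice([-1, 1], 100)
            y = rng.uniform(-35, 35, 100)
            pts = geom.center + np.stack([x, y], axis=-1)
        F = ph.analytic_deformation_gradient(geom, deform, pts)
        E = 0.5 * (np.einsum("...ji,...jk->...ik", F, F) - np.eye(2))
        h = 1e-4
        F_fd = np.empty_like(F)
        for j, e in enumerate(np.eye(2)):
            up = ph.analytic_displacement(geom, deform, pts + h * e, tol_mm=1.0)
            um = ph.analytic_displacement(geom, deform, pts - h * e, tol_mm=1.0)
            F_fd[..., :, j] = (up - um) / (2 * h) + e
        E_fd = 0.5 * (np.einsum("...ji,...jk->...ik", F_fd, F_fd) - np.eye(2))
        assert np.nanmax(np.abs(E - E_fd)) * 100 < 0.1  # strain-%


class TestSubjectGeneration:
    def test_same_seed_is_bitwise_identical(self):
        from tests.conftest import CONTROL_PARAMS
        a = ph.generate_subject("s", "control", dict(CONTROL_PARAMS), snr=20.0, seed=3)
        b = ph.generate_subject("s", "control", dict(CONTROL_PARAMS), snr=20.0, seed=3)
        for sa, sb in zip(a.slices, b.slices):
            np.testing.assert_array_equal(sa.images.phases, sb.images.phases)
        np.testing.assert_array_equal(a.scar_fractions, b.scar_fractions)

    def test_control_subject_has_zero_scar(self, control_subject):
        assert control_subject.scar_fractions.shape == (16,)
        np.testing.assert_array_equal(control_subject.scar_fractions, 0.0)
        assert len(control_subject.slices) == 6

    def test_sector_covering_60pct_of_one_segment(self):
        # segment 1 (anterior) spans [60, 120) deg; a 36-deg sector inside it
        # covers ~0.6 of that segment and nothing else
        from tests.conftest import CONTROL_PARAMS
        sector = ph.ScarSector(63.0, 99.0, contraction_scale=0.4, transition_deg=5.0)
        params = dict(CONTROL_PARAMS, scar_sectors=(sector,))
        subj = ph.generate_subject("s", "scar", params, snr=np.inf, seed=0)
        frac = subj.scar_fractions
        # anterior basal (id 1) and mid (id 7) are covered 0.6 > 0.5; the
        # apical anterior segment spans 90 deg, so the same sector covers
        # only ~0.4 of it and stays below the endpoint
        assert (frac > 0.5).sum() == 2
        assert frac[0] == pytest.approx(0.6, abs=0.06)
        assert frac[6] == pytest.approx(0.6, abs=0.06)
        assert 0.0 < frac[12] < 0.5
        assert frac[[1, 2, 3, 4, 5]].max() == 0.0


class TestCohort:
    def test_counts_groups_and_determinism(self):
        spec = ph.CohortSpec(n_control=3, n_mixed=1, n_scar=2, seed=5)
        cohort = ph.generate_cohort(spec)
        assert len(cohort) == 6
        groups = [s.group for s in cohort]
        assert groups.count("control") == 3 and groups.count("scar") == 2
        for s in cohort:
            if s.group != "scar":
                np.testing.assert_array_equal(s.scar_fractions, 0.0)
        again = ph.generate_cohort(spec)
        np.testing.assert_array_equal(cohort[-1].slices[0].images.phases,
                                      again[-1].slices[0].images.phases)

    def test_noise_seed_changes_noise_not_geometry(self):
        a = ph.generate_cohort(ph.CohortSpec(n_control=1, n_scar=0, seed=5, snr=20.0))
        b = ph.generate_cohort(ph.CohortSpec(n_control=1, n_scar=0, seed=5, snr=20.0,
                                             noise_seed=99))
        assert a[0].params["contraction_ratio"] == b[0].params["contraction_ratio"]
        np.testing.assert_array_equal(a[0].slices[0].mask, b[0].slices[0].mask)
        assert not np.array_equal(a[0].slices[0].images.phases,
                                  b[0].slices[0].images.phases)

    def test_degenerate_severity_equals_control_strain(self):
        sector = ph.ScarSector(0.0, 90.0, contraction_scale=1.0)
        from tests.conftest import CONTROL_PARAMS
        scar = ph.generate_subject("a", "scar", dict(CONTROL_PARAMS, scar_sectors=(sector,)),
                                   snr=np.inf, seed=2)
        ctrl = ph.generate_subject("a", "control", dict(CONTROL_PARAMS), snr=np.inf, seed=2)
        np.testing.assert_allclose(scar.slices[0].images.phases,
                                   ctrl.slices[0].images.phases, atol=1e-12)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            ph.generate_cohort(ph.CohortSpec(n_control=0, n_mixed=0, n_scar=0))


def test_scar_fraction_in_segment_below_unscarred_magnitude(sa_geom):
    """|E_cc| inside a scar sector is strictly below the unscarred value at matched radius."""
    sector = ph.ScarSector(180.0, 300.0, contraction_scale=0.5, transition_deg=8.0)
    deform = ph.DeformationParams(endo_radius_deformed_mm=20.0, scar_sectors=(sector,))
    ang = np.radians(240.0)
    scar_pt = sa_geom.center + 30.0 * np.array([[np.cos(ang), np.sin(ang)]])
    norm_pt = sa_geom.center + 30.0 * np.array([[1.0, 0.0]])
    s = ph.analytic_strain(sa_geom, deform, np.vstack([scar_pt, norm_pt]))
    assert abs(s["circumferential"][0]) < abs(s["circumferential"][1])
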