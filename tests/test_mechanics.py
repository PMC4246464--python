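"""Mesh construction, Green-Lagrange strain, twist, torsion, pipeline."""

import numpy as np
import pytest

from cinedense import contours as ct
from cinedense import mechanics as mech
from cinedense import phantom as ph
from cinedense.errors import (
    GeometryError,
    InsufficientDataError,
    StageError,
    ValidationError,
)
from geomutil import circle_points


def _circle_contour(r, frame=0, boundary=ct.ENDO, n=256, cx=0.0, cy=0.0):
    return ct.Contour(circle_points(r, cx, cy, n), frame, boundary)


class TestRestingMesh:
    def test_node_element_counts_and_ring_radii(self):
        mesh = mech.build_resting_mesh(
            _circle_contour(1.0), _circle_contour(2.0, boundary=ct.EPI)
        )
        assert mesh.n_nodes == 768
        assert mesh.n_elements == 640
        radii = np.linalg.norm(mesh.nodes_px, axis=2).mean(axis=1)
        np.testing.assert_allclose(radii, [1.0, 1.2, 1.4, 1.6, 1.8, 2.0], atol=1e-3)

    def test_rv_insertion_ray(self):
        mesh = mech.build_resting_mesh(
            _circle_contour(1.0), _circle_contour(2.0, boundary=ct.EPI), rv_insertion=0.0
        )
        first_col = mesh.nodes_px[:, 0, :]
        assert np.all(np.abs(first_col[:, 1]) < 1e-6)  # on the +x axis
        assert np.all(first_col[:, 0] > 0)

    def test_rv_insertion_as_point(self):
        mesh = mech.build_resting_mesh(
            _circle_contour(1.0),
            _circle_contour(2.0, boundary=ct.EPI),
            rv_insertion=(0.0, 5.0),  # straight up from the center
        )
        first_col = mesh.nodes_px[:, 0, :]
        assert np.all(np.abs(first_col[:, 0]) < 1e-6)
        assert np.all(first_col[:, 1] > 0)

    def test_ellipse_pair_positive_areas(self):
        th = 2 * np.pi * np.arange(128) / 128
        endo = np.column_stack([2.0 * np.cos(th), 1.2 * np.sin(th)])
        epi = np.column_stack([3.5 * np.cos(th), 2.6 * np.sin(th)])
        mesh = mech.build_resting_mesh(
            ct.Contour(endo, 0, ct.ENDO), ct.Contour(epi, 0, ct.EPI)
        )
        corners = mesh.flat_nodes_px[mesh.element_corner_indices()]
        areas = 0.5 * np.sum(
            corners[:, :, 0] * np.roll(corners[:, :, 1], -1, axis=1)
            - np.roll(corners[:, :, 0], -1, axis=1) * corners[:, :, 1],
            axis=1,
        )
        assert np.all(areas > 0)

    def test_endo_outside_epi_rejected(self):
        with pytest.raises(GeometryError):
            mech.build_resting_mesh(
                _circle_contour(2.5), _circle_contour(2.0, boundary=ct.EPI)
            )


def _annulus_elements(n_circ=128, r_in=1.0, r_out=2.0, n_rad=5):
    """Element corner arrays built with continuous (unwrapped) angles."""
    radii = np.linspace(r_in, r_out, n_rad + 1)
    th = 2 * np.pi * np.arange(n_circ + 1) / n_circ
    rest = []
    for i in range(n_rad):
        for j in range(n_circ):
            t0, t1 = th[j], th[j + 1]
            r0, r1 = radii[i], radii[i + 1]
            rest.append(
                [
                    [r0 * np.cos(t0), r0 * np.sin(t0)],
                    [r1 * np.cos(t0), r1 * np.sin(t0)],
                    [r1 * np.cos(t1), r1 * np.sin(t1)],
                    [r0 * np.cos(t1), r0 * np.sin(t1)],
                ]
            )
    rest = np.asarray(rest)
    centroids = rest.mean(axis=1)
    e_rad = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    e_circ = np.column_stack([-e_rad[:, 1], e_rad[:, 0]])
    return rest, e_circ, e_rad


class TestElementStrain:
    def test_identity_zero(self):
        rest, e_circ, e_rad = _annulus_elements(n_circ=32)
        ecc, err = mech.element_strain(rest, rest, e_circ, e_rad)
        np.testing.assert_allclose(ecc, 0.0, atol=1e-10)
        np.testing.assert_allclose(err, 0.0, atol=1e-10)

    def test_pure_circumferential_scaling(self):
        """Angular compression theta -> 0.9*theta at fixed radius gives
        Ecc = 100*(0.9^2-1)/2 = -9.5% within the discretization error."""
        rest, e_circ, e_rad = _annulus_elements(n_circ=128)
        th = np.arctan2(rest[..., 1], rest[..., 0])
        th = np.unwrap(th, axis=1)  # keep element-local angles continuous
        r = np.hypot(rest[..., 0], rest[..., 1])
        deformed = np.stack([r * np.cos(0.9 * th), r * np.sin(0.9 * th)], axis=-1)
        ecc, err = mech.element_strain(rest, deformed, e_circ, e_rad)
        assert np.max(np.abs(ecc - (-9.5))) < 0.2
        assert np.max(np.abs(err)) < 0.2

    def test_rigid_rotation_invariance(self):
        rest, e_circ, e_rad = _annulus_elements(n_circ=64)
        a = np.deg2rad(30)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        deformed = rest @ rot.T
        ecc, err = mech.element_strain(rest, deformed, e_circ, e_rad)
        assert np.max(np.abs(ecc)) < 1e-6
        assert np.max(np.abs(err)) < 1e-6

    def test_degenerate_element_rejected(self):
        rest = np.zeros((1, 4, 2))
        with pytest.raises(GeometryError):
            mech.element_strain(rest, rest, np.array([[1.0, 0]]), np.array([[0, 1.0]]))


class TestSegments:
    def test_column_split_128_by_6(self):
        seg = mech.segment_of_element(128, 6)
        counts = np.bincount(seg)
        assert sorted(counts.tolist()) == [21, 21, 21, 21, 22, 22]
        assert counts[0] == 22 and counts[1] == 22  # deterministic assignment

    def test_constant_field_segment_means(self):
        per_elem = np.full((3, 24), 5.5)
        seg = mech.segment_of_element(12, 4, np.tile(np.arange(12), 2))
        out = mech.segment_average(per_elem, seg, 4)
        np.testing.assert_allclose(out, 5.5)

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(0)
        per_elem = rng.normal(size=(5, 36))
        cols = np.tile(np.arange(18), 2)
        seg = mech.segment_of_element(18, 5, cols)
        out = mech.segment_average(per_elem, seg, 5)
        for s in range(5):
            np.testing.assert_allclose(
                out[:, s], per_elem[:, seg == s].mean(axis=1), atol=1e-12
            )


class TestTwistTorsion:
    def test_rigid_rotation_five_degrees(self):
        rng = np.random.default_rng(2)
        nodes = rng.uniform(-3, 3, (50, 2)) + 10.0
        a = np.deg2rad(5.0)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        deformed = (nodes - 10.0) @ rot.T + 10.0
        assert mech.twist_angle(nodes, deformed, (10.0, 10.0)) == pytest.approx(
            5.0, abs=1e-6
        )

    def test_identity_zero_twist(self):
        nodes = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]]) + 4.0
        assert mech.twist_angle(nodes, nodes, (4.0, 4.0)) == 0.0

    def test_translation_objectivity(self):
        """A rigid translation changes no twist when the center moves along."""
        rng = np.random.default_rng(3)
        nodes = rng.uniform(-2, 2, (40, 2))
        a = np.deg2rad(7.0)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        deformed = nodes @ rot.T
        t = np.array([3.3, -1.7])
        tw0 = mech.twist_angle(nodes, deformed, (0.0, 0.0))
        tw1 = mech.twist_angle(nodes + t, deformed + t, t)
        assert tw0 == pytest.approx(tw1, abs=1e-9)

    def test_torsion_exact_line(self):
        res = mech.torsion_slope(
            [np.array([0.0]), np.array([2.0]), np.array([4.0])],
            [0.0, 1.0, 2.0],
            [np.array([0.0])] * 3,
        )
        assert res.slope_deg_per_cm[0] == pytest.approx(2.0)

    def test_torsion_equal_twists_zero(self):
        res = mech.torsion_slope(
            [np.array([3.0, 3.0])] * 3,
            [0.0, 1.0, 2.0],
            [np.array([0.0, 10.0])] * 3,
        )
        np.testing.assert_allclose(res.slope_deg_per_cm, 0.0, atol=1e-12)

    def test_torsion_requires_two_slices(self):
        with pytest.raises(InsufficientDataError):
            mech.torsion_slope([np.array([1.0])], [0.0], [np.array([0.0])])

    def test_torsion_identical_locations_rejected(self):
        with pytest.raises(ValidationError):
            mech.torsion_slope(
                [np.array([1.0]), np.array([2.0])], [1.0, 1.0], [np.array([0.0])] * 2
            )

    def test_torsion_resamples_different_frame_grids(self):
        t_a = np.array([0.0, 10.0, 20.0])
        t_b = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        twist_a = 0.1 * t_a  # 0 -> 2 deg over 20 ms
        twist_b = 0.2 * t_b  # 0 -> 4 deg
        res = mech.torsion_slope([twist_a, twist_b], [0.0, 2.0], [t_a, t_b])
        # slope at the final time: (4 - 2) / 2 = 1 deg/cm
        assert res.slope_deg_per_cm[-1] == pytest.approx(1.0)


class TestPipeline:
    def test_peak_midwall_ecc_recovered(self, small_phantom, small_full_result):
        _, gt = small_phantom
        assert abs(
            small_full_result.peak_midwall_ecc_percent - gt.peak_midwall_ecc_percent
        ) < 1.0

    def test_twist_recovered(self, small_spec, small_phantom, small_full_result):
        _, gt = small_phantom
        f = small_spec.peak_frame
        assert small_full_result.twist_deg[f] == pytest.approx(
            gt.twist_deg[f], abs=0.1
        )

    def test_frame0_strains_exactly_zero(self, small_full_result):
        np.testing.assert_array_equal(small_full_result.ecc_elements[0], 0.0)
        np.testing.assert_array_equal(small_full_result.err_elements[0], 0.0)
        assert small_full_result.twist_deg[0] == 0.0

    def test_zero_deformation_noise_floor(self):
        """Static phantom with phase noise at the standard acquisition size:
        peak strains stay within a 0.3% noise floor."""
        spec = ph.PhantomSpec(
            contraction_peak=0.0, twist_peak_deg=0.0, phase_noise_sd_rad=0.05, seed=12,
        )
        dense, gt = ph.render_slice(spec)
        res = mech.analyze_slice(dense, gt.contour_set)
        assert np.max(np.abs(res.peak_ecc_per_segment)) < 0.3
        assert np.max(np.abs(res.peak_err_per_segment)) < 0.3

    def test_simplified_matches_full(self, small_spec, small_phantom, small_full_result):
        dense, gt = small_phantom
        cs = gt.contour_set
        es = ct.detect_es_frame(cs)
        simple = ct.generate_simplified_set(
            cs.get(0, ct.ENDO), cs.get(0, ct.EPI), cs.get(es, ct.ENDO),
            small_spec.n_frames, 0, es,
        )
        res_s = mech.analyze_slice(dense, simple)
        assert abs(
            res_s.peak_midwall_ecc_percent - small_full_result.peak_midwall_ecc_percent
        ) < 1.0

    def test_nonzero_reference_frame_rejected(self, small_phantom):
        dense, gt = small_phantom
        cs = ct.ContourSet(
            contours=gt.contour_set.contours,
            reference_frame=1,
            es_frame=gt.contour_set.es_frame,
        )
        with pytest.raises(StageError) as exc_info:
            mech.analyze_slice(dense, cs)
        assert exc_info.value.stage == "validate"

    def test_long_axis_reports_ell(self, small_spec):
        """Long-axis slices run the identical chain and report the
        wall-tangent strain as Ell with 4 segments."""
        from dataclasses import replace

        spec = replace(small_spec, orientation="long_axis", n_frames=8)
        dense, gt = ph.render_slice(spec)
        res = mech.analyze_slice(dense, gt.contour_set)
        assert res.n_segments == 4
        table = res.to_table()
        assert table.curves["Ell_percent"].notna().all()
        assert table.curves["Ecc_percent"].isna().all()
        assert (table.peaks["peak_Ell_percent"] < 0).all()

    def test_study_torsion(self, small_spec):
        from dataclasses import replace

        base = replace(small_spec, twist_peak_deg=1.0, n_frames=10)
        rendered, tau = ph.render_study(base, [0.0, 1.0, 2.0], 1.5)
        _, torsion = mech.analyze_study(
            [d for d, _ in rendered], [g.contour_set for _, g in rendered]
        )
        assert torsion is not None
        assert abs(torsion.peak_torsion_deg_per_cm - tau) / tau < 0.1
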