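"""Occlusal frame fitting and trait measurement geometry."""

import numpy as np
import pytest
from scipy import linalg

from parscore.errors import DegenerateFrameError, DomainError, MissingLandmarkError
from parscore.geometry import (
    GeometryConfig,
    Landmark,
    OcclusalFrame,
    TraitMeasurements,
    contact_displacement,
    extract_traits,
    fit_occlusal_frame,
    measure_centerline,
    measure_overbite,
    measure_overjet,
)
from parscore.synthetic import ZERO_SEVERITY, generate_dentition

from conftest import make_arches, make_landmark, random_rigid_transform


def canonical_frame():
    return OcclusalFrame(
        origin=np.zeros(3),
        normal=np.array([0.0, 0.0, 1.0]),
        anterior_axis=np.array([0.0, 1.0, 0.0]),
        transverse_axis=np.array([1.0, 0.0, 0.0]),
    )


class TestFitOcclusalFrame:
    def test_coplanar_symmetric_case(self, flat_arches):
        frame = fit_occlusal_frame(*flat_arches)
        # anchors at z=0 with incisors toward +y: canonical axes
        assert np.allclose(frame.normal, [0, 0, 1], atol=1e-12)
        assert np.allclose(frame.anterior_axis, [0, 1, 0], atol=1e-12)
        assert np.allclose(frame.transverse_axis, [1, 0, 0], atol=1e-12)

    def test_normal_points_toward_upper_arch(self, flat_arches):
        # the upper arch sits at z > 0 here (contacts above the plane)
        upper, lower = flat_arches
        shifted = upper.transformed(np.eye(3), np.array([0, 0, 2.0]))
        frame = fit_occlusal_frame(shifted, lower)
        assert frame.normal @ [0, 0, 1] > 0

    def test_rigid_motion_equivariance(self, flat_arches):
        upper, lower = flat_arches
        frame = fit_occlusal_frame(upper, lower)
        rng = np.random.default_rng(7)
        R, t = random_rigid_transform(rng)
        frame2 = fit_occlusal_frame(upper.transformed(R, t), lower.transformed(R, t))
        assert np.allclose(frame2.normal, R @ frame.normal, atol=1e-9)
        assert np.allclose(frame2.anterior_axis, R @ frame.anterior_axis, atol=1e-9)
        assert np.allclose(frame2.origin, R @ frame.origin + t, atol=1e-9)

    def test_plane_matches_least_squares_oracle(self, flat_arches):
        """Noisy anchors: fitted plane equals the eigen-decomposition oracle."""
        upper, lower = flat_arches
        rng = np.random.default_rng(11)
        R = np.eye(3)
        noisy_u = upper.transformed(R, np.zeros(3))
        # perturb anchor z-coordinates out of plane
        for lm in noisy_u.landmarks:
            lm.position[2] += rng.normal(0, 0.4)
        noisy_l = lower.transformed(R, np.zeros(3))
        for lm in noisy_l.landmarks:
            if lm.name == "buccal_cusp":
                lm.position[2] += rng.normal(0, 0.4)
        frame = fit_occlusal_frame(noisy_u, noisy_l)

        cfg = GeometryConfig()
        arches = {"upper": noisy_u, "lower": noisy_l}
        pts = np.array(
            [arches[a].get(f, n).position for a, f, n in cfg.plane_anchors if arches[a].get(f, n)]
        )
        centered = pts - pts.mean(axis=0)
        # independent oracle: smallest-eigenvalue eigenvector of the scatter matrix
        w, v = linalg.eigh(centered.T @ centered)
        oracle_normal = v[:, 0] * np.sign(v[:, 0] @ frame.normal)
        assert np.allclose(frame.normal, oracle_normal, atol=1e-9)
        # residuals match too
        res_fit = np.abs(centered @ frame.normal)
        res_oracle = np.abs(centered @ oracle_normal)
        assert np.allclose(res_fit, res_oracle, atol=1e-9)

    def test_too_few_anchors_degenerate(self):
        upper, lower = make_arches(
            [(14, "buccal_cusp", -22, 25, 0), (24, "buccal_cusp", 22, 25, 0)],
            [(41, "incisal_edge", 0, 40, 0)],
        )
        with pytest.raises(DegenerateFrameError):
            fit_occlusal_frame(upper, lower)

    def test_collinear_anchors_degenerate(self):
        upper, lower = make_arches(
            [
                (14, "buccal_cusp", -10, 0, 0),
                (24, "buccal_cusp", 0, 0, 0),
                (16, "buccal_cusp", 10, 0, 0),
            ],
            [(41, "incisal_edge", 0, 40, 0)],
        )
        with pytest.raises(DegenerateFrameError):
            fit_occlusal_frame(upper, lower)


class TestContactDisplacement:
    def test_coincident_points_zero(self):
        frame = canonical_frame()
        a = make_landmark(11, "mesial_contact", 1, 2, 3)
        b = make_landmark(21, "mesial_contact", 1, 2, 3)
        assert contact_displacement(a, b, frame) == 0.0

    def test_purely_vertical_offset_excluded(self):
        # "parallel to the occlusal plane": a normal-axis offset contributes 0
        frame = canonical_frame()
        a = make_landmark(11, "mesial_contact", 1, 2, 0)
        b = make_landmark(21, "mesial_contact", 1, 2, 5)
        assert contact_displacement(a, b, frame) == pytest.approx(0.0, abs=1e-12)

    def test_matches_projection_matrix_oracle(self):
        frame = canonical_frame()
        rng = np.random.default_rng(3)
        n = frame.normal
        P = np.eye(3) - np.outer(n, n)  # independent projection-matrix oracle
        for _ in range(20):
            pa, pb = rng.normal(size=3), rng.normal(size=3)
            a = make_landmark(11, "mesial_contact", *pa)
            b = make_landmark(21, "mesial_contact", *pb)
            assert contact_displacement(a, b, frame) == pytest.approx(
                np.linalg.norm(P @ (pa - pb)), abs=1e-12
            )

    def test_symmetric_in_landmarks(self):
        frame = canonical_frame()
        a = make_landmark(11, "mesial_contact", 0.3, -1.2, 2.0)
        b = make_landmark(21, "mesial_contact", -0.7, 0.4, -1.0)
        assert contact_displacement(a, b, frame) == contact_displacement(b, a, frame)


class TestOverjet:
    def test_directly_above_zero(self):
        frame = canonical_frame()
        u = make_landmark(11, "incisal_edge", 0, 10, 2)
        l = make_landmark(41, "labial_surface", 0, 10, 0)
        assert measure_overjet([u], [l], frame) == 0.0

    def test_hand_projection(self):
        # 4 mm along the sagittal axis, 2 mm vertical: only the sagittal counts
        frame = canonical_frame()
        u = make_landmark(11, "incisal_edge", 0, 14, 2)
        l = make_landmark(41, "labial_surface", 0, 10, 0)
        assert measure_overjet([u], [l], frame) == pytest.approx(4.0, abs=1e-12)

    def test_largest_pair_wins(self):
        frame = canonical_frame()
        us = [make_landmark(11, "incisal_edge", 0, 13, 0), make_landmark(21, "incisal_edge", 5, 16.2, 0)]
        ls = [make_landmark(41, "labial_surface", 0, 10, 0), make_landmark(31, "labial_surface", 5, 10, 0)]
        assert measure_overjet(us, ls, frame) == pytest.approx(6.2)

    def test_reverse_overjet_clamped_at_zero(self):
        frame = canonical_frame()
        u = make_landmark(11, "incisal_edge", 0, 8, 0)
        l = make_landmark(41, "labial_surface", 0, 10, 0)
        assert measure_overjet([u], [l], frame) == 0.0

    def test_monotone_in_sagittal_separation(self):
        frame = canonical_frame()
        l = [make_landmark(41, "labial_surface", 0, 10, 0)]
        vals = [
            measure_overjet([make_landmark(11, "incisal_edge", 0, 10 + d, 1)], l, frame)
            for d in np.linspace(0, 8, 17)
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_empty_lists_error(self):
        with pytest.raises(MissingLandmarkError):
            measure_overjet([], [], canonical_frame())


class TestOverbite:
    def test_edge_to_edge_zero(self):
        frame = canonical_frame()
        u = make_landmark(11, "incisal_edge", 0, 10, 0)
        l = make_landmark(41, "incisal_edge", 0, 10, 0)
        assert measure_overbite(u, l, frame) == 0.0

    def test_overlap_positive(self):
        # upper edge 2.5 mm below the lower edge along the normal: overlap
        frame = canonical_frame()
        u = make_landmark(11, "incisal_edge", 0, 10, -2.5)
        l = make_landmark(41, "incisal_edge", 0, 10, 0)
        assert measure_overbite(u, l, frame) == pytest.approx(2.5, abs=1e-12)

    def test_open_bite_negative(self):
        frame = canonical_frame()
        u = make_landmark(11, "incisal_edge", 0, 10, 1.5)
        l = make_landmark(41, "incisal_edge", 0, 10, 0)
        assert measure_overbite(u, l, frame) == pytest.approx(-1.5, abs=1e-12)


class TestCenterline:
    def test_coincident_midlines_zero(self):
        frame = canonical_frame()
        u = make_landmark(11, "midline", 0, 43, 0)
        l = make_landmark(41, "midline", 0, 41, 0)
        assert measure_centerline(u, l, 5.0, frame) == 0.0

    def test_direct_quotient(self):
        frame = canonical_frame()
        u = make_landmark(11, "midline", 2.0, 43, 0)
        l = make_landmark(41, "midline", 0, 41, 0)
        assert measure_centerline(u, l, 5.0, frame) == pytest.approx(0.4)

    def test_sagittal_offset_is_not_deviation(self):
        frame = canonical_frame()
        u = make_landmark(11, "midline", 0, 47, 0)
        l = make_landmark(41, "midline", 0, 41, 0)
        assert measure_centerline(u, l, 5.0, frame) == 0.0

    def test_nonpositive_width_rejected(self):
        frame = canonical_frame()
        u = make_landmark(11, "midline", 1, 43, 0)
        l = make_landmark(41, "midline", 0, 41, 0)
        with pytest.raises(DomainError):
            measure_centerline(u, l, 0.0, frame)


class TestExtractTraits:
    def test_ideal_dentition_all_zero(self):
        upper, lower, _ = generate_dentition(ZERO_SEVERITY, seed=0)
        traits = extract_traits(upper, lower)
        assert all(cd.value_mm == pytest.approx(0.0, abs=1e-9) for cd in traits.contact_displacements)
        assert traits.centerline_fraction == pytest.approx(0.0, abs=1e-12)
        assert 0.0 <= traits.overjet_mm <= 3.0  # ideal band
        assert traits.anterior_crossbite_teeth == 0
        assert all(
            (c.sagittal, c.vertical, c.transverse) == (0, 0, 0) for c in traits.posterior.values()
        )

    def test_single_constructed_offset(self):
        # one 3.0 mm in-plane contact offset: exactly one nonzero displacement
        from parscore.geometry import ContactDisplacement

        truth = TraitMeasurements(
            contact_displacements=[ContactDisplacement("upper_anterior", (11, 21), 3.0)],
            overjet_mm=2.0,
            overbite_overlap_mm=2.0,
        )
        upper, lower, _ = generate_dentition(truth, seed=0)
        traits = extract_traits(upper, lower)
        nonzero = [cd for cd in traits.contact_displacements if cd.value_mm > 1e-9]
        assert len(nonzero) == 1
        assert nonzero[0].teeth == (11, 21)
        assert nonzero[0].value_mm == pytest.approx(3.0, abs=1e-9)

    def test_rigid_invariance(self):
        upper, lower, truth = generate_dentition(ZERO_SEVERITY, seed=1)
        base = extract_traits(upper, lower)
        rng = np.random.default_rng(42)
        R, t = random_rigid_transform(rng)
        moved = extract_traits(upper.transformed(R, t), lower.transformed(R, t))
        assert moved.overjet_mm == pytest.approx(base.overjet_mm, abs=1e-9)
        assert moved.overbite_overlap_mm == pytest.approx(base.overbite_overlap_mm, abs=1e-9)
        assert moved.centerline_fraction == pytest.approx(base.centerline_fraction, abs=1e-12)

    def test_extraction_space_excluded_unless_prosthetic(self):
        from parscore.geometry import TraitMeasurements as TM

        upper, lower, _ = generate_dentition(TM(overjet_mm=2.0, overbite_overlap_mm=2.0), seed=0)
        n_pairs_full = len(extract_traits(upper, lower).contact_displacements)

        # extract tooth 12: pairs (13,12) and (12,11) become a single gap
        upper.case_flags[12] = {"missing"}
        traits = extract_traits(upper, lower)
        upper_pairs = [cd for cd in traits.contact_displacements if cd.segment == "upper_anterior"]
        assert not any(12 in cd.teeth for cd in upper_pairs)
        assert len(traits.contact_displacements) == n_pairs_full - 2

        # a prosthetic plan keeps the space scoreable: bridging pair (13, 11)
        upper.case_flags[12] = {"missing", "prosthetic_planned"}
        traits = extract_traits(upper, lower)
        bridged = [cd for cd in traits.contact_displacements if cd.teeth == (13, 11)]
        assert len(bridged) == 1

    def test_whole_segment_absent_skipped(self):
        from parscore.geometry import TraitMeasurements as TM

        upper, lower, _ = generate_dentition(TM(overjet_mm=2.0, overbite_overlap_mm=2.0), seed=0)
        for t in (13, 12, 11, 21, 22, 23):
            upper.case_flags[t] = {"extracted"}
        traits = extract_traits(upper, lower)
        assert "upper_anterior" in traits.skipped_segments
        assert not any(cd.segment == "upper_anterior" for cd in traits.contact_displacements)
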