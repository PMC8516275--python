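"""Rod-lattice generation, membership geometry and BV/TV calibration."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from osteodose.framework import (
    CalibrationError,
    Framework,
    GeometryError,
    _calibration_vf,
    calibrate_spacing,
    generate_framework,
    point_in_bone,
    points_in_bone,
    rasterized_volume_fraction,
)


def _regular_micro(tiny_micro):
    """Zero within-specimen variability: a perfectly regular cubic rod lattice."""
    return dataclasses.replace(tiny_micro, intra_cv_th=0.0, intra_cv_sp=0.0)


def _brute_force_membership(fw: Framework, pts: np.ndarray) -> np.ndarray:
    """Independent numpy oracle: point-to-frustum distance over all rods."""
    a = fw.node_pos[fw.rods[:, 0]]  # (M, 3)
    b = fw.node_pos[fw.rods[:, 1]]
    ra = fw.node_radius[fw.rods[:, 0]]
    rb = fw.node_radius[fw.rods[:, 1]]
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    out = np.zeros(len(pts), dtype=bool)
    for q, p in enumerate(pts):
        t = np.clip(((p - a) * ab).sum(1) / ab2, 0.0, 1.0)
        closest = a + t[:, None] * ab
        r_t = ra + t * (rb - ra)
        d2 = ((p - closest) ** 2).sum(1)
        out[q] = bool(np.any(d2 <= r_t**2))
    return out


class TestGeneration:
    def test_same_seed_identical(self, tiny_micro):
        box = ((0.0, 0.5),) * 3
        f1 = generate_framework(tiny_micro, box, 11)
        f2 = generate_framework(tiny_micro, box, 11)
        np.testing.assert_array_equal(f1.node_pos, f2.node_pos)
        np.testing.assert_array_equal(f1.node_radius, f2.node_radius)
        np.testing.assert_array_equal(f1.rods, f2.rods)

    def test_box_too_small_raises(self, tiny_micro):
        with pytest.raises(GeometryError):
            generate_framework(tiny_micro, ((0.0, 0.1),) * 3, 1)

    def test_thickness_mean_recovers_input(self, tiny_micro):
        fw = generate_framework(tiny_micro, ((0.0, 1.2),) * 3, 5)
        assert fw.n_nodes >= 1000
        mean_th_mm = 2.0 * fw.node_radius.mean() * 10.0
        se = mean_th_mm * (tiny_micro.intra_cv_th / 100.0) / math.sqrt(fw.n_nodes)
        assert abs(mean_th_mm - tiny_micro.tb_th) < 2.0 * se + 1e-9

    def test_rods_reference_distinct_nodes(self, tiny_micro):
        fw = generate_framework(tiny_micro, ((0.0, 0.5),) * 3, 3)
        assert np.all(fw.rods[:, 0] != fw.rods[:, 1])


class TestRegularLatticeVolumeFraction:
    def test_matches_closed_form(self, tiny_micro):
        """Unperturbed cubic rod lattice vs the analytic union volume.

        Per unit cell of spacing a with rod radius r the bone volume is
        3*pi*r^2*a - 8*sqrt(2)*r^3 (three orthogonal cylinders minus their
        Steinmetz overlaps; node spheres of the same radius are subsumed).
        """
        micro = _regular_micro(tiny_micro)
        fw = generate_framework(micro, ((0.0, 0.3),) * 3, 1)
        a = fw.lattice_spacing
        r = micro.tb_th / 20.0  # cm
        analytic = (3.0 * math.pi * r**2 * a - 8.0 * math.sqrt(2.0) * r**3) / a**3
        pts = np.random.default_rng(7).uniform(a, 0.3 - a, size=(1_000_000, 3))
        measured = points_in_bone(fw, pts).mean()
        assert measured == pytest.approx(analytic, rel=0.005)


class TestPointInBone:
    def test_node_center_inside(self, tiny_micro):
        fw = generate_framework(tiny_micro, ((0.0, 0.5),) * 3, 2)
        inside = [n for n in fw.node_pos if all(0 <= c <= 0.5 for c in n)][0]
        assert point_in_bone(fw, inside)

    def test_cell_body_center_outside_regular_lattice(self, tiny_micro):
        micro = _regular_micro(tiny_micro)
        fw = generate_framework(micro, ((0.0, 0.5),) * 3, 2)
        a = fw.lattice_spacing
        assert not point_in_bone(fw, (a / 2.0, a / 2.0, a / 2.0))

    def test_outside_box_raises(self, tiny_micro):
        fw = generate_framework(tiny_micro, ((0.0, 0.5),) * 3, 2)
        with pytest.raises(GeometryError):
            point_in_bone(fw, (5.0, 5.0, 5.0))

    def test_agrees_with_brute_force_oracle(self, tiny_micro, rng):
        fw = generate_framework(tiny_micro, ((0.0, 0.4),) * 3, 9)
        pts = rng.uniform(0.0, 0.4, size=(10_000, 3))
        kernel = points_in_bone(fw, pts)
        oracle = _brute_force_membership(fw, pts)
        assert np.array_equal(kernel, oracle)


class TestCalibration:
    def test_fixed_point(self, tiny_micro):
        vf1 = _calibration_vf(tiny_micro, 12, 4, 1.0)
        micro = dataclasses.replace(tiny_micro, bvtv=vf1, bvtv_min=0.5 * vf1, bvtv_max=1.5 * vf1)
        assert calibrate_spacing(micro, rng_seed=4, tol=0.01) == pytest.approx(1.0, abs=0.02)

    def test_volume_fraction_monotone_in_spacing(self, tiny_micro):
        vfs = [_calibration_vf(tiny_micro, 10, 4, s) for s in (0.5, 0.75, 1.0, 1.5, 2.0)]
        assert all(a > b for a, b in zip(vfs, vfs[1:]))

    def test_unreachable_target_raises(self, tiny_micro):
        micro = dataclasses.replace(tiny_micro, bvtv=0.95, bvtv_min=0.9, bvtv_max=0.99)
        with pytest.raises(CalibrationError):
            calibrate_spacing(micro, rng_seed=1, s_lo=0.8, s_hi=1.2)

    def test_bad_tolerance_rejected(self, tiny_micro):
        with pytest.raises(ValueError):
            calibrate_spacing(tiny_micro, tol=0.2)


class TestStatisticalProperties:
    def test_isotropy_of_orthogonal_slabs(self, tiny_micro):
        fw = generate_framework(tiny_micro, ((0.0, 1.0),) * 3, 21)
        a = fw.lattice_spacing
        res = tiny_micro.tb_th / 40.0
        slabs = [
            ((a, 1.0 - a), (a, 1.0 - a), (0.4, 0.6)),
            ((a, 1.0 - a), (0.4, 0.6), (a, 1.0 - a)),
            ((0.4, 0.6), (a, 1.0 - a), (a, 1.0 - a)),
        ]
        vfs = [rasterized_volume_fraction(fw, s, res) for s in slabs]
        assert max(vfs) - min(vfs) < 0.15 * np.mean(vfs)

    def test_translation_invariance(self, tiny_micro):
        fw = generate_framework(tiny_micro, ((0.0, 1.0),) * 3, 22)
        res = tiny_micro.tb_th / 40.0
        v1 = rasterized_volume_fraction(fw, ((0.2, 0.7),) * 3, res)
        v2 = rasterized_volume_fraction(fw, ((0.27, 0.77),) * 3, res)
        assert v2 == pytest.approx(v1, rel=0.12)
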