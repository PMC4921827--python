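"""Disk-union footprints, blurred isosurfaces, Cn packing, assemblies."""

import math

import numpy as np
import pytest

from cscmorph import footprint as fp
from cscmorph.synthgen import make_toy_bundle

from conftest import monte_carlo_union_area

TWO_DISK_LENS = 2.0 * math.acos(0.5) - math.sqrt(3.0) / 2.0  # r=1, d=1


def disks(xyrl):
    arr = np.asarray(xyrl, dtype=float)
    return fp.DiskSet(arr[:, 0], arr[:, 1], arr[:, 2],
                      arr[:, 3].astype(int) if arr.shape[1] > 3
                      else np.ones(len(arr), int))


class TestProjectSlab:
    def test_single_atom_disk_area(self):
        from cscmorph.synthgen import ToyAtomicModel
        model = ToyAtomicModel(np.array([[0.0, 0.0, 0.0, 0.2, 1.0]]))
        d = fp.project_slab(model)
        assert fp.union_area(d) == pytest.approx(math.pi * 0.04, rel=5e-3)

    def test_boundary_atom_included(self):
        from cscmorph.synthgen import ToyAtomicModel
        model = ToyAtomicModel(np.array([[0.0, 0.0, 2.0, 0.2, 1.0],
                                         [0.0, 0.0, 2.0001, 0.2, 1.0]]),
                               slab_half_thickness=2.0)
        d = fp.project_slab(model, half_thickness=2.0)
        assert len(d) == 1   # closed interval keeps z == 2.0, drops beyond

    def test_toy_bundle_disk_count(self):
        model = make_toy_bundle(8)
        d = fp.project_slab(model)
        assert len(d) == len(model.atoms)

    def test_empty_slab_rejected(self):
        from cscmorph.synthgen import ToyAtomicModel
        model = ToyAtomicModel(np.array([[0.0, 0.0, 10.0, 0.2, 1.0]]))
        with pytest.raises(ValueError):
            fp.project_slab(model, half_thickness=2.0)

    def test_unknown_element_warns_default_radius(self, tmp_path):
        pdb = tmp_path / "odd.pdb"
        pdb.write_text(
            "ATOM      1 XX   UNK A   1       0.000   0.000   0.000"
            "  1.00  0.00          XX\nEND\n")
        with pytest.warns(UserWarning, match="unknown element"):
            d = fp.project_slab(pdb, slab_midplane=0.0)
        assert d.r[0] == pytest.approx(fp.DEFAULT_VDW_NM)


class TestUnionArea:
    def test_single_unit_disk(self):
        assert fp.union_area(disks([[0, 0, 1, 1]])) == pytest.approx(math.pi, rel=5e-3)

    def test_disjoint_disks_add(self):
        d = disks([[0, 0, 1, 1], [10, 0, 1, 2]])
        assert fp.union_area(d) == pytest.approx(2 * math.pi, rel=5e-3)

    def test_two_disk_lens_closed_form(self):
        d = disks([[0, 0, 1, 1], [1, 0, 1, 2]])
        assert fp.union_area(d) == pytest.approx(2 * math.pi - TWO_DISK_LENS,
                                                 rel=5e-3)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            n = int(rng.integers(1, 8))
            sets = np.column_stack([rng.uniform(0, 5, n), rng.uniform(0, 5, n),
                                    rng.uniform(0.3, 1.5, n), np.ones(n)])
            d = disks(sets)
            grid = fp.union_area(d, 0.05)
            mc = monte_carlo_union_area(d, 10 ** 6, rng)
            assert abs(grid - mc) / mc <= 0.005

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            fp.union_area(disks([[0, 0, 1, 1]]), grid_resolution=0.0)


class TestBlurAndThreshold:
    def test_autocalibrated_area_matches_hard_union(self):
        mono = fp.project_slab(make_toy_bundle(8))
        for ds in (disks([[0, 0, 1, 1]]),
                   disks([[0, 0, 1, 1], [1.5, 0, 0.8, 2]]),
                   mono):
            hard = fp.union_area(ds)
            _, area = fp.blur_and_threshold(ds, R=2.5)
            assert area == pytest.approx(hard, rel=0.01)

    def test_small_blur_limit_without_calibration(self):
        d = disks([[0, 0, 1, 1]])
        _, area = fp.blur_and_threshold(d, R=0.01, tau=0.5)
        assert area == pytest.approx(math.pi, rel=0.01)

    def test_scaling_by_two_quadruples_area(self):
        d = disks([[0, 0, 0.6, 1], [1.0, 0.3, 0.5, 1]])
        _, a1 = fp.blur_and_threshold(d, R=1.0)
        d2 = fp.DiskSet(2 * d.x, 2 * d.y, 2 * d.r, d.label)
        _, a2 = fp.blur_and_threshold(d2, R=2.0)
        assert a2 == pytest.approx(4 * a1, rel=0.01)

    def test_invalid_tau_rejected(self):
        d = disks([[0, 0, 1, 1]])
        with pytest.raises(ValueError):
            fp.blur_and_threshold(d, R=1.0, tau=1.5)


class TestCnOligomer:
    def test_single_disk_dimer_tangent(self):
        mono = disks([[0, 0, 1, 1]])
        olig, layout = fp.build_cn_oligomer(mono, 2, contact_tolerance=0.0)
        assert layout.r_mono == pytest.approx(1.0, abs=0.01)
        d = math.hypot(olig.x[0] - olig.x[1], olig.y[0] - olig.y[1])
        assert d == pytest.approx(2.0, abs=0.02)
        assert fp.union_area(olig) == pytest.approx(2 * math.pi, rel=5e-3)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_zero_tolerance_additive_area(self, n):
        mono = fp.project_slab(make_toy_bundle(8))
        a_mono = fp.union_area(mono)
        olig, _ = fp.build_cn_oligomer(mono, n, contact_tolerance=0.0,
                                       phase_step_deg=15.0)
        assert fp.union_area(olig) == pytest.approx(n * a_mono, rel=5e-3)

    def test_areas_increase_with_order_and_bounded(self):
        mono = fp.project_slab(make_toy_bundle(8))
        a1 = fp.union_area(mono)
        areas = []
        for n in range(2, 7):
            olig, _ = fp.build_cn_oligomer(mono, n, contact_tolerance=0.0,
                                           phase_step_deg=15.0)
            a = fp.union_area(olig)
            areas.append(a)
            assert a1 <= a <= n * a1 * (1 + 5e-3)
        assert all(b > a for a, b in zip(areas, areas[1:]))

    def test_invalid_order_rejected(self):
        mono = disks([[0, 0, 1, 1]])
        with pytest.raises(ValueError):
            fp.build_cn_oligomer(mono, 7)


class TestSixfoldAssembly:
    def test_opposite_lobe_spacing_from_ring_radius(self):
        mono = disks([[0, 0, 0.5, 1]])
        asm, _ = fp.build_sixfold_assembly(mono, r_ring=8.5,
                                           lobe_rotation=0.0)
        centers = np.array([[asm.x[asm.label == l].mean(),
                             asm.y[asm.label == l].mean()]
                            for l in range(1, 7)])
        from cscmorph.metrology import opposite_lobe_spacings
        _, mean_sp = opposite_lobe_spacings(centers)
        assert mean_sp == pytest.approx(17.0, abs=1e-9)

    def test_point_like_oligomer_has_no_clash(self):
        mono = disks([[0, 0, 0.01, 1]])
        _, layout = fp.build_sixfold_assembly(mono, r_ring=5.0)
        assert layout.clash_area == 0.0

    def test_oversized_lobes_report_positive_clash(self):
        """Lobes with bounding radius above r_ring*sin(30 deg) must overlap
        their neighbours."""
        r_ring = 4.0
        mono = disks([[0, 0, r_ring * 0.6, 1]])   # radius > r_ring/2
        _, layout = fp.build_sixfold_assembly(mono, r_ring=r_ring,
                                              lobe_rotation=0.0)
        assert layout.clash_area > 0.0

    def test_sixfold_symmetry_of_areas(self):
        mono = fp.project_slab(make_toy_bundle(4))
        asm, _ = fp.build_sixfold_assembly(mono, r_ring=8.5, lobe_rotation=0.0)
        areas = [fp.union_area(fp.DiskSet(asm.x[asm.label == l],
                                          asm.y[asm.label == l],
                                          asm.r[asm.label == l],
                                          asm.label[asm.label == l]))
                 for l in range(1, 7)]
        np.testing.assert_allclose(areas, areas[0], rtol=5e-3)

    def test_invalid_ring_radius_rejected(self):
        mono = disks([[0, 0, 1, 1]])
        with pytest.raises(ValueError):
            fp.build_sixfold_assembly(mono, r_ring=0.0)
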