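"""Stoichiometry calls, overlay fits, published arithmetic, pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cscmorph import compare, footprint as fp, reference
from cscmorph.compare import (overlay_fit, percent_excess,
                              published_comparisons, run_pipeline,
                              stoichiometry_call)
from cscmorph.synthgen import SimulationConfig


class TestPercentExcess:
    def test_published_perimeter_comparison(self):
        assert percent_excess(78.4, 74.8) == pytest.approx(4.8, abs=0.05)

    def test_published_trimer_area_comparison(self):
        assert round(percent_excess(41.9, 39.5)) == 6

    def test_identity_is_zero(self):
        assert percent_excess(3.7, 3.7) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4))
    def test_sign_follows_difference(self, a, b):
        v = percent_excess(a, b)
        assert (v > 0) == (a > b) or v == 0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_excess(1.0, 0.0)


class TestStoichiometryCall:
    def test_published_8tmh_row_calls_trimer(self):
        call = stoichiometry_call(reference.oligomer_areas("8tmh"), 39.5)
        assert call.best_order == 3
        assert call.cesa_count == 18

    def test_published_7tmh_row_calls_trimer(self):
        call = stoichiometry_call(reference.oligomer_areas("7tmh_cesa"), 39.5)
        assert call.best_order == 3

    def test_missing_orders_warn_and_degenerate_call(self):
        with pytest.warns(UserWarning):
            call = stoichiometry_call({2: 28.7}, 39.5)
        assert call.best_order == 2
        assert call.cesa_count == 12

    def test_tie_breaks_to_smaller_order(self):
        call = stoichiometry_call({2: 38.0, 3: 41.0, 4: 50.0, 5: 60.0, 6: 70.0},
                                  39.5)
        assert call.best_order == 2

    def test_invariant_under_uniform_rescaling(self):
        areas = reference.oligomer_areas("8tmh")
        c1 = stoichiometry_call(areas, 39.5)
        c2 = stoichiometry_call({n: 3.5 * a for n, a in areas.items()},
                                3.5 * 39.5)
        assert c1.best_order == c2.best_order


class TestPublishedComparisons:
    def test_overall_means_reproduced(self):
        pub = published_comparisons()
        m = pub["overall_means"]
        assert round(m["perimeter"], 1) == 77.3
        assert round(m["diameter"], 1) == 23.4
        assert round(m["lobe_area"], 1) == 39.5

    def test_means_rows_reproduced(self):
        pub = published_comparisons()
        g = pub["group_means"]
        assert round(g["original"]["perimeter"], 1) == 76.6
        assert round(g["class_averages"]["perimeter"], 1) == 78.0
        assert round(g["original"]["lobe_area"], 1) == 39.9
        assert round(g["class_averages"]["lobe_area"], 1) == 39.1

    def test_diameter_offset_and_perimeter_excess(self):
        pub = published_comparisons()
        assert round(pub["diameter_class_avg_minus_original_nm"], 1) == 0.5
        assert round(pub["perimeter_circle_vs_hexagon_excess_pct"], 1) == 4.8
        assert round(pub["perimeter_circle_minus_hexagon_nm"], 1) == 3.6

    def test_cytosolic_comparisons(self):
        pub = published_comparisons()
        assert round(pub["sixfold_cytosolic_vs_saxs_schematic_excess_pct"]) == 21
        assert round(pub["cytosolic_vs_membrane_diameter_excess_pct"]) == 28

    def test_negstain_range_endpoints(self):
        pub = published_comparisons()
        assert round(pub["negstain_vs_computational_excess_pct_of_model"]) == 4
        assert round(pub["negstain_vs_saxs_excess_pct_of_image"]) == 8


class TestOverlayFit:
    def _disc_image(self, r_px=20, h=101, soft=False):
        ys, xs = np.mgrid[0:h, 0:h] - h // 2
        d2 = xs ** 2 + ys ** 2
        return np.where(d2 <= r_px ** 2, 1.0, 0.0)

    def test_footprint_equal_to_mask(self):
        h, px = 101, 0.25
        img = self._disc_image(20, h)
        d = fp.DiskSet([0.0], [0.0], [20 * px], [1])
        fit = overlay_fit(d, img, px)
        assert fit.coverage == pytest.approx(1.0, abs=0.02)
        assert fit.spill == pytest.approx(0.0, abs=0.02)

    def test_empty_footprint_rejected(self):
        img = self._disc_image()
        with pytest.raises(ValueError):
            overlay_fit(fp.DiskSet([], [], [], []), img, 0.25)

    def test_scale_mismatch_detected(self):
        img = self._disc_image()
        d = fp.DiskSet([0.0], [0.0], [500.0], [1])
        with pytest.raises(ValueError, match="scale mismatch"):
            overlay_fit(d, img, 0.25)

    def test_trimer_scale_beats_dimer_and_tetramer(self):
        """On a rosette with 40 nm^2 lobes at the mean (class-average)
        geometry, a ~40 nm^2-per-lobe six-fold footprint scores better
        (coverage - spill) than ~29 or ~47 nm^2 footprints."""
        from cscmorph import synthgen
        from cscmorph.classavg import extract_boxes, invert_contrast
        from cscmorph.synthgen import make_toy_bundle

        cfg = SimulationConfig(n_particles=1, seed=5, noise_sd=0.0,
                               halo_strength=0.0, five_lobe_fraction=0.0,
                               centroid_jitter_sd=0.0, lobe_area_sd=0.0,
                               lobe_area_mean=40.0, lobe_shape_mix=0.0)
        micrograph, records = synthgen.simulate_micrograph(cfg)
        stack, _ = extract_boxes(micrograph, [records[0].center], cfg.box_size)
        img = invert_contrast(stack).images[0]

        mono = fp.project_slab(make_toy_bundle(8))
        scores = {}
        for n, area in ((2, 28.7), (3, 39.9), (4, 47.2)):
            olig, _ = fp.build_cn_oligomer(mono, n, contact_tolerance=0.0,
                                           phase_step_deg=15.0)
            asm, _ = fp.build_sixfold_assembly(olig.scaled_to_area(area),
                                               r_ring=cfg.ring_radius,
                                               lobe_rotation=0.0)
            fit = overlay_fit(asm, img, cfg.pixel_size, rotation_step_deg=2.0)
            scores[n] = fit.coverage - fit.spill
        assert scores[3] > scores[2]
        assert scores[3] > scores[4]


@pytest.fixture(scope="module")
def run(tmp_path_factory):
    cfg = SimulationConfig(n_particles=12, seed=42)
    out = tmp_path_factory.mktemp("pipe")
    report = run_pipeline(cfg, out, n_trials=2, align_iters=3,
                          oligomer_phase_step_deg=30.0)
    return cfg, out, report


class TestPipeline:
    def test_report_written_with_all_stages(self, run):
        _, out, report = run
        for name in ("micrograph.tif", "ground_truth.tsv", "measurements.tsv",
                     "class_averages.tif", "lobe_scores.tsv",
                     "oligomer_areas.tsv", "report.json", "report.tsv"):
            assert (out / name).exists()
        assert report.toy_call.cesa_count == 6 * report.toy_call.best_order

    def test_synthetic_call_is_trimeric(self, run):
        """Toy oligomer areas vs a ~39.9 nm^2 imaged mean call a trimer,
        hence 18 synthases."""
        _, _, report = run
        assert report.toy_call.best_order == 3
        assert report.toy_call.cesa_count == 18

    def test_determinism_for_fixed_seed(self, run, tmp_path):
        cfg, _, report = run
        report2 = run_pipeline(cfg, tmp_path / "again", n_trials=2,
                               align_iters=3, oligomer_phase_step_deg=30.0)
        assert report2.to_json() == report.to_json()

    def test_missing_seed_rejected_before_compute(self, tmp_path):
        with pytest.raises(ValueError, match="seed"):
            run_pipeline({"n_particles": 4}, tmp_path / "x")
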