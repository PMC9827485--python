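"""Synthetic study generator: determinism, geometry, rater bias, chemistry,
rendering."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from hemoscore import (
    AnnotatorProfile,
    ChemistryParams,
    SlideManifest,
    StudyConfig,
    compute_ths,
    generate_slide,
    generate_study,
    grade_from_content,
    ground_truth_annotations,
    make_default_profiles,
    render_slide_image,
    simulate_annotator,
    simulate_chemistry,
)
from hemoscore.matching import match_annotations


class TestGenerateStudy:
    def test_structure_and_ranges(self):
        config = StudyConfig(n_slide_pairs=3, cell_count_range=(596, 8954))
        manifests, cells = generate_study(config, seed=5)
        assert len(manifests) == 6
        for m in manifests:
            assert 596 <= m.n_macrophages <= 8954
        # paired slides share sample and severity, differ in stain
        for k in range(3):
            pb, tb = manifests[2 * k], manifests[2 * k + 1]
            assert pb.sample_id == tb.sample_id
            assert pb.severity == tb.severity
            assert {pb.stain, tb.stain} == {"prussian_blue", "turnbull_blue"}

    def test_deterministic_under_seed(self):
        config = StudyConfig(n_slide_pairs=1, cell_count_range=(300, 400))
        out1 = generate_study(config, seed=9)
        out2 = generate_study(config, seed=9)
        assert out1 == out2
        out3 = generate_study(config, seed=10)
        assert out3 != out1

    def test_zero_severity_means_ths_zero(self):
        config = StudyConfig(
            n_slide_pairs=2, cell_count_range=(300, 350), severity_range=(0.0, 0.0)
        )
        manifests, cells = generate_study(config, seed=3)
        for m in manifests:
            anns = ground_truth_annotations(
                [c for c in cells if c.slide_id == m.slide_id]
            )
            assert compute_ths(anns, allow_fewer=True).ths == 0.0


class TestGenerateSlide:
    def manifest(self, n=50, severity=0.5, side=2000):
        return SlideManifest(
            slide_id="t1", stain="prussian_blue", severity=severity,
            n_macrophages=n, width=side, height=side,
        )

    def test_single_cell(self):
        cells = generate_slide(self.manifest(n=1), seed=0)
        assert len(cells) == 1  # distractor count rounds to 0

    def test_grades_consistent_with_contents(self):
        cells = generate_slide(self.manifest(n=200, side=3000), seed=1)
        for c in cells:
            assert c.grade == grade_from_content(c.content)

    def test_minimum_spacing_respected(self):
        cells = generate_slide(self.manifest(n=150, side=3000), seed=2)
        xy = np.array([[c.x, c.y] for c in cells])
        d, _ = cKDTree(xy).query(xy, k=2)
        assert d[:, 1].min() >= 110.0

    def test_full_severity_slide_is_eiph_positive(self):
        cells = generate_slide(self.manifest(n=300, severity=1.0, side=4000), seed=4)
        ths = compute_ths(ground_truth_annotations(cells), allow_fewer=True).ths
        assert ths >= 75.0

    def test_extent_too_small(self):
        with pytest.raises(ValueError, match="extent too small"):
            generate_slide(self.manifest(n=500, side=1000), seed=0)

    def test_coordinates_inside_extent(self):
        m = self.manifest(n=100, side=2500)
        for c in generate_slide(m, seed=6):
            assert 0 <= c.x < m.width and 0 <= c.y < m.height


class TestSimulateAnnotator:
    def test_identity_annotator_reproduces_ground_truth(
        self, slide_cells, identity_profile
    ):
        anns = simulate_annotator(slide_cells, identity_profile, seed=1)
        gt = {(c.x, c.y): c.grade for c in slide_cells if c.is_macrophage}
        assert len(anns) == 300
        for a in anns:
            assert gt[(a.x, a.y)] == a.grade

    def test_n_target_exceeds_supply(self, slide_cells):
        prof = AnnotatorProfile(annotator_id="x", n_target=10_000)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_annotator(slide_cells, prof, seed=1)

    def test_negative_shift_inflates_ths(self, slide_cells):
        base = AnnotatorProfile(
            annotator_id="b", threshold_shift=0.0, perception_sd=0.0,
            misid_rate=0.0, jitter_sd=0.0,
        )
        shifted = AnnotatorProfile(
            annotator_id="s", threshold_shift=-0.05, perception_sd=0.0,
            misid_rate=0.0, jitter_sd=0.0,
        )
        t0 = compute_ths(simulate_annotator(slide_cells, base, seed=7)).ths
        t1 = compute_ths(simulate_annotator(slide_cells, shifted, seed=7)).ths
        assert t1 > t0

    def test_stronger_negative_shift_means_larger_bias(self, slide_cells):
        ths = []
        for shift in (0.0, -0.04, -0.08, -0.12):
            prof = AnnotatorProfile(
                annotator_id=f"s{shift}", threshold_shift=shift,
                perception_sd=0.0, misid_rate=0.0, jitter_sd=0.0,
            )
            ths.append(compute_ths(simulate_annotator(slide_cells, prof, seed=3)).ths)
        assert ths == sorted(ths)

    def test_misid_rate_controls_matched_fraction(self, slide_cells, gt_annotations):
        fractions = []
        for k in range(8):
            prof = AnnotatorProfile(
                annotator_id=f"m{k}", misid_rate=0.23, jitter_sd=10.0,
            )
            anns = simulate_annotator(slide_cells, prof, seed=100 + k)
            m = match_annotations(anns, gt_annotations)
            fractions.append(m.matched_fraction_a())
        # binomial expectation: matched fraction ~ 1 - misid_rate = 0.77
        assert np.mean(fractions) == pytest.approx(0.77, abs=0.03)

    def test_selection_patterns_cover_requested_count(self, slide_cells):
        for pattern in ("uniform_random", "clustered_fields", "meander"):
            prof = AnnotatorProfile(
                annotator_id=pattern, selection_pattern=pattern, misid_rate=0.0,
            )
            anns = simulate_annotator(slide_cells, prof, seed=11)
            assert len(anns) == 300
            # selections are distinct cells
            assert len({(a.x, a.y) for a in anns}) == 300

    def test_default_cohort(self):
        profiles = make_default_profiles()
        assert len(profiles) == 10
        assert all(p.n_target == 300 for p in profiles)
        # mostly-negative threshold shifts: the cohort over-grades on average
        assert np.mean([p.threshold_shift for p in profiles]) < 0


class TestSimulateChemistry:
    def manifest(self):
        return SlideManifest(
            slide_id="c1", stain="prussian_blue", severity=0.5,
            n_macrophages=4000, width=1000, height=1000,
        )

    def test_zero_signal_is_censored(self):
        params = ChemistryParams(iron_baseline=0.0)
        m = simulate_chemistry(self.manifest(), 0.0, params, seed=1)
        assert m.iron_censored and m.iron == pytest.approx(0.4)

    def test_no_value_inside_censoring_gap(self):
        for s in range(200):
            m = simulate_chemistry(self.manifest(), float(s % 40) * 10, seed=s)
            assert m.iron_censored or m.iron >= 0.4

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ChemistryParams(iron_slope=-1.0)
        with pytest.raises(ValueError):
            simulate_chemistry(self.manifest(), 500.0, seed=0)

    def test_study_level_correlations(self):
        """Iron tracks the ground-truth THS; RBC and hemoglobin do not."""
        config = StudyConfig()  # full 52-slide default design
        manifests, cells = generate_study(config, seed=12)
        by_slide = {}
        for c in cells:
            if c.is_macrophage:
                by_slide.setdefault(c.slide_id, []).append(c.grade)
        ths, iron, rbc = [], [], []
        for i, m in enumerate(manifests):
            t = 100.0 * float(np.mean(by_slide[m.slide_id]))
            mm = simulate_chemistry(m, t, seed=1000 + i)
            ths.append(t)
            iron.append(mm.iron)
            rbc.append(mm.rbc)
        assert spearmanr(ths, iron).statistic > 0.6
        assert abs(spearmanr(ths, rbc).statistic) < 0.3


class TestRenderSlideImage:
    def cells(self, contents, spacing=140.0, is_macrophage=True):
        from hemoscore import GroundTruthCell

        return [
            GroundTruthCell(
                slide_id="r1", cell_id=f"c{i}", x=100.0 + i * spacing, y=100.0,
                content=float(p), grade=grade_from_content(p),
                is_macrophage=is_macrophage,
            )
            for i, p in enumerate(contents)
        ]

    def test_empty_slide_is_blank_background(self):
        img, registry = render_slide_image([], seed=1)
        assert registry == []
        assert img.std() < 5.0 and img.mean() > 235

    def test_zero_content_has_no_pigment(self):
        from hemoscore.imaging import PIGMENT, classify_pixels

        img, registry = render_slide_image(self.cells([0.0]), seed=2)
        assert registry[0]["pigment_fraction"] == 0.0
        labels = classify_pixels(img).labels
        assert (labels == PIGMENT).sum() == 0

    def test_pigment_fraction_close_to_content(self):
        contents = [0.0, 0.1, 0.3, 0.6, 0.9, 1.0]
        _, registry = render_slide_image(self.cells(contents), seed=3)
        for want, entry in zip(contents, registry):
            assert entry["pigment_fraction"] == pytest.approx(want, abs=0.05)

    def test_deterministic(self):
        cells = self.cells([0.2, 0.7])
        img1, reg1 = render_slide_image(cells, seed=8)
        img2, reg2 = render_slide_image(cells, seed=8)
        assert np.array_equal(img1, img2) and reg1 == reg2

    def test_extent_overflow(self):
        with pytest.raises(ValueError, match="overflow"):
            render_slide_image(self.cells([0.5]), seed=0, shape=(50, 50))
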