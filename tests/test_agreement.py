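"""Variance decomposition, error reduction and the uncertainty interval."""

import numpy as np
import pytest

from hemoscore import (
    ThsTable,
    error_reduction,
    measurement_errors,
    uncertainty_interval,
    variance_components,
)


def table(values, slides=None, annotators=None):
    values = np.asarray(values, dtype=float)
    S, A = values.shape
    return ThsTable(
        slides=tuple(slides or (f"s{i}" for i in range(S))),
        annotators=tuple(annotators or (f"a{j}" for j in range(A))),
        values=values,
    )


def simulate_table(rng, S=52, A=10, s2_slide=2500.0, s2_annot=900.0, s2_resid=400.0,
                   mu=150.0):
    y = (
        mu
        + rng.normal(0, np.sqrt(s2_slide), size=(S, 1))
        + rng.normal(0, np.sqrt(s2_annot), size=(1, A))
        + rng.normal(0, np.sqrt(s2_resid), size=(S, A))
    )
    return table(np.clip(y, 0, 400))


class TestThsTable:
    def test_shape_and_range_validation(self):
        with pytest.raises(ValueError, match="shape"):
            ThsTable(("s1",), ("a1", "a2"), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="outside"):
            table([[0.0, 500.0]])
        with pytest.raises(ValueError, match="incomplete"):
            table([[0.0, np.nan]])

    def test_from_records_requires_complete_design(self):
        from hemoscore import ThsRecord

        recs = [
            ThsRecord("s1", "a1", 300, 10.0, False),
            ThsRecord("s1", "a2", 300, 20.0, False),
            ThsRecord("s2", "a1", 300, 30.0, False),
        ]
        with pytest.raises(ValueError, match="incomplete"):
            ThsTable.from_records(recs)
        recs.append(ThsRecord("s2", "a2", 300, 40.0, False))
        t = ThsTable.from_records(recs)
        assert t.values[1, 1] == 40.0

    def test_csv_round_trip(self, tmp_path):
        t = table([[10.0, 20.0], [30.0, 40.0]])
        t.to_csv(tmp_path / "t.csv")
        back = ThsTable.from_csv(tmp_path / "t.csv")
        assert back.slides == t.slides and back.annotators == t.annotators
        assert np.allclose(back.values, t.values)


class TestVarianceComponents:
    def test_constant_table_degenerate(self):
        vc = variance_components(table(np.full((4, 3), 100.0)))
        assert vc.degenerate
        assert vc.sigma2_slide == vc.sigma2_annotator == vc.sigma2_residual == 0.0
        assert vc.icc_agreement == 0.0 and vc.error_partition == 0.0

    def test_pure_annotator_offsets(self):
        # identical slides, annotators offset by {0,10,20,30}: all variance is
        # systematic between-annotator error
        offsets = np.array([0.0, 10.0, 20.0, 30.0])
        vc = variance_components(table(np.tile(offsets, (6, 1))))
        assert vc.sigma2_residual == pytest.approx(0.0, abs=1e-9)
        assert vc.sigma2_slide == pytest.approx(0.0, abs=1e-9)
        assert vc.sigma2_annotator > 0
        assert vc.error_partition == pytest.approx(1.0)

    def test_pure_slide_differences(self):
        values = np.tile(np.array([[0.0], [100.0], [200.0]]), (1, 5))
        vc = variance_components(table(values))
        assert vc.sigma2_annotator == pytest.approx(0.0, abs=1e-9)
        assert vc.icc_agreement == pytest.approx(1.0)
        assert vc.error_partition == 0.0

    def test_negative_estimate_truncated_with_warning(self):
        # pure interaction pattern drives the annotator/slide MoM solutions
        # negative
        with pytest.warns(UserWarning, match="truncated"):
            vc = variance_components(table([[0.0, 10.0], [10.0, 0.0]]))
        assert vc.sigma2_annotator == 0.0 and vc.sigma2_slide == 0.0
        assert vc.sigma2_residual > 0

    def test_small_design_rejected(self):
        with pytest.raises(ValueError, match="A=1"):
            variance_components(table([[1.0], [2.0]]))

    def test_parameter_recovery(self, rng):
        """MoM estimates are unbiased at the study's design size."""
        est = np.zeros(3)
        n = 60
        for _ in range(n):
            t = simulate_table(rng, mu=180.0, s2_slide=2000, s2_annot=700, s2_resid=300)
            vc = variance_components(t)
            est += (vc.sigma2_slide, vc.sigma2_annotator, vc.sigma2_residual)
        est /= n
        assert est[0] == pytest.approx(2000, rel=0.15)
        assert est[1] == pytest.approx(700, rel=0.20)
        assert est[2] == pytest.approx(300, rel=0.10)

    def test_mom_reconstructs_grand_variance(self, rng):
        t = simulate_table(rng)
        vc = variance_components(t)
        total = vc.sigma2_slide + vc.sigma2_annotator + vc.sigma2_residual
        assert total == pytest.approx(np.var(t.values, ddof=1), rel=0.15)

    def test_ratios_scale_invariant(self, rng):
        t = simulate_table(rng, mu=100, s2_slide=900, s2_annot=100, s2_resid=100)
        vc1 = variance_components(t)
        vc2 = variance_components(table(t.values / 4.0))
        assert vc2.icc_agreement == pytest.approx(vc1.icc_agreement, rel=1e-9)
        assert vc2.error_partition == pytest.approx(vc1.error_partition, rel=1e-9)

    def test_reml_agrees_with_mom_on_balanced_data(self, rng):
        t = simulate_table(rng)
        mom = variance_components(t, method="anova_mom")
        reml = variance_components(t, method="reml")
        # REML equals MoM at interior solutions of balanced designs up to df
        # corrections; agreement within a few percent
        assert reml.sigma2_residual == pytest.approx(mom.sigma2_residual, rel=0.1)
        assert reml.icc_agreement == pytest.approx(mom.icc_agreement, abs=0.05)


class TestErrorReduction:
    def test_no_change_means_zero(self, rng):
        t = simulate_table(rng)
        red = error_reduction(t, t)
        assert red.overall_pct == pytest.approx(0.0, abs=1e-9)
        assert red.between_annotator_pct == pytest.approx(0.0, abs=1e-9)
        assert red.residual_pct == pytest.approx(0.0, abs=1e-9)

    def test_offsets_removed_is_full_between_reduction(self, rng):
        S, A = 20, 6
        slides = rng.uniform(50, 250, size=(S, 1))
        noise = rng.normal(0, 5, size=(S, A))
        offsets = np.linspace(0, 50, A)
        raw = table(np.clip(slides + offsets + noise, 0, 400))
        std = table(np.clip(slides + noise, 0, 400))
        red = error_reduction(raw, std)
        assert red.between_annotator_pct == pytest.approx(100.0, abs=1.0)
        assert abs(red.residual_pct) < 30.0  # noise kept

    def test_zero_raw_component_undefined(self):
        t = table(np.tile(np.array([[10.0], [200.0]]), (1, 3)))
        red = error_reduction(t, t)
        assert red.between_annotator_pct is None

    def test_mismatched_tables_rejected(self, rng):
        t1 = simulate_table(rng, S=5, A=3)
        t2 = simulate_table(rng, S=5, A=4)
        with pytest.raises(ValueError):
            error_reduction(t1, t2)


class TestMeasurementErrors:
    def test_constant_and_two_value_slides(self):
        assert np.allclose(measurement_errors(table(np.full((3, 4), 50.0))), 0.0)
        errs = measurement_errors(table([[60.0, 80.0]]))
        assert sorted(errs) == pytest.approx([-10.0, 10.0])

    def test_errors_sum_to_zero_per_slide(self, rng):
        t = simulate_table(rng, S=7, A=5)
        errs = measurement_errors(t).reshape(7, 5)
        assert np.allclose(errs.sum(axis=1), 0.0, atol=1e-9)


class TestUncertaintyInterval:
    def test_degenerate_zero_errors(self):
        ui = uncertainty_interval(np.zeros(100))
        assert (ui.lower, ui.upper) == (75.0, 75.0)

    def test_interpolated_quantiles(self):
        errors = np.arange(-50.0, 51.0, 10.0)  # 11 values
        ui = uncertainty_interval(errors)
        assert ui.q_low == pytest.approx(-40.0)
        assert ui.q_high == pytest.approx(40.0)
        assert (ui.lower, ui.upper) == (pytest.approx(35.0), pytest.approx(115.0))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="coverage"):
            uncertainty_interval([1.0, -1.0], coverage=1.2)
        with pytest.raises(ValueError, match="at least 2"):
            uncertainty_interval([1.0])

    def test_width_monotone_under_spread(self, rng):
        base = rng.normal(0, 10, size=400)
        ui1 = uncertainty_interval(base)
        # mean-preserving spread: symmetric extra dispersion
        spread = np.concatenate([base, base + 30, base - 30])
        ui2 = uncertainty_interval(spread)
        assert (ui2.upper - ui2.lower) >= (ui1.upper - ui1.lower)
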