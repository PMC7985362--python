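"""Q-score statistics, detection calls, standard curves, power analysis."""

import numpy as np
import pytest

from qbead import (
    CircuitParams,
    EventTable,
    FrequencyPanel,
    QScoreResult,
    SampleSpec,
    ShellMap,
    StandardCurve,
    detection_call,
    fit_length_response,
    fit_standard_curve,
    ipr_spectrum,
    q_score,
    quantify_unknown,
    simulate_ipr_table,
    subsample_power,
)
from qbead.detect import Event


def table_from_ipr(ipr: np.ndarray) -> EventTable:
    ipr = np.atleast_2d(np.asarray(ipr, dtype=float))
    events = [
        Event(start=i * 100, end=i * 100 + 50, apex_time=float(i), transit_time=0.038,
              ipr=row)
        for i, row in enumerate(ipr)
    ]
    return EventTable(events, n_frequencies=ipr.shape[1])


def qresult(values, label="") -> QScoreResult:
    v = np.asarray(values, dtype=float)
    se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return QScoreResult(float(v.mean()), se, v.size, v, label=label)


class TestSpectrum:
    def test_two_event_hand_arithmetic(self):
        table = table_from_ipr([[1.0] * 8, [3.0] * 8])
        spec = ipr_spectrum(table)
        np.testing.assert_allclose(spec.mean, 2.0)
        np.testing.assert_allclose(spec.sem, 1.0)  # sd sqrt(2), / sqrt(2)

    def test_single_event_warns(self):
        with pytest.warns(UserWarning):
            spec = ipr_spectrum(table_from_ipr([[0.5] * 8]))
        np.testing.assert_allclose(spec.sem, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ipr_spectrum(EventTable([], n_frequencies=8))


class TestQScore:
    def test_unit_ipr_panel(self):
        res = q_score(table_from_ipr(np.ones((5, 8))))
        assert res.q_mean == pytest.approx(8.0)
        assert res.q_se == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        res = q_score(table_from_ipr([[0.1] * 8, [0.3] * 8]))
        assert res.q_mean == pytest.approx(1.6)

    def test_linearity_under_scaling(self):
        rng = np.random.default_rng(0)
        ipr = rng.uniform(0, 0.05, (30, 8))
        assert q_score(table_from_ipr(3 * ipr)).q_mean == pytest.approx(
            3 * q_score(table_from_ipr(ipr)).q_mean, rel=1e-12
        )

    def test_identity_sum_of_means(self):
        rng = np.random.default_rng(1)
        ipr = rng.uniform(0, 0.05, (40, 8))
        res = q_score(table_from_ipr(ipr))
        assert res.q_mean == pytest.approx(ipr.mean(axis=0).sum(), rel=1e-12)

    def test_baseline_offset_invariance(self, circuit, panel, shell_map):
        """A common baseline offset cancels in normalized IPR, hence in Q."""
        from qbead import DetectorParams, TraceSet, detect_events, simulate_traces
        from conftest import fast_settings

        spec = SampleSpec("s", 300, 4.75e4, 15)
        acq = fast_settings(duration=8.0, seed=3)
        traces = simulate_traces(spec, circuit, acq, panel, shell_map)
        det = DetectorParams.for_transit(acq.mean_transit_time)
        q_a = q_score(detect_events(traces, det)).q_mean
        shifted = TraceSet(
            traces.time, 1.25 * traces.channels, traces.panel, traces.settings
        )
        q_b = q_score(detect_events(shifted, det)).q_mean
        assert q_b == pytest.approx(q_a, rel=1e-9)


class TestDetectionCall:
    def test_separated_populations_detected(self):
        rng = np.random.default_rng(0)
        control = qresult(1.0 + 1e-3 * rng.standard_normal(50))
        sample = qresult(2.0 + 1e-3 * rng.standard_normal(50))
        call = detection_call(sample, control)
        assert call.detected and call.p_value < 1e-10

    def test_identical_samples_not_detected(self):
        v = np.linspace(0.9, 1.1, 40)
        call = detection_call(qresult(v), qresult(v))
        assert not call.detected and call.margin < 0

    def test_degenerate_variance_identical_means(self):
        call = detection_call(qresult(np.ones(10)), qresult(np.ones(10)))
        assert call.p_value == 1.0 and not call.detected

    def test_type_i_error_rate(self):
        """Null detection rate stays below alpha over seeded replicates."""
        rng = np.random.default_rng(123)
        hits = 0
        reps = 1000
        for _ in range(reps):
            a = qresult(rng.lognormal(0, 0.2, 100))
            b = qresult(rng.lognormal(0, 0.2, 100))
            hits += detection_call(a, b, alpha=0.05).detected
        assert hits / reps <= 0.06

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            detection_call(qresult([1.0]), qresult([1.0, 2.0]))


class TestStandardCurve:
    def test_collinear_points_exact(self):
        quantities = np.logspace(-3, 0, 5)
        points = [(q, qresult([2.0 * np.log10(q) + 5.0] * 3)) for q in quantities]
        curve = fit_standard_curve(points)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.slope == pytest.approx(2.0, abs=1e-10)
        assert curve.intercept == pytest.approx(5.0, abs=1e-10)

    def test_saturated_plateau_excluded(self):
        lin = [(10.0**e, qresult([1.0 * e + 4.0] * 3)) for e in (-3.0, -2.0, -1.0, 0.0)]
        flat = [(10.0**e, qresult([4.05, 4.0, 3.95])) for e in (1.0, 2.0)]
        curve = fit_standard_curve(lin + flat)
        assert curve.linear_range == pytest.approx((1e-3, 1.0))
        assert curve.n_points == 4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(0.1, qresult([1.0])), (1.0, qresult([2.0]))])

    def test_zero_quantity_rejected(self):
        pts = [(q, qresult([1.0, 1.1])) for q in (0.0, 0.1, 1.0)]
        with pytest.raises(ValueError):
            fit_standard_curve(pts)


class TestQuantifyUnknown:
    def test_inverse_of_fit(self):
        curve = StandardCurve(slope=1.5, intercept=4.0, r_squared=0.99,
                              linear_range=(1e-3, 1.0))
        for q in (1e-3, 0.05, 1.0):
            est = quantify_unknown(qresult([curve.predict(q)] * 3), curve)
            assert est.quantity_fmol == pytest.approx(q, rel=1e-6)
            assert est.in_linear_range

    def test_out_of_range_flagged(self):
        curve = StandardCurve(slope=1.5, intercept=4.0, r_squared=0.99,
                              linear_range=(1e-3, 1.0))
        est = quantify_unknown(qresult([curve.predict(1e-5)] * 3), curve)
        assert not est.in_linear_range

    def test_flat_curve_rejected(self):
        curve = StandardCurve(slope=0.0, intercept=4.0, r_squared=0.5,
                              linear_range=(1e-3, 1.0))
        with pytest.raises(ValueError):
            quantify_unknown(qresult([4.0, 4.1]), curve)


class TestLengthResponse:
    def test_simulated_lengths_positive_slope(self, circuit, panel, shell_map):
        """Longer fragments at equal copies/bead carry more mass, higher Q."""
        points = []
        for bp in (157, 300, 613):
            df = simulate_ipr_table(
                SampleSpec(f"{bp}bp", bp, 4.75e5, 400), circuit, panel, shell_map, seed=5
            )
            points.append((bp, 0.39, qresult(df.to_numpy().sum(axis=1))))
        fit = fit_length_response(points)
        assert fit.slope > 0

    def test_collinear_r2(self):
        points = [(bp, 0.39, qresult([0.01 * bp + 1.0] * 3)) for bp in (100, 200, 300)]
        assert fit_length_response(points).r_squared == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_length_rejected(self):
        points = [(100, 0.39, qresult([1.0, 1.1]))] * 3
        with pytest.raises(ValueError):
            fit_length_response(points)

    def test_unequal_molarity_rejected(self):
        points = [
            (100, 0.39, qresult([1.0, 1.1])),
            (200, 0.19, qresult([2.0, 2.1])),
            (300, 0.39, qresult([3.0, 3.1])),
        ]
        with pytest.raises(ValueError):
            fit_length_response(points)


class TestSubsamplePower:
    def _tables(self, n=200):
        circuit, panel, shell_map = CircuitParams(), FrequencyPanel(), ShellMap()
        s = simulate_ipr_table(SampleSpec("s", 300, 4.75e5, n), circuit, panel, shell_map, seed=2)
        c = simulate_ipr_table(SampleSpec("c", 0, 0.0, n), circuit, panel, shell_map, seed=3)
        return table_from_ipr(s.to_numpy()), table_from_ipr(c.to_numpy())

    def test_full_subsample_reproduces_full_call(self):
        sample, control = self._tables()
        full = detection_call(q_score(sample), q_score(control)).detected
        frac = subsample_power(sample, control, n_sub=200, reps=10, seed=0)
        assert frac == (1.0 if full else 0.0)

    def test_null_fraction_bounded(self):
        _, control = self._tables()
        frac = subsample_power(control, control, n_sub=100, reps=200, seed=1)
        assert frac <= 0.05 + 3 * np.sqrt(0.05 / 200)

    def test_separated_sample_high_power(self):
        sample, control = self._tables()
        frac = subsample_power(sample, control, n_sub=150, reps=100, seed=2)
        assert frac >= 0.95

    def test_tiny_subsample_rejected(self):
        sample, control = self._tables(10)
        with pytest.raises(ValueError):
            subsample_power(sample, control, n_sub=1, reps=5)
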