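import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbcflow.errors import (
    DegenerateDataError,
    EmptyBinError,
    RejectedInputError,
    UndefinedRatioError,
    UndefinedScoreError,
)
from rbcflow.shapes import HEALTHY_CLASSES, PATHOLOGICAL_CLASSES, ShapeClass
from rbcflow.stats import (
    YW_GRID,
    binned_lateral_pdfs,
    compare_groups,
    control_reference,
    deviation_score,
    fit_storage_series,
    lateral_pdf,
    nonslipper_ratio,
    phase_diagram,
    shape_ratio,
    storage_threshold,
    storage_trend,
    storage_trend_panel,
    transition_velocity,
    velocity_bin_index,
)
from rbcflow.synth import FlowPopulationConfig, sample_tracks, slipper_probability


def _integral(dist):
    return np.trapezoid(dist.pdf, dist.grid)


class TestLateralPdf:
    def test_unit_integral_and_counts(self):
        rng = np.random.default_rng(0)
        vals = np.clip(np.abs(rng.normal(0.1, 0.05, 500)), 0, 0.5)
        d = lateral_pdf(vals)
        assert _integral(d) == pytest.approx(1.0, abs=1e-6)
        assert d.hist_counts.sum() == d.n_cells == 500
        assert (d.pdf >= 0).all()

    def test_degenerate_all_on_centerline(self):
        d = lateral_pdf(np.zeros(100))
        assert d.mode() == 0.0
        assert _integral(d) == pytest.approx(1.0, abs=1e-6)
        # mass concentrated near 0: >95% below 0.05
        sel = d.grid <= 0.05
        assert np.trapezoid(d.pdf[sel], d.grid[sel]) > 0.95

    def test_duplicating_data_identical_density(self):
        vals = np.array([0.05, 0.1, 0.2, 0.3])
        d1 = lateral_pdf(vals, bandwidth=0.02)
        d2 = lateral_pdf(np.repeat(vals, 2), bandwidth=0.02)
        assert np.allclose(d1.pdf, d2.pdf)

    def test_empty_bin_signals(self):
        with pytest.raises(EmptyBinError):
            lateral_pdf(np.array([]))

    def test_out_of_range_rejected(self):
        with pytest.raises(RejectedInputError):
            lateral_pdf(np.array([0.7]))

    def test_slipper_mode_recovered_at_high_velocity(self):
        cfg = FlowPopulationConfig(velocity_range=(9.0, 10.0))
        df = sample_tracks(cfg, n=800, rng=1)
        d = lateral_pdf(df.true_offset_yW.to_numpy())
        assert d.mode(min_yw=0.05) == pytest.approx(0.125, abs=0.02)


class TestReferenceAndDeviation:
    def _dists(self, center, n=300, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.clip(np.abs(rng.normal(center, 0.02, n)), 0, 0.5)
        v = rng.uniform(4.0, 5.0, n)
        return binned_lateral_pdfs(v, vals)

    def test_single_control_is_its_own_reference(self):
        d = self._dists(0.1)
        ref = control_reference([d])
        for b in d:
            assert np.allclose(ref[b], d[b].pdf)

    def test_two_identical_controls(self):
        d = self._dists(0.1)
        ref = control_reference([d, d])
        for b in d:
            assert np.allclose(ref[b], d[b].pdf)

    def test_bimodal_reference_from_two_modes(self):
        d0, d1 = self._dists(0.0, seed=1), self._dists(0.25, seed=2)
        ref = control_reference([d0, d1])
        for b, pdf in ref.items():
            assert np.trapezoid(pdf, YW_GRID) == pytest.approx(1.0, abs=1e-6)
            mode_lo = pdf[YW_GRID < 0.05].max()
            mode_hi = pdf[np.abs(YW_GRID - 0.25) < 0.05].max()
            trough = pdf[np.abs(YW_GRID - 0.125) < 0.02].min()
            assert mode_lo > trough and mode_hi > trough

    def test_identity_gives_zero(self):
        d = self._dists(0.1)
        ref = control_reference([d])
        assert deviation_score(d, ref) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_approach_two(self):
        d0 = self._dists(0.0)
        d1 = self._dists(0.4, seed=5)
        ref = control_reference([d0])
        score = deviation_score(d1, ref)
        assert 1.9 < score <= 2.0 + 1e-9

    def test_no_shared_bins_undefined(self):
        d0 = self._dists(0.1)
        rng = np.random.default_rng(3)
        vals = np.clip(np.abs(rng.normal(0.1, 0.02, 100)), 0, 0.5)
        d1 = binned_lateral_pdfs(rng.uniform(8.0, 9.0, 100), vals)
        with pytest.raises(UndefinedScoreError):
            deviation_score(d1, control_reference([d0]))


class TestRatios:
    def test_no_pathological_zero(self):
        labels = [ShapeClass.CROISSANT] * 100
        v = np.full(100, 5.0)
        assert shape_ratio(labels, v) == 0.0

    def test_even_split_is_one(self):
        labels = [ShapeClass.ACANTHOCYTE] * 50 + [ShapeClass.CROISSANT] * 50
        v = np.full(100, 5.0)
        assert shape_ratio(labels, v) == 1.0

    def test_zero_denominator_undefined(self):
        labels = [ShapeClass.SPHERE] * 10
        with pytest.raises(UndefinedRatioError):
            shape_ratio(labels, np.full(10, 5.0))

    def test_mixture_fraction_recovered(self):
        cfg = FlowPopulationConfig(fraction_pathological=0.05)
        df = sample_tracks(cfg, n=4000, rng=2)
        r = shape_ratio(df.true_class, df.true_velocity_mm_s, velocity_range=(0.5, 10.0))
        expected = 0.05 / 0.95
        se = 3 * np.sqrt(0.05 * 0.95 / 4000) / 0.95**2
        assert abs(r - expected) < se + 0.01

    def test_nonslipper_all_slippers(self):
        labels = [ShapeClass.SLIPPER] * 60
        assert nonslipper_ratio(labels, np.full(60, 9.0)) == 0.0

    def test_nonslipper_half(self):
        labels = [ShapeClass.CROISSANT] * 30 + [ShapeClass.SLIPPER] * 60
        assert nonslipper_ratio(labels, np.full(90, 9.0)) == pytest.approx(0.5)

    def test_nonslipper_no_slippers_undefined(self):
        with pytest.raises(UndefinedRatioError):
            nonslipper_ratio([ShapeClass.SPHERE] * 5, np.full(5, 9.0))


class TestPhaseDiagram:
    def test_fractions_sum_to_one_and_empty_bins_flagged(self):
        labels = [ShapeClass.CROISSANT, ShapeClass.SLIPPER, ShapeClass.SPHERE]
        v = [1.5, 1.7, 4.2]
        pd_ = phase_diagram(labels, v)
        populated = pd_.n_per_bin > 0
        assert populated.sum() == 2
        assert np.allclose(np.nansum(pd_.fractions[populated], axis=1), 1.0, atol=1e-9)
        assert np.isnan(pd_.fractions[~populated]).all()

    def test_all_croissant(self):
        labels = [ShapeClass.CROISSANT] * 10
        pd_ = phase_diagram(labels, np.linspace(1.0, 9.0, 10))
        populated = pd_.n_per_bin > 0
        assert np.allclose(pd_.fraction_of(ShapeClass.CROISSANT)[populated], 1.0)

    def test_slipper_fraction_tracks_logistic(self):
        cfg = FlowPopulationConfig(fraction_pathological=0.0)
        df = sample_tracks(cfg, n=5000, rng=4)
        pd_ = phase_diagram(df.true_class, df.true_velocity_mm_s)
        for b in range(10):
            n = pd_.n_per_bin[b]
            if n == 0:
                continue
            mid_expected = slipper_probability(
                df.true_velocity_mm_s[
                    velocity_bin_index(df.true_velocity_mm_s.to_numpy()) == b
                ],
                cfg,
            ).mean()
            bound = 2.576 * np.sqrt(mid_expected * (1 - mid_expected) / n)
            assert abs(pd_.fraction_of(ShapeClass.SLIPPER)[b] - mid_expected) <= bound

    def test_empty_input_rejected(self):
        with pytest.raises(RejectedInputError):
            phase_diagram([], [])


class TestTransitionVelocity:
    def _diagram(self, slipper_from):
        labels, v = [], []
        for mid in np.arange(0.5, 10.0, 1.0):
            cls = ShapeClass.SLIPPER if mid > slipper_from else ShapeClass.CROISSANT
            labels += [cls] * 10
            v += [mid] * 10
        return phase_diagram(labels, v)

    def test_step_mixture_at_six(self):
        assert transition_velocity(self._diagram(6.0)) == pytest.approx(6.5)

    def test_all_slipper_first_bin(self):
        assert transition_velocity(self._diagram(-1.0)) == pytest.approx(0.5)

    def test_never_crossing_none(self):
        assert transition_velocity(self._diagram(99.0)) is None


class TestStorageTrend:
    def test_exact_linear_crossing(self):
        weeks = np.array([1.0, 3.0, 5.0, 7.0])
        norm = 0.5 + 1.0 * weeks  # crosses 6.0 at week 5.5 exactly
        s = storage_trend(weeks, norm * 2.0, normalizer=2.0, threshold=6.0)
        assert s.slope == pytest.approx(1.0)
        assert s.crossing_week == pytest.approx(5.5, abs=1e-12)
        assert s.fitted(s.crossing_week) == pytest.approx(s.threshold)

    def test_flat_below_threshold_never_crosses(self):
        s = storage_trend([1, 2, 3, 4], [1.0, 1.0, 1.0, 1.0], 1.0, threshold=2.0)
        assert s.crossing_week is None

    def test_crossing_beyond_horizon_is_none(self):
        s = storage_trend([1, 2], [1.0, 1.01], 1.0, threshold=10.0)
        assert s.crossing_week is None

    def test_too_few_points_rejected(self):
        with pytest.raises(RejectedInputError):
            fit_storage_series([1], [1.0], 1.0)

    def test_weeks_must_increase(self):
        with pytest.raises(RejectedInputError):
            fit_storage_series([2, 1], [1.0, 2.0], 1.0)

    def test_threshold_is_mean_of_fits(self):
        a = fit_storage_series([0, 1], [1.0, 2.0], 1.0)  # fit(7) = 8
        b = fit_storage_series([0, 1], [1.0, 3.0], 1.0)  # fit(7) = 15
        assert storage_threshold([a, b], 7.0) == pytest.approx(11.5)


class TestStorageTrendProperties:
    @given(
        slope=st.floats(0.05, 2.0),
        intercept=st.floats(0.5, 2.0),
        cross_at=st.floats(1.5, 11.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_exact_linear_input_solves_crossing_exactly(self, slope, intercept, cross_at):
        weeks = np.arange(1.0, 9.0)
        values = intercept + slope * weeks
        threshold = intercept + slope * cross_at
        s = storage_trend(weeks, values, normalizer=1.0, threshold=threshold)
        assert s.slope == pytest.approx(slope, rel=1e-9)
        assert s.crossing_week == pytest.approx(cross_at, rel=1e-6)
        assert s.fitted(s.crossing_week) == pytest.approx(threshold, rel=1e-9)


class TestVelocityBinning:
    @given(st.floats(0.0001, 10.0))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_half_open_membership(self, v):
        from rbcflow.stats import VELOCITY_EDGES

        b = int(velocity_bin_index(np.array([v]))[0])
        assert 0 <= b < len(VELOCITY_EDGES) - 1
        assert VELOCITY_EDGES[b] < v <= VELOCITY_EDGES[b + 1]


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_groups({"a": g, "b": g.copy()})
        assert res["p"] > 0.9
        assert res["pairs"][("a", "b")]["stars"] == "ns"

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        res = compare_groups(
            {
                "a": 0.0 + rng.normal(0, 1e-3, 4),
                "b": 10.0 + rng.normal(0, 1e-3, 4),
            }
        )
        assert res["p"] < 1e-3
        assert res["pairs"][("a", "b")]["stars"] == "**"

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            compare_groups({"a": np.zeros(4), "b": np.zeros(4)})


class TestPermutationInvariance:
    def test_statistics_invariant_under_track_order(self):
        cfg = FlowPopulationConfig(fraction_pathological=0.1)
        df = sample_tracks(cfg, n=500, rng=9)
        perm = df.sample(frac=1.0, random_state=1)
        r1 = shape_ratio(df.true_class, df.true_velocity_mm_s)
        r2 = shape_ratio(perm.true_class, perm.true_velocity_mm_s)
        assert r1 == r2
        d1 = binned_lateral_pdfs(df.true_velocity_mm_s, df.true_offset_yW)
        d2 = binned_lateral_pdfs(perm.true_velocity_mm_s, perm.true_offset_yW)
        for b in d1:
            assert np.allclose(d1[b].pdf, d2[b].pdf)
        p1 = phase_diagram(df.true_class, df.true_velocity_mm_s)
        p2 = phase_diagram(perm.true_class, perm.true_velocity_mm_s)
        assert np.allclose(p1.fractions, p2.fractions, equal_nan=True)
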