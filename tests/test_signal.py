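import numpy as np
import pandas as pd
import pytest

from orsmoke import signal as sig
from orsmoke.errors import CalibrationError, ProcessingError, ValidationError
from orsmoke.synth import SimConfig, simulate_operation


def make_series(values, channels=("a",), op_id="op0", segments=None):
    """Small series on a 1 s grid; default: 10 s blank, 10 s calib, 30 s op."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and len(channels) > 1:
        values = np.repeat(values, len(channels), axis=0)
    n = values.shape[1]
    data = pd.DataFrame(values.T, columns=list(channels),
                        index=pd.Index(np.arange(n, dtype=float), name="time_s"))
    segments = segments or {"blank_pre": (0.0, 10.0), "calib": (10.0, 20.0),
                            "operation": (20.0, float(n))}
    return sig.IonTimeSeries(op_id=op_id, data=data, segments=segments)


class TestSubtractBlank:
    def test_constant_series_becomes_zero(self):
        series = make_series(np.full(50, 5.0))
        out = sig.subtract_blank(series)
        assert np.allclose(out.data.to_numpy(), 0.0)
        assert out.segments == series.segments

    def test_zero_blank_is_identity(self):
        values = np.concatenate([np.zeros(20), np.random.default_rng(0).normal(3, 1, 30)])
        series = make_series(values)
        out = sig.subtract_blank(series)
        pd.testing.assert_frame_equal(out.data, series.data)

    def test_missing_blank_names_operation(self):
        series = make_series(np.ones(30), op_id="op-x",
                             segments={"operation": (0.0, 30.0)})
        with pytest.raises(ProcessingError, match="op-x"):
            sig.subtract_blank(series)

    def test_simulated_blank_post_mean_near_zero(self, short_design):
        # background removal: post-operation blank should centre on zero
        residuals = []
        for seed in range(100):
            cfg = SimConfig(seed=seed, background_ppb=3.0, noise_sd_ppb=0.1)
            series, _ = simulate_operation(short_design(duration=120.0), cfg, ["a"])
            out = sig.subtract_blank(series)
            residuals.append(out.segment("blank_post")["a"].mean())
        residuals = np.array(residuals)
        se = residuals.std(ddof=1) / np.sqrt(residuals.size)
        assert abs(residuals.mean()) < 3 * se


class TestCalibrate:
    def test_matching_calib_mean_is_identity(self):
        values = np.concatenate([np.zeros(10), np.full(10, 50.0), np.ones(30)])
        series = make_series(values)
        out = sig.calibrate(series, {"a": 50.0})
        pd.testing.assert_frame_equal(out.data, series.data)

    def test_half_sensitivity_doubles_samples(self):
        values = np.concatenate([np.zeros(10), np.full(10, 25.0), np.ones(30)])
        series = make_series(values)
        out = sig.calibrate(series, {"a": 50.0})
        assert np.allclose(out.data.to_numpy(), 2.0 * series.data.to_numpy())

    def test_channel_without_standard_flagged_untouched(self):
        series = make_series(np.ones(30), channels=("a", "b"),
                             segments={"blank_pre": (0.0, 5.0), "calib": (5.0, 10.0),
                                       "operation": (10.0, 30.0)})
        out = sig.calibrate(series, {"a": 1.0})
        assert out.uncalibrated_channels == frozenset({"b"})
        pd.testing.assert_series_equal(out.data["b"], series.data["b"])

    def test_nonpositive_calib_mean_is_an_error(self):
        values = np.concatenate([np.zeros(20), np.ones(30)])
        series = make_series(values)
        with pytest.raises(CalibrationError):
            sig.calibrate(series, {"a": 50.0})

    def test_recovers_inverse_sensitivity_from_simulation(self, short_design):
        # instrument sensitivity 0.8 -> calibration factor 1/0.8 within 2 %
        factors = []
        for seed in range(30):
            cfg = SimConfig(seed=seed, calib_true_factor=0.8, calib_standard_ppb=100.0,
                            background_ppb=0.0, noise_sd_ppb=0.2)
            series, _ = simulate_operation(short_design(duration=120.0), cfg, ["a"])
            calib_mean = series.segment("calib")["a"].mean()
            factors.append(100.0 / calib_mean)
        assert np.mean(factors) == pytest.approx(1.0 / 0.8, rel=0.02)


class TestTotalVoc:
    def test_single_channel_subset_is_identity(self):
        series = make_series(np.arange(30.0), channels=("a", "b"))
        out = sig.total_voc(series, ["a"], name="a")
        pd.testing.assert_frame_equal(out.data, series.data[["a"]])

    def test_sum_matches_elementwise_addition(self):
        rng = np.random.default_rng(4)
        series = make_series(rng.normal(size=(2, 40)), channels=("c1", "c2"))
        out = sig.total_voc(series, ["c1", "c2"])
        assert np.allclose(out.data["total_voc"], series.data["c1"] + series.data["c2"])

    def test_unknown_channel_is_lookup_error(self):
        series = make_series(np.ones(30))
        with pytest.raises(KeyError):
            sig.total_voc(series, ["nope"])

    def test_commutes_with_blank_subtraction(self):
        rng = np.random.default_rng(9)
        series = make_series(rng.normal(5, 2, size=(3, 60)), channels=("a", "b", "c"))
        lhs = sig.total_voc(sig.subtract_blank(series), "all")
        rhs = sig.subtract_blank(sig.total_voc(series, "all"))
        assert np.allclose(lhs.data.to_numpy(), rhs.data.to_numpy())


class TestSummarizeOperation:
    def test_constant_channel_earliest_tie(self, short_design):
        series = make_series(np.full(40, 7.0))
        summary = sig.summarize_operation(series, short_design())
        row = summary.channel_stats.loc["a"]
        assert row["mean_ppb"] == row["max_ppb"] == 7.0
        assert row["argmax_time_fraction"] == 0.0

    def test_linear_ramp_argmax_at_end(self, short_design):
        series = make_series(np.arange(100.0))
        summary = sig.summarize_operation(series, short_design())
        frac = summary.channel_stats.loc["a", "argmax_time_fraction"]
        assert frac == pytest.approx(1.0, abs=2.0 / 80.0)

    def test_simulated_event_at_quarter_of_segment(self, short_design):
        design = short_design(duration=400.0)
        cfg = SimConfig(noise_sd_ppb=0.0, background_ppb=0.0)
        t0 = design.operation_start + 0.25 * design.duration
        series, _ = simulate_operation(
            design, cfg, ["a"],
            event_times_override=np.array([t0]), amplitudes_override={"a": [50.0]},
        )
        summary = sig.summarize_operation(series, design)
        frac = summary.channel_stats.loc["a", "argmax_time_fraction"]
        assert frac == pytest.approx(0.25, abs=1.0 / design.duration)

    def test_channel_order_invariance(self, short_design):
        rng = np.random.default_rng(2)
        series = make_series(rng.normal(5, 2, size=(3, 60)), channels=("a", "b", "c"))
        permuted = sig.IonTimeSeries(
            op_id=series.op_id, data=series.data[["c", "a", "b"]], segments=series.segments
        )
        s1 = sig.summarize_operation(series, short_design())
        s2 = sig.summarize_operation(permuted, short_design())
        pd.testing.assert_frame_equal(
            s1.channel_stats.sort_index(), s2.channel_stats.sort_index()
        )
        assert s1.total_voc_mean_ppb == pytest.approx(s2.total_voc_mean_ppb)

    def test_max_of_sum_at_most_sum_of_maxima(self, short_design):
        rng = np.random.default_rng(21)
        series = make_series(rng.normal(0, 3, size=(4, 80)), channels=list("abcd"))
        summary = sig.summarize_operation(series, short_design())
        assert summary.harmful_total_max_ppb <= summary.channel_stats["max_ppb"].sum() + 1e-9

    def test_statistics_exclude_blank_and_calib(self, short_design):
        values = np.concatenate([np.full(10, 100.0), np.full(10, 100.0), np.ones(30)])
        series = make_series(values)
        summary = sig.summarize_operation(series, short_design())
        assert summary.channel_stats.loc["a", "max_ppb"] == 1.0

    def test_harmful_subset_of_total(self, registry, short_design):
        rng = np.random.default_rng(5)
        series = make_series(
            np.abs(rng.normal(5, 2, size=(3, 60))), channels=("Benzene", "Toluene", "m57")
        )
        summary = sig.summarize_operation(series, short_design(), registry)
        assert summary.harmful_total_mean_ppb <= summary.total_voc_mean_ppb + 1e-9
        assert summary.harmful_total_max_ppb <= summary.total_voc_max_ppb + 1e-9


class TestSeriesIO:
    def test_round_trip(self, tmp_path, short_design):
        cfg = SimConfig(seed=3)
        design = short_design(duration=60.0)
        series, _ = simulate_operation(design, cfg, ["a", "b"])
        path = tmp_path / "op0.csv"
        sig.write_series(series, path, design=design)
        loaded, loaded_design = sig.read_series(path)
        pd.testing.assert_frame_equal(
            loaded.data, series.data, check_names=False, check_freq=False
        )
        assert loaded.segments == series.segments
        assert loaded_design == design

    def test_summaries_round_trip(self, tmp_path, registry, short_design):
        cfg = SimConfig(seed=8)
        summaries = []
        for i in range(3):
            design = short_design(op_id=f"op{i}", duration=90.0)
            series, _ = simulate_operation(design, cfg, ["Benzene", "Toluene"])
            summaries.append(sig.summarize_operation(series, design, registry))
        totals = tmp_path / "totals.csv"
        channels = tmp_path / "channels.csv"
        sig.write_summaries(summaries, totals, channels)
        loaded = sig.read_summaries(totals, channels)
        assert [s.op_id for s in loaded] == [s.op_id for s in summaries]
        for a, b in zip(loaded, summaries):
            assert a.design == b.design
            assert a.harmful_total_mean_ppb == pytest.approx(b.harmful_total_mean_ppb)
            pd.testing.assert_frame_equal(
                a.channel_stats, b.channel_stats, check_names=False
            )


def test_invalid_series_rejected():
    data = pd.DataFrame({"a": [1.0, 2.0]}, index=pd.Index([0.0, 0.0], name="time_s"))
    with pytest.raises(ValidationError):
        sig.IonTimeSeries(op_id="x", data=data, segments={"operation": (0.0, 2.0)})
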