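"""Partial correlation, streaming feedback, and thermometer mapping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fcnf.fc import (
    DegenerateWindowError,
    FeedbackConfig,
    displayed_segment,
    fc_to_thermometer,
    partial_correlation,
    stream_fc,
    windowed_partial_correlation,
)
from fcnf.schedule import build_run_schedule


def closed_form_partial(x, y, c):
    """Independent oracle: (r_xy − r_xc·r_yc)/sqrt((1−r_xc²)(1−r_yc²))."""

    def r(a, b):
        a = np.asarray(a, float) - np.mean(a)
        b = np.asarray(b, float) - np.mean(b)
        return (a @ b) / np.sqrt((a @ a) * (b @ b))

    rxy, rxc, ryc = r(x, y), r(x, c), r(y, c)
    return (rxy - rxc * ryc) / np.sqrt((1 - rxc**2) * (1 - ryc**2))


class TestPartialCorrelation:
    def test_identical_series_give_unity(self):
        assert partial_correlation([1, 2, 3, 4, 6], [1, 2, 3, 4, 6], [1, 1, 2, 2, 3]) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_unity(self):
        x = np.array([1, 2, 3, 4, 6.0])
        assert partial_correlation(x, -x, [1, 1, 2, 2, 3]) == pytest.approx(-1.0)

    def test_matches_closed_form_on_worked_example(self):
        x, y, c = [1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5], [1, 3, 2, 5, 4, 6]
        expected = 0.9817025841567109  # frozen from the closed-form oracle
        assert closed_form_partial(x, y, c) == pytest.approx(expected, abs=1e-12)
        assert partial_correlation(x, y, c) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateWindowError, match="degenerate window"):
            partial_correlation([1, 1, 1, 1], [1, 2, 3, 4], [2, 3, 1, 4])

    def test_short_window_rejected(self):
        with pytest.raises(DegenerateWindowError, match="window too short"):
            partial_correlation([1, 2], [3, 4], [5, 6])

    @given(st.integers(0, 10_000))
    def test_closed_form_and_residualization_agree(self, seed):
        rng = np.random.default_rng(seed)
        x, y, c = rng.standard_normal((3, 20))
        assert partial_correlation(x, y, c) == pytest.approx(
            closed_form_partial(x, y, c), abs=1e-12
        )

    @given(
        st.integers(0, 1000),
        st.floats(0.1, 5.0),
        st.floats(-10, 10),
        st.floats(0.1, 5.0),
        st.floats(-10, 10),
    )
    def test_affine_invariance(self, seed, a1, b1, a2, b2):
        rng = np.random.default_rng(seed)
        x, y, c = rng.standard_normal((3, 20))
        base = partial_correlation(x, y, c)
        scaled = partial_correlation(a1 * x + b1, a2 * y + b2, 0.5 * c - 2.0)
        assert scaled == pytest.approx(base, abs=1e-10)

    @given(st.integers(0, 1000))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        x, y, c = rng.standard_normal((3, 8))
        assert -1.0 <= partial_correlation(x, y, c) <= 1.0


class TestStreaming:
    def test_defined_position_count(self, exp12_schedule, weighted_config, rng):
        import pandas as pd

        n = 60
        sched = build_run_schedule(20, 1, 20, 20, "fcnf")
        samples = pd.DataFrame(rng.standard_normal((n, 3)), columns=["pfc", "amy", "cst"])
        stream = stream_fc(samples, sched, weighted_config)
        defined = stream.defined()
        assert len(defined) == 41
        assert defined["volume"].min() == 20 and defined["volume"].max() == 60

    def test_streaming_matches_batch_recomputation(self, exp12_schedule, weighted_config, rng):
        import pandas as pd

        samples = pd.DataFrame(
            rng.standard_normal((exp12_schedule.n_volumes, 3)),
            columns=["pfc", "amy", "cst"],
        )
        stream = stream_fc(samples, exp12_schedule, weighted_config)
        for t in range(20, exp12_schedule.n_volumes + 1):
            win = samples.iloc[t - 20 : t]
            expected = partial_correlation(win["pfc"], win["amy"], win["cst"])
            assert stream.table["r_p"].iloc[t - 1] == pytest.approx(expected, abs=1e-10)

    def test_flat_segment_flags_exactly_affected_windows(self, weighted_config, rng):
        import pandas as pd

        sched = build_run_schedule(20, 2, 20, 20, "fcnf")
        samples = pd.DataFrame(
            rng.standard_normal((sched.n_volumes, 3)), columns=["pfc", "amy", "cst"]
        )
        # a short plateau never fills a whole window: nothing undefined
        samples.loc[39:43, "pfc"] = 5.0
        rp = stream_fc(samples, sched, weighted_config).table["r_p"].to_numpy()
        assert np.isfinite(rp[19:]).all()
        # a 20-volume plateau makes exactly the one fully-flat window undefined
        samples.loc[70:89, "pfc"] = 5.0  # rows 70..89 -> volumes 71..90
        rp = stream_fc(samples, sched, weighted_config).table["r_p"].to_numpy()
        assert not np.isfinite(rp[89])  # window 71..90 is constant in pfc
        assert np.isfinite(rp[88]) and np.isfinite(rp[90])

    def test_length_mismatch_rejected(self, exp12_schedule, weighted_config, rng):
        import pandas as pd

        samples = pd.DataFrame(rng.standard_normal((10, 3)), columns=["pfc", "amy", "cst"])
        with pytest.raises(ValueError, match="does not match schedule"):
            stream_fc(samples, exp12_schedule, weighted_config)

    def test_windowed_vectorized_matches_scalar(self, rng):
        x, y, c = rng.standard_normal((3, 120))
        out = windowed_partial_correlation(x, y, c, 20)
        assert np.isnan(out[:19]).all()
        for t in range(20, 121):
            expected = partial_correlation(x[t - 20 : t], y[t - 20 : t], c[t - 20 : t])
            assert out[t - 1] == pytest.approx(expected, abs=1e-10)


class TestThermometer:
    @pytest.mark.parametrize(
        "implementation, width",
        [("negative", 0.1), ("weighted_negative", 0.03), ("positive", 0.1)],
    )
    def test_segment_boundary_spacing(self, implementation, width):
        cfg = FeedbackConfig(implementation)
        assert cfg.segment_width == pytest.approx(width)
        # boundary spacing measured from the mapping itself: the r values at
        # which the displayed segment increments are exactly `width` apart
        sign = 1.0 if cfg.upper_bound > 0 else -1.0
        boundaries = []
        grid = np.arange(0.0, 1.0 + 1e-12, 1e-4) * cfg.upper_bound
        segs = fc_to_thermometer(grid, cfg)
        jumps = np.flatnonzero(np.diff(segs) != 0)
        boundaries = sign * np.diff(grid[jumps])
        assert np.allclose(np.abs(boundaries), width, atol=1e-3)

    def test_zero_maps_to_empty_thermometer(self):
        for impl in ("negative", "weighted_negative", "positive"):
            assert fc_to_thermometer(0.0, FeedbackConfig(impl)) == 0

    def test_quantization_examples(self):
        assert fc_to_thermometer(-0.15, FeedbackConfig("weighted_negative")) == 5
        assert fc_to_thermometer(-0.2, FeedbackConfig("positive")) == 0  # clamped

    def test_upper_bound_fills_thermometer(self):
        for impl in ("negative", "weighted_negative", "positive"):
            cfg = FeedbackConfig(impl)
            assert fc_to_thermometer(cfg.upper_bound, cfg) == cfg.n_segments

    @given(st.floats(-1, 1), st.floats(-1, 1))
    def test_monotone_toward_upper_bound(self, r1, r2):
        cfg = FeedbackConfig("weighted_negative")
        # monotone in the normalized coordinate running from lower to upper bound
        t1 = (r1 - cfg.lower_bound) / (cfg.upper_bound - cfg.lower_bound)
        t2 = (r2 - cfg.lower_bound) / (cfg.upper_bound - cfg.lower_bound)
        if t1 >= t2:
            assert fc_to_thermometer(r1, cfg) >= fc_to_thermometer(r2, cfg)
        else:
            assert fc_to_thermometer(r1, cfg) <= fc_to_thermometer(r2, cfg)


class TestDisplayedSegment:
    def test_nonf_frozen_at_six(self, weighted_config):
        assert displayed_segment("nonf", 0.73, weighted_config) == 6
        assert displayed_segment("nonf", None, weighted_config) == 6

    def test_fcnf_at_upper_bound_saturates(self, weighted_config):
        assert displayed_segment("fcnf", weighted_config.upper_bound, weighted_config) == 10

    def test_fixation_displays_nothing(self, weighted_config):
        assert displayed_segment("fixation", -0.1, weighted_config) is None

    def test_undefined_fc_falls_back_to_frozen(self, weighted_config):
        assert displayed_segment("fcnf", float("nan"), weighted_config) == 6

    def test_unknown_condition_rejected(self, weighted_config):
        with pytest.raises(ValueError, match="unknown condition"):
            displayed_segment("rest", 0.0, weighted_config)


def test_feedback_config_validation():
    with pytest.raises(ValueError):
        FeedbackConfig("weighted_negative", upper_bound=0.0)
    with pytest.raises(ValueError):
        FeedbackConfig("negative", frozen_segment=11)
    with pytest.raises(ValueError):
        FeedbackConfig("sigmoid")
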