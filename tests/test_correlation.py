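"""Standard and time-delayed correlation networks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vmibench.correlation import (CorrelationNetwork, delayed_correlation,
                                  load_correlation, save_correlation,
                                  standard_correlation)
from vmibench.dynamics import SampleSet


def make_samples(h_rows, v_rows, frequency=2.0):
    h = np.atleast_2d(np.asarray(h_rows, dtype=float))
    v = np.atleast_2d(np.asarray(v_rows, dtype=float))
    S = h.shape[1]
    t = frequency * np.arange(1, S + 1)
    return SampleSet(t=t, h=h, v=v, frequency=frequency,
                     duration=frequency * S)


class TestStandardCorrelation:
    def test_identical_series(self):
        x = np.sin(np.arange(20))
        R = standard_correlation(make_samples(x, x))
        assert R.R[0, 0] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.sin(np.arange(20))
        R = standard_correlation(make_samples(x, -x + 5.0))
        assert R.R[0, 0] == pytest.approx(-1.0)

    def test_hand_computed_three_points(self):
        samples = make_samples([1.0, 2.0, 4.0], [1.0, 3.0, 5.0])
        # direct evaluation: r = 6 / sqrt((14/3) * 8) = 3*sqrt(21)/14
        assert standard_correlation(samples, "pearson").R[0, 0] == \
            pytest.approx(3 * np.sqrt(21) / 14)
        assert standard_correlation(samples, "spearman").R[0, 0] == \
            pytest.approx(1.0)
        assert standard_correlation(samples, "kendall").R[0, 0] == \
            pytest.approx(1.0)

    def test_constant_series_yields_zero_with_warning(self):
        samples = make_samples(np.ones(10), np.arange(10.0))
        with pytest.warns(UserWarning):
            R = standard_correlation(samples)
        assert R.R[0, 0] == 0.0

    def test_matrix_shape(self, samples10):
        R = standard_correlation(samples10)
        assert R.R.shape == (10, 10)
        assert np.abs(R.R).max() <= 1.0

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pearson_affine_invariance(self, a, b):
        x = np.sin(0.7 * np.arange(15))
        y = np.cos(0.7 * np.arange(15))
        base = standard_correlation(make_samples(x, y)).R[0, 0]
        scaled = standard_correlation(make_samples(x, a * y + b)).R[0, 0]
        flipped = standard_correlation(make_samples(x, -a * y + b)).R[0, 0]
        assert scaled == pytest.approx(base, abs=1e-10)
        assert flipped == pytest.approx(-base, abs=1e-10)

    def test_rank_metrics_monotone_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        for metric in ("spearman", "kendall"):
            base = standard_correlation(make_samples(x, y), metric).R[0, 0]
            warped = standard_correlation(
                make_samples(np.exp(x), y ** 3), metric).R[0, 0]
            assert warped == pytest.approx(base, abs=1e-12)


class TestDelayedCorrelation:
    def test_recovers_constructed_shift(self):
        t_all = 2.0 * np.arange(1, 161)
        S = 100
        # ramp envelope keeps the optimum unique (no periodic aliases; an
        # exponential envelope would be shift-proportional, hence invisible
        # to Pearson correlation)
        wave = lambda t: np.sin(2 * np.pi * t / 50.0) * (1.0 + t / 100.0)
        host = wave(t_all[:S])
        virus = wave(t_all - 10.0)           # lags the host by 10 h
        samples = make_samples(host, virus[:S])
        extended = make_samples(host, virus)
        R = delayed_correlation(samples, extended, max_delay=100.0)
        assert R.delays[0, 0] == pytest.approx(10.0)
        assert R.R[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_zero_max_delay_equals_standard(self, samples10, sim10):
        from vmibench.dynamics import sample
        extended = sample(sim10, 2.0, 300.0)
        R0 = delayed_correlation(samples10, extended, max_delay=0.0)
        Rs = standard_correlation(samples10)
        assert np.allclose(R0.R, Rs.R)

    def test_quarter_period_sinusoid(self):
        period = 40.0
        t_all = 2.0 * np.arange(1, 161)
        host = np.sin(2 * np.pi * t_all / period)
        virus = np.sin(2 * np.pi * (t_all - period / 4) / period)
        S = 100
        samples = make_samples(host[:S], virus[:S])
        extended = make_samples(host[:S], virus)
        R = delayed_correlation(samples, extended, max_delay=100.0)
        assert abs(R.delays[0, 0] - period / 4) <= 2.0
        R0 = standard_correlation(samples)
        assert abs(R.R[0, 0]) > abs(R0.R[0, 0])

    def test_delayed_never_worse_than_standard(self, samples10, sim10):
        from vmibench.dynamics import sample
        extended = sample(sim10, 2.0, 300.0)
        Rd = delayed_correlation(samples10, extended, max_delay=100.0)
        Rs = standard_correlation(samples10)
        assert (np.abs(Rd.R) >= np.abs(Rs.R) - 1e-12).all()

    def test_short_extended_rejected(self, samples10):
        with pytest.raises(ValueError):
            delayed_correlation(samples10, samples10, max_delay=100.0)


def test_correlation_roundtrip(tmp_path, samples10):
    R = standard_correlation(samples10)
    path = tmp_path / "corr.csv"
    save_correlation(R, path)
    back = load_correlation(path)
    assert np.allclose(back.R, R.R)
    assert back.method == "pearson"
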