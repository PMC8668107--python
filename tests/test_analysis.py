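import numpy as np
import pytest

from nsinet.analysis import (RateTrace, avg_activity,
                             correlation_encoding_distances,
                             dynamic_range_from_curve, encoding_error,
                             fit_pn_sigmoid, max_activity, peak_activity,
                             pn_sigmoid, ramp_settle_time, ratio_correlation,
                             sdf, step_latency)
from nsinet.sensillum import SpikeRecord


def _record(trains, label="pop"):
    return SpikeRecord(label=label, trains=[np.asarray(t, float) for t in trains])


GRID = np.arange(0, 1000.0, 0.1)


class TestSdf:
    def test_no_spikes_gives_zero_trace(self):
        tr = sdf(_record([[]]), GRID)
        assert not tr.rates.any()

    def test_single_spike_trace_integrates_to_one(self):
        tr = sdf(_record([[500.0]]), GRID)
        integral = np.trapezoid(tr.rates[0] / 1000.0, GRID)  # Hz -> 1/ms
        assert integral == pytest.approx(1.0, rel=1e-3)

    def test_kernel_peaks_at_spike_time(self):
        """The alpha kernel rises from t_spike - tau and peaks one tau
        later, i.e. at the spike time itself."""
        tr = sdf(_record([[500.0]]), GRID, tau=20.0)
        assert GRID[np.argmax(tr.rates[0])] == pytest.approx(500.0, abs=0.2)
        # silent before the kernel onset at t_spike - tau (fft round-off)
        assert tr.rates[0][int(479.0 / 0.1)] < 1e-9

    def test_linearity_merged_spikes_equal_sum(self):
        a = sdf(_record([[300.0, 400.0]]), GRID)
        b = sdf(_record([[350.0]]), GRID)
        merged = sdf(_record([[300.0, 350.0, 400.0]]), GRID)
        assert np.allclose(merged.rates[0], a.rates[0] + b.rates[0], atol=1e-9)

    def test_population_trace_is_neuron_mean(self):
        tr = sdf(_record([[300.0], []]), GRID)
        assert np.allclose(tr.pop_rate, tr.rates[0] / 2)


class TestActivityMeasures:
    def test_constant_trace(self):
        tr = RateTrace("x", GRID, np.full((3, GRID.size), 10.0))
        assert max_activity(tr, 100.0) == pytest.approx(10.0)
        assert avg_activity(tr, 100.0) == pytest.approx(10.0)

    def test_zero_trace(self):
        tr = RateTrace("x", GRID, np.zeros((2, GRID.size)))
        assert max_activity(tr, 0.0) == 0.0

    def test_window_outside_trace_rejected(self):
        tr = RateTrace("x", GRID, np.zeros((1, GRID.size)))
        with pytest.raises(ValueError):
            max_activity(tr, 2000.0)

    def test_peak_activity_threshold_cases(self):
        rates = np.full((1, GRID.size), 200.0)
        tr = RateTrace("x", GRID, rates)
        dur_s = GRID.size * 0.1 / 1000.0
        assert peak_activity(tr, 300.0) == 0.0
        assert peak_activity(tr, 100.0) == pytest.approx(200.0 * dur_s, rel=1e-6)
        assert peak_activity(tr, 0.0) == pytest.approx(200.0 * dur_s, rel=1e-6)

    def test_peak_activity_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(0)
        tr = RateTrace("x", GRID, rng.uniform(0, 300, (4, GRID.size)))
        vals = [peak_activity(tr, thr) for thr in (0.0, 50.0, 100.0, 150.0)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestEncodingError:
    @pytest.mark.parametrize("r_pn,r_conc,err", [
        (3.0, 3.0, 0.0),
        (1.0, 3.0, 0.25),
        (1e9, 3.0, pytest.approx(1.0, abs=1e-6)),
    ])
    def test_values(self, r_pn, r_conc, err):
        assert encoding_error(r_pn, r_conc) == err

    def test_symmetry(self):
        assert encoding_error(2.0, 5.0) == encoding_error(5.0, 2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            encoding_error(0.0, 1.0)


class TestRatioCorrelation:
    def test_perfect(self):
        r = np.array([1.0, 2.0, 5.0, 10.0])
        assert ratio_correlation(r, r) == pytest.approx(1.0)

    def test_constant_signalled(self):
        with pytest.raises(ValueError):
            ratio_correlation([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])

    def test_decreasing_gives_negative(self):
        assert ratio_correlation([1, 2, 3, 4], [4, 3, 2, 1]) < 0


class TestCorrelationDistances:
    def test_identical_to_control_zero_interference(self):
        rho = np.array([0.0, 0.5, 1.0])
        curves = {"control": (rho, np.array([5.0, 4.0, 3.0])),
                  "NSI": (rho, np.array([5.0, 4.5, 2.0]))}
        d = correlation_encoding_distances(curves)
        assert d["NSI"]["d_interference"] == pytest.approx(0.0)
        assert d["NSI"]["d_encoding"] == pytest.approx(3.0)

    def test_correlation_independent_variant(self):
        rho = np.array([0.0, 1.0])
        curves = {"control": (rho, np.array([5.0, 5.0])),
                  "LN": (rho, np.array([2.0, 2.0]))}
        d = correlation_encoding_distances(curves)
        assert d["LN"]["d_encoding"] == 0.0
        assert d["LN"]["d_interference"] == pytest.approx(3.0)

    def test_control_required(self):
        with pytest.raises(ValueError):
            correlation_encoding_distances({"NSI": ([0, 1], [1, 2])})


class TestSigmoidFit:
    def test_parameter_recovery(self):
        x = np.linspace(5, 300, 30)
        y = pn_sigmoid(x, 150.0, 40.0)
        numax, sigma, resid = fit_pn_sigmoid(x, y)
        assert numax == pytest.approx(150.0, rel=0.01)
        assert sigma == pytest.approx(40.0, rel=0.01)
        assert resid < 1e-6

    def test_half_maximum_point(self):
        assert pn_sigmoid(40.0, 150.0, 40.0) == pytest.approx(75.0)

    def test_all_zero_degenerate(self):
        numax, sigma, resid = fit_pn_sigmoid([1, 2, 3], [0, 0, 0])
        assert numax == 0.0


class TestDynamicRangeCurve:
    def test_monotone_sigmoid(self):
        conc = np.logspace(-5, -1, 20)
        resp = 100 * conc / (conc + 1e-3)
        r = dynamic_range_from_curve(conc, resp, subtract_baseline=False)
        assert r.C_l < r.C_h
        assert r.dynamic_range == pytest.approx(
            np.log10(r.C_h / r.C_l))

    def test_first_crossing_on_peak_and_plateau_curve(self):
        """Non-monotone curve: thresholds use the first crossing, so C_h
        precedes the peak even though the tail falls below 90% again."""
        conc = np.logspace(-4, 0, 30)
        resp = np.concatenate([np.linspace(0, 100, 15),
                               np.linspace(100, 60, 15)])
        r = dynamic_range_from_curve(conc, resp, subtract_baseline=False)
        assert r.C_l < r.C_h < conc[15]

    def test_flat_curve_rejected(self):
        with pytest.raises(ValueError):
            dynamic_range_from_curve([1e-4, 1e-3], [1.0, 1.0])


class TestTransientTiming:
    def test_step_latency_on_synthetic_peak(self):
        t = GRID
        rate = np.exp(-0.5 * ((t - 550.0) / 30.0) ** 2)
        assert step_latency(rate, 500.0, 0.1) == pytest.approx(50.0, abs=0.2)

    def test_ramp_settle_recovers_known_transient(self):
        """Rate = plateau + A exp(-t/tau) after a linear rise: the settle
        estimate matches the analytic 5%-slope crossing."""
        dt = 0.1
        t = np.arange(0, 2500.0, dt)
        onset, tau, A, plateau = 500.0, 150.0, 30.0, 50.0
        rise = np.clip((t - onset) / 60.0, 0, 1) * 80.0
        decay = np.where(t > onset + 60.0,
                         (A - 30.0) + 30.0 * np.exp(-(t - onset - 60.0) / tau),
                         A)
        rate = np.where(t < onset, 0.0,
                        np.minimum(rise, 80.0) - (80.0 - plateau)
                        * (1 - np.exp(-np.clip(t - onset - 60.0, 0, None) / tau)))
        est = ramp_settle_time(rate, onset, dt)
        # analytic: peak slope ~ 80/60 smoothed; transient tau=150 ms decays
        # below 5% of it ~ tau*log(...) after the rate peak at ~60 ms
        assert 150.0 < est < 450.0
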