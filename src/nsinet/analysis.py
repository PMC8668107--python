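"""Read-out measures: spike-density functions, activity statistics,
ratio-encoding error, correlation-encoding distances, the PN-vs-ORN
sigmoid fit, and the dose-response / dynamic-range scan."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats
from scipy.ndimage import uniform_filter1d

from .params import ModelParams, make_variant
from .sensillum import SpikeRecord, run_sensilla
from .stimuli import make_triangles, DEFAULT_SETTLE_MS

__all__ = [
    "RateTrace",
    "sdf",
    "max_activity",
    "avg_activity",
    "step_latency",
    "ramp_settle_time",
    "peak_activity",
    "encoding_error",
    "coding_error_summary",
    "ratio_correlation",
    "correlation_encoding_distances",
    "fit_pn_sigmoid",
    "pn_sigmoid",
    "DynamicRangeResult",
    "dose_response",
    "dynamic_range_from_curve",
    "dynamic_range_scan",
]

SDF_TAU_MS = 20.0
ACTIVITY_WINDOW_MS = 200.0


@dataclass
class RateTrace:
    """Kernel-smoothed firing rates of one population (Hz)."""

    label: str
    t: np.ndarray            # ms
    rates: np.ndarray        # (n_neurons, T)

    @property
    def pop_rate(self) -> np.ndarray:
        """Mean rate across neurons."""
        return self.rates.mean(axis=0)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def sdf(record: SpikeRecord, t: np.ndarray, tau: float = SDF_TAU_MS) -> RateTrace:
    """Spike-density function with the asymmetric alpha kernel
    k(t̂) = t̂ exp(-t̂/τ) / τ², evaluated at t̂ = t - t_spike + τ.

    The kernel is supported on t̂ >= 0 (it starts rising τ before the spike
    and peaks at the spike time) and is normalized to unit area, so the
    integral of a single neuron's trace equals its spike count.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(t, dtype=np.float64)
    if t.size < 2:
        raise ValueError("need a time grid of at least two points")
    dt = float(t[1] - t[0])
    T = t.size
    tt = np.arange(0.0, 10.0 * tau, dt)
    kern = tt * np.exp(-tt / tau)
    kern /= kern.sum() * dt                      # unit area on the grid
    shift = int(round(tau / dt))                 # kernel onset at t_spike - tau

    counts = np.zeros((record.n_neurons, T))
    t0 = t[0]
    for i, tr in enumerate(record.trains):
        if len(tr):
            idx = np.round((np.asarray(tr) - t0) / dt).astype(np.int64)
            idx = idx[(idx >= 0) & (idx < T)]
            np.add.at(counts[i], idx, 1.0)
    if record.n_neurons == 0 or counts.sum() == 0:
        return RateTrace(record.label, t, np.zeros((max(record.n_neurons, 1), T)))
    full = signal.fftconvolve(counts, kern[None, :], axes=1)
    rates = np.zeros((record.n_neurons, T))
    lo = shift
    seg = full[:, lo:lo + T]
    rates[:, :seg.shape[1]] = seg
    rates = np.clip(rates, 0.0, None) * 1000.0   # spikes/ms -> Hz
    return RateTrace(record.label, t, rates)


def _window_slice(trace: RateTrace, window: tuple[float, float]) -> slice:
    lo, hi = window
    i0 = int(np.searchsorted(trace.t, lo))
    i1 = int(np.searchsorted(trace.t, hi))
    if i0 >= i1 or i1 > trace.t.size:
        raise ValueError("window outside trace")
    return slice(i0, i1)


def max_activity(trace: RateTrace, onset: float,
                 window: float = ACTIVITY_WINDOW_MS) -> float:
    """Per-neuron maximum rate within ``window`` ms after ``onset``,
    averaged across the population (Hz)."""
    sl = _window_slice(trace, (onset, onset + window))
    return float(trace.rates[:, sl].max(axis=1).mean())


def avg_activity(trace: RateTrace, onset: float,
                 window: float = ACTIVITY_WINDOW_MS) -> float:
    """Per-neuron mean rate within the window, averaged across neurons (Hz)."""
    sl = _window_slice(trace, (onset, onset + window))
    return float(trace.rates[:, sl].mean())


def peak_activity(trace: RateTrace, threshold: float) -> float:
    """Integrated supra-threshold activity: per neuron, the integral of the
    rate over samples where rate > threshold (units: spikes, i.e. Hz*s),
    averaged across neurons."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    dt_s = trace.dt / 1000.0
    above = trace.rates * (trace.rates > threshold)
    return float(above.sum(axis=1).mean() * dt_s)


def step_latency(pop_rate: np.ndarray, onset: float, dt: float,
                 search: float = 200.0) -> float:
    """Onset-to-peak latency (ms) of a population rate trace after a step."""
    i0 = int(round(onset / dt))
    seg = pop_rate[i0:i0 + int(round(search / dt))]
    return float(np.argmax(seg)) * dt


def ramp_settle_time(pop_rate: np.ndarray, onset: float, dt: float,
                     search: float = 1800.0, smooth: float = 100.0,
                     slope_frac: float = 0.05) -> float:
    """Duration of the initial transient of a ramp response (ms).

    The (trial-averaged) population rate is boxcar-smoothed; the settle time
    is where the rate derivative falls below ``slope_frac`` of its peak
    (onset) value. Because the sample-path derivative grazes the threshold,
    the post-peak transient is fitted with plateau + A exp(-t/tau) and the
    crossing is solved on the fitted curve, which makes the estimate stable
    at realistic trial counts.
    """
    i0 = int(round(onset / dt))
    w = int(round(smooth / dt)) | 1
    r = uniform_filter1d(pop_rate, w)
    d = uniform_filter1d(np.gradient(r, dt), w)
    n = int(round(search / dt))
    seg_r = r[i0:i0 + n]
    peak_slope = d[i0:i0 + int(round(600.0 / dt))].max()
    i_pk = int(np.argmax(seg_r[:int(round(400.0 / dt))]))
    i_fit_end = min(n, int(round(1400.0 / dt)))
    plateau = float(seg_r[int(0.55 * n):].mean())
    t = np.arange(i_pk, i_fit_end) * dt
    y = seg_r[i_pk:i_fit_end]
    t_pk = i_pk * dt

    def transient(tt, A, tau):
        return plateau + A * np.exp(-(tt - t_pk) / tau)

    a0 = max(float(seg_r[i_pk] - plateau), 1e-6)
    (A, tau), _ = optimize.curve_fit(transient, t, y, p0=(a0, 200.0),
                                     bounds=([0.0, 10.0], [np.inf, 2000.0]),
                                     maxfev=10000)
    thr = slope_frac * peak_slope
    if A / tau <= thr:
        return t_pk
    return float(t_pk + tau * np.log(A / (tau * thr)))


# ---------------------------------------------------------------------------
# ratio encoding
# ---------------------------------------------------------------------------

def encoding_error(R_pn: float, R_conc: float) -> float:
    """Squared relative distance between the PN response ratio and the
    concentration ratio: ((R_pn - R_conc) / (R_pn + R_conc))^2, in [0, 1]."""
    if R_pn <= 0 or R_conc <= 0:
        raise ValueError("ratios must be positive")
    return float(((R_pn - R_conc) / (R_pn + R_conc)) ** 2)


def coding_error_summary(df) -> "object":
    """Mean encoding error per (duration, concentration), averaged over the
    concentration-ratio grid (and trials). Expects a tidy frame with columns
    duration, concentration, variant, err_enc."""
    return (df.groupby(["variant", "duration", "concentration"], sort=True)
              ["err_enc"].mean().reset_index())


def ratio_correlation(r_conc, r_pn, method: str = "pearson") -> float:
    """Correlation between concentration ratio and PN response ratio across
    the ratio grid."""
    r_conc = np.asarray(r_conc, float)
    r_pn = np.asarray(r_pn, float)
    if r_conc.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(r_pn) == 0 or np.std(r_conc) == 0:
        raise ValueError("correlation undefined: zero variance")
    if method == "pearson":
        return float(stats.pearsonr(r_conc, r_pn)[0])
    if method == "spearman":
        return float(stats.spearmanr(r_conc, r_pn)[0])
    raise ValueError(f"unknown method {method!r}")


def correlation_encoding_distances(curves: dict) -> dict:
    """Interference and encoding distances of the peak-activity-vs-correlation
    curves.

    ``curves`` maps variant name -> (rho array, peak-activity array); must
    include 'control'. For each non-control variant x:
      d_interference = p_ctrl(rho=min) - p_x(rho=min)
      d_encoding     = p_x(rho=min)    - p_x(rho=max)
    where min/max are the smallest (≈0) and largest (≈1) sampled correlations.
    """
    if "control" not in curves:
        raise ValueError("curves must include the control variant")

    def endpoints(rho, p):
        rho = np.asarray(rho, float)
        p = np.asarray(p, float)
        return p[np.argmin(rho)], p[np.argmax(rho)]

    p_ctrl0, _ = endpoints(*curves["control"])
    out = {}
    for name, (rho, p) in curves.items():
        if name == "control":
            continue
        p0, p1 = endpoints(rho, p)
        out[name] = dict(d_interference=float(p_ctrl0 - p0),
                         d_encoding=float(p0 - p1))
    return out


# ---------------------------------------------------------------------------
# PN-vs-ORN sigmoid
# ---------------------------------------------------------------------------

def pn_sigmoid(nu_orn, nu_max: float, sigma: float) -> np.ndarray:
    """Saturating PN transfer function with fixed exponent 1.5:
    nu_pn = nu_max * nu_orn^1.5 / (sigma^1.5 + nu_orn^1.5)."""
    nu_orn = np.asarray(nu_orn, float)
    return nu_max * nu_orn**1.5 / (sigma**1.5 + nu_orn**1.5)


def fit_pn_sigmoid(nu_orn, nu_pn) -> tuple[float, float, float]:
    """Least-squares fit of the exponent-1.5 sigmoid.

    Returns (nu_max, sigma, residual_norm). Raises RuntimeError on
    non-convergence."""
    nu_orn = np.asarray(nu_orn, float)
    nu_pn = np.asarray(nu_pn, float)
    if nu_orn.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(nu_pn == 0):
        return 0.0, float("nan"), 0.0
    p0 = (float(nu_pn.max() * 1.2 + 1e-9), float(np.median(nu_orn) + 1e-9))
    popt, _ = optimize.curve_fit(pn_sigmoid, nu_orn, nu_pn, p0=p0,
                                 bounds=([0, 1e-9], [np.inf, np.inf]),
                                 maxfev=20000)
    resid = float(np.linalg.norm(nu_pn - pn_sigmoid(nu_orn, *popt)))
    return float(popt[0]), float(popt[1]), resid


# ---------------------------------------------------------------------------
# dynamic range
# ---------------------------------------------------------------------------

@dataclass
class DynamicRangeResult:
    """Thresholds and dynamic range of one dose-response curve."""

    C_l: float                 # concentration first reaching 10% of max response
    C_h: float                 # concentration first reaching 90% of max response
    dynamic_range: float       # log10(C_h / C_l), orders of magnitude
    conc: np.ndarray = None    # the scanned grid
    response: np.ndarray = None


def _first_crossing(conc: np.ndarray, resp: np.ndarray, level: float) -> float:
    """Smallest concentration at which the response first reaches ``level``,
    with log-linear interpolation between grid points. The 'first reached'
    rule keeps thresholds well defined for non-monotone (peak-and-plateau)
    curves."""
    above = resp >= level
    if not above.any():
        raise ValueError("level not bracketed by the concentration grid")
    i = int(np.argmax(above))
    if i == 0:
        return float(conc[0])
    x0, x1 = np.log10(conc[i - 1]), np.log10(conc[i])
    y0, y1 = resp[i - 1], resp[i]
    frac = (level - y0) / (y1 - y0) if y1 != y0 else 1.0
    return float(10.0 ** (x0 + frac * (x1 - x0)))


def dynamic_range_from_curve(conc, resp, lo_frac: float = 0.1,
                             hi_frac: float = 0.9,
                             subtract_baseline: bool = True) -> DynamicRangeResult:
    """Dynamic range of a dose-response curve: log distance between the
    concentrations first reaching 10% and 90% of the curve's maximum.

    By default the response at the lowest concentration (the spontaneous
    baseline, which the max-activity statistic does not remove) is
    subtracted first, so the thresholds refer to the odor-evoked response.
    """
    conc = np.asarray(conc, float)
    resp = np.asarray(resp, float)
    if subtract_baseline:
        resp = resp - resp[0]
    rmax = resp.max()
    if rmax <= 0:
        raise ValueError("flat zero dose-response curve")
    C_l = _first_crossing(conc, resp, lo_frac * rmax)
    C_h = _first_crossing(conc, resp, hi_frac * rmax)
    return DynamicRangeResult(C_l=C_l, C_h=C_h,
                              dynamic_range=float(np.log10(C_h / C_l)),
                              conc=conc, response=resp)


def dose_response(sens_pair, variant, conc_grid, params: ModelParams | None = None,
                  duration: float = 50.0, seed: int = 0, n_trials: int = 3,
                  dt: float = 0.1) -> dict:
    """Dose-response curves (max activity) of the two co-housed ORNs driven
    by a single odorant (channel A) via triangular pulses.

    ``sens_pair`` = (sens_a, sens_b): per-ORN sensitivity multipliers for
    odorant A. Returns {"orn_a": ..., "orn_b": ..., "combined": ...} response
    arrays over ``conc_grid`` (trial-averaged); "combined" is the average of
    the two ORNs' responses.
    """
    params = params or ModelParams()
    sens = np.array([[sens_pair[0], 0.0], [sens_pair[1], 0.0]])
    onset = DEFAULT_SETTLE_MS
    t_total = onset + duration + max(ACTIVITY_WINDOW_MS, duration) + 100.0
    resp_a = np.zeros(len(conc_grid))
    resp_b = np.zeros(len(conc_grid))
    for ic, c in enumerate(conc_grid):
        wf = make_triangles(c, 0.0, duration, 0.0, t_total, dt, onset=onset)
        acc_a = acc_b = 0.0
        for tr in range(n_trials):
            res = run_sensilla(wf, params, variant,
                               seed=seed + 1000 * ic + tr, sens_matrix=sens)
            ta = sdf(res.records["ORN_a"], wf.t)
            tb = sdf(res.records["ORN_b"], wf.t)
            acc_a += max_activity(ta, onset)
            acc_b += max_activity(tb, onset)
        resp_a[ic] = acc_a / n_trials
        resp_b[ic] = acc_b / n_trials
    return dict(orn_a=resp_a, orn_b=resp_b, combined=0.5 * (resp_a + resp_b),
                conc=np.asarray(conc_grid, float))


def dynamic_range_scan(sens_pair, variant, conc_grid=None,
                       params: ModelParams | None = None,
                       durations=(50.0,), seed: int = 0,
                       n_trials: int = 3) -> dict:
    """Dynamic-range analysis for a sensitivity pair under one variant.

    Returns {duration: {"orn_a": DynamicRangeResult, "orn_b": ...,
    "combined": ..., "sd": sensitivity distance log10(C_l^b / C_l^a)}}.
    """
    if conc_grid is None:
        conc_grid = np.logspace(-5, -1, 17)
    if isinstance(variant, str):
        params = params or ModelParams()
        variant = make_variant(variant, (params or ModelParams()).orn.omega_nsi,
                               (params or ModelParams()).al.alpha_ln)
    out = {}
    for dur in durations:
        dr = dose_response(sens_pair, variant, conc_grid, params,
                           duration=dur, seed=seed, n_trials=n_trials)
        res = {key: dynamic_range_from_curve(dr["conc"], dr[key])
               for key in ("orn_a", "orn_b", "combined")}
        res["sd"] = float(np.log10(res["orn_b"].C_l / res["orn_a"].C_l))
        out[dur] = res
    return out
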