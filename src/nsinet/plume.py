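"""Synthetic naturalistic odor plumes.

Turbulent plumes at a fixed sensor are intermittent: stretches of odor
("whiffs") alternate with clean air ("blanks"). Near-ground open-field
measurements show whiff and blank durations distributed as a power law
with exponent -3/2, and whiff concentrations (normalized by their mean)
following a piecewise CDF

    F(x) = (5/3) x                      for 0 <= x <= 0.3
    F(x) = 1 - 10^-(a1 + b1 x)          otherwise,   a1=0.22, b1=0.26

The two branches disagree by ~0.3% at x = 0.3; the form is implemented
verbatim with the branch switch at F = 0.5.

Pairs of plumes with a controllable inter-odorant correlation are built
with a Gaussian copula: bivariate standard normals with correlation rho
are mapped through the normal CDF to correlated uniforms, which are then
pushed through the inverse CDFs of the duration and concentration
distributions. Whiff durations, blank durations and whiff concentrations
are correlated pairwise across the two channels; whiff-onset alignment
emerges from the cumulative durations. Each whiff has a single constant
concentration (rectangular whiffs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .stimuli import StimulusWaveform

__all__ = [
    "PlumeSpec",
    "PlumeStats",
    "sample_correlated_uniform_pairs",
    "inv_powerlaw_duration",
    "inv_concentration",
    "mean_normalized_concentration",
    "generate_plume_pair",
    "measure_plume_stats",
    "fit_powerlaw_exponent",
]


@dataclass
class PlumeSpec:
    """Statistical specification of a correlated plume pair."""

    rho_target: float = 0.0      # intended inter-odorant correlation, [0, 1]
    t_total: float = 200.0       # duration (s)
    whiff_min: float = 0.03      # whiff-duration lower bound (s)
    whiff_max: float = 3.0       # whiff-duration upper bound (s); ~ distance from source
    blank_min: float = 0.03      # blank-duration bounds (s)
    blank_max: float | None = None   # defaults to whiff_max
    exponent: float = -1.5       # power-law exponent of durations
    a1: float = 0.22             # concentration-CDF parameters
    b1: float = 0.26
    mean_conc: float = 1.5e-3    # mean concentration over whiff samples
    dt: float = 0.1              # sampling step of the output waveform (ms)
    seed: int = 0

    def __post_init__(self):
        if self.blank_max is None:
            self.blank_max = self.whiff_max
        if not 0.0 <= self.rho_target <= 1.0:
            raise ValueError("rho_target must lie in [0, 1]")
        if not 0 < self.whiff_min < self.whiff_max:
            raise ValueError("require 0 < whiff_min < whiff_max")
        if not 0 < self.blank_min < self.blank_max:
            raise ValueError("require 0 < blank_min < blank_max")
        if self.exponent >= -1:
            raise ValueError("power-law exponent must be < -1")
        if self.t_total < self.whiff_min + self.blank_min:
            raise ValueError("t_total shorter than one whiff+blank cycle")


@dataclass
class PlumeStats:
    """Realized statistics of a generated plume pair."""

    intermittency: tuple          # fraction of time conc > 0, per channel
    mean_conc: tuple              # mean concentration per channel (whole series)
    rho_realized: float           # Pearson correlation of the two channels
    exponent_hat: float | None    # MLE tail exponent of whiff durations
    n_whiffs: tuple = (0, 0)

    def to_dict(self) -> dict:
        return dict(intermittency=list(self.intermittency),
                    mean_conc=list(self.mean_conc),
                    rho_realized=self.rho_realized,
                    exponent_hat=self.exponent_hat,
                    n_whiffs=list(self.n_whiffs))


def sample_correlated_uniform_pairs(rho: float, n: int,
                                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` pairs of uniforms with Gaussian-copula correlation ``rho``.

    Returns an (n, 2) array; each marginal is U(0,1).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2_indep = rng.standard_normal(n)  # always drawn: keeps the stream
    # aligned across rho so runs with a shared seed are paired
    z2 = rho * z1 + np.sqrt(max(1.0 - rho**2, 0.0)) * z2_indep
    return np.column_stack([special.ndtr(z1), special.ndtr(z2)])


def inv_powerlaw_duration(u, t_min: float, t_max: float, exponent: float = -1.5):
    """Inverse CDF of the truncated power-law density p(t) ~ t^exponent on
    [t_min, t_max]. For exponent -3/2 this reduces to
    t = (t_min^-1/2 - u (t_min^-1/2 - t_max^-1/2))^-2.
    """
    if not 0 < t_min < t_max:
        raise ValueError("require 0 < t_min < t_max")
    if exponent >= -1:
        raise ValueError("exponent must be < -1")
    u = np.asarray(u, dtype=np.float64)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("u must lie in [0, 1]")
    g1 = exponent + 1.0
    t = (t_min**g1 + u * (t_max**g1 - t_min**g1)) ** (1.0 / g1)
    return float(t) if t.ndim == 0 else t


def inv_concentration(u, a1: float = 0.22, b1: float = 0.26):
    """Inverse of the piecewise whiff-concentration CDF; returns the
    normalized concentration x = C / <C>."""
    u = np.asarray(u, dtype=np.float64)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u must lie in [0, 1); the upper branch is unbounded at 1")
    lower = (3.0 / 5.0) * u
    with np.errstate(divide="ignore"):
        upper = (-np.log10(1.0 - u) - a1) / b1
    x = np.where(u <= 0.5, lower, upper)
    return float(x) if x.ndim == 0 else x


def mean_normalized_concentration(a1: float = 0.22, b1: float = 0.26) -> float:
    """Analytic mean of x under the piecewise CDF (used to scale whiff
    concentrations so the whiff-sample mean hits ``mean_conc``)."""
    lower = (3.0 / 5.0) * 0.125                      # int_0^0.5 (3/5) u du
    # int_0^0.5 -log10(v) dv = (v - v ln v)|_0^0.5 / ln 10
    int_log = (0.5 - 0.5 * np.log(0.5)) / np.log(10.0)
    upper = (int_log - 0.5 * a1) / b1
    return lower + upper


def _event_series(durs_w, durs_b, concs, t_total: float):
    """Assemble one channel: alternate blank -> whiff using successive draws.

    Returns (onsets, offsets, levels) of whiffs inside [0, t_total]."""
    onsets, offsets, levels = [], [], []
    t = 0.0
    for dw, db, cc in zip(durs_w, durs_b, concs):
        t += db                          # leading blank
        if t >= t_total:
            break
        onsets.append(t)
        offsets.append(min(t + dw, t_total))
        levels.append(cc)
        t += dw
        if t >= t_total:
            break
    return np.array(onsets), np.array(offsets), np.array(levels)


def generate_plume_pair(spec: PlumeSpec) -> StimulusWaveform:
    """Generate a correlated pair of plume concentration time series.

    The k-th whiff (and blank, and concentration) of channel A is coupled
    to the k-th of channel B through the copula; with rho_target = 1 the
    two channels are identical.
    """
    rng = np.random.default_rng(spec.seed)
    # conservative estimate of events needed to span t_total
    g1 = spec.exponent + 1.0
    z = (spec.whiff_max**g1 - spec.whiff_min**g1)
    mean_dur = (spec.exponent + 1.0) / (spec.exponent + 2.0) * \
        (spec.whiff_max**(g1 + 1.0) - spec.whiff_min**(g1 + 1.0)) / z
    n_ev = max(16, int(2.5 * spec.t_total / (2.0 * mean_dur)) + 16)

    while True:
        u_w = sample_correlated_uniform_pairs(spec.rho_target, n_ev, rng)
        u_b = sample_correlated_uniform_pairs(spec.rho_target, n_ev, rng)
        u_c = sample_correlated_uniform_pairs(spec.rho_target, n_ev, rng)
        u_c = np.clip(u_c, 0.0, 1.0 - 1e-12)
        scale = spec.mean_conc / mean_normalized_concentration(spec.a1, spec.b1)
        chans = []
        complete = True
        for ch in range(2):
            dw = inv_powerlaw_duration(u_w[:, ch], spec.whiff_min, spec.whiff_max,
                                       spec.exponent)
            db = inv_powerlaw_duration(u_b[:, ch], spec.blank_min, spec.blank_max,
                                       spec.exponent)
            cc = scale * inv_concentration(u_c[:, ch], spec.a1, spec.b1)
            total = np.sum(dw) + np.sum(db)
            if total < spec.t_total:
                complete = False
                break
            chans.append(_event_series(dw, db, cc, spec.t_total))
        if complete:
            break
        n_ev *= 2  # rare: power-law draws fell short; redraw a longer block

    n_samp = int(round(spec.t_total * 1000.0 / spec.dt))
    t_ms = np.arange(n_samp) * spec.dt
    series = np.zeros((n_samp, 2))
    for ch, (on, off, lev) in enumerate(chans):
        i0 = np.round(on * 1000.0 / spec.dt).astype(np.int64)
        i1 = np.round(off * 1000.0 / spec.dt).astype(np.int64)
        for a, b, c in zip(i0, i1, lev):
            series[a:b, ch] = c
    meta = dict(generator="plume", rho_target=spec.rho_target,
                t_total_s=spec.t_total, whiff_max=spec.whiff_max,
                mean_conc=spec.mean_conc, seed=spec.seed)
    return StimulusWaveform(t_ms, series[:, 0], series[:, 1], meta)


def _whiff_durations(conc: np.ndarray, dt_ms: float) -> np.ndarray:
    """Durations (s) of the maximal runs with conc > 0."""
    active = np.concatenate([[0], (conc > 0).astype(np.int8), [0]])
    d = np.diff(active)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return (ends - starts) * dt_ms / 1000.0


def fit_powerlaw_exponent(durations: np.ndarray, t_min: float | None = None,
                          t_max: float | None = None) -> float:
    """Truncation-aware MLE of the exponent of p(t) ~ t^g on [t_min, t_max].

    Bounds default to the sample extrema. The log-likelihood per point is
    log((g+1)/(t_max^(g+1) - t_min^(g+1))) + g log t, maximized over
    g in (-3, -1.001).
    """
    d = np.asarray(durations, dtype=np.float64)
    d = d[d > 0]
    if d.size < 10:
        raise ValueError("need at least 10 durations for a tail fit")
    lo = float(np.min(d)) if t_min is None else t_min
    hi = float(np.max(d)) if t_max is None else t_max
    if not lo < hi:
        raise ValueError("degenerate duration range")
    s_log = float(np.mean(np.log(d)))

    def nll(g):
        g1 = g + 1.0  # g1 < 0, hi**g1 < lo**g1, so the ratio below is positive
        return -(np.log(g1 / (hi**g1 - lo**g1)) + g * s_log)

    res = optimize.minimize_scalar(nll, bounds=(-2.999, -1.001), method="bounded")
    return float(res.x)


def measure_plume_stats(waveform: StimulusWaveform,
                        fit_exponent: bool = True) -> PlumeStats:
    """Realized intermittency, mean concentration, inter-channel correlation
    and (optionally) whiff-duration tail exponent of a plume pair."""
    conc = waveform.conc
    inter = tuple(float(np.mean(conc[:, ch] > 0)) for ch in range(2))
    means = tuple(float(np.mean(conc[:, ch])) for ch in range(2))
    if np.std(conc[:, 0]) == 0 or np.std(conc[:, 1]) == 0:
        raise ValueError("correlation undefined: a channel is constant")
    rho = float(stats.pearsonr(conc[:, 0], conc[:, 1])[0])
    durs = np.concatenate([_whiff_durations(conc[:, ch], waveform.dt)
                           for ch in range(2)])
    exp_hat = None
    if fit_exponent and durs.size >= 10:
        exp_hat = fit_powerlaw_exponent(durs)
    return PlumeStats(intermittency=inter, mean_conc=means, rho_realized=rho,
                      exponent_hat=exp_hat,
                      n_whiffs=tuple(int(len(_whiff_durations(conc[:, ch], waveform.dt)))
                                     for ch in range(2)))
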