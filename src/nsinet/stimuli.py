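"""Deterministic two-channel odorant-concentration waveforms.

Steps, ramps, parabolas and triangular pulses, each on a uniform time grid.
Concentrations use the same v/v dilution proxy as the transduction model.
All generators place the stimulus after a settle period (default 500 ms)
so that adaptation variables can reach baseline before stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusWaveform",
    "DEFAULT_SETTLE_MS",
    "make_step",
    "make_ramp",
    "make_parabola",
    "make_triangles",
]

DEFAULT_SETTLE_MS = 500.0


@dataclass
class StimulusWaveform:
    """Two odorant-concentration channels sampled on one uniform grid."""

    t: np.ndarray          # time (ms)
    conc_a: np.ndarray     # channel A concentration
    conc_b: np.ndarray     # channel B concentration
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.conc_a = np.asarray(self.conc_a, dtype=np.float64)
        self.conc_b = np.asarray(self.conc_b, dtype=np.float64)
        if not (self.t.shape == self.conc_a.shape == self.conc_b.shape):
            raise ValueError("time grid and both channels must share one shape")
        if np.any(self.conc_a < 0) or np.any(self.conc_b < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0

    @property
    def conc(self) -> np.ndarray:
        """(n_samples, 2) concentration matrix, channels as columns."""
        return np.stack([self.conc_a, self.conc_b], axis=1)

    def to_csv(self, path) -> None:
        header = f"nsinet-waveform dt_ms={self.dt} units=v/v\nt_ms,conc_a,conc_b"
        np.savetxt(path, np.column_stack([self.t, self.conc_a, self.conc_b]),
                   delimiter=",", header=header, comments="# ")

    @classmethod
    def from_csv(cls, path) -> "StimulusWaveform":
        arr = np.loadtxt(path, delimiter=",", comments="#")
        return cls(t=arr[:, 0], conc_a=arr[:, 1], conc_b=arr[:, 2],
                   meta={"generator": "from_csv", "path": str(path)})


def _grid(t_total: float, dt: float) -> np.ndarray:
    if dt <= 0 or t_total < dt:
        raise ValueError("require dt > 0 and t_total >= dt")
    n = int(round(t_total / dt))
    return np.arange(n) * dt


def make_step(peak_conc_a: float, peak_conc_b: float, onset: float,
              duration: float, t_total: float, dt: float = 0.1) -> StimulusWaveform:
    """Rectangular concentration step on each channel, zero elsewhere."""
    if peak_conc_a < 0 or peak_conc_b < 0:
        raise ValueError("concentrations must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if onset + duration > t_total:
        raise ValueError("stimulus extends beyond t_total")
    t = _grid(t_total, dt)
    inside = (t >= onset) & (t < onset + duration)
    conc_a = np.where(inside, peak_conc_a, 0.0)
    conc_b = np.where(inside, peak_conc_b, 0.0)
    meta = dict(generator="step", peak_conc_a=peak_conc_a, peak_conc_b=peak_conc_b,
                onset=onset, duration=duration)
    return StimulusWaveform(t, conc_a, conc_b, meta)


def make_ramp(slope: float, onset: float, duration: float, t_total: float,
              dt: float = 0.1, slope_b: float | None = None) -> StimulusWaveform:
    """Linear rise from zero at rate ``slope`` (concentration per ms) over the
    stimulus window; zero outside. ``slope_b`` defaults to channel A's slope
    applied to channel B as well; pass 0 for a single-odorant ramp."""
    if slope < 0 or (slope_b is not None and slope_b < 0):
        raise ValueError("slope must be non-negative")
    if onset + duration > t_total:
        raise ValueError("stimulus extends beyond t_total")
    t = _grid(t_total, dt)
    rel = np.clip(t - onset, 0.0, None)
    inside = (t >= onset) & (t < onset + duration)
    conc_a = np.where(inside, slope * rel, 0.0)
    sb = slope if slope_b is None else slope_b
    conc_b = np.where(inside, sb * rel, 0.0)
    return StimulusWaveform(t, conc_a, conc_b,
                            dict(generator="ramp", slope=slope, slope_b=sb,
                                 onset=onset, duration=duration))


def make_parabola(curvature: float, onset: float, duration: float, t_total: float,
                  dt: float = 0.1, curvature_b: float | None = None) -> StimulusWaveform:
    """Quadratic rise ``curvature * (t - onset)^2`` over the stimulus window."""
    if curvature < 0 or (curvature_b is not None and curvature_b < 0):
        raise ValueError("curvature must be non-negative")
    if onset + duration > t_total:
        raise ValueError("stimulus extends beyond t_total")
    t = _grid(t_total, dt)
    rel = np.clip(t - onset, 0.0, None)
    inside = (t >= onset) & (t < onset + duration)
    cb = curvature if curvature_b is None else curvature_b
    conc_a = np.where(inside, curvature * rel**2, 0.0)
    conc_b = np.where(inside, cb * rel**2, 0.0)
    return StimulusWaveform(t, conc_a, conc_b,
                            dict(generator="parabola", curvature=curvature,
                                 curvature_b=cb, onset=onset, duration=duration))


def _triangle(t: np.ndarray, onset: float, duration: float, peak: float) -> np.ndarray:
    """Isoceles triangle: linear rise to ``peak`` at onset + duration/2,
    symmetric fall back to zero."""
    if duration <= 0 or peak == 0:
        return np.zeros_like(t)
    half = duration / 2.0
    rel = t - onset
    up = peak * rel / half
    down = peak * (duration - rel) / half
    tri = np.minimum(up, down)
    return np.clip(np.where((rel >= 0) & (rel <= duration), tri, 0.0), 0.0, None)


def make_triangles(peak_conc_a: float, peak_conc_b: float, duration: float,
                   delay: float, t_total: float, dt: float = 0.1,
                   onset: float = DEFAULT_SETTLE_MS) -> StimulusWaveform:
    """Triangular pulse per channel; channel B starts ``delay`` ms after A.

    Mimics single whiffs in a plume: symmetric linear increase and decrease,
    apex at onset + duration/2. Typical durations 10-200 ms (up to 500 ms),
    delays 0-500 ms.
    """
    if peak_conc_a < 0 or peak_conc_b < 0:
        raise ValueError("concentrations must be non-negative")
    if delay < 0:
        raise ValueError("delay must be >= 0")
    if onset + delay + duration > t_total:
        raise ValueError("t_total too short to contain both pulses")
    t = _grid(t_total, dt)
    conc_a = _triangle(t, onset, duration, peak_conc_a)
    conc_b = _triangle(t, onset + delay, duration, peak_conc_b)
    return StimulusWaveform(t, conc_a, conc_b,
                            dict(generator="triangles", peak_conc_a=peak_conc_a,
                                 peak_conc_b=peak_conc_b, duration=duration,
                                 delay=delay, onset=onset))
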