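"""Sensillum stage: transduction, ORN spike generation and NSI coupling.

Each sensillum houses one ORN_a and one ORN_b in shared lymph. Odorant
binding follows a single-stage rate equation; spikes are produced by a
leaky integrate-and-fire membrane with a potassium-like spike-rate
adaptation conductance; receptor noise is an Ornstein-Uhlenbeck process
added to the bound-receptor fraction inside the receptor current. The
non-synaptic interaction (NSI) shifts each ORN's receptor-current reversal
potential toward rest in proportion to the *partner's* receptor
activation, producing mutual, graded, instantaneous inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import ModelParams, VariantSpec, make_variant
from .stimuli import StimulusWaveform

__all__ = [
    "SpikeRecord",
    "SensillumResult",
    "OrnState",
    "step_transduction",
    "nsi_reversal",
    "step_orn",
    "run_sensilla",
]


@dataclass
class SpikeRecord:
    """Spike times (ms) of one population, one array per neuron."""

    label: str
    trains: list  # list of 1-D float arrays

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(tr) for tr in self.trains))

    def rates(self, t_start: float, t_stop: float) -> np.ndarray:
        """Mean firing rate (Hz) per neuron over [t_start, t_stop)."""
        span_s = (t_stop - t_start) / 1000.0
        return np.array([np.sum((tr >= t_start) & (tr < t_stop)) / span_s
                         for tr in self.trains])

    @classmethod
    def from_raster(cls, raster: np.ndarray, dt: float, label: str) -> "SpikeRecord":
        """raster: (T, n_neurons) spike-count matrix on a dt grid."""
        trains = [np.flatnonzero(raster[:, i]).astype(np.float64) * dt
                  for i in range(raster.shape[1])]
        return cls(label=label, trains=trains)

    # -- I/O --------------------------------------------------------------
    def to_text(self, path) -> None:
        """Two columns: neuron index, spike time (ms)."""
        rows = [(i, t) for i, tr in enumerate(self.trains) for t in tr]
        arr = np.array(rows, dtype=np.float64).reshape(-1, 2)
        np.savetxt(path, arr, fmt=["%d", "%.4f"], delimiter="\t",
                   header=f"population={self.label} n_neurons={self.n_neurons}",
                   comments="# ")

    @classmethod
    def from_text(cls, path, label: str = "", n_neurons: int | None = None) -> "SpikeRecord":
        arr = np.loadtxt(path, comments="#", ndmin=2)
        if arr.size == 0:
            return cls(label=label, trains=[np.array([])] * (n_neurons or 0))
        n = n_neurons or int(arr[:, 0].max()) + 1
        trains = [np.sort(arr[arr[:, 0] == i, 1]) for i in range(n)]
        return cls(label=label, trains=trains)


def save_spikes_hdf5(path, records: dict) -> None:
    """Write a {label: SpikeRecord} mapping to an HDF5 container, one group
    per population, one dataset per neuron."""
    import h5py

    with h5py.File(path, "w") as fh:
        for label, rec in records.items():
            grp = fh.create_group(label)
            for i, tr in enumerate(rec.trains):
                grp.create_dataset(f"n{i:04d}", data=np.asarray(tr, dtype=np.float64))


def load_spikes_hdf5(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for label in fh:
            keys = sorted(fh[label].keys())
            out[label] = SpikeRecord(label=label,
                                     trains=[fh[label][k][...] for k in keys])
    return out


# ---------------------------------------------------------------------------
# single-step operations (thin wrappers over the jitted scalar rules)
# ---------------------------------------------------------------------------

def step_transduction(r: float, c: float, params: ModelParams, dt: float,
                      include_c0: bool = True) -> float:
    """One Euler step of the receptor-binding equation; result in [0, 1]."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    tp = params.transduction
    c_eff = c + (tp.c0 if include_c0 else 0.0)
    return float(_kernels.step_transduction_scalar(
        r, c_eff, tp.n, tp.alpha_r, tp.beta_r, dt))


def nsi_reversal(V_rev: float, V_rest: float, omega_nsi: float,
                 r_other: float) -> float:
    """Effective receptor-current reversal under the NSI:
    V_rev - omega_nsi * r_other * (V_rev - V_rest)."""
    return float(_kernels.nsi_reversal_scalar(V_rev, V_rest, omega_nsi, r_other))


@dataclass
class OrnState:
    """State of a single ORN (for step-wise simulation in analyses/tests)."""

    V: float
    y: float = 0.0
    refr: float = 0.0


def step_orn(state: OrnState, r_self: float, r_other: float,
             params: ModelParams, omega_nsi: float, dt: float,
             zeta: float = 0.0) -> tuple[OrnState, bool]:
    """Advance one ORN membrane by one step; returns (new state, spiked?).

    ``zeta`` is the current receptor-noise value (0 for noise-free runs).
    """
    op = params.orn
    if not np.isfinite(state.V):
        raise FloatingPointError("non-finite membrane potential")
    y = state.y * (1.0 - dt * op.beta_y)
    if state.refr > 0:
        return OrnState(V=op.V_rest, y=y, refr=state.refr - dt), False
    v_rev = nsi_reversal(op.V_rev, op.V_rest, omega_nsi, r_other)
    g_rec = op.g_r * r_self * (1.0 + zeta)
    g_sum = op.gl + op.g_y * y + g_rec
    gv_sum = op.gl * op.V_rest + op.g_y * y * op.V_K + g_rec * v_rev
    V = float(_kernels.membrane_update(state.V, g_sum, gv_sum, op.C, dt))
    if V > op.theta:
        return OrnState(V=op.V_rest, y=y + op.y_jump, refr=op.tau_ref), True
    return OrnState(V=V, y=y, refr=0.0), False


# ---------------------------------------------------------------------------
# population run
# ---------------------------------------------------------------------------

@dataclass
class SensillumResult:
    """Output of a sensillum-population simulation."""

    t: np.ndarray                 # time grid (ms)
    records: dict                 # {"ORN_a": SpikeRecord, "ORN_b": SpikeRecord}
    raster: np.ndarray            # (T, 2 n_sensilla) uint8, glomerulus-blocked
    r_mean: np.ndarray            # (T, 2) sensilla-averaged receptor activation
    y_mean: np.ndarray            # (T, 2) sensilla-averaged adaptation
    meta: dict = field(default_factory=dict)


def run_sensilla(waveform: StimulusWaveform, params: ModelParams | None = None,
                 variant: VariantSpec | str = "control", seed: int = 0,
                 sens_matrix: np.ndarray | None = None) -> SensillumResult:
    """Simulate the full sensillum population driven by a two-channel waveform.

    Each of ``layout.n_orn_per_type`` sensilla holds an independent ORN_a /
    ORN_b pair with its own noise stream; channel A drives ORN_a and channel
    B drives ORN_b unless ``sens_matrix`` (2x2, ORN x channel) overrides the
    strict selectivity.
    """
    params = params or ModelParams()
    if isinstance(variant, str):
        variant = make_variant(variant, params.orn.omega_nsi, params.al.alpha_ln)
    sens = np.eye(2) if sens_matrix is None else np.asarray(sens_matrix, float)
    if sens.shape != (2, 2):
        raise ValueError("sens_matrix must be 2x2 (ORN x channel)")
    tp, op, lay = params.transduction, params.orn, params.layout
    dt = waveform.dt
    conc = np.ascontiguousarray(waveform.conc)
    kernel_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] & 0x7FFFFFFF)
    raster, r_mean, y_mean = _kernels.run_orn_kernel(
        conc, sens, dt, kernel_seed, lay.n_orn_per_type,
        tp.n, tp.alpha_r, tp.beta_r, tp.c0, tp.r_noise, tp.tau_noise,
        op.C, op.gl, op.V_rest, op.V_rev, op.V_K, op.g_r, op.g_y,
        op.y_jump, op.beta_y, op.theta, op.tau_ref,
        variant.omega_nsi_effective)
    ns = lay.n_orn_per_type
    records = {
        "ORN_a": SpikeRecord.from_raster(raster[:, :ns], dt, "ORN_a"),
        "ORN_b": SpikeRecord.from_raster(raster[:, ns:], dt, "ORN_b"),
    }
    return SensillumResult(t=waveform.t, records=records, raster=raster,
                           r_mean=r_mean, y_mean=y_mean,
                           meta=dict(variant=variant.name, seed=seed,
                                     omega_nsi=variant.omega_nsi_effective))
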