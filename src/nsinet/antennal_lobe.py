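"""Antennal-lobe stage: two glomeruli of PNs and LNs with conductance-based
synapses and cross-glomerular lateral inhibition.

All ORNs of one receptor type converge onto the PNs of their glomerulus
(pooled excitation). PNs excite the LNs of their own glomerulus; LNs
inhibit the PNs of the *other* glomeruli only. PNs carry a spike-rate
adaptation conductance with inhibitory reversal; LNs are plain LIF units.
Setting the LN release factor alpha_ln to zero (control and NSI variants)
silences lateral inhibition without changing anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import ModelParams, NetworkLayout, VariantSpec, make_variant
from .sensillum import SensillumResult, SpikeRecord

__all__ = [
    "build_connectivity",
    "step_synapse",
    "PnState",
    "LnState",
    "step_pn",
    "step_ln",
    "AlResult",
    "run_network",
]


def build_connectivity(layout: NetworkLayout) -> dict:
    """Binary connectivity matrices of the glomerulus-blocked wiring.

    Returns dict with
      w : (n_pn_tot, n_orn_tot) ORN -> PN, all-to-all within a glomerulus
      v : (n_ln_tot, n_pn_tot)  PN -> LN, within-glomerulus
      u : (n_pn_tot, n_ln_tot)  LN -> PN, strictly cross-glomerulus
    """
    layout.validate()
    G, no, np_, nl = layout.n_glom, layout.n_orn_per_type, layout.n_pn_per_glom, layout.n_ln_per_glom
    w = np.zeros((G * np_, G * no), dtype=np.int8)
    v = np.zeros((G * nl, G * np_), dtype=np.int8)
    u = np.zeros((G * np_, G * nl), dtype=np.int8)
    for g in range(G):
        w[g * np_:(g + 1) * np_, g * no:(g + 1) * no] = 1
        v[g * nl:(g + 1) * nl, g * np_:(g + 1) * np_] = 1
        for h in range(G):
            if h != g:
                u[g * np_:(g + 1) * np_, h * nl:(h + 1) * nl] = 1
    return dict(w=w, v=v, u=u)


def step_synapse(act: float, n_pre_spikes: int, alpha: float, tau: float,
                 dt: float) -> float:
    """One step of a presynaptic activation variable: exponential decay with
    time constant ``tau`` plus a saturating jump alpha (1 - act) per spike."""
    act = act - dt * act / tau
    for _ in range(int(n_pre_spikes)):
        act = float(_kernels.synapse_jump(act, alpha))
    return act


@dataclass
class PnState:
    V: float
    x: float = 0.0     # adaptation activation, in [0, 1]
    refr: float = 0.0


@dataclass
class LnState:
    V: float
    refr: float = 0.0


def step_pn(state: PnState, s_i: float, y_i: float, params: ModelParams,
            dt: float, noise: float = 0.0) -> tuple[PnState, bool]:
    """Advance one PN membrane by one step.

    s_i / y_i are the pooled excitatory (ORN) and inhibitory (LN) synaptic
    activations; ``noise`` is a standard-normal draw (0 = noise-free).
    """
    al = params.al
    if not np.isfinite(state.V):
        raise FloatingPointError("non-finite membrane potential")
    x = state.x * (1.0 - dt / al.tau_ad)
    if state.refr > 0:
        return PnState(V=al.V_rest, x=x, refr=state.refr - dt), False
    g_exc = al.g_orn * s_i
    g_inh = al.g_ad * x + al.g_ln * y_i
    g_sum = al.gl_pn + g_exc + g_inh
    gv_sum = al.gl_pn * al.V_rest + g_exc * al.V_revE + g_inh * al.V_revI
    V = float(_kernels.membrane_update(state.V, g_sum, gv_sum, al.C, dt))
    V += al.I_noise_pn * np.sqrt(dt) / al.C * noise
    if V > al.theta:
        x = float(_kernels.synapse_jump(x, al.alpha_ad))
        return PnState(V=al.V_rest, x=x, refr=al.tau_ref), True
    return PnState(V=V, x=x, refr=0.0), False


def step_ln(state: LnState, z_i: float, params: ModelParams, dt: float,
            noise: float = 0.0) -> tuple[LnState, bool]:
    """Advance one LN membrane by one step (no adaptation, no inhibition)."""
    al = params.al
    if not np.isfinite(state.V):
        raise FloatingPointError("non-finite membrane potential")
    if state.refr > 0:
        return LnState(V=al.V_rest, refr=state.refr - dt), False
    g_exc = al.g_pn * z_i
    g_sum = al.gl_ln + g_exc
    gv_sum = al.gl_ln * al.V_rest + g_exc * al.V_revE
    V = float(_kernels.membrane_update(state.V, g_sum, gv_sum, al.C, dt))
    V += al.I_noise_ln * np.sqrt(dt) / al.C * noise
    if V > al.theta:
        return LnState(V=al.V_rest, refr=al.tau_ref), True
    return LnState(V=V, refr=0.0), False


@dataclass
class AlResult:
    """Output of an antennal-lobe simulation."""

    t: np.ndarray
    records: dict        # PN_a / PN_b / LN_a / LN_b SpikeRecords
    pn_raster: np.ndarray
    ln_raster: np.ndarray
    meta: dict = field(default_factory=dict)


def run_network(orn: SensillumResult | np.ndarray, params: ModelParams | None = None,
                variant: VariantSpec | str = "control", seed: int = 0,
                t: np.ndarray | None = None, dt: float | None = None) -> AlResult:
    """Simulate the antennal lobe on an ORN spike raster.

    ``orn`` is a SensillumResult (preferred) or a raw (T, n_orn_total)
    raster, in which case ``t``/``dt`` must be given.
    """
    params = params or ModelParams()
    if isinstance(variant, str):
        variant = make_variant(variant, params.orn.omega_nsi, params.al.alpha_ln)
    if isinstance(orn, SensillumResult):
        raster = orn.raster
        t = orn.t
        dt = float(t[1] - t[0])
    else:
        raster = np.asarray(orn, dtype=np.uint8)
        if t is None or dt is None:
            raise ValueError("raw raster input requires t and dt")
    al, lay = params.al, params.layout
    kernel_seed = int(np.random.SeedSequence([seed, 0xA1]).generate_state(1)[0]
                      & 0x7FFFFFFF)
    pn_raster, ln_raster = _kernels.run_al_kernel(
        np.ascontiguousarray(raster), dt, kernel_seed,
        lay.n_orn_per_type, lay.n_pn_per_glom, lay.n_ln_per_glom, lay.n_glom,
        al.C, al.gl_pn, al.V_rest, al.theta, al.tau_ref, al.V_revE, al.V_revI,
        al.g_orn, al.g_ln, al.g_ad, al.alpha_ad, al.tau_ad, al.I_noise_pn,
        al.gl_ln, al.g_pn, al.I_noise_ln,
        al.alpha_orn, al.tau_orn, al.alpha_pn, al.tau_pn,
        variant.alpha_ln_effective, al.tau_ln)
    npn, nln = lay.n_pn_per_glom, lay.n_ln_per_glom
    records = {
        "PN_a": SpikeRecord.from_raster(pn_raster[:, :npn], dt, "PN_a"),
        "PN_b": SpikeRecord.from_raster(pn_raster[:, npn:], dt, "PN_b"),
        "LN_a": SpikeRecord.from_raster(ln_raster[:, :nln], dt, "LN_a"),
        "LN_b": SpikeRecord.from_raster(ln_raster[:, nln:], dt, "LN_b"),
    }
    return AlResult(t=t, records=records, pn_raster=pn_raster,
                    ln_raster=ln_raster,
                    meta=dict(variant=variant.name, seed=seed,
                              alpha_ln=variant.alpha_ln_effective))
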