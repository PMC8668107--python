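"""Jitted time-stepping kernels for the sensillum and antennal-lobe stages.

These functions are the single source of the model's update rules; the
public single-step operations in :mod:`nsinet.sensillum` and
:mod:`nsinet.antennal_lobe` call the same scalar helpers.

Numerics: membrane potentials relax exponentially toward their
instantaneous conductance-weighted equilibrium each step (exact for the
linear membrane equation with frozen conductances), which keeps the
integration stable for the projection neurons whose membrane time constant
C/gl equals the default step size. All slow gating and synaptic variables
use forward Euler. Spike increments are applied as instantaneous,
step-size-independent jumps.
"""

import numpy as np
from numba import njit

__all__ = [
    "step_transduction_scalar",
    "nsi_reversal_scalar",
    "membrane_update",
    "synapse_jump",
    "run_orn_kernel",
    "run_al_kernel",
]


@njit(cache=True)
def step_transduction_scalar(r, c_eff, n_hill, alpha_r, beta_r, dt):
    """One forward-Euler step of dr/dt = alpha_r c^n (1-r) - beta_r r,
    clipped to [0, 1]. ``c_eff`` already includes the c0 offset."""
    r = r + dt * (alpha_r * c_eff**n_hill * (1.0 - r) - beta_r * r)
    if r < 0.0:
        r = 0.0
    elif r > 1.0:
        r = 1.0
    return r


@njit(cache=True)
def nsi_reversal_scalar(V_rev, V_rest, omega_nsi, r_other):
    """Receptor-current reversal shifted by the partner ORN's activation."""
    return V_rev - omega_nsi * r_other * (V_rev - V_rest)


@njit(cache=True)
def membrane_update(V, g_sum, gv_sum, C, dt):
    """Relax V toward gv_sum/g_sum with rate g_sum/C over one step."""
    if abs(g_sum) < 1e-12:
        return V + dt * gv_sum / C
    v_inf = gv_sum / g_sum
    return v_inf + (V - v_inf) * np.exp(-g_sum * dt / C)


@njit(cache=True)
def synapse_jump(act, alpha):
    """Saturating presynaptic-release jump: act -> act + alpha (1 - act)."""
    return act + alpha * (1.0 - act)


@njit(cache=True)
def run_orn_kernel(conc, sens, dt, seed, n_sensilla,
                   n_hill, alpha_r, beta_r, c0, r_noise, tau_noise,
                   C, gl, V_rest, V_rev, V_K, g_r, g_y, y_jump, beta_y,
                   theta, tau_ref, omega_nsi):
    """Simulate ``n_sensilla`` independent sensilla, each housing one ORN_a
    and one ORN_b coupled by the NSI.

    conc : (T, 2) concentration of odorants A and B per step.
    sens : (2, 2) sensitivity matrix; effective input of ORN k is
           sens[k, 0] * c_A + sens[k, 1] * c_B (identity = strict selectivity).

    Returns (raster, r_mean, y_mean): raster is (T, 2 n_sensilla) uint8 with
    ORN_a in columns [0, n_sensilla) and ORN_b in [n_sensilla, 2 n_sensilla);
    r_mean / y_mean are (T, 2) sensilla-averaged state traces.
    """
    np.random.seed(seed)
    T = conc.shape[0]
    n_orn = 2 * n_sensilla
    raster = np.zeros((T, n_orn), dtype=np.uint8)
    r = np.zeros((n_sensilla, 2))
    V = np.full((n_sensilla, 2), V_rest)
    y = np.zeros((n_sensilla, 2))
    zeta = np.zeros((n_sensilla, 2))
    refr = np.zeros((n_sensilla, 2))
    r_mean = np.zeros((T, 2))
    y_mean = np.zeros((T, 2))
    ou_decay = dt / tau_noise
    ou_sd = np.sqrt(2.0 * dt / tau_noise) * r_noise

    for it in range(T):
        ca = conc[it, 0]
        cb = conc[it, 1]
        for s in range(n_sensilla):
            for k in range(2):
                c_eff = sens[k, 0] * ca + sens[k, 1] * cb + c0
                r[s, k] = step_transduction_scalar(r[s, k], c_eff, n_hill,
                                                  alpha_r, beta_r, dt)
            for k in range(2):
                if r_noise > 0.0:
                    zeta[s, k] += -ou_decay * zeta[s, k] + ou_sd * np.random.normal()
                y[s, k] -= dt * beta_y * y[s, k]
                if refr[s, k] > 0.0:
                    refr[s, k] -= dt
                    V[s, k] = V_rest
                    continue
                v_rev_eff = nsi_reversal_scalar(V_rev, V_rest, omega_nsi, r[s, 1 - k])
                g_rec = g_r * r[s, k] * (1.0 + zeta[s, k])
                g_sum = gl + g_y * y[s, k] + g_rec
                gv_sum = gl * V_rest + g_y * y[s, k] * V_K + g_rec * v_rev_eff
                V[s, k] = membrane_update(V[s, k], g_sum, gv_sum, C, dt)
                if V[s, k] > theta:
                    raster[it, k * n_sensilla + s] = 1
                    V[s, k] = V_rest
                    refr[s, k] = tau_ref
                    y[s, k] += y_jump
        for k in range(2):
            acc_r = 0.0
            acc_y = 0.0
            for s in range(n_sensilla):
                acc_r += r[s, k]
                acc_y += y[s, k]
            r_mean[it, k] = acc_r / n_sensilla
            y_mean[it, k] = acc_y / n_sensilla
    return raster, r_mean, y_mean


@njit(cache=True)
def run_al_kernel(orn_raster, dt, seed, n_orn_per_type, n_pn, n_ln, n_glom,
                  C, gl_pn, V_rest, theta, tau_ref, V_revE, V_revI,
                  g_orn, g_ln, g_ad, alpha_ad, tau_ad, I_noise_pn,
                  gl_ln, g_pn_syn, I_noise_ln,
                  alpha_orn, tau_orn, alpha_pn, tau_pn, alpha_ln, tau_ln):
    """Simulate the antennal lobe driven by an ORN spike raster.

    orn_raster : (T, n_glom * n_orn_per_type) uint8, glomerulus-blocked
    columns (ORNs of glomerulus g occupy columns
    [g n_orn_per_type, (g+1) n_orn_per_type)).

    Wiring: every ORN drives every PN of its glomerulus; every PN drives
    every LN of its glomerulus; every LN inhibits every PN of the *other*
    glomeruli only. ``alpha_ln`` = 0 disables lateral inhibition (control
    and NSI variants).

    Returns (pn_raster, ln_raster), shapes (T, n_glom*n_pn) and
    (T, n_glom*n_ln), glomerulus-blocked.
    """
    np.random.seed(seed)
    T = orn_raster.shape[0]
    n_pn_tot = n_glom * n_pn
    n_ln_tot = n_glom * n_ln
    n_orn_tot = n_glom * n_orn_per_type

    s_hat = np.zeros(n_orn_tot)
    z_hat = np.zeros(n_pn_tot)
    y_hat = np.zeros(n_ln_tot)
    V_pn = np.full(n_pn_tot, V_rest)
    x_pn = np.zeros(n_pn_tot)
    refr_pn = np.zeros(n_pn_tot)
    V_ln = np.full(n_ln_tot, V_rest)
    refr_ln = np.zeros(n_ln_tot)
    pn_raster = np.zeros((T, n_pn_tot), dtype=np.uint8)
    ln_raster = np.zeros((T, n_ln_tot), dtype=np.uint8)

    noise_pn = I_noise_pn * np.sqrt(dt) / C
    noise_ln = I_noise_ln * np.sqrt(dt) / C

    s_glom = np.zeros(n_glom)
    z_glom = np.zeros(n_glom)
    y_glom = np.zeros(n_glom)

    for it in range(T):
        # ORN -> PN synaptic activations
        for j in range(n_orn_tot):
            s_hat[j] -= dt * s_hat[j] / tau_orn
            for _ in range(orn_raster[it, j]):
                s_hat[j] = synapse_jump(s_hat[j], alpha_orn)
        # per-glomerulus pooled drives
        for g in range(n_glom):
            acc = 0.0
            for j in range(g * n_orn_per_type, (g + 1) * n_orn_per_type):
                acc += s_hat[j]
            s_glom[g] = acc
            acc = 0.0
            for j in range(g * n_ln, (g + 1) * n_ln):
                acc += y_hat[j]
            y_glom[g] = acc
        # PNs: excitatory ORN drive, adaptation, cross-glomerular LN inhibition
        for i in range(n_pn_tot):
            g = i // n_pn
            x_pn[i] -= dt * x_pn[i] / tau_ad
            z_hat[i] -= dt * z_hat[i] / tau_pn
            if refr_pn[i] > 0.0:
                refr_pn[i] -= dt
                V_pn[i] = V_rest
                continue
            y_other = 0.0
            for gg in range(n_glom):
                if gg != g:
                    y_other += y_glom[gg]
            g_exc = g_orn * s_glom[g]
            g_inh = g_ad * x_pn[i] + g_ln * y_other
            g_sum = gl_pn + g_exc + g_inh
            gv_sum = gl_pn * V_rest + g_exc * V_revE + g_inh * V_revI
            V_pn[i] = membrane_update(V_pn[i], g_sum, gv_sum, C, dt)
            V_pn[i] += noise_pn * np.random.normal()
            if V_pn[i] > theta:
                pn_raster[it, i] = 1
                V_pn[i] = V_rest
                refr_pn[i] = tau_ref
                x_pn[i] = synapse_jump(x_pn[i], alpha_ad)
                z_hat[i] = synapse_jump(z_hat[i], alpha_pn)
        # LNs driven by their glomerulus's PNs
        for g in range(n_glom):
            acc = 0.0
            for i in range(g * n_pn, (g + 1) * n_pn):
                acc += z_hat[i]
            z_glom[g] = acc
        for j in range(n_ln_tot):
            g = j // n_ln
            y_hat[j] -= dt * y_hat[j] / tau_ln
            if refr_ln[j] > 0.0:
                refr_ln[j] -= dt
                V_ln[j] = V_rest
                continue
            g_exc = g_pn_syn * z_glom[g]
            g_sum = gl_ln + g_exc
            gv_sum = gl_ln * V_rest + g_exc * V_revE
            V_ln[j] = membrane_update(V_ln[j], g_sum, gv_sum, C, dt)
            V_ln[j] += noise_ln * np.random.normal()
            if V_ln[j] > theta:
                ln_raster[it, j] = 1
                V_ln[j] = V_rest
                refr_ln[j] = tau_ref
                # LN->PN release pool is linear (non-saturating): with the
                # small g_LN, inhibition only reaches functional strength
                # through accumulation y_ss ~ alpha_ln * rate * tau_ln
                y_hat[j] += alpha_ln
    return pn_raster, ln_raster
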