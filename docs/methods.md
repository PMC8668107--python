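# Methods

This note documents the model equations as implemented, the unit system,
the assumptions made where the source physiology leaves choices open, the
numerical scheme, and what the synthetic stimuli do and do not capture.

## Units and conventions

All internal quantities use mV, ms, µS and nF, so conductance × voltage
gives currents in nA and `dV/dt = I/C` is in mV/ms; rate constants are in
kHz (1/ms). Odorant concentration is a v/v liquid-dilution proxy
(dimensionless); behaviourally relevant values run from ~10⁻⁵ to ~10⁻².
Published values for this parameter set mix units (a reversal potential
labelled µS, one noise amplitude in nA and the other in mV); every such
number is read as a magnitude in the internal system, with the
interpretations below.

## Transduction

`dr/dt = α_r c^n (1−r) − β_r r`, forward Euler, clipped to [0, 1].
Defaults α_r = 12.62 kHz, β_r = 0.077 kHz, n = 0.82. A constant offset
c₀ = 1.85·10⁻⁴ is added to the stimulus concentration, giving a baseline
occupancy r ≈ 0.12 that sustains spontaneous activity; it can be disabled.
Half activation sits at c ≈ 2·10⁻³ (where α_r c^n = β_r).

## ORN spike generator

Conductance-based LIF with adaptation:

C dV/dt = g_l(V_rest−V) + g_y·y(V_K−V) + g_r·r(1+ζ)(V'_rev−V)

* **Adaptation.** y decays at β_y = 0.0035 kHz (τ ≈ 286 ms) and jumps at
  each spike by α_y·w, where α_y = 0.45 kHz is the impulse rate and
  w = 0.1 ms the fixed width of the spike impulse, i.e. an increment of
  0.045 per spike, independent of the integration step. The adaptation
  reversal V_K (not part of the published set) defaults to −70 mV.
  Together with θ = −30 mV and V_rest = −33 mV this yields spontaneous
  rates ≈ 10 Hz, step-response peaks of 100–250 Hz decaying to a plateau,
  and sustained rates up to ≈ 150 Hz — the operating range the downstream
  circuit needs. Treating the printed α_y as a bare per-spike increment
  of 0.45 makes adaptation an order of magnitude stronger, capping all
  sustained rates below ~15 Hz and silencing the projection neurons; we
  therefore regard the impulse-width reading as the functional one.
* **Receptor noise.** ζ is an Ornstein–Uhlenbeck process with sd
  r_noise = 0.5 and correlation time 20 ms (comparable to the transduction
  kinetics 1/(α_r c^n + β_r) ≈ 7–100 ms; the correlation time is not
  constrained by the source). ζ enters multiplicatively — the receptor
  conductance is g_r·r(1+ζ), i.e. r_noise is the *relative* sd of receptor
  activation. An additive term g_r(r+ζ) with sd 0.5 would make noise alone
  drive firing at half the evoked level (spontaneous rates of 30–90 Hz)
  and erase the low-baseline, sigmoidal ORN→PN transfer this model is
  constrained to show. Noise streams are independent across ORNs.
* **NSI.** The receptor-current reversal of each ORN is shifted toward
  rest in proportion to its sensillum partner's receptor activation:
  V'_rev = V_rev − ω_NSI·r_partner·(V_rev − V_rest). The interaction is
  instantaneous, graded, symmetric, and acts before any spike is fired —
  the defining differences from LN inhibition.
* Spike at V > θ; reset to V_rest; absolute refractory τ_ref = 2 ms.

Each of the 20 sensilla holds one ORN_a and one ORN_b with independent
noise; by default ORN_a responds only to odorant A and ORN_b to odorant B.
A 2×2 sensitivity matrix generalizes this for the dynamic-range analysis,
where both ORNs sense a single odorant with a tunable sensitivity ratio.

## Antennal lobe

Two glomeruli; 5 PNs and 3 LNs each. All ORNs of a type excite all PNs of
their glomerulus; all PNs of a glomerulus excite its LNs; LNs inhibit the
PNs of the *other* glomerulus only. PNs carry an adaptation conductance
(g_ad = 12.2 µS toward V_revI = −80 mV, increment α_ad(1−x), τ_ad =
258 ms); LNs have none. The LN→PN term uses the same inhibitory reversal
V_revI (no separate value exists for it).

Synaptic release variables decay exponentially (τ_ORN = 26.8 ms, τ_PN =
19 ms, τ_LN = 250 ms) and jump at presynaptic spikes. ORN→PN and PN→LN
jumps are saturating, α(1−ŝ), keeping those activations in [0, 1]. The
LN→PN pool is **linear** (ŷ += α_LN per spike, no saturation): with the
small inhibitory conductance g_LN = 0.1 µS, a saturating pool would bound
lateral inhibition at 3 LNs × 0.1 µS = 0.3 µS — 3% of the PN leak — and
the LN circuit would be behaviourally identical to the control. Linear
accumulation (steady state α_LN·ν·τ_LN ≈ 20–40 during bursts) is what
makes the printed α_LN = 0.6 kHz, τ_LN = 250 ms and g_LN = 0.1 µS jointly
produce suppression of the delayed glomerulus with recovery by ~500 ms,
and makes τ_LN = 25 ms behave like the control, as this circuit is known
to do.

Membrane noise is a white-noise current I·η/√dt (η standard normal), so
voltage variance is step-size invariant. The published amplitudes are
printed in inconsistent units (nA for PNs, mV for LNs); the defaults here,
22 and 24 nA·√ms, were fixed once so that spontaneous rates (PN ≈ 8 Hz,
LN ≈ 19 Hz) and the half-max of the PN transfer (σ ≈ 80 Hz) fall in the
physiological ranges reported for this circuit, and were not revisited.

Variant switches: control (ω_NSI = 0, α_LN = 0), NSI (α_LN = 0), LN
(ω_NSI = 0), mix (both active). Zeroed strengths reproduce the control
bit-for-bit under matched seeds.

## Numerics

Forward Euler with dt = 0.1 ms for all slow variables (r, y, x, synaptic
pools, OU noise). Membrane potentials use the exponential update
V ← V_∞ + (V−V_∞)·exp(−g_tot·dt/C) toward the instantaneous
conductance-weighted equilibrium: the PN membrane time constant C/g_l =
0.1 ms equals the default step and total conductance during bursts
exceeds 20 µS, where plain forward Euler is unstable. The exponential
update is exact for frozen conductances and agrees with Euler for the
slow ORN membrane. Spike increments are instantaneous jumps, never scaled
by dt, so halving dt changes summary statistics only within stochastic
tolerance. dt must not exceed τ_ref (validated).

Per-stage seeds are derived from the user seed through `SeedSequence`, so
every result is bit-reproducible given (config, seed) and the ORN and AL
stages have independent streams.

## Naturalistic plumes

A plume pair is an alternating sequence of blanks and rectangular whiffs
per channel. Whiff and blank durations are drawn from a truncated power
law p(t) ∝ t^(−3/2) (defaults: bounds 0.03–3 s; the upper bound is the
distance-from-source knob, scanned 0.03–50 s); whiff concentrations from
the piecewise CDF F(x) = (5/3)x for x ≤ 0.3, else 1 − 10^−(a₁+b₁x)
(a₁ = 0.22, b₁ = 0.26, x = C/⟨C⟩). The two CDF branches disagree by ~0.3%
at x = 0.3; the form is implemented verbatim with the branch switch at
F = 0.5. Whiff concentration is constant within a whiff and scaled by
mean_conc/E[x] (E[x] ≈ 1.0656 analytically) so the mean over whiff
samples equals `mean_conc` (default 1.5·10⁻³, mid dynamic range of the
transduction model). Blanks share the whiff power law and lower bound.

Inter-odorant correlation uses a Gaussian copula: bivariate standard
normals with correlation ρ mapped through Φ to correlated uniforms, then
through the inverse CDFs; durations, blanks and concentrations are
correlated pairwise across channels, and whiff-onset alignment emerges
from the cumulative sums. At ρ = 1 the channels are identical. For ρ < 1
the *realized* series correlation is strongly compressed toward zero
(onsets drift apart as duration differences accumulate, the more so the
longer the series), which is why analyses report the post-hoc correlation
and the default target grid (0, 0.9, 0.99, 1) is weighted toward 1. The
sampler always consumes the same number of random draws regardless of ρ,
so runs with a shared seed are paired (common random numbers): channel A
is identical across correlation levels, isolating the correlation effect
from plume-realization noise.

Marginal statistics (intermittency, mean concentration, duration
exponent) are independent of ρ by construction. The realized tail
exponent is recovered by a truncation-aware maximum-likelihood fit.

What the generator does not emulate: within-whiff concentration dynamics
(rise/decay, turbulent fine structure), crosswind-distance dependence
beyond the whiff_max knob, wind direction, and any fluid-dynamics
correlation structure between duration and concentration. Passing tests
on these plumes therefore speak to encoding of intermittency, overlap and
amplitude statistics — not to fine temporal structure within whiffs.

## Read-out measures

* **SDF**: each spike contributes the asymmetric alpha kernel
  k(t̂) = t̂·e^(−t̂/τ)/τ² with t̂ = t − t_spike + τ, τ = 20 ms — support
  starts τ before the spike, peak at the spike time, unit area (one
  spike integrates to 1). A divergent sign variant of this kernel appears
  in print; the normalized alpha function is the standard reading.
* **Max / average activity**: per-neuron max (resp. mean) rate in the
  200 ms window after stimulus onset, averaged over the glomerulus.
  Activity windows are referenced to each channel's own pulse onset.
* **Peak activity**: per-neuron integral of the rate over samples above a
  threshold (50/100/150 Hz), in spikes (Hz·s), averaged over neurons.
* **Encoding error**: err = ((R_PN − R_conc)/(R_PN + R_conc))², in [0, 1],
  zero iff the PN activity ratio equals the concentration ratio.
* **Ratio correlation**: Pearson by default, Spearman by flag.
* **Correlation-encoding distances**: interference p_ctrl(0) − p_x(0) and
  encoding depth p_x(0) − p_x(1) from peak-activity-vs-correlation curves.
* **Dose–response thresholds**: the response at the lowest concentration
  (the spontaneous pedestal, which max activity does not remove) is
  subtracted; C_l / C_h are the concentrations *first* reaching 10% / 90%
  of the curve maximum, log-linearly interpolated — the first-crossing
  rule keeps both defined for the non-monotone peak-and-plateau curves
  the NSI produces. Dynamic range = log₁₀(C_h/C_l); sensitivity distance
  = log₁₀(C_l^b/C_l^a) of the isolated ORNs.
* **Step latency**: argmax of the population SDF within 200 ms of onset.
* **Ramp settle time**: the trial-averaged population SDF is smoothed
  (100 ms boxcar); the settle time is where the rate derivative falls
  below 5% of its onset peak. Because the sample-path derivative grazes
  that threshold for long stretches, the post-peak transient is fitted
  with plateau + A·e^(−t/τ) and the crossing is solved on the fitted
  curve; direct stays-below detectors have a standard deviation of
  100–350 ms at realistic trial counts, the parametric version ~20–30 ms.
  The default ramp rises to 2·10⁻², into the transduction-saturating
  range: a genuine rate plateau requires the receptor drive to stop
  growing, which a ramp that stays below half activation never achieves.

## Experiment protocols and default sizes

All experiments use a 500 ms settle period before stimulus onset, dt =
0.1 ms, and derive per-trial seeds from the experiment seed. Defaults:
ratio grid {1, 2, 3, 5, 7, 10} with six weak-odorant concentrations
log-spaced 10⁻⁴–5·10⁻³; pulse durations 10–200 ms (50 ms standard);
delays {0, 50, 100, 200, 500} ms; 10 trials. Plume runs default to 200 s
per condition with a 4 s demo option; the test suite uses 20 s plumes and
5 seeds per correlation level to keep the default run in minutes. The
dynamic-range scan uses 16 concentrations spanning 10⁻⁵–1 so that the
less-sensitive ORN's activation range is covered at sensitivity distances
up to ~2, with 3 trials per point.

## Known limitations

One sensillum type, two glomeruli, one LN class, symmetric NSIs; no
odorant competition at the receptor, no delivery-device dynamics, no
higher-brain decoding (all read-outs are simple PN statistics). The
ambiguities resolved above (adaptation impulse width, noise conventions,
V_K, the linear LN release pool) are modeling commitments of this
package; each was chosen once, on physiological grounds, and is exposed
as a parameter so the alternatives can be explored.
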