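"""Model parameters, circuit variants and simulation settings.

Single source of truth for every constant of the model. The internal unit
system is mV / ms / uS / nF, so conductance x voltage gives currents in nA
and rate constants are in kHz (1/ms). A handful of published values carry
ambiguous printed units; they are interpreted as magnitudes in this system
(see the config schema notes in each dataclass).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import yaml

__all__ = [
    "TransductionParams",
    "OrnParams",
    "AlParams",
    "NetworkLayout",
    "VariantSpec",
    "SimSettings",
    "ModelParams",
    "default_params",
    "make_variant",
    "VARIANT_NAMES",
]

VARIANT_NAMES = ("control", "NSI", "LN", "mix")


class ParameterError(ValueError):
    """A parameter violates one of its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass
class TransductionParams:
    """Odorant transduction: d r/dt = alpha_r * c^n * (1 - r) - beta_r * r.

    ``c`` is the odorant concentration (v/v liquid-dilution proxy).
    ``c0`` is a constant additive offset to the concentration input,
    representing noise injected into the transduction layer; set to 0 to
    disable.
    """

    n: float = 0.82              # Hill-type exponent (unitless)
    alpha_r: float = 12.62       # binding rate (kHz)
    beta_r: float = 0.077        # unbinding rate (kHz)
    c0: float = 1.85e-4          # baseline concentration offset
    r_noise: float = 0.5         # receptor-noise relative sd (unitless)
    tau_noise: float = 20.0      # receptor-noise correlation time (ms)

    def validate(self) -> None:
        _require(self.alpha_r > 0, "alpha_r must be > 0")
        _require(self.beta_r > 0, "beta_r must be > 0")
        _require(self.n > 0, "n must be > 0")
        _require(self.r_noise >= 0, "r_noise must be >= 0")
        _require(self.c0 >= 0, "c0 must be >= 0")
        _require(self.tau_noise > 0, "tau_noise must be > 0")


@dataclass
class OrnParams:
    """ORN leaky integrate-and-fire spike generator with adaptation.

    C dV/dt = gl (V_rest - V) + g_y y (V_K - V) + g_r r (1 + zeta) (V_rev' - V)
    with the adaptation variable y jumping by alpha_y * pulse_ms at each
    spike (the spike's delta impulse is a rectangle of fixed width
    ``pulse_ms``) and decaying at rate beta_y. zeta is relative
    (multiplicative) receptor noise. V_rev' is the receptor-current reversal,
    shifted by the partner ORN's receptor activation when the non-synaptic
    interaction (NSI) is on:  V_rev' = V_rev - omega_nsi * r_partner *
    (V_rev - V_rest).

    V_K defaults to -70 mV (typical potassium reversal); the published
    parameter table leaves it unstated.
    """

    C: float = 1.0               # membrane capacitance (nF)
    gl: float = 0.442            # leak conductance (uS)
    V_rest: float = -33.0        # resting potential (mV)
    V_rev: float = 0.0           # receptor-current reversal (mV)
    V_K: float = -70.0           # adaptation reversal (mV); assumption
    g_r: float = 0.381           # receptor-current conductance (uS)
    g_y: float = 0.257           # adaptation conductance (uS)
    alpha_y: float = 0.45        # adaptation impulse rate (kHz)
    pulse_ms: float = 0.1        # spike-impulse width (ms); y jumps alpha_y*pulse_ms
    beta_y: float = 0.0035       # adaptation decay rate (kHz)
    theta: float = -30.0         # spike threshold (mV)
    tau_ref: float = 2.0         # refractory period (ms)
    omega_nsi: float = 0.6       # NSI strength (unitless, in [0, 1])

    def validate(self) -> None:
        _require(self.V_rest < self.theta, "V_rest must be below theta")
        _require(self.tau_ref >= 0, "tau_ref must be >= 0")
        _require(0.0 <= self.omega_nsi <= 1.0, "omega_nsi must lie in [0, 1]")
        for name in ("gl", "g_r", "g_y"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.C > 0, "C must be > 0")
        _require(self.alpha_y >= 0, "alpha_y must be >= 0")
        _require(self.pulse_ms > 0, "pulse_ms must be > 0")
        _require(self.beta_y > 0, "beta_y must be > 0")

    @property
    def y_jump(self) -> float:
        """Adaptation increment per spike: alpha_y * pulse_ms."""
        return self.alpha_y * self.pulse_ms


@dataclass
class AlParams:
    """Antennal-lobe parameters: PN and LN membranes plus the three
    conductance-based synapse classes (ORN->PN, PN->LN, LN->PN).

    Noise amplitudes are interpreted as magnitudes of a white-noise current
    in the internal nA system (the published table prints the LN value with
    an mV label); the injected current per step is I_noise * eta / sqrt(dt)
    so that membrane-potential variance is step-size invariant.
    """

    C: float = 1.0               # nF, both PN and LN
    # PN membrane
    gl_pn: float = 10.0          # uS
    V_rest: float = -65.0        # mV (PN and LN)
    theta: float = -35.0         # mV (PN and LN)
    tau_ref: float = 2.0         # ms
    V_revE: float = 0.0          # excitatory reversal (mV)
    V_revI: float = -80.0        # inhibitory reversal (mV); also used for
                                 # the LN->PN term (no separate value exists)
    g_orn: float = 0.6           # ORN->PN conductance (uS)
    g_ln: float = 0.1            # LN->PN conductance (uS)
    g_ad: float = 12.2           # adaptation conductance (uS)
    alpha_ad: float = 0.02       # adaptation increment (x jumps by alpha_ad*(1-x))
    tau_ad: float = 258.0        # adaptation decay (ms)
    I_noise_pn: float = 22.0     # PN noise amplitude (nA sqrt(ms) convention)
    # LN membrane
    gl_ln: float = 6.2           # uS
    g_pn: float = 2.1            # PN->LN conductance (uS)
    I_noise_ln: float = 24.0     # LN noise amplitude (nA sqrt(ms) convention)
    # synapses
    alpha_orn: float = 0.5       # ORN->PN vesicle-release factor (per spike)
    tau_orn: float = 26.8        # ms
    alpha_pn: float = 0.25       # PN->LN
    tau_pn: float = 19.0         # ms
    alpha_ln: float = 0.6        # LN->PN
    tau_ln: float = 250.0        # ms (GABA_B-like; 25 ms models fast inhibition)

    def validate(self) -> None:
        _require(self.V_revI < self.V_rest < self.theta < self.V_revE,
                 "require V_revI < V_rest < theta < V_revE")
        for name in ("tau_orn", "tau_pn", "tau_ln", "tau_ad"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        for name in ("alpha_orn", "alpha_pn", "alpha_ln", "alpha_ad"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("gl_pn", "gl_ln", "g_orn", "g_ln", "g_ad", "g_pn"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")


@dataclass
class NetworkLayout:
    """Counts of model neurons; the circuit has two glomeruli by default."""

    n_orn_per_type: int = 20
    n_pn_per_glom: int = 5
    n_ln_per_glom: int = 3
    n_glom: int = 2

    def validate(self) -> None:
        for name in ("n_orn_per_type", "n_pn_per_glom", "n_ln_per_glom", "n_glom"):
            _require(getattr(self, name) >= 1, f"{name} must be >= 1")


@dataclass
class VariantSpec:
    """One of the four circuit variants.

    control : no lateral interaction of any kind.
    NSI     : sensillum-level non-synaptic interaction only.
    LN      : antennal-lobe LN->PN inhibition only.
    mix     : both mechanisms.
    """

    name: Literal["control", "NSI", "LN", "mix"]
    omega_nsi_effective: float
    alpha_ln_effective: float

    def validate(self) -> None:
        _require(self.name in VARIANT_NAMES, f"unknown variant {self.name!r}")
        if self.name == "control":
            _require(self.omega_nsi_effective == 0 and self.alpha_ln_effective == 0,
                     "control variant requires both strengths = 0")
        elif self.name == "NSI":
            _require(self.alpha_ln_effective == 0, "NSI variant requires alpha_ln = 0")
        elif self.name == "LN":
            _require(self.omega_nsi_effective == 0, "LN variant requires omega_nsi = 0")
        else:
            _require(self.omega_nsi_effective > 0 and self.alpha_ln_effective > 0,
                     "mix variant requires both strengths > 0")


@dataclass
class SimSettings:
    dt: float = 0.1              # integration step (ms)
    t_total: float = 1000.0      # simulated duration (ms)
    seed: int = 0
    n_trials: int = 1

    def validate(self) -> None:
        _require(self.dt > 0, "dt must be > 0")
        _require(self.t_total >= self.dt, "t_total must be >= dt")
        _require(self.n_trials >= 1, "n_trials must be >= 1")


@dataclass
class ModelParams:
    """Full parameter bundle: one attribute per parameter group."""

    transduction: TransductionParams = field(default_factory=TransductionParams)
    orn: OrnParams = field(default_factory=OrnParams)
    al: AlParams = field(default_factory=AlParams)
    layout: NetworkLayout = field(default_factory=NetworkLayout)
    sim: SimSettings = field(default_factory=SimSettings)

    def validate(self) -> None:
        for group in (self.transduction, self.orn, self.al, self.layout, self.sim):
            group.validate()
        _require(self.orn.tau_ref == 0 or self.sim.dt <= self.orn.tau_ref,
                 "dt must not exceed tau_ref")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        p = cls(
            transduction=TransductionParams(**d.get("transduction", {})),
            orn=OrnParams(**d.get("orn", {})),
            al=AlParams(**d.get("al", {})),
            layout=NetworkLayout(**d.get("layout", {})),
            sim=SimSettings(**d.get("sim", {})),
        )
        p.validate()
        return p

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(text) or {})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def replace(self, **groups) -> "ModelParams":
        """Return a copy with whole parameter groups replaced."""
        p = dataclasses.replace(self, **groups)
        p.validate()
        return p


def default_params() -> ModelParams:
    """Published defaults for transduction, ORNs, antennal lobe and layout."""
    p = ModelParams()
    p.validate()
    return p


def make_variant(name: str, omega_nsi: float = 0.6, alpha_ln: float = 0.6) -> VariantSpec:
    """Build a circuit-variant spec, zeroing strengths as the variant requires.

    ``omega_nsi`` / ``alpha_ln`` are the strengths used *where the variant
    enables the mechanism*; disabled mechanisms are forced to zero.
    """
    if name not in VARIANT_NAMES:
        raise ParameterError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
    omega = omega_nsi if name in ("NSI", "mix") else 0.0
    aln = alpha_ln if name in ("LN", "mix") else 0.0
    v = VariantSpec(name=name, omega_nsi_effective=omega, alpha_ln_effective=aln)
    v.validate()
    return v
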