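"""End-to-end experiment protocols: stimulus -> sensilla -> antennal lobe ->
read-out, for the four circuit variants, with tidy tabular output.

Five experiment families are provided:

step_response      dose series of concentration steps; ORN/PN/LN rates and
                   the PN-vs-ORN sigmoid fit.
ratio_encoding     synchronous triangular two-odorant pulses over a grid of
                   concentration ratios and absolute concentrations;
                   response ratios and the encoding error.
async_pulses       equal-amplitude triangular pulses with channel-B delays;
                   the PN response ratio per delay.
plume_correlation  naturalistic plume pairs over a grid of inter-odorant
                   correlations; average and supra-threshold PN activity.
dynamic_range      single-odorant dose-response of a sensillum with tunable
                   sensitivity asymmetry; thresholds and dynamic range.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (ACTIVITY_WINDOW_MS, avg_activity, dynamic_range_scan,
                       encoding_error, fit_pn_sigmoid, max_activity,
                       peak_activity, sdf)
from .antennal_lobe import AlResult, run_network
from .params import ModelParams, VariantSpec, make_variant
from .plume import PlumeSpec, generate_plume_pair, measure_plume_stats
from .sensillum import SensillumResult, run_sensilla
from .stimuli import DEFAULT_SETTLE_MS, StimulusWaveform, make_step, make_triangles

__all__ = [
    "ExperimentSpec",
    "run_model",
    "run_experiment",
    "compare_variants",
    "EXPERIMENTS",
]

EXPERIMENTS = ("step_response", "ratio_encoding", "async_pulses",
               "plume_correlation", "dynamic_range")

RATIO_GRID = (1.0, 2.0, 3.0, 5.0, 7.0, 10.0)
WEAK_CONC_GRID = tuple(np.logspace(-4.0, np.log10(5e-3), 6))
DELAY_GRID = (0.0, 50.0, 100.0, 200.0, 500.0)
# draw-level copula correlations; the realized series correlation is
# strongly compressed toward 0 for targets < 1 (whiff onsets drift apart as
# durations accumulate), so the grid is weighted toward 1
RHO_GRID = (0.0, 0.9, 0.99, 1.0)


@dataclass
class ExperimentSpec:
    """Configuration of one experiment run."""

    name: str
    variants: tuple = ("control", "NSI", "LN", "mix")
    n_trials: int = 10
    seed: int = 0
    params: ModelParams = field(default_factory=ModelParams)
    overrides: dict = field(default_factory=dict)   # experiment-specific knobs
    out_dir: str | None = None

    def validate(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}; "
                             f"expected one of {EXPERIMENTS}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for v in self.variants:
            make_variant(v)  # raises on unknown names
        self.params.validate()


def run_model(waveform: StimulusWaveform, variant: VariantSpec | str,
              params: ModelParams | None = None, seed: int = 0,
              sens_matrix=None) -> tuple[SensillumResult, AlResult]:
    """Full pipeline: sensilla then antennal lobe for one variant/trial."""
    params = params or ModelParams()
    if isinstance(variant, str):
        variant = make_variant(variant, params.orn.omega_nsi, params.al.alpha_ln)
    orn = run_sensilla(waveform, params, variant, seed=seed,
                       sens_matrix=sens_matrix)
    al = run_network(orn, params, variant, seed=seed)
    return orn, al


def _trial_seed(base: int, *idx) -> int:
    return int(np.random.SeedSequence([base, *idx]).generate_state(1)[0]
               & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# experiment families
# ---------------------------------------------------------------------------

def _exp_step_response(spec: ExperimentSpec) -> pd.DataFrame:
    ov = spec.overrides
    concs = ov.get("concentrations", tuple(np.logspace(-4.6, -1.3, 9)))
    duration = ov.get("duration", 500.0)
    onset = DEFAULT_SETTLE_MS
    dt = spec.params.sim.dt
    rows = []
    for variant in spec.variants:
        for c in concs:
            wf = make_step(c, 0.0, onset, duration, onset + duration + 300.0, dt)
            for trial in range(spec.n_trials):
                seed = _trial_seed(spec.seed, 0, trial)
                orn, al = run_model(wf, variant, spec.params, seed)
                rows.append(dict(
                    experiment="step_response", variant=variant, trial=trial,
                    seed=seed, concentration=c, duration=duration,
                    orn_rate=orn.records["ORN_a"].rates(onset, onset + duration).mean(),
                    pn_rate=al.records["PN_a"].rates(onset, onset + duration).mean(),
                    ln_rate=al.records["LN_a"].rates(onset, onset + duration).mean(),
                ))
    return pd.DataFrame(rows)


def _ratio_row(wf, variant, params, seed, onset, measure="max"):
    orn, al = run_model(wf, variant, params, seed)
    f = max_activity if measure == "max" else avg_activity
    vals = {}
    for pop in ("ORN_a", "ORN_b", "PN_a", "PN_b"):
        rec = orn.records.get(pop) or al.records.get(pop)
        vals[pop] = f(sdf(rec, wf.t), onset)
    return vals


def _exp_ratio_encoding(spec: ExperimentSpec) -> pd.DataFrame:
    ov = spec.overrides
    ratios = ov.get("ratios", RATIO_GRID)
    concs = ov.get("concentrations", WEAK_CONC_GRID)
    duration = ov.get("duration", 50.0)
    measure = ov.get("measure", "max")
    onset = DEFAULT_SETTLE_MS
    dt = spec.params.sim.dt
    t_total = onset + duration + ACTIVITY_WINDOW_MS + 100.0
    rows = []
    for variant in spec.variants:
        for c in concs:
            for ratio in ratios:
                wf = make_triangles(c, c * ratio, duration, 0.0, t_total, dt)
                for trial in range(spec.n_trials):
                    seed = _trial_seed(spec.seed, 1, trial)
                    v = _ratio_row(wf, variant, spec.params, seed, onset, measure)
                    r_orn = v["ORN_b"] / v["ORN_a"] if v["ORN_a"] > 0 else np.nan
                    r_pn = v["PN_b"] / v["PN_a"] if v["PN_a"] > 0 else np.nan
                    err = (encoding_error(r_pn, ratio)
                           if np.isfinite(r_pn) and r_pn > 0 else np.nan)
                    rows.append(dict(
                        experiment="ratio_encoding", variant=variant,
                        trial=trial, seed=seed, concentration=c, ratio=ratio,
                        duration=duration, measure=measure,
                        r_orn=r_orn, r_pn=r_pn, err_enc=err, **{
                            k.lower(): val for k, val in v.items()}))
    return pd.DataFrame(rows)


def _exp_async_pulses(spec: ExperimentSpec) -> pd.DataFrame:
    ov = spec.overrides
    delays = ov.get("delays", DELAY_GRID)
    duration = ov.get("duration", 50.0)
    conc = ov.get("concentration", 2e-3)
    measure = ov.get("measure", "max")
    tau_ln = ov.get("tau_ln", spec.params.al.tau_ln)
    onset = DEFAULT_SETTLE_MS
    params = spec.params
    if tau_ln != params.al.tau_ln:
        import dataclasses as _dc
        params = params.replace(al=_dc.replace(params.al, tau_ln=tau_ln))
    dt = params.sim.dt
    rows = []
    for variant in spec.variants:
        for delay in delays:
            t_total = onset + delay + duration + ACTIVITY_WINDOW_MS + 100.0
            wf = make_triangles(conc, conc, duration, delay, t_total, dt)
            for trial in range(spec.n_trials):
                seed = _trial_seed(spec.seed, 2, trial)
                orn, al = run_model(wf, variant, params, seed)
                f = max_activity if measure == "max" else avg_activity
                # window of each glomerulus referenced to its own pulse onset
                nu_a = f(sdf(al.records["PN_a"], wf.t), onset)
                nu_b = f(sdf(al.records["PN_b"], wf.t), onset + delay)
                rows.append(dict(
                    experiment="async_pulses", variant=variant, trial=trial,
                    seed=seed, delay=delay, duration=duration,
                    concentration=conc, tau_ln=tau_ln, measure=measure,
                    pn_a=nu_a, pn_b=nu_b,
                    r_pn=nu_b / nu_a if nu_a > 0 else np.nan))
    return pd.DataFrame(rows)


def _exp_plume_correlation(spec: ExperimentSpec) -> pd.DataFrame:
    ov = spec.overrides
    rhos = ov.get("rhos", RHO_GRID)
    t_total_s = ov.get("t_total_s", 200.0)
    whiff_max = ov.get("whiff_max", 3.0)
    mean_conc = ov.get("mean_conc", 1.5e-3)
    thresholds = ov.get("thresholds", (50.0, 100.0, 150.0))
    dt = spec.params.sim.dt
    rows = []
    # common random numbers across rho: with a shared trial seed the copula
    # keeps channel A identical across correlation levels, so the
    # correlation effect is not confounded by plume-realization noise
    for rho in rhos:
        for trial in range(spec.n_trials):
            pseed = _trial_seed(spec.seed, 3, trial)
            wf = generate_plume_pair(PlumeSpec(
                rho_target=rho, t_total=t_total_s, whiff_max=whiff_max,
                mean_conc=mean_conc, dt=dt, seed=pseed))
            stats = measure_plume_stats(wf, fit_exponent=False)
            orn_cache = {}
            for variant in spec.variants:
                vs = make_variant(variant, spec.params.orn.omega_nsi,
                                  spec.params.al.alpha_ln)
                key = vs.omega_nsi_effective
                if key not in orn_cache:
                    orn_cache[key] = run_sensilla(wf, spec.params, vs, seed=pseed)
                orn = orn_cache[key]
                al = run_network(orn, spec.params, vs, seed=pseed)
                t_end = wf.t[-1]
                pn_tr = sdf(al.records["PN_a"], wf.t)
                row = dict(
                    experiment="plume_correlation", variant=variant,
                    trial=trial, seed=pseed, rho_target=rho,
                    rho_realized=stats.rho_realized,
                    intermittency_a=stats.intermittency[0],
                    t_total_s=t_total_s, whiff_max=whiff_max,
                    orn_rate=orn.records["ORN_a"].rates(0, t_end).mean(),
                    pn_rate=al.records["PN_a"].rates(0, t_end).mean(),
                )
                for thr in thresholds:
                    row[f"peak_pn_{int(thr)}"] = peak_activity(pn_tr, thr)
                rows.append(row)
    return pd.DataFrame(rows)


def _exp_dynamic_range(spec: ExperimentSpec) -> pd.DataFrame:
    ov = spec.overrides
    sens_pairs = ov.get("sens_pairs", ((1.0, 1.0), (1.0, 1e-2)))
    durations = ov.get("durations", (50.0,))
    conc_grid = ov.get("conc_grid", np.logspace(-5, 0, 16))
    variants = [v for v in spec.variants if v in ("control", "NSI")]
    rows = []
    for variant in variants:
        for sa, sb in sens_pairs:
            scan = dynamic_range_scan((sa, sb), variant, conc_grid,
                                      spec.params, durations, seed=spec.seed,
                                      n_trials=spec.n_trials)
            for dur, res in scan.items():
                for which in ("orn_a", "orn_b", "combined"):
                    r = res[which]
                    rows.append(dict(
                        experiment="dynamic_range", variant=variant,
                        sens_a=sa, sens_b=sb, duration=dur, curve=which,
                        C_l=r.C_l, C_h=r.C_h, dynamic_range=r.dynamic_range,
                        sd=res["sd"], seed=spec.seed))
    return pd.DataFrame(rows)


_RUNNERS = {
    "step_response": _exp_step_response,
    "ratio_encoding": _exp_ratio_encoding,
    "async_pulses": _exp_async_pulses,
    "plume_correlation": _exp_plume_correlation,
    "dynamic_range": _exp_dynamic_range,
}


def run_experiment(spec: ExperimentSpec, verbose: bool = False) -> pd.DataFrame:
    """Run one experiment family; optionally write tidy CSV plus a JSON
    manifest (config hash, seeds, timing) to ``spec.out_dir``."""
    spec.validate()
    t0 = time.time()
    df = _RUNNERS[spec.name](spec)
    elapsed = time.time() - t0
    if verbose:
        print(f"[nsinet] {spec.name}: {len(df)} rows in {elapsed:.1f} s")
    if spec.out_dir is not None:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / f"{spec.name}.csv"
        df.to_csv(csv_path, index=False)
        cfg = dict(experiment=spec.name, variants=list(spec.variants),
                   n_trials=spec.n_trials, seed=spec.seed,
                   overrides={k: (list(v) if isinstance(v, (tuple, np.ndarray))
                                  else v) for k, v in spec.overrides.items()},
                   params=spec.params.to_dict())
        blob = json.dumps(cfg, sort_keys=True, default=float)
        manifest = dict(config=json.loads(blob),
                        config_sha256=hashlib.sha256(blob.encode()).hexdigest(),
                        elapsed_s=elapsed, rows=len(df),
                        csv=str(csv_path.name))
        (out / f"{spec.name}.manifest.json").write_text(
            json.dumps(manifest, indent=2, default=float))
    return df


def measure_step_latency(params: ModelParams | None = None, conc: float = 2e-3,
                         n_seeds: int = 10, seed: int = 0) -> float:
    """Mean onset-to-peak latency (ms) of the ORN population SDF for a
    500 ms concentration step, averaged over ``n_seeds`` runs."""
    from .analysis import sdf, step_latency
    params = params or ModelParams()
    onset = DEFAULT_SETTLE_MS
    dt = params.sim.dt
    wf = make_step(conc, 0.0, onset, 500.0, onset + 800.0, dt)
    lats = []
    for k in range(n_seeds):
        res = run_sensilla(wf, params, "control", seed=_trial_seed(seed, 4, k))
        pop = sdf(res.records["ORN_a"], wf.t).pop_rate
        lats.append(step_latency(pop, onset, dt))
    return float(np.mean(lats))


def measure_ramp_settle(params: ModelParams | None = None,
                        conc_end: float = 2e-2, ramp_ms: float = 2000.0,
                        n_seeds: int = 10, seed: int = 0) -> float:
    """Initial-transient duration (ms) of the ORN population response to a
    2 s linear ramp, from the seed-averaged population SDF.

    The ramp rises into the saturating concentration range so that the
    rate settles to a genuine plateau after the onset transient.
    """
    from .analysis import ramp_settle_time, sdf
    from .stimuli import make_ramp
    params = params or ModelParams()
    onset = DEFAULT_SETTLE_MS
    dt = params.sim.dt
    wf = make_ramp(conc_end / ramp_ms, onset, ramp_ms,
                   onset + ramp_ms + 500.0, dt)
    acc = None
    for k in range(n_seeds):
        res = run_sensilla(wf, params, "control", seed=_trial_seed(seed, 5, k))
        pop = sdf(res.records["ORN_a"], wf.t).pop_rate
        acc = pop if acc is None else acc + pop
    return ramp_settle_time(acc / n_seeds, onset, dt,
                            search=ramp_ms - 200.0)


def compare_variants(df: pd.DataFrame, metric: str = "err_enc",
                     n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Rank variants by the mean of ``metric`` with a bootstrap CI over
    trials. Expects a tidy frame holding >= 2 variants on identical
    conditions (same stimuli and trial seeds)."""
    if "variant" not in df.columns or metric not in df.columns:
        raise ValueError("frame must have 'variant' and metric columns")
    variants = df["variant"].unique()
    if len(variants) < 2:
        raise ValueError("need results from at least 2 variants")
    rng = np.random.default_rng(seed)
    rows = []
    for v in variants:
        vals = df.loc[df["variant"] == v, metric].dropna().to_numpy()
        boot = np.array([rng.choice(vals, len(vals)).mean()
                         for _ in range(n_boot)])
        rows.append(dict(variant=v, metric=metric, mean=vals.mean(),
                         ci_lo=np.quantile(boot, 0.025),
                         ci_hi=np.quantile(boot, 0.975), n=len(vals)))
    out = pd.DataFrame(rows).sort_values("mean").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
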