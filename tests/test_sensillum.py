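import numpy as np
import pytest

from nsinet.params import VariantSpec, default_params
from nsinet.sensillum import (OrnState, SpikeRecord, nsi_reversal,
                              run_sensilla, step_orn, step_transduction,
                              save_spikes_hdf5, load_spikes_hdf5)
from nsinet.stimuli import make_step
from nsinet.analysis import sdf


class TestTransduction:
    def test_pure_unbinding_decay(self, params):
        """With zero concentration (offset off) r decays at rate beta_r."""
        r, dt = 0.8, 0.1
        r1 = step_transduction(r, 0.0, params, dt, include_c0=False)
        assert r1 == pytest.approx(r * (1 - dt * params.transduction.beta_r))

    def test_steady_state_matches_closed_form(self, params):
        tp = params.transduction
        c = 1e-3
        drive = tp.alpha_r * (c + tp.c0) ** tp.n
        expected = drive / (drive + tp.beta_r)
        r = 0.0
        for _ in range(200000):
            r = step_transduction(r, c, params, 0.1)
        assert r == pytest.approx(expected, rel=1e-3)

    def test_half_activation_concentration(self, params):
        """alpha_r c^n = beta_r at c ~ 1.99e-3, giving steady state r = 1/2."""
        r = 0.0
        for _ in range(200000):
            r = step_transduction(r, 1.99e-3, params, 0.1, include_c0=False)
        assert r == pytest.approx(0.5, abs=0.01)

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ValueError):
            step_transduction(0.1, -1.0, params, 0.1)


class TestNsiReversal:
    def test_zero_strength_identity(self):
        assert nsi_reversal(0.0, -33.0, 0.0, 0.9) == 0.0

    def test_full_shunt_limit(self):
        assert nsi_reversal(0.0, -33.0, 1.0, 1.0) == pytest.approx(-33.0)

    def test_direct_evaluation(self):
        assert nsi_reversal(0.0, -33.0, 0.6, 0.5) == pytest.approx(-9.9)


class TestStepOrn:
    def test_leak_only_equilibrium(self, params):
        st = OrnState(V=params.orn.V_rest)
        for _ in range(1000):
            st, spiked = step_orn(st, 0.0, 0.0, params, 0.0, 0.1)
            assert not spiked
        assert st.V == pytest.approx(params.orn.V_rest)

    def test_spike_increments_adaptation_by_impulse_area(self, params):
        st = OrnState(V=params.orn.theta - 1e-6, y=0.0)
        # strong drive guarantees a spike within a step
        st2, spiked = step_orn(st, 1.0, 0.0, params, 0.0, 0.5)
        assert spiked
        assert st2.y == pytest.approx(params.orn.y_jump, rel=1e-9)
        assert st2.refr == params.orn.tau_ref

    def test_interspike_interval_matches_lif_closed_form(self, params):
        """Constant r=1, no noise, no adaptation: the conductance-based LIF
        has ISI = tau_ref + tau_m ln((V_inf - V_rest)/(V_inf - theta))."""
        import dataclasses
        p = params.replace(orn=dataclasses.replace(params.orn, g_y=0.0))
        op = p.orn
        g = op.gl + op.g_r
        v_inf = (op.gl * op.V_rest + op.g_r * op.V_rev) / g
        tau_m = op.C / g
        expected = op.tau_ref + tau_m * np.log(
            (v_inf - op.V_rest) / (v_inf - op.theta))
        dt = 0.01
        st = OrnState(V=op.V_rest)
        spikes = []
        for i in range(int(20.0 / dt)):
            st, spiked = step_orn(st, 1.0, 0.0, p, 0.0, dt)
            if spiked:
                spikes.append(i * dt)
        isis = np.diff(spikes)
        assert isis.std() < 2 * dt
        assert isis.mean() == pytest.approx(expected, abs=2 * dt)

    def test_nonfinite_state_signalled(self, params):
        with pytest.raises(FloatingPointError):
            step_orn(OrnState(V=np.nan), 0.5, 0.0, params, 0.0, 0.1)


class TestRunSensilla:
    def test_zero_nsi_equals_control_bit_exactly(self, params, step_waveform):
        a = run_sensilla(step_waveform, params, "control", seed=3)
        nsi_off = VariantSpec("NSI", 0.0, 0.0)
        b = run_sensilla(step_waveform, params, nsi_off, seed=3)
        assert np.array_equal(a.raster, b.raster)

    def test_step_response_peaks_then_decays_to_plateau(self, params,
                                                        step_run, step_waveform):
        pop = sdf(step_run.records["ORN_a"], step_waveform.t).pop_rate
        on = int(500.0 / 0.1)
        peak = pop[on:on + 2000].max()
        plateau = pop[on + 4000:on + 4900].mean()
        spont = pop[1000:on - 200].mean()
        assert peak > 1.5 * plateau > 1.5 * spont

    def test_refractoriness_respected(self, step_run, params):
        for rec in step_run.records.values():
            for tr in rec.trains:
                if len(tr) > 1:
                    assert np.diff(tr).min() >= params.orn.tau_ref

    def test_receptor_activation_bounded(self, step_run):
        assert step_run.r_mean.min() >= 0.0
        assert step_run.r_mean.max() <= 1.0
        assert step_run.y_mean.min() >= 0.0

    def test_dose_response_monotone_in_concentration(self, params):
        rates = []
        for c in (2e-4, 1e-3, 5e-3, 2e-2):
            wf = make_step(c, 0.0, 500.0, 500.0, 1100.0, 0.1)
            res = run_sensilla(wf, params, "control", seed=4)
            rates.append(res.records["ORN_a"].rates(500.0, 1000.0).mean())
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_nsi_mutual_inhibition(self, params):
        """Both channels active: each ORN fires no more than in the control
        variant with the same noise stream."""
        wf = make_step(2e-3, 2e-3, 500.0, 500.0, 1100.0, 0.1)
        ctrl = run_sensilla(wf, params, "control", seed=5)
        nsi = run_sensilla(wf, params, "NSI", seed=5)
        for pop in ("ORN_a", "ORN_b"):
            assert (nsi.records[pop].rates(500.0, 1000.0).mean()
                    <= ctrl.records[pop].rates(500.0, 1000.0).mean())

    def test_unstimulated_partner_suppressed_below_spontaneous(self, params):
        wf = make_step(2e-3, 0.0, 500.0, 500.0, 1100.0, 0.1)
        rates = []
        for seed in range(3):
            res = run_sensilla(wf, params, "NSI", seed=seed)
            rates.append((res.records["ORN_b"].rates(500.0, 1000.0).mean(),
                          res.records["ORN_b"].rates(0.0, 490.0).mean()))
        evoked, spont = np.array(rates).T
        assert evoked.mean() < spont.mean()


class TestSpikeRecordIO:
    def test_text_round_trip(self, tmp_path, step_run):
        rec = step_run.records["ORN_a"]
        path = tmp_path / "spikes.txt"
        rec.to_text(path)
        back = SpikeRecord.from_text(path, label="ORN_a",
                                     n_neurons=rec.n_neurons)
        assert back.n_neurons == rec.n_neurons
        for a, b in zip(back.trains, rec.trains):
            assert np.allclose(a, b, atol=1e-4)

    def test_hdf5_round_trip(self, tmp_path, step_run):
        path = tmp_path / "spikes.h5"
        save_spikes_hdf5(path, step_run.records)
        back = load_spikes_hdf5(path)
        assert set(back) == set(step_run.records)
        for k in back:
            for a, b in zip(back[k].trains, step_run.records[k].trains):
                assert np.array_equal(a, b)
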