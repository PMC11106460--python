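"""Sweep feature extraction against the model's closed forms."""

import numpy as np
import pytest

from ca1pyr import (
    APTemplate, MembraneParams, SweepSet, analytic_impedance,
    analytic_sag_ratio, calibrate_h_conductance, detect_spikes,
    impedance_profile, inject_ap_templates, passive_features,
    rheobase_and_ap_features, resonance_argmax, sag_features,
    select_sag_sweep, simulate_chirp, simulate_membrane, simulate_step_family,
)
from ca1pyr.sweeps import Sweep, step_current


def _random_resonant_params(rng):
    return MembraneParams(
        c_pf=float(rng.uniform(300, 800)),
        g_l_ns=float(rng.uniform(15, 40)),
        g_h_ns=float(rng.uniform(5, 60)),
        tau_h_ms=float(rng.uniform(30, 90)),
    )


class TestPassive:
    def test_input_resistance_by_ohms_law(self):
        p = MembraneParams(c_pf=500, g_l_ns=25, g_h_ns=0)  # 40 MΩ
        feats = passive_features(simulate_step_family(p))
        assert feats.input_resistance_mohm == pytest.approx(40.0, rel=0.01)
        assert feats.resting_potential_mv == pytest.approx(-70.0, abs=1e-6)

    def test_time_constant_from_fit(self):
        p = MembraneParams(c_pf=500, g_l_ns=25, g_h_ns=0)  # C/g_L = 20 ms
        feats = passive_features(simulate_step_family(p))
        assert feats.tau_ms == pytest.approx(20.0, rel=0.05)

    def test_missing_target_sweep_uses_nearest(self):
        p = MembraneParams(c_pf=500, g_l_ns=25, g_h_ns=0)
        fam = simulate_step_family(p, amps_pa=[-150.0, -100.0, -50.0])
        with pytest.warns(UserWarning, match="nearest"):
            feats = passive_features(fam)
        assert feats.input_resistance_mohm == pytest.approx(40.0, rel=0.01)

    def test_no_hyperpolarizing_sweep_is_error(self):
        p = MembraneParams(g_h_ns=0)
        fam = simulate_step_family(p, amps_pa=[50.0])
        with pytest.raises(ValueError):
            passive_features(fam)


class TestSagSweepSelection:
    def _fake_sweep(self, ss_mv, amp_pa, fs=1000.0):
        t, i, on, off = step_current(amp_pa, fs=fs)
        v = np.full_like(t, -70.0)
        v[(t >= on) & (t < off)] = -70.0 + ss_mv
        return Sweep(t=t, i=i, v=v, fs=fs, onset=on, offset=off)

    def test_nearest_to_minus_3(self):
        sweeps = SweepSet([self._fake_sweep(-1.0, -25), self._fake_sweep(-2.8, -75),
                           self._fake_sweep(-5.0, -125)])
        assert select_sag_sweep(sweeps).step_amplitude() == pytest.approx(-75.0)

    def test_single_sweep_returned(self):
        sweeps = SweepSet([self._fake_sweep(-1.0, -25)])
        assert select_sag_sweep(sweeps) is sweeps.sweeps[0]

    def test_simulated_family_on_40_mohm_model(self):
        """ΔV_ss = R·I: the −75 pA sweep of a 40 MΩ cell sits at −3.0 mV."""
        p = MembraneParams(c_pf=500, g_l_ns=25, g_h_ns=0)
        chosen = select_sag_sweep(simulate_step_family(p))
        assert chosen.step_amplitude() == pytest.approx(-75.0)


class TestSagFeatures:
    def test_passive_cell_has_no_sag(self):
        p = MembraneParams(c_pf=500, g_l_ns=25, g_h_ns=0)
        # monotone charging: the minimum sits on the search-window edge,
        # which the extractor reports while widening the window
        with pytest.warns(UserWarning, match="widened"):
            sf = sag_features(select_sag_sweep(simulate_step_family(p)))
        assert sf.sag_ratio == pytest.approx(0.0, abs=1e-3)

    def test_matches_two_exponential_closed_form(self):
        """Extracted ratio within 2% of the eigen-decomposition oracle over
        20 random resonant parameter draws."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = _random_resonant_params(rng)
            ref = analytic_sag_ratio(p)
            sf = sag_features(select_sag_sweep(simulate_step_family(p, fs_hz=5000.0)))
            assert sf.sag_ratio == pytest.approx(ref, rel=0.02, abs=2e-3)

    def test_ratio_definition(self):
        p = MembraneParams(c_pf=500, g_l_ns=25, g_h_ns=30, tau_h_ms=60)
        sf = sag_features(select_sag_sweep(simulate_step_family(p, fs_hz=5000.0)))
        assert sf.sag_ratio == pytest.approx(
            sf.delta_sag_peak_mv / sf.delta_steady_state_mv, rel=1e-9)


class TestImpedanceProfile:
    def test_zap_matches_closed_form_within_2_percent(self):
        """|Z(f)| from the FFT ratio vs. the analytic impedance, 20 draws."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = _random_resonant_params(rng)
            prof = impedance_profile(simulate_chirp(p, fs_hz=5000.0))
            ref = np.abs(analytic_impedance(p, prof.f_hz))
            assert np.max(np.abs(prof.impedance_mohm - ref) / ref) <= 0.02
            f_ref = resonance_argmax(p)
            if f_ref > 0.6:  # analytic peak inside the stimulated band
                assert prof.f_res_hz == pytest.approx(f_ref, abs=0.1)

    def test_passive_profile_is_low_pass_and_non_resonant(self):
        p = MembraneParams(c_pf=500, g_l_ns=25, g_h_ns=0)
        prof = impedance_profile(simulate_chirp(p, fs_hz=5000.0))
        assert not prof.resonant
        assert prof.f_res_hz == pytest.approx(prof.f_hz[0], abs=1e-9)
        assert np.all(np.diff(prof.impedance_mohm) < 1e-6)

    def test_f_res_invariant_to_chirp_variant(self):
        p = calibrate_h_conductance(2.9, MembraneParams(c_pf=500, g_l_ns=25,
                                                        g_h_ns=0, tau_h_ms=50))
        f_a = impedance_profile(simulate_chirp(p, f1_hz=30.0, dur_s=10.0,
                                               fs_hz=5000.0)).f_res_hz
        f_b = impedance_profile(simulate_chirp(p, f1_hz=40.0, dur_s=20.0,
                                               fs_hz=5000.0)).f_res_hz
        assert f_a == pytest.approx(f_b, abs=0.1)

    def test_h_block_abolishes_resonance(self):
        """Zeroing the h-conductance (pharmacological HCN block in the
        model) flips a resonant cell to non-resonant."""
        p = calibrate_h_conductance(2.9, MembraneParams(c_pf=500, g_l_ns=25,
                                                        g_h_ns=0, tau_h_ms=50))
        assert impedance_profile(simulate_chirp(p, fs_hz=5000.0)).resonant
        blocked = MembraneParams(c_pf=p.c_pf, g_l_ns=p.g_l_ns, g_h_ns=0.0,
                                 tau_h_ms=p.tau_h_ms)
        assert not impedance_profile(simulate_chirp(blocked, fs_hz=5000.0)).resonant

    def test_step_sweep_rejected(self):
        p = MembraneParams()
        t, i, on, off = step_current(-25.0, fs=1000.0)
        sw = simulate_membrane(p, t, i, on, off, "step", 1000.0)
        with pytest.raises(ValueError):
            impedance_profile(sw)


class TestSpikes:
    p = MembraneParams(c_pf=500, g_l_ns=25, g_h_ns=0)

    def _step(self, amp, fs=20000.0, **kw):
        t, i, on, off = step_current(amp, fs=fs)
        return simulate_membrane(kw.pop("params", self.p), t, i, on, off, "step", fs)

    def test_subthreshold_sweep_has_no_spikes(self):
        assert len(detect_spikes(self._step(100.0))) == 0

    def test_injected_templates_detected_at_peaks(self):
        sw, truth = inject_ap_templates(self._step(300.0), APTemplate(),
                                        [0.3, 0.6, 0.9])
        times = detect_spikes(sw)
        assert len(times) == 3
        assert np.max(np.abs(times - truth["spike_times_s"])) <= 1.0 / sw.fs

    def test_noise_only_specificity(self):
        """No false detections on 0.3 mV noise across 100 seeds."""
        total = 0
        for seed in range(100):
            params = MembraneParams(c_pf=500, g_l_ns=25, g_h_ns=0,
                                    noise_sd_mv=0.3, seed=seed)
            total += len(detect_spikes(self._step(100.0, fs=10000.0,
                                                  params=params)))
        assert total == 0


class TestAPFeatures:
    base = MembraneParams(c_pf=500, g_l_ns=25, g_h_ns=0)

    def _rheo_family(self, template, spike_times, rheo=300.0):
        sweeps = []
        truth = None
        for amp in (100.0, 200.0, rheo):
            t, i, on, off = step_current(amp)
            sw = simulate_membrane(self.base, t, i, on, off, "step")
            if amp == rheo:
                sw, truth = inject_ap_templates(sw, template, spike_times)
            sweeps.append(sw)
        return SweepSet(sweeps), truth

    def test_rheobase_is_first_spiking_sweep(self):
        fam, _ = self._rheo_family(APTemplate(), [0.5])
        assert rheobase_and_ap_features(fam).rheobase_pa == pytest.approx(300.0)

    def test_template_recovery_within_2_percent(self):
        """Threshold/amplitude/halfwidth/up/downstroke vs. the dense-sampled
        template oracle, over amplitudes 60-100 mV and a range of widths."""
        rng = np.random.default_rng(3)
        for _ in range(12):
            amp = rng.uniform(60, 100)
            tpl = APTemplate(peak_mv=-70 + amp + rng.uniform(10, 20),
                             rise_w_ms=rng.uniform(0.35, 0.8),
                             fall_w_ms=rng.uniform(0.7, 2.0))
            fam, truth = self._rheo_family(tpl, [0.45])
            ap = rheobase_and_ap_features(fam)
            assert ap.threshold_mv == pytest.approx(truth["threshold_mv"], rel=0.02)
            assert ap.amplitude_mv == pytest.approx(truth["amplitude_mv"], rel=0.02)
            assert ap.halfwidth_ms == pytest.approx(truth["halfwidth_ms"], rel=0.02)
            assert ap.upstroke_mv_per_ms == pytest.approx(
                truth["upstroke_mv_per_ms"], rel=0.02)
            assert ap.downstroke_mv_per_ms == pytest.approx(
                truth["downstroke_mv_per_ms"], rel=0.02)
            assert ap.upstroke_mv_per_ms > 0 > ap.downstroke_mv_per_ms

    def test_fast_doublet_flags_burst_candidate(self):
        """Two spikes 9.4 ms apart: instantaneous frequency > 100 Hz."""
        fam, _ = self._rheo_family(APTemplate(rise_w_ms=0.4, fall_w_ms=0.7),
                                   [0.5, 0.5094])
        ap = rheobase_and_ap_features(fam)
        assert ap.inst_freq_hz > 100.0
        assert ap.meta["burst_candidate"]

    def test_threshold_stable_under_doubled_sampling(self):
        tpl = APTemplate()
        thresholds = []
        for fs in (20000.0, 40000.0):
            t, i, on, off = step_current(300.0, fs=fs)
            sw = simulate_membrane(self.base, t, i, on, off, "step", fs)
            sw, _ = inject_ap_templates(sw, tpl, [0.45])
            thresholds.append(rheobase_and_ap_features(SweepSet([sw])).threshold_mv)
        assert abs(thresholds[0] - thresholds[1]) < 0.5

    def test_no_spike_up_to_max_is_flagged_missing(self):
        fam = simulate_step_family(self.base, amps_pa=[100.0, 200.0])
        with pytest.warns(UserWarning, match="no spike"):
            ap = rheobase_and_ap_features(fam)
        assert np.isnan(ap.rheobase_pa) and np.isnan(ap.threshold_mv)
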