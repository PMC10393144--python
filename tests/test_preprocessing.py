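"""Filtering, epoching, baseline, rejection and channel repair."""

import numpy as np
import pandas as pd
import pytest

from esport_erp import preprocessing as pp
from esport_erp.data import EPOCH_SPECS, EpochSet
from esport_erp.montage import CHANNELS_32
from esport_erp.synthetic import SimulationConfig, generate_epochs


def _freq_response(taps, f, srate):
    w = 2 * np.pi * f / srate
    n = np.arange(taps.size)
    return np.abs(np.sum(taps * np.exp(-1j * w * n)))


class TestFIRDesign:
    def test_lowpass_stopband_attenuation(self):
        taps = pp.design_fir(pp.DEFAULT_LOWPASS, 250.0)
        gain_pass = _freq_response(taps, 10.0, 250.0)
        gain_stop = _freq_response(taps, 60.0, 250.0)
        assert 20 * np.log10(gain_pass / gain_stop) >= 50.0

    def test_lowpass_passband_within_one_percent(self):
        taps = pp.design_fir(pp.DEFAULT_LOWPASS, 250.0)
        t = np.arange(2000) / 250.0
        x = np.sin(2 * np.pi * 10.0 * t)
        y = pp.apply_fir(x, taps)
        amp = y[500:1500].max()
        assert amp == pytest.approx(1.0, abs=0.01)

    def test_highpass_kills_dc(self):
        taps = pp.design_fir(pp.DEFAULT_HIGHPASS, 250.0)
        y = pp.apply_fir(np.full(8000, 7.5), taps)
        assert np.abs(y[3000:5000]).max() < 7.5e-3

    def test_dc_gains(self):
        lp = pp.design_fir(pp.DEFAULT_LOWPASS, 250.0)
        hp = pp.design_fir(pp.DEFAULT_HIGHPASS, 250.0)
        assert lp.sum() == pytest.approx(1.0, abs=1e-6)
        assert hp.sum() == pytest.approx(0.0, abs=5e-3)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.design_fir(pp.FilterSpec("lowpass", 130.0, 184), 250.0)

    def test_zero_phase_preserves_pulse_center(self):
        taps = pp.design_fir(pp.DEFAULT_LOWPASS, 250.0)
        x = np.zeros(500)
        x[240:261] = np.hanning(21)  # symmetric pulse centred at 250
        y = pp.apply_fir(x, taps)
        com_x = np.sum(np.arange(500) * x) / x.sum()
        com_y = np.sum(np.arange(500) * np.abs(y)) / np.abs(y).sum()
        assert abs(com_x - com_y) <= 1.0


class TestEpoching:
    def test_brb_epoch_has_200_samples(self):
        assert EPOCH_SPECS["B/RB"].n_samples(250.0) == 200

    def test_constant_offset_baselined_to_zero(self, profiles):
        e = generate_epochs(SimulationConfig(seed=0, noise_amplitude_uV=0,
                                             alpha_amplitude_uV=0),
                            "B/RB", {g: profiles[g].scaled_sds(0) for g in profiles},
                            n_targets=2, n_nontargets=2)
        e.data += 42.0  # constant offset everywhere
        out = pp.baseline_correct(e)
        pre = out.times_ms < 0
        assert np.allclose(out.data[:, pre, :][:, -10:, :], 0.0, atol=1e-9)

    def test_baseline_idempotent(self, small_st_epochs):
        once = pp.baseline_correct(small_st_epochs)
        twice = pp.baseline_correct(once)
        assert np.allclose(once.data, twice.data)

    def test_first_two_events_per_block_excluded(self):
        srate = 250.0
        cont = np.random.default_rng(0).normal(size=(32, 25000))
        events = pd.DataFrame({
            "sample": np.arange(10) * 2000 + 1000,
            "is_target": [True] * 10,
            "block": [0] * 5 + [1] * 5,
        })
        out = pp.epoch_and_baseline(cont, srate, events, EPOCH_SPECS["B/RB"])
        assert out.n_trials == 10 - 2 * 2

    def test_edge_events_dropped(self):
        cont = np.zeros((32, 1000))
        events = pd.DataFrame({"sample": [10, 500, 995],
                               "is_target": [True] * 3})
        out = pp.epoch_and_baseline(cont, 250.0, events, EPOCH_SPECS["B/RB"],
                                    exclude_first=0)
        assert out.n_trials == 1  # only the middle event fits


class TestRejection:
    def _flat_set(self, n_trials=10):
        data = np.zeros((32, 100, n_trials))
        return EpochSet(data=data, srate=250.0,
                        times_ms=np.arange(100) * 4.0 - 100.0,
                        channels=CHANNELS_32,
                        trials=pd.DataFrame({
                            "subject": ["s0"] * (n_trials // 2) + ["s1"] * (n_trials - n_trials // 2),
                            "group": ["PRO"] * n_trials,
                            "target": [True] * n_trials,
                            "index": np.arange(n_trials)}))

    def test_planted_spikes_rejected_exactly(self):
        e = self._flat_set(10)
        e.data += np.random.default_rng(1).normal(0, 3, size=e.data.shape)
        for k in (1, 3, 5, 6, 8):
            e.data[4, 50, k] += 800.0
        out, rep = pp.reject_epochs(e, threshold_uv=500.0)
        assert (~out.retained).sum() == 5
        assert set(np.flatnonzero(~out.retained)) == {1, 3, 5, 6, 8}

    def test_small_amplitudes_survive(self):
        e = self._flat_set()
        e.data += np.random.default_rng(2).uniform(-10, 10, size=e.data.shape)
        out, rep = pp.reject_epochs(e)
        assert out.retained.all()
        assert (rep["rejected_fraction"] == 0).all()

    def test_monotone_in_threshold(self):
        e = self._flat_set()
        spikes = [100, 200, 300, 400, 450, 100, 600, 700, 850, 900]
        for k, a in enumerate(spikes):
            e.data[3, 40, k] = a
        strict, _ = pp.reject_epochs(e, threshold_uv=400.0)
        loose, _ = pp.reject_epochs(e, threshold_uv=800.0)
        # anything rejected at the loose threshold is rejected at the strict one
        assert not np.any(~loose.retained & strict.retained)
        assert (~strict.retained).sum() > (~loose.retained).sum()

    def test_total_loss_for_subject_raises(self):
        e = self._flat_set(4)
        e.data[0, 0, :2] = 1000.0  # wipe out subject s0 entirely
        with pytest.raises(ValueError, match="s0"):
            pp.reject_epochs(e)


class TestChannelRepair:
    def test_planted_noisy_channel_flagged(self):
        rng = np.random.default_rng(4)
        data = rng.normal(0, 5, size=(32, 200, 20))
        data[7] = rng.normal(0, 50, size=(200, 20))  # FC5 10x noise
        e = EpochSet(data=data, srate=250.0,
                     times_ms=np.arange(200) * 4.0 - 100.0)
        out, flagged = pp.flag_and_interpolate_channels(e)
        assert flagged == ["FC5"]

    def test_homogeneous_channels_untouched(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 5, size=(32, 200, 10))
        e = EpochSet(data=data, srate=250.0,
                     times_ms=np.arange(200) * 4.0 - 100.0)
        out, flagged = pp.flag_and_interpolate_channels(e)
        assert flagged == []
        assert np.array_equal(out.data, e.data)

    def test_interpolated_channel_tracks_neighbors(self):
        # smooth spatial pattern: every channel = common signal, one ruined
        rng = np.random.default_rng(6)
        common = rng.normal(0, 5, size=(200, 10))
        data = np.tile(common, (32, 1, 1))
        data += rng.normal(0, 0.5, size=data.shape)  # small sensor noise
        data[22] = rng.normal(0, 60, size=(200, 10))  # Pz destroyed
        e = EpochSet(data=data, srate=250.0,
                     times_ms=np.arange(200) * 4.0 - 100.0)
        out, flagged = pp.flag_and_interpolate_channels(e)
        assert "Pz" in flagged
        r = np.corrcoef(out.data[22].ravel(), common.ravel())[0, 1]
        assert r > 0.99

    def test_at_most_two_channels_interpolated(self):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 5, size=(32, 200, 10))
        for ch in (2, 9, 15):
            data[ch] = rng.normal(0, 80, size=(200, 10))
        e = EpochSet(data=data, srate=250.0,
                     times_ms=np.arange(200) * 4.0 - 100.0)
        out, flagged = pp.flag_and_interpolate_channels(e)
        assert len(flagged) == 2
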