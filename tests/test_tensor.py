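"""Trial tensors and CPD with orthogonal spatial factors."""

import numpy as np
import pandas as pd
import pytest

from esport_erp import tensor
from esport_erp.data import EpochSet
from esport_erp.tensor import (FactorModel, TrialTensor, build_order3,
                               build_order4, explained_fit, fit_cpd,
                               subject_power, subject_power_and_test)
from esport_erp.vmd import FREQ_GRID_HZ


def _labels(n, groups=("PRO", "NOVICE"), per_subject=5):
    rows = []
    k = 0
    while len(rows) < n:
        g = groups[(k // per_subject) % len(groups)]
        rows.append((f"{g}_{k // (per_subject * 2):02d}", g))
        k += 1
    return pd.DataFrame(rows[:n], columns=["subject", "group"])


def _rank_tensor(shapes, rank, rng, orthogonal_spatial=True):
    factors = [rng.standard_normal((s, rank)) for s in shapes]
    if orthogonal_spatial:
        factors[0], _ = np.linalg.qr(factors[0])
    x = np.einsum("ir,jr,kr->ijk", *factors)
    return x, factors


def congruence(a, b):
    """Max-matched absolute column cosine between two factor matrices."""
    an = a / np.linalg.norm(a, axis=0)
    bn = b / np.linalg.norm(b, axis=0)
    c = np.abs(an.T @ bn)
    # greedy matching is enough at these ranks
    out = []
    used = set()
    for i in range(c.shape[0]):
        j = int(np.argmax([c[i, j] if j not in used else -1
                           for j in range(c.shape[1])]))
        used.add(j)
        out.append(c[i, j])
    return min(out)


class TestBuildTensors:
    def test_order3_shape_and_pooling(self, small_st_epochs):
        t3 = build_order3(small_st_epochs)
        assert t3.data.shape[0] == 32
        assert t3.data.shape[1] == 251  # -100..+900 ms at 250 Hz
        # target trials of both groups pooled: 20 subjects x 8 targets
        assert t3.data.shape[2] == 20 * 8
        assert t3.axes["times_ms"][0] == pytest.approx(-100.0)
        assert t3.axes["times_ms"][-1] == pytest.approx(900.0)

    def test_constant_epochs_become_zero_tensor(self):
        data = np.full((32, 351, 6), 3.14)
        e = EpochSet(data=data, srate=250.0,
                     times_ms=-500 + np.arange(351) * 4.0)
        t3 = build_order3(e)
        assert np.allclose(t3.data, 0.0)

    def test_short_epochs_rejected(self):
        e = EpochSet(data=np.zeros((32, 200, 3)), srate=250.0,
                     times_ms=-200 + np.arange(200) * 4.0)
        with pytest.raises(ValueError):
            build_order3(e)

    def test_order4_high_band_crops_frequencies(self):
        rng = np.random.default_rng(0)
        spect = rng.random((4, 101, 151, 10))
        labels = _labels(10)
        t4 = build_order4(spect, labels)
        t4h = build_order4(spect, labels, high_band=True)
        assert t4.data.shape[1] == 101
        assert t4h.data.shape[1] == (FREQ_GRID_HZ >= 3.0).sum()
        assert (t4h.axes["freqs_hz"] >= 3.0).all()

    def test_order4_energy_conservation(self):
        rng = np.random.default_rng(1)
        spect = rng.random((3, 101, 51, 4))
        t4 = build_order4(spect, _labels(4))
        assert (t4.data ** 2).sum() == pytest.approx((spect ** 2).sum())


class TestFitCPD:
    def test_rank1_exact_recovery(self):
        rng = np.random.default_rng(2)
        x, f_true = _rank_tensor((12, 20, 15), 1, rng)
        m = fit_cpd(TrialTensor(data=x), rank=1, seed=0, n_restarts=2)
        assert m.fit > 0.999
        assert congruence(m.spatial, f_true[0]) > 0.999
        assert congruence(m.factors[1], f_true[1]) > 0.999

    def test_rank3_orthogonal_recovery_with_noise(self):
        rng = np.random.default_rng(3)
        x, f_true = _rank_tensor((16, 40, 60), 3, rng)
        x_noisy = x + 0.01 * np.linalg.norm(x) / np.sqrt(x.size) * \
            rng.standard_normal(x.shape)
        m = fit_cpd(TrialTensor(data=x_noisy), rank=3, seed=1, n_restarts=3)
        assert 1.0 - m.fit < 0.05
        for mode in range(3):
            assert congruence(m.factors[mode], f_true[mode]) > 0.95

    def test_fit_monotone_across_sweeps(self):
        rng = np.random.default_rng(4)
        x, _ = _rank_tensor((8, 10, 12), 2, rng)
        x += 0.1 * rng.standard_normal(x.shape)
        m = fit_cpd(TrialTensor(data=x), rank=2, seed=2, n_restarts=1)
        hist = np.array(m.fit_history)
        assert np.all(np.diff(hist) >= -1e-9)

    def test_higher_rank_explains_no_less(self):
        rng = np.random.default_rng(5)
        x, _ = _rank_tensor((8, 10, 12), 3, rng)
        x += 0.05 * rng.standard_normal(x.shape)
        t = TrialTensor(data=x)
        fits = [fit_cpd(t, rank=r, seed=3, n_restarts=3).fit for r in (1, 2, 3)]
        assert fits[0] <= fits[1] + 1e-6 <= fits[2] + 2e-6

    def test_spatial_orthonormality(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((10, 14, 18))
        m = fit_cpd(TrialTensor(data=x), rank=4, seed=4, n_restarts=1)
        gram = m.spatial.T @ m.spatial
        assert np.abs(gram - np.eye(4)).max() < 1e-8

    def test_explained_fit_consistent(self):
        rng = np.random.default_rng(7)
        x, _ = _rank_tensor((6, 8, 10), 2, rng)
        t = TrialTensor(data=x)
        m = fit_cpd(t, rank=2, seed=5, n_restarts=2)
        assert explained_fit(t, m) == pytest.approx(m.fit, abs=1e-6)

    def test_rank_too_large_rejected(self):
        with pytest.raises(ValueError):
            fit_cpd(TrialTensor(data=np.zeros((3, 4, 5)) + 1), rank=4)


class TestSubjectPower:
    def _model(self, trial_factor, labels):
        rank = trial_factor.shape[1]
        return FactorModel(rank=rank,
                           factors=[np.eye(3, rank), np.eye(4, rank),
                                    trial_factor],
                           fit=1.0, converged=True, n_iter=1, labels=labels)

    def test_all_ones_trial_factor_counts_trials(self):
        labels = _labels(20)
        m = self._model(np.ones((20, 2)), labels)
        scores = subject_power(m)
        counts = labels.groupby("subject").size()
        for _, row in scores.iterrows():
            assert row["comp1"] == counts[row["subject"]]

    def test_mirrored_groups_p_one(self):
        # per-subject sums PRO {1, 4} vs NOVICE {2, 3}: U sits exactly at
        # the centre of its null, so the exact two-sided p is 1
        labels = pd.DataFrame({
            "subject": ["PRO_0"] * 2 + ["PRO_1"] * 2 + ["NOV_0"] * 2 + ["NOV_1"] * 2,
            "group": ["PRO"] * 4 + ["NOVICE"] * 4})
        trial = np.array([0.5, 0.5, 2.0, 2.0, 1.0, 1.0, 1.5, 1.5])[:, None]
        m = self._model(trial, labels)
        res = subject_power_and_test(m)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_planted_group_scale_detected(self):
        rng = np.random.default_rng(8)
        labels = _labels(200, per_subject=10)
        trial = np.abs(rng.normal(1.0, 0.2, size=(200, 1)))
        pro = (labels["group"] == "PRO").to_numpy()
        trial[pro] *= 2.0
        m = self._model(trial, labels)
        res = subject_power_and_test(m)
        assert res.loc[0, "p"] < 0.05

    def test_unlabeled_trials_rejected(self):
        m = self._model(np.ones((10, 1)), None)
        with pytest.raises(ValueError):
            subject_power(m)
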