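"""Synthetic two-group oddball EEG and cognitive-test logs.

The generator emulates the statistical structure the analysis pipeline
assumes: two groups (PRO / NOVICE) of ``n_subjects_per_group`` subjects, four
oddball paradigms with the study's trial counts, target epochs carrying
P200/N200/P300 bumps whose per-subject amplitudes and latencies are drawn
from the group profile tables, a 1/f background plus posterior alpha
oscillations scaled per group, and trial logs for the reaction-time and
visual-search tests with configurable out-of-threshold contamination.

Everything is driven by a single integer seed: identical
:class:`SimulationConfig` values produce bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (COMPONENTS, EPOCH_SPECS, PARADIGMS, POLARITY, EpochSet,
                   EpochSpec, ParadigmSpec)
from .montage import CHANNELS_32, posterior_weights
from .profiles import GROUPS, GroupERPProfile, default_profiles

#: Gaussian bump full width at half maximum per component, ms. The later,
#: broader P300 gets twice the width of the earlier components.
COMPONENT_WIDTH_MS = {"P200": 60.0, "N200": 60.0, "P300": 120.0}

_PARADIGM_ID = {name: i for i, name in enumerate(PARADIGMS)}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-EEG generator.

    noise_amplitude_uV is the per-channel standard deviation of the 1/f
    background; alpha_amplitude_uV the posterior alpha sinusoid amplitude
    before the group power scale is applied. `attrition` marks a random
    fraction of trials as rejected, mimicking artifact loss.
    """

    n_subjects_per_group: int = 10
    sampling_rate: float = 250.0
    n_channels: int = 32
    noise_exponent: float = 1.0
    noise_amplitude_uV: float = 5.0
    alpha_freq: float = 10.0
    alpha_bandwidth: float = 2.0
    alpha_amplitude_uV: float = 4.0
    trial_jitter_frac: float = 1.0 / 3.0
    attrition: float = 0.0
    outlier_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.n_channels != len(CHANNELS_32):
            raise ValueError("montage is fixed at 32 channels")
        if not 0.0 <= self.attrition < 1.0:
            raise ValueError("attrition must be in [0, 1)")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier fraction must be in [0, 1)")


def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _one_over_f_noise(rng, n_ch, n_t, n_trials, srate, exponent, amplitude):
    """1/f^exponent Gaussian noise, std `amplitude` per channel/trial."""
    if amplitude == 0:
        return np.zeros((n_ch, n_t, n_trials))
    freqs = np.fft.rfftfreq(n_t, 1.0 / srate)
    shape_f = np.ones_like(freqs)
    shape_f[1:] = freqs[1:] ** (-exponent / 2.0)
    shape_f[0] = 0.0
    z = rng.standard_normal((n_ch, n_trials, freqs.size)) + \
        1j * rng.standard_normal((n_ch, n_trials, freqs.size))
    x = np.fft.irfft(z * shape_f, n=n_t, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return np.moveaxis(x / sd * amplitude, 1, 2)


#: Flat-top half-width of the component bump, ms. The plateau spans the
#: +/-10 ms peak-smoothing window of the measurement stage, so a noiseless
#: isolated component measures back at exactly its configured amplitude.
_PLATEAU_HALF_MS = 10.0


def _component_bump(times_ms, lat_ms, fwhm_ms):
    """Flat-top bump: unit plateau of +/-10 ms with Gaussian shoulders.

    `fwhm_ms` is the total effective width; the shoulders use what remains
    after the plateau. A vanishing quadratic tilt (1e-9 relative) across
    the plateau makes the maximum sample unique at the configured latency.
    """
    shoulder_fwhm = max(fwhm_ms - 2.0 * _PLATEAU_HALF_MS, 10.0)
    sigma = shoulder_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d = np.abs(times_ms - lat_ms)
    shoulder = np.clip(d - _PLATEAU_HALF_MS, 0.0, None)
    bump = np.exp(-0.5 * (shoulder / sigma) ** 2)
    return bump * (1.0 - 1e-9 * ((times_ms - lat_ms) / _PLATEAU_HALF_MS) ** 2)


def generate_epochs(config: SimulationConfig,
                    paradigm: str | ParadigmSpec = "B/RB",
                    profiles: dict[str, GroupERPProfile] | None = None,
                    epoch_spec: EpochSpec | None = None,
                    n_targets: int | None = None,
                    n_nontargets: int | None = None) -> EpochSet:
    """Simulate one oddball block for both groups.

    Returns an :class:`EpochSet` of ``n_channels x n_times x n_trials`` with
    ``n_trials = 2 * n_subjects_per_group * (n_targets + n_nontargets)``.
    Target trials carry the three component bumps projected onto a posterior
    spatial pattern; every trial carries 1/f noise and an alpha oscillation
    whose amplitude is scaled by the group's ``alpha_power_scale``.
    ``n_targets`` / ``n_nontargets`` override the paradigm's counts (used to
    scale simulations down); per-subject parameter draws are unaffected by
    the override so subject identities are stable across sizes.
    """
    if isinstance(paradigm, str):
        if paradigm not in PARADIGMS:
            raise KeyError(f"unknown paradigm {paradigm!r}")
        pspec = PARADIGMS[paradigm]
    else:
        pspec = paradigm
        if pspec.name not in PARADIGMS:
            raise KeyError(f"unknown paradigm {pspec.name!r}")
    profiles = profiles if profiles is not None else default_profiles()
    espec = epoch_spec if epoch_spec is not None else EPOCH_SPECS[pspec.name]
    nt_tar = pspec.n_targets if n_targets is None else int(n_targets)
    nt_non = pspec.n_nontargets if n_nontargets is None else int(n_nontargets)

    srate = config.sampling_rate
    times = espec.times_ms(srate)
    n_t = times.size
    n_sub = config.n_subjects_per_group
    per_sub = nt_tar + nt_non
    n_trials = 2 * n_sub * per_sub

    rng = _rng_for(config, 1000 + _PARADIGM_ID[pspec.name])
    w_spatial = posterior_weights()

    data = np.zeros((config.n_channels, n_t, n_trials))
    rows = []
    tr0 = 0
    for g in GROUPS:
        prof = profiles[g]
        for s in range(n_sub):
            sid = f"{g}_{s:02d}"
            # per-subject component parameters (between-subject variability)
            sub_par = {}
            for c in COMPONENTS:
                cs = prof.component(pspec.name, c)
                sub_par[c] = (
                    rng.normal(cs.amp_mean, cs.amp_sd),
                    rng.normal(cs.lat_mean, cs.lat_sd),
                    cs.amp_sd, cs.lat_sd,
                )
            order = rng.permutation(per_sub)
            is_target = np.zeros(per_sub, dtype=bool)
            is_target[order[:nt_tar]] = True
            sl = slice(tr0, tr0 + per_sub)

            # background: 1/f noise + alpha, all trials
            data[:, :, sl] += _one_over_f_noise(
                rng, config.n_channels, n_t, per_sub, srate,
                config.noise_exponent, config.noise_amplitude_uV)
            if config.alpha_amplitude_uV > 0:
                # alpha frequency wanders trial to trial within the band,
                # with random phase per trial
                f_a = rng.uniform(config.alpha_freq - config.alpha_bandwidth / 2,
                                  config.alpha_freq + config.alpha_bandwidth / 2,
                                  size=per_sub)
                phase = rng.uniform(0, 2 * np.pi, size=per_sub)
                osc = np.sin(2 * np.pi * f_a[None, :] * times[:, None] / 1000.0
                             + phase[None, :])  # (time, trial)
                amp_a = config.alpha_amplitude_uV * np.sqrt(prof.alpha_power_scale)
                data[:, :, sl] += amp_a * w_spatial[:, None, None] * osc[None, :, :]

            # component bumps on target trials
            tgt_idx = np.flatnonzero(is_target)
            for c in COMPONENTS:
                amp_s, lat_s, amp_sd, lat_sd = sub_par[c]
                amp_tr = amp_s + rng.normal(0, amp_sd * config.trial_jitter_frac
                                            if amp_sd > 0 else 0, size=nt_tar)
                lat_tr = lat_s + rng.normal(0, lat_sd * config.trial_jitter_frac
                                            if lat_sd > 0 else 0, size=nt_tar)
                bump = _component_bump(times[:, None], lat_tr[None, :],
                                       COMPONENT_WIDTH_MS[c])  # (time, n_tar)
                signed = POLARITY[c] * amp_tr[None, :] * bump
                data[:, :, sl.start + tgt_idx] += w_spatial[:, None, None] * signed[None, :, :]

            for k in range(per_sub):
                rows.append((sid, g, bool(is_target[k]), tr0 + k, k))
            tr0 += per_sub

    trials = pd.DataFrame(rows, columns=["subject", "group", "target",
                                         "index", "order"])
    retained = np.ones(n_trials, dtype=bool)
    if config.attrition > 0:
        retained &= rng.random(n_trials) >= config.attrition
    return EpochSet(data=data, srate=srate, times_ms=times,
                    channels=CHANNELS_32, trials=trials, retained=retained,
                    paradigm=pspec.name,
                    meta={"seed": config.seed, "synthetic": True})


# ---------------------------------------------------------------------------
# cognitive-test logs

#: Trials per cognitive test (the choice-reaction example in the study uses
#: 30 trials; the visual-search score/rate summaries are consistent with 23).
DEFAULT_TEST_TRIALS = {"RTM": 30, "RTK": 30, "RTD": 30, "VS": 23}

_RT_SHIFT_MS = 100.0     # shifted-lognormal shift for reaction times
_VS_SHIFT_S = 0.3        # shift for visual-search times


def _shifted_lognormal(rng, mean, sd, shift, size):
    """Draws with expectation `mean` and sd `sd`, support > `shift`."""
    mu_l = mean - shift
    if mu_l <= 0:
        raise ValueError("mean must exceed the lognormal shift")
    if sd == 0:
        return np.full(size, float(mean))
    sigma2 = np.log1p((sd / mu_l) ** 2)
    mu = np.log(mu_l) - sigma2 / 2.0
    return shift + rng.lognormal(mu, np.sqrt(sigma2), size=size)


def generate_cognitive_log(config: SimulationConfig,
                           profiles: dict[str, GroupERPProfile] | None = None,
                           n_trials: dict[str, int] | None = None) -> pd.DataFrame:
    """Trial-level cognitive-test log for both groups.

    One row per trial for the reaction-time tests (RTM, RTK, RTD) and the
    visual-search test (VS), plus one row per subject per oddball counting
    paradigm (MT, ST) carrying the counted and true target numbers. Columns:
    ``subject_id, group, test, trial, rt_ms, stimulus, response, correct,
    counted, true_count``. A fraction ``config.outlier_fraction`` of RT
    trials is replaced with out-of-threshold values to exercise filtering.
    """
    profiles = profiles if profiles is not None else default_profiles()
    n_trials = dict(DEFAULT_TEST_TRIALS, **(n_trials or {}))
    rng = _rng_for(config, 2000)
    rows = []

    for g in GROUPS:
        prof = profiles[g]
        for s in range(config.n_subjects_per_group):
            sid = f"{g}_{s:02d}"
            # --- simple and choice reaction-time tests
            for test in ("RTM", "RTK", "RTD"):
                st = prof.rt[test]
                m_sub = rng.normal(st.mean, st.sd / 2.0) if st.sd > 0 else st.mean
                sd_within = st.sd * np.sqrt(3.0) / 2.0
                m_sub = max(m_sub, _RT_SHIFT_MS + 20.0)
                rts = _shifted_lognormal(rng, m_sub, sd_within, _RT_SHIFT_MS,
                                         n_trials[test])
                out = rng.random(n_trials[test]) < config.outlier_fraction
                rts[out] = rng.choice([rng.uniform(40, 110), rng.uniform(900, 2000)],
                                      size=out.sum())
                if test == "RTD":
                    stim = rng.choice(["red", "blue"], size=n_trials[test])
                    correct = rng.random(n_trials[test]) < prof.rtd_correct_rate / 100.0
                    resp = np.where(correct,
                                    np.where(stim == "red", "left", "right"),
                                    np.where(stim == "red", "right", "left"))
                else:
                    stim = np.array(["go"] * n_trials[test])
                    resp = np.array(["click" if test == "RTM" else "key"] * n_trials[test])
                    correct = np.ones(n_trials[test], dtype=bool)
                for k in range(n_trials[test]):
                    rows.append((sid, g, test, k, float(rts[k]), stim[k],
                                 resp[k], bool(correct[k]), np.nan, np.nan))
            # --- visual search
            nvs = n_trials["VS"]
            cond = rng.permutation(np.array(["L"] * (nvs // 2) +
                                            ["noL"] * (nvs - nvs // 2)))
            correct = rng.random(nvs) < prof.vs_correct_rate / 100.0
            t_l = _shifted_lognormal(rng, prof.vs_search_l.mean,
                                     prof.vs_search_l.sd, _VS_SHIFT_S, nvs)
            t_n = _shifted_lognormal(rng, prof.vs_search_nol.mean,
                                     prof.vs_search_nol.sd, _VS_SHIFT_S, nvs)
            t_s = np.where(cond == "L", t_l, t_n)
            resp = np.where(correct, cond,
                            np.where(cond == "L", "noL", "L"))
            for k in range(nvs):
                rows.append((sid, g, "VS", k, float(t_s[k] * 1000.0), cond[k],
                             resp[k], bool(correct[k]), np.nan, np.nan))
            # --- oddball counting (MT / ST paradigms)
            for par in ("MT", "ST"):
                true_n = PARADIGMS[par].n_targets
                st = prof.count_error[par]
                err = rng.normal(st.mean, st.sd) if st.sd > 0 else st.mean
                counted = int(round(true_n * (1.0 + err / 100.0)))
                rows.append((sid, g, par, 0, np.nan, "count", "count", True,
                             counted, true_n))

    return pd.DataFrame(rows, columns=["subject_id", "group", "test", "trial",
                                       "rt_ms", "stimulus", "response",
                                       "correct", "counted", "true_count"])


def generate_hours(config: SimulationConfig,
                   profiles: dict[str, GroupERPProfile] | None = None) -> pd.DataFrame:
    """Per-subject in-game experience (hours); defined for groups whose
    profile carries an ``hours_in_game`` range, NaN otherwise."""
    profiles = profiles if profiles is not None else default_profiles()
    rng = _rng_for(config, 3000)
    rows = []
    for g in GROUPS:
        rng_g = profiles[g].hours_in_game
        for s in range(config.n_subjects_per_group):
            h = rng.uniform(*rng_g) if rng_g is not None else np.nan
            rows.append((f"{g}_{s:02d}", g, h))
    return pd.DataFrame(rows, columns=["subject_id", "group", "hours"])
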