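"""EEG preprocessing: FIR filtering, epoching, baseline, rejection, repair.

The filters are Kaiser-windowed sinc FIRs (beta 5.65; low-pass 30 Hz order
184, high-pass 0.5 Hz) applied zero-phase: the taps are linear-phase
(symmetric), the data are extended by odd reflection and convolved with the
kernel centred ('same'), which cancels the group delay exactly.

Artifact handling follows simple, reproducible rules: epochs whose
peak-to-peak amplitude exceeds 500 uV on any channel are rejected; channels
whose activity (sd across time and retained trials) has a robust z-score
above 3.0 — with the robust sd taken as 0.7413 x IQR — are replaced by an
inverse-distance-weighted average of montage neighbours, at most two
channels per recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.signal as sig

from .data import EpochSet, EpochSpec
from .montage import CHANNELS_32, channel_positions

log = logging.getLogger(__name__)

KAISER_BETA = 5.65


@dataclass(frozen=True)
class FilterSpec:
    """Kaiser-windowed sinc FIR: `kind` in {'lowpass','highpass'}."""

    kind: str
    cutoff: float       # Hz
    order: int          # taps - 1
    beta: float = KAISER_BETA

    def __post_init__(self):
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError("kind must be 'lowpass' or 'highpass'")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


#: Default band limits: low-pass 30 Hz with the published order 184;
#: high-pass 0.5 Hz with order 1200 (DC leakage ~3e-4) — long enough for a
#: 0.5 Hz cutoff yet applicable to continuous recordings of a few seconds.
#: Published continuous-data pipelines use even longer high-pass kernels
#: (order in the thousands); configurable via FilterSpec.
DEFAULT_LOWPASS = FilterSpec("lowpass", 30.0, 184)
DEFAULT_HIGHPASS = FilterSpec("highpass", 0.5, 1200)


def design_fir(spec: FilterSpec, srate: float) -> np.ndarray:
    """Design the linear-phase Kaiser sinc FIR taps for `spec`.

    DC gain is 1 for a low-pass and 0 for a high-pass. High-pass kernels
    must have an odd tap count (type-I linear phase); an even `order` is
    required in that case.
    """
    if spec.cutoff >= srate / 2.0:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist {srate / 2} Hz")
    numtaps = spec.order + 1
    if spec.kind == "highpass" and numtaps % 2 == 0:
        raise ValueError("high-pass FIR needs an even order (odd tap count)")
    return sig.firwin(numtaps, spec.cutoff, window=("kaiser", spec.beta),
                      pass_zero=(spec.kind == "lowpass"), fs=srate)


def apply_fir(x: np.ndarray, taps: np.ndarray, axis: int = -1) -> np.ndarray:
    """Zero-phase application of symmetric FIR taps along `axis`.

    The signal is extended by odd reflection (at least 3x the filter order
    where the signal allows, never more than its length minus one) before a
    centred convolution, so edge transients fall on the padding.
    """
    x = np.asarray(x, dtype=float)
    order = len(taps) - 1
    n = x.shape[axis]
    if n < 2:
        raise ValueError("signal too short to filter")
    pad = int(min(3 * order, n - 1))
    xm = np.moveaxis(x, axis, -1)
    left = 2 * xm[..., :1] - xm[..., pad:0:-1]
    right = 2 * xm[..., -1:] - xm[..., -2:-pad - 2:-1]
    ext = np.concatenate([left, xm, right], axis=-1)
    y = sig.fftconvolve(ext, taps[(None,) * (ext.ndim - 1)], mode="same", axes=-1)
    return np.moveaxis(y[..., pad:pad + n], -1, axis)


def filter_epochs(e: EpochSet, specs=(DEFAULT_HIGHPASS, DEFAULT_LOWPASS)) -> EpochSet:
    """Apply band filters to every epoch (time axis), zero-phase."""
    data = e.data
    for spec in specs:
        data = apply_fir(data, design_fir(spec, e.srate), axis=1)
    return replace(e, data=data)


# ---------------------------------------------------------------------------
# epoching

def epoch_and_baseline(continuous: np.ndarray, srate: float,
                       events: pd.DataFrame, spec: EpochSpec,
                       channels=CHANNELS_32,
                       exclude_first: int = 2) -> EpochSet:
    """Cut epochs out of a continuous recording and baseline-correct them.

    `events` needs columns ``sample`` (stimulus onset), ``is_target`` and
    optionally ``code`` and ``block``; the first `exclude_first` events of
    each block are dropped, as are events whose epoch would leave the
    recording (logged). The mean of the last ``spec.baseline_ms`` before the
    stimulus is subtracted channel-wise per epoch.
    """
    continuous = np.asarray(continuous, dtype=float)
    n_ch, n_samp = continuous.shape
    n_pre = int(round(spec.pre_ms * srate / 1000.0))
    n_tot = spec.n_samples(srate)
    ev = events.copy()
    if "block" not in ev:
        ev["block"] = 0
    ev["rank_in_block"] = ev.groupby("block").cumcount()
    ev = ev[ev["rank_in_block"] >= exclude_first]

    keep, cut = [], 0
    for _, r in ev.iterrows():
        start = int(r["sample"]) - n_pre
        if start < 0 or start + n_tot > n_samp:
            cut += 1
            continue
        keep.append((start, bool(r["is_target"]),
                     r.get("subject", "s0"), r.get("group", "NA")))
    if cut:
        log.warning("dropped %d events too close to the recording edge", cut)

    data = np.stack([continuous[:, s:s + n_tot] for s, *_ in keep], axis=-1) \
        if keep else np.zeros((n_ch, n_tot, 0))
    trials = pd.DataFrame(
        [(sub, grp, tgt, i) for i, (_, tgt, sub, grp) in enumerate(keep)],
        columns=["subject", "group", "target", "index"])
    out = EpochSet(data=data, srate=srate, times_ms=spec.times_ms(srate),
                   channels=channels, trials=trials)
    return baseline_correct(out, spec.baseline_ms)


def baseline_correct(e: EpochSet, baseline_ms: float = 100.0) -> EpochSet:
    """Subtract the mean of the last `baseline_ms` pre-stimulus per epoch."""
    win = (e.times_ms >= -baseline_ms - 1e-9) & (e.times_ms < 0)
    if not win.any():
        raise ValueError("no samples in the baseline window")
    base = e.data[:, win, :].mean(axis=1, keepdims=True)
    return replace(e, data=e.data - base)


def load_edf(path, channels=CHANNELS_32):
    """Read a continuous EDF recording; returns (data uV, srate).

    Channels are reordered to the package montage; missing channels raise.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    missing = [c for c in channels if c not in raw.ch_names]
    if missing:
        raise KeyError(f"EDF lacks montage channels: {missing}")
    raw.pick(list(channels)).reorder_channels(list(channels))
    return raw.get_data() * 1e6, float(raw.info["sfreq"])


# ---------------------------------------------------------------------------
# artifact rejection and channel repair

def reject_epochs(e: EpochSet, threshold_uv: float = 500.0):
    """Mask epochs whose peak-to-peak span exceeds `threshold_uv` anywhere.

    Returns ``(epochs, report)`` where `report` lists the rejected fraction
    per subject. Raises if every epoch of some subject is rejected.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    ptp = e.data.max(axis=1) - e.data.min(axis=1)      # (channels, trials)
    bad = (ptp > threshold_uv).any(axis=0)
    retained = e.retained & ~bad
    rep = (pd.DataFrame({"subject": e.trials["subject"],
                         "was": e.retained, "now": retained})
           .groupby("subject")
           .apply(lambda d: 1.0 - d["now"].sum() / max(d["was"].sum(), 1),
                  include_groups=False)
           .rename("rejected_fraction").reset_index())
    dead = rep.loc[rep["rejected_fraction"] >= 1.0, "subject"].tolist()
    if dead:
        raise ValueError(f"all epochs rejected for subject(s): {dead}")
    return replace(e, retained=retained), rep


def flag_and_interpolate_channels(e: EpochSet, z_threshold: float = 3.0,
                                  max_interp: int = 2,
                                  radius_mm: float = 80.0):
    """Robust-z channel screening with inverse-distance interpolation.

    The activity score is each channel's sd over time and retained trials;
    robust z uses the median and 0.7413 x IQR. Channels above `z_threshold`
    are replaced by the inverse-distance-weighted mean of neighbours within
    `radius_mm`; at most `max_interp` channels (the worst offenders) are
    repaired, with a warning if more were flagged.
    """
    if len(e.channels) < 4:
        raise ValueError("need at least 4 channels for robust screening")
    x = e.data[:, :, e.retained]
    score = x.reshape(x.shape[0], -1).std(axis=1, ddof=0)
    med = np.median(score)
    q1, q3 = np.percentile(score, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return e, []
    z = (score - med) / (0.7413 * iqr)
    flagged = np.flatnonzero(z > z_threshold)
    if flagged.size == 0:
        return e, []
    if flagged.size > max_interp:
        log.warning("%d channels flagged, interpolating worst %d",
                    flagged.size, max_interp)
        flagged = flagged[np.argsort(z[flagged])[::-1][:max_interp]]

    pos = channel_positions(e.channels)
    data = e.data.copy()
    good = np.setdiff1d(np.arange(len(e.channels)), flagged)
    for ch in flagged:
        d = np.linalg.norm(pos[good] - pos[ch], axis=1)
        nb = good[d < radius_mm]
        if nb.size == 0:                      # fall back to nearest 3
            nb = good[np.argsort(d)[:3]]
        w = 1.0 / np.linalg.norm(pos[nb] - pos[ch], axis=1)
        w /= w.sum()
        data[ch] = np.tensordot(w, data[nb], axes=(0, 0))
    return replace(e, data=data), [e.channels[i] for i in flagged]
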