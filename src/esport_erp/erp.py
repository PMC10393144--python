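"""ERP waveforms and component measurement.

Per-subject ERPs are averages over retained target epochs. Components
(P200, N200, P300) are measured automatically inside polarity-aware search
windows: the peak is the windowed extremum of the component's polarity, the
amplitude is the mean of the signal within +/-10 ms of that peak, and the
latency is the 50% fractional-area point — the earliest time splitting the
polarity-rectified area under the window in two equal halves, which is more
robust to noise than the raw peak sample. Measures where no sample of the
right polarity exists are flagged invalid rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .data import COMPONENTS, EpochSet, ComponentWindow, default_windows
from .montage import POSTERIOR_ROI, channel_index

SMOOTH_HALF_WIDTH_MS = 10.0


@dataclass
class ERPWaveform:
    """One subject's target-locked average: channels x time."""

    subject: str
    group: str
    paradigm: str
    data: np.ndarray
    times_ms: np.ndarray
    channels: tuple[str, ...]
    n_trials_averaged: int


@dataclass
class ComponentMeasure:
    subject: str
    group: str
    paradigm: str
    component: str
    channel: str                 # channel name or ROI label
    amplitude_uV: float          # signed, polarity-consistent
    latency_ms: float
    valid: bool


def subject_waveforms(e: EpochSet) -> list[ERPWaveform]:
    """Average retained target epochs per subject."""
    out = []
    for sid in e.subjects():
        sub = e.select(subject=sid, target=True)
        if sub.n_trials == 0:
            continue
        out.append(ERPWaveform(
            subject=sid, group=sub.trials["group"].iloc[0], paradigm=e.paradigm,
            data=sub.data.mean(axis=2), times_ms=e.times_ms,
            channels=e.channels, n_trials_averaged=sub.n_trials))
    return out


def grand_average(waveforms: list[ERPWaveform], roi=POSTERIOR_ROI):
    """ROI time course averaged over subjects.

    Returns ``(times_ms, mean, sd)`` where the ROI channels are averaged
    first, then subjects; `sd` is the between-subject standard deviation.
    """
    if not waveforms:
        raise ValueError("no waveforms")
    if len(roi) == 0:
        raise ValueError("empty ROI")
    t0 = waveforms[0].times_ms
    for w in waveforms:
        if w.times_ms.shape != t0.shape or not np.allclose(w.times_ms, t0):
            raise ValueError("waveforms do not share a time axis")
    idx = channel_index(roi, waveforms[0].channels)
    stack = np.stack([w.data[idx].mean(axis=0) for w in waveforms])
    sd = stack.std(axis=0, ddof=1) if len(waveforms) > 1 else np.zeros_like(t0)
    return t0, stack.mean(axis=0), sd


def fractional_area_latency(times_ms: np.ndarray, y: np.ndarray,
                            polarity: int, fraction: float = 0.5) -> float:
    """Earliest time where the cumulative rectified area reaches `fraction`.

    The signal is multiplied by the polarity and clipped at zero before
    trapezoidal integration; the crossing is located by linear interpolation
    of the cumulative area between samples.
    """
    r = np.clip(polarity * np.asarray(y, dtype=float), 0.0, None)
    seg = 0.5 * (r[1:] + r[:-1]) * np.diff(times_ms)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return float("nan")
    target = fraction * total
    k = int(np.searchsorted(cum, target))
    if k == 0:
        return float(times_ms[0])
    frac = (target - cum[k - 1]) / (cum[k] - cum[k - 1])
    return float(times_ms[k - 1] + frac * (times_ms[k] - times_ms[k - 1]))


def measure_component(times_ms: np.ndarray, y: np.ndarray,
                      win: ComponentWindow, srate: float,
                      subject: str = "", group: str = "",
                      paradigm: str = "", channel: str = "") -> ComponentMeasure:
    """Measure one component on a 1-D waveform.

    Amplitude is the mean within +/-10 ms of the windowed extremum of the
    component's polarity (signed); latency is the 50% fractional-area point
    of the rectified signal within the search window. If the window contains
    no sample of the correct polarity the measure is marked invalid.
    """
    sel = (times_ms >= win.start_ms) & (times_ms <= win.end_ms)
    if not sel.any():
        raise ValueError("component window outside the epoch")
    tw, yw = times_ms[sel], np.asarray(y, dtype=float)[sel]
    signed = win.polarity * yw
    top = signed.max()
    # near-ties (1e-6 relative) count as one plateau resolving to its centre
    ties = np.flatnonzero(signed >= top - 1e-6 * max(1.0, abs(top)))
    peak = int(ties[ties.size // 2])
    valid = bool(signed[peak] > 0)
    t_peak = tw[peak]
    near = np.abs(times_ms - t_peak) <= SMOOTH_HALF_WIDTH_MS + 1e-9
    amplitude = float(np.asarray(y, dtype=float)[near].mean())
    latency = fractional_area_latency(tw, yw, win.polarity)
    if np.isnan(latency):
        valid = False
        latency = float(t_peak)
    return ComponentMeasure(subject, group, paradigm, win.component, channel,
                            amplitude, latency, valid)


def measure_components(e: EpochSet, windows: dict[str, ComponentWindow] | None = None,
                       roi=POSTERIOR_ROI, per_channel: bool = False) -> pd.DataFrame:
    """Tidy component table for every subject of an epoch set.

    By default components are measured on the ROI-averaged waveform (one row
    per subject x component); with ``per_channel=True`` every channel is
    measured separately (rows carry the channel name) for topographic use.
    """
    windows = windows or default_windows(e.paradigm)
    rows = []
    for w in subject_waveforms(e):
        targets = ([(ch, w.data[i]) for i, ch in enumerate(w.channels)]
                   if per_channel else
                   [("|".join(roi), w.data[channel_index(roi, w.channels)].mean(0))])
        for ch_label, y in targets:
            for comp in COMPONENTS:
                if comp not in windows:
                    continue
                m = measure_component(w.times_ms, y, windows[comp], e.srate,
                                      subject=w.subject, group=w.group,
                                      paradigm=w.paradigm, channel=ch_label)
                rows.append(m.__dict__)
    return pd.DataFrame(rows)


def compare_groups_pointwise(waves_a: list[ERPWaveform],
                             waves_b: list[ERPWaveform],
                             roi=POSTERIOR_ROI,
                             params: stats.TFCEParams = stats.TFCEParams(),
                             n_perm: int = 1000, seed=None,
                             alpha: float = 0.05) -> stats.StatResult:
    """Pointwise Welch t over subjects on the ROI time course, TFCE-corrected.

    Returns a StatResult over time; `meta['spans_ms']` lists the significant
    intervals (start, end) in ms.
    """
    if len(waves_a) < 2 or len(waves_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    idx = channel_index(roi, waves_a[0].channels)
    A = np.stack([w.data[idx].mean(0) for w in waves_a])
    B = np.stack([w.data[idx].mean(0) for w in waves_b])
    res = stats.tfce_group_comparison(A, B, params=params, n_perm=n_perm,
                                      seed=seed, alpha=alpha)
    times = waves_a[0].times_ms
    res.meta["times_ms"] = times
    res.meta["spans_ms"] = significant_spans(times, res.mask)
    return res


def significant_spans(times_ms: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous True runs of `mask` as (start_ms, end_ms) intervals."""
    spans, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = times_ms[i]
        elif not m and start is not None:
            spans.append((float(start), float(times_ms[i - 1])))
            start = None
    if start is not None:
        spans.append((float(start), float(times_ms[-1])))
    return spans
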