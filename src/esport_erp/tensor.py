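"""Trial tensors and canonical polyadic decomposition (CPD).

Spatial-temporal analysis stacks target epochs of both groups into an
order-3 tensor (channels x time x trials, time -100...+900 ms); spatial-
temporal-spectral analysis concatenates per-trial Hilbert spectrograms into
an order-4 tensor (channels x frequency x time x trials). Both are
approximated by a rank-R CPD fitted with alternating least squares where
the spatial factor is re-orthonormalised every sweep (polar projection),
which prevents the degenerate, mutually-cancelling components plain CPD is
prone to on EEG data.

Component post-processing resolves CPD's scale/sign/permutation ambiguity:
all non-trial factor columns are scaled to unit norm (the trial factor
absorbs the scale), each component's temporal peak is made positive and its
dominant spatial weight positive (sign flips compensated in the trial
factor), and components are ordered by descending explained energy. A
component's per-subject "power" is the signed sum of that subject's trial
coefficients; group differences of those scores are tested with the
Mann-Whitney U test (exact null for 10-per-group samples without ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .data import EpochSet
from .vmd import FREQ_GRID_HZ

OFFSET_WINDOW_MS = 80.0
ORDER3_SPAN_MS = (-100.0, 900.0)


@dataclass
class TrialTensor:
    """Data tensor with axis metadata; trials are always the last axis."""

    data: np.ndarray
    axes: dict = field(default_factory=dict)   # e.g. channels, times_ms, freqs_hz
    labels: pd.DataFrame = None                # per-trial subject/group

    def __post_init__(self):
        if self.labels is not None and len(self.labels) != self.data.shape[-1]:
            raise ValueError("trial labels must align with the last axis")


def build_order3(e: EpochSet, span_ms=ORDER3_SPAN_MS) -> TrialTensor:
    """Channels x time x trials tensor from pooled target epochs.

    Per trial, the mean of the first 80 ms of the epoch is subtracted as an
    offset; the time axis is then cropped to -100...+900 ms (251 samples at
    250 Hz). Target trials of both groups are pooled — the per-subject
    scoring splits them again after the joint decomposition.
    """
    tol = 0.5 * 1000.0 / e.srate
    if e.times_ms[0] > span_ms[0] + tol or e.times_ms[-1] < span_ms[1] - tol:
        raise ValueError("epochs do not cover the required span "
                         f"{span_ms[0]}..{span_ms[1]} ms")
    sub = e.select(target=True)
    first = e.times_ms <= e.times_ms[0] + OFFSET_WINDOW_MS - tol
    offset = sub.data[:, first, :].mean(axis=1, keepdims=True)
    data = sub.data - offset
    sel = (e.times_ms >= span_ms[0] - tol) & (e.times_ms <= span_ms[1] + tol)
    return TrialTensor(
        data=data[:, sel, :],
        axes={"channels": sub.channels, "times_ms": e.times_ms[sel]},
        labels=sub.trials.reset_index(drop=True))


def build_order4(spectrograms: np.ndarray, labels: pd.DataFrame,
                 freqs_hz: np.ndarray = FREQ_GRID_HZ,
                 times_ms: np.ndarray | None = None,
                 channels=None, high_band: bool = False) -> TrialTensor:
    """Channels x frequency x time x trials tensor of Hilbert spectrograms.

    ``high_band=True`` restricts the frequency axis to 3-30 Hz, removing the
    dominant low-frequency (ERP-locked) power so oscillatory components such
    as alpha become visible.
    """
    spectrograms = np.asarray(spectrograms, dtype=float)
    if spectrograms.ndim != 4:
        raise ValueError("expected channels x freq x time x trials")
    if spectrograms.shape[1] != freqs_hz.size:
        raise ValueError("frequency grid mismatch")
    if high_band:
        keep = freqs_hz >= 3.0
        spectrograms = spectrograms[:, keep]
        freqs_hz = freqs_hz[keep]
    axes = {"freqs_hz": freqs_hz}
    if times_ms is not None:
        axes["times_ms"] = times_ms
    if channels is not None:
        axes["channels"] = channels
    return TrialTensor(data=spectrograms, axes=axes, labels=labels)


# ---------------------------------------------------------------------------
# CPD with ALS

@dataclass
class FactorModel:
    """CPD factors; ``factors[0]`` spatial, ``factors[-1]`` trial."""

    rank: int
    factors: list            # list of (dim_n x R) arrays
    fit: float               # 1 - ||X - Xhat|| / ||X||
    converged: bool
    n_iter: int
    labels: pd.DataFrame = None
    fit_history: list = None  # fit after each ALS sweep (best restart)

    @property
    def spatial(self): return self.factors[0]

    @property
    def trial(self): return self.factors[-1]


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    # column-wise Kronecker, first matrix varying slowest
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, out.shape[1])
    return out


def fit_cpd(t: TrialTensor, rank: int, orthogonal_spatial: bool = True,
            tol: float = 1e-8, max_iter: int = 500, n_restarts: int = 5,
            seed=None, ridge: float = 1e-12) -> FactorModel:
    """Rank-R CPD via ALS, optionally with an orthonormal spatial factor.

    Each restart initialises factors from a seeded standard-normal draw;
    the best-fitting restart is kept (the objective is non-convex). The
    spatial-factor update is projected to the nearest orthonormal matrix
    (polar decomposition of the least-squares target), which keeps the ALS
    residual monotone while enforcing A^T A = I. Rank-deficient normal
    equations fall back to a ridge-regularised solve.
    """
    x = np.asarray(t.data, dtype=float)
    if any(rank > s for s in x.shape):
        raise ValueError("rank exceeds a tensor dimension")
    norm_x = np.linalg.norm(x)
    if norm_x == 0:
        raise ValueError("zero tensor")
    n_modes = x.ndim
    unfolds = [_unfold(x, m) for m in range(n_modes)]
    rng_master = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        factors = [rng.standard_normal((s, rank)) for s in x.shape]
        if orthogonal_spatial:
            factors[0], _ = np.linalg.qr(factors[0])
        grams = [f.T @ f for f in factors]
        fit_prev = -np.inf
        converged = False
        history = []
        it = 0
        for it in range(1, max_iter + 1):
            for m in range(n_modes):
                # remaining modes in ascending order, matching the unfolding
                kr = _khatri_rao([factors[i] for i in range(n_modes) if i != m])
                mttkrp = unfolds[m] @ kr
                if m == 0 and orthogonal_spatial:
                    # polar projection: argmin_{A^T A = I} ||X_(0) - A M^T||
                    u, _, vt = np.linalg.svd(mttkrp, full_matrices=False)
                    factors[m] = u @ vt
                else:
                    gram = np.ones((rank, rank))
                    for i in range(n_modes):
                        if i != m:
                            gram = gram * grams[i]
                    try:
                        sol = np.linalg.solve(gram, mttkrp.T).T
                    except np.linalg.LinAlgError:
                        sol = np.linalg.solve(
                            gram + ridge * np.trace(gram) * np.eye(rank),
                            mttkrp.T).T
                    factors[m] = sol
                grams[m] = factors[m].T @ factors[m]
            # fit via the last-updated mode's MTTKRP
            gram_all = np.ones((rank, rank))
            for i in range(n_modes):
                gram_all = gram_all * grams[i]
            norm_hat_sq = max(gram_all.sum(), 0.0)
            inner = np.sum(mttkrp * factors[-1])
            resid_sq = max(norm_x ** 2 - 2 * inner + norm_hat_sq, 0.0)
            fit = 1.0 - np.sqrt(resid_sq) / norm_x
            history.append(fit)
            if abs(fit - fit_prev) < tol:
                converged = True
                break
            fit_prev = fit
        cand = (fit, factors, converged, it, history)
        if best is None or cand[0] > best[0]:
            best = cand

    fit, factors, converged, it, history = best
    factors = _normalize_components(factors)
    return FactorModel(rank=rank, factors=factors, fit=float(fit),
                       converged=converged, n_iter=it,
                       labels=t.labels, fit_history=history)


def _normalize_components(factors: list[np.ndarray]) -> list[np.ndarray]:
    """Unit-norm non-trial columns, scale/sign into the trial factor,
    temporal peak and dominant spatial weight positive, order by energy."""
    factors = [f.copy() for f in factors]
    rank = factors[0].shape[1]
    trial = factors[-1]
    for r in range(rank):
        for f in factors[:-1]:
            nrm = np.linalg.norm(f[:, r])
            if nrm > 0:
                f[:, r] /= nrm
                trial[:, r] *= nrm
        # temporal factor is mode 1; flip its extremum positive
        temporal = factors[1][:, r]
        if temporal[np.argmax(np.abs(temporal))] < 0:
            factors[1][:, r] *= -1
            trial[:, r] *= -1
        spatial = factors[0][:, r]
        if spatial[np.argmax(np.abs(spatial))] < 0:
            factors[0][:, r] *= -1
            trial[:, r] *= -1
    energy = np.linalg.norm(trial, axis=0)
    order = np.argsort(energy)[::-1]
    return [f[:, order] for f in factors]


def explained_fit(t: TrialTensor, m: FactorModel) -> float:
    """1 - relative residual of the model on `t` (recomputed exactly)."""
    x = np.asarray(t.data, dtype=float)
    hat = _khatri_rao(m.factors[:-1]) @ m.factors[-1].T
    resid = np.linalg.norm(_unfold(x, x.ndim - 1).T - hat)
    return 1.0 - resid / np.linalg.norm(x)


# ---------------------------------------------------------------------------
# per-subject power scores and the group test

def subject_power(m: FactorModel, labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Signed per-subject sum of trial-factor coefficients per component."""
    labels = labels if labels is not None else m.labels
    if labels is None:
        raise ValueError("trial labels required")
    if len(labels) != m.trial.shape[0]:
        raise ValueError("labels do not align with the trial factor")
    df = pd.DataFrame(m.trial,
                      columns=[f"comp{r + 1}" for r in range(m.rank)])
    df["subject"] = labels["subject"].to_numpy()
    df["group"] = labels["group"].to_numpy()
    return df.groupby(["subject", "group"], as_index=False).sum()


def subject_power_and_test(m: FactorModel,
                           labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mann-Whitney comparison of per-subject component power, PRO vs NOVICE.

    Returns one row per component with the U statistic, two-sided p, and the
    group medians. Requires every trial to be labelled with subject and group.
    """
    scores = subject_power(m, labels)
    rows = []
    for r in range(m.rank):
        col = f"comp{r + 1}"
        a = scores.loc[scores["group"] == "PRO", col].to_numpy()
        b = scores.loc[scores["group"] == "NOVICE", col].to_numpy()
        if a.size == 0 or b.size == 0:
            raise ValueError("both groups must contribute subjects")
        u, p = stats.mann_whitney_u(a, b)
        rows.append({"component": col, "U": u, "p": p,
                     "median_PRO": float(np.median(a)),
                     "median_NOVICE": float(np.median(b))})
    return pd.DataFrame(rows)
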