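"""Shared statistical engine.

Implements the inferential core used by every analysis stage:

* Welch's unequal-variance t statistic (raw data or printed summaries),
* label-permutation tests built on Welch's t (exact enumeration for tiny
  samples, seeded Monte Carlo otherwise),
* Hedges' g standardized mean difference with the exact small-sample
  correction factor,
* Mann-Whitney U (exact null for small untied samples, via SciPy),
* threshold-free cluster enhancement (TFCE) over 1-D/2-D lattices and
  arbitrary channel graphs, with max-statistic permutation inference,
* channel-wise Spearman correlation maps with TFCE permutation inference.

Conventions: all permutation p-values are two-sided; Monte Carlo p-values use
the add-one rule ``p = (1 + #extreme) / (n_perm + 1)`` so p is never 0; exact
enumeration divides by the number of distinct splits. A point at height
exactly ``h`` is counted as suprathreshold at ``h`` (``>=``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.special as special
import scipy.stats as sps

__all__ = [
    "TFCEParams", "StatResult",
    "welch_t", "welch_t_from_summary", "welch_t_map",
    "permutation_test", "hedges_g", "hedges_g_from_summary",
    "mann_whitney_u", "tfce", "lattice_adjacency",
    "tfce_group_comparison", "spearman_rho", "spearman_tfce_map",
]


# ---------------------------------------------------------------------------
# parameters / results

@dataclass(frozen=True)
class TFCEParams:
    """TFCE settings: ``TFCE(p) = sum_h extent(p, h)^E * h^H * dh``.

    ``dh = None`` resolves to ``max(|map|) / n_steps`` at call time.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    n_steps: int = 100

    def __post_init__(self):
        if self.E <= 0 or self.H <= 0:
            raise ValueError("TFCE exponents must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")


@dataclass
class StatResult:
    """Statistic map with TFCE enhancement and permutation p-values."""

    statistic: np.ndarray
    enhanced: np.ndarray | None
    p: np.ndarray
    n_permutations: int
    alpha: float = 0.05
    effect_size: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        """Boolean significance mask at ``alpha``."""
        return self.p < self.alpha


# ---------------------------------------------------------------------------
# t statistics and effect sizes

def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t and Welch-Satterthwaite df.

    Zero variance in both samples with equal means yields ``t = 0``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    return welch_t_from_summary(a.mean(), a.std(ddof=1), a.size,
                                b.mean(), b.std(ddof=1), b.size)


def welch_t_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b):
    """Welch t and df from summary statistics (mean, sample sd, n)."""
    va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
    denom = math.sqrt(va + vb)
    diff = mean_a - mean_b
    if denom == 0.0:
        return (0.0 if diff == 0 else math.copysign(math.inf, diff)), float(n_a + n_b - 2)
    t = diff / denom
    df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    return t, df


def welch_t_map(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pointwise Welch t over the leading (subject) axis of two stacks."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    diff = A.mean(axis=0) - B.mean(axis=0)
    denom = np.sqrt(A.var(axis=0, ddof=1) / na + B.var(axis=0, ddof=1) / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        return np.where(denom == 0,
                        np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)


def _hedges_correction(df: float) -> float:
    # exact J(df) = Gamma(df/2) / (sqrt(df/2) * Gamma((df-1)/2))
    return math.exp(special.gammaln(df / 2.0)
                    - 0.5 * math.log(df / 2.0)
                    - special.gammaln((df - 1.0) / 2.0))


def hedges_g(a, b) -> float:
    """Hedges' g with the exact gamma-function small-sample correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return hedges_g_from_summary(a.mean(), a.std(ddof=1), a.size,
                                 b.mean(), b.std(ddof=1), b.size)


def hedges_g_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> float:
    if n_a < 2 or n_b < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = n_a + n_b - 2
    s_pooled = math.sqrt(((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2) / df)
    if s_pooled == 0.0:
        if mean_a == mean_b:
            return 0.0
        return math.nan  # undefined effect size, flagged as NaN
    return _hedges_correction(df) * (mean_a - mean_b) / s_pooled


# ---------------------------------------------------------------------------
# permutation test on scalar samples

def _t_for_splits(pooled: np.ndarray, idx_a: np.ndarray) -> np.ndarray:
    """Welch t for many splits at once; idx_a is (n_splits, n_a) indices."""
    n = pooled.size
    na = idx_a.shape[1]
    nb = n - na
    take_a = pooled[idx_a]
    mask = np.ones((idx_a.shape[0], n), dtype=bool)
    np.put_along_axis(mask, idx_a, False, axis=1)
    take_b = pooled[np.nonzero(mask)[1]].reshape(idx_a.shape[0], nb)
    ma, mb = take_a.mean(1), take_b.mean(1)
    va, vb = take_a.var(1, ddof=1) / na, take_b.var(1, ddof=1) / nb
    denom = np.sqrt(va + vb)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        return np.where(denom == 0,
                        np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)


def permutation_test(a, b, n_perm: int = 100_000, seed=None,
                     statistic: Callable | None = None):
    """Two-sided label-permutation test of mean difference via Welch's t.

    Enumerates all ``C(n_a+n_b, n_a)`` splits when that count does not exceed
    ``n_perm`` (exact p, no add-one smoothing); otherwise draws ``n_perm``
    uniform random splits and applies the add-one rule. Returns
    ``(t_obs, df, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size + b.size < 4:
        raise ValueError("need a combined sample of at least 4")
    if statistic is None:
        t_obs, df = welch_t(a, b)
        stat = None
    else:
        t_obs, df = statistic(a, b), math.nan
        stat = statistic
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    n_splits = math.comb(n, na)
    tol = 1e-12 * max(1.0, abs(t_obs))

    if n_splits <= n_perm:
        idx_a = np.array(list(itertools.combinations(range(n), na)))
        if stat is None:
            t_perm = _t_for_splits(pooled, idx_a)
        else:
            t_perm = np.array([stat(pooled[i], np.delete(pooled, i)) for i in idx_a])
        p = np.mean(np.abs(t_perm) >= abs(t_obs) - tol)
        return t_obs, df, float(p)

    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # random splits: first na entries of random permutations
        idx_a = np.argsort(rng.random((m, n)), axis=1)[:, :na]
        if stat is None:
            t_perm = _t_for_splits(pooled, idx_a)
        else:
            t_perm = np.array([stat(pooled[i], np.delete(pooled, i)) for i in idx_a])
        count += int(np.sum(np.abs(t_perm) >= abs(t_obs) - tol))
        done += m
    return t_obs, df, (1.0 + count) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# Mann-Whitney U

def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null for untied samples of size <= 10."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 10) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# TFCE

def lattice_adjacency(shape: tuple[int, ...]) -> sp.csr_matrix:
    """Orthogonal-neighbour adjacency of a 1-D/2-D lattice, flattened order."""
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    rows, cols = [], []
    for ax in range(len(shape)):
        a = np.moveaxis(idx, ax, 0)
        rows.append(a[:-1].ravel())
        cols.append(a[1:].ravel())
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    adj = sp.csr_matrix((np.ones(r.size, bool), (r, c)), shape=(n, n))
    return adj + adj.T


def _enhance_positive(m: np.ndarray, E: float, H: float, dh: float,
                      adjacency: sp.csr_matrix | None) -> np.ndarray:
    """TFCE of the non-negative part of ``m``; lattice path uses ndimage."""
    out = np.zeros_like(m, dtype=float)
    top = float(m.max(initial=0.0))
    if top <= 0:
        return out
    heights = np.arange(dh, top + dh / 2, dh)
    use_lattice = adjacency is None and m.ndim <= 2
    for h in heights:
        # small tolerance so values sitting exactly on a threshold count
        supra = m >= h - 1e-9 * max(1.0, h)
        if not supra.any():
            break
        if use_lattice:
            labels, n_lab = ndi.label(supra)
            if n_lab == 0:
                continue
            extents = np.bincount(labels.ravel())[1:]  # skip background
            contrib = np.zeros(n_lab + 1)
            contrib[1:] = extents.astype(float) ** E * h ** H * dh
            out += contrib[labels]
        else:
            nodes = np.flatnonzero(supra.ravel())
            sub = adjacency[nodes][:, nodes]
            n_comp, lab = csgraph.connected_components(sub, directed=False)
            extents = np.bincount(lab)
            out.ravel()[nodes] += extents[lab].astype(float) ** E * h ** H * dh
    return out


def tfce(stat_map: np.ndarray, params: TFCEParams = TFCEParams(),
         adjacency: sp.csr_matrix | None = None) -> np.ndarray:
    """Signed TFCE enhancement of a statistic map.

    Positive and negative excursions are enhanced separately (the negative
    part on the negated map, re-negated), so the output keeps the sign of the
    input. For 1-D/2-D maps without an explicit adjacency an orthogonal
    lattice neighbourhood is assumed; pass a sparse `adjacency` (over the
    flattened map) for graph domains such as electrode topographies.
    """
    m = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("TFCE input must be finite")
    dh = params.dh
    if dh is None:
        top = float(np.max(np.abs(m), initial=0.0))
        if top == 0.0:
            return np.zeros_like(m)
        dh = top / params.n_steps
    pos = _enhance_positive(np.maximum(m, 0.0), params.E, params.H, dh, adjacency)
    neg = _enhance_positive(np.maximum(-m, 0.0), params.E, params.H, dh, adjacency)
    return pos - neg


def _max_stat_p(enh_obs: np.ndarray, max_null: np.ndarray) -> np.ndarray:
    """FWE-corrected p per point from the max-|enhanced| permutation null."""
    n = max_null.size
    # add-one rule; broadcast compare each point against the null maxima
    exceed = (max_null[:, None] >= np.abs(enh_obs).ravel()[None, :] - 1e-12).sum(0)
    return ((1.0 + exceed) / (n + 1.0)).reshape(enh_obs.shape)


def tfce_group_comparison(A: np.ndarray, B: np.ndarray,
                          params: TFCEParams = TFCEParams(),
                          adjacency: sp.csr_matrix | None = None,
                          n_perm: int = 1000, seed=None,
                          alpha: float = 0.05) -> StatResult:
    """Pointwise Welch t between subject stacks + TFCE permutation inference.

    ``A``/``B`` are subjects x map; group labels are permuted, the TFCE of the
    permuted t map is reduced to its maximum absolute value, and per-point
    p-values are computed against that max-statistic null (family-wise error
    controlled over the map).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    t_obs = welch_t_map(A, B)
    if not np.all(np.isfinite(t_obs)):
        # degenerate zero-variance points: clip to large finite value
        finite_max = np.max(np.abs(t_obs[np.isfinite(t_obs)]), initial=1.0)
        t_obs = np.nan_to_num(t_obs, posinf=10 * finite_max, neginf=-10 * finite_max)
    # freeze dh on the observed map so permuted maps are enhanced on the same grid
    dh = params.dh
    if dh is None:
        top = float(np.max(np.abs(t_obs), initial=0.0))
        dh = top / params.n_steps if top > 0 else 1.0
    frozen = TFCEParams(params.E, params.H, dh, params.n_steps)
    enh_obs = tfce(t_obs, frozen, adjacency)

    pooled = np.concatenate([A, B], axis=0)
    n, na = pooled.shape[0], A.shape[0]
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        t_p = welch_t_map(pooled[perm[:na]], pooled[perm[na:]])
        t_p = np.nan_to_num(t_p, posinf=0.0, neginf=0.0)
        max_null[i] = np.max(np.abs(tfce(t_p, frozen, adjacency)))
    p = _max_stat_p(enh_obs, max_null)
    # pointwise Hedges g for reporting
    df = n - 2
    sp_pool = np.sqrt(((na - 1) * A.var(0, ddof=1) + (n - na - 1) * B.var(0, ddof=1)) / df)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = _hedges_correction(df) * (A.mean(0) - B.mean(0)) / sp_pool
    g = np.where(sp_pool == 0, 0.0, g)
    return StatResult(statistic=t_obs, enhanced=enh_obs, p=p,
                      n_permutations=n_perm, alpha=alpha, effect_size=g)


# ---------------------------------------------------------------------------
# Spearman correlation maps

def spearman_rho(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Spearman rho of ``x`` (n,) against each column of ``Y`` (n, k); mid-rank ties."""
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != x.size:
        raise ValueError("x and Y must have matching first dimension")
    rx = sps.rankdata(x)
    rY = sps.rankdata(Y, axis=0)
    rx = rx - rx.mean()
    rY = rY - rY.mean(axis=0)
    denom = np.sqrt((rx ** 2).sum() * (rY ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = rx @ rY / denom
    return np.where(denom == 0, np.nan, rho)


def spearman_tfce_map(x: np.ndarray, Y: np.ndarray,
                      adjacency: sp.csr_matrix,
                      params: TFCEParams = TFCEParams(),
                      n_perm: int = 1000, seed=None,
                      alpha: float = 0.05) -> StatResult:
    """Channel-wise Spearman correlation with TFCE max-statistic permutation.

    ``x`` is one scalar per subject, ``Y`` a per-subject per-channel feature
    (n_subjects x n_channels, row-aligned with ``x``); the null shuffles ``x``
    across subjects. Requires at least 5 subjects. Constant ``x`` raises.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 subjects")
    if np.unique(x).size == 1:
        raise ValueError("constant predictor: correlations undefined")
    rho = spearman_rho(x, Y)
    rho_f = np.nan_to_num(rho)
    dh = params.dh
    if dh is None:
        top = float(np.max(np.abs(rho_f), initial=0.0))
        dh = top / params.n_steps if top > 0 else 1.0
    frozen = TFCEParams(params.E, params.H, dh, params.n_steps)
    enh = tfce(rho_f, frozen, adjacency)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for i in range(n_perm):
        r_p = np.nan_to_num(spearman_rho(rng.permutation(x), Y))
        max_null[i] = np.max(np.abs(tfce(r_p, frozen, adjacency)))
    p = _max_stat_p(enh, max_null)
    return StatResult(statistic=rho, enhanced=enh, p=p,
                      n_permutations=n_perm, alpha=alpha,
                      meta={"kind": "spearman_tfce"})
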