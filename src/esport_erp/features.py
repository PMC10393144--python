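"""Per-subject feature tables and intragroup correlation analyses.

Feature tables have one row per subject of one group and deterministic
column names: cognitive-test features (mean filtered reaction times, RTD
correct rate, visual-search score/rate/mean search times), optional hours of
in-game experience, and ERP features named
``{amp|lat}_{P200|N200|P300}_{BRB|BT|MT|ST}_{channel|FzCzPz}``. Combined
features average the Fz/Cz/Pz channels, giving exactly 24 combined ERP
columns (3 components x 4 paradigms x amplitude/latency). Amplitude
features are polarity-rectified (an N200 of -8 uV enters as 8), matching
how component magnitudes are tabulated.

Because the groups differ systematically, correlations are only meaningful
within a group; the builders therefore never mix group rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from . import stats
from .cognitive import DEFAULT_THRESHOLDS, filter_rts, vs_metrics, correct_rate
from .data import POLARITY

COMBINED_CHANNELS = ("Fz", "Cz", "Pz")
_PARADIGM_TAG = {"B/RB": "BRB", "BT": "BT", "MT": "MT", "ST": "ST"}
CLOSE_PARADIGMS = ("MT", "ST")


def subject_cognitive_features(log: pd.DataFrame,
                               thresholds=None) -> pd.DataFrame:
    """Per-subject cognitive-test features (means of filtered trials)."""
    thresholds = thresholds or DEFAULT_THRESHOLDS
    rows = []
    for (sid, grp), sub in log.groupby(["subject_id", "group"]):
        row = {"subject": sid, "group": grp}
        for test, col in (("RTM", "rtm_mean_ms"), ("RTK", "rtk_mean_ms")):
            tr = sub[sub["test"] == test]
            if len(tr):
                kept, _ = filter_rts(tr["rt_ms"], thresholds[test])
                row[col] = kept.mean() if kept.size else np.nan
        rtd = sub[sub["test"] == "RTD"]
        if len(rtd):
            kept, _ = filter_rts(rtd.loc[rtd["correct"], "rt_ms"],
                                 thresholds["RTD"])
            row["rtd_correct_rt_ms"] = kept.mean() if kept.size else np.nan
            row["rtd_correct_rate"] = correct_rate(rtd["correct"])
        vs = sub[sub["test"] == "VS"]
        if len(vs):
            m = vs_metrics(vs)
            row["vs_final_score"] = m["final_score"]
            row["vs_correct_rate"] = m["correct_rate"]
            row["vs_search_l_s"] = (np.mean(m["search_l_s"])
                                    if m["search_l_s"] else np.nan)
            row["vs_search_nol_s"] = (np.mean(m["search_nol_s"])
                                      if m["search_nol_s"] else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def build_feature_table(measures: pd.DataFrame,
                        cognitive: pd.DataFrame | None = None,
                        hours: pd.DataFrame | None = None,
                        group: str = "PRO",
                        combined_only: bool = False) -> pd.DataFrame:
    """Assemble one group's feature table (subjects x named features).

    `measures` is the tidy per-channel component table (columns subject,
    group, paradigm, component, channel, amplitude_uV, latency_ms). Combined
    Fz/Cz/Pz features are always built; per-channel columns are added unless
    ``combined_only``. Rows with missing constituents keep NaN and are
    flagged in ``table.attrs['incomplete_subjects']``.
    """
    m = measures[measures["group"] == group].copy()
    if m.empty:
        raise ValueError(f"no measures for group {group!r}")
    m["rect_amp"] = m.apply(
        lambda r: r["amplitude_uV"] * POLARITY[r["component"]], axis=1)

    cols = {}
    subjects = sorted(m["subject"].unique())
    for (par, comp), d in m.groupby(["paradigm", "component"]):
        tag = _PARADIGM_TAG[par]
        comb = d[d["channel"].isin(COMBINED_CHANNELS)]
        amp = comb.groupby("subject")["rect_amp"].mean()
        lat = comb.groupby("subject")["latency_ms"].mean()
        cols[f"amp_{comp}_{tag}_FzCzPz"] = amp
        cols[f"lat_{comp}_{tag}_FzCzPz"] = lat
        if not combined_only:
            for ch, dc in d.groupby("channel"):
                if "|" in ch:
                    continue  # ROI-labelled rows are not channel features
                cols[f"amp_{comp}_{tag}_{ch}"] = dc.set_index("subject")["rect_amp"]
                cols[f"lat_{comp}_{tag}_{ch}"] = dc.set_index("subject")["latency_ms"]

    table = pd.DataFrame(cols, index=pd.Index(subjects, name="subject"))
    if cognitive is not None:
        cg = cognitive[cognitive["group"] == group].set_index("subject")
        table = table.join(cg.drop(columns=["group"]))
    if hours is not None:
        h = hours[hours["group"] == group].set_index("subject_id")["hours"]
        if h.notna().any():
            table["hours_in_game"] = h
    table.attrs["group"] = group
    table.attrs["incomplete_subjects"] = (
        table.index[table.isna().any(axis=1)].tolist())
    return table


def combined_block(table: pd.DataFrame) -> pd.DataFrame:
    """The 24-column combined (FzCzPz) ERP feature block."""
    cols = [c for c in table.columns if c.endswith("_FzCzPz")]
    return table[cols]


# ---------------------------------------------------------------------------
# heatmap

def _pairwise_spearman_p(x, y, n_perm, rng):
    rho = float(stats.spearman_rho(x, y[:, None])[0])
    if np.isnan(rho):
        return rho, np.nan
    n = x.size
    rx = sps.rankdata(x) - (n + 1) / 2.0
    ry = sps.rankdata(y) - (n + 1) / 2.0
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    # permute the ranks of x wholesale: one matmul for the whole null
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    rho_null = (rx[perm] @ ry) / denom
    p = (1.0 + np.sum(np.abs(rho_null) >= abs(rho) - 1e-12)) / (n_perm + 1.0)
    return rho, p


def heatmap_correlations(table: pd.DataFrame, n_perm: int = 2000,
                         seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman matrix with per-cell permutation p-values.

    Returns ``(rho, p)`` DataFrames over all feature columns; constant
    columns yield NaN cells. Requires at least 5 subjects.
    """
    if len(table) < 5:
        raise ValueError("need at least 5 subjects")
    cols = list(table.columns)
    n = len(cols)
    rho = np.full((n, n), np.nan)
    pmat = np.full((n, n), np.nan)
    rng = np.random.default_rng(seed)
    vals = {c: table[c].to_numpy(dtype=float) for c in cols}
    for i in range(n):
        rho[i, i] = 1.0
        pmat[i, i] = 0.0
        if np.unique(vals[cols[i]][~np.isnan(vals[cols[i]])]).size <= 1:
            rho[i, i] = np.nan
        for j in range(i + 1, n):
            x, y = vals[cols[i]], vals[cols[j]]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 5 or np.unique(x[ok]).size <= 1 or np.unique(y[ok]).size <= 1:
                continue
            r, p = _pairwise_spearman_p(x[ok], y[ok], n_perm, rng)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pmat, index=cols, columns=cols))


# ---------------------------------------------------------------------------
# channel-wise correlation and the two significance criteria

@dataclass
class CriteriaFlags:
    """The two-part significance rule for small-sample correlation maps.

    criterion1: the significant-channel pattern is concordant across close
    paradigms (both members of the pair show significant channels whose
    dominant correlation sign agrees). criterion2: the map contains at least
    two significant channels joined by an adjacency edge (a contiguous
    area, not isolated electrodes). overall = criterion1 AND criterion2.
    """

    feature: str
    criterion1: bool
    criterion2: bool

    @property
    def overall(self) -> bool:
        return self.criterion1 and self.criterion2


def channelwise_feature_correlation(x, Y, adjacency, n_perm: int = 1000,
                                    seed=None, alpha: float = 0.05) -> stats.StatResult:
    """Spearman correlation of a scalar feature against a per-channel map.

    Thin wrapper over the TFCE-permutation Spearman engine; `x` is one value
    per subject of a single group, `Y` the matching subjects x channels
    feature (intragroup only — mixing groups distorts the correlations).
    """
    return stats.spearman_tfce_map(np.asarray(x, dtype=float),
                                   np.asarray(Y, dtype=float),
                                   adjacency, n_perm=n_perm, seed=seed,
                                   alpha=alpha)


def _has_adjacent_pair(sig_idx: np.ndarray, adjacency) -> bool:
    if sig_idx.size < 2:
        return False
    sub = adjacency[sig_idx][:, sig_idx]
    return bool(sub.nnz > 0)


def evaluate_criteria(results: dict[str, stats.StatResult], adjacency,
                      feature: str = "",
                      pair: tuple[str, str] = CLOSE_PARADIGMS) -> CriteriaFlags:
    """Apply the two-criteria rule to per-paradigm correlation maps.

    `results` maps paradigm name to the StatResult of the same feature
    against the same per-channel ERP feature family.
    """
    signs = []
    crit2 = False
    for par in pair:
        if par not in results:
            return CriteriaFlags(feature, False, False)
        res = results[par]
        sig = np.flatnonzero(res.mask)
        if sig.size == 0:
            signs.append(0)
        else:
            signs.append(int(np.sign(np.nan_to_num(res.statistic)[sig].mean())))
        crit2 = crit2 or _has_adjacent_pair(sig, adjacency)
    crit1 = all(s != 0 for s in signs) and len(set(signs)) == 1
    return CriteriaFlags(feature, crit1, crit2)


def spearman_reference(x, y) -> tuple[float, float]:
    """Independent Spearman (rho, p) via SciPy, for cross-checking."""
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
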