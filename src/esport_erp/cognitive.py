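"""Cognitive-test metrics and group comparisons.

Reaction-time trials are cleaned per subject in two stages: physiological
threshold exclusion first (simple tests 120-500 ms, choice test 140-700 ms),
then a 1.5-IQR fence on the remaining values. Trial-level metrics (reaction
times, visual-search times) are pooled across a group's subjects after that
per-subject filtering; complex per-subject parameters (correct rate, final
score, count error) contribute exactly one value per subject. Group rows
report mean +/- sd per group, Welch's t with its df, a label-permutation p
(default 100000 permutations) and Hedges' g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .profiles import SummaryStat


@dataclass(frozen=True)
class RTThresholds:
    test: str
    min_ms: float
    max_ms: float

    def __post_init__(self):
        if self.max_ms <= self.min_ms:
            raise ValueError("max_ms must exceed min_ms")


DEFAULT_THRESHOLDS = {
    "RTM": RTThresholds("RTM", 120.0, 500.0),
    "RTK": RTThresholds("RTK", 120.0, 500.0),
    "RTD": RTThresholds("RTD", 140.0, 700.0),
}


def filter_rts(rts, th: RTThresholds | None):
    """Per-subject RT cleaning: threshold exclusion, then the 1.5-IQR fence.

    Returns ``(kept, report)``; `report` counts removals per stage. Passing
    ``th=None`` skips the threshold stage (used for search times).
    """
    rts = np.asarray(rts, dtype=float)
    n0 = rts.size
    if th is not None:
        rts = rts[(rts >= th.min_ms) & (rts <= th.max_ms)]
    n_thresh = n0 - rts.size
    if rts.size >= 4:
        q1, q3 = np.percentile(rts, [25, 75])
        iqr = q3 - q1
        keep = (rts >= q1 - 1.5 * iqr) & (rts <= q3 + 1.5 * iqr)
        n_iqr = int((~keep).sum())
        rts = rts[keep]
    else:
        n_iqr = 0
    return rts, {"n_total": n0, "removed_threshold": n_thresh,
                 "removed_iqr": n_iqr, "kept": rts.size}


def correct_rate(correct) -> float:
    """Percentage of correct responses."""
    correct = np.asarray(correct, dtype=bool)
    if correct.size == 0:
        raise ValueError("no responses")
    return 100.0 * correct.mean()


def vs_metrics(trials: pd.DataFrame) -> dict:
    """Visual-search metrics for one subject.

    `trials` needs columns ``stimulus`` ('L'/'noL'), ``correct`` and
    ``rt_ms``. Final score starts at zero, +1 per right and -1 per wrong
    answer; search times (s) are restricted to correct answers and split by
    condition.
    """
    corr = trials["correct"].to_numpy(dtype=bool)
    score = int(corr.sum() - (~corr).sum())
    ok = trials[corr]
    return {
        "final_score": score,
        "correct_rate": correct_rate(corr),
        "search_l_s": (ok.loc[ok["stimulus"] == "L", "rt_ms"] / 1000.0).tolist(),
        "search_nol_s": (ok.loc[ok["stimulus"] == "noL", "rt_ms"] / 1000.0).tolist(),
    }


def count_error(counted: int, true_count: int) -> float:
    """Signed percentage deviation of the counted from the true target number."""
    if true_count <= 0:
        raise ValueError("true_count must be positive")
    return 100.0 * (counted - true_count) / true_count


# ---------------------------------------------------------------------------
# group metrics from a trial log

def group_metrics(log: pd.DataFrame,
                  thresholds: dict[str, RTThresholds] | None = None) -> dict:
    """Assemble every group metric from a cognitive-test log.

    Returns ``{metric_name: {group: np.ndarray}}``. Trial-level metrics are
    pooled over subjects after per-subject filtering; per-subject metrics
    contribute one value each. Subjects whose trials are all filtered out
    are skipped for the affected pooled metric.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    out: dict[str, dict[str, list]] = {}

    def add(name, group, values):
        out.setdefault(name, {}).setdefault(group, []).extend(np.atleast_1d(values))

    for (sid, grp), sub in log.groupby(["subject_id", "group"]):
        for test in ("RTM", "RTK"):
            tr = sub[sub["test"] == test]
            if len(tr):
                kept, _ = filter_rts(tr["rt_ms"], thresholds[test])
                add(f"{test} reaction time (ms)", grp, kept)
        rtd = sub[sub["test"] == "RTD"]
        if len(rtd):
            ok = rtd[rtd["correct"]]
            kept, _ = filter_rts(ok["rt_ms"], thresholds["RTD"])
            add("RTD reaction time correct (ms)", grp, kept)
            add("RTD correct rate (%)", grp, correct_rate(rtd["correct"]))
        vs = sub[sub["test"] == "VS"]
        if len(vs):
            m = vs_metrics(vs)
            add("VS final score", grp, m["final_score"])
            add("VS correct rate (%)", grp, m["correct_rate"])
            l_kept, _ = filter_rts(np.asarray(m["search_l_s"]), None)
            n_kept, _ = filter_rts(np.asarray(m["search_nol_s"]), None)
            add("VS search time of L (s)", grp, l_kept)
            add("VS search time of no L (s)", grp, n_kept)
        for par in ("MT", "ST"):
            cnt = sub[sub["test"] == par]
            if len(cnt):
                r = cnt.iloc[0]
                add(f"{par} count error (%)", grp,
                    count_error(int(r["counted"]), int(r["true_count"])))

    return {name: {g: np.asarray(v, dtype=float) for g, v in groups.items()}
            for name, groups in out.items()}


# ---------------------------------------------------------------------------
# comparison rows

def compare_group_metrics(pro, novice, n_perm: int = 100_000, seed=None) -> dict:
    """One comparison row: mean +/- sd per group, Welch t(df), permutation p, g."""
    pro = np.asarray(pro, dtype=float)
    novice = np.asarray(novice, dtype=float)
    if pro.size == 0 or novice.size == 0:
        raise ValueError("both group metrics must be non-empty")
    t, df, p = stats.permutation_test(pro, novice, n_perm=n_perm, seed=seed)
    g = stats.hedges_g(pro, novice)
    return {
        "PRO_mean": pro.mean(), "PRO_sd": pro.std(ddof=1),
        "NOVICE_mean": novice.mean(), "NOVICE_sd": novice.std(ddof=1),
        "n_PRO": pro.size, "n_NOVICE": novice.size,
        "t": t, "df": df, "p": p, "g": abs(g),
        "significant": p < 0.05,
    }


def compare_from_summary(pro: SummaryStat, novice: SummaryStat,
                         n_pro: int, n_novice: int) -> dict:
    """Welch t and Hedges g from printed summaries (no permutation p)."""
    t, df = stats.welch_t_from_summary(pro.mean, pro.sd, n_pro,
                                       novice.mean, novice.sd, n_novice)
    g = stats.hedges_g_from_summary(pro.mean, pro.sd, n_pro,
                                    novice.mean, novice.sd, n_novice)
    return {"t": t, "df": df, "g": abs(g),
            "delta": pro.mean - novice.mean}


def metrics_report(log: pd.DataFrame,
                   thresholds: dict[str, RTThresholds] | None = None,
                   n_perm: int = 10_000, seed=None) -> pd.DataFrame:
    """Group-comparison table over all metrics found in `log`.

    t is rounded to one decimal and g to two in the printed columns, while
    the unrounded values are kept alongside.
    """
    gm = group_metrics(log, thresholds)
    rows = []
    for name, groups in gm.items():
        if "PRO" not in groups or "NOVICE" not in groups:
            continue
        row = compare_group_metrics(groups["PRO"], groups["NOVICE"],
                                    n_perm=n_perm, seed=seed)
        row["metric"] = name
        row["t_printed"] = round(row["t"], 1)
        row["g_printed"] = round(row["g"], 2)
        rows.append(row)
    cols = ["metric", "PRO_mean", "PRO_sd", "NOVICE_mean", "NOVICE_sd",
            "n_PRO", "n_NOVICE", "t", "df", "p", "g", "t_printed",
            "g_printed", "significant"]
    return pd.DataFrame(rows)[cols]
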