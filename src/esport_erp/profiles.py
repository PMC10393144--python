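"""Group statistical profiles for the simulator and for worked examples.

The defaults encode the published per-group summaries of the study this
pipeline is modelled on: ERP component amplitudes/latencies per paradigm
(professional vs novice esports players), reaction-time and visual-search
test summaries, oddball count errors, and hours of in-game experience for
the professional group. They drive the synthetic-data generator and the
summary-statistics worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .data import COMPONENTS, PARADIGMS

GROUPS = ("PRO", "NOVICE")


@dataclass(frozen=True)
class ComponentStats:
    """Component magnitude/latency distribution across subjects.

    `amp_mean` is the unsigned magnitude in uV (the component's polarity
    supplies the sign), `lat_mean` in ms post-stimulus.
    """

    amp_mean: float
    amp_sd: float
    lat_mean: float
    lat_sd: float

    def __post_init__(self):
        if self.amp_sd < 0 or self.lat_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


# --- published group summaries -------------------------------------------
# ERP latency (ms) and amplitude magnitude (uV) per paradigm x component,
# mean +/- between-subject sd, n = 10 subjects per group.
_ERP_PRO = {
    ("B/RB", "P200"): ComponentStats(6.78, 4.08, 177, 22),
    ("B/RB", "N200"): ComponentStats(1.35, 4.57, 221, 19),
    ("B/RB", "P300"): ComponentStats(10.66, 2.83, 335, 29),
    ("BT", "P200"): ComponentStats(13.64, 4.84, 187, 15),
    ("BT", "N200"): ComponentStats(11.22, 5.41, 228, 27),
    ("BT", "P300"): ComponentStats(21.44, 6.78, 324, 25),
    ("MT", "P200"): ComponentStats(14.29, 2.97, 195, 12),
    ("MT", "N200"): ComponentStats(10.04, 4.05, 245, 34),
    ("MT", "P300"): ComponentStats(21.84, 6.11, 347, 25),
    ("ST", "P200"): ComponentStats(17.30, 3.78, 209, 22),
    ("ST", "N200"): ComponentStats(10.90, 3.82, 273, 31),
    ("ST", "P300"): ComponentStats(15.87, 5.40, 493, 52),
}
_ERP_NOVICE = {
    ("B/RB", "P200"): ComponentStats(4.84, 2.63, 208, 20),
    ("B/RB", "N200"): ComponentStats(1.42, 2.79, 250, 20),
    ("B/RB", "P300"): ComponentStats(9.28, 3.38, 361, 13),
    ("BT", "P200"): ComponentStats(10.42, 5.19, 209, 14),
    ("BT", "N200"): ComponentStats(6.65, 5.78, 261, 20),
    ("BT", "P300"): ComponentStats(14.68, 5.49, 362, 22),
    ("MT", "P200"): ComponentStats(8.41, 3.24, 217, 14),
    ("MT", "N200"): ComponentStats(5.22, 3.21, 278, 24),
    ("MT", "P300"): ComponentStats(13.48, 3.54, 389, 17),
    ("ST", "P200"): ComponentStats(9.91, 4.44, 222, 15),
    ("ST", "N200"): ComponentStats(4.69, 4.23, 289, 20),
    ("ST", "P300"): ComponentStats(7.75, 3.16, 568, 32),
}

# Cognitive-test group summaries (reaction times in ms, search times in s,
# rates/scores/count errors as printed).
_COG_PRO = {
    "rt": {"RTM": SummaryStat(219, 32), "RTK": SummaryStat(242, 35),
           "RTD": SummaryStat(332, 74)},
    "rtd_correct_rate": 88.3,           # %
    "vs_correct_rate": 87.2,            # %
    "vs_search_l": SummaryStat(2.53, 1.73),    # s, correct "L present"
    "vs_search_nol": SummaryStat(5.16, 2.52),  # s, correct "L absent"
    "count_error": {"MT": SummaryStat(-0.3, 0.8), "ST": SummaryStat(0.4, 4.8)},
}
_COG_NOVICE = {
    "rt": {"RTM": SummaryStat(271, 61), "RTK": SummaryStat(267, 33),
           "RTD": SummaryStat(396, 92)},
    "rtd_correct_rate": 89.7,
    "vs_correct_rate": 92.0,
    "vs_search_l": SummaryStat(2.33, 1.26),
    "vs_search_nol": SummaryStat(5.22, 3.74),
    "count_error": {"MT": SummaryStat(0.0, 1.7), "ST": SummaryStat(-7.3, 5.7)},
}


@dataclass(frozen=True)
class GroupERPProfile:
    """Everything the simulator needs to emulate one group."""

    group: str
    erp: dict = field(default_factory=dict)      # (paradigm, comp) -> ComponentStats
    alpha_power_scale: float = 1.0
    rt: dict = field(default_factory=dict)       # test -> SummaryStat (ms)
    rtd_correct_rate: float = 90.0               # %
    vs_correct_rate: float = 90.0                # %
    vs_search_l: SummaryStat = SummaryStat(2.5, 1.5)
    vs_search_nol: SummaryStat = SummaryStat(5.0, 3.0)
    count_error: dict = field(default_factory=dict)  # paradigm -> SummaryStat (%)
    hours_in_game: tuple[float, float] | None = None  # uniform range, PRO only

    def __post_init__(self):
        for (par, comp), cs in self.erp.items():
            if par not in PARADIGMS or comp not in COMPONENTS:
                raise KeyError(f"unknown paradigm/component {(par, comp)}")
        for key in ("rtd_correct_rate", "vs_correct_rate"):
            v = getattr(self, key)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{key} must be a percentage in [0, 100]")
        # latencies must be ordered P200 < N200 < P300 within each paradigm
        for par in {p for p, _ in self.erp}:
            lats = [self.erp[(par, c)].lat_mean for c in COMPONENTS
                    if (par, c) in self.erp]
            if lats != sorted(lats):
                raise ValueError(f"component latencies out of order in {par}")

    def component(self, paradigm: str, comp: str) -> ComponentStats:
        return self.erp[(paradigm, comp)]

    def scaled_sds(self, factor: float) -> "GroupERPProfile":
        """Copy with all between-subject ERP sds multiplied by `factor`."""
        erp = {k: replace(v, amp_sd=v.amp_sd * factor, lat_sd=v.lat_sd * factor)
               for k, v in self.erp.items()}
        return replace(self, erp=erp)


def default_profiles() -> dict[str, GroupERPProfile]:
    """The two study groups with published summary values as parameters.

    The professionals get a stimulus-locked alpha-power scale of 1.5 (the
    spectrogram comparison in the study shows stronger alpha for that group;
    no magnitude is printed, 1.5x is this package's choice) and 1800-8000
    uniformly distributed hours of in-game experience.
    """
    pro = GroupERPProfile(
        group="PRO", erp=dict(_ERP_PRO), alpha_power_scale=1.5,
        rt=dict(_COG_PRO["rt"]),
        rtd_correct_rate=_COG_PRO["rtd_correct_rate"],
        vs_correct_rate=_COG_PRO["vs_correct_rate"],
        vs_search_l=_COG_PRO["vs_search_l"],
        vs_search_nol=_COG_PRO["vs_search_nol"],
        count_error=dict(_COG_PRO["count_error"]),
        hours_in_game=(1800.0, 8000.0),
    )
    novice = GroupERPProfile(
        group="NOVICE", erp=dict(_ERP_NOVICE), alpha_power_scale=1.0,
        rt=dict(_COG_NOVICE["rt"]),
        rtd_correct_rate=_COG_NOVICE["rtd_correct_rate"],
        vs_correct_rate=_COG_NOVICE["vs_correct_rate"],
        vs_search_l=_COG_NOVICE["vs_search_l"],
        vs_search_nol=_COG_NOVICE["vs_search_nol"],
        count_error=dict(_COG_NOVICE["count_error"]),
    )
    return {"PRO": pro, "NOVICE": novice}


#: Published cognitive-test comparison rows (group mean, sd, n) used by the
#: worked examples: metric -> (PRO SummaryStat, NOVICE SummaryStat, n per group).
TABLE_COGNITIVE_SUMMARIES = {
    "RTM reaction time (ms)": (SummaryStat(219, 32), SummaryStat(271, 61), (282, 281)),
    "RTK reaction time (ms)": (SummaryStat(242, 35), SummaryStat(267, 33), (281, 281)),
    "RTD reaction time correct (ms)": (SummaryStat(332, 74), SummaryStat(396, 92), (259, 258)),
    "RTD correct rate (%)": (SummaryStat(88.3, 3.2), SummaryStat(89.7, 7.8), (10, 10)),
    "VS final score": (SummaryStat(16.90, 6.05), SummaryStat(19.10, 6.37), (10, 10)),
    "VS search time of L (s)": (SummaryStat(2.53, 1.73), SummaryStat(2.33, 1.26), (94, 93)),
    "VS search time of no L (s)": (SummaryStat(5.16, 2.52), SummaryStat(5.22, 3.74), (115, 113)),
    "VS correct rate (%)": (SummaryStat(87.2, 6.7), SummaryStat(92.0, 6.0), (10, 10)),
    "MT count error (%)": (SummaryStat(-0.3, 0.8), SummaryStat(0.0, 1.7), (10, 10)),
    "ST count error (%)": (SummaryStat(0.4, 4.8), SummaryStat(-7.3, 5.7), (10, 10)),
}
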