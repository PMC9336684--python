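"""Reference summary tables from the 52-week cynomolgus-monkey toxicity
program and the pediatric clinical program of the weekly PEGylated rhGH
(40 kDa branched PEG on a 22 kDa protein, clinical dose 0.2 mg/kg/week).

These are the published *inputs* that the analysis operates on: observed
steady-state toxicokinetic exposure metrics by dose group, the
choroid-plexus severity-grade tallies by necropsy day, and the clinical
adverse-reaction counts by trial phase and treatment period.  Raw
animal- and patient-level data were never deposited; the synthetic-data
module generates statistically matched stand-ins for those.
"""

from __future__ import annotations

import pandas as pd

from .clinical import ARTable
from .pk_core import ExposureMetrics

#: observed steady-state exposure metrics (Cmax ng/ml, AUClast ng*h/ml)
#: in monkeys by weekly dose, and in GHD children at the clinical dose
MONKEY_TK_METRICS = {
    0.3: ExposureMetrics(Cmax=3170.0, Tmax=float("nan"), AUClast=182550.0),
    1.0: ExposureMetrics(Cmax=13480.0, Tmax=float("nan"), AUClast=1120960.0),
    3.0: ExposureMetrics(Cmax=46290.0, Tmax=float("nan"), AUClast=4487000.0),
}
HUMAN_TK_METRICS = ExposureMetrics(Cmax=340.0, Tmax=float("nan"), AUClast=37229.0)

#: no-observed-effect / no-observed-adverse-effect levels (mg/kg/week)
NOEL_DOSE = 0.3
NOAEL_DOSE = 3.0

#: median vacuole/cell ratio in the excipient control group at the end
#: of the 52-week treatment period (spontaneous background)
CONTROL_BACKGROUND_RATIO = 0.0595

#: choroid-plexus severity-grade tallies: 52-week study (and its 104-
#: and 157-week recovery necropsies) plus the 26-week study arm.
#: Each entry: (group label, dose mg/kg/week, necropsy day, {grade: count})
CP_GRADE_TALLIES = [
    ("group1_control", 0.0, 374, {"-": 6, "+": 2}),
    ("group1_control", 0.0, 1096, {"-": 2}),
    ("group1_control", 0.0, 1465, {"-": 1, "+": 1}),
    ("group2_0.3", 0.3, 374, {"-": 7, "+": 1}),
    ("group2_0.3", 0.3, 1096, {"-": 2}),
    ("group2_0.3", 0.3, 1465, {"-": 2}),
    ("group4_1", 1.0, 374, {"+": 2, "++": 6}),
    ("group4_1", 1.0, 1096, {"+": 2}),
    ("group4_1", 1.0, 1465, {"+": 2}),
    ("group5_3", 3.0, 374, {"++": 5, "+++": 3}),
    ("group5_3", 3.0, 1096, {"++": 2}),
    ("group5_3", 3.0, 1465, {"++": 2}),
    # 26-week arm (group 3): terminal necropsy and 26-week recovery
    ("group3_1_26wk", 1.0, 184, {"-": 1, "+": 4, "++": 1}),
    ("group3_1_26wk", 1.0, 366, {"+": 3, "++": 1}),
]


def cp_grade_observations() -> pd.DataFrame:
    """Per-animal severity-grade observation table expanded from the
    published tallies (synthetic sequential animal ids; ratio and area
    were not published per animal and are left missing)."""
    rows = []
    counter = 0
    for group, dose, day, tally in CP_GRADE_TALLIES:
        for grade, count in tally.items():
            for _ in range(count):
                counter += 1
                rows.append(
                    {
                        "animal_id": f"A{counter:03d}",
                        "group": group,
                        "dose": dose,
                        "day": day,
                        "vacuole_ratio": float("nan"),
                        "mean_area_um2": float("nan"),
                        "grade": grade,
                    }
                )
    return pd.DataFrame(rows)


#: clinical adverse-reaction counts: (arm, period, n, n_ar, n_cns_ar)
CLINICAL_AR_COUNTS = [
    ("phase3_peg_rhgh_0.2qw", "overall", 228, 72, 4),
    ("phase3_daily_rhgh_0.25qd", "overall", 115, 26, 1),
    ("phase3_peg_rhgh_0.2qw", "week_1_4", 228, 59, 2),
    ("phase3_daily_rhgh_0.25qd", "week_1_4", 115, 15, 0),
    ("phase3_peg_rhgh_0.2qw", "week_5_13", 226, 41, 2),
    ("phase3_daily_rhgh_0.25qd", "week_5_13", 115, 14, 1),
    ("phase3_peg_rhgh_0.2qw", "week_14_25", 220, 22, 0),
    ("phase3_daily_rhgh_0.25qd", "week_14_25", 114, 10, 1),
    ("phase4_1_peg_rhgh_0.2qw", "overall", 686, 74, 5),
    ("phase4_1_daily_rhgh_0.25qd", "overall", 91, 9, 0),
    ("phase4_2_peg_rhgh_lt0.15", "overall", 82, 3, 0),
    ("phase4_2_peg_rhgh_0.15_0.17", "overall", 186, 13, 1),
    ("phase4_2_peg_rhgh_0.17_0.2", "overall", 153, 22, 1),
    ("phase4_2_peg_rhgh_0.2", "overall", 269, 22, 2),
    ("phase4_followup_peg_rhgh_0.2qw", "year_1", 644, 64, 3),
    ("phase4_followup_peg_rhgh_0.2qw", "year_2", 411, 9, 1),
    ("phase4_followup_peg_rhgh_0.2qw", "year_3", 401, 5, 0),
]


def clinical_ar_table() -> ARTable:
    """The published AR count table as an :class:`~pegtk.clinical.ARTable`."""
    return ARTable(pd.DataFrame(CLINICAL_AR_COUNTS, columns=["arm", "period", "n", "n_ar", "n_cns_ar"]))
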