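"""Published summary data of the cefaclor fine-granules acceptability study.

The study's raw evaluations are not shareable, but its published report
prints complete per-variable counts: observer-reported outcomes over time
(58/57/58 evaluations at timepoints 1/2/3), the same outcomes by age
group (33/71/48/21 evaluations pooled over timepoints), and the
end-of-treatment adherence distribution (56 patients).  This module ships
those printed counts verbatim as :class:`~acceptmap.stats.ContingencyTable`
inputs, together with the test flag (Fisher vs chi-squared) printed next
to each testable variable.

Note the two published tables are mutually inconsistent in their missing
tallies (e.g. 170 non-missing reactions over time vs 167 across age
groups), so no single row-level dataset can reproduce both;
:func:`study_evaluations` therefore reconstructs a synthetic row-level
set matching the over-time marginals only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codebook import DEFAULT_CODEBOOK
from .schema import EvaluationSet
from .stats import ContingencyTable

__all__ = [
    "TABLE1_TEST_FLAGS",
    "TABLE2_TEST_FLAGS",
    "adherence_counts",
    "study_evaluations",
    "table1_counts",
    "table2_counts",
]

_T1_COLS = [1, 2, 3]  # timepoints; n = 58, 57, 58
_TABLE1: dict[str, dict[str, tuple[int, ...]]] = {
    "result_intake": {"fully": (57, 57, 57), "partly": (0, 0, 0), "not_taken": (1, 0, 1)},
    "reaction": {"positive": (32, 31, 35), "neutral": (19, 21, 20), "negative": (5, 4, 3)},
    "prep_admin_time": {"short": (3, 8, 7), "medium": (26, 23, 29), "long": (20, 19, 14)},
    "divided_dose": {"no": (55, 55, 57), "yes": (3, 2, 1)},
    "food_drink": {"no": (50, 49, 50), "yes": (8, 8, 8)},
    "alteration": {"no": (58, 57, 58), "yes": (0, 0, 0)},
    "extra_device": {"no": (26, 26, 25), "yes": (32, 31, 33)},
    "reward": {"no": (58, 57, 58), "yes": (0, 0, 0)},
    "restraint": {"no": (57, 56, 57), "yes": (1, 1, 1)},
}
_TABLE1_MISSING = {
    "reaction": (2, 1, 0),
    "prep_admin_time": (9, 7, 8),
}

#: Test flags printed over time: F = Fisher exact, chi2 = Pearson chi-squared.
TABLE1_TEST_FLAGS = {
    "result_intake": "fisher_exact",
    "reaction": "fisher_exact",
    "prep_admin_time": "chi_square",
    "divided_dose": "fisher_exact",
    "extra_device": "chi_square",
}

_T2_COLS = ["0-2", "3-5", "6-11", "12-17"]  # n = 33, 71, 48, 21
_TABLE2: dict[str, dict[str, tuple[int, ...]]] = {
    "result_intake": {"fully": (33, 68, 48, 21), "partly": (0, 0, 0, 0), "not_taken": (0, 3, 0, 0)},
    "reaction": {"positive": (6, 39, 30, 21), "neutral": (21, 21, 15, 0), "negative": (3, 8, 3, 0)},
    "prep_admin_time": {"short": (0, 6, 0, 3), "medium": (21, 30, 24, 3), "long": (9, 29, 15, 6)},
    "divided_dose": {"no": (30, 65, 48, 21), "yes": (3, 6, 0, 0)},
    "food_drink": {"no": (24, 65, 42, 18), "yes": (9, 6, 6, 3)},
    "alteration": {"no": (33, 71, 48, 21), "yes": (0, 0, 0, 0)},
    "extra_device": {"no": (12, 30, 18, 18), "yes": (21, 41, 30, 3)},
    "reward": {"no": (33, 71, 48, 21), "yes": (0, 0, 0, 0)},
    "restraint": {"no": (33, 68, 48, 21), "yes": (0, 3, 0, 0)},
}
_TABLE2_MISSING = {
    "reaction": (3, 3, 0, 0),
    "prep_admin_time": (3, 6, 9, 9),
}

#: Test flags printed across age groups.
TABLE2_TEST_FLAGS = {
    "result_intake": "fisher_exact",
    "reaction": "chi_square",
    "prep_admin_time": "chi_square",
    "divided_dose": "fisher_exact",
    "food_drink": "chi_square",
    "extra_device": "chi_square",
    "restraint": "fisher_exact",
}

#: Adherence bands of the 56 patients with end-of-treatment information.
_ADHERENCE = {"81-100": 54, "61-80": 2}
_N_DIFFICULTY = 2


def _build(raw, missing_map, cols) -> dict[str, ContingencyTable]:
    out = {}
    for var, rows in raw.items():
        counts = pd.DataFrame(rows, index=cols).T
        missing = pd.Series(missing_map.get(var, (0,) * len(cols)), index=cols)
        out[var] = ContingencyTable(counts=counts, missing_per_col=missing)
    return out


def table1_counts() -> dict[str, ContingencyTable]:
    """Published outcome counts per timepoint, one table per variable."""
    return _build(_TABLE1, _TABLE1_MISSING, _T1_COLS)


def table2_counts() -> dict[str, ContingencyTable]:
    """Published outcome counts per age group, one table per variable."""
    return _build(_TABLE2, _TABLE2_MISSING, _T2_COLS)


def adherence_counts() -> dict[str, int]:
    """Published adherence-band counts (56 reporting patients)."""
    return dict(_ADHERENCE)


def study_evaluations() -> EvaluationSet:
    """Synthetic row-level reconstruction of the study's evaluation set.

    Reproduces exactly the published per-timepoint marginals (counts and
    missing tallies of every variable, 58/57/58 evaluations) and the
    published metadata distribution (ages 11/24/16/7 per group, 42 boys /
    16 girls, 52 first exposures, dosing frequency 44x3/13x1/1x5 per day,
    56 adherence reports of which 54 in the 81-100% band).  The joint
    row-level structure is synthetic: the publication prints only
    marginals, so categories are assigned to patients deterministically
    in patient order, one variable at a time.
    """
    codebook = DEFAULT_CODEBOOK
    pids = [f"P{i + 1:02d}" for i in range(58)]
    rows = []
    for t_idx, tp in enumerate(_T1_COLS):
        present = pids if tp != 2 else pids[:-1]  # one patient missed timepoint 2
        frame: dict[str, list] = {"patient_id": present, "timepoint": [tp] * len(present)}
        for var in codebook.variable_names:
            values: list = []
            for cat in codebook.categories(var):
                values += [cat] * _TABLE1[var][cat][t_idx]
            values += [np.nan] * _TABLE1_MISSING.get(var, (0, 0, 0))[t_idx]
            assert len(values) == len(present)
            frame[var] = values
        rows.append(pd.DataFrame(frame))
    evaluations = pd.concat(rows, ignore_index=True)

    ages = [1.0] * 11 + [4.0] * 24 + [8.0] * 16 + [14.0] * 7
    sexes = ["M"] * 42 + ["F"] * 16
    first = [True] * 52 + [False] * 6
    dosing = [3] * 44 + [1] * 13 + [5]
    meta = pd.DataFrame(
        {
            "age_years": ages,
            "sex": sexes,
            "first_exposure": first,
            "dosing_frequency": dosing,
            "treatment_duration": [5] * 58,
        },
        index=pd.Index(pids, name="patient_id"),
    )
    reporting = pids[:56]
    bands = ["81-100"] * 54 + ["61-80"] * 2
    difficulty = [False] * 54 + [True] * _N_DIFFICULTY
    adherence = pd.DataFrame(
        {"band": bands, "difficulty": difficulty},
        index=pd.Index(reporting, name="patient_id"),
    )
    return EvaluationSet(
        evaluations=evaluations, meta=meta, adherence=adherence, codebook=codebook
    )
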