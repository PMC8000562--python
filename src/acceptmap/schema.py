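"""Data model, validation and CSV I/O for acceptability evaluations.

One *evaluation* is the standardized observer report of a single medicine
intake by a single patient at one of three timepoints (first intake after
inclusion, 24 h later, last intake of the treatment).  It records the
nine observational variables of the codebook; any of them may be missing.
Patient metadata (age, sex, prior exposure, dosing frequency, treatment
duration) and an optional end-of-treatment adherence report (percentage
band of the prescribed dose taken, and whether any difficulty with
preparation/administration influenced adherence) are attached per
patient.

The on-disk format is a single flat UTF-8, comma-delimited CSV with one
row per (patient, timepoint) evaluation; see :data:`CSV_COLUMNS`.  Empty
cells encode missing observational values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .codebook import DEFAULT_CODEBOOK, Codebook, CodebookError

__all__ = [
    "AGE_GROUPS",
    "ADHERENCE_BANDS",
    "CSV_COLUMNS",
    "EvaluationSet",
    "IntegrityError",
    "ParseError",
    "SchemaError",
    "age_group",
    "classify_time",
    "read_evaluations",
    "write_evaluations",
]


class SchemaError(ValueError):
    """Base class for evaluation-data validation failures."""


class ParseError(SchemaError):
    """Malformed cell; carries the offending row number and column name."""

    def __init__(self, row: int, column: str, message: str):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column {column!r}: {message}")


class IntegrityError(SchemaError):
    """Cross-row inconsistency, e.g. duplicate (patient, timepoint)."""


ADHERENCE_BANDS = ("0-20", "21-40", "41-60", "61-80", "81-100")
AGE_GROUPS = ("0-2", "3-5", "6-11", "12-17")

META_COLUMNS = [
    "age_years",
    "sex",
    "first_exposure",
    "dosing_frequency",
    "treatment_duration",
]
ADHERENCE_COLUMNS = ["adherence_band", "adherence_difficulty"]
CSV_COLUMNS = (
    ["patient_id", "timepoint"]
    + DEFAULT_CODEBOOK.variable_names
    + META_COLUMNS
    + ADHERENCE_COLUMNS
)

TIMEPOINTS = (1, 2, 3)


def classify_time(total_seconds: float) -> str:
    """Classify the summed preparation + administration time.

    ``short`` is one minute and less, ``medium`` runs up to and including
    2 min 30 s, anything longer is ``long``.
    """
    if total_seconds < 0:
        raise ValueError(f"total_seconds must be non-negative, got {total_seconds}")
    if total_seconds <= 60:
        return "short"
    if total_seconds <= 150:
        return "medium"
    return "long"


def age_group(age_years: float) -> str:
    """Map an age in (completed) years to its pediatric age group."""
    if not 0 <= age_years < 18:
        raise ValueError(f"age_years must be in [0, 18), got {age_years}")
    if age_years < 3:
        return "0-2"
    if age_years < 6:
        return "3-5"
    if age_years < 12:
        return "6-11"
    return "12-17"


@dataclass
class EvaluationSet:
    """Validated collection of evaluations plus per-patient metadata.

    Attributes
    ----------
    evaluations : DataFrame
        One row per (patient, timepoint); columns ``patient_id``,
        ``timepoint`` and the nine observational variables (object dtype,
        ``NaN`` for missing).
    meta : DataFrame
        Indexed by patient_id with columns ``age_years``, ``sex``,
        ``first_exposure``, ``dosing_frequency``, ``treatment_duration``.
    adherence : DataFrame or None
        Indexed by patient_id with columns ``band`` and ``difficulty``.
    latent_profile : Series or None
        Generator ground truth (profile name per evaluation); set only by
        the synthetic generators, never serialized to CSV.
    """

    evaluations: pd.DataFrame
    meta: pd.DataFrame
    adherence: pd.DataFrame | None = None
    codebook: Codebook = field(default_factory=lambda: DEFAULT_CODEBOOK)
    latent_profile: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ev = self.evaluations
        required = ["patient_id", "timepoint"] + self.codebook.variable_names
        missing_cols = [c for c in required if c not in ev.columns]
        if missing_cols:
            raise SchemaError(f"evaluations frame lacks columns {missing_cols}")
        dup = ev.duplicated(subset=["patient_id", "timepoint"])
        if dup.any():
            pair = ev.loc[dup.idxmax(), ["patient_id", "timepoint"]].tolist()
            raise IntegrityError(f"duplicate (patient, timepoint) pair {tuple(pair)}")
        bad_tp = ~ev["timepoint"].isin(TIMEPOINTS)
        if bad_tp.any():
            raise SchemaError(
                f"timepoint must be one of {TIMEPOINTS}, got "
                f"{ev.loc[bad_tp.idxmax(), 'timepoint']!r}"
            )
        for var in self.codebook.variable_names:
            col = ev[var]
            ok = col.isna() | col.isin(self.codebook.categories(var))
            if not ok.all():
                raise SchemaError(
                    f"{col[~ok].iloc[0]!r} is not a category of {var!r}"
                )
        for pid in ev["patient_id"].unique():
            if pid not in self.meta.index:
                raise IntegrityError(f"patient {pid!r} has no metadata")
        ages = self.meta["age_years"]
        if ((ages < 0) | (ages >= 18)).any():
            raise SchemaError("age_years must lie in [0, 18)")
        if (self.meta["dosing_frequency"] < 1).any():
            raise SchemaError("dosing_frequency must be >= 1")
        if self.adherence is not None and len(self.adherence):
            bad = ~self.adherence["band"].isin(ADHERENCE_BANDS)
            if bad.any():
                raise SchemaError(
                    f"unknown adherence band {self.adherence['band'][bad].iloc[0]!r}"
                )

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.evaluations)

    @property
    def observational(self) -> pd.DataFrame:
        """The N x 9 categorical frame (NaN = missing), evaluation order."""
        return self.evaluations[self.codebook.variable_names]

    @property
    def n_missing_cells(self) -> int:
        return int(self.observational.isna().sum().sum())

    def with_age_groups(self) -> pd.DataFrame:
        """Evaluations joined with metadata plus a derived age_group column.

        Age groups are attached at analysis time from ``age_years`` rather
        than stored, so they can never drift out of sync.
        """
        joined = self.evaluations.merge(
            self.meta, left_on="patient_id", right_index=True, how="left"
        )
        joined["age_group"] = joined["age_years"].map(age_group)
        return joined

    def subset(self, mask: Iterable[bool]) -> "EvaluationSet":
        mask = np.asarray(list(mask), dtype=bool)
        ev = self.evaluations.loc[mask].reset_index(drop=True)
        latent = None
        if self.latent_profile is not None:
            latent = self.latent_profile.loc[mask].reset_index(drop=True)
        return EvaluationSet(
            evaluations=ev,
            meta=self.meta,
            adherence=self.adherence,
            codebook=self.codebook,
            latent_profile=latent,
        )

    def copy(self) -> "EvaluationSet":
        return EvaluationSet(
            evaluations=self.evaluations.copy(),
            meta=self.meta.copy(),
            adherence=None if self.adherence is None else self.adherence.copy(),
            codebook=self.codebook,
            latent_profile=None
            if self.latent_profile is None
            else self.latent_profile.copy(),
        )


# -- CSV I/O -------------------------------------------------------------


def _parse_bool(raw: str, row: int, column: str) -> bool:
    low = raw.strip().lower()
    if low in {"true", "1", "yes"}:
        return True
    if low in {"false", "0", "no"}:
        return False
    raise ParseError(row, column, f"cannot parse boolean from {raw!r}")


def read_evaluations(path: str | Path, codebook: Codebook | None = None) -> EvaluationSet:
    """Read and validate an evaluation CSV (schema in :data:`CSV_COLUMNS`).

    Unknown category strings are rejected with the row and column named;
    empty observational cells become missing values.
    """
    codebook = codebook or DEFAULT_CODEBOOK
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"{path} lacks required columns {missing_cols}")

    ev_rows: list[dict] = []
    meta_rows: dict[str, dict] = {}
    adh_rows: dict[str, dict] = {}
    for i, rec in enumerate(raw.to_dict("records")):
        rownum = i + 2  # 1-based, after the header
        pid = rec["patient_id"].strip()
        if not pid:
            raise ParseError(rownum, "patient_id", "empty patient id")
        try:
            tp = int(rec["timepoint"])
        except ValueError:
            raise ParseError(rownum, "timepoint", f"not an integer: {rec['timepoint']!r}")
        row: dict = {"patient_id": pid, "timepoint": tp}
        for var in codebook.variable_names:
            cell = rec[var].strip()
            if cell == "":
                row[var] = np.nan
            else:
                try:
                    codebook.validate_value(var, cell)
                except CodebookError as exc:
                    raise ParseError(rownum, var, str(exc)) from exc
                row[var] = cell
        ev_rows.append(row)

        if pid not in meta_rows:
            try:
                meta_rows[pid] = {
                    "age_years": float(rec["age_years"]),
                    "sex": rec["sex"].strip(),
                    "first_exposure": _parse_bool(rec["first_exposure"], rownum, "first_exposure"),
                    "dosing_frequency": int(rec["dosing_frequency"]),
                    "treatment_duration": int(rec["treatment_duration"]),
                }
            except ValueError as exc:
                raise ParseError(rownum, "age_years", f"bad metadata: {exc}") from exc
        band = rec["adherence_band"].strip()
        if band and pid not in adh_rows:
            if band not in ADHERENCE_BANDS:
                raise ParseError(rownum, "adherence_band", f"unknown band {band!r}")
            adh_rows[pid] = {
                "band": band,
                "difficulty": _parse_bool(rec["adherence_difficulty"] or "no", rownum, "adherence_difficulty"),
            }

    evaluations = pd.DataFrame(ev_rows, columns=["patient_id", "timepoint"] + codebook.variable_names)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "patient_id"
    adherence = None
    if adh_rows:
        adherence = pd.DataFrame.from_dict(adh_rows, orient="index")
        adherence.index.name = "patient_id"
    return EvaluationSet(evaluations=evaluations, meta=meta, adherence=adherence, codebook=codebook)


def write_evaluations(evalset: EvaluationSet, path: str | Path) -> None:
    """Write an :class:`EvaluationSet` to the flat CSV schema (round-trip safe)."""
    rows = []
    for _, rec in evalset.evaluations.iterrows():
        pid = rec["patient_id"]
        meta = evalset.meta.loc[pid]
        out = {"patient_id": pid, "timepoint": int(rec["timepoint"])}
        for var in evalset.codebook.variable_names:
            val = rec[var]
            out[var] = "" if (isinstance(val, float) and math.isnan(val)) else val
        out.update(
            {
                "age_years": meta["age_years"],
                "sex": meta["sex"],
                "first_exposure": bool(meta["first_exposure"]),
                "dosing_frequency": int(meta["dosing_frequency"]),
                "treatment_duration": int(meta["treatment_duration"]),
            }
        )
        if evalset.adherence is not None and pid in evalset.adherence.index:
            adh = evalset.adherence.loc[pid]
            out["adherence_band"] = adh["band"]
            out["adherence_difficulty"] = bool(adh["difficulty"])
        else:
            out["adherence_band"] = ""
            out["adherence_difficulty"] = ""
        rows.append(out)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
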