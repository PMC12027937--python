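"""Subject and cohort containers plus their CSV serialisation.

A :class:`Subject` is one phenotyped individual: demographics, anthropometry,
gas exchange, fasting labs, blood pressure and treatment flags.  Blood
pressure fields hold the already-averaged reading (the clinical protocol
averages three seated measurements upstream of this data model).

The CSV dialect is fixed so fixtures stay bit-stable: comma separated, UTF-8,
"." decimals, mandatory header, booleans written as 0/1 and sex as F/M.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationError

#: Column order of the cohort CSV schema.
CSV_COLUMNS = (
    "id",
    "group",
    "sex",
    "age",
    "weight",
    "height",
    "wc",
    "resistance",
    "vo2",
    "vco2",
    "glucose",
    "insulin",
    "hba1c",
    "total_c",
    "ldl_c",
    "hdl_c",
    "tg",
    "crp",
    "sbp",
    "dbp",
    "on_lipid_treatment",
    "on_bp_treatment",
    "diagnosed_t2dm",
)

_BOOL_COLUMNS = ("on_lipid_treatment", "on_bp_treatment", "diagnosed_t2dm")
_NONNEG = ("glucose", "insulin", "hba1c", "total_c", "ldl_c", "hdl_c", "tg", "crp")


@dataclass
class Subject:
    """One phenotyped individual.

    Units: age years, weight kg, height m, waist circumference (wc) cm,
    resistance ohm, vo2/vco2 L/min (STPD), labs in conventional units
    (mg/dL except insulin µU/mL and HbA1c %), blood pressure mmHg.
    """

    id: str
    group: str
    sex: str
    age: float
    weight: float
    height: float
    wc: float
    resistance: float
    vo2: float
    vco2: float
    glucose: float
    insulin: float
    hba1c: float
    total_c: float
    ldl_c: float
    hdl_c: float
    tg: float
    crp: float
    sbp: float
    dbp: float
    on_lipid_treatment: bool = False
    on_bp_treatment: bool = False
    diagnosed_t2dm: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"subject {self.id}: sex must be 'F' or 'M', got {self.sex!r}")
        if not self.weight > 0:
            raise ValidationError(f"subject {self.id}: weight must be > 0")
        if not self.height > 0:
            raise ValidationError(f"subject {self.id}: height must be > 0")
        for name in _NONNEG:
            if getattr(self, name) < 0:
                raise ValidationError(f"subject {self.id}: {name} must be >= 0")
        if not self.sbp > self.dbp:
            raise ValidationError(
                f"subject {self.id}: systolic pressure ({self.sbp}) must exceed diastolic ({self.dbp})"
            )


@dataclass
class Cohort:
    """Ordered collection of subjects sharing a group label.

    ``targets`` optionally carries the latent per-subject values the
    synthetic generator assigned (e.g. target BMR and FFM) so round-trip
    properties can be checked; it is never serialised.
    """

    label: str
    subjects: list[Subject]
    targets: Optional[pd.DataFrame] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValidationError("cohort must contain at least one subject")
        bad = {s.group for s in self.subjects} - {self.label}
        if bad:
            raise ValidationError(f"cohort {self.label!r} contains subjects with group labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {f.name: getattr(s, f.name) for f in fields(Subject)}
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
        for col in _BOOL_COLUMNS:
            df[col] = df[col].astype(int)
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str | None = None) -> "Cohort":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing column(s): {', '.join(missing)}")
        subjects = []
        for i, rec in enumerate(df.to_dict("records")):
            kwargs = {c: rec[c] for c in CSV_COLUMNS}
            for col in _BOOL_COLUMNS:
                kwargs[col] = bool(int(kwargs[col]))
            kwargs["id"] = str(kwargs["id"])
            kwargs["group"] = str(kwargs["group"])
            kwargs["sex"] = str(kwargs["sex"])
            try:
                subjects.append(Subject(**kwargs))
            except (ValidationError, TypeError, ValueError) as exc:
                raise ValidationError(f"row {i + 2}: {exc}") from exc  # +2: header + 1-based
        labels = {s.group for s in subjects}
        if label is None:
            if len(labels) != 1:
                raise ValidationError(f"cohort file mixes group labels {sorted(labels)}")
            label = labels.pop()
        return cls(label=label, subjects=subjects)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "Cohort":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"cohort file not found: {path}")
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_dataframe(df, label=label)


def concat_cohorts(cohorts: Iterable[Cohort]) -> pd.DataFrame:
    """Stack several cohorts into one subject-level DataFrame."""
    return pd.concat([c.to_dataframe() for c in cohorts], ignore_index=True)
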