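"""Derived cardiometabolic indices: HOMA-IR, VAI and the continuous
metabolic-syndrome (MetS) z-score, with explicit unit conversion.

Unit contract
-------------
HOMA-IR takes insulin in µU/mL and glucose in mmol/L.  The visceral
adiposity index takes triglycerides and HDL in mmol/L — its constants
(1.03/0.81 mmol/L TG, 1.31/1.52 mmol/L HDL) are sex-specific population
reference values on the molar scale.  The MetS z-score works on the
conventional scale (mg/dL, cm, mmHg) where its anchor values (e.g. HDL
40/50 mg/dL, WC 94/80 cm) are defined.  Conversions are always explicit
through :func:`convert`; the default table carries precise molar factors,
and a preset with two-decimal rounded factors is available for strict
replication of sources that print rounded conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

# Factors are "conventional units per SI unit": mg/dL per mmol/L for the
# metabolites, µU/mL per pmol/L for insulin (retained for I/O only).
MOLAR_FACTORS: dict[str, float] = {
    "glucose": 18.016,
    "total_cholesterol": 38.67,
    "ldl_cholesterol": 38.67,
    "hdl_cholesterol": 38.67,
    "triglycerides": 88.57,
    "insulin": 1.0 / 7.18,
}

# Rounded two-decimal factors as sometimes printed in clinical reports
# (1 mg/dL = 0.06 mmol/L glucose, 0.03 cholesterol, 0.01 TG).
PAPER_ROUNDED_FACTORS: dict[str, float] = {
    "glucose": 1.0 / 0.06,
    "total_cholesterol": 1.0 / 0.03,
    "ldl_cholesterol": 1.0 / 0.03,
    "hdl_cholesterol": 1.0 / 0.03,
    "triglycerides": 1.0 / 0.01,
    "insulin": 1.0 / 7.18,
}

CONVERSION_PRESETS: dict[str, Mapping[str, float]] = {
    "molar": MOLAR_FACTORS,
    "paper_rounded": PAPER_ROUNDED_FACTORS,
}


def conversion_table(preset: str = "molar") -> Mapping[str, float]:
    try:
        return CONVERSION_PRESETS[preset]
    except KeyError:
        raise ConfigurationError(
            f"unknown conversion preset {preset!r}; choose from {sorted(CONVERSION_PRESETS)}"
        ) from None


def convert(value, analyte: str, direction: str, table: Mapping[str, float] | None = None):
    """Convert an analyte between conventional and SI units.

    ``direction`` is ``"to_mmol"`` (conventional → SI) or ``"to_mgdl"``
    (SI → conventional); the two are exact inverses.
    """
    table = MOLAR_FACTORS if table is None else table
    if analyte not in table:
        raise ConfigurationError(f"unknown analyte {analyte!r}; known: {sorted(table)}")
    value = np.asarray(value, dtype=float)
    if direction == "to_mmol":
        out = value / table[analyte]
    elif direction == "to_mgdl":
        out = value * table[analyte]
    else:
        raise ValidationError(f"direction must be 'to_mmol' or 'to_mgdl', got {direction!r}")
    return float(out) if out.ndim == 0 else out


def homa_ir(insulin, glucose_mmol):
    """Homeostatic model assessment of insulin resistance.

    insulin [µU/mL] × glucose [mmol/L] / 22.5; bilinear in its inputs.
    """
    insulin = np.asarray(insulin, dtype=float)
    glucose_mmol = np.asarray(glucose_mmol, dtype=float)
    if np.any(insulin < 0) or np.any(glucose_mmol < 0):
        raise ValidationError("insulin and glucose must be non-negative")
    out = insulin * glucose_mmol / 22.5
    return float(out) if out.ndim == 0 else out


def vai(sex: str, wc, bmi, tg_mmol, hdl_mmol):
    """Visceral adiposity index (sex-specific, TG and HDL in mmol/L).

    men:   (WC / (39.68 + 1.88·BMI)) · (TG/1.03) · (1.31/HDL)
    women: (WC / (36.58 + 1.89·BMI)) · (TG/0.81) · (1.52/HDL)
    """
    wc = np.asarray(wc, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    tg_mmol = np.asarray(tg_mmol, dtype=float)
    hdl_mmol = np.asarray(hdl_mmol, dtype=float)
    if np.any(wc <= 0) or np.any(bmi <= 0) or np.any(tg_mmol <= 0):
        raise ValidationError("WC, BMI and TG must be > 0")
    if np.any(hdl_mmol <= 0):
        raise ValidationError("HDL must be > 0")
    if sex == "M":
        out = (wc / (39.68 + 1.88 * bmi)) * (tg_mmol / 1.03) * (1.31 / hdl_mmol)
    elif sex == "F":
        out = (wc / (36.58 + 1.89 * bmi)) * (tg_mmol / 0.81) * (1.52 / hdl_mmol)
    else:
        raise ValidationError(f"sex must be 'F' or 'M', got {sex!r}")
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SdVector:
    """Per-component standard deviations scaling the MetS z-score terms.

    Component units: HDL/TG/glucose mg/dL, WC cm, SBP/DBP mmHg.  The
    source population of these SDs is an analysis decision; the pipeline
    default is the pooled analysis sample so that scores of different
    groups live on one common scale.
    """

    hdl: float
    tg: float
    glucose: float
    wc: float
    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValidationError(f"SdVector.{f.name} must be > 0, got {v}")


#: Sex-specific anchor values of the z-score components (conventional units).
DEFAULT_ANCHORS: dict[str, dict[str, float]] = {
    "M": {"hdl": 40.0, "tg": 150.0, "glucose": 100.0, "wc": 94.0, "sbp": 130.0, "dbp": 85.0},
    "F": {"hdl": 50.0, "tg": 150.0, "glucose": 100.0, "wc": 80.0, "sbp": 130.0, "dbp": 85.0},
}

_Z_COMPONENTS = ("hdl", "tg", "glucose", "wc", "sbp", "dbp")


def component_sds(cohort_values: Mapping[str, Sequence[float]]) -> SdVector:
    """Sample SDs (n−1 denominator) of the six z-score components.

    ``cohort_values`` maps component name → values over the analysis
    population (by default the pooled sample of all groups compared).
    """
    sds = {}
    for name in _Z_COMPONENTS:
        if name not in cohort_values:
            raise ValidationError(f"missing z-score component {name!r}")
        vals = np.asarray(cohort_values[name], dtype=float)
        if vals.size < 2:
            raise ValidationError(f"component {name!r} needs at least 2 values to estimate an SD")
        sd = float(np.std(vals, ddof=1))
        if sd <= 0:
            raise ValidationError(f"component {name!r} is constant; its SD cannot scale a z-score")
        sds[name] = sd
    return SdVector(**sds)


def mets_zscore(
    sex: str,
    hdl: float,
    tg: float,
    glucose: float,
    wc: float,
    sbp: float,
    dbp: float,
    sds: SdVector,
    anchors: Mapping[str, Mapping[str, float]] | None = None,
) -> float:
    """Continuous cardiometabolic risk score.

    Sum of six SD-scaled deviations from the sex-specific anchors; the HDL
    term is reversed, (anchor − HDL)/SD, so that higher HDL lowers risk.
    Exactly zero for a subject sitting at the anchor point, for any valid
    SD vector.
    """
    anchors = DEFAULT_ANCHORS if anchors is None else anchors
    if sex not in anchors:
        raise ValidationError(f"sex must be one of {sorted(anchors)}, got {sex!r}")
    a = anchors[sex]
    missing = [c for c in _Z_COMPONENTS if c not in a]
    if missing:
        raise ValidationError(f"anchor set for sex {sex!r} missing components {missing}")
    values = {"hdl": hdl, "tg": tg, "glucose": glucose, "wc": wc, "sbp": sbp, "dbp": dbp}
    for name, v in values.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValidationError(f"missing z-score component {name!r}")
    score = (a["hdl"] - values["hdl"]) / sds.hdl
    for name in ("tg", "glucose", "wc", "sbp", "dbp"):
        score += (values[name] - a[name]) / getattr(sds, name)
    return float(score)
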