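"""Indirect calorimetry, BIA body composition, BMI and BMR normalisation.

Energy expenditure from gas exchange uses the abbreviated Weir equation
(no urinary-nitrogen term, appropriate when no urine collection is done):

    EE [kcal/day] = (3.941 * VO2 + 1.106 * VCO2) * 1440,   VO2/VCO2 in L/min.

Fat-free mass is predicted from whole-body electrical resistance with
sex-specific linear equations of the standard BIA form

    FFM [kg] = a + b * height_cm^2 / R + c * weight + d * age.

Heights are stored in metres throughout the package; the cm^2 conversion
happens inside :func:`predict_ffm` so no silent 1e4 factor can creep in.
The default coefficients are *placeholders* of plausible magnitude, not a
transcription of any published population-specific equation; for clinical
use supply the published male (Gray-type) and female (Bedogni-type)
coefficients through the configuration file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import numpy as np

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class WeirCoefficients:
    """Caloric equivalents of the abbreviated Weir equation."""

    o2_coeff: float = 3.941  # kcal per litre O2
    co2_coeff: float = 1.106  # kcal per litre CO2
    minutes_per_day: float = 1440.0

    def __post_init__(self) -> None:
        if self.o2_coeff <= 0 or self.co2_coeff <= 0:
            raise ValidationError("Weir coefficients must be positive")


DEFAULT_WEIR = WeirCoefficients()


@dataclass(frozen=True)
class FfmEquation:
    """Sex-specific linear BIA prediction of fat-free mass."""

    sex: str
    intercept: float
    coeff_ht2_over_r: float
    coeff_weight: float
    coeff_age: float

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"FfmEquation sex must be 'F' or 'M', got {self.sex!r}")


# Placeholder coefficients of the standard BIA linear form — see module
# docstring; override with published population-specific values via config.
DEFAULT_FFM_EQUATIONS: dict[str, FfmEquation] = {
    "F": FfmEquation(sex="F", intercept=0.0, coeff_ht2_over_r=0.60, coeff_weight=0.20, coeff_age=-0.10),
    "M": FfmEquation(sex="M", intercept=0.0, coeff_ht2_over_r=0.65, coeff_weight=0.26, coeff_age=-0.10),
}

EquationSet = Union[Mapping[str, FfmEquation], Iterable[FfmEquation]]


def _as_equation_map(equations: EquationSet | None) -> Mapping[str, FfmEquation]:
    if equations is None:
        return DEFAULT_FFM_EQUATIONS
    if isinstance(equations, Mapping):
        return equations
    return {eq.sex: eq for eq in equations}


@dataclass(frozen=True)
class BodyComposition:
    ffm_kg: float
    fm_kg: float
    ffm_pct: float
    fm_pct: float
    bmi: float


@dataclass(frozen=True)
class BmrPanel:
    bmr_kcal_day: float
    bmr_per_kg_ffm: float
    bmr_per_kg_bw: float


def weir_bmr(vo2, vco2, coeffs: WeirCoefficients = DEFAULT_WEIR):
    """Energy expenditure (kcal/day) from O2 uptake and CO2 output (L/min).

    Accepts scalars or arrays; linear and monotone in both gas inputs.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValidationError("gas-exchange rates must be non-negative")
    out = (coeffs.o2_coeff * vo2 + coeffs.co2_coeff * vco2) * coeffs.minutes_per_day
    return float(out) if out.ndim == 0 else out


def vo2_for_bmr(bmr_kcal_day, rq: float = 0.85, coeffs: WeirCoefficients = DEFAULT_WEIR):
    """Invert the Weir equation at a fixed respiratory quotient.

    Returns (vo2, vco2) in L/min such that ``weir_bmr`` recovers
    ``bmr_kcal_day`` exactly and vco2/vo2 = rq.
    """
    if not 0 < rq <= 1.2:
        raise ValidationError(f"respiratory quotient {rq} outside plausible range (0, 1.2]")
    bmr = np.asarray(bmr_kcal_day, dtype=float)
    if np.any(bmr < 0):
        raise ValidationError("BMR must be non-negative")
    vo2 = bmr / (coeffs.minutes_per_day * (coeffs.o2_coeff + coeffs.co2_coeff * rq))
    return vo2, rq * vo2


def compute_bmi(weight, height):
    """Body mass index: weight (kg) / height (m) squared."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0):
        raise ValidationError("height must be > 0")
    out = weight / height**2
    return float(out) if out.ndim == 0 else out


def ffm_from_resistance(height_m: float, resistance: float, weight: float, age: float, eq: FfmEquation) -> float:
    """Evaluate a BIA equation (raw, unclamped)."""
    ht_cm2 = (height_m * 100.0) ** 2
    return eq.intercept + eq.coeff_ht2_over_r * ht_cm2 / resistance + eq.coeff_weight * weight + eq.coeff_age * age


def resistance_for_ffm(ffm: float, height_m: float, weight: float, age: float, eq: FfmEquation) -> float:
    """Invert the BIA equation for resistance (used by the synthetic generator).

    Requires a positive ht^2/R coefficient and a target FFM above the
    resistance-free part of the equation.
    """
    if eq.coeff_ht2_over_r <= 0:
        raise ValidationError("cannot invert a BIA equation with non-positive ht^2/R coefficient")
    denom = ffm - eq.intercept - eq.coeff_weight * weight - eq.coeff_age * age
    if denom <= 0:
        raise ValidationError(
            f"target FFM {ffm:.1f} kg is not attainable with the configured {eq.sex} BIA equation"
        )
    return eq.coeff_ht2_over_r * (height_m * 100.0) ** 2 / denom


_FFM_FLOOR = 1e-6


def predict_ffm(subject, equations: EquationSet | None = None) -> float:
    """Fat-free mass (kg) of a subject from its BIA resistance.

    The sex-matched equation is applied and the result clamped into
    (0, weight] — a linear population equation can stray outside the
    physical range for extreme inputs.
    """
    eqs = _as_equation_map(equations)
    if subject.sex not in eqs:
        raise ConfigurationError(f"no FFM prediction equation configured for sex {subject.sex!r}")
    if subject.resistance <= 0:
        raise ValidationError(f"subject {subject.id}: resistance must be > 0")
    raw = ffm_from_resistance(subject.height, subject.resistance, subject.weight, subject.age, eqs[subject.sex])
    return float(min(max(raw, min(_FFM_FLOOR, subject.weight)), subject.weight))


def body_composition(weight: float, ffm: float, height: float) -> BodyComposition:
    """Split body mass into fat-free and fat compartments.

    Mass is conserved exactly: fm = weight − ffm and the two percentage
    shares sum to 100.
    """
    if not 0 < ffm <= weight:
        raise ValidationError(f"FFM must lie in (0, weight]; got ffm={ffm}, weight={weight}")
    fm = weight - ffm
    ffm_pct = 100.0 * ffm / weight
    return BodyComposition(
        ffm_kg=ffm,
        fm_kg=fm,
        ffm_pct=ffm_pct,
        fm_pct=100.0 - ffm_pct,
        bmi=compute_bmi(weight, height),
    )


def normalize_bmr(bmr: float, comp: BodyComposition, weight: float) -> BmrPanel:
    """BMR per kg of fat-free mass and per kg of body weight."""
    if bmr < 0:
        raise ValidationError("BMR must be non-negative")
    if comp.ffm_kg <= 0 or weight <= 0:
        raise ValidationError("FFM and weight must be > 0 to normalise BMR")
    return BmrPanel(bmr_kcal_day=bmr, bmr_per_kg_ffm=bmr / comp.ffm_kg, bmr_per_kg_bw=bmr / weight)
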