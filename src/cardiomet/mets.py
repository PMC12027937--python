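"""Five-criterion metabolic-syndrome classification and prevalence tables.

A subject is MetS+ when at least ``min_criteria`` (default 3) of five
components are altered:

i.   abdominal obesity: WC ≥ 102 cm (men) / ≥ 88 cm (women);
ii.  triglycerides ≥ 150 mg/dL, or lipid-lowering treatment;
iii. HDL-C < 40 mg/dL (men) / < 50 mg/dL (women), or lipid treatment;
iv.  SBP ≥ 130 mmHg or DBP ≥ 85 mmHg, or antihypertensive treatment;
v.   fasting glucose ≥ 100 mg/dL, or previously diagnosed T2DM.

Boundary behaviour is deliberate and asymmetric: WC/TG/BP/FPG use an
inclusive ≥ while HDL uses a strict <, exactly as the criteria are stated.
One lipid-treatment flag serves both the TG and HDL criteria since the
same treatment clause is attached to both.  Note the WC cut-offs are the
ATP-III values even where sources label the rule "IDF"; the thresholds are
fully overridable so true-IDF or harmonised variants can be configured.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import NamedTuple, Sequence

import pandas as pd

from .cohort import Cohort, Subject
from .errors import ValidationError
from .utils import round_half_up


@dataclass(frozen=True)
class CriterionThresholds:
    wc_male: float = 102.0
    wc_female: float = 88.0
    tg: float = 150.0
    hdl_male: float = 40.0
    hdl_female: float = 50.0
    sbp: float = 130.0
    dbp: float = 85.0
    fpg: float = 100.0
    min_criteria: int = 3

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"threshold {f.name} must be positive")
        if not 1 <= self.min_criteria <= 5:
            raise ValidationError("min_criteria must be in 1..5")


DEFAULT_THRESHOLDS = CriterionThresholds()


class MetSFlags(NamedTuple):
    wc: bool
    tg: bool
    hdl: bool
    bp: bool
    fpg: bool


@dataclass(frozen=True)
class MetSResult:
    flags: MetSFlags
    n_altered: int
    status: str  # "MetS+" or "MetS-"


def component_flags(subject: Subject, thresholds: CriterionThresholds = DEFAULT_THRESHOLDS) -> MetSFlags:
    """Evaluate the five component criteria for one subject."""
    for name in ("wc", "tg", "hdl_c", "sbp", "dbp", "glucose", "sex"):
        v = getattr(subject, name, None)
        if v is None or (isinstance(v, float) and v != v):
            raise ValidationError(f"subject {subject.id}: missing field {name!r}")
    wc_cut = thresholds.wc_male if subject.sex == "M" else thresholds.wc_female
    hdl_cut = thresholds.hdl_male if subject.sex == "M" else thresholds.hdl_female
    return MetSFlags(
        wc=subject.wc >= wc_cut,
        tg=subject.tg >= thresholds.tg or subject.on_lipid_treatment,
        hdl=subject.hdl_c < hdl_cut or subject.on_lipid_treatment,
        bp=subject.sbp >= thresholds.sbp or subject.dbp >= thresholds.dbp or subject.on_bp_treatment,
        fpg=subject.glucose >= thresholds.fpg or subject.diagnosed_t2dm,
    )


def classify(flags: MetSFlags, thresholds: CriterionThresholds = DEFAULT_THRESHOLDS) -> MetSResult:
    """Combine component flags into a MetS+/− status."""
    if len(flags) != 5:
        raise ValidationError("expected five component flags")
    n = int(sum(bool(f) for f in flags))
    return MetSResult(flags=MetSFlags(*map(bool, flags)), n_altered=n,
                      status="MetS+" if n >= thresholds.min_criteria else "MetS-")


def classify_subject(subject: Subject, thresholds: CriterionThresholds = DEFAULT_THRESHOLDS) -> MetSResult:
    return classify(component_flags(subject, thresholds), thresholds)


def prevalence_table(cohort: Cohort, results: Sequence[MetSResult]) -> pd.DataFrame:
    """Component-alteration counts overall and within the MetS+/− strata.

    Returns one row per (stratum, component) with numerator, denominator
    and the percentage rounded half-up to integer percent, the convention
    of clinical prevalence tables.
    """
    if len(results) != len(cohort):
        raise ValidationError(
            f"results ({len(results)}) and cohort ({len(cohort)}) are misaligned"
        )
    strata = {
        "all": list(range(len(results))),
        "MetS+": [i for i, r in enumerate(results) if r.status == "MetS+"],
        "MetS-": [i for i, r in enumerate(results) if r.status == "MetS-"],
    }
    rows = []
    for stratum, idx in strata.items():
        denom = len(idx)
        for comp in MetSFlags._fields:
            num = sum(getattr(results[i].flags, comp) for i in idx)
            pct = round_half_up(100.0 * num / denom) if denom else 0.0
            rows.append(
                {
                    "group": cohort.label,
                    "stratum": stratum,
                    "component": comp,
                    "n_altered": num,
                    "n": denom,
                    "pct": pct,
                }
            )
    return pd.DataFrame(rows)
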