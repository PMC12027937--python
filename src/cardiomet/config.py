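"""Run configuration, loadable from YAML.

Example
-------
::

    seed: 20250401
    n_per_group: 32
    conversion_preset: molar        # or paper_rounded
    sd_source: pooled               # pooled | per_cohort
    outdir: out
    thresholds:
      wc_male: 102
      wc_female: 88
    ffm_equations:
      F: {intercept: 0.0, coeff_ht2_over_r: 0.60, coeff_weight: 0.20, coeff_age: -0.10}
      M: {intercept: 0.0, coeff_ht2_over_r: 0.65, coeff_weight: 0.26, coeff_age: -0.10}

``cohort_csvs`` (a list of paths) switches the pipeline from synthetic
generation to reading existing cohort files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ConfigurationError
from .mets import DEFAULT_THRESHOLDS, CriterionThresholds
from .physiology import DEFAULT_FFM_EQUATIONS, FfmEquation


@dataclass
class RunConfig:
    seed: int = 12345
    n_per_group: Optional[int] = None
    cohort_csvs: Optional[Sequence[str]] = None
    conversion_preset: str = "molar"
    sd_source: str = "pooled"
    thresholds: CriterionThresholds = field(default_factory=lambda: DEFAULT_THRESHOLDS)
    ffm_equations: dict[str, FfmEquation] = field(default_factory=lambda: dict(DEFAULT_FFM_EQUATIONS))
    outdir: str = "cardiomet_out"
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        if "thresholds" in kwargs and isinstance(kwargs["thresholds"], dict):
            base = dataclasses.asdict(DEFAULT_THRESHOLDS)
            base.update(kwargs["thresholds"])
            kwargs["thresholds"] = CriterionThresholds(**base)
        if "ffm_equations" in kwargs and isinstance(kwargs["ffm_equations"], dict):
            eqs = {}
            for sex, coeffs in kwargs["ffm_equations"].items():
                if isinstance(coeffs, FfmEquation):
                    eqs[sex] = coeffs
                else:
                    eqs[sex] = FfmEquation(sex=sex, **coeffs)
            kwargs["ffm_equations"] = eqs
        return cls(**kwargs)
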