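"""Bundled read-only summary of the published cohort tables.

The package ships the printed group summaries (means and 95% CIs for the
PWS and EOB cohorts and their MetS+/− subgroups), the headline percent
differences, and the component-prevalence counts.  These feed the default
parameters of the synthetic-cohort generator and the arithmetic
verification report; they are never modified at run time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Any, Mapping

from .errors import ValidationError


@dataclass(frozen=True)
class PaperSummary:
    """Thin accessor over the bundled JSON fixture."""

    data: Mapping[str, Any]

    @property
    def groups(self) -> Mapping[str, Any]:
        return self.data["groups"]

    @property
    def subgroups(self) -> Mapping[str, Any]:
        return self.data["subgroups"]

    @property
    def percent_differences(self) -> list[dict]:
        return list(self.data["percent_differences"])

    def n(self, group: str) -> int:
        return int(self.data["n"][group])

    def n_female(self, group: str) -> int:
        return int(self.data["n_female"][group])

    def cell(self, scope: str, group: str, variable: str) -> dict:
        table = self.data[scope]
        try:
            return table[group][variable]
        except KeyError:
            raise ValidationError(f"no fixture cell for {scope}/{group}/{variable}") from None

    def mean(self, scope: str, group: str, variable: str) -> float:
        return float(self.cell(scope, group, variable)["mean"])

    def ci(self, scope: str, group: str, variable: str) -> tuple[float, float]:
        lo, hi = self.cell(scope, group, variable)["ci"]
        return float(lo), float(hi)


@lru_cache(maxsize=1)
def load_paper_summary() -> PaperSummary:
    text = resources.files("cardiomet").joinpath("data/paper_summary.json").read_text(encoding="utf-8")
    return PaperSummary(data=json.loads(text))
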