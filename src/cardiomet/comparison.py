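"""Covariate-adjusted group comparison (the statistical core).

Two matched cohorts are compared variable by variable with an analysis of
covariance adjusting for age and sex: an OLS fit of

    y ~ intercept + group + age + sex

whose group coefficient and two-sided t-test p-value are reported.  Each
variable is routed to a parametric or rank-based path by a Shapiro–Wilk
test on the residuals of the parametric fit (p < 0.05 → rank path); the
rank path replaces y by mid-ranks and refits the same model, a
Conover-style rank-transform ANCOVA.  "Non-parametric ANCOVA" is
under-specified in the clinical literature; the rank transform is the
defensible, simple reading and the routing is logged per variable.

Four-subgroup comparisons (each cohort split by MetS status) use the same
adjusted model with group dummies; the omnibus test is an F-test on the
dummies, post-hoc pairwise tests are Tukey HSD on adjusted means when the
variable passed normality and Bonferroni-corrected pairwise rank ANCOVAs
otherwise.  Significant pairs (α = 0.05) are coded with shared letters —
note the convention: *identical letters mark a significant difference*,
the (unusual) convention of the tables this pipeline renders.

The model-level interface is :class:`CohortComparison` (built from a tidy
subject-level DataFrame) whose :meth:`~CohortComparison.fit` returns a
:class:`CohortComparisonResults` carrying per-variable estimates, CIs,
percent differences, p-values and post-hoc letters, with ``summary()``.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger("cardiomet")

ALPHA = 0.05  # significance level of the analysis plan


@dataclass(frozen=True)
class SummaryCell:
    """Group mean with a t-based confidence interval."""

    mean: float
    ci_low: float
    ci_high: float
    n: int


def mean_ci(values: Sequence[float], level: float = 0.95) -> SummaryCell:
    """Mean ± t_{(1+level)/2, n−1} · SD/√n."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValidationError("need at least 2 values for a confidence interval")
    m = float(vals.mean())
    half = float(stats.t.ppf((1 + level) / 2, vals.size - 1) * vals.std(ddof=1) / np.sqrt(vals.size))
    return SummaryCell(mean=m, ci_low=m - half, ci_high=m + half, n=int(vals.size))


def percent_difference(reference_mean: float, comparison_mean: float) -> float:
    """100 · (comparison − reference) / reference.

    The headline effect measure of the comparison tables: e.g. the PWS
    group mean relative to the EOB group mean.  Satisfies
    (1 + d₁/100)(1 + d₂/100) = 1 when computed both ways.
    """
    if reference_mean == 0:
        raise ValidationError("reference mean must be non-zero")
    return 100.0 * (comparison_mean - reference_mean) / reference_mean


def normality_p(values: Sequence[float]) -> float:
    """Shapiro–Wilk p-value; p < 0.05 routes a variable to the rank path."""
    vals = np.asarray(values, dtype=float)
    if not 3 <= vals.size <= 5000:
        raise ValidationError(f"Shapiro–Wilk needs 3 <= n <= 5000, got n={vals.size}")
    if np.ptp(vals) == 0:
        raise ValidationError("cannot test normality of a constant sample")
    return float(stats.shapiro(vals).pvalue)


def _encode_sex(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "OU":
        return (arr == "M").astype(float)
    return arr.astype(float)


def _build_design(group_ind: np.ndarray, age, sex) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(group_ind, dtype=float), group_ind.astype(float)]
    names = ["const", "group"]
    for cov_name, cov in (("age", age), ("sex", sex)):
        if cov is None:
            continue
        arr = _encode_sex(cov) if cov_name == "sex" else np.asarray(cov, dtype=float)
        if np.ptp(arr) == 0:
            logger.warning("covariate %r is constant; dropped from the ANCOVA design", cov_name)
            continue
        cols.append(arr)
        names.append(cov_name)
    return np.column_stack(cols), names


@dataclass(frozen=True)
class AncovaFit:
    """Group effect from a covariate-adjusted linear comparison."""

    estimate: float
    pvalue: float
    se: float
    df_resid: float
    params: pd.Series
    reference: str
    comparison: str
    method: str  # "parametric" or "rank"

    def __iter__(self):  # allows: estimate, p = ancova_two_group(...)
        return iter((self.estimate, self.pvalue))


def ancova_two_group(y, group, age=None, sex=None, rank: bool = False, reference: str | None = None) -> AncovaFit:
    """Adjusted two-group comparison; returns the group effect and p-value.

    The group coefficient is the adjusted mean difference
    (comparison − reference); by default the reference level is the first
    group label in sorted order.  ``rank=True`` replaces y by mid-ranks
    before the same fit (rank-transform ANCOVA).
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {levels}")
    if reference is None:
        reference = levels[0]
    elif reference not in levels:
        raise ValidationError(f"reference {reference!r} not among groups {levels}")
    comparison = next(l for l in levels if l != reference)
    counts = {l: int((group == l).sum()) for l in levels}
    if min(counts.values()) < 2:
        raise ValidationError(f"need >= 2 subjects per group, got {counts}")
    if np.isnan(y).any():
        raise ValidationError("missing values in the response")
    if rank:
        y = stats.rankdata(y)  # mid-ranks
    ind = (group == comparison).astype(float)
    design, names = _build_design(ind, age, sex)
    fit = sm.OLS(y, design).fit()
    return AncovaFit(
        estimate=float(fit.params[1]),
        pvalue=float(fit.pvalues[1]),
        se=float(fit.bse[1]),
        df_resid=float(fit.df_resid),
        params=pd.Series(fit.params, index=names),
        reference=str(reference),
        comparison=str(comparison),
        method="rank" if rank else "parametric",
    )


@dataclass(frozen=True)
class PosthocLetters:
    """Pairwise significance of four adjusted subgroups, letter-coded.

    ``letters[g]`` concatenates one letter per significant pair that g
    belongs to; identical letters on two subgroups mark a significant
    difference between them (the rendered tables' convention).
    """

    groups: tuple[str, ...]
    omnibus_p: float
    pair_p: Mapping[tuple[str, str], float]
    alpha: float
    method: str  # "tukey" or "bonferroni"
    letters: Mapping[str, str]

    def p(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.pair_p else (b, a)
        return self.pair_p[key]

    def significant(self, a: str, b: str) -> bool:
        return self.p(a, b) < self.alpha

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, p in self.pair_p.items() if p < self.alpha]


def four_group_comparison(y, group4, age=None, sex=None, normal: bool = True, alpha: float = ALPHA) -> PosthocLetters:
    """Omnibus adjusted comparison of four subgroups with post-hoc letters.

    ``normal=True`` → Tukey HSD on the covariate-adjusted means (p from
    the studentized range); otherwise Bonferroni-corrected pairwise
    rank-transform ANCOVAs.
    """
    y = np.asarray(y, dtype=float)
    group4 = np.asarray(group4)
    levels = sorted(pd.unique(group4).tolist())
    if len(levels) != 4:
        raise ValidationError(f"expected 4 non-empty subgroups, got {levels}")
    counts = {l: int((group4 == l).sum()) for l in levels}
    if min(counts.values()) < 2:
        raise ValidationError(f"need >= 2 subjects per subgroup, got {counts}")

    # dummy design, reference = first level; dummy coefs are adjusted
    # differences versus the reference (covariates shared across groups)
    dummies = np.column_stack([(group4 == l).astype(float) for l in levels[1:]])
    base, names = _build_design(dummies[:, 0], age, sex)
    design = np.column_stack([base[:, :1], dummies, base[:, 2:]])
    fit = sm.OLS(stats.rankdata(y) if not normal else y, design).fit()
    r = np.zeros((3, design.shape[1]))
    r[:, 1:4] = np.eye(3)
    omnibus_p = float(fit.f_test(r).pvalue)

    pair_p: dict[tuple[str, str], float] = {}
    if normal:
        cov = fit.cov_params()
        k = len(levels)
        contrast = {levels[0]: np.zeros(design.shape[1])}
        for j, l in enumerate(levels[1:], start=1):
            c = np.zeros(design.shape[1])
            c[j] = 1.0
            contrast[l] = c
        for a, b in itertools.combinations(levels, 2):
            c = contrast[b] - contrast[a]
            diff = float(c @ fit.params)
            se = float(np.sqrt(c @ cov @ c))
            q = abs(diff) / se * np.sqrt(2.0)
            pair_p[(a, b)] = float(stats.studentized_range.sf(q, k, fit.df_resid))
        method = "tukey"
    else:
        for a, b in itertools.combinations(levels, 2):
            mask = (group4 == a) | (group4 == b)
            sub_age = None if age is None else np.asarray(age)[mask]
            sub_sex = None if sex is None else np.asarray(sex)[mask]
            res = ancova_two_group(y[mask], group4[mask], sub_age, sub_sex, rank=True, reference=a)
            pair_p[(a, b)] = min(1.0, res.pvalue * 6)
        method = "bonferroni"

    letters: dict[str, str] = {l: "" for l in levels}
    alphabet = iter(string.ascii_lowercase)
    for pair in itertools.combinations(levels, 2):
        if pair_p[pair] < alpha:
            letter = next(alphabet)
            letters[pair[0]] += letter
            letters[pair[1]] += letter
    return PosthocLetters(
        groups=tuple(levels),
        omnibus_p=omnibus_p,
        pair_p=pair_p,
        alpha=alpha,
        method=method,
        letters=letters,
    )


@dataclass(frozen=True)
class ComparisonRow:
    variable: str
    cells: Mapping[str, SummaryCell]
    estimate: Optional[float]
    p_adjusted: Optional[float]
    percent_diff: Optional[float]
    method: str
    normality_pvalue: Optional[float]
    letters: Optional[Mapping[str, str]] = None
    omnibus_p: Optional[float] = None


class CohortComparison:
    """Adjusted comparison of cohorts over a set of variables.

    Parameters
    ----------
    data
        Tidy subject-level DataFrame, one row per subject.
    variables
        Columns to compare (default: all numeric columns other than the
        grouping and covariate columns).
    group
        Grouping column; 2 levels give the two-cohort comparison, 4 the
        subgroup comparison with post-hoc letters.
    covariates
        Adjustment columns, default ``("age", "sex")``; a constant
        covariate is dropped with a logged warning.
    reference
        Reference group level for the effect and percent difference
        (2-group case); defaults to the first level in sorted order.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        variables: Sequence[str] | None = None,
        group: str = "group",
        covariates: Sequence[str] = ("age", "sex"),
        reference: str | None = None,
        alpha: float = ALPHA,
    ) -> None:
        if group not in data.columns:
            raise ValidationError(f"grouping column {group!r} not in data")
        for cov in covariates:
            if cov not in data.columns:
                raise ValidationError(f"covariate column {cov!r} not in data")
        self.data = data
        self.group = group
        self.covariates = tuple(covariates)
        self.alpha = alpha
        self.levels = sorted(data[group].unique().tolist())
        if len(self.levels) not in (2, 4):
            raise ValidationError(f"need 2 or 4 groups, got {len(self.levels)}: {self.levels}")
        self.reference = reference if reference is not None else self.levels[0]
        if variables is None:
            skip = {group, *covariates}
            variables = [
                c
                for c in data.columns
                if c not in skip and pd.api.types.is_numeric_dtype(data[c]) and not pd.api.types.is_bool_dtype(data[c])
            ]
        self.variables = list(variables)
        missing = [v for v in self.variables if v not in data.columns]
        if missing:
            raise ValidationError(f"variables not in data: {missing}")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "CohortComparison":
        return cls(data, **kwargs)

    def _covariate(self, name: str):
        return self.data[name].to_numpy() if name in self.covariates else None

    def fit(self) -> "CohortComparisonResults":
        age = self._covariate("age")
        sex = self._covariate("sex")
        group = self.data[self.group].to_numpy()
        two_group = len(self.levels) == 2
        rows = []
        for var in self.variables:
            y = self.data[var].to_numpy(dtype=float)
            cells = {
                l: mean_ci(y[group == l]) for l in self.levels
            }
            # normality on residuals of the parametric adjusted fit
            if two_group:
                fit0 = ancova_two_group(y, group, age, sex, rank=False, reference=self.reference)
                design_resid = y - self._fitted(y, group, age, sex)
            else:
                design_resid = y - self._fitted(y, group, age, sex)
            try:
                norm_p = normality_p(design_resid)
                normal = norm_p >= self.alpha
            except ValidationError:
                norm_p, normal = None, True  # degenerate residuals: keep parametric path
            method = "parametric" if normal else "rank"
            logger.info("variable %s routed to the %s path (Shapiro-Wilk p=%s)", var, method, norm_p)
            if two_group:
                res = fit0 if normal else ancova_two_group(y, group, age, sex, rank=True, reference=self.reference)
                comparison = res.comparison
                pdiff = percent_difference(cells[self.reference].mean, cells[comparison].mean)
                rows.append(
                    ComparisonRow(
                        variable=var,
                        cells=cells,
                        estimate=res.estimate,
                        p_adjusted=res.pvalue,
                        percent_diff=pdiff,
                        method=method,
                        normality_pvalue=norm_p,
                    )
                )
            else:
                ph = four_group_comparison(y, group, age, sex, normal=normal, alpha=self.alpha)
                rows.append(
                    ComparisonRow(
                        variable=var,
                        cells=cells,
                        estimate=None,
                        p_adjusted=None,
                        percent_diff=None,
                        method=f"{method}/{ph.method}",
                        normality_pvalue=norm_p,
                        letters=ph.letters,
                        omnibus_p=ph.omnibus_p,
                    )
                )
        return CohortComparisonResults(model=self, rows=rows)

    def _fitted(self, y, group, age, sex) -> np.ndarray:
        levels = sorted(pd.unique(group).tolist())
        dummies = np.column_stack([(group == l).astype(float) for l in levels[1:]])
        base, _ = _build_design(dummies[:, 0], age, sex)
        design = np.column_stack([base[:, :1], dummies, base[:, 2:]])
        return sm.OLS(np.asarray(y, dtype=float), design).fit().fittedvalues


@dataclass
class CohortComparisonResults:
    """Fitted comparison: per-variable summaries, effects and letters."""

    model: CohortComparison
    rows: list[ComparisonRow] = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec: dict = {"variable": row.variable}
            for level, cell in row.cells.items():
                rec[f"{level}_mean"] = cell.mean
                rec[f"{level}_ci_low"] = cell.ci_low
                rec[f"{level}_ci_high"] = cell.ci_high
            if row.estimate is not None:
                rec["estimate"] = row.estimate
                rec["p_adjusted"] = row.p_adjusted
                rec["percent_diff"] = row.percent_diff
            if row.omnibus_p is not None:
                rec["omnibus_p"] = row.omnibus_p
            rec["method"] = row.method
            rec["normality_p"] = row.normality_pvalue
            if row.letters is not None:
                for level, letters in row.letters.items():
                    rec[f"{level}_letters"] = letters
            records.append(rec)
        return pd.DataFrame(records)

    def summary(self, float_format: str = "%.3f") -> str:
        df = self.table
        header = (
            f"Adjusted cohort comparison ({' vs '.join(self.model.levels)}); "
            f"covariates: {', '.join(self.model.covariates) or 'none'}; alpha={self.model.alpha}\n"
            "Cells are group mean (95% CI). Identical letters mark a significant pairwise difference.\n"
        )
        with pd.option_context("display.width", 200, "display.max_columns", None):
            body = df.to_string(index=False, float_format=lambda v: float_format % v)
        return header + body

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
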