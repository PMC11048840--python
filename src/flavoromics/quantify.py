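"""Sugar/acid quantification: external-standard calibration, the HPLC content
formula, sugar-acid panels, and group comparison with compact letter display.

Contents are expressed mg per g dry weight (DW).  The content of an analyte
in a sample follows the external-standard workflow:

    content (mg/g) = concentration (mg/mL) * constant volume (mL) / sample mass (g)

where the concentration is read off an ordinary least-squares calibration
line fitted to a standard series (conventionally five levels spanning
0.05-1.0 mg/mL).  The sugar-acid ratio SAR = TSC / TAC summarizes the
sweetness/sourness balance; TSC and TAC come from bulk assays (anthrone
colorimetry, acid-base titration) and are taken as inputs rather than summed
from chromatographic analytes, whose panel sum is exposed separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .io_core import ValidationError


@dataclass(frozen=True)
class CalibrationSeries:
    """A standard series for one analyte: (concentration mg/mL, response)."""

    analyte: str
    levels: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple((float(c), float(r)) for c, r in self.levels))
        if len(self.levels) < 3:
            raise ValidationError(f"{self.analyte}: need >= 3 calibration levels, got {len(self.levels)}")
        concs = [c for c, _ in self.levels]
        if any(c <= 0 for c in concs):
            raise ValidationError(f"{self.analyte}: concentrations must be > 0")
        if max(concs) == min(concs):
            raise ValidationError(f"{self.analyte}: zero concentration variance")


@dataclass(frozen=True)
class CalibrationModel:
    analyte: str
    slope: float  # response per (mg/mL)
    intercept: float  # response units
    r_squared: float

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


class CalibrationCurve(BaseEstimator, RegressorMixin):
    """Unweighted OLS line ``response = slope * concentration + intercept``.

    scikit-learn-compatible wrapper used by :func:`fit_calibration`; the
    fitted attributes are ``slope_``, ``intercept_`` and ``r_squared_``.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size < 3:
            raise ValidationError("need >= 3 calibration levels")
        if np.ptp(x) == 0:
            raise ValidationError("zero concentration variance")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        # rvalue**2 is the OLS coefficient of determination for a 1-D fit
        self.r_squared_ = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.slope_ * np.asarray(X, dtype=float) + self.intercept_

    def inverse(self, response):
        check_is_fitted(self, "slope_")
        if self.slope_ == 0:
            raise ValidationError("cannot invert a flat calibration line (slope 0)")
        return (np.asarray(response, dtype=float) - self.intercept_) / self.slope_


def fit_calibration(series: CalibrationSeries) -> CalibrationModel:
    """Fit the OLS standard curve for one analyte."""
    x = [c for c, _ in series.levels]
    y = [r for _, r in series.levels]
    est = CalibrationCurve().fit(x, y)
    return CalibrationModel(series.analyte, est.slope_, est.intercept_, est.r_squared_)


def invert_calibration(model: CalibrationModel, response: float) -> float:
    """Inverse prediction: detector response -> concentration (mg/mL).

    May return a negative concentration for responses below the intercept;
    clipping is left to the caller.
    """
    if model.slope == 0:
        raise ValidationError(f"{model.analyte}: cannot invert slope 0")
    return (response - model.intercept) / model.slope


def compute_content(concentration: float, constant_volume: float, sample_mass: float) -> float:
    """content (mg/g) = concentration (mg/mL) x constant volume (mL) / mass (g)."""
    if constant_volume <= 0:
        raise ValidationError(f"constant volume must be > 0, got {constant_volume}")
    if sample_mass <= 0:
        raise ValidationError(f"sample mass must be > 0, got {sample_mass}")
    return concentration * constant_volume / sample_mass


@dataclass(frozen=True)
class SugarAcidPanel:
    group_id: str
    sugar_contents: Mapping[str, float]  # analyte -> mg/g DW
    acid_contents: Mapping[str, float]
    tsc: float  # total sugar content, mg/g DW (bulk assay)
    tac: float  # total acid content, mg/g DW (bulk assay)
    sar: float  # sugar-acid ratio = tsc / tac

    @property
    def sum_of_sugar_analytes(self) -> float:
        return sum(self.sugar_contents.values())

    @property
    def sum_of_acid_analytes(self) -> float:
        return sum(self.acid_contents.values())


def summarize_panel(
    group_id: str,
    sugar_contents: Mapping[str, float],
    acid_contents: Mapping[str, float],
    tsc: float,
    tac: float,
) -> SugarAcidPanel:
    """Bundle per-analyte contents with bulk TSC/TAC and SAR = TSC/TAC."""
    if tac <= 0:
        raise ValidationError(f"TAC must be > 0 to form a sugar-acid ratio, got {tac}")
    bad = {k: v for k, v in {**sugar_contents, **acid_contents}.items() if v < 0}
    if bad:
        raise ValidationError(f"negative contents: {bad}")
    return SugarAcidPanel(
        group_id=group_id,
        sugar_contents=dict(sugar_contents),
        acid_contents=dict(acid_contents),
        tsc=float(tsc),
        tac=float(tac),
        sar=float(tsc) / float(tac),
    )


@dataclass(frozen=True)
class GroupSummary:
    group_id: str
    mean: float
    sd: float
    n: int
    letter: str


@dataclass(frozen=True)
class GroupComparison:
    summaries: tuple[GroupSummary, ...]
    anova_f: float
    anova_p: float
    shapiro_p: Mapping[str, float]  # per-group normality diagnostic
    levene_p: float  # homogeneity-of-variance diagnostic
    alpha: float

    def letters(self) -> dict[str, str]:
        return {s.group_id: s.letter for s in self.summaries}


def _compact_letters(group_ids: Sequence[str], means: Mapping[str, float], distinct: set[frozenset]) -> dict[str, str]:
    """Greedy compact letter display: groups sharing a letter are not
    significantly different.  Groups are processed in descending mean order,
    as conventional in agronomy figures ('a' marks the largest mean)."""
    ordered = sorted(group_ids, key=lambda g: (-means[g], g))
    columns: list[set[str]] = []  # each column = one letter
    for g in ordered:
        placed = False
        for col in columns:
            if all(frozenset((g, other)) not in distinct for other in col):
                col.add(g)
                placed = True
        if not placed:
            columns.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in group_ids}
    for i, col in enumerate(columns):
        for g in ordered:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def compare_groups(values: Mapping[str, Sequence[float]], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA with all-pairs Tukey HSD and significance letters.

    Shapiro-Wilk (per group) and Levene (across groups) p-values are reported
    as diagnostics; failing them raises a warning, not an error.  Letters are
    assigned so that groups sharing a letter do not differ at ``alpha``.
    """
    if len(values) < 2:
        raise ValidationError("need >= 2 groups to compare")
    arrays: dict[str, np.ndarray] = {}
    for g, v in values.items():
        arr = np.asarray(list(v), dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {g!r} has < 2 replicates")
        arrays[g] = arr
    group_ids = list(arrays)

    shapiro_p: dict[str, float] = {}
    for g, arr in arrays.items():
        if np.ptp(arr) == 0:
            shapiro_p[g] = 1.0  # constant replicates: normality test undefined
        else:
            shapiro_p[g] = float(stats.shapiro(arr).pvalue)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # constant groups
            levene_p = float(stats.levene(*arrays.values()).pvalue)
    except Exception:
        levene_p = float("nan")
    if any(p < alpha for p in shapiro_p.values()) or (not math.isnan(levene_p) and levene_p < alpha):
        warnings.warn(
            "normality or variance-homogeneity diagnostic below alpha; "
            "ANOVA assumptions may be violated",
            stacklevel=2,
        )

    if all(np.ptp(arr) == 0 for arr in arrays.values()) and len({arr[0] for arr in arrays.values()}) == 1:
        # all observations identical: no variation to test
        anova_f, anova_p = 0.0, 1.0
        distinct: set[frozenset] = set()
    else:
        anova = stats.f_oneway(*arrays.values())
        anova_f, anova_p = float(anova.statistic), float(anova.pvalue)
        hsd = stats.tukey_hsd(*arrays.values())
        distinct = set()
        for i in range(len(group_ids)):
            for j in range(i + 1, len(group_ids)):
                if hsd.pvalue[i, j] < alpha:
                    distinct.add(frozenset((group_ids[i], group_ids[j])))

    means = {g: float(arr.mean()) for g, arr in arrays.items()}
    letters = _compact_letters(group_ids, means, distinct)
    summaries = tuple(
        GroupSummary(g, means[g], float(arrays[g].std(ddof=1)), int(arrays[g].size), letters[g])
        for g in group_ids
    )
    return GroupComparison(summaries, anova_f, anova_p, shapiro_p, levene_p, alpha)
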