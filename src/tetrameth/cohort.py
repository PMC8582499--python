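"""Association statistics for the tumor/normal cohort analysis.

Cross-tabulation of somatic-demethylation class against clinicopathological
factors (exact 2x2 tests), correlation with Fisher-z confidence intervals,
paired and summary-statistic t-tests, and per-factor / joint linear models of
the continuous somatic demethylation value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError

__all__ = [
    "CohortTable",
    "ContingencyTable2x2",
    "CrosstabResult",
    "fisher_exact",
    "crosstab",
    "pearson_ci",
    "paired_t",
    "summary_t",
    "continuous_association",
]

DEMETH_CLASSES = ("none", "moderate", "strong")

#: Clinicopathological factor columns a cohort table may carry.
FACTOR_COLUMNS = (
    "gender",
    "age_group",
    "ethnicity",
    "location",
    "stage_group",
    "msi_status",
    "tp53",
    "kras",
    "braf",
)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table [[a, b], [c, d]] of non-negative counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ParameterError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise DataError("all-zero contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


class CohortTable:
    """Per-patient somatic demethylation values with clinical annotations.

    Wraps a DataFrame with one row per patient: ``patient_id``,
    ``delta_rdl_sst1``, ``delta_rdl_line1``, ``class_sst1`` (one of
    none/moderate/strong) and any subset of :data:`FACTOR_COLUMNS`
    (categorical, missing allowed).
    """

    REQUIRED = ("patient_id", "delta_rdl_sst1", "delta_rdl_line1", "class_sst1")

    def __init__(self, data: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise DataError(f"cohort table missing columns: {missing}")
        bad = set(data["class_sst1"].dropna().unique()) - set(DEMETH_CLASSES)
        if bad:
            raise DataError(f"unknown demethylation classes: {sorted(bad)}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def factors(self) -> list[str]:
        return [c for c in FACTOR_COLUMNS if c in self.data.columns]

    def __repr__(self) -> str:  # pragma: no cover
        return f"CohortTable(n={self.n}, factors={self.factors})"


def fisher_exact(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the minimum-likelihood rule: the p-value sums the hypergeometric
    probabilities of all tables with the observed margins whose point
    probability does not exceed that of the observed table.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


@dataclass
class CrosstabResult:
    """A 2x2 cross-tabulation with its exact test."""

    table: ContingencyTable2x2
    p_value: float
    factor: str
    contrast: str
    factor_levels: tuple[str, str]
    row_labels: tuple[str, str]
    n_used: int
    n_missing: int
    degenerate: bool


def _contrast_rows(classes: pd.Series, contrast: str) -> tuple[pd.Series, tuple[str, str]]:
    if contrast == "none_vs_rest":
        keep = classes.notna()
        rows = np.where(classes == "none", "none", "moderate_or_strong")
        labels = ("none", "moderate_or_strong")
    elif contrast == "strong_vs_rest":
        keep = classes.notna()
        rows = np.where(classes == "strong", "strong", "rest")
        labels = ("strong", "rest")
    elif contrast == "none_vs_strong":
        keep = classes.isin(["none", "strong"])
        rows = classes.astype(object)
        labels = ("none", "strong")
    else:
        raise ParameterError(f"unknown contrast {contrast!r}")
    return pd.Series(rows, index=classes.index)[keep], labels


def crosstab(cohort: CohortTable, factor: str, contrast: str = "none_vs_rest") -> CrosstabResult:
    """Cross-tabulate demethylation class against a two-level factor and test
    independence with the exact test.  Patients with a missing factor value
    (or outside the contrast) are excluded pairwise."""
    if factor not in cohort.data.columns:
        raise DataError(f"factor {factor!r} not in cohort table")
    rows, row_labels = _contrast_rows(cohort.data["class_sst1"], contrast)
    fvals = cohort.data.loc[rows.index, factor]
    keep = fvals.notna()
    rows, fvals = rows[keep], fvals[keep]
    n_used = len(rows)
    n_missing = cohort.n - n_used

    levels = sorted(fvals.unique())
    if len(levels) != 2:
        if len(levels) < 2:
            return CrosstabResult(
                table=ContingencyTable2x2(0, 0, 0, 1),
                p_value=float("nan"),
                factor=factor,
                contrast=contrast,
                factor_levels=("", ""),
                row_labels=row_labels,
                n_used=n_used,
                n_missing=n_missing,
                degenerate=True,
            )
        raise DataError(f"factor {factor!r} has {len(levels)} levels; need 2")

    counts = np.zeros((2, 2), dtype=int)
    for i, r in enumerate(row_labels):
        for j, lv in enumerate(levels):
            counts[i, j] = int(np.sum((rows.values == r) & (fvals.values == lv)))
    degenerate = bool((counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any())
    table = ContingencyTable2x2(*counts.ravel().tolist())
    p = float("nan") if degenerate else fisher_exact(table)
    return CrosstabResult(
        table=table,
        p_value=p,
        factor=factor,
        contrast=contrast,
        factor_levels=(str(levels[0]), str(levels[1])),
        row_labels=row_labels,
        n_used=n_used,
        n_missing=n_missing,
        degenerate=degenerate,
    )


def pearson_ci(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float], float]:
    """Pearson correlation with a Fisher-z confidence interval.

    Returns ``(r, (lo, hi), p)``; p is the two-sided t-distribution p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-d vectors of equal length")
    if len(x) < 4:
        raise DataError("need at least 4 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return float(res.statistic), (float(ci.low), float(ci.high)), float(res.pvalue)


def paired_t(x_tumor, x_normal) -> float:
    """Two-sided paired t-test p-value on matched vectors."""
    x = np.asarray(x_tumor, dtype=float)
    y = np.asarray(x_normal, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("paired vectors must have equal length")
    if len(x) < 3:
        raise DataError("need at least 3 pairs")
    diff = x - y
    if np.std(diff, ddof=1) == 0:
        if np.all(diff == 0):
            return 1.0  # t = 0 exactly
        raise DataError("zero within-pair variance with non-zero shift")
    return float(stats.ttest_rel(x, y).pvalue)


def summary_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from summary statistics.

    Returns ``(t, df, p)`` with the two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise DataError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ParameterError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


@dataclass
class ContinuousAssociationResult:
    """Per-factor tests and a joint OLS fit of the continuous response."""

    per_factor: pd.DataFrame
    ols_results: object | None  # statsmodels RegressionResults
    degenerate: bool

    def summary(self) -> str:
        lines = ["Per-factor two-group comparisons", str(self.per_factor)]
        if self.ols_results is not None:
            lines += ["", "Joint OLS fit", str(self.ols_results.summary())]
        elif self.degenerate:
            lines += ["", "Joint fit degenerate (constant response or collinear design)"]
        return "\n".join(lines)


def continuous_association(
    cohort: CohortTable,
    response: str = "delta_rdl_sst1",
    factors: Iterable[str] | None = None,
) -> ContinuousAssociationResult:
    """Association of each factor with the continuous response, plus a joint
    ordinary-least-squares fit including all factors.

    Per factor: pooled two-sample t on the two factor levels (pairwise
    deletion of missing values).  Joint: OLS of the response on all factors
    simultaneously; coefficient p-values reported.
    """
    import statsmodels.api as sm

    if factors is None:
        factors = cohort.factors
    factors = list(factors)
    df = cohort.data
    y_all = df[response].astype(float)

    degenerate = bool(np.std(y_all.dropna()) == 0)

    rows = []
    for f in factors:
        sub = df[[response, f]].dropna()
        levels = sorted(sub[f].unique())
        if len(levels) != 2:
            rows.append({"factor": f, "level_high": None, "t": np.nan, "p": np.nan, "n": len(sub)})
            continue
        g1 = sub.loc[sub[f] == levels[0], response].values
        g2 = sub.loc[sub[f] == levels[1], response].values
        if degenerate or len(g1) < 2 or len(g2) < 2 or np.std(g1, ddof=1) + np.std(g2, ddof=1) == 0:
            t, p = np.nan, (1.0 if degenerate else np.nan)
        else:
            t, df_, p = summary_t(
                g1.mean(), g1.std(ddof=1), len(g1), g2.mean(), g2.std(ddof=1), len(g2)
            )
        rows.append({"factor": f, "level_high": str(levels[1]), "t": t, "p": p, "n": len(sub)})
    per_factor = pd.DataFrame(rows)

    ols_results = None
    if not degenerate and factors:
        sub = df[[response] + factors].dropna()
        X = pd.get_dummies(sub[factors].astype(str), drop_first=True, dtype=float)
        if len(sub) > X.shape[1] + 1 and X.shape[1] > 0:
            X = sm.add_constant(X)
            if np.linalg.matrix_rank(X.values) == X.shape[1]:
                ols_results = sm.OLS(sub[response].astype(float), X).fit()
            else:
                degenerate = True
    return ContinuousAssociationResult(per_factor=per_factor, ols_results=ols_results, degenerate=degenerate)
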