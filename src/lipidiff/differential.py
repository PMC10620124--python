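"""Per-lipid two-group contrasts and differential-regulation calls.

For each lipid, a contrast between a test group and a reference group
(e.g. a cancer line vs the healthy control, or treated vs untreated of one
line) yields

* ``log2fc`` — log2 of the ratio of present-replicate means (test over
  reference) of the mol% values, and
* ``p_value`` — a two-tailed two-sample Student's t-test on the
  per-replicate mol% values (classical equal-variance by default; Welch
  via ``equal_variance=False``).

Missing replicate values are neglected, and a lipid enters a contrast only
with at least ``min_replicates`` (default 2) present values in *both*
groups.  A differentially regulated lipid (DRL) is one with
``p_value < alpha`` (default 0.05, uncorrected); its direction is Up or
Down by the sign of ``log2fc``.

Edge conventions (documented, tested): identical group values give p = 1;
zero pooled variance with unequal means gives p = 0 (the t statistic
diverges); a group mean of exactly 0 makes log2fc undefined and excludes
the lipid from the contrast with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .ingest import ConcentrationTable
from .errors import ValidationError

__all__ = [
    "AnalysisParams",
    "ContrastResult",
    "GroupContrast",
    "compute_contrast",
    "drl_table",
    "rollup_counts",
]

RESULT_COLUMNS = [
    "lipid",
    "lipid_class",
    "category",
    "log2fc",
    "p_value",
    "n_ref",
    "n_test",
    "is_drl",
    "direction",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Calling rules for one contrast; the defaults are the study's rules."""

    alpha: float = 0.05
    min_replicates: int = 2
    equal_variance: bool = True
    fdr_correct: bool = False  # Benjamini-Hochberg; a deviation, off by default

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.min_replicates < 2:
            raise ValidationError("min_replicates must be >= 2")


@dataclass(frozen=True)
class ContrastResult:
    """One lipid's result in one two-group contrast."""

    lipid: str
    lipid_class: str
    category: str
    reference_group: tuple[str, str]
    test_group: tuple[str, str]
    log2fc: float
    p_value: float
    n_ref: int
    n_test: int
    is_drl: bool
    direction: str  # "Up" | "Down" | "none"


def _two_sample_t(
    x_ref: np.ndarray, x_test: np.ndarray, equal_variance: bool
) -> np.ndarray:
    """Vectorized two-tailed two-sample t-test over lipids (rows).

    NaN entries are absent replicates.  Rows must already satisfy the
    minimum-replicate rule.  Zero-variance rows follow the documented
    conventions (p = 1 for equal means, p = 0 otherwise).
    """
    n1 = np.sum(~np.isnan(x_ref), axis=1)
    n2 = np.sum(~np.isnan(x_test), axis=1)
    m1 = np.nanmean(x_ref, axis=1)
    m2 = np.nanmean(x_test, axis=1)
    v1 = np.nanvar(x_ref, axis=1, ddof=1)
    v2 = np.nanvar(x_test, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_variance:
            df = n1 + n2 - 2.0
            pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        else:
            se2 = v1 / n1 + v2 / n2
            se = np.sqrt(se2)
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = (m2 - m1) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # Degenerate variance: a standard error below float resolution of the
    # means (1e-12 relative) is numerical noise, not evidence; then p = 1
    # when the means agree to a relative 1e-9 and p = 0 otherwise.
    scale = np.maximum(np.abs(m1), np.abs(m2))
    zero_se = ~(se > 1e-12 * scale)
    means_equal = np.isclose(m1, m2, rtol=1e-9, atol=0.0)
    p = np.where(zero_se & means_equal, 1.0, p)
    p = np.where(zero_se & ~means_equal, 0.0, p)
    # Welch df is NaN when both variances are 0; conventions above cover it.
    return p


class GroupContrast(BaseEstimator):
    """sklearn-style estimator for one two-group differential contrast.

    Fit on ``X`` (samples x lipids, NaN = missing) and ``y`` (group label
    per sample); exactly two labels must occur and ``reference`` names the
    reference one.  Fitted attributes follow the trailing-underscore
    convention: ``log2fc_``, ``p_value_``, ``n_ref_``, ``n_test_``,
    ``is_drl_``, ``direction_``, ``eligible_`` and ``excluded_reasons_``.
    Lipids failing the replicate rule or with an undefined fold change are
    ineligible (``eligible_`` False) and carry NaN statistics.
    """

    def __init__(
        self,
        reference: str,
        alpha: float = 0.05,
        min_replicates: int = 2,
        equal_variance: bool = True,
        fdr_correct: bool = False,
    ):
        self.reference = reference
        self.alpha = alpha
        self.min_replicates = min_replicates
        self.equal_variance = equal_variance
        self.fdr_correct = fdr_correct

    def _params(self) -> AnalysisParams:
        return AnalysisParams(
            alpha=self.alpha,
            min_replicates=self.min_replicates,
            equal_variance=self.equal_variance,
            fdr_correct=self.fdr_correct,
        )

    def fit(self, X, y):
        params = self._params()  # validates
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be samples x lipids aligned with y")
        labels = pd.unique(y)
        if len(labels) != 2:
            raise ValidationError(f"need exactly 2 group labels, got {list(labels)}")
        if self.reference not in labels:
            raise ValidationError(f"reference {self.reference!r} not among {list(labels)}")
        test_label = next(l for l in labels if l != self.reference)

        x_ref = X[y == self.reference].T  # lipids x replicates
        x_test = X[y == test_label].T
        n_ref = np.sum(~np.isnan(x_ref), axis=1)
        n_test = np.sum(~np.isnan(x_test), axis=1)
        eligible = (n_ref >= params.min_replicates) & (n_test >= params.min_replicates)

        reasons = np.where(eligible, "", "fewer than min_replicates present")
        m_ref = _safe_rowmean(x_ref)
        m_test = _safe_rowmean(x_test)
        zero_mean = eligible & ~((m_ref > 0) & (m_test > 0))
        reasons = np.where(zero_mean, "group mean not positive; log2fc undefined", reasons)
        eligible = eligible & ~zero_mean

        log2fc = np.full(X.shape[1], np.nan)
        p_value = np.full(X.shape[1], np.nan)
        if eligible.any():
            idx = np.flatnonzero(eligible)
            log2fc[idx] = np.log2(m_test[idx] / m_ref[idx])
            p_value[idx] = _two_sample_t(
                x_ref[idx], x_test[idx], params.equal_variance
            )
            if params.fdr_correct:
                from statsmodels.stats.multitest import multipletests

                p_value[idx] = multipletests(p_value[idx], method="fdr_bh")[1]

        is_drl = eligible & (p_value < params.alpha) & (log2fc != 0)
        direction = np.where(
            is_drl & (log2fc > 0), "Up", np.where(is_drl & (log2fc < 0), "Down", "none")
        )

        self.test_label_ = test_label
        self.n_ref_ = n_ref
        self.n_test_ = n_test
        self.eligible_ = eligible
        self.excluded_reasons_ = reasons
        self.log2fc_ = log2fc
        self.p_value_ = p_value
        self.is_drl_ = is_drl
        self.direction_ = direction
        self.n_features_in_ = X.shape[1]
        return self


def _safe_rowmean(x: np.ndarray) -> np.ndarray:
    """Row means over present values; NaN for all-missing rows, no warnings."""
    n = np.sum(~np.isnan(x), axis=1)
    s = np.nansum(x, axis=1)
    return np.where(n > 0, s / np.maximum(n, 1), np.nan)


def compute_contrast(
    table: ConcentrationTable,
    reference_group: tuple[str, str],
    test_group: tuple[str, str],
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Contrast two (cell_line, treatment) groups of a mol% table.

    Returns one row per *eligible* lipid with columns
    ``lipid, lipid_class, category, log2fc, p_value, n_ref, n_test,
    is_drl, direction``; contrast identity and exclusion reasons travel in
    ``DataFrame.attrs``.  Raises on a self-contrast.
    """
    params = params or AnalysisParams()
    if tuple(reference_group) == tuple(test_group):
        raise ValidationError(f"self-contrast: {reference_group} vs {test_group}")
    if table.unit != "mol_pct":
        raise ValidationError("contrast requires a mol%-normalized table")
    ref_cols = table.group_columns(*reference_group)
    test_cols = table.group_columns(*test_group)

    X = table.values[ref_cols + test_cols].to_numpy(dtype=float).T
    y = np.array(["ref"] * len(ref_cols) + ["test"] * len(test_cols))
    est = GroupContrast(
        reference="ref",
        alpha=params.alpha,
        min_replicates=params.min_replicates,
        equal_variance=params.equal_variance,
        fdr_correct=params.fdr_correct,
    ).fit(X, y)

    keep = est.eligible_
    result = pd.DataFrame(
        {
            "lipid": np.asarray(table.lipid_names)[keep],
            "lipid_class": [s.lipid_class for s, k in zip(table.lipids, keep) if k],
            "category": [s.category for s, k in zip(table.lipids, keep) if k],
            "log2fc": est.log2fc_[keep],
            "p_value": est.p_value_[keep],
            "n_ref": est.n_ref_[keep],
            "n_test": est.n_test_[keep],
            "is_drl": est.is_drl_[keep],
            "direction": est.direction_[keep],
        }
    )
    result.attrs["reference_group"] = tuple(reference_group)
    result.attrs["test_group"] = tuple(test_group)
    result.attrs["alpha"] = params.alpha
    result.attrs["excluded"] = {
        name: reason
        for name, reason, k in zip(table.lipid_names, est.excluded_reasons_, keep)
        if not k
    }
    return result


def to_records(contrast: pd.DataFrame) -> list[ContrastResult]:
    """View a contrast table as typed records."""
    ref = contrast.attrs.get("reference_group", ("", ""))
    test = contrast.attrs.get("test_group", ("", ""))
    return [
        ContrastResult(
            lipid=row.lipid,
            lipid_class=row.lipid_class,
            category=row.category,
            reference_group=tuple(ref),
            test_group=tuple(test),
            log2fc=row.log2fc,
            p_value=row.p_value,
            n_ref=int(row.n_ref),
            n_test=int(row.n_test),
            is_drl=bool(row.is_drl),
            direction=row.direction,
        )
        for row in contrast.itertuples(index=False)
    ]


def drl_table(contrast: pd.DataFrame) -> pd.DataFrame:
    """DRL subset of a contrast, stably sorted by class then lipid name.

    Per-class and per-category Up/Down roll-up counts are attached as
    ``attrs["class_counts"]`` and ``attrs["category_counts"]``.
    """
    drls = contrast[contrast["is_drl"]].sort_values(
        ["lipid_class", "lipid"], kind="stable"
    )
    drls = drls.reset_index(drop=True)
    drls.attrs.update(contrast.attrs)
    drls.attrs["class_counts"] = rollup_counts(drls, by="lipid_class")
    drls.attrs["category_counts"] = rollup_counts(drls, by="category")
    return drls


def rollup_counts(drls: pd.DataFrame, by: str = "lipid_class") -> pd.DataFrame:
    """Up/Down DRL counts per class or category."""
    if drls.empty:
        return pd.DataFrame(columns=["Up", "Down"])
    counts = (
        drls.groupby([by, "direction"], observed=True).size().unstack(fill_value=0)
    )
    for col in ("Up", "Down"):
        if col not in counts.columns:
            counts[col] = 0
    return counts[["Up", "Down"]]
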