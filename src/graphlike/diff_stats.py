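"""Differential-expression statistics and PCA.

Uni-variate two-sided Welch t-tests (unequal variances, Welch-Satterthwaite
degrees of freedom) per entity between two sample groups, with
Benjamini-Hochberg control of the false discovery rate across the tested
entities of a table. Measurements are assumed to arrive already
log-transformed/normalised, so the fold change is the difference of group
means. An optional log2 preprocessing helper is provided for raw uploads.

PCA treats samples as observations and entities as variables; variables are
centred and, by default, scaled to unit variance so that scree plots are
comparable across omics with different measurement units.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .formats_io import FormatWarning, MeasurementTable

__all__ = [
    "DEResult",
    "PCAResult",
    "welch_ttest_de",
    "apply_de",
    "bh_adjust",
    "run_pca",
    "log2_transform",
]


@dataclasses.dataclass
class DEResult:
    """Per-entity Welch t-test results for one group comparison.

    ``table`` columns: fold_change, t_statistic, df, raw_p, padj (NaN for
    untestable entities); ``untestable`` maps entity id -> reason.
    """

    comparison: str
    table: pd.DataFrame
    untestable: dict[str, str]

    @property
    def tested_ids(self) -> list[str]:
        return list(self.table.index[self.table["raw_p"].notna()])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    ``adj_(i) = min_{j>=i} (m * p_(j) / j)`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_ttest_de(table: MeasurementTable, group1: str, group2: str) -> DEResult:
    """Two-sided Welch t-test per entity, BH-adjusted across the table.

    Fold change is mean(group1) - mean(group2) on the stored (log-scale)
    values. Entities with fewer than two non-missing samples in either group
    are untestable and reported, not tested. Entities with zero variance in
    both groups get p = 1 when the means agree and are flagged untestable
    when they differ (a nonzero difference with zero spread carries no
    finite-variance evidence to quantify).
    """
    s1 = table.samples_of_group(group1)
    s2 = table.samples_of_group(group2)
    if not s1:
        raise KeyError(f"unknown or empty group: {group1!r}")
    if not s2:
        raise KeyError(f"unknown or empty group: {group2!r}")
    x1 = table.values[s1].to_numpy(dtype=float)
    x2 = table.values[s2].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(x1), axis=1)
    n2 = np.sum(~np.isnan(x2), axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices handled below
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        v1 = np.nanvar(x1, axis=1, ddof=1)
        v2 = np.nanvar(x2, axis=1, ddof=1)

    fc = m1 - m2
    t = np.full(len(fc), np.nan)
    df = np.full(len(fc), np.nan)
    raw_p = np.full(len(fc), np.nan)
    untestable: dict[str, str] = {}

    enough = (n1 >= 2) & (n2 >= 2)
    se2 = np.where(enough, v1 / np.maximum(n1, 1) + v2 / np.maximum(n2, 1), np.nan)
    zero_var = enough & (se2 == 0)
    testable = enough & (se2 > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t[testable] = fc[testable] / np.sqrt(se2[testable])
        df[testable] = se2[testable] ** 2 / (
            (v1[testable] / n1[testable]) ** 2 / (n1[testable] - 1)
            + (v2[testable] / n2[testable]) ** 2 / (n2[testable] - 1)
        )
    raw_p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), df[testable])

    same_mean = zero_var & np.isclose(fc, 0.0)
    t[same_mean] = 0.0
    raw_p[same_mean] = 1.0
    df[same_mean] = n1[same_mean] + n2[same_mean] - 2

    ids = table.entity_ids
    for i in np.flatnonzero(~enough):
        untestable[ids[i]] = "fewer than 2 usable samples in a group"
    for i in np.flatnonzero(zero_var & ~same_mean):
        untestable[ids[i]] = "zero variance in both groups with unequal means"

    if not np.any(~np.isnan(raw_p)):
        raise ValueError(
            f"no entity is testable for {group1} vs {group2} "
            "(need >=2 usable samples per group)"
        )
    if untestable:
        warnings.warn(
            f"{len(untestable)} entities untestable for {group1} vs {group2}",
            FormatWarning,
            stacklevel=2,
        )

    padj = np.full(len(fc), np.nan)
    tested = ~np.isnan(raw_p)
    padj[tested] = bh_adjust(raw_p[tested])

    frame = pd.DataFrame(
        {
            "fold_change": fc,
            "t_statistic": t,
            "df": df,
            "raw_p": raw_p,
            "padj": padj,
        },
        index=pd.Index(ids, name="id"),
    )
    return DEResult(comparison=f"{group1}_vs_{group2}", table=frame, untestable=untestable)


def apply_de(table: MeasurementTable, result: DEResult) -> None:
    """Write a DE result back into the table's FC_/padj_ columns."""
    table.set_de(
        result.comparison,
        result.table["fold_change"].to_numpy(),
        result.table["padj"].to_numpy(),
    )


@dataclasses.dataclass
class PCAResult:
    """Sample scores, per-component explained-variance fractions, loadings."""

    scores: pd.DataFrame  # samples x components
    explained_variance_fraction: np.ndarray
    loadings: pd.DataFrame  # entities x components

    def __post_init__(self) -> None:
        f = self.explained_variance_fraction
        if np.any(f < -1e-12) or f.sum() > 1 + 1e-9:
            raise ValueError("explained variance fractions must be in [0, 1] and sum <= 1")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("explained variance fractions must be non-increasing")


def run_pca(table: MeasurementTable, n_components: int, scale: bool = True) -> PCAResult:
    """PCA of samples over entity variables.

    Entities with missing values or (when scaling) zero variance are dropped
    with a warning; an all-constant table is an error.
    """
    X = table.values.to_numpy(dtype=float).T  # samples x entities
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    keep = ~np.isnan(X).any(axis=0)
    n_dropped_missing = int((~keep).sum())
    variances = np.zeros(X.shape[1])
    variances[keep] = X[:, keep].var(axis=0)
    nonconstant = variances > 0
    if not np.any(keep & nonconstant):
        raise ValueError("no usable entities: table is constant or all-missing")
    if scale:
        keep = keep & nonconstant
    dropped = X.shape[1] - int(keep.sum())
    if dropped:
        warnings.warn(
            f"PCA dropped {dropped} entities ({n_dropped_missing} with missing values"
            + (", rest zero-variance)" if scale else ")"),
            FormatWarning,
            stacklevel=2,
        )
    X = X[:, keep]
    entity_index = table.values.index[keep]
    if not (1 <= n_components <= min(X.shape)):
        raise ValueError(
            f"n_components must be in [1, {min(X.shape)}] for this table"
        )
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    component_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.sample_ids, columns=component_names),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(
            pca.components_.T, index=entity_index, columns=component_names
        ),
    )


def log2_transform(table: MeasurementTable, pseudocount: float = 1.0) -> MeasurementTable:
    """Optional preprocessing for raw (non-log) uploads: log2(x + c)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    values = np.log2(table.values + pseudocount)
    return MeasurementTable(
        omics_kind=table.omics_kind,
        values=values,
        group_of=dict(table.group_of),
        de=table.de.copy(),
    )
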