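"""Fold-change clustering and PCA of mol% lipid profiles.

Clustering operates on a lipids x contrasts matrix of log2 fold changes
where every cell that is not a significant DRL — whether missing (lipid
not evaluable in that contrast) or simply non-significant — is replaced
by zero; a provenance mask records why each zero is there.  Profiles are
compared by Pearson correlation distance (1 - r) under average linkage.
Zero-variance profiles have undefined correlation; by convention they sit
at distance 1 (uncorrelated) from every other profile.

PCA runs on mol%/sample profiles (samples as observations), column-
centered and unscaled.  The per-component sign indeterminacy is fixed by
making the largest-magnitude loading of each component positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .ingest import ConcentrationTable
from .errors import ValidationError

__all__ = [
    "Log2FCMatrix",
    "PCAResult",
    "ClusterResult",
    "LipidPCA",
    "CorrelationClusterer",
    "build_log2fc_matrix",
    "cluster",
    "pca_molpct",
    "pearson_distance_matrix",
]

#: mask codes for zero-filled cells
MASK_DRL = "drl"                      # significant: genuine log2fc kept
MASK_NONSIGNIFICANT = "nonsignificant"  # eligible but not called; filled 0
MASK_MISSING = "missing"              # not in the contrast's eligible set
MASK_ZERO = "zero"                    # eligible with log2fc exactly 0


@dataclass
class Log2FCMatrix:
    """Zero-filled lipids x contrasts log2 fold-change matrix with provenance."""

    values: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("log2fc matrix must have no missing entries")
        if self.values.shape != self.mask.shape:
            raise ValidationError("values and mask shapes differ")


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a lipidome PCA."""

    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # lipids x components
    explained_variance_fraction: np.ndarray
    dropped_lipids: list[str] = field(default_factory=list)


@dataclass
class ClusterResult:
    """Agglomerative clustering output for one axis."""

    labels: list[str]
    linkage: np.ndarray         # scipy linkage matrix
    leaf_order: list[str]
    distances: pd.DataFrame     # pairwise Pearson distances


def build_log2fc_matrix(contrasts: dict[str, pd.DataFrame]) -> Log2FCMatrix:
    """Assemble the clustering matrix from per-contrast result tables.

    Rows are the union of lipids over all contrasts; a cell holds the
    lipid's log2fc where it is a DRL in that contrast and 0 otherwise.
    The mask distinguishes significant values from non-significant fills,
    replicate-rule exclusions and exact zeros.
    """
    labels = list(contrasts)
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate contrast labels: {labels}")
    if not labels:
        raise ValidationError("need >= 1 contrast")
    lipids = sorted({l for df in contrasts.values() for l in df["lipid"]})
    values = pd.DataFrame(0.0, index=pd.Index(lipids, name="lipid"), columns=labels)
    mask = pd.DataFrame(MASK_MISSING, index=values.index, columns=labels)
    for label, df in contrasts.items():
        fc = dict(zip(df["lipid"], df["log2fc"]))
        drl = dict(zip(df["lipid"], df["is_drl"]))
        for lipid in df["lipid"]:
            if drl[lipid]:
                values.loc[lipid, label] = fc[lipid]
                mask.loc[lipid, label] = MASK_DRL
            elif fc[lipid] == 0:
                mask.loc[lipid, label] = MASK_ZERO
            else:
                mask.loc[lipid, label] = MASK_NONSIGNIFICANT
    return Log2FCMatrix(values=values, mask=mask)


def pearson_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r over rows; zero-variance rows at distance 1.

    The diagonal is 0.  Distances are clipped into [0, 2] to absorb
    floating-point excursions.
    """
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    sd = profiles.std(axis=1)
    constant = ~(sd > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles)
    corr = np.atleast_2d(corr)
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


class CorrelationClusterer(BaseEstimator):
    """Average-linkage agglomerative clustering on Pearson distance.

    Fit on observations x features; fitted attributes are ``linkage_``
    (scipy linkage matrix) and ``leaf_order_`` (dendrogram leaf indices).
    Deterministic: ties are broken by scipy's stable merge ordering on
    the condensed distance index.
    """

    def __init__(self, linkage_method: str = "average"):
        self.linkage_method = linkage_method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("need >= 2 observations to cluster")
        dist = pearson_distance_matrix(X)
        condensed = squareform(dist, checks=False)
        self.distances_ = dist
        self.linkage_ = hierarchy.linkage(condensed, method=self.linkage_method)
        self.leaf_order_ = list(hierarchy.leaves_list(self.linkage_))
        self.n_features_in_ = X.shape[1]
        return self


def cluster(
    matrix: Log2FCMatrix, axis: str = "lipids", linkage_method: str = "average"
) -> ClusterResult:
    """Cluster lipids (rows) or contrasts (columns) of a zero-filled matrix."""
    if axis not in ("lipids", "contrasts"):
        raise ValidationError(f"axis must be 'lipids' or 'contrasts', got {axis!r}")
    frame = matrix.values if axis == "lipids" else matrix.values.T
    labels = list(frame.index)
    if len(labels) < 2:
        raise ValidationError(f"need >= 2 {axis} to cluster, got {len(labels)}")
    est = CorrelationClusterer(linkage_method=linkage_method).fit(frame.to_numpy())
    return ClusterResult(
        labels=labels,
        linkage=est.linkage_,
        leaf_order=[labels[i] for i in est.leaf_order_],
        distances=pd.DataFrame(est.distances_, index=labels, columns=labels),
    )


class LipidPCA(TransformerMixin, BaseEstimator):
    """Column-centered, unscaled PCA with a fixed sign convention.

    Thin wrapper over :class:`sklearn.decomposition.PCA` (full SVD solver,
    deterministic) that flips each component so its largest-magnitude
    loading is positive, making scores reproducible across runs and BLAS
    builds.  Set ``scale=True`` to standardize features first (off by
    default: mol% values share a scale).
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n_samples, n_features = X.shape
        limit = min(n_samples - 1, n_features)
        if not 1 <= self.n_components <= limit:
            raise ValidationError(
                f"n_components must be in [1, {limit}] for {n_samples} samples "
                f"x {n_features} lipids"
            )
        if np.isnan(X).any():
            raise ValidationError("PCA input must have no missing values")
        self.scale_ = X.std(axis=0, ddof=0) if self.scale else None
        if self.scale_ is not None:
            X = X / np.where(self.scale_ > 0, self.scale_, 1.0)
        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        flip = np.where(
            pca.components_[
                np.arange(self.n_components),
                np.argmax(np.abs(pca.components_), axis=1),
            ]
            < 0,
            -1.0,
            1.0,
        )
        self.components_ = pca.components_ * flip[:, None]
        self.mean_ = pca.mean_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.scores_ = scores * flip[None, :]
        self.n_features_in_ = n_features
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.scale_ is not None:
            X = X / np.where(self.scale_ > 0, self.scale_, 1.0)
        return (X - self.mean_) @ self.components_.T


def pca_molpct(
    table: ConcentrationTable, n_components: int = 2, scale: bool = False
) -> PCAResult:
    """PCA of mol% profiles with samples as observations.

    Lipids with any missing value across the included samples are dropped
    (they are listed in ``PCAResult.dropped_lipids``).
    """
    if table.unit != "mol_pct":
        raise ValidationError("PCA requires a mol%-normalized table")
    if table.n_samples < 2:
        raise ValidationError("PCA needs >= 2 samples")
    complete = table.values.dropna(axis=0)
    dropped = [l for l in table.values.index if l not in set(complete.index)]
    X = complete.to_numpy(dtype=float).T  # samples x lipids
    est = LipidPCA(n_components=n_components, scale=scale).fit(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(est.scores_, index=table.values.columns, columns=comp_names),
        loadings=pd.DataFrame(est.components_.T, index=complete.index, columns=comp_names),
        explained_variance_fraction=est.explained_variance_ratio_,
        dropped_lipids=dropped,
    )
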