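"""Reading concentration matrices, acquisition filtering and mol% scaling.

The central container is :class:`ConcentrationTable`: a lipids x samples
matrix of non-negative concentrations (pmol) with *explicit* missingness
(NaN) plus per-sample metadata (cell line, treatment, replicate).  Missing
means "below the detection limit, not measurable" and is never imputed;
a stored 0.0 is a measured zero and is kept distinct from missing.

mol% normalization divides each sample's present values by the sample's
present-value sum and multiplies by 100, so every non-degenerate sample
sums to exactly 100 mol%.  Replicate averaging uses present values only.

The acquisition-stage identification filter keeps a (lipid, sample) cell
only when signal/noise exceeds ``snr_min`` (strictly) AND the signal
exceeds ``blank_fold_min`` times the lipid's blank-sample intensity.  It
applies to intensity-level inputs (real or synthetic); pmol tables are
assumed pre-filtered upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import nomenclature
from .errors import DegenerateSampleError, SchemaError, ValidationError

__all__ = [
    "TREATMENTS",
    "FilterParams",
    "ConcentrationTable",
    "MolPercentNormalizer",
    "read_table",
    "read_metadata",
    "acquisition_filter",
    "normalize_mol_pct",
    "average_replicates",
    "group_means",
]

#: recognised treatment labels; "none" marks untreated samples
TREATMENTS = ("none", "Wnt3a", "Dkk1")

_META_COLUMNS = ("cell_line", "treatment", "replicate")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the acquisition-stage identification filter."""

    snr_min: float = 5.0
    blank_fold_min: float = 5.0

    def __post_init__(self) -> None:
        if self.snr_min <= 0 or self.blank_fold_min <= 0:
            raise ValidationError("filter thresholds must be > 0")


@dataclass
class ConcentrationTable:
    """Lipids x samples concentrations with metadata and explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by canonical lipid name, one column per sample id.
        NaN marks a missing (non-measurable) cell.
    lipids
        Parsed species, aligned with ``values.index``.
    samples
        DataFrame indexed by sample id with columns ``cell_line``,
        ``treatment``, ``replicate``; aligned with ``values.columns``.
    unit
        ``"pmol"`` (absolute) or ``"mol_pct"`` (percent of sample total).
    """

    values: pd.DataFrame
    lipids: list[nomenclature.LipidSpecies]
    samples: pd.DataFrame
    unit: str = "pmol"

    def __post_init__(self) -> None:
        if self.unit not in ("pmol", "mol_pct"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if len(self.lipids) != len(self.values.index):
            raise ValidationError("lipids and value rows are not aligned")
        if list(self.values.columns) != list(self.samples.index):
            raise SchemaError("value columns and sample metadata are not aligned")
        missing_cols = [c for c in _META_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise SchemaError(f"sample metadata lacks columns {missing_cols}")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("concentrations must be non-negative")
        triples = self.samples[list(_META_COLUMNS)].apply(tuple, axis=1)
        if triples.duplicated().any():
            dup = triples[triples.duplicated()].iloc[0]
            raise SchemaError(f"duplicate (cell_line, treatment, replicate) {dup}")

    # -- convenience views -------------------------------------------------
    @property
    def n_lipids(self) -> int:
        return len(self.lipids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def lipid_names(self) -> list[str]:
        return list(self.values.index)

    def group_columns(self, cell_line: str, treatment: str) -> list[str]:
        """Sample ids of one (cell_line, treatment) group."""
        mask = (self.samples["cell_line"] == cell_line) & (
            self.samples["treatment"] == treatment
        )
        cols = list(self.samples.index[mask])
        if not cols:
            raise ValidationError(f"no samples for group {(cell_line, treatment)}")
        return cols

    def groups(self) -> list[tuple[str, str]]:
        """All (cell_line, treatment) groups present, in metadata order."""
        seen: dict[tuple[str, str], None] = {}
        for _, row in self.samples.iterrows():
            seen.setdefault((row["cell_line"], row["treatment"]), None)
        return list(seen)

    def normalize(self) -> "ConcentrationTable":
        return normalize_mol_pct(self)

    def to_csv(self, matrix_path: Path | str, metadata_path: Path | str) -> None:
        """Write matrix + metadata in the same layout :func:`read_table` reads."""
        out = self.values.copy()
        out.index.name = "lipid"
        out.to_csv(matrix_path)
        meta = self.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path)


class MolPercentNormalizer(TransformerMixin, BaseEstimator):
    """Scale each sample to percent-of-total over its present lipid values.

    Follows the sklearn transformer protocol with samples as rows and
    lipids as features.  Stateless: ``fit`` only validates.  NaN cells are
    ignored in the denominator and stay NaN in the output.
    """

    def __init__(self, scale: float = 100.0):
        self.scale = scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("expected a 2-D samples x lipids array")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if np.nanmin(X, initial=0.0) < 0:
            raise ValidationError("concentrations must be non-negative")
        totals = np.nansum(X, axis=1)
        degenerate = ~(totals > 0) | np.all(np.isnan(X), axis=1)
        if degenerate.any():
            idx = int(np.flatnonzero(degenerate)[0])
            raise DegenerateSampleError(
                f"sample at row {idx} has no positive present values"
            )
        return X / totals[:, None] * self.scale


def read_metadata(metadata_path: Path | str) -> pd.DataFrame:
    """Read sample metadata (sample_id, cell_line, treatment, replicate)."""
    meta = pd.read_csv(metadata_path, sep=None, engine="python", dtype=str)
    if "sample_id" not in meta.columns:
        raise SchemaError("metadata must have a 'sample_id' column")
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata lacks columns {missing}")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][0]
        raise SchemaError(f"duplicate sample id {dup!r} in metadata")
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["replicate"] < 1).any():
        raise SchemaError("replicate numbers must be >= 1")
    return meta[list(_META_COLUMNS)]


def read_table(matrix_path: Path | str, metadata_path: Path | str) -> ConcentrationTable:
    """Read a delimited concentration matrix plus its sample metadata.

    The matrix has lipid names in the first column and one column per
    sample id; the delimiter (comma or tab) is auto-detected.  Empty cells
    are missing values, never zeros.  Every matrix column must appear in
    the metadata and vice versa.
    """
    raw = pd.read_csv(matrix_path, sep=None, engine="python", index_col=0)
    meta = read_metadata(metadata_path)
    unmatched = [c for c in raw.columns if c not in meta.index]
    if unmatched:
        raise SchemaError(f"matrix columns not in metadata: {unmatched}")
    absent = [s for s in meta.index if s not in raw.columns]
    if absent:
        raise SchemaError(f"metadata samples not in matrix: {absent}")
    values = raw[list(meta.index)].astype(float)
    if (values < 0).any().any():
        bad = values.index[(values < 0).any(axis=1)][0]
        raise ValidationError(f"negative concentration for lipid {bad!r}")
    lipids = nomenclature.parse_many(values.index)
    values.index = pd.Index(
        [nomenclature.canonical_name(s) for s in lipids], name="lipid"
    )
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise SchemaError(f"duplicate lipid {dup!r} after canonicalization")
    return ConcentrationTable(values=values, lipids=lipids, samples=meta, unit="pmol")


def acquisition_filter(signal, noise, blank, params: FilterParams | None = None):
    """Keep-mask of the identification filter on intensity-level data.

    A cell is kept iff ``signal/noise > snr_min`` (strict) and
    ``signal > blank_fold_min * blank``.  ``blank`` is per lipid (1-D,
    broadcast across samples) or a full grid.

    Returns a boolean array (or DataFrame, matching the input type).
    """
    params = params or FilterParams()
    sig = np.asarray(signal, dtype=float)
    noi = np.asarray(noise, dtype=float)
    blk = np.asarray(blank, dtype=float)
    if noi.shape != sig.shape:
        raise ValidationError(f"noise shape {noi.shape} != signal shape {sig.shape}")
    if blk.ndim == 1:
        if blk.shape[0] != sig.shape[0]:
            raise ValidationError("per-lipid blank length must match signal rows")
        blk = blk[:, None]
    elif blk.shape != sig.shape:
        raise ValidationError(f"blank shape {blk.shape} incompatible with signal")
    if np.any(noi <= 0):
        raise ValidationError("noise must be > 0 everywhere")
    if np.any(blk < 0):
        raise ValidationError("blank intensities must be >= 0")
    keep = (sig / noi > params.snr_min) & (sig > params.blank_fold_min * blk)
    if isinstance(signal, pd.DataFrame):
        return pd.DataFrame(keep, index=signal.index, columns=signal.columns)
    return keep


def normalize_mol_pct(table: ConcentrationTable) -> ConcentrationTable:
    """Convert a pmol table to mol% per sample.

    Each present value is divided by its sample's present-value sum and
    multiplied by 100; missing cells stay missing.  Idempotent up to
    floating-point error.  A sample with no positive present value raises
    :class:`DegenerateSampleError` naming the sample.
    """
    X = table.values.to_numpy(dtype=float).T  # samples x lipids
    totals = np.nansum(X, axis=1)
    degenerate = ~(totals > 0)
    if degenerate.any():
        sample = table.samples.index[int(np.flatnonzero(degenerate)[0])]
        raise DegenerateSampleError(
            f"sample {sample!r} has no positive present values"
        )
    normalized = MolPercentNormalizer().fit(X).transform(X)
    values = pd.DataFrame(
        normalized.T, index=table.values.index, columns=table.values.columns
    )
    return replace(table, values=values, unit="mol_pct")


def average_replicates(
    table: ConcentrationTable, group_key: tuple[str, str]
) -> pd.DataFrame:
    """Per-lipid mean and present-replicate count for one group.

    Missing replicate values are neglected: the mean is over present values
    only, and a lipid with zero present replicates gets mean NaN, count 0.
    Returns a DataFrame with columns ``mean`` and ``n``.
    """
    cols = table.group_columns(*group_key)  # raises on unknown group
    block = table.values[cols]
    return pd.DataFrame(
        {"mean": block.mean(axis=1), "n": block.notna().sum(axis=1).astype(int)}
    )


def group_means(table: ConcentrationTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Means and present-replicate counts for every (cell_line, treatment).

    Returns ``(means, counts)`` DataFrames with lipids as rows and groups
    (as ``cell_line:treatment`` labels) as columns.
    """
    means, counts = {}, {}
    for cell_line, treatment in table.groups():
        label = f"{cell_line}:{treatment}"
        avg = average_replicates(table, (cell_line, treatment))
        means[label] = avg["mean"]
        counts[label] = avg["n"]
    return pd.DataFrame(means), pd.DataFrame(counts)
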