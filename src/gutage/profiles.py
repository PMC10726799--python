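"""Abundance-matrix data model and I/O.

Matrices are pandas DataFrames with features as rows and samples as columns
(the common export layout for metagenomic gene profiles). Values are
nonnegative relative abundances; after :func:`normalize_relative` every
sample column sums to 1.

A *feature map* (gene -> KO, or gene -> cluster) is a plain mapping or a
two-column DataFrame; each feature maps to at most one group.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "normalize_relative",
    "aggregate_ko",
    "mgs_abundance",
    "read_matrix",
    "write_matrix",
    "validate_matrix",
]


def validate_matrix(matrix: pd.DataFrame, *, normalized: bool = False) -> None:
    """Check AbundanceMatrix invariants; raise ValueError on violation."""
    if (matrix.values < 0).any():
        raise ValueError("abundance matrix contains negative entries")
    if matrix.index.has_duplicates:
        raise ValueError("duplicate feature ids")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    if normalized:
        sums = matrix.sum(axis=0).to_numpy()
        ok = (np.abs(sums - 1.0) <= 1e-6) | (sums == 0.0)
        if not ok.all():
            bad = matrix.columns[~ok].tolist()
            raise ValueError(f"columns not normalized: {bad}")


def normalize_relative(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its sum so columns sum to 1.

    Raises ValueError naming the first all-zero sample, since a sample with
    no signal has no defined composition.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    sums = counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total abundance")
    return counts.div(sums, axis=1)


def _as_map(feature_map: Mapping[str, str] | pd.DataFrame) -> pd.Series:
    if isinstance(feature_map, pd.DataFrame):
        if feature_map.shape[1] != 2:
            raise ValueError("feature map frame must have exactly two columns")
        s = pd.Series(
            feature_map.iloc[:, 1].to_numpy(), index=feature_map.iloc[:, 0]
        )
    else:
        s = pd.Series(dict(feature_map))
    if s.index.has_duplicates:
        raise ValueError("a feature maps to more than one group")
    return s


def aggregate_ko(genes: pd.DataFrame, feature_map: Mapping[str, str] | pd.DataFrame) -> pd.DataFrame:
    """Sum gene relative abundances into KO (group) abundances per sample.

    Unmapped genes contribute to no group; the result is NOT renormalized, so
    per-sample group totals equal the summed abundance of mapped genes.
    """
    mapping = _as_map(feature_map)
    if len(mapping) == 0:
        warnings.warn("empty feature map: returning empty matrix", stacklevel=2)
        return pd.DataFrame(columns=genes.columns, dtype=float)
    unknown = mapping.index.difference(genes.index)
    if len(unknown):
        raise ValueError(f"feature map references unknown genes: {list(unknown[:5])}")
    sub = genes.loc[mapping.index]
    out = sub.groupby(mapping.to_numpy()).sum()
    out.index.name = genes.index.name
    return out


def mgs_abundance(genes: pd.DataFrame, membership: Mapping[str, str] | pd.DataFrame) -> pd.DataFrame:
    """Per-sample cluster abundance = median of member-gene abundances.

    Even-sized clusters use the midpoint of the two central values (the
    standard statistical median).
    """
    mapping = _as_map(membership)
    if len(mapping) == 0:
        raise ValueError("empty cluster membership")
    unknown = mapping.index.difference(genes.index)
    if len(unknown):
        raise ValueError(f"cluster references unknown genes: {list(unknown[:5])}")
    sub = genes.loc[mapping.index]
    out = sub.groupby(mapping.to_numpy()).median()
    out.index.name = "cluster"
    return out


def read_matrix(path) -> pd.DataFrame:
    """Read a features x samples TSV matrix (first column = feature id)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    return m.astype(float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a features x samples TSV; round-trips to 12 significant digits."""
    matrix.to_csv(path, sep="\t", float_format="%.12g")
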