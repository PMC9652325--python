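"""Cross-sample comparability of compartment scores.

Raw compartment scores from different samples (and replicates) live on
arbitrary scales: each is a principal component of a different correlation
matrix. Quantile normalization, applied per chromosome across all replicate
columns jointly, forces every column onto the shared distribution of mean
order statistics; replicate columns are then averaged into one score per
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, FormatError, NumericError
from .genome import BinSet, read_bedgraph

__all__ = [
    "ScoreMatrix",
    "QuantileNormalizer",
    "quantile_normalize",
    "average_replicates",
    "load_precomputed_scores",
]


@dataclass
class ScoreMatrix:
    """bins x columns matrix of compartment scores.

    Rows follow ``bin_frame`` (chrom, start, end; chromosomes concatenated
    in file order). ``columns`` labels each score column; ``samples`` gives
    the sample each column belongs to. NaN marks a masked bin; a bin masked
    in any one column is treated as masked in all of them.
    """

    bin_frame: pd.DataFrame
    values: np.ndarray
    columns: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bin_frame), len(self.columns)):
            raise ValueError("ScoreMatrix shape mismatch")
        if len(self.samples) != len(self.columns):
            raise ValueError("one sample label per column required")

    @property
    def complete_rows(self) -> np.ndarray:
        """Boolean mask of bins defined in every column."""
        return np.isfinite(self.values).all(axis=1)

    def chrom_slices(self):
        for chrom, grp in self.bin_frame.groupby("chrom", sort=False):
            yield chrom, grp.index.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        out = self.bin_frame.reset_index(drop=True).copy()
        for j, label in enumerate(self.columns):
            out[label] = self.values[:, j]
        return out


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization of score columns.

    ``fit`` learns the reference distribution (the across-column mean of
    order statistics); ``transform`` maps each column onto it by rank, with
    ties receiving the average of the tied reference values. ``fit_transform``
    on the same matrix is the usual joint quantile normalization.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise NumericError("quantile normalization needs >= 2 columns")
        if X.shape[0] < 2:
            raise NumericError("quantile normalization needs >= 2 rows")
        if not np.isfinite(X).all():
            raise NumericError("quantile normalization input must be complete")
        self.reference_quantiles_ = np.sort(X, axis=0).mean(axis=1)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        ref = self.reference_quantiles_
        grid = np.arange(1, len(ref) + 1, dtype=float)
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            # average ranks -> averaged reference values for ties
            r = rankdata(X[:, j], method="average") * (len(ref) / X.shape[0])
            out[:, j] = np.interp(r, grid, ref)
        return out


def quantile_normalize(scores: ScoreMatrix) -> ScoreMatrix:
    """Quantile-normalize all columns jointly, independently per chromosome.

    Bins masked (NaN) in any column are excluded from the normalization
    pool for every column and stay masked in the output.
    """
    values = scores.values.copy()
    complete = scores.complete_rows
    values[~complete] = np.nan
    for chrom, idx in scores.chrom_slices():
        rows = idx[complete[idx]]
        if len(rows) == 0:
            continue
        if len(rows) < 2:
            raise NumericError(f"{chrom}: fewer than 2 usable bins for normalization")
        values[rows] = QuantileNormalizer().fit_transform(values[rows])
    return replace(scores, values=values)


def average_replicates(
    scores: ScoreMatrix, design: Mapping[str, Sequence[str]]
) -> ScoreMatrix:
    """Collapse replicate columns to one column per sample (per-bin mean).

    ``design`` maps sample name -> its replicate column labels, all of which
    must exist in ``scores``.
    """
    col_index = {c: j for j, c in enumerate(scores.columns)}
    out = np.empty((scores.values.shape[0], len(design)))
    samples = list(design)
    for k, sample in enumerate(samples):
        cols = []
        for rep in design[sample]:
            if rep not in col_index:
                raise ConfigError(f"replicate column {rep!r} absent from score matrix")
            cols.append(col_index[rep])
        out[:, k] = scores.values[:, cols].mean(axis=1)
    return ScoreMatrix(scores.bin_frame, out, samples, samples)


def load_precomputed_scores(
    files: Sequence[tuple[str, str, str | Path]], binset: BinSet
) -> ScoreMatrix:
    """Assemble a ScoreMatrix from per-column bedGraph score tracks.

    ``files`` is a sequence of (sample, replicate, path). Every file must be
    on the bin grid of ``binset``; bins missing from any file come out
    masked (NaN) in that column.
    """
    frame = binset.frame
    key = {(c, s): i for i, (c, s) in enumerate(zip(frame.chrom, frame.start))}
    values = np.full((len(frame), len(files)), np.nan)
    columns, samples = [], []
    for j, (sample, replicate, path) in enumerate(files):
        bg = read_bedgraph(path)
        for chrom, start, end, value in bg.itertuples(index=False):
            i = key.get((chrom, start))
            if i is None or int(frame.end.iloc[i]) != end:
                raise FormatError(
                    f"{path}: interval {chrom}:{start}-{end} is not on the bin grid"
                )
            values[i, j] = value
        columns.append(f"{sample}:{replicate}" if replicate else sample)
        samples.append(sample)
    return ScoreMatrix(frame, values, columns, samples)
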