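"""Differential chromatin interactions within differential compartments.

Significant cis interactions (e.g. FitHiC2 calls) are filtered to those
anchored in at least one differential compartment bin, converted to
per-sample log2(observed/expected) values under the shared distance-decay
expectation, and tested with the same Mahalanobis / chi-square machinery as
the compartments — here with a fixed per-sample center and no outlier
pre-pass.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .compartment import expected_by_diagonal
from .differential import MDConfig, _bh, mahalanobis, robust_inverse_covariance
from .errors import FormatError, NumericError
from .genome import BinSet, ContactMap

__all__ = [
    "read_fithic",
    "records_to_bins",
    "overlap_filter",
    "interaction_oe",
    "md_interactions",
    "DifferentialInteractions",
]

#: fewest qualifying records for a usable covariance estimate
MIN_RECORDS = 10


def read_fithic(path: str | Path) -> pd.DataFrame:
    """Read a FitHiC2-style interactions TSV (cis rows only).

    Expected columns: chrom1, pos1, chrom2, pos2[, count, q-value]; a header
    line is detected and skipped. Positions are fragment/bin midpoints or
    starts — anything inside the intended bin.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: need >= 4 columns (chr1 pos1 chr2 pos2)")
    if not df.iloc[0, 1].lstrip("-").isdigit():  # header row
        df = df.iloc[1:].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "chrom1": df[0],
            "pos1": df[1].astype(int),
            "chrom2": df[2],
            "pos2": df[3].astype(int),
        }
    )
    return out[out.chrom1 == out.chrom2].reset_index(drop=True)


def records_to_bins(records: pd.DataFrame, binset: BinSet) -> pd.DataFrame:
    """Map interaction anchor positions onto bin indices (binA <= binB)."""
    rows = []
    for chrom1, pos1, _, pos2 in records.itertuples(index=False):
        if chrom1 not in binset:
            raise FormatError(f"interaction chromosome {chrom1} not in bins")
        i = binset[chrom1].index_of(pos1)
        j = binset[chrom1].index_of(pos2)
        rows.append((chrom1, min(i, j), max(i, j)))
    return pd.DataFrame(rows, columns=["chrom", "binA", "binB"]).drop_duplicates(
        ignore_index=True
    )


def overlap_filter(
    records: pd.DataFrame, significant: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Keep records with >= 1 anchor in a significant differential bin.

    ``significant`` maps chromosome -> boolean per-bin array. Records kept
    once regardless of whether one or both anchors overlap.
    """
    keep = []
    for chrom, a, b in records[["chrom", "binA", "binB"]].itertuples(index=False):
        sig = significant.get(chrom)
        if sig is None:
            keep.append(False)
            continue
        if not (0 <= a < len(sig) and 0 <= b < len(sig)):
            raise FormatError(f"{chrom}: anchor bin outside the bin grid")
        keep.append(bool(sig[a] or sig[b]))
    return records[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def interaction_oe(
    cmap: ContactMap,
    records: pd.DataFrame,
    pseudocount: float = 1.0,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """log2((observed + c)/(expected + c)) per record for one sample's map.

    The expected value is the per-diagonal mean over valid bins, the same
    distance-decay model used for compartment O/E.
    """
    if valid is None:
        valid = cmap.counts.sum(axis=0) > 0
    expected = expected_by_diagonal(cmap.counts, valid)
    n = cmap.n_bins
    out = np.empty(len(records))
    for k, (a, b) in enumerate(records[["binA", "binB"]].itertuples(index=False)):
        if not (0 <= a < n and 0 <= b < n):
            raise FormatError(f"{cmap.chrom}: record ({a},{b}) outside map bounds")
        obs = cmap.counts[a, b]
        exp = expected[abs(b - a)]
        out[k] = np.log2((obs + pseudocount) / (exp + pseudocount))
    return out


def md_interactions(
    oe: np.ndarray,
    cfg: MDConfig | None = None,
    robust: bool = True,
    center: str = "mean",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mahalanobis test of records x samples log2(O/E) values.

    The center is the per-sample mean (or 10%-trimmed mean) over the tested
    set; covariance is MCD (``robust=False`` for the classical estimate); p
    is the chi-square survival probability with df = number of samples,
    BH-adjusted.
    """
    cfg = cfg or MDConfig()
    oe = np.asarray(oe, dtype=float)
    if oe.ndim != 2 or oe.shape[1] < 2:
        raise NumericError("need a records x samples matrix with >= 2 samples")
    if oe.shape[0] < MIN_RECORDS:
        raise NumericError(
            f"only {oe.shape[0]} qualifying interactions (< {MIN_RECORDS}); "
            "covariance estimate unusable"
        )
    if center == "trimmed":
        mu = stats.trim_mean(oe, 0.1, axis=0)
    else:
        mu = oe.mean(axis=0)
    if robust:
        sigma_inv = robust_inverse_covariance(oe, cfg)
    else:
        sigma_inv = np.linalg.inv(np.cov(oe, rowvar=False))
    md = mahalanobis(oe, np.broadcast_to(mu, oe.shape), sigma_inv)
    df = cfg.df or oe.shape[1]
    p = stats.chi2.sf(md, df)
    return md, p, _bh(p)


class DifferentialInteractions(BaseEstimator):
    """Estimator wrapper over :func:`md_interactions`.

    ``fit`` takes the records x samples log2(O/E) matrix and exposes
    ``md_``, ``pvalues_``, ``padj_`` and ``center_``.
    """

    def __init__(
        self,
        df: int | None = None,
        fdr_threshold: float = 0.10,
        robust: bool = True,
        center: str = "mean",
        random_state: int = 0,
    ):
        self.df = df
        self.fdr_threshold = fdr_threshold
        self.robust = robust
        self.center = center
        self.random_state = random_state

    def fit(self, X, y=None):
        cfg = MDConfig(df=self.df, random_state=self.random_state)
        X = np.asarray(X, dtype=float)
        if self.center == "trimmed":
            self.center_ = stats.trim_mean(X, 0.1, axis=0)
        else:
            self.center_ = X.mean(axis=0)
        self.md_, self.pvalues_, self.padj_ = md_interactions(
            X, cfg, robust=self.robust, center=self.center
        )
        self.significant_ = self.padj_ < self.fdr_threshold
        return self
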