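"""Per-chromosome A/B compartment scores from a cis contact map.

The classic pipeline: divide the contact map by its distance-decay
expectation (O/E), correlate O/E rows to expose the plaid pattern, take the
leading principal components of the correlation matrix, then pick the
component that tracks GC content and gene density and orient it so that
positive scores mean the A (GC-rich, gene-dense) compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.linalg
from sklearn.base import BaseEstimator

from .errors import CannotOrientError, DegenerateChromosomeError, NumericError
from .genome import ContactMap, CovariateTrack

__all__ = [
    "OEMatrix",
    "CorrelationMatrix",
    "PCResult",
    "oe_transform",
    "correlation_matrix",
    "partial_svd",
    "select_and_orient",
    "CompartmentScorer",
    "compartment_scores",
    "expected_by_diagonal",
]

#: fewest unmasked bins for which correlation PCA is considered meaningful
MIN_BINS_DEFAULT = 20


@dataclass
class OEMatrix:
    """Observed/expected ratio matrix with a per-bin exclusion mask."""

    values: np.ndarray
    mask: np.ndarray  # True = bin excluded from downstream statistics
    chrom: str = ""


@dataclass
class CorrelationMatrix:
    """Pearson correlation of O/E rows over the unmasked bins.

    ``indices`` maps the m rows/columns back to original bin indices.
    """

    values: np.ndarray
    indices: np.ndarray
    chrom: str = ""


@dataclass
class PCResult:
    """Top-k singular triplets of a correlation matrix and its PCs.

    ``pcs`` holds the projections X @ V (columns ordered by decreasing
    singular value); ``indices`` maps rows to original bin indices.
    """

    u: np.ndarray
    singular_values: np.ndarray
    v: np.ndarray
    pcs: np.ndarray
    indices: np.ndarray
    chrom: str = ""
    selected: int | None = None
    sign: int = 1
    covariate_correlations: pd.DataFrame | None = None


def expected_by_diagonal(counts: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Mean count at each diagonal offset, over pairs of valid bins only.

    Offsets with no valid pair get expected 0 (and O/E 0 downstream).
    """
    n = counts.shape[0]
    expected = np.zeros(n)
    v = valid.astype(float)
    for d in range(n):
        pair_valid = v[: n - d] * v[d:]
        m = pair_valid.sum()
        if m > 0:
            expected[d] = (np.diagonal(counts, d) * pair_valid).sum() / m
    return expected


def oe_transform(cmap: ContactMap, min_coverage_frac: float = 0.01) -> OEMatrix:
    """Distance-normalize a contact map.

    Bins with zero marginal count, or whose fraction of nonzero cis entries
    falls below ``min_coverage_frac``, are masked; the per-diagonal expected
    value is the mean over unmasked pairs, and entries with expected 0 get
    O/E 0.
    """
    counts = cmap.counts
    n = cmap.n_bins
    nonzero_frac = (counts != 0).sum(axis=0) / n
    mask = (counts.sum(axis=0) == 0) | (nonzero_frac < min_coverage_frac)
    if mask.all():
        raise DegenerateChromosomeError(f"{cmap.chrom}: all bins masked in O/E step")
    expected = expected_by_diagonal(counts, ~mask)
    offsets = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    exp_full = expected[offsets]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp_full > 0, counts / np.where(exp_full > 0, exp_full, 1.0), 0.0)
    oe[mask, :] = 0.0
    oe[:, mask] = 0.0
    return OEMatrix(oe, mask, chrom=cmap.chrom)


def correlation_matrix(oe: OEMatrix) -> CorrelationMatrix:
    """Pearson correlation of O/E rows over unmasked columns.

    Rows with zero variance are masked in place (they carry no plaid
    information and would produce undefined correlations).
    """
    idx = np.flatnonzero(~oe.mask)
    sub = oe.values[np.ix_(idx, idx)]
    constant = sub.std(axis=1) == 0
    if constant.any():
        oe.mask[idx[constant]] = True
        idx = idx[~constant]
        sub = oe.values[np.ix_(idx, idx)]
    if len(idx) < 3:
        raise DegenerateChromosomeError(
            f"{oe.chrom}: only {len(idx)} usable bins for the correlation matrix"
        )
    corr = np.corrcoef(sub)
    return CorrelationMatrix(corr, idx, chrom=oe.chrom)


def _deterministic_sign(v: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude loading is positive."""
    j = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[j, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return v * signs


def partial_svd(corr: CorrelationMatrix, k: int = 2) -> PCResult:
    """Leading k singular triplets of the correlation matrix and PC = X @ V.

    Deterministic: a fixed start vector for the iterative solver and a
    largest-loading-positive sign convention.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = corr.values
    m = x.shape[0]
    try:
        if m <= max(5 * k, 200):
            evals, evecs = np.linalg.eigh(x)
        else:
            evals, evecs = scipy.sparse.linalg.eigsh(
                x, k=min(k, m - 1), which="LM", v0=np.ones(m) / np.sqrt(m)
            )
    except (np.linalg.LinAlgError, scipy.sparse.linalg.ArpackError) as exc:
        raise NumericError(f"{corr.chrom}: SVD failed to converge: {exc}") from exc
    order = np.argsort(-np.abs(evals))[:k]
    sing = np.abs(evals[order])
    v = _deterministic_sign(evecs[:, order])
    # for symmetric X the left singular vectors are V up to the eigenvalue sign
    u = v * np.sign(evals[order])
    return PCResult(u, sing, v, x @ v, corr.indices, chrom=corr.chrom)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
        return 0.0
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def select_and_orient(
    pcs: PCResult,
    gc: CovariateTrack,
    gene_density: CovariateTrack,
    n_bins: int | None = None,
) -> np.ndarray:
    """Pick the PC tracking GC/gene density and orient positive = A.

    Among the retained PCs, select the one maximizing |r_GC| + |r_gene|
    (ties: lower index); flip the sign when r_GC < 0 so GC-rich bins score
    positive. Returns a full-length score vector with NaN at masked bins;
    selection metadata is recorded on ``pcs``.
    """
    if n_bins is None:
        n_bins = max(len(gc.values), int(pcs.indices.max()) + 1)
    gc_sub = np.where(gc.mask, np.nan, gc.values)[pcs.indices]
    gd_sub = np.where(gene_density.mask, np.nan, gene_density.values)[pcs.indices]
    if np.nanstd(gc_sub) == 0 and np.nanstd(gd_sub) == 0:
        raise CannotOrientError(
            f"{pcs.chrom}: GC and gene-density covariates are both constant"
        )
    rows = []
    for j in range(pcs.pcs.shape[1]):
        r_gc = _safe_pearson(pcs.pcs[:, j], gc_sub)
        r_gd = _safe_pearson(pcs.pcs[:, j], gd_sub)
        rows.append((j, r_gc, r_gd, abs(r_gc) + abs(r_gd)))
    table = pd.DataFrame(rows, columns=["pc", "r_gc", "r_gene", "score"])
    sel = int(table["score"].idxmax())
    r_gc = table.loc[sel, "r_gc"]
    sign = -1 if r_gc < 0 else 1
    if r_gc == 0:  # degenerate: fall back to the gene-density correlation sign
        sign = -1 if table.loc[sel, "r_gene"] < 0 else 1
    pcs.selected, pcs.sign, pcs.covariate_correlations = sel, sign, table
    scores = np.full(n_bins, np.nan)
    scores[pcs.indices] = sign * pcs.pcs[:, sel]
    return scores


class CompartmentScorer(BaseEstimator):
    """Compartment-score estimator for one chromosome's contact map.

    Parameters
    ----------
    n_components : int
        Number of leading PCs considered for covariate selection.
    min_coverage_frac : float
        Bins whose fraction of nonzero cis contacts is below this are
        masked before the correlation step.
    min_bins : int
        Fewest unmasked bins for which scoring is attempted.

    Attributes (after ``fit``)
    --------------------------
    scores_ : per-bin oriented compartment score, NaN at masked bins
    mask_ : boolean exclusion mask
    pc_result_ : :class:`PCResult` with selection metadata
    selected_component_, orientation_sign_, covariate_correlations_
    """

    def __init__(
        self,
        n_components: int = 2,
        min_coverage_frac: float = 0.01,
        min_bins: int = MIN_BINS_DEFAULT,
    ):
        self.n_components = n_components
        self.min_coverage_frac = min_coverage_frac
        self.min_bins = min_bins

    def fit(self, X, y=None, *, gc: CovariateTrack, gene_density: CovariateTrack):
        cmap = X if isinstance(X, ContactMap) else ContactMap("", np.asarray(X))
        oe = oe_transform(cmap, self.min_coverage_frac)
        corr = correlation_matrix(oe)
        if len(corr.indices) < self.min_bins:
            raise DegenerateChromosomeError(
                f"{cmap.chrom}: {len(corr.indices)} unmasked bins < min_bins={self.min_bins}"
            )
        pcs = partial_svd(corr, k=self.n_components)
        self.scores_ = select_and_orient(pcs, gc, gene_density, n_bins=cmap.n_bins)
        self.mask_ = oe.mask
        self.pc_result_ = pcs
        self.selected_component_ = pcs.selected
        self.orientation_sign_ = pcs.sign
        self.covariate_correlations_ = pcs.covariate_correlations
        return self

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, **fit_params).scores_


def compartment_scores(
    cmap: ContactMap,
    gc: CovariateTrack,
    gene_density: CovariateTrack,
    **params,
) -> np.ndarray:
    """Thin functional wrapper around :class:`CompartmentScorer`."""
    return CompartmentScorer(**params).fit_transform(
        cmap, gc=gc, gene_density=gene_density
    )
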