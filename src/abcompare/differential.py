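"""Differential compartment calling via a weighted Mahalanobis statistic.

Each genomic bin carries a vector of quantile-normalized compartment scores,
one entry per sample. Bins where samples agree sit near the diagonal of that
score space; differential bins sit off it. The statistic is a Mahalanobis
distance with per-bin weighted centers: cross-sample disagreement per bin is
summarized by a distance-derived z-score, mapped through the normal CDF to a
weight w in (0, 1), and the center is shrunk so that high-disagreement bins
deviate more. Covariance comes from the Minimum Covariance Determinant (MCD)
estimator, refined by a two-pass scheme that drops first-pass outliers
before the final covariance fit. Significance is the upper-tail chi-square
probability of the distance, with BH correction — optionally weighted by a
replicate-variability covariate in the spirit of independent hypothesis
weighting (IHW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, NumericError
from .normalize import ScoreMatrix

__all__ = [
    "MDConfig",
    "pairwise_distances",
    "weighted_centers",
    "robust_inverse_covariance",
    "mahalanobis",
    "chi2_pvalues",
    "two_pass_md",
    "replicate_covariate",
    "adjust_pvalues",
    "classify_transitions",
    "DifferentialCompartments",
    "differential_compartments",
]


@dataclass
class MDConfig:
    """Tunables of the Mahalanobis test.

    df: chi-square degrees of freedom; None means the number of samples M.
    outlier_quantile: chi-square quantile for first-pass outlier removal.
    fdr_threshold: adjusted-p cutoff used when flagging significant bins.
    weight_mode: "distant" centers mu_i = s_i (1 - w_i) so that bins distant
        across samples deviate more (the intended behaviour); "verbatim"
        uses mu_i = s_i w_i.
    """

    df: int | None = None
    outlier_quantile: float = 0.90
    fdr_threshold: float = 0.10
    mcd_support_fraction: float | None = 0.9
    weight_mode: str = "distant"
    random_state: int = 0
    n_covariate_groups: int = 5
    n_folds: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.outlier_quantile < 1:
            raise ConfigError("outlier_quantile must be in (0, 1)")
        if self.df is not None and self.df < 1:
            raise ConfigError("df must be >= 1")
        if self.weight_mode not in ("distant", "verbatim"):
            raise ConfigError(f"unknown weight_mode {self.weight_mode!r}")


def pairwise_distances(q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin cross-sample distances, their z-scores, and the weight w.

    For bin i and sample N, d[i, N] = sqrt(sum_t (q[i, t] - q[i, N])^2)/(M-1);
    z standardizes d within each sample across bins; w_i = Phi(max_N z[i, N]).
    A sample whose distances are constant across bins gets z = 0 (w
    contribution 0.5) with a warning.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[1] < 2:
        raise NumericError("need a bins x samples matrix with >= 2 samples")
    m = q.shape[1]
    d = np.empty_like(q)
    for n in range(m):
        d[:, n] = np.sqrt(((q - q[:, [n]]) ** 2).sum(axis=1)) / (m - 1)
    sd = d.std(axis=0)
    mean = d.mean(axis=0)
    z = np.zeros_like(d)
    for n in range(m):
        if sd[n] == 0:
            warnings.warn(f"column {n}: zero spread of cross-sample distances; z set to 0")
        else:
            z[:, n] = (d[:, n] - mean[n]) / sd[n]
    w = stats.norm.cdf(z.max(axis=1))
    return d, z, w


def weighted_centers(q: np.ndarray, w: np.ndarray, mode: str = "distant") -> np.ndarray:
    """Per-bin weighted centers mu_i.

    mode "distant": mu_i = s_i (1 - w_i), so the deviation s_i - mu_i grows
    with the disagreement weight; "verbatim": mu_i = s_i w_i.
    """
    w = np.asarray(w, dtype=float)[:, None]
    return q * w if mode == "verbatim" else q * (1.0 - w)


def robust_inverse_covariance(X: np.ndarray, cfg: MDConfig | None = None) -> np.ndarray:
    """Inverse of the MCD covariance estimate of the columns of X.

    Deterministic for a fixed ``cfg.random_state``. Collinear columns are
    reported by index before the (singular) fit is attempted.
    """
    cfg = cfg or MDConfig()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 5 * p:
        raise NumericError(f"MCD needs >= {5 * p} rows for {p} columns, got {n}")
    corr = np.corrcoef(X, rowvar=False)
    bad = [
        (a, b)
        for a in range(p)
        for b in range(a + 1, p)
        if abs(corr[a, b]) > 1 - 1e-12
    ]
    if bad:
        raise NumericError(f"collinear score columns {bad}: covariance is singular")
    mcd = MinCovDet(
        support_fraction=cfg.mcd_support_fraction, random_state=cfg.random_state
    ).fit(X)
    try:
        return np.linalg.inv(mcd.covariance_)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise NumericError(f"singular MCD covariance: {exc}") from exc


def mahalanobis(s: np.ndarray, mu: np.ndarray, sigma_inv: np.ndarray) -> np.ndarray:
    """Row-wise quadratic form (s_i - mu_i)^T Sigma^-1 (s_i - mu_i)."""
    s = np.asarray(s, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if not (np.isfinite(s).all() and np.isfinite(mu).all() and np.isfinite(sigma_inv).all()):
        raise NumericError("non-finite inputs to the Mahalanobis form")
    dev = np.atleast_2d(s - mu)
    md = np.einsum("ij,jk,ik->i", dev, sigma_inv, dev)
    return np.maximum(md, 0.0)


def chi2_pvalues(md: np.ndarray, df: int) -> np.ndarray:
    """Upper-tail chi-square survival probability of the distances."""
    return stats.chi2.sf(md, df)


def two_pass_md(
    q: np.ndarray, cfg: MDConfig | None = None
) -> dict[str, np.ndarray]:
    """Weighted Mahalanobis distances with two-pass outlier refinement.

    Pass 1 computes distances with MCD covariance on all bins; bins above
    the chi-square ``outlier_quantile`` critical value are removed and the
    covariance refit on the survivors; pass 2 recomputes the distance for
    every bin against the refined covariance, and p-values are the
    chi-square survival probabilities.
    """
    cfg = cfg or MDConfig()
    q = np.asarray(q, dtype=float)
    m = q.shape[1]
    df = cfg.df or m
    d, z, w = pairwise_distances(q)
    mu = weighted_centers(q, w, cfg.weight_mode)
    sigma_inv1 = robust_inverse_covariance(q, cfg)
    md1 = mahalanobis(q, mu, sigma_inv1)
    threshold = stats.chi2.ppf(cfg.outlier_quantile, df)
    keep = md1 <= threshold
    if keep.mean() < 0.5:
        warnings.warn(
            f"first pass removed {100 * (1 - keep.mean()):.1f}% of bins; "
            "null model suspect"
        )
    sigma_inv2 = robust_inverse_covariance(q[keep], cfg)
    md2 = mahalanobis(q, mu, sigma_inv2)
    return {
        "d": d,
        "z": z,
        "w": w,
        "md_pass1": md1,
        "md": md2,
        "p": chi2_pvalues(md2, df),
        "kept": keep,
        "sigma_inv": sigma_inv2,
    }


def replicate_covariate(
    r: np.ndarray, samples: Sequence[str], cfg: MDConfig | None = None
) -> np.ndarray:
    """Replicate-variability Mahalanobis covariate per bin.

    ``r`` holds one column per replicate (all samples pooled, R columns);
    ``samples`` names the sample of each column. Distances are computed only
    among replicates of the same sample; the quadratic form uses the
    diagonal-masked inverse MCD covariance and centers r_i (1 - srw_i), so
    bins with noisy replicates score high.
    """
    cfg = cfg or MDConfig()
    r = np.asarray(r, dtype=float)
    samples = list(samples)
    if r.shape[1] != len(samples):
        raise ConfigError("one sample label per replicate column required")
    counts = pd.Series(samples).value_counts()
    if (counts < 2).any():
        raise ConfigError("replicate covariate requires >= 2 replicates per sample")
    d = np.empty_like(r)
    for sample in counts.index:
        cols = [j for j, s in enumerate(samples) if s == sample]
        sub = r[:, cols]
        rs = len(cols)
        for k, j in enumerate(cols):
            d[:, j] = np.sqrt(((sub - sub[:, [k]]) ** 2).sum(axis=1)) / (rs - 1)
    sd = d.std(axis=0)
    z = np.zeros_like(d)
    for j in range(d.shape[1]):
        if sd[j] == 0:
            warnings.warn(f"replicate column {j}: identical replicates; z set to 0")
        else:
            z[:, j] = (d[:, j] - d[:, j].mean()) / sd[j]
    srw = stats.norm.cdf(z.max(axis=1))
    dev = r - r * (1.0 - srw[:, None])  # = r * srw
    sigma_inv = robust_inverse_covariance(r, cfg)
    diag = np.diag(np.diag(sigma_inv))
    return mahalanobis(r, r - dev, diag)


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def _storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    pi0 = (p > lam).mean() / (1.0 - lam)
    return float(min(max(pi0, 0.05), 1.0))


def adjust_pvalues(
    p: np.ndarray,
    covariate: np.ndarray | None = None,
    cfg: MDConfig | None = None,
) -> np.ndarray:
    """Multiple-testing adjustment: BH, or covariate-weighted BH.

    Without a covariate this is plain Benjamini-Hochberg. With one, bins are
    stratified into covariate quantile groups and per-group weights
    (inverse estimated null proportion, learned by cross-fitting on held-out
    folds, normalized to mean 1) rescale the p-values before BH — an
    approximation of IHW that degenerates to plain BH for an uninformative
    covariate. Adjusted values are floored at the raw p-value.
    """
    cfg = cfg or MDConfig()
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise NumericError("p-values must lie in [0, 1]")
    if covariate is None:
        return _bh(p)
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != p.shape:
        raise NumericError("covariate length must match p-values")
    groups = pd.qcut(
        pd.Series(covariate).rank(method="first"),
        q=cfg.n_covariate_groups,
        labels=False,
        duplicates="drop",
    ).to_numpy()
    if len(np.unique(covariate)) < 2 or len(np.unique(groups)) < 2:
        return _bh(p)
    rng = np.random.default_rng(cfg.random_state)
    fold = rng.permutation(len(p)) % cfg.n_folds
    weights = np.ones(len(p))
    for f in range(cfg.n_folds):
        train = fold != f
        for g in np.unique(groups):
            tr = train & (groups == g)
            if tr.sum() >= 20:
                weights[(fold == f) & (groups == g)] = 1.0 / _storey_pi0(p[tr])
    weights /= weights.mean()  # mean-1 weight budget
    adj = _bh(np.clip(p / weights, 0.0, 1.0))
    return np.maximum(adj, p)


def classify_transitions(
    scores: np.ndarray, sample_names: Sequence[str] | None = None
) -> list[str]:
    """Compartment-transition labels from per-sample scores.

    Two samples: "A->B"/"B->A" on sign change; "sA->wA"/"wA->sA" when both
    positive and the magnitude drops/rises ("sB..." when both negative;
    strong/weak is the relative absolute score). A score of exactly 0 counts
    as A (boundary-inclusive). More samples: the per-sample A/B sign string
    plus the max-|score| sample.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    m = scores.shape[1]
    if sample_names is None:
        sample_names = [f"S{j + 1}" for j in range(m)]
    labels = []
    for row in scores:
        signs = ["A" if v >= 0 else "B" for v in row]
        if m == 2:
            a, b = row
            if signs[0] != signs[1]:
                labels.append(f"{signs[0]}->{signs[1]}")
            elif abs(a) > abs(b):
                labels.append(f"s{signs[0]}->w{signs[1]}")
            elif abs(a) < abs(b):
                labels.append(f"w{signs[0]}->s{signs[1]}")
            else:
                labels.append(f"{signs[0]}->{signs[1]}")
        else:
            top = sample_names[int(np.argmax(np.abs(row)))]
            labels.append(f"{''.join(signs)}(max={top})")
    return labels


class DifferentialCompartments(BaseEstimator):
    """Differential-compartment test over a bins x samples score matrix.

    Parameters mirror :class:`MDConfig`; ``use_ihw`` toggles the
    covariate-weighted adjustment when replicate scores are supplied.

    Attributes (after ``fit``; full-length arrays, NaN/None on masked bins)
    ----------------------------------------------------------------------
    md_ : second-pass Mahalanobis distance
    pvalues_, padj_ : chi-square p-values and adjusted p-values
    weights_ : the per-bin disagreement weight w
    covariate_ : replicate-variability covariate (NaN when unavailable)
    labels_ : transition labels
    significant_ : boolean, padj_ < fdr_threshold
    """

    def __init__(
        self,
        df: int | None = None,
        outlier_quantile: float = 0.90,
        fdr_threshold: float = 0.10,
        mcd_support_fraction: float | None = 0.9,
        weight_mode: str = "distant",
        random_state: int = 0,
        use_ihw: bool = True,
        n_covariate_groups: int = 5,
        n_folds: int = 5,
    ):
        self.df = df
        self.outlier_quantile = outlier_quantile
        self.fdr_threshold = fdr_threshold
        self.mcd_support_fraction = mcd_support_fraction
        self.weight_mode = weight_mode
        self.random_state = random_state
        self.use_ihw = use_ihw
        self.n_covariate_groups = n_covariate_groups
        self.n_folds = n_folds

    def _config(self) -> MDConfig:
        return MDConfig(
            df=self.df,
            outlier_quantile=self.outlier_quantile,
            fdr_threshold=self.fdr_threshold,
            mcd_support_fraction=self.mcd_support_fraction,
            weight_mode=self.weight_mode,
            random_state=self.random_state,
            n_covariate_groups=self.n_covariate_groups,
            n_folds=self.n_folds,
        )

    def fit(
        self,
        X,
        y=None,
        *,
        replicates: np.ndarray | None = None,
        replicate_samples: Sequence[str] | None = None,
        sample_names: Sequence[str] | None = None,
    ):
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        complete = np.isfinite(X).all(axis=1)
        if replicates is not None:
            replicates = np.asarray(replicates, dtype=float)
            complete &= np.isfinite(replicates).all(axis=1)
        idx = np.flatnonzero(complete)
        res = two_pass_md(X[idx], cfg)

        covariate = None
        if replicates is not None and self.use_ihw:
            covariate = replicate_covariate(replicates[idx], replicate_samples, cfg)
        padj = adjust_pvalues(res["p"], covariate, cfg)

        def expand(v, fill=np.nan):
            out = np.full(n, fill)
            out[idx] = v
            return out

        self.mask_ = ~complete
        self.weights_ = expand(res["w"])
        self.md_pass1_ = expand(res["md_pass1"])
        self.md_ = expand(res["md"])
        self.pvalues_ = expand(res["p"])
        self.padj_ = expand(padj)
        self.covariate_ = expand(covariate) if covariate is not None else np.full(n, np.nan)
        self.significant_ = np.where(complete, self.padj_ < cfg.fdr_threshold, False)
        labels = np.full(n, "", dtype=object)
        labels[idx] = classify_transitions(X[idx], sample_names)
        self.labels_ = labels
        return self


def differential_compartments(
    sample_scores: ScoreMatrix,
    replicate_scores: ScoreMatrix | None = None,
    **params,
) -> pd.DataFrame:
    """Run the full differential test on sample-level (averaged) scores.

    ``replicate_scores`` (quantile-normalized, one column per replicate)
    enables the replicate-variability covariate when every sample has at
    least two replicates. Returns the per-bin result table.
    """
    replicates = replicate_samples = None
    if replicate_scores is not None:
        counts = pd.Series(replicate_scores.samples).value_counts()
        if (counts >= 2).all():
            replicates = replicate_scores.values
            replicate_samples = replicate_scores.samples
    est = DifferentialCompartments(**params).fit(
        sample_scores.values,
        replicates=replicates,
        replicate_samples=replicate_samples,
        sample_names=sample_scores.columns,
    )
    out = sample_scores.to_frame()
    out["mahalanobis"] = est.md_
    out["pvalue"] = est.pvalues_
    out["padj"] = est.padj_
    out["replicate_covariate"] = est.covariate_
    out["label"] = est.labels_
    out["significant"] = est.significant_
    return out
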