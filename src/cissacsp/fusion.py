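"""Feature fusion: mutual-information ranking (MIBIF) and PCA reduction.

The time-frequency-spatial feature table has d = 2*M*B*T columns — 96 for
the default configuration — and is highly redundant.  Two fusion routes are
provided:

* MIBIF ranks each column by its estimated mutual information with the
  class label, ``I(F_i; Omega) = H(Omega) - H(Omega | F_i)``, and keeps the
  top k.  The conditional entropy is estimated with class-conditional
  univariate Parzen densities (Gaussian kernel, Silverman bandwidth per
  class subsample) turned into posteriors by Bayes' rule with empirical
  priors, averaged over the training points.
* PCA projects onto the top-k eigenvectors of the (1/(n-1)) sample
  covariance of the mean-centred feature vectors, decorrelating the
  features before classification.

Both are fitted on training rows only; the pipeline applies the fitted
transform to held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.decomposition import PCA

__all__ = [
    "FeatureMatrix",
    "MibifRanking",
    "PcaModel",
    "class_entropy",
    "mibif_scores",
    "mibif_select",
    "pca_fit",
    "pca_transform",
    "pairwise_feature_mi",
]

_LOG2 = np.log(2.0)


@dataclass
class FeatureMatrix:
    """trials x d feature table with a provenance tag per column.

    ``columns[i]`` identifies feature i, e.g. ``(segment, band, rank)``
    for raw pipeline features or ``("pc", i)`` after PCA.
    """

    values: np.ndarray
    labels: np.ndarray
    columns: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got {self.values.ndim}-D")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels length must match the number of rows")
        if not self.columns:
            self.columns = [("f", i) for i in range(self.values.shape[1])]
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("one column tag required per feature column")
        if len(set(map(tuple, (c if isinstance(c, tuple) else (c,) for c in self.columns)))) != len(self.columns):
            raise ValueError("column tags must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class MibifRanking:
    """Per-column mutual information (bits) and the descending-MI order."""

    mi: np.ndarray
    order: np.ndarray
    k: int | None = None


@dataclass
class PcaModel:
    """Mean vector, orthonormal projection (d x k), component variances."""

    mean: np.ndarray
    W: np.ndarray
    variances: np.ndarray

    @property
    def d(self) -> int:
        return self.W.shape[0]

    @property
    def k(self) -> int:
        return self.W.shape[1]


# ---------------------------------------------------------------------------
# entropies and mutual information with the class label
# ---------------------------------------------------------------------------

def class_entropy(labels) -> float:
    """Plug-in base-2 entropy of the empirical label distribution."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule on a subsample; 0 signals a degenerate (constant) input."""
    n = x.size
    if n < 2:
        return 0.0
    sd = x.std(ddof=1)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return float(0.9 * scale * n ** (-0.2))


def _gauss_log_kde(query: np.ndarray, sample: np.ndarray, h: float) -> np.ndarray:
    """Log Parzen density of ``sample`` evaluated at ``query`` points."""
    z = (query[:, None] - sample[None, :]) / h
    logk = -0.5 * z * z - np.log(h * np.sqrt(2 * np.pi))
    return logsumexp(logk, axis=1) - np.log(sample.size)


def _column_label_mi(x: np.ndarray, labels: np.ndarray, bandwidth: float | None) -> float:
    """I(F; Omega) in bits for one feature column via Parzen posteriors."""
    h_omega = class_entropy(labels)
    spread = x.std()
    if spread <= 0:
        return 0.0  # constant feature carries no information
    log_joint = np.empty((x.size, 2))
    for col, label in enumerate((1, 2)):
        xs = x[labels == label]
        prior = xs.size / x.size
        h = bandwidth if bandwidth is not None else _silverman_bandwidth(xs)
        if h <= 0:
            # class subsample constant but feature varies: fall back to a
            # narrow kernel tied to the overall spread
            h = max(1e-3 * spread, 1e-12)
        log_joint[:, col] = np.log(prior) + _gauss_log_kde(x, xs, h)
    log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
    post = np.exp(log_post)
    point_entropy = -(post * log_post).sum(axis=1) / _LOG2
    h_cond = point_entropy.mean()
    return max(0.0, h_omega - h_cond)


def mibif_scores(F: FeatureMatrix, bandwidth: float | None = None) -> MibifRanking:
    """Rank every feature column by mutual information with the label.

    ``bandwidth`` overrides the per-class Silverman kernel width (useful
    for controlled fixtures); ties in MI break by ascending column index.
    """
    labels = F.labels
    present = set(np.unique(labels))
    if present != {1, 2}:
        raise ValueError(f"both classes required, present: {sorted(present)}")
    for label in (1, 2):
        if (labels == label).sum() < 4:
            raise ValueError(f"need >= 4 trials in class {label}")
    mi = np.array(
        [_column_label_mi(F.values[:, i], labels, bandwidth) for i in range(F.d)]
    )
    order = np.argsort(-mi, kind="stable")
    return MibifRanking(mi=mi, order=order)


def mibif_select(ranking: MibifRanking, k: int, F: FeatureMatrix) -> FeatureMatrix:
    """Keep the top-k ranked columns, in ranking order."""
    if not 1 <= k <= F.d:
        raise ValueError(f"k={k} out of range [1, {F.d}]")
    sel = ranking.order[:k]
    return FeatureMatrix(
        values=F.values[:, sel],
        labels=F.labels,
        columns=[F.columns[i] for i in sel],
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_fit(F: FeatureMatrix, k: int) -> PcaModel:
    """Top-k principal axes of the mean-centred feature covariance."""
    n, d = F.n, F.d
    if n < 2:
        raise ValueError("need at least 2 rows to fit PCA")
    if not 1 <= k <= min(d, n - 1):
        raise ValueError(f"k={k} out of range [1, {min(d, n - 1)}]")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(F.values)
    return PcaModel(
        mean=pca.mean_.copy(),
        W=pca.components_.T.copy(),
        variances=pca.explained_variance_.copy(),
    )


def pca_transform(model: PcaModel, F: FeatureMatrix) -> FeatureMatrix:
    """Project ``(values - mean)`` onto the fitted principal axes."""
    if F.d != model.d:
        raise ValueError(f"model fitted for d={model.d}, got d={F.d}")
    projected = (F.values - model.mean) @ model.W
    return FeatureMatrix(
        values=projected,
        labels=F.labels,
        columns=[("pc", i) for i in range(model.k)],
    )


# ---------------------------------------------------------------------------
# feature-feature mutual information diagnostic
# ---------------------------------------------------------------------------

def _kde_entropy_1d(x: np.ndarray, h: float) -> float:
    """Leave-one-out Parzen entropy estimate (bits).

    Excluding the self-term removes the resubstitution bias that would
    otherwise inflate MI = H(X) + H(Y) - H(X, Y) on independent inputs.
    """
    n = x.size
    z = (x[:, None] - x[None, :]) / h
    logk = -0.5 * z * z - np.log(h * np.sqrt(2 * np.pi))
    np.fill_diagonal(logk, -np.inf)
    logp = logsumexp(logk, axis=1) - np.log(n - 1)
    return float(-logp.mean() / _LOG2)


def _kde_entropy_2d(x: np.ndarray, y: np.ndarray, hx: float, hy: float) -> float:
    n = x.size
    zx = (x[:, None] - x[None, :]) / hx
    zy = (y[:, None] - y[None, :]) / hy
    logk = (
        -0.5 * (zx * zx + zy * zy)
        - np.log(hx * np.sqrt(2 * np.pi))
        - np.log(hy * np.sqrt(2 * np.pi))
    )
    np.fill_diagonal(logk, -np.inf)
    logp = logsumexp(logk, axis=1) - np.log(n - 1)
    return float(-logp.mean() / _LOG2)


def pairwise_feature_mi(F: FeatureMatrix, columns=None) -> np.ndarray:
    """Parzen resubstitution estimate of MI between feature pairs (bits).

    ``I(X; Y) = H(X) + H(Y) - H(X, Y)`` with product-Gaussian kernels and
    per-column Silverman bandwidths.  The diagonal applies the same
    estimator to (i, i), so a duplicated column's off-diagonal entry equals
    the diagonal by construction.  Used to visualize redundancy among
    MIBIF-selected versus PCA features.
    """
    cols = list(columns) if columns is not None else list(range(F.d))
    if len(cols) < 2:
        raise ValueError("need at least 2 columns")
    X = F.values[:, cols]
    hs = []
    for i in range(X.shape[1]):
        h = _silverman_bandwidth(X[:, i])
        hs.append(h if h > 0 else max(1e-3 * max(X[:, i].std(), 1.0), 1e-12))
    h1 = [_kde_entropy_1d(X[:, i], hs[i]) for i in range(X.shape[1])]
    m = len(cols)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            hij = _kde_entropy_2d(X[:, i], X[:, j], hs[i], hs[j])
            out[i, j] = out[j, i] = h1[i] + h1[j] - hij
    return out
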