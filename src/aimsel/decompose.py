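"""PCA of dosage matrices and k-means cluster-number selection by BIC.

Missing dosages are mean-imputed per marker before decomposition (the
standard choice for SNP PCA when no reference panel is available). The
cluster scan runs k-means on the leading principal-component scores for each
candidate k and scores the solutions with

    BIC(k) = n * ln(W_k / n) + kappa(k) * ln(n)

where W_k is the total within-cluster sum of squared Euclidean distances and
kappa(k) the parameter count: k under the default convention (one parameter
per cluster, the convention of the DAPC literature's find-clusters
procedure) or k*d under the ``kd`` variant. The best k minimizes BIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class PcaResult:
    scores: np.ndarray            # samples x components
    loadings: np.ndarray          # markers x components
    explained_variance: np.ndarray  # per-component fractions, non-increasing
    centering: np.ndarray         # per-marker means used for imputation/centering
    scaling: np.ndarray | None    # per-marker scale (None when unscaled)
    sample_ids: pd.Index
    marker_ids: pd.Index

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def n_components_for_variance(self, fraction: float) -> int:
        """Smallest number of leading components covering >= ``fraction``."""
        cum = np.cumsum(self.explained_variance)
        if cum[-1] < fraction:
            return self.n_components
        return int(np.searchsorted(cum, fraction) + 1)

    def transform(self, calls: np.ndarray) -> np.ndarray:
        """Project new dosage rows (same marker order) onto the components."""
        x = np.asarray(calls, dtype=float).copy()
        nan = np.isnan(x)
        if nan.any():
            x[nan] = np.broadcast_to(self.centering, x.shape)[nan]
        x = x - self.centering
        if self.scaling is not None:
            x = x / self.scaling
        return x @ self.loadings


def impute_and_center(calls: np.ndarray, scale: bool = False):
    """Mean-impute missing dosages per marker, center, optionally scale."""
    x = np.asarray(calls, dtype=float).copy()
    means = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    means = np.where(np.isnan(means), 0.0, means)  # all-missing marker -> 0
    nan = np.isnan(x)
    if nan.any():
        x[nan] = np.broadcast_to(means, x.shape)[nan]
    x = x - means
    scales = None
    if scale:
        scales = x.std(axis=0, ddof=0)
        scales = np.where(scales == 0, 1.0, scales)
        x = x / scales
    return x, means, scales


def run_pca(gm, scale: bool = False) -> PcaResult:
    """Principal components of the imputed, centered dosage matrix.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive; explained-variance fractions over the full rank
    sum to 1 (a zero-variance matrix yields all-zero scores and fractions).
    """
    if gm.n_samples < 2 or gm.n_snps < 1:
        raise ValueError("PCA needs at least 2 samples and 1 marker")
    x, means, scales = impute_and_center(gm.calls, scale=scale)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    if total > 0:
        explained = s**2 / total
    else:
        explained = np.zeros_like(s)
    scores = u * s
    loadings = vt.T
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance=explained,
        centering=means,
        scaling=scales,
        sample_ids=gm.sample_ids,
        marker_ids=gm.marker_ids,
    )


@dataclass
class ClusterScan:
    """BIC-vs-k curve and the best k-means clustering on PC scores."""

    k_range: tuple[int, int]
    bic: dict[int, float]
    within_ss: dict[int, float]
    best_k: int
    assignment: pd.Series  # sample_id -> cluster index for best_k
    n_pcs_used: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": list(self.bic), "bic": list(self.bic.values()), "within_ss": list(self.within_ss.values())}
        )


def _bic(n: int, d: int, k: int, w: float, penalty: str) -> float:
    kappa = k * d if penalty == "kd" else k
    return n * np.log(max(w, 1e-300) / n) + kappa * np.log(n)


def kmeans_bic_scan(
    pca: PcaResult,
    k_min: int = 1,
    k_max: int = 5,
    n_pcs: int | None = None,
    seed: int = 0,
    n_starts: int = 10,
    penalty: str = "k",
    init: str = "k-means++",
) -> ClusterScan:
    """Scan candidate cluster numbers with k-means and score them by BIC.

    ``n_pcs`` defaults to the number of leading components covering >= 90%
    of the variance. Given (seed, n_starts) the scan is deterministic;
    increasing ``n_starts`` can only lower each W_k.
    """
    n = pca.scores.shape[0]
    if not 1 <= k_min <= k_max <= n:
        raise ValueError(f"need 1 <= k_min <= k_max <= {n}")
    if n_pcs is None:
        n_pcs = pca.n_components_for_variance(0.90)
    n_pcs = int(min(max(n_pcs, 1), pca.n_components))
    x = pca.scores[:, :n_pcs]
    d = n_pcs

    bic: dict[int, float] = {}
    within: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        if k == 1:
            w = float(((x - x.mean(axis=0)) ** 2).sum())
            lab = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_starts, init=init,
                        random_state=int(seed) % (2**31)).fit(x)
            w = float(km.inertia_)
            lab = km.labels_
        within[k] = w
        bic[k] = _bic(n, d, k, w, penalty)
        labels[k] = lab
    best_k = min(bic, key=lambda k: (bic[k], k))
    return ClusterScan(
        k_range=(k_min, k_max),
        bic=bic,
        within_ss=within,
        best_k=best_k,
        assignment=pd.Series(labels[best_k], index=pca.sample_ids, name="cluster"),
        n_pcs_used=n_pcs,
        seed=int(seed),
    )
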