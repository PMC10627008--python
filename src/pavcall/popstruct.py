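"""Population-structure assessment: distances, pool clustering, PCA.

Two-pool hybrid-breeding populations separate cleanly on raw genotype
dosages, so distances are computed on the unstandardized numeric coding.
The ordination entry point accepts either the data matrix (classical PCA
of the column-centered data) or a Euclidean distance matrix (classical
multidimensional scaling via double-centering); for Euclidean distances
the two coincide up to sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .containers import PavcallError


@dataclass
class PoolAssignment:
    """Sample -> pool label (``A``/``B``) with the marker set it came from."""

    sample_ids: np.ndarray
    labels: np.ndarray  # strings "A"/"B"
    marker_set: str = "snp"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.sample_ids) != len(self.labels):
            raise PavcallError("sample_ids and labels differ in length")
        if len(set(self.labels)) > 2:
            raise PavcallError("more than two pool labels")

    def as_bool(self) -> np.ndarray:
        """True where the label equals the lexicographically larger level."""
        levels = sorted(set(self.labels))
        return self.labels == levels[-1]


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained, dtype=float)
        if (np.diff(ve) > 1e-9).any():
            raise PavcallError("variance_explained must be non-increasing")


def euclidean_distance(m: np.ndarray) -> np.ndarray:
    """Symmetric pairwise Euclidean distance matrix between rows of *m*."""
    m = np.asarray(m, dtype=float)
    if np.isnan(m).any():
        raise PavcallError("distance input contains missing values")
    return squareform(pdist(m, metric="euclidean"))


def kmeans_pools(
    m: np.ndarray,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 25,
    marker_set: str = "snp",
    sample_ids=None,
) -> PoolAssignment:
    """Cluster samples into *k* pools with seeded k-means++ (best of restarts).

    Cluster 0/1 are relabelled ``A``/``B`` with ``A`` the cluster containing
    the first sample, so labels are stable across runs of the same seed.
    """
    m = np.asarray(m, dtype=float)
    if len(np.unique(m, axis=0)) < k:
        raise PavcallError(f"fewer than {k} distinct genotype rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(m)
    first = raw[0]
    labels = np.where(raw == first, "A", "B").astype(object)
    if sample_ids is None:
        sample_ids = np.arange(m.shape[0]).astype(str)
    return PoolAssignment(np.asarray(sample_ids, dtype=object), labels, marker_set)


def pca(m: np.ndarray, ncomp: int = 2) -> PCAResult:
    """Classical PCA of the column-centered data matrix."""
    m = np.asarray(m, dtype=float)
    if m.shape[0] < 2:
        raise PavcallError("need at least 2 samples")
    x = m - m.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    lam = s**2  # n-1 scaling cancels in variance fractions
    total = lam.sum()
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if ncomp > rank:
        import warnings

        warnings.warn(f"ncomp={ncomp} exceeds rank {rank}; truncating", stacklevel=2)
        ncomp = rank
    scores = u[:, :ncomp] * s[:ncomp]
    return PCAResult(scores, lam[:ncomp] / total if total > 0 else lam[:ncomp])


def pca_from_distance(d: np.ndarray, ncomp: int = 2) -> PCAResult:
    """Classical MDS of a Euclidean distance matrix (double-centering).

    Equivalent to :func:`pca` of the underlying centered data when the
    distances are Euclidean.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    lam, vec = np.linalg.eigh(b)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    pos = lam > max(lam[0], 0) * 1e-12
    lam_pos = lam[pos]
    if ncomp > pos.sum():
        import warnings

        warnings.warn(f"ncomp={ncomp} exceeds rank {int(pos.sum())}; truncating", stacklevel=2)
        ncomp = int(pos.sum())
    scores = vec[:, :ncomp] * np.sqrt(lam[:ncomp])
    return PCAResult(scores, lam[:ncomp] / lam_pos.sum())


def label_agreement(a: PoolAssignment, b: PoolAssignment) -> dict:
    """Compare two 2-pool assignments on the same samples.

    Returns confusion counts, the misassignment count under the best of the
    two label matchings, and the adjusted Rand index.
    """
    if set(a.sample_ids) != set(b.sample_ids):
        raise PavcallError("assignments cover different sample sets")
    order = {s: i for i, s in enumerate(a.sample_ids)}
    idx = np.asarray([order[s] for s in b.sample_ids])
    la = a.as_bool()[idx]
    lb = b.as_bool()
    n11 = int((la & lb).sum())
    n10 = int((la & ~lb).sum())
    n01 = int((~la & lb).sum())
    n00 = int((~la & ~lb).sum())
    mis = min(n10 + n01, n11 + n00)  # direct vs swapped matching
    return {
        "confusion": {"both": n11, "a_only": n10, "b_only": n01, "neither": n00},
        "misassigned": mis,
        "ari": float(adjusted_rand_score(la, lb)),
    }
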