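"""Descriptive multivariate layer: PCA and Ward hierarchical clustering
of the genotype matrix, with locus-bootstrap support for tree nodes.

Missing genotypes are mean-imputed per locus (configurable to drop
incomplete loci), the matrix is column-centred (no variance scaling),
and the tree is built from Euclidean distances with Ward's minimum-
variance criterion (squared-distance Lance–Williams update, heights on
the distance scale — the "ward.D2" convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage, leaves_list
from sklearn.decomposition import PCA as _SkPCA

from .genio import GenotypeMatrix


def _imputed(gm_or_array, strategy: str = "mean") -> tuple[np.ndarray, list]:
    """Float dosage matrix with missing handled; drops all-missing loci."""
    if isinstance(gm_or_array, GenotypeMatrix):
        X = gm_or_array.G.astype(float)
        X[gm_or_array.missing_mask] = np.nan
        labels = list(gm_or_array.samples)
    else:
        X = np.asarray(gm_or_array, dtype=float)
        labels = [str(i) for i in range(X.shape[0])]
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing loci")
        X = X[:, ~all_missing]
    if strategy == "drop":
        X = X[:, ~np.isnan(X).any(axis=0)]
    else:
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    return X, labels


@dataclass
class PcaResult:
    samples: list
    scores: np.ndarray  # (n_samples, k)
    explained_fraction: np.ndarray
    loadings: np.ndarray  # (n_loci_used, k), orthonormal columns


def pca(gm, n_components: int = 10, impute: str = "mean") -> PcaResult:
    """PCA of the centred dosage matrix.

    Components carry a deterministic sign: the largest-magnitude loading
    of each component is positive. Explained fractions are of the total
    variance (non-increasing, sum ≤ 1).
    """
    X, labels = _imputed(gm, impute)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 loci")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    model = _SkPCA(n_components=k, svd_solver="full")
    with np.errstate(invalid="ignore"):
        scores = model.fit_transform(X)
    frac = np.nan_to_num(model.explained_variance_ratio_, nan=0.0)
    load = model.components_.T  # (loci, k)
    for j in range(k):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        samples=labels,
        scores=scores,
        explained_fraction=frac,
        loadings=load,
    )


@dataclass
class Dendrogram:
    samples: list
    Z: np.ndarray  # scipy linkage matrix, heights on the distance scale
    support: dict | None = None  # frozenset(leaf ids) -> support in [0,1]

    def leaf_order(self) -> list:
        return [self.samples[i] for i in leaves_list(self.Z)]

    def bipartitions(self) -> list:
        """Leaf-ID set under each internal node (excluding the root)."""
        return _cluster_leafsets(self.Z, len(self.samples))

    def newick(self) -> str:
        """Newick string with bootstrap support as internal node labels."""
        n = len(self.samples)
        sets = {i: frozenset([i]) for i in range(n)}
        name = {i: self.samples[i].replace(" ", "_") for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.Z):
            a, b = int(a), int(b)
            node = n + k
            sets[node] = sets[a] | sets[b]
            sup = ""
            if self.support is not None and k < len(self.Z) - 1:
                sup = f"{self.support.get(sets[node], 0.0):.2f}"
            name[node] = f"({name[a]},{name[b]}){sup}"
        return name[n + len(self.Z) - 1] + ";"


def _cluster_leafsets(Z, n) -> list:
    sets = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, row in enumerate(Z):
        s = sets[int(row[0])] | sets[int(row[1])]
        sets[n + k] = s
        if len(s) < n:  # the root split carries no information
            out.append(s)
    return out


def ward_tree(gm, impute: str = "mean") -> Dendrogram:
    """Ward minimum-variance tree on Euclidean distances of the imputed,
    centred dosage matrix. Scipy's ordering gives deterministic ties."""
    X, labels = _imputed(gm, impute)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    X = X - X.mean(axis=0)
    Z = linkage(X, method="ward")
    return Dendrogram(samples=labels, Z=Z)


def bootstrap_support(gm, B: int = 100, seed: int = 0, impute: str = "mean") -> Dendrogram:
    """Locus-bootstrap node support for the Ward tree.

    Loci are resampled with replacement B times; the support of an
    internal node is the fraction of replicate trees containing the same
    leaf set as a cluster. Returns the observed tree with supports
    attached.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X, labels = _imputed(gm, impute)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    Xc = X - X.mean(axis=0)
    obs = Dendrogram(samples=labels, Z=linkage(Xc, method="ward"))
    target = obs.bipartitions()
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    L = X.shape[1]
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        Xi = X[:, cols]
        Xi = Xi - Xi.mean(axis=0)
        Zb = linkage(Xi, method="ward")
        found = set(_cluster_leafsets(Zb, len(labels)))
        for s in target:
            if s in found:
                counts[s] += 1
    obs.support = {s: c / B for s, c in counts.items()}
    return obs
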