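"""Parenchymal phenotype derivation by hierarchical clustering.

Scans are clustered on their z-scored 26-feature vectors with Ward
linkage and Euclidean distance.  The number of phenotypes K is selected
by Monti-style consensus clustering (resampled co-clustering stability,
delta-area criterion on the consensus CDF).  Dendrograms built per
reconstruction kernel are compared by the entanglement coefficient of
their displayed leaf orders, and phenotypes are transported to an
independent cohort by nearest-centroid mapping in the training cohort's
standardized feature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------------------
# dendrograms


@dataclass
class Dendrogram:
    """Hierarchical tree over scans with a mutable displayed leaf order.

    ``Z`` is the scipy linkage matrix; ``labels`` the scan identifiers;
    ``flips`` records, per merge node, whether its children are swapped
    in the displayed order (used by entanglement untangling).
    Standardization parameters of the feature space are retained so that
    centroids remain comparable across cohorts.
    """

    Z: np.ndarray
    labels: list
    mean: np.ndarray
    sd: np.ndarray
    X: np.ndarray  # standardized features, row-aligned with labels
    linkage_name: str = "ward"
    flips: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.Z.shape[0] != n - 1:
            raise ValueError("linkage must contain n-1 merges")
        if self.flips is None:
            self.flips = np.zeros(n - 1, dtype=bool)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[int]:
        """Displayed leaf indices (left to right) honouring flips."""
        n = self.n_leaves
        order: list[int] = []
        stack: list[int] = [2 * n - 2]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
                continue
            i = node - n
            a, b = int(self.Z[i, 0]), int(self.Z[i, 1])
            if self.flips[i]:
                a, b = b, a
            stack.append(b)
            stack.append(a)
        return order

    def leaf_ranks(self) -> dict:
        """Map label -> displayed rank (0-based)."""
        return {self.labels[leaf]: r for r, leaf in enumerate(self.leaf_order())}

    def copy(self) -> "Dendrogram":
        return Dendrogram(
            Z=self.Z.copy(),
            labels=list(self.labels),
            mean=self.mean.copy(),
            sd=self.sd.copy(),
            X=self.X.copy(),
            linkage_name=self.linkage_name,
            flips=self.flips.copy(),
        )


def hierarchical_cluster(
    features: pd.DataFrame | np.ndarray,
    labels: list | None = None,
    method: str = "ward",
) -> Dendrogram:
    """Ward-linkage dendrogram on z-scored features.

    Zero-variance features are excluded from the distance with a warning
    (they carry no between-scan information and would divide by zero).
    """
    if isinstance(features, pd.DataFrame):
        from .harmonization import feature_columns

        cols = feature_columns(features) or list(features.columns)
        X = features[cols].to_numpy(float)
        if labels is None:
            labels = (
                features["scan_id"].tolist() if "scan_id" in features.columns else list(features.index)
            )
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            labels = list(range(X.shape[0]))
    if X.shape[0] < 3:
        raise ValueError("hierarchical clustering requires >= 3 scans")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance feature(s) from clustering")
    sd_safe = np.where(keep, sd, 1.0)
    Xs = (X - mean) / sd_safe
    Z = linkage(pdist(Xs[:, keep]), method=method)
    return Dendrogram(Z=Z, labels=list(labels), mean=mean, sd=sd_safe, X=Xs, linkage_name=method)


def _order_cluster_labels(X: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..K by descending size, ties by ascending centroid norm."""
    ids = np.unique(raw)
    stats = []
    for cid in ids:
        sel = raw == cid
        stats.append((-int(sel.sum()), float(np.linalg.norm(X[sel].mean(axis=0))), cid))
    stats.sort()
    mapping = {cid: k + 1 for k, (_, _, cid) in enumerate(stats)}
    return np.array([mapping[c] for c in raw], dtype=int)


def cut_clusters(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cut the tree into exactly k groups; labels 1..k by descending size."""
    n = dendrogram.n_leaves
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    raw = fcluster(dendrogram.Z, t=k, criterion="maxclust")
    return _order_cluster_labels(dendrogram.X, raw)


# ---------------------------------------------------------------------------
# entanglement


@dataclass
class EntanglementResult:
    coefficient: float
    norm_exponent: float
    untangle_method: str

    def __post_init__(self) -> None:
        if not 0 <= self.coefficient <= 1:
            raise ValueError("entanglement coefficient must lie in [0, 1]")


def _entanglement_coefficient(ranks_a: dict, ranks_b: dict, L: float) -> float:
    labels = list(ranks_a)
    x = np.array([ranks_a[l] for l in labels], dtype=float)
    y = np.array([ranks_b[l] for l in labels], dtype=float)
    n = len(labels)
    num = np.sum(np.abs(x - y) ** L)
    i = np.arange(n, dtype=float)
    denom = np.sum(np.abs(i - i[::-1]) ** L)  # reversal attains the maximum
    if denom == 0:
        return 0.0
    return float(num / denom)


def _untangle_step2side(dend_a: Dendrogram, dend_b: Dendrogram, L: float, max_passes: int = 10) -> None:
    """Greedy two-sided subtree rotation minimizing the coefficient in place."""
    for _ in range(max_passes):
        improved = False
        for dend, other in ((dend_a, dend_b), (dend_b, dend_a)):
            other_ranks = other.leaf_ranks()
            current = _entanglement_coefficient(dend.leaf_ranks(), other_ranks, L)
            for i in range(len(dend.flips)):
                dend.flips[i] = ~dend.flips[i]
                trial = _entanglement_coefficient(dend.leaf_ranks(), other_ranks, L)
                if trial < current - 1e-15:
                    current = trial
                    improved = True
                else:
                    dend.flips[i] = ~dend.flips[i]
        if not improved:
            break


def entanglement(
    dend_a: Dendrogram,
    dend_b: Dendrogram,
    L: float = 1.5,
    untangle: str = "step2side",
) -> EntanglementResult:
    """Entanglement in [0, 1] between two dendrograms on the same scans.

    With x_i, y_i the displayed leaf ranks of scan i in each tree, the
    coefficient is ``sum |x_i - y_i|^L`` normalized by its maximum over
    permutation pairings (attained by the order reversal); 0 means the
    displayed orders coincide, 1 full entanglement.  ``untangle`` may be
    "step2side" (greedy two-sided subtree rotations minimizing the
    coefficient before measuring) or "none".
    """
    set_a, set_b = set(dend_a.labels), set(dend_b.labels)
    if set_a != set_b:
        raise ValueError(
            f"dendrograms have different leaf sets; only in a: {sorted(set_a - set_b)}, "
            f"only in b: {sorted(set_b - set_a)}"
        )
    if untangle not in ("step2side", "none"):
        raise ValueError(f"unknown untangle method {untangle!r}")
    a, b = dend_a.copy(), dend_b.copy()
    if untangle == "step2side":
        # the greedy pass order matters; run both orders and keep the
        # better alignment so the coefficient stays symmetric in (a, b)
        _untangle_step2side(a, b, L)
        c1 = _entanglement_coefficient(a.leaf_ranks(), b.leaf_ranks(), L)
        a2, b2 = dend_b.copy(), dend_a.copy()
        _untangle_step2side(a2, b2, L)
        c2 = _entanglement_coefficient(a2.leaf_ranks(), b2.leaf_ranks(), L)
        coeff = min(c1, c2)
    else:
        coeff = _entanglement_coefficient(a.leaf_ranks(), b.leaf_ranks(), L)
    return EntanglementResult(coefficient=coeff, norm_exponent=L, untangle_method=untangle)


# ---------------------------------------------------------------------------
# consensus clustering


@dataclass
class ConsensusResult:
    consensus_matrices: dict[int, np.ndarray]
    areas: dict[int, float]
    deltas: dict[int, float]
    selected_k: int
    n_resamples: int
    subsample_frac: float
    seed: int | None


class ConsensusClusterer(ClusterMixin, BaseEstimator):
    """Monti consensus clustering with hierarchical inner clustering.

    For each resample, a fraction of scans is drawn without replacement
    and Ward-clustered; the tree is cut at every scanned K and pairwise
    co-clustering is accumulated.  The consensus matrix entry (i, j) is
    the fraction of co-samples in which i and j co-clustered.  K is
    selected by the delta-area criterion on the consensus CDF: the area
    under the empirical CDF of consensus entries (computed exactly as
    ``1 - mean(entries)``), with K = 2 scored by its raw area and K > 2
    by the relative area increase; the argmax is selected.

    Parameters
    ----------
    k_range : iterable of int
        Candidate cluster counts (default 2..6).
    n_resamples : int
    subsample_frac : float
    random_state : int or None
    """

    def __init__(
        self,
        k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
        n_resamples: int = 250,
        subsample_frac: float = 0.8,
        random_state: int | None = None,
        linkage_method: str = "ward",
    ) -> None:
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.subsample_frac = subsample_frac
        self.random_state = random_state
        self.linkage_method = linkage_method

    def fit(self, X: np.ndarray, y=None) -> "ConsensusClusterer":
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        ks = sorted(int(k) for k in self.k_range)
        if self.n_resamples < 50:
            raise ValueError("n_resamples must be >= 50 for stable consensus")
        if ks[0] < 2 or ks[-1] > n - 1:
            raise ValueError(f"k_range must lie within [2, {n - 1}]")
        rng = np.random.default_rng(self.random_state)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - mean) / sd
        m = max(2, int(round(self.subsample_frac * n)))
        co_cluster = {k: np.zeros((n, n)) for k in ks}
        co_sample = np.zeros((n, n))
        for _ in range(self.n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            idx.sort()
            co_sample[np.ix_(idx, idx)] += 1
            Z = linkage(pdist(Xs[idx]), method=self.linkage_method)
            for k in ks:
                lab = fcluster(Z, t=k, criterion="maxclust")
                same = lab[:, None] == lab[None, :]
                co_cluster[k][np.ix_(idx, idx)] += same
        if np.any(co_sample[np.triu_indices(n, 1)] == 0):
            warnings.warn(
                "some scan pairs were never co-sampled; their consensus is set to 0 "
                "(raise subsample_frac or n_resamples)"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = {
                k: np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), 0.0)
                for k in ks
            }
        for k in ks:
            np.fill_diagonal(consensus[k], 1.0)
        iu = np.triu_indices(n, 1)
        areas = {k: float(1.0 - consensus[k][iu].mean()) for k in ks}
        deltas: dict[int, float] = {}
        for j, k in enumerate(ks):
            if j == 0:
                deltas[k] = areas[k]
            else:
                prev = areas[ks[j - 1]]
                deltas[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
        selected = max(ks, key=lambda k: deltas[k])
        self.consensus_matrices_ = consensus
        self.areas_ = areas
        self.deltas_ = deltas
        self.selected_k_ = int(selected)
        dend = hierarchical_cluster(X)
        self.labels_ = cut_clusters(dend, self.selected_k_)
        return self

    def result(self) -> ConsensusResult:
        check_is_fitted(self, "selected_k_")
        return ConsensusResult(
            consensus_matrices=self.consensus_matrices_,
            areas=self.areas_,
            deltas=self.deltas_,
            selected_k=self.selected_k_,
            n_resamples=self.n_resamples,
            subsample_frac=self.subsample_frac,
            seed=self.random_state,
        )


def consensus_select_k(
    features: pd.DataFrame | np.ndarray,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_resamples: int = 250,
    subsample_frac: float = 0.8,
    seed: int | None = None,
) -> ConsensusResult:
    """Functional wrapper over :class:`ConsensusClusterer`."""
    if isinstance(features, pd.DataFrame):
        from .harmonization import feature_columns

        features = features[feature_columns(features) or list(features.columns)].to_numpy(float)
    cc = ConsensusClusterer(
        k_range=k_range,
        n_resamples=n_resamples,
        subsample_frac=subsample_frac,
        random_state=seed,
    )
    cc.fit(features)
    return cc.result()


# ---------------------------------------------------------------------------
# centroid model and mapping


class CentroidClusterMapper(BaseEstimator):
    """Nearest-centroid transport of learned phenotypes to a new cohort.

    ``fit`` standardizes the training features (storing mean/SD), computes
    per-cluster centroids in that space and renumbers clusters 1..K by
    descending size (ties by ascending centroid norm).  ``predict``
    standardizes new scans with the *training* parameters and assigns
    each to the Euclidean-nearest centroid, ties to the lower label.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CentroidClusterMapper":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and assignments must align")
        for cid in np.unique(y):
            if (y == cid).sum() == 0:  # pragma: no cover — unique() precludes this
                raise ValueError(f"empty cluster {cid}")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.mean_) / self.sd_
        ordered = _order_cluster_labels(Xs, y)
        ids = np.unique(ordered)
        self.classes_ = ids
        self.centroids_ = np.vstack([Xs[ordered == cid].mean(axis=0) for cid in ids])
        self.labels_ = ordered
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "centroids_")
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))
            raise ValueError(f"non-finite feature value at (scan, feature) {bad[0].tolist()}")
        Xs = (X - self.mean_) / self.sd_
        d = np.linalg.norm(Xs[:, None, :] - self.centroids_[None, :, :], axis=2)
        # argmin takes the first minimum → ties resolve to the lower label
        return self.classes_[np.argmin(d, axis=1)]


def fit_centroids(features: np.ndarray | pd.DataFrame, assignments: np.ndarray) -> CentroidClusterMapper:
    if isinstance(features, pd.DataFrame):
        from .harmonization import feature_columns

        features = features[feature_columns(features) or list(features.columns)].to_numpy(float)
    return CentroidClusterMapper().fit(features, assignments)


def map_clusters(model: CentroidClusterMapper, new_features: np.ndarray | pd.DataFrame) -> np.ndarray:
    if isinstance(new_features, pd.DataFrame):
        from .harmonization import feature_columns

        new_features = new_features[
            feature_columns(new_features) or list(new_features.columns)
        ].to_numpy(float)
    return model.predict(new_features)


def cluster_separation_pvalue(
    X: np.ndarray,
    labels: np.ndarray,
    n_simulations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation-style significance of a clustering's separation.

    The statistic is the between/within sum-of-squares ratio; the null
    reference is the same statistic on Gaussian data matched to the
    pooled mean/variance with the same label partition.  This is an
    interpretive check of cluster separation, not a canonical test.
    Returns (statistic, p).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)

    def stat(M: np.ndarray) -> float:
        grand = M.mean(axis=0)
        between = 0.0
        within = 0.0
        for cid in np.unique(labels):
            sub = M[labels == cid]
            c = sub.mean(axis=0)
            between += len(sub) * np.sum((c - grand) ** 2)
            within += np.sum((sub - c) ** 2)
        return between / within if within > 0 else np.inf

    obs = stat(X)
    rng = np.random.default_rng(seed)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    count = 0
    for _ in range(n_simulations):
        sim = rng.normal(mu, sd, size=X.shape)
        if stat(sim) >= obs:
            count += 1
    return obs, (1 + count) / (1 + n_simulations)
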