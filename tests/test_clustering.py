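"""Clustering, consensus-K, entanglement and centroid-mapping tests."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import rand_score

from lungphen.clustering import (
    CentroidClusterMapper,
    ConsensusClusterer,
    cluster_separation_pvalue,
    consensus_select_k,
    cut_clusters,
    entanglement,
    fit_centroids,
    hierarchical_cluster,
    map_clusters,
)
from lungphen.synthetic import generate_feature_table

SHIFT8 = np.zeros(26)
SHIFT8[:8] = 4.0


# ---------------------------------------------------------------------------
# Ward linkage against a brute-force Lance-Williams oracle


def ward_oracle_heights(X: np.ndarray) -> list[float]:
    """Exhaustive O(n^3) agglomeration with the Ward Lance-Williams update."""
    n = X.shape[0]
    d = {(i, j): float(np.linalg.norm(X[i] - X[j])) for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        (a, b), dist = min(
            ((p, v) for p, v in d.items() if p[0] in active and p[1] in active),
            key=lambda kv: kv[1],
        )
        heights.append(dist)
        sa, sb = size[a], size[b]
        for c in active - {a, b}:
            dac = d[tuple(sorted((a, c)))]
            dbc = d[tuple(sorted((b, c)))]
            dab = dist
            sc = size[c]
            s = sa + sb + sc
            new = np.sqrt(
                ((sa + sc) * dac**2 + (sb + sc) * dbc**2 - sc * dab**2) / s
            )
            d[tuple(sorted((next_id, c)))] = float(new)
        size[next_id] = sa + sb
        active -= {a, b}
        active.add(next_id)
        next_id += 1
    return heights


@pytest.mark.parametrize("n", [4, 5, 6, 7])
def test_ward_heights_match_bruteforce_oracle(n):
    rng = np.random.default_rng(n)
    for rep in range(12):
        X = rng.standard_normal((n, 5))
        dend = hierarchical_cluster(X)
        ours = sorted(dend.Z[:, 2].tolist())
        # the oracle works on the same standardized coordinates
        ref = sorted(ward_oracle_heights(dend.X))
        np.testing.assert_allclose(ours, ref, atol=1e-10)


def test_coincident_pair_merges_first():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
    dend = hierarchical_cluster(X)
    assert dend.Z[0, 2] == 0.0
    assert {int(dend.Z[0, 0]), int(dend.Z[0, 1])} == {0, 1}


def test_row_permutation_preserves_topology():
    rng = np.random.default_rng(17)
    X = rng.standard_normal((10, 26))
    labels = [f"s{i}" for i in range(10)]
    d1 = hierarchical_cluster(X, labels)
    perm = rng.permutation(10)
    d2 = hierarchical_cluster(X[perm], [labels[i] for i in perm])
    for k in (2, 3, 4):
        a1 = dict(zip(d1.labels, cut_clusters(d1, k)))
        a2 = dict(zip(d2.labels, cut_clusters(d2, k)))
        v1 = [a1[l] for l in labels]
        v2 = [a2[l] for l in labels]
        assert rand_score(v1, v2) == 1.0


def test_zero_variance_feature_warns_and_proceeds():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((8, 5))
    X[:, 2] = 3.0
    with pytest.warns(UserWarning, match="zero-variance"):
        hierarchical_cluster(X)


# ---------------------------------------------------------------------------
# cutting and label conventions


def test_cut_full_and_errors():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((6, 4))
    dend = hierarchical_cluster(X)
    assert len(set(cut_clusters(dend, 6))) == 6
    with pytest.raises(ValueError):
        cut_clusters(dend, 7)


def test_cut_two_blobs_matches_truth():
    df = generate_feature_table(60, cluster_shift=SHIFT8, seed=31)
    dend = hierarchical_cluster(df)
    assign = cut_clusters(dend, 2)
    assert rand_score(df["population"].to_numpy(), assign) == 1.0


def test_labels_ordered_by_descending_size():
    df = generate_feature_table(60, cluster_shift=SHIFT8, seed=31, cluster_fraction=0.25)
    dend = hierarchical_cluster(df)
    assign = cut_clusters(dend, 2)
    sizes = [np.sum(assign == k) for k in (1, 2)]
    assert sizes[0] >= sizes[1]


# ---------------------------------------------------------------------------
# entanglement


def test_entanglement_identical_dendrograms_zero():
    df = generate_feature_table(20, cluster_shift=SHIFT8, seed=8)
    d1 = hierarchical_cluster(df)
    assert entanglement(d1, d1.copy(), untangle="none").coefficient == 0.0


def test_entanglement_reversal_attains_maximum():
    """Reversing the displayed order hits the permutation-pair maximum.

    Brute force over all pairings confirms the reversal is the worst case
    for the L = 1.5 norm at n = 6.
    """
    n = 6
    ranks = np.arange(n, dtype=float)
    L = 1.5
    worst = max(
        sum(abs(i - p[i]) ** L for i in range(n)) for p in itertools.permutations(range(n))
    )
    assert np.isclose(worst, sum(abs(ranks - ranks[::-1]) ** L))
    # a ladder dendrogram whose display is reversed by flipping every merge
    X = np.array([[float(2**i)] for i in range(n)])
    d1 = hierarchical_cluster(X)
    d2 = d1.copy()
    d2.flips[:] = True
    order1 = d1.leaf_order()
    order2 = d2.leaf_order()
    assert order2 == order1[::-1]
    assert np.isclose(entanglement(d1, d2, untangle="none").coefficient, 1.0)


def test_entanglement_symmetry_and_bounds_property():
    rng = np.random.default_rng(99)
    for _ in range(100):
        n = int(rng.integers(5, 15))
        a = hierarchical_cluster(rng.standard_normal((n, 6)))
        b = hierarchical_cluster(rng.standard_normal((n, 6)))
        b.labels = list(a.labels)
        e_ab = entanglement(a, b, untangle="none").coefficient
        e_ba = entanglement(b, a, untangle="none").coefficient
        assert 0.0 <= e_ab <= 1.0
        assert abs(e_ab - e_ba) < 1e-12


def test_entanglement_untangle_never_increases():
    rng = np.random.default_rng(7)
    for _ in range(10):
        a = hierarchical_cluster(rng.standard_normal((12, 6)))
        b = hierarchical_cluster(rng.standard_normal((12, 6)))
        b.labels = list(a.labels)
        raw = entanglement(a, b, untangle="none").coefficient
        opt = entanglement(a, b, untangle="step2side").coefficient
        assert opt <= raw + 1e-12


def test_entanglement_mismatched_leaves_rejected():
    rng = np.random.default_rng(4)
    a = hierarchical_cluster(rng.standard_normal((5, 3)), labels=list("abcde"))
    b = hierarchical_cluster(rng.standard_normal((5, 3)), labels=list("abcdf"))
    with pytest.raises(ValueError, match="leaf sets"):
        entanglement(a, b)


# ---------------------------------------------------------------------------
# consensus clustering


def test_consensus_selects_two_for_two_populations():
    df = generate_feature_table(120, cluster_shift=SHIFT8, seed=55)
    res = consensus_select_k(df, seed=55)
    assert res.selected_k == 2
    for M in res.consensus_matrices.values():
        assert np.all(M >= 0) and np.all(M <= 1)
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)


def test_consensus_duplicate_points_always_cocluster():
    rng = np.random.default_rng(12)
    half = rng.standard_normal((20, 26))
    X = np.vstack([half, half])  # scan i and i+20 are exact duplicates
    cc = ConsensusClusterer(k_range=(2, 3, 4), n_resamples=60, random_state=0).fit(X)
    for k, M in cc.consensus_matrices_.items():
        for i in range(20):
            # exact duplicates co-cluster whenever co-sampled
            assert M[i, i + 20] in (0.0, 1.0) or M[i, i + 20] == pytest.approx(1.0)


def test_consensus_seeded_determinism():
    df = generate_feature_table(60, cluster_shift=SHIFT8, seed=2)
    r1 = consensus_select_k(df, n_resamples=60, seed=3)
    r2 = consensus_select_k(df, n_resamples=60, seed=3)
    assert r1.selected_k == r2.selected_k
    for k in r1.consensus_matrices:
        np.testing.assert_array_equal(r1.consensus_matrices[k], r2.consensus_matrices[k])


def test_consensus_validation():
    df = generate_feature_table(30, seed=1)
    with pytest.raises(ValueError):
        consensus_select_k(df, n_resamples=10)
    with pytest.raises(ValueError):
        consensus_select_k(df, k_range=(1, 2))


# ---------------------------------------------------------------------------
# centroids and mapping


def test_centroid_examples():
    X = np.array([[1.0, 0.0], [3.0, 0.0], [0.0, 5.0]])
    y = np.array([1, 1, 2])
    m = CentroidClusterMapper().fit(X, y)
    # de-standardized centroids equal raw-space means
    raw = m.centroids_ * m.sd_ + m.mean_
    np.testing.assert_allclose(sorted(raw[:, 0].tolist()), sorted([2.0, 0.0]), atol=1e-10)
    single = CentroidClusterMapper().fit(np.array([[1.0, 2.0], [5.0, 6.0]]), np.array([1, 2]))
    destd = single.centroids_ * single.sd_ + single.mean_
    np.testing.assert_allclose(sorted(map(tuple, destd)), [(1.0, 2.0), (5.0, 6.0)], atol=1e-10)


def test_map_point_at_centroid_and_tie_break():
    X = np.vstack([np.zeros((3, 2)), np.ones((3, 2)) * 4])
    y = np.array([1, 1, 1, 2, 2, 2])
    m = CentroidClusterMapper().fit(X, y)
    at_c2 = (np.ones(2) * 4)[None, :]
    assert m.predict(at_c2)[0] == m.classes_[np.argmin(np.linalg.norm(m.centroids_ - ((at_c2 - m.mean_) / m.sd_), axis=1))]
    midpoint = (np.ones(2) * 2)[None, :]
    assert m.predict(midpoint)[0] == 1  # exact tie -> lower label


def test_map_nonfinite_rejected():
    m = CentroidClusterMapper().fit(np.eye(3), np.array([1, 1, 2]))
    with pytest.raises(ValueError, match="non-finite"):
        m.predict(np.array([[np.nan, 0.0, 0.0]]))


def test_mapping_reproduces_training_assignments():
    df = generate_feature_table(100, cluster_shift=SHIFT8, seed=77)
    dend = hierarchical_cluster(df)
    assign = cut_clusters(dend, 2)
    model = fit_centroids(df, assign)
    mapped = map_clusters(model, df)
    assert rand_score(assign, mapped) >= 0.95


def test_separation_pvalue_detects_structure():
    df = generate_feature_table(60, cluster_shift=SHIFT8, seed=5)
    X = df[[c for c in df.columns if c.startswith(("hist", "glcm", "glrlm"))]].to_numpy()
    dend = hierarchical_cluster(X)
    assign = cut_clusters(dend, 2)
    stat, p = cluster_separation_pvalue(X, assign, n_simulations=199, seed=1)
    assert p < 0.05
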