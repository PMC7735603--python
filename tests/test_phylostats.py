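"""Phylogenetic signal, PGLS, bgPCA, distances, ancestral states, hulls."""
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from molarmap import (
    ComputationError,
    InputError,
    ancestral_states,
    between_group_pca,
    hull_coverage,
    k_mult,
    k_permutation_test,
    mantel_test,
    pgls_categorical,
    phenetic_distance_matrix,
    phylo_covariance,
    pseudo_genetic_distance,
    wt_disparity_correlation,
)
from molarmap.synthetic import random_coalescent_tree, simulate_bm_traits


# ---------------------------------------------------------------------------
# BM covariance
# ---------------------------------------------------------------------------


def test_covariance_two_independent_tips():
    C, labels = phylo_covariance("(A:1,B:1);")
    assert labels == ["A", "B"]
    assert np.allclose(C, np.eye(2))


def test_covariance_three_tip_path_arithmetic():
    C, labels = phylo_covariance("((A:1,B:1):1,C:2);")
    expect = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 2]])
    assert labels == ["A", "B", "C"]
    assert np.allclose(C, expect)


def test_covariance_ultrametric_constant_diagonal():
    tree = random_coalescent_tree(10, seed=1)
    C, _ = phylo_covariance(tree)
    assert np.ptp(np.diag(C)) < 1e-9
    eigmin = np.linalg.eigvalsh(C).min()
    assert eigmin > -1e-10


# ---------------------------------------------------------------------------
# multivariate K
# ---------------------------------------------------------------------------


def test_k_equals_one_on_star_tree():
    rng = np.random.default_rng(0)
    C = 3.0 * np.eye(12)
    for _ in range(5):
        X = rng.standard_normal((12, 7))
        assert k_mult(X, C) == pytest.approx(1.0, abs=1e-10)


def _univariate_blomberg_k(x, C):
    """Independent direct implementation (explicit inverses, scalars)."""
    N = len(x)
    Ci = np.linalg.inv(C)
    ones = np.ones(N)
    a_hat = (ones @ Ci @ x) / (ones @ Ci @ ones)
    dev = x - a_hat
    mse0 = dev @ dev / (N - 1)
    mse = dev @ Ci @ dev / (N - 1)
    expected = (np.trace(C) - N / (ones @ Ci @ ones)) / (N - 1)
    return (mse0 / mse) / expected


def test_k_matches_univariate_oracle_when_p_is_one():
    tree = random_coalescent_tree(8, seed=11)
    C, _ = phylo_covariance(tree)
    rng = np.random.default_rng(3)
    for _ in range(5):
        x = rng.standard_normal(8)
        assert k_mult(x[:, None], C) == pytest.approx(
            _univariate_blomberg_k(x, C), abs=1e-10
        )


def test_k_matches_r_phytools_phylosig(tmp_path):
    """Cross-check the univariate case against phytools::phylosig."""
    tree = random_coalescent_tree(8, seed=3)
    tree.write(path=str(tmp_path / "t.nwk"), schema="newick")
    X, labels = simulate_bm_traits(tree, 1, seed=5)
    np.savetxt(tmp_path / "x.csv", X, delimiter=",")
    (tmp_path / "labels.txt").write_text("\n".join(labels))
    script = (
        'suppressMessages(library(phytools));'
        f'tr <- read.tree("{tmp_path}/t.nwk");'
        f'x <- scan("{tmp_path}/x.csv");'
        f'names(x) <- readLines("{tmp_path}/labels.txt");'
        'cat(sprintf("%.12f", phylosig(tr, x, method="K")))'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    C, _ = phylo_covariance(tree)
    assert k_mult(X, C) == pytest.approx(float(out.stdout), abs=1e-8)


def test_k_brownian_motion_expectation():
    tree = random_coalescent_tree(15, seed=21)
    C, _ = phylo_covariance(tree)
    ks = [k_mult(simulate_bm_traits(tree, 8, seed=rep)[0], C)
          for rep in range(100)]
    assert 0.9 < np.mean(ks) < 1.1


def test_k_invariant_to_trait_order():
    tree = random_coalescent_tree(9, seed=5)
    C, _ = phylo_covariance(tree)
    X, _ = simulate_bm_traits(tree, 6, seed=9)
    perm = np.random.default_rng(0).permutation(6)
    assert k_mult(X, C) == pytest.approx(k_mult(X[:, perm], C), rel=1e-12)


def test_k_permutation_detects_strong_signal():
    tree = random_coalescent_tree(16, seed=7)
    X, _ = simulate_bm_traits(tree, 20, seed=1)
    C, _ = phylo_covariance(tree)
    _, p = k_permutation_test(X, C, n_perm=199, seed=0)
    assert p <= 0.05


def test_k_permutation_null_calibrated():
    """i.i.d. tip data on a structured tree: rejection near nominal."""
    tree = random_coalescent_tree(10, seed=13)
    C, _ = phylo_covariance(tree)
    rng = np.random.default_rng(0)
    rejections = 0
    n_sims = 200
    for s in range(n_sims):
        X = rng.standard_normal((10, 4))
        _, p = k_permutation_test(X, C, n_perm=99, seed=s)
        rejections += p <= 0.05
    assert abs(rejections / n_sims - 0.05) < 0.04


def test_k_permutation_requires_permutations():
    with pytest.raises(InputError):
        k_permutation_test(np.zeros((4, 2)), np.eye(4), n_perm=0)


# ---------------------------------------------------------------------------
# between-group PCA
# ---------------------------------------------------------------------------


def test_bgpca_collinear_means_are_rank_one():
    rng = np.random.default_rng(1)
    direction = rng.standard_normal(5)
    X = np.stack([t * direction for t in (0.0, 1.0, 2.0)])
    space = between_group_pca(X, ["a", "b", "c"])
    assert space.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)
    assert space.variance_fractions[1] == pytest.approx(0.0, abs=1e-12)


def test_bgpca_identical_means_rejected():
    X = np.tile([1.0, 2.0, 3.0], (4, 1))
    with pytest.raises(ComputationError):
        between_group_pca(X, ["a", "a", "b", "b"])


def test_bgpca_single_group_rejected():
    with pytest.raises(InputError):
        between_group_pca(np.random.default_rng(0).random((4, 3)), ["a"] * 4)


def test_bgpca_scores_preserve_intermean_distances():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((6, 20))
    space = between_group_pca(X, list("abcdef"))
    from scipy.spatial.distance import pdist

    assert np.allclose(pdist(space.scores), pdist(X), atol=1e-9)


def test_bgpca_invariant_to_orthogonal_rotation():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((12, 6))
    groups = list("aabbccddeeff")
    Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
    s1 = between_group_pca(X, groups)
    s2 = between_group_pca(X @ Q, groups)
    assert np.allclose(np.abs(s1.scores), np.abs(s2.scores), atol=1e-8)
    assert np.allclose(s1.variance_fractions, s2.variance_fractions, atol=1e-10)


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------


def test_root_state_two_tips_closed_form():
    ids, st = ancestral_states("(A:2,B:1);", np.array([[0.0], [3.0]]))
    assert st[0, 0] == pytest.approx((0 / 2 + 3 / 1) / (1 / 2 + 1 / 1))


def test_root_state_equal_branches_is_midpoint():
    _, st = ancestral_states("(A:1,B:1);", np.array([[2.0], [6.0]]))
    assert st[0, 0] == pytest.approx(4.0)


def test_constant_tips_reconstruct_exactly():
    tree = random_coalescent_tree(7, seed=2)
    tips = np.full((7, 3), 1.7)
    _, st = ancestral_states(tree, tips)
    assert np.allclose(st, 1.7, atol=1e-10)


def test_ancestral_states_match_numeric_minimizer():
    """Direct minimization of sum (dx)^2 / t over internal states."""
    for seed in range(3):
        tree = random_coalescent_tree(5, seed=seed)
        X, labels = simulate_bm_traits(tree, 2, seed=seed + 50)
        ids, st = ancestral_states(tree, X, tip_order=labels)

        t = tree
        internals = [nd for nd in t.preorder_node_iter() if not nd.is_leaf()]
        leaves = {lf: i for i, lf in enumerate(t.leaf_node_iter())}
        lab2row = {lab: i for i, lab in enumerate(labels)}

        def objective(flat):
            states = {nd: flat[2 * i: 2 * i + 2]
                      for i, nd in enumerate(internals)}
            total = 0.0
            for nd in t.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                child = (states[nd] if nd in states
                         else X[lab2row[nd.taxon.label]])
                diff = child - states[nd.parent_node]
                total += float(diff @ diff) / nd.edge.length
            return total

        res = minimize(objective, np.zeros(2 * len(internals)), method="BFGS",
                       options={"gtol": 1e-12})
        assert np.abs(res.x.reshape(-1, 2) - st).max() < 1e-6


def test_zero_branch_length_rejected():
    with pytest.raises(InputError):
        ancestral_states("(A:0,B:1);", np.array([[0.0], [1.0]]))


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------


def _direct_permutation_manova(Y, labels, n_perm, seed):
    """Ordinary (non-phylogenetic) trace-based permutation MANOVA."""
    labels = np.asarray(labels)
    n = len(labels)
    grand = Y.mean(axis=0)
    sst = float(np.sum((Y - grand) ** 2))

    def ss_model(Ym):
        return sum(
            (labels == g).sum() * float(np.sum((Ym[labels == g].mean(0) - Ym.mean(0)) ** 2))
            for g in np.unique(labels)
        )

    return ss_model(Y) / sst


def test_pgls_identity_tree_reduces_to_manova():
    rng = np.random.default_rng(4)
    Y = rng.standard_normal((18, 4))
    labels = ["x"] * 6 + ["y"] * 6 + ["z"] * 6
    res = pgls_categorical(Y, np.eye(18), labels, n_perm=49, seed=0)
    assert res["R2"] == pytest.approx(
        _direct_permutation_manova(Y, labels, 49, 0), abs=1e-10
    )


def test_pgls_detects_large_category_shifts():
    tree = random_coalescent_tree(16, seed=31)
    C, labels = phylo_covariance(tree)
    cats = ["a", "b", "c", "d"] * 4
    rng = np.random.default_rng(5)
    hits = 0
    for s in range(20):
        noise, _ = simulate_bm_traits(tree, 3, seed=400 + s)
        shift = np.array([{"a": 0, "b": 8, "c": -8, "d": 16}[c] for c in cats])
        Y = noise * 0.2 + shift[:, None]
        if pgls_categorical(Y, C, cats, n_perm=199, seed=s)["p"] <= 0.01:
            hits += 1
    assert hits >= 18


def test_pgls_size_mismatch_rejected():
    with pytest.raises(InputError):
        pgls_categorical(np.zeros((4, 2)), np.eye(4), ["a", "b"])


# ---------------------------------------------------------------------------
# pseudo-genetic distances
# ---------------------------------------------------------------------------


def test_pseudo_genetic_worked_example():
    """One homozygous-null plus one heterozygous-null locus: 1 + 0.5."""
    from_wt, _ = pseudo_genetic_distance({"mut": {"geneA": "loss",
                                                  "geneB": "hetero"}})
    assert from_wt["mut"] == pytest.approx(1.5)


def test_pseudo_genetic_wild_type_and_gain():
    from_wt, pair = pseudo_genetic_distance({
        "WT": {},
        "over": {"geneA": "gain"},
        "null": {"geneA": "loss"},
    })
    assert from_wt["WT"] == 0.0
    assert from_wt["over"] == 1.0  # |2 - 1|
    assert pair.loc["over", "null"] == pytest.approx(2.0)
    assert pair.loc["WT", "null"] == pytest.approx(1.0)


def test_unknown_dosage_class_rejected():
    with pytest.raises(InputError):
        pseudo_genetic_distance({"s": {"g": "duplicated"}})


from hypothesis import given, settings  # noqa: E402
from hypothesis import strategies as st  # noqa: E402

_dosage = st.sampled_from(["loss", "hetero", "normal", "gain"])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.dictionaries(
    st.sampled_from(["s1", "s2", "s3"]),
    st.dictionaries(st.sampled_from(["gA", "gB", "gC"]), _dosage, max_size=3),
    min_size=2, max_size=3,
))
def test_pseudo_genetic_distance_is_a_metric(genotypes):
    """L1 coding distances: symmetric, zero diagonal, triangle inequality,
    and the WT distance equals the pairwise distance to an all-normal row."""
    genotypes = dict(genotypes)
    genotypes["WT"] = {}
    from_wt, pair = pseudo_genetic_distance(genotypes)
    M = pair.to_numpy()
    assert np.allclose(M, M.T)
    assert np.allclose(np.diag(M), 0.0)
    n = len(M)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert M[i, j] <= M[i, k] + M[k, j] + 1e-12
    for s in genotypes:
        assert from_wt[s] == pytest.approx(pair.loc[s, "WT"])


# ---------------------------------------------------------------------------
# Mantel test and disparity correlation
# ---------------------------------------------------------------------------


def _random_distance_matrix(rng, n):
    D = np.abs(rng.standard_normal((n, n)))
    D = D + D.T
    np.fill_diagonal(D, 0.0)
    return D


def test_mantel_perfect_and_affine_correlation():
    rng = np.random.default_rng(6)
    D = _random_distance_matrix(rng, 9)
    r, _ = mantel_test(D, D, n_perm=9, seed=0)
    assert r == pytest.approx(1.0)
    D2 = 2.0 * D + 3.0
    np.fill_diagonal(D2, 0.0)
    r2, _ = mantel_test(D, D2, n_perm=9, seed=0)
    assert r2 == pytest.approx(1.0)


def test_mantel_r_matches_scikit_bio():
    from skbio.stats.distance import mantel as skbio_mantel

    rng = np.random.default_rng(7)
    D1 = _random_distance_matrix(rng, 10)
    D2 = _random_distance_matrix(rng, 10)
    r_ours, _ = mantel_test(D1, D2, n_perm=9, seed=0)
    r_ref = skbio_mantel(D1, D2, permutations=0)[0]
    assert r_ours == pytest.approx(float(r_ref), abs=1e-12)


def test_mantel_rejects_bad_inputs():
    with pytest.raises(InputError):
        mantel_test(np.zeros((3, 3)), np.zeros((4, 4)))
    with pytest.raises(ComputationError):
        D = np.ones((4, 4)) - np.eye(4)
        mantel_test(D, D.copy())


def test_wt_disparity_correlation_recovers_linear_link():
    rng = np.random.default_rng(8)
    g = rng.uniform(0, 3, 20)
    f = 2.0 * g + rng.normal(0, 1e-6, 20)
    r, r2, p = wt_disparity_correlation(g, f)
    assert r == pytest.approx(1.0, abs=1e-6)
    assert r2 == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# phenetic distances and hull coverage
# ---------------------------------------------------------------------------


def _toy_space():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((9, 6))
    return between_group_pca(X, list("abcabcabc"))


def test_phenetic_distance_all_axes_equals_mean_distance():
    space = _toy_space()
    from scipy.spatial.distance import pdist, squareform

    D = phenetic_distance_matrix(space, axes=space.scores.shape[1])
    centred = space.group_means - space.group_means.mean(axis=0)
    assert np.allclose(D.to_numpy(), squareform(pdist(centred)), atol=1e-9)


def test_phenetic_distance_hand_example():
    scores = np.array([[0.0, 0.0], [3.0, 4.0], [0.0, -1.0]])
    space = between_group_pca(
        np.hstack([scores, np.zeros((3, 1))]), ["a", "b", "c"]
    )
    D = phenetic_distance_matrix(space, axes=2)
    centred = scores - scores.mean(axis=0)
    expect = np.linalg.norm(centred[0] - centred[1])
    assert D.iloc[0, 1] == pytest.approx(expect, abs=1e-12)


def test_phenetic_distance_axes_validated():
    with pytest.raises(InputError):
        phenetic_distance_matrix(_toy_space(), axes=0)


def _brute_force_inside(hull_pts, q, tol=1e-9):
    """Orientation test against every hull edge (CCW polygon)."""
    n = len(hull_pts)
    for i in range(n):
        a, b = hull_pts[i], hull_pts[(i + 1) % n]
        cross = (b[0] - a[0]) * (q[1] - a[1]) - (b[1] - a[1]) * (q[0] - a[0])
        if cross < -tol:
            return False
    return True


def test_hull_subset_is_inside():
    rng = np.random.default_rng(10)
    A = rng.standard_normal((12, 2))
    B = A[:5]
    scores = pd.DataFrame(np.vstack([A, B]),
                          index=[f"a{i}" for i in range(12)] + [f"b{i}" for i in range(5)])
    cov = hull_coverage(scores, [f"a{i}" for i in range(12)],
                        [f"b{i}" for i in range(5)])
    assert cov.b_inside_a.all()


def test_hull_translated_set_is_outside():
    rng = np.random.default_rng(11)
    A = rng.standard_normal((8, 2))
    B = rng.standard_normal((8, 2)) + 100.0
    scores = pd.DataFrame(np.vstack([A, B]),
                          index=[f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)])
    cov = hull_coverage(scores, [f"a{i}" for i in range(8)],
                        [f"b{i}" for i in range(8)])
    assert not cov.b_inside_a.any()
    assert not cov.a_inside_b.any()


def test_hull_flags_match_orientation_oracle():
    rng = np.random.default_rng(12)
    for _ in range(5):
        A = rng.standard_normal((20, 2))
        B = rng.standard_normal((20, 2)) * 1.5
        scores = pd.DataFrame(
            np.vstack([A, B]),
            index=[f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)],
        )
        cov = hull_coverage(scores, [f"a{i}" for i in range(20)],
                            [f"b{i}" for i in range(20)])
        for i in range(20):
            assert cov.b_inside_a.iloc[i] == _brute_force_inside(cov.hull_a, B[i])


def test_hull_needs_three_points():
    scores = pd.DataFrame(np.zeros((4, 2)), index=list("abcd"))
    with pytest.raises(InputError):
        hull_coverage(scores, ["a", "b"], ["c", "d"])
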