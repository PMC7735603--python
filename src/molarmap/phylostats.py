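"""Comparative and multivariate statistics.

Implements the downstream toolbox: the Brownian-motion phylogenetic
covariance, the multivariate generalization of Blomberg's K with a
tip-permutation test, between-group PCA, squared-change-parsimony
ancestral states, phylogenetic generalized least squares with a
categorical predictor (residual-randomization significance), the
pseudo-genetic dosage coding and its L1 distances, the Mantel test,
phenetic distance matrices, and convex-hull coverage in morphospace.

Trees are dendropy objects (or Newick strings/paths); trait matrices
are plain numpy arrays with rows ordered as the tip-label list.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform

from .errors import ComputationError, InputError

__all__ = [
    "as_tree",
    "phylo_covariance",
    "k_mult",
    "k_permutation_test",
    "Morphospace",
    "between_group_pca",
    "ancestral_states",
    "pgls_categorical",
    "DOSAGE_CODES",
    "pseudo_genetic_distance",
    "mantel_test",
    "phenetic_distance_matrix",
    "hull_coverage",
    "wt_disparity_correlation",
]

#: per-gene expression dosage codes
DOSAGE_CODES = {"loss": 0.0, "hetero": 0.5, "normal": 1.0, "gain": 2.0}


# ---------------------------------------------------------------------------
# trees and the BM covariance
# ---------------------------------------------------------------------------


def as_tree(tree) -> dendropy.Tree:
    """Coerce a Newick string/path or dendropy Tree to a rooted Tree."""
    if isinstance(tree, dendropy.Tree):
        return tree
    text = str(tree)
    if "(" not in text:  # a path
        return dendropy.Tree.get(path=text, schema="newick")
    return dendropy.Tree.get(data=text, schema="newick")


def tip_labels(tree) -> list:
    return [leaf.taxon.label for leaf in as_tree(tree).leaf_node_iter()]


def phylo_covariance(tree, order=None):
    """Shared-path-length matrix C under Brownian motion.

    ``C[i, j]`` is the path length from the root to the most recent
    common ancestor of tips i and j; the diagonal holds tip depths.

    Returns ``(C, labels)`` with rows ordered as ``order`` when given.
    """
    t = as_tree(tree)
    leaves = list(t.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise InputError("tree tips are not uniquely labeled")

    depth = {}
    for node in t.preorder_node_iter():
        el = node.edge.length
        if el is None:
            el = 0.0
        if el < 0:
            raise InputError("negative branch length in tree")
        depth[node] = (depth[node.parent_node] if node.parent_node else 0.0) + el

    # postorder: set of leaf indices under each node
    n = len(leaves)
    C = np.zeros((n, n))
    leaf_index = {lf: i for i, lf in enumerate(leaves)}
    under = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            under[node] = [leaf_index[node]]
            C[leaf_index[node], leaf_index[node]] = depth[node]
        else:
            groups = [under[ch] for ch in node.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.array(groups[a])
                    ib = np.array(groups[b])
                    C[np.ix_(ia, ib)] = depth[node]
                    C[np.ix_(ib, ia)] = depth[node]
            under[node] = [i for g in groups for i in g]

    if order is not None:
        order = list(order)
        if set(order) != set(labels):
            raise InputError("tip labels do not match the requested order")
        idx = [labels.index(lbl) for lbl in order]
        C = C[np.ix_(idx, idx)]
        labels = order
    return C, labels


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------


def k_mult(X: np.ndarray, C: np.ndarray) -> float:
    """Multivariate Blomberg's K (Adams 2014 generalization).

    With phylogenetic mean ``a = (1' C^-1 1)^-1 1' C^-1 X``, the
    statistic is the ratio of observed to BM-expected
    (Euclidean : phylogenetically-corrected) sum-of-squares ratios:

        K = [tr(E'E) / tr(E' C^-1 E)] /
            [(tr C - N / (1' C^-1 1)) / (N - 1)],   E = X - 1a.

    Equals 1 for any data on a star phylogeny and in expectation under
    Brownian motion; values below 1 mean relatives resemble each other
    less than BM predicts.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != C.shape[0]:
        raise InputError("trait rows must match the covariance dimension")
    N = C.shape[0]
    if N < 3:
        raise InputError("need at least 3 tips")
    try:
        cf = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        raise ComputationError("singular phylogenetic covariance") from exc
    one = np.ones((N, 1))
    Ci1 = cho_solve(cf, one)
    denom_a = float((one.T @ Ci1).item())
    a = (Ci1.T @ X) / denom_a
    E = X - one @ a
    D0 = float(np.sum(E * E))
    D = float(np.sum(E * cho_solve(cf, E)))
    if D <= 0:
        raise ComputationError("degenerate trait matrix (no variation)")
    expected = (np.trace(C) - N / denom_a) / (N - 1)
    return (D0 / D) / expected


def k_permutation_test(X, tree_or_C, n_perm: int = 999, seed: int = 0):
    """Tip-label permutation test for the multivariate K.

    Returns ``(K_obs, p)`` with ``p = (1 + #{K_perm >= K_obs}) /
    (n_perm + 1)``.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    C = tree_or_C if isinstance(tree_or_C, np.ndarray) else phylo_covariance(tree_or_C)[0]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k_obs = k_mult(X, C)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[0])
        if k_mult(X[perm], C) >= k_obs:
            count += 1
    return k_obs, (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# between-group PCA and morphospace
# ---------------------------------------------------------------------------


@dataclass
class Morphospace:
    """Between-group principal components and everything projected in."""

    group_labels: list
    group_means: np.ndarray  # (g, p)
    center: np.ndarray  # (p,)
    components: np.ndarray  # (p, m) columns are eigenvectors
    eigenvalues: np.ndarray  # (m,)
    variance_fractions: np.ndarray
    scores: np.ndarray  # (g, m) group-mean scores
    projected: dict = field(default_factory=dict)  # name -> (labels, scores)

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.center) @ self.components


def between_group_pca(X, groups, project=None) -> Morphospace:
    """PCA of the covariance matrix of group means.

    ``X`` is (n, p) with a group label per row; the eigendecomposition
    is of the covariance of the group means, and individuals (``X``
    itself, or extra matrices in ``project``: name -> array) are
    projected onto the axes after centring on the grand mean of means.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise InputError("between-group PCA needs at least 2 groups")
    means = np.stack([X[groups == g].mean(axis=0) for g in labels])
    center = means.mean(axis=0)
    centred = means - center
    if float(np.sum(centred**2)) <= 1e-30:
        raise ComputationError("group means are identical (zero variance)")
    cov = centred.T @ centred / (len(labels) - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    m = min(len(labels) - 1, X.shape[1])
    eigvals, eigvecs = eigvals[:m], eigvecs[:, :m]
    fractions = eigvals / eigvals.sum()

    ms = Morphospace(
        group_labels=labels,
        group_means=means,
        center=center,
        components=eigvecs,
        eigenvalues=eigvals,
        variance_fractions=fractions,
        scores=centred @ eigvecs,
    )
    if project:
        for name, extra in project.items():
            ms.projected[name] = ms.project(np.asarray(extra, dtype=float))
    return ms


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------


def ancestral_states(tree, tip_scores, tip_order=None):
    """Branch-length-weighted squared-change parsimony.

    Internal-node states minimize ``sum_branches (dx)^2 / t`` per trait,
    which coincides with the maximum-likelihood reconstruction of
    internal nodes under Brownian motion.  Solved as one sparse linear
    system per tree.

    Returns ``(node_ids, states)`` where states is (n_internal, p) in
    preorder and node_ids are dendropy node labels or preorder indices.
    """
    import scipy.sparse as sp
    from scipy.sparse.linalg import spsolve

    t = as_tree(tree)
    labels = tip_labels(t)
    tip_scores = np.atleast_2d(np.asarray(tip_scores, dtype=float))
    if tip_order is not None:
        idx = [list(tip_order).index(lbl) for lbl in labels]
        tip_scores = tip_scores[idx]
    if tip_scores.shape[0] != len(labels):
        raise InputError("one row of tip scores per tree tip required")

    internals = [nd for nd in t.preorder_node_iter() if not nd.is_leaf()]
    index = {nd: i for i, nd in enumerate(internals)}
    leaf_row = {lf: i for i, lf in enumerate(t.leaf_node_iter())}

    n = len(internals)
    A = sp.lil_matrix((n, n))
    b = np.zeros((n, tip_scores.shape[1]))
    for nd in internals:
        i = index[nd]
        neighbors = list(nd.child_nodes())
        if nd.parent_node is not None:
            neighbors.append(nd.parent_node)
        for nb in neighbors:
            edge = nd.edge if nb is nd.parent_node else nb.edge
            el = edge.length
            if el is None or el <= 0:
                raise InputError("ancestral states require positive branch lengths")
            w = 1.0 / el
            A[i, i] += w
            if nb.is_leaf():
                b[i] += w * tip_scores[leaf_row[nb]]
            else:
                A[i, index[nb]] -= w
    states = spsolve(A.tocsr(), b)
    states = np.atleast_2d(states)
    if states.shape[0] != n:
        states = states.T
    ids = [nd.label if nd.label else f"node{index[nd]}" for nd in internals]
    return ids, states


# ---------------------------------------------------------------------------
# PGLS with a categorical predictor
# ---------------------------------------------------------------------------


def _dummy_design(categories):
    cats = list(dict.fromkeys(categories))
    if len(cats) < 2:
        raise InputError("need at least 2 categories")
    X = np.zeros((len(categories), len(cats)))
    for i, c in enumerate(categories):
        X[i, cats.index(c)] = 1.0
    # intercept + treatment coding
    return np.hstack([np.ones((len(categories), 1)), X[:, 1:]]), cats


def _hat(X):
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def pgls_categorical(Y, tree_or_C, categories, n_perm: int = 999, seed: int = 0):
    """Phylogenetic generalized least squares, categorical predictor.

    Y and the dummy design are premultiplied by ``P = Lchol(C)^-1``
    (so that ``P'P = C^-1``), multivariate sums of squares are taken as
    traces of the transformed cross-products, and significance comes
    from randomizing the residuals of the reduced (intercept-only)
    model (RRPP).

    Returns a dict with ``R2``, ``F``, ``p`` and the degrees of freedom.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    N = Y.shape[0]
    C = tree_or_C if isinstance(tree_or_C, np.ndarray) else phylo_covariance(tree_or_C)[0]
    if C.shape[0] != N or len(categories) != N:
        raise InputError("Y, tree and categories must agree in size")
    try:
        Lc = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ComputationError("singular phylogenetic covariance") from exc
    Yt = solve_triangular(Lc, Y, lower=True)
    Xfull, cats = _dummy_design(categories)
    Xr = np.ones((N, 1))
    Xft = solve_triangular(Lc, Xfull, lower=True)
    Xrt = solve_triangular(Lc, Xr, lower=True)

    Hf = _hat(Xft)
    Hr = _hat(Xrt)
    df1 = len(cats) - 1
    df2 = N - len(cats)
    if df2 <= 0:
        raise InputError("more categories than residual degrees of freedom")

    Rred = Yt - Hr @ Yt  # residuals of the reduced model
    fitted_red = Hr @ Yt

    def stats(Ymat):
        ssm = float(np.sum(Ymat * ((Hf - Hr) @ Ymat)))
        ssr = float(np.sum(Ymat * ((np.eye(N) - Hf) @ Ymat)))
        sst = float(np.sum(Ymat * ((np.eye(N) - Hr) @ Ymat)))
        F = (ssm / df1) / (ssr / df2) if ssr > 0 else np.inf
        return ssm, ssr, sst, F

    ssm, ssr, sst, F_obs = stats(Yt)
    if sst <= 0:
        raise ComputationError("no variation in the response")
    R2 = ssm / sst

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(N)
        Yp = fitted_red + Rred[perm]
        if stats(Yp)[3] >= F_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return {"R2": R2, "F": F_obs, "p": p, "df": (df1, df2), "categories": cats}


# ---------------------------------------------------------------------------
# pseudo-genetic distances, Mantel, phenetic distances, hulls
# ---------------------------------------------------------------------------


def pseudo_genetic_distance(genotypes):
    """Dosage coding (loss 0, hetero 0.5, normal 1, gain 2) and L1 distances.

    ``genotypes`` maps strain -> {gene: dosage class}; genes absent from
    a strain are wild-type ('normal').  Returns ``(from_wt, pairwise)``:
    a Series of distances from the all-normal genotype (sum over loci of
    |code - 1|) and the strain-by-strain L1 distance matrix.
    """
    if isinstance(genotypes, pd.DataFrame):
        table = {s: genotypes.loc[s].dropna().to_dict() for s in genotypes.index}
    else:
        table = dict(genotypes)
    genes = sorted({g for d in table.values() for g in d})
    strains = list(table)
    codes = np.ones((len(strains), len(genes)))
    for i, s in enumerate(strains):
        for g, cls in table[s].items():
            if cls not in DOSAGE_CODES:
                raise InputError(f"unknown dosage class {cls!r} for {s}/{g}")
            codes[i, genes.index(g)] = DOSAGE_CODES[cls]
    from_wt = pd.Series(np.abs(codes - 1.0).sum(axis=1), index=strains)
    pairwise = pd.DataFrame(
        squareform(pdist(codes, metric="cityblock")), index=strains, columns=strains
    )
    return from_wt, pairwise


def mantel_test(D1, D2, n_perm: int = 999, seed: int = 0):
    """Mantel correlation of two distance matrices.

    Pearson r of the upper off-diagonal triangles; the p-value permutes
    rows and columns of D2 simultaneously.
    """
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    if D1.shape != D2.shape or D1.shape[0] != D1.shape[1]:
        raise InputError("distance matrices must be square and equal-sized")
    for D in (D1, D2):
        if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
            raise InputError("inputs must be symmetric with zero diagonal")
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    n = D1.shape[0]
    iu = np.triu_indices(n, 1)
    x = D1[iu]
    if x.std() == 0 or D2[iu].std() == 0:
        raise ComputationError("constant distance matrix")

    def corr(Dp):
        y = Dp[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(D2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(D2[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)


def phenetic_distance_matrix(morphospace: Morphospace, axes: int = 2):
    """Euclidean distances between group means on the first PC axes."""
    if axes < 1:
        raise InputError("axes must be >= 1")
    if axes > morphospace.scores.shape[1]:
        raise InputError("more axes requested than components available")
    S = morphospace.scores[:, :axes]
    return pd.DataFrame(
        squareform(pdist(S)),
        index=morphospace.group_labels,
        columns=morphospace.group_labels,
    )


def wt_disparity_correlation(genetic_from_wt, phenetic_from_wt):
    """Pearson correlation of genetic vs phenetic disparity from WT.

    Returns ``(r, r_squared, p)`` across strains (WT excluded from the
    inputs by the caller if desired; a zero-zero point is legitimate).
    """
    from scipy.stats import pearsonr

    g = np.asarray(genetic_from_wt, dtype=float)
    f = np.asarray(phenetic_from_wt, dtype=float)
    if g.shape != f.shape:
        raise InputError("disparity vectors must align")
    r, p = pearsonr(g, f)
    return float(r), float(r**2), float(p)


@dataclass
class HullCoverage:
    """Mutual convex-hull coverage of two point sets in a 2D morphospace."""

    b_inside_a: pd.Series
    a_inside_b: pd.Series
    hull_a: np.ndarray  # hull vertex coordinates, CCW
    hull_b: np.ndarray


def _inside_hull(hull: ConvexHull, points: np.ndarray, tol: float = 1e-9):
    eq = hull.equations  # (n_facets, 3): a, b, offset with a.x + off <= 0 inside
    vals = points @ eq[:, :2].T + eq[:, 2]
    return (vals <= tol).all(axis=1)


def hull_coverage(scores, set_a, set_b) -> HullCoverage:
    """Classify each point of one set against the other's 2D convex hull.

    ``scores`` is a DataFrame (index = labels, first two columns = PC1,
    PC2) or an (n, >=2) array with ``set_a``/``set_b`` as row indices.
    """
    if isinstance(scores, pd.DataFrame):
        A = scores.loc[list(set_a)].iloc[:, :2].to_numpy(dtype=float)
        B = scores.loc[list(set_b)].iloc[:, :2].to_numpy(dtype=float)
        names_a, names_b = list(set_a), list(set_b)
    else:
        arr = np.asarray(scores, dtype=float)[:, :2]
        A, B = arr[list(set_a)], arr[list(set_b)]
        names_a, names_b = list(set_a), list(set_b)
    if len(A) < 3 or len(B) < 3:
        raise InputError("each set needs at least 3 points for a hull")
    span = max(np.abs(np.concatenate([A, B])).max(), 1.0)
    tol = 1e-9 * span
    hull_a = ConvexHull(A)
    hull_b = ConvexHull(B)
    return HullCoverage(
        b_inside_a=pd.Series(_inside_hull(hull_a, B, tol), index=names_b),
        a_inside_b=pd.Series(_inside_hull(hull_b, A, tol), index=names_a),
        hull_a=A[hull_a.vertices],
        hull_b=B[hull_b.vertices],
    )
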