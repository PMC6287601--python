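"""Phylogenetic comparative methods on shape data.

Brownian-motion phylogenetic covariance, squared-change parsimony mapping of
a phylogeny into a morphospace, tip-permutation tests of phylogenetic
signal, and phylogenetic two-block partial least squares (PLS) for
morphological integration between asymmetry spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _as_matrix(tip_data, labels: list[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(tip_data, pd.DataFrame):
        return tip_data.to_numpy(dtype=float), list(tip_data.index)
    X = np.asarray(tip_data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if labels is None:
        raise ValueError("labels are required when tip_data is a plain array")
    if len(labels) != X.shape[0]:
        raise ValueError("labels and tip_data row count differ")
    return X, list(labels)


def _match_tips(tree: dendropy.Tree, labels: list[str]) -> None:
    tips = set(tip_labels(tree))
    data = set(labels)
    if tips != data:
        missing = sorted(tips - data)
        extra = sorted(data - tips)
        raise ValueError(
            f"tip/data mismatch: missing from data {missing}, not on tree {extra}"
        )


def phylo_cov(tree: dendropy.Tree, labels: list[str] | None = None) -> pd.DataFrame:
    """Brownian-motion phylogenetic covariance matrix C.

    C[i, j] is the depth (root-to-node path length) of the most recent common
    ancestor of tips i and j; C[i, i] is the root-to-tip path length.
    Returned as a DataFrame indexed by tip label.
    """
    if labels is None:
        labels = tip_labels(tree)
    else:
        _match_tips(tree, labels)
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depth[node] = 0.0
        else:
            length = node.edge.length if node.edge.length is not None else 0.0
            depth[node] = depth[parent] + length
    S = len(labels)
    C = np.zeros((S, S))
    tipsets: dict[dendropy.Node, set[int]] = {}
    pos = {lbl: i for i, lbl in enumerate(labels)}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = {pos[node.taxon.label]}
            C[pos[node.taxon.label], pos[node.taxon.label]] = depth[node]
        else:
            children = [tipsets[c] for c in node.child_nodes()]
            merged: set[int] = set()
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = depth[node]
                for i in children[a]:
                    merged.add(i)
            tipsets[node] = merged
    return pd.DataFrame(C, index=labels, columns=labels)


def _tree_system(
    tree: dendropy.Tree,
    labels: list[str],
    weighted: bool,
    zero_length: float = 1e-8,
):
    """Graph Laplacian of the tree split into tip/internal blocks."""
    nodes = list(tree.preorder_node_iter())
    index = {node: i for i, node in enumerate(nodes)}
    N = len(nodes)
    L = np.zeros((N, N))
    edges = []
    warned = False
    for node in nodes:
        parent = node.parent_node
        if parent is None:
            continue
        length = node.edge.length
        if weighted:
            if length is None or length <= 0:
                if not warned:
                    warnings.warn(
                        f"zero/absent branch length treated as {zero_length}",
                        stacklevel=3,
                    )
                    warned = True
                length = zero_length
            w = 1.0 / length
        else:
            w = 1.0
        i, j = index[parent], index[node]
        L[i, i] += w
        L[j, j] += w
        L[i, j] -= w
        L[j, i] -= w
        edges.append((i, j, w))
    pos = {lbl: t for t, lbl in enumerate(labels)}
    tip_idx = np.full(len(labels), -1, dtype=int)
    is_tip = np.zeros(N, dtype=bool)
    for node in nodes:
        if node.is_leaf():
            tip_idx[pos[node.taxon.label]] = index[node]
            is_tip[index[node]] = True
    internal_idx = np.flatnonzero(~is_tip)
    return L, tip_idx, internal_idx, nodes, edges


@dataclass
class SCPResult:
    """Squared-change parsimony reconstruction over a tree."""

    labels: list[str]
    tip_states: np.ndarray  # (S, D)
    node_states: dict  # dendropy.Node -> (D,) state (internal nodes)
    q_total: float
    q_per_dim: np.ndarray
    branch_contributions: list[tuple]  # (parent node, child node, squared change / length)
    optimality_residual: float

    def root_state(self, tree: dendropy.Tree) -> np.ndarray:
        return self.node_states[tree.seed_node]


def squared_change_parsimony(
    tree: dendropy.Tree,
    tip_data,
    labels: list[str] | None = None,
    weighted: bool = True,
    zero_length: float = 1e-8,
) -> SCPResult:
    """Ancestral states minimizing the (branch-length weighted) squared change.

    Minimizes Q = sum over branches of |state change|^2 / branch length
    (length taken as 1 when ``weighted=False``).  Equivalent to
    Brownian-motion generalized least squares ancestral reconstruction.
    """
    X, lbls = _as_matrix(tip_data, labels)
    _match_tips(tree, lbls)
    L, tip_idx, internal_idx, nodes, edges = _tree_system(tree, lbls, weighted, zero_length)
    N = L.shape[0]
    full = np.zeros((N, X.shape[1]))
    full[tip_idx] = X
    L_II = L[np.ix_(internal_idx, internal_idx)]
    L_IT = L[np.ix_(internal_idx, tip_idx)]
    full[internal_idx] = -np.linalg.solve(L_II, L_IT @ X)
    residual = float(
        np.abs(L_II @ full[internal_idx] + L_IT @ X).max()
    ) if internal_idx.size else 0.0
    q_per_dim = np.zeros(X.shape[1])
    contributions = []
    for i, j, w in edges:
        delta2 = w * (full[j] - full[i]) ** 2
        q_per_dim += delta2
        contributions.append((nodes[i], nodes[j], float(delta2.sum())))
    node_states = {nodes[i]: full[i] for i in internal_idx}
    return SCPResult(
        labels=lbls,
        tip_states=X,
        node_states=node_states,
        q_total=float(q_per_dim.sum()),
        q_per_dim=q_per_dim,
        branch_contributions=contributions,
        optimality_residual=residual,
    )


def scp_quadratic_form(
    tree: dendropy.Tree,
    labels: list[str],
    weighted: bool = True,
    zero_length: float = 1e-8,
) -> np.ndarray:
    """Matrix M (tips x tips) with Q = sum_d x_d' M x_d for tip data x.

    Schur complement of the internal block of the tree Laplacian; lets the
    permutation test recompute Q with a matrix product per shuffle.
    """
    L, tip_idx, internal_idx, _, _ = _tree_system(tree, labels, weighted, zero_length)
    L_TT = L[np.ix_(tip_idx, tip_idx)]
    if internal_idx.size == 0:
        return L_TT
    L_TI = L[np.ix_(tip_idx, internal_idx)]
    L_II = L[np.ix_(internal_idx, internal_idx)]
    return L_TT - L_TI @ np.linalg.solve(L_II, L_TI.T)


@dataclass
class SignalTestResult:
    """Tip-permutation test of phylogenetic signal (left tail of Q)."""

    q_observed: float
    q_permuted: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None


def phylo_signal_test(
    tree: dendropy.Tree,
    tip_data,
    labels: list[str] | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
    weighted: bool = True,
) -> SignalTestResult:
    """Permutation test of phylogenetic signal in multivariate tip data.

    Shuffles the tip rows across the tree's tips and recomputes the total
    squared change Q; data more clumped on the tree than random give small
    Q, so p is the left tail: (#{Q_perm <= Q_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, lbls = _as_matrix(tip_data, labels)
    _match_tips(tree, lbls)
    M = scp_quadratic_form(tree, lbls, weighted=weighted)
    q_obs = float(np.einsum("ij,id,jd->", M, X, X))
    rng = np.random.default_rng(seed)
    q_perm = np.empty(n_perm)
    for t in range(n_perm):
        Xp = X[rng.permutation(X.shape[0])]
        q_perm[t] = np.einsum("ij,id,jd->", M, Xp, Xp)
    tol = 1e-9 * max(abs(q_obs), 1.0)
    p = (int((q_perm <= q_obs + tol).sum()) + 1) / (n_perm + 1)
    return SignalTestResult(q_obs, q_perm, p, n_perm, seed)


def phylo_gls_mean(C: np.ndarray, X: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Generalized least squares estimate of the phylogenetic (root) mean.

    a = (1' C^-1 1)^-1 1' C^-1 X.  A singular C can be regularized with a
    small ridge (added to the diagonal), with a warning.
    """
    C = np.asarray(C, dtype=float)
    X = np.asarray(X, dtype=float)
    if ridge > 0:
        C = C + ridge * np.eye(C.shape[0])
    try:
        Cinv_X = np.linalg.solve(C, X)
        Cinv_1 = np.linalg.solve(C, np.ones(C.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular phylogenetic covariance; pass ridge > 0 to regularize"
        ) from exc
    return (np.ones(C.shape[0]) @ Cinv_X) / Cinv_1.sum()


def inv_sqrt_psd(C: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition (eigenvalue floor)."""
    w, V = np.linalg.eigh(np.asarray(C, dtype=float))
    w = np.maximum(w, floor * max(float(w.max()), 1.0))
    return (V / np.sqrt(w)) @ V.T


@dataclass
class IntegrationResult:
    """Phylogenetic two-block PLS result."""

    r_pls: float
    singular_values: np.ndarray
    x_vectors: np.ndarray  # (D1, n_axes) singular warps, block X
    y_vectors: np.ndarray  # (D2, n_axes)
    x_scores: np.ndarray  # first-axis scores per species
    y_scores: np.ndarray
    labels: list[str]
    p_value: float
    r_permuted: np.ndarray
    n_perm: int
    seed: int | None


def _pls_core(Xt: np.ndarray, Yt: np.ndarray):
    R = Xt.T @ Yt / (Xt.shape[0] - 1)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    u1 = U[:, 0]
    v1 = Vt[0]
    sx = Xt @ u1
    sy = Yt @ v1
    denom = sx.std() * sy.std()
    r = abs(float(np.corrcoef(sx, sy)[0, 1])) if denom > 0 else 0.0
    return U, s, Vt, sx, sy, r


def phylo_pls(
    tree: dendropy.Tree,
    block_x,
    block_y,
    labels: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> IntegrationResult:
    """Two-block PLS of evolutionary covariation under Brownian motion.

    Both blocks are phylogenetically transformed — GLS mean subtracted, then
    premultiplied by C^(-1/2) — and the cross-block covariance of the
    transformed data decomposed by SVD.  r_PLS is the absolute correlation of
    the first pair of singular-axis scores.  Significance: the Y block's tip
    assignment is permuted each replicate in the phylogenetically transformed
    space (whose rows are exchangeable under Brownian motion, so the null
    p-values are uniform); p = (#{r_perm >= r_obs} + 1) / (n_perm + 1).
    """
    X, lx = _as_matrix(block_x, labels)
    if isinstance(block_y, pd.DataFrame):
        if set(block_y.index) != set(lx):
            raise ValueError(
                f"block species mismatch: {sorted(set(lx) ^ set(block_y.index))}"
            )
        block_y = block_y.reindex(lx)
    Y, _ = _as_matrix(block_y, lx)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks differ in species count")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 species")
    _match_tips(tree, lx)
    C = phylo_cov(tree, lx).to_numpy()
    E = inv_sqrt_psd(C)

    def transform(Z: np.ndarray) -> np.ndarray:
        a = phylo_gls_mean(C, Z)
        return E @ (Z - a)

    Xt = transform(X)
    Yt = transform(Y)
    U, s, Vt, sx, sy, r_obs = _pls_core(Xt, Yt)

    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for t in range(n_perm):
        *_, r_perm[t] = _pls_core(Xt, Yt[rng.permutation(Yt.shape[0])])
    p = (int((r_perm >= r_obs - 1e-12).sum()) + 1) / (n_perm + 1)

    x_vec = U.copy()
    y_vec = Vt.T.copy()
    for j in range(x_vec.shape[1]):
        if x_vec[np.argmax(np.abs(x_vec[:, j])), j] < 0:
            x_vec[:, j] = -x_vec[:, j]
            y_vec[:, j] = -y_vec[:, j]
            if j == 0:
                sx, sy = -sx, -sy
    return IntegrationResult(
        r_pls=r_obs,
        singular_values=s,
        x_vectors=x_vec,
        y_vectors=y_vec,
        x_scores=sx,
        y_scores=sy,
        labels=lx,
        p_value=p,
        r_permuted=r_perm,
        n_perm=n_perm,
        seed=seed,
    )


def prune_to(tree: dendropy.Tree, labels: list[str]) -> dendropy.Tree:
    """Copy of `tree` retaining only the named tips."""
    pruned = tree.extract_tree_with_taxa_labels(labels)
    pruned.is_rooted = True
    return pruned
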