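"""Tree-derived quantities.

Cophenetic (tip-to-tip patristic) and root-to-tip distances, normalized
Robinson-Foulds congruence between topologies, and Pagel's lambda
phylogenetic signal for continuous genome features under a Brownian-motion
model.

A :class:`PhyloTree` wraps a dendropy tree; trees are inputs here, never
re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
from scipy import linalg, optimize, stats

from ._util import logger
from .datatypes import DistanceMatrix, TestResult


class PhyloTree:
    """Rooted or unrooted phylogeny with nonnegative branch lengths."""

    def __init__(self, tree: dendropy.Tree, n_imputed_lengths: int = 0):
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) < 2:
            raise ValueError("a tree needs at least 2 tips")
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")
        self._tree = tree
        self.n_imputed_lengths = int(n_imputed_lengths)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        from .io import read_newick

        return read_newick(text)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def is_rooted(self) -> bool:
        # a bifurcating seed node marks a rooted tree
        return len(self._tree.seed_node.child_nodes()) == 2

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions, each canonicalized.

        Each internal edge splits the tips in two; the split is stored as the
        side *not* containing the alphabetically first tip, so two trees on
        the same tip set yield comparable keys regardless of rooting.
        """
        all_tips = frozenset(self.tip_labels)
        anchor = min(all_tips)
        splits: set[frozenset] = set()
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node or node.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(below) < 2 or len(all_tips - below) < 2:
                continue  # trivial
            side = below if anchor not in below else all_tips - below
            splits.add(side)
        return splits


def cophenetic_from_tree(tree: PhyloTree) -> DistanceMatrix:
    """Pairwise sum of branch lengths between all tip pairs.

    Refuses trees where branch lengths had to be imputed on read: a
    topology-only tree supports nRF but not patristic distances.
    """
    if tree.n_imputed_lengths > 0:
        raise ValueError(
            f"{tree.n_imputed_lengths} branch lengths were imputed as 0; "
            "cophenetic distances would be meaningless"
        )
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    labels = tree.tip_labels
    taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(d, labels)


def patristic_root_distances(tree: PhyloTree) -> dict[str, float]:
    """Root-to-tip path length for every tip (the 'distRoot' behavior)."""
    if not tree.is_rooted:
        raise ValueError("tree is unrooted; root it before computing root distances")
    if tree.n_imputed_lengths > 0:
        raise ValueError("imputed branch lengths present; refusing root distances")
    out = {}
    for leaf in tree.dendropy_tree.leaf_node_iter():
        dist = 0.0
        node = leaf
        while node.parent_node is not None:
            dist += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = dist
    return dict(sorted(out.items()))


def robinson_foulds(t1: PhyloTree, t2: PhyloTree, normalized: bool = True) -> TestResult:
    """Robinson-Foulds distance between two topologies on the same tips.

    RF counts non-trivial bipartitions present in exactly one tree; the
    normalized form divides by the total number of non-trivial bipartitions
    in both trees, so nRF is in [0, 1] (0 = congruent, 1 = incongruent) for
    multifurcating trees too.  For two fully binary trees the denominator
    equals 2(n-3).  Comparison is on unrooted bipartitions, so the result is
    invariant to rooting and tip order.
    """
    tips1, tips2 = set(t1.tip_labels), set(t2.tip_labels)
    if tips1 != tips2:
        diff = sorted(tips1 ^ tips2)
        raise ValueError(f"tip sets differ; symmetric difference: {diff}")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    rf = len(b1 ^ b2)
    denom = len(b1) + len(b2)
    stat = rf / denom if (normalized and denom > 0) else float(rf)
    return TestResult(
        name="nRF" if normalized else "RF",
        statistic=stat,
        p_value=np.nan,
        extra={"rf": rf, "max_rf": denom, "n_tips": len(tips1)},
    )


@dataclass(frozen=True)
class LambdaFit:
    """Maximum-likelihood Pagel's lambda fit with LRT against lambda = 0."""

    lambda_hat: float
    loglik: float
    loglik_zero: float
    lrt: float
    p_value: float
    sigma2: float
    root_state: float
    lambda_max: float

    def as_test_result(self) -> TestResult:
        return TestResult(
            name="pagel_lambda_lrt",
            statistic=self.lrt,
            p_value=self.p_value,
            df=1,
            effect=self.lambda_hat,
            effect_name="lambda",
            extra={"loglik": self.loglik, "loglik_zero": self.loglik_zero},
        )


def bm_covariance(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance: C_ij = depth of the MRCA of tips i, j."""
    if not tree.is_rooted:
        raise ValueError("BM covariance requires a rooted tree")
    dt = tree.dendropy_tree
    labels = tree.tip_labels
    depth = {}
    for leaf in dt.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depth[leaf.taxon.label] = d
    pdm = dt.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in dt.taxon_namespace}
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        C[i, i] = depth[a]
        for j in range(i + 1, n):
            b = labels[j]
            dij = pdm.patristic_distance(taxa[a], taxa[b])
            C[i, j] = C[j, i] = 0.5 * (depth[a] + depth[b] - dij)
    return C, labels


def _profile_loglik(lam: float, C: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Profile log-likelihood of lambda; sigma^2 and the root state are
    profiled out analytically (ML, not REML)."""
    n = len(y)
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    logdet = 2.0 * np.log(np.diag(L)).sum()
    ones = np.ones(n)
    Vi_y = linalg.cho_solve((L, True), y)
    Vi_1 = linalg.cho_solve((L, True), ones)
    a = (ones @ Vi_y) / (ones @ Vi_1)
    r = y - a
    Vi_r = linalg.cho_solve((L, True), r)
    sigma2 = (r @ Vi_r) / n
    if sigma2 <= 0:
        return -np.inf, np.nan, np.nan
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, sigma2, a


def _lambda_upper_bound(C: np.ndarray, cap: float = 1.0) -> float:
    """Largest lambda (up to ``cap``) keeping C(lambda) positive definite."""

    def pd_ok(lam):
        V = C * lam
        np.fill_diagonal(V, np.diag(C))
        try:
            linalg.cholesky(V, lower=True)
            return True
        except linalg.LinAlgError:
            return False

    if pd_ok(cap):
        return cap
    lo, hi = 0.0, cap
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if pd_ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def pagel_lambda(
    tree: PhyloTree, trait: Mapping[str, float], lambda_cap: float = 1.0
) -> LambdaFit:
    """ML estimate of Pagel's lambda for a continuous tip trait.

    The BM covariance's off-diagonal entries are multiplied by lambda
    (diagonals unchanged); lambda is maximized over [0, lambda_max] where
    lambda_max is the largest value keeping the covariance positive definite
    (capped at ``lambda_cap``).  The LRT compares against lambda = 0, i.e.
    phylogenetically independent tips, with a chi-square(1) reference.
    """
    C, labels = bm_covariance(tree)
    missing = [l for l in labels if l not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing[:5]}")
    if len(labels) < 4:
        raise ValueError("need at least 4 tips for a lambda fit")
    y = np.array([float(trait[l]) for l in labels])
    if np.allclose(y.var(), 0):
        raise ValueError("trait has zero variance")
    lam_max = _lambda_upper_bound(C, cap=lambda_cap)

    def neg(lam):
        return -_profile_loglik(lam, C, y)[0]

    res = optimize.minimize_scalar(neg, bounds=(0.0, lam_max), method="bounded",
                                   options={"xatol": 1e-8})
    lam_hat = float(res.x)
    ll_hat, sigma2, root = _profile_loglik(lam_hat, C, y)
    ll_zero, _, _ = _profile_loglik(0.0, C, y)
    # the optimum can never be below the lambda = 0 endpoint
    if ll_zero > ll_hat:
        lam_hat, ll_hat = 0.0, ll_zero
        _, sigma2, root = _profile_loglik(0.0, C, y)
    lrt = max(0.0, 2.0 * (ll_hat - ll_zero))
    p = float(stats.chi2.sf(lrt, df=1))
    return LambdaFit(
        lambda_hat=lam_hat,
        loglik=ll_hat,
        loglik_zero=ll_zero,
        lrt=lrt,
        p_value=p,
        sigma2=float(sigma2),
        root_state=float(root),
        lambda_max=lam_max,
    )
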