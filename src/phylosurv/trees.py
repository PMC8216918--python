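"""Phylogenetic trees and the species covariance matrices they induce.

Under a Brownian-motion model of trait evolution, the covariance between two
species is the branch length shared on their root paths, i.e. the depth of
their most recent common ancestor.  Dividing by the root-to-tip depths turns
this into a correlation matrix, which is the scale on which the regression
model consumes phylogenies (one matrix per candidate tree).  Pagel's lambda
discounts the off-diagonal entries: lambda = 0 removes all phylogenetic
dependence, lambda = 1 keeps the full Brownian covariance.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "parse_newick",
    "write_newick",
    "tree_vcv",
    "scale_vcv",
    "lambda_transform",
    "random_tree",
    "CovarianceSet",
]

#: symmetry tolerance for covariance matrices
SYM_TOL = 1e-10
#: most-negative admissible eigenvalue for a (numerically) PSD matrix
EIG_TOL = -1e-8


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick string into a rooted tree.

    Raises ``ValueError`` for malformed input, duplicate tip labels, missing
    or negative branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"could not parse Newick string: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels in Newick string: {dupes}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            where = node.taxon.label if node.taxon else "an internal node"
            raise ValueError(f"missing branch length above {where}")
        if node.edge.length < 0:
            raise ValueError(f"negative branch length {node.edge.length}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree back to a one-line Newick string.

    Branch lengths are written with 17 significant digits, so a
    parse-write-parse cycle preserves them exactly.
    """
    return tree.as_string(
        schema="newick", suppress_rooting=True, real_value_format_specifier=".17g"
    ).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's own leaf order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_vcv(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Shared-path-length (Brownian) variance-covariance matrix of a tree.

    Entry (i, j) is the summed branch length from the root to the MRCA of
    tips i and j; the diagonal holds root-to-tip depths.

    Returns
    -------
    V : (n, n) ndarray
    labels : list of tip labels giving the row/column order
    """
    labels = tip_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))

    # node depth from root
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    # postorder: covariance of tips in different child subtrees = node depth
    tips_below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            V[i, i] = depth[id(node)]
            tips_below[id(node)] = [i]
        else:
            children = [tips_below.pop(id(c)) for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = V[j, i] = d
            tips_below[id(node)] = [i for sub in children for i in sub]
    return V, labels


def scale_vcv(V: np.ndarray) -> np.ndarray:
    """Scale a covariance matrix to a correlation matrix.

    ``C_ij = V_ij / sqrt(V_ii V_jj)``; for an ultrametric tree of depth T
    this is simply V / T.
    """
    V = np.asarray(V, dtype=float)
    d = np.diag(V)
    if np.any(d <= 0):
        bad = np.where(d <= 0)[0].tolist()
        raise ValueError(f"non-positive diagonal entries at indices {bad} (tip at root?)")
    s = 1.0 / np.sqrt(d)
    C = V * np.outer(s, s)
    np.fill_diagonal(C, 1.0)
    return C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Apply Pagel's lambda: multiply off-diagonal correlations by ``lam``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def random_tree(n_tips: int, seed=None, rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Simulate a random rooted binary tree.

    Topology by recursive random splitting (each split size equally likely,
    tip assignment by a uniform random permutation) and branch lengths drawn
    i.i.d. Uniform(0, 1) — the scheme of the classic ``rtree`` simulator.
    Deterministic given ``seed``. Tips are labelled ``t1..tn``.
    """
    if n_tips < 2:
        raise ValueError(f"need at least 2 tips, got {n_tips}")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_tips)]
    perm = rng.permutation(n_tips)
    shuffled = [labels[i] for i in perm]

    def build(tips: list[str]) -> str:
        if len(tips) == 1:
            return f"{tips[0]}:{rng.uniform():.17g}"
        m = int(rng.integers(1, len(tips)))
        left, right = build(tips[:m]), build(tips[m:])
        return f"({left},{right}):{rng.uniform():.17g}"

    body = build(shuffled)
    # strip the root's branch length
    newick = body[: body.rfind(":")] + ";"
    return parse_newick(newick)


def _check_corr(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name}: matrix must be square, got shape {M.shape}")
    if np.max(np.abs(M - M.T)) > SYM_TOL:
        raise ValueError(f"{name}: matrix not symmetric within {SYM_TOL}")
    if np.max(np.abs(np.diag(M) - 1.0)) > SYM_TOL:
        raise ValueError(f"{name}: diagonal not 1 after scaling")
    if np.min(np.linalg.eigvalsh(M)) < EIG_TOL:
        raise ValueError(f"{name}: matrix has eigenvalue below {EIG_TOL}; rejecting (no clipping)")
    return M


class CovarianceSet:
    """K candidate species correlation matrices with a shared species order.

    Each matrix is the scaled Brownian covariance of one candidate phylogeny;
    the sampler places a discrete-uniform prior over the K candidates.
    """

    def __init__(self, matrices, species_order):
        self.species_order = list(species_order)
        n = len(self.species_order)
        self.matrices = []
        for k, M in enumerate(matrices):
            M = _check_corr(M, f"matrix {k}")
            if M.shape[0] != n:
                raise ValueError(
                    f"matrix {k} has dimension {M.shape[0]} but {n} species are listed"
                )
            self.matrices.append(M)
        if not self.matrices:
            raise ValueError("CovarianceSet needs at least one matrix")

    @property
    def K(self) -> int:
        return len(self.matrices)

    @property
    def n(self) -> int:
        return len(self.species_order)

    @classmethod
    def from_trees(cls, trees: list[dendropy.Tree]) -> "CovarianceSet":
        """Build the set of scaled covariance matrices from candidate trees."""
        mats, order = [], None
        for tree in trees:
            V, labels = tree_vcv(tree)
            if order is None:
                order = sorted(labels)
            idx = _order_index(labels, order, "tree")
            mats.append(scale_vcv(V)[np.ix_(idx, idx)])
        return cls(mats, order)

    @classmethod
    def from_newick_file(cls, path) -> "CovarianceSet":
        with open(path) as fh:
            text = fh.read()
        trees = [parse_newick(chunk + ";") for chunk in text.split(";") if chunk.strip()]
        if not trees:
            raise ValueError(f"no trees found in {path}")
        return cls.from_trees(trees)

    @classmethod
    def from_csv(cls, paths) -> "CovarianceSet":
        """Read matrices from CSVs with species labels as header row and index."""
        mats, order = [], None
        for path in paths:
            df = pd.read_csv(path, index_col=0)
            labels = [str(x) for x in df.index]
            if list(df.columns) != labels:
                raise ValueError(f"{path}: row and column species labels disagree")
            if order is None:
                order = labels
            idx = _order_index(labels, order, str(path))
            mats.append(df.to_numpy(dtype=float)[np.ix_(idx, idx)])
        return cls(mats, order)

    def reorder(self, species: list[str]) -> "CovarianceSet":
        """Permute all matrices to a trait table's species order.

        Species present in the table but absent from the matrices are a hard
        error — no imputation.
        """
        idx = _order_index(self.species_order, list(species), "covariance set")
        return CovarianceSet([M[np.ix_(idx, idx)] for M in self.matrices], list(species))


def _order_index(have: list[str], want: list[str], what: str) -> np.ndarray:
    pos = {lab: i for i, lab in enumerate(have)}
    missing = [s for s in want if s not in pos]
    if missing:
        raise ValueError(f"{what}: species missing from phylogeny: {missing}")
    if len(want) != len(have):
        raise ValueError(
            f"{what}: {len(have)} species in phylogeny but {len(want)} requested"
        )
    return np.array([pos[s] for s in want])
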