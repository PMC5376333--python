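"""Phylogeny input/output and phylogenetic covariance matrices.

Trees are rooted, with branch lengths in arbitrary time or substitution
units.  Under Brownian-motion trait evolution the expected covariance of a
trait between two tips equals the branch length shared by their root-to-tip
paths; this module builds that matrix and applies Pagel's lambda
transformation (off-diagonal shrinkage) to it.

Parsing and pruning are delegated to :mod:`dendropy`; the wrapper enforces
the validation rules the downstream statistics require (unique nonempty tip
labels, nonnegative branch lengths, at least two tips).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "VCVMatrix",
    "TreeValidationError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "vcv_matrix",
    "lambda_transform",
]


class TreeValidationError(ValueError):
    """A tree violates a structural requirement (labels, lengths, size)."""


def _normalize_label(label: str, fold_underscores: bool = False) -> str:
    label = label.strip()
    if fold_underscores:
        label = label.replace("_", " ")
    return label


@dataclass
class PhyloTree:
    """A rooted phylogeny with branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that guarantees unique,
    nonempty tip labels and nonnegative branch lengths.  Tip order is the
    tree's left-to-right leaf order and is the row/column order of any
    covariance matrix derived from it.
    """

    _tree: dendropy.Tree

    def __post_init__(self) -> None:
        self._validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def tips(self) -> list[str]:
        """Tip labels in tree (left-to-right) order."""
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def as_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        )
        return s.strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        depths = _root_to_tip_depths(self._tree)
        return bool(np.ptp(list(depths.values())) <= tol)

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not str(leaf.taxon.label).strip():
                raise TreeValidationError("tree contains an unlabeled or empty-label tip")
            labels.append(leaf.taxon.label)
        if len(labels) < 2:
            raise TreeValidationError(f"tree has {len(labels)} tip(s); at least 2 required")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        zero_terminals = []
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            length = node.edge.length
            if length is None:
                raise TreeValidationError(
                    "edge without a branch length; re-parse with missing_lengths='zero' "
                    "to assign zero"
                )
            if length < 0:
                raise TreeValidationError(f"negative branch length {length}")
            if length == 0 and node.is_leaf():
                zero_terminals.append(node.taxon.label)
        if zero_terminals:
            warnings.warn(
                f"zero-length terminal branches at {zero_terminals}: identical tip "
                "positions make the phylogenetic covariance matrix singular",
                UserWarning,
                stacklevel=3,
            )


@dataclass
class VCVMatrix:
    """Tip-by-tip phylogenetic covariance matrix.

    ``values[i, j]`` is the branch length shared by the root-to-tip paths of
    tips ``labels[i]`` and ``labels[j]``; the diagonal holds root-to-tip
    distances.  ``lambda_applied`` records a Pagel's-lambda off-diagonal
    rescaling, ``None`` for the untransformed Brownian-motion matrix.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    lambda_applied: float | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("phylogenetic covariance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: list[str] | tuple[str, ...]) -> "VCVMatrix":
        """Return a copy with rows/columns in the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return VCVMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.lambda_applied)

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor; raises with an actionable message if singular."""
        try:
            return np.linalg.cholesky(self.values)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "phylogenetic covariance matrix is not positive definite; this "
                "usually means two tips sit at an identical position (zero-length "
                "terminal branches) or the tree has a zero-depth root"
            ) from exc


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str, missing_lengths: str = "error") -> PhyloTree:
    """Parse a single Newick tree from a string.

    Unquoted underscores in labels are preserved verbatim; internal node
    labels are ignored.  Edges without a branch length raise unless
    ``missing_lengths='zero'``.
    """
    if missing_lengths not in ("error", "zero"):
        raise ValueError("missing_lengths must be 'error' or 'zero'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeValidationError(f"could not parse Newick: {exc}") from exc
    if missing_lengths == "zero":
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node and node.edge.length is None:
                node.edge.length = 0.0
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None:
            leaf.taxon.label = _normalize_label(leaf.taxon.label)
    return PhyloTree(tree)


def read_newick(path, missing_lengths: str = "error") -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read(), missing_lengths=missing_lengths)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_to_taxa(tree: PhyloTree, keep) -> PhyloTree:
    """Restrict ``tree`` to the tip set ``keep``.

    Path lengths between retained tips, and their root-to-tip distances, are
    preserved: unbranched internal nodes created by the pruning are collapsed
    with their branch lengths summed.
    """
    keep = set(keep)
    tips = set(tree.tips)
    missing = sorted(keep - tips)
    if missing:
        raise TreeValidationError(f"labels not in tree: {missing}")
    if len(keep) < 2:
        raise TreeValidationError(f"cannot prune to {len(keep)} tip(s); at least 2 required")
    clone = tree._tree.clone(depth=1)
    clone.retain_taxa_with_labels(sorted(keep))
    # keep root-to-tip distances intact: a unifurcating original root is
    # collapsed by dendropy with the stem length moved onto the new seed edge,
    # which vcv_matrix adds back in.
    return PhyloTree(clone)


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------

def _root_to_tip_depths(tree: dendropy.Tree) -> dict:
    depth = {}
    root_edge = tree.seed_node.edge.length or 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            depth[node] = float(root_edge)
        else:
            depth[node] = depth[node.parent_node] + float(node.edge.length or 0.0)
    return {leaf: depth[leaf] for leaf in tree.leaf_node_iter()}


def vcv_matrix(tree: PhyloTree) -> VCVMatrix:
    """Brownian-motion covariance: shared root-to-tip path length per tip pair."""
    t = tree._tree
    leaves = list(t.leaf_node_iter())
    index = {leaf: i for i, leaf in enumerate(leaves)}
    labels = tuple(leaf.taxon.label for leaf in leaves)
    n = len(leaves)

    depth = {}
    root_edge = t.seed_node.edge.length or 0.0
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            depth[node] = float(root_edge)
        else:
            depth[node] = depth[node.parent_node] + float(node.edge.length or 0.0)

    C = np.zeros((n, n))
    tips_below: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            C[i, i] = depth[node]
            tips_below[node] = np.array([i], dtype=int)
        else:
            groups = [tips_below.pop(child) for child in node.child_nodes()]
            d = depth[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    C[np.ix_(groups[a], groups[b])] = d
                    C[np.ix_(groups[b], groups[a])] = d
            tips_below[node] = np.concatenate(groups)
    return VCVMatrix(labels, C, lambda_applied=None)


def lambda_transform(C: VCVMatrix, lam: float) -> VCVMatrix:
    """Pagel's lambda transformation: multiply off-diagonal entries by ``lam``.

    ``lam=1`` leaves the Brownian-motion covariance intact (full phylogenetic
    correlation); ``lam=0`` removes all between-tip covariance (phylogenetic
    independence).  The search domain is restricted to [0, 1], the range on
    which the parameter is interpretable and positive definiteness is
    guaranteed for valid trees.
    """
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    values = C.values * lam
    np.fill_diagonal(values, np.diag(C.values))
    return VCVMatrix(C.labels, values, lambda_applied=lam)
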