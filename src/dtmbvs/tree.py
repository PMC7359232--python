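"""Tree and tabular input handling.

A rooted phylogeny is flattened into an ordered set of *branches*
(parent->child edges).  Each internal node defines a local multinomial
over its children, so a leaf-level count matrix decomposes into one
small subjects x children count table per internal node.  Branch
indexing is deterministic: depth-first from the root with children kept
in Newick source order, so the same input always yields the same
branch -> (intercept, coefficient) mapping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "CountMatrix",
    "CovariateMatrix",
    "NodeCounts",
    "NewickParseError",
    "TreeStructureError",
    "LabelMismatchError",
    "parse_newick",
    "star_tree",
    "decompose_counts",
    "standardize",
    "read_counts",
    "read_covariates",
    "read_graph",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeStructureError(ValueError):
    """Raised when a tree violates structural requirements (e.g. one leaf)."""


class LabelMismatchError(ValueError):
    """Raised when count-matrix taxa and tree leaves are not an exact match."""


@dataclass(frozen=True)
class PhyloTree:
    """Rooted tree with deterministic branch indexing.

    Attributes
    ----------
    node_branches : list of int arrays
        For each internal node (indexed in depth-first discovery order,
        root = node 0), the branch ids of its child edges, in source order.
    branch_parent_node : int array, shape (B,)
        Internal-node index of each branch's parent.
    branch_child_node : int array, shape (B,)
        Internal-node index of the child if it is internal, else -1.
    branch_labels : list of str
        Leaf name for leaf branches, synthesized ``node_<k>`` otherwise.
    leaf_labels : list of str
        Taxon names in branch-index order of their incident leaf branches.
    branch_leaf_sets : list of int arrays
        For each branch, the sorted indices (into ``leaf_labels``) of the
        leaves in the subtree below it.
    """

    node_branches: list[np.ndarray]
    branch_parent_node: np.ndarray
    branch_child_node: np.ndarray
    branch_labels: list[str]
    leaf_labels: list[str]
    branch_leaf_sets: list[np.ndarray]

    @property
    def n_branches(self) -> int:
        return len(self.branch_labels)

    @property
    def n_internal(self) -> int:
        return len(self.node_branches)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def branch_position(self, b: int) -> tuple[int, int]:
        """(parent node, column position within that node's child table)."""
        v = int(self.branch_parent_node[b])
        pos = int(np.flatnonzero(self.node_branches[v] == b)[0])
        return v, pos

    def incoming_branch(self, node: int) -> int | None:
        """Branch ending at internal node ``node`` (None for the root)."""
        hits = np.flatnonzero(self.branch_child_node == node)
        return int(hits[0]) if hits.size else None

    def path_branches(self, leaf_label: str) -> list[int]:
        """Branch ids along the root -> leaf path, root end first."""
        if leaf_label not in self.leaf_labels:
            raise KeyError(f"unknown taxon {leaf_label!r}; known leaves: "
                           f"{sorted(self.leaf_labels)}")
        leaf_idx = self.leaf_labels.index(leaf_label)
        # the leaf branch is the one whose leaf set is exactly {leaf_idx}
        b = next(i for i, s in enumerate(self.branch_leaf_sets)
                 if s.size == 1 and s[0] == leaf_idx)
        path = [b]
        while True:
            parent = int(self.branch_parent_node[path[-1]])
            up = self.incoming_branch(parent)
            if up is None:
                break
            path.append(up)
        return path[::-1]


@dataclass(frozen=True)
class CountMatrix:
    """Subjects x taxa nonnegative integer counts."""

    values: np.ndarray
    subject_ids: list[str]
    taxon_labels: list[str]

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(v == np.floor(v)):
                raise ValueError("counts must be integers")
            v = v.astype(np.int64)
        if (v < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "values", v.astype(np.int64))
        if len(self.taxon_labels) != v.shape[1]:
            raise ValueError("taxon_labels length does not match columns")
        if len(self.subject_ids) != v.shape[0]:
            raise ValueError("subject_ids length does not match rows")


@dataclass(frozen=True)
class CovariateMatrix:
    """Subjects x covariates design matrix.

    ``center``/``scale`` record the standardization applied to each
    column (identity for indicator columns) so reports can map
    coefficients back to the original covariate scale.
    """

    values: np.ndarray
    covariate_names: list[str]
    standardized: bool = False
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("covariate matrix must be 2-dimensional")
        if not np.isfinite(v).all():
            raise ValueError("covariates must be finite")
        object.__setattr__(self, "values", v)
        if len(self.covariate_names) != v.shape[1]:
            raise ValueError("covariate_names length does not match columns")

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class NodeCounts:
    """Per-internal-node subjects x children count tables."""

    tables: list[np.ndarray]

    @property
    def n_subjects(self) -> int:
        return self.tables[0].shape[0]

    def node_totals(self, v: int) -> np.ndarray:
        return self.tables[v].sum(axis=1)


def _build(root_children, get_children, get_label) -> PhyloTree:
    """Flatten a generic rooted tree into a PhyloTree via edge depth-first."""
    node_branches: list[list[int]] = []
    branch_parent: list[int] = []
    branch_child_node: list[int] = []
    branch_labels: list[str] = []
    leaf_labels: list[str] = []
    branch_leaf_sets: list[list[int]] = []

    def visit(children) -> tuple[int, list[int]]:
        """Returns (internal node index, leaf indices under it)."""
        v = len(node_branches)
        node_branches.append([])
        my_leaves: list[int] = []
        for child in children:
            b = len(branch_labels)
            node_branches[v].append(b)
            branch_parent.append(v)
            sub = get_children(child)
            if sub:
                branch_child_node.append(-2)  # patched after recursion
                branch_labels.append("")
                branch_leaf_sets.append([])
                w, sub_leaves = visit(sub)
                branch_child_node[b] = w
                branch_labels[b] = f"node_{w}"
                branch_leaf_sets[b] = sub_leaves
                my_leaves.extend(sub_leaves)
            else:
                label = get_label(child)
                if label is None or label == "":
                    raise NewickParseError("leaf without a label")
                leaf_idx = len(leaf_labels)
                leaf_labels.append(label)
                branch_child_node.append(-1)
                branch_labels.append(label)
                branch_leaf_sets.append([leaf_idx])
                my_leaves.append(leaf_idx)
        return v, my_leaves

    visit(root_children)

    if len(set(leaf_labels)) != len(leaf_labels):
        dupes = sorted({x for x in leaf_labels if leaf_labels.count(x) > 1})
        raise TreeStructureError(f"duplicate leaf labels: {dupes}")

    return PhyloTree(
        node_branches=[np.asarray(bs, dtype=np.int64) for bs in node_branches],
        branch_parent_node=np.asarray(branch_parent, dtype=np.int64),
        branch_child_node=np.asarray(branch_child_node, dtype=np.int64),
        branch_labels=branch_labels,
        leaf_labels=leaf_labels,
        branch_leaf_sets=[np.sort(np.asarray(s, dtype=np.int64))
                          for s in branch_leaf_sets],
    )


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    Branch lengths and internal-node labels are accepted and discarded
    (the model is topology-only).  Unary internal nodes are collapsed:
    a node with a single child is a degenerate multinomial and would
    contribute non-identifiable parameters.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = getattr(exc, "col_num", None)
        where = f" near character {offset}" if offset is not None else ""
        raise NewickParseError(f"malformed Newick{where}: {exc}") from exc
    dtree.suppress_unifurcations()
    root = dtree.seed_node
    kids = root.child_nodes()
    if not kids:
        raise TreeStructureError("tree must have at least 2 leaves")

    def get_children(n):
        return n.child_nodes()

    def get_label(n):
        return n.taxon.label if n.taxon is not None else n.label

    tree = _build(kids, get_children, get_label)
    if tree.n_leaves < 2:
        raise TreeStructureError("tree must have at least 2 leaves")
    return tree


def star_tree(labels) -> PhyloTree:
    """One root with every taxon as a direct child (B = J).

    Running the full tree model on a star tree is exactly a
    Dirichlet-multinomial regression on the raw count matrix, the
    recommended fallback for large data sets where the phylogeny is
    not informative or not available.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise TreeStructureError("star tree needs at least 2 labels")
    return _build(labels, lambda n: None, lambda n: n)


def decompose_counts(counts: CountMatrix, tree: PhyloTree) -> NodeCounts:
    """Aggregate leaf counts into per-internal-node child count tables.

    The child count of branch (v, c) for subject i is the sum of
    subject i's counts over the leaves descending from c; root totals
    equal the subjects' leaf-row sums by construction.
    """
    tree_set = set(tree.leaf_labels)
    data_set = set(counts.taxon_labels)
    if tree_set != data_set:
        only_tree = sorted(tree_set - data_set)
        only_data = sorted(data_set - tree_set)
        raise LabelMismatchError(
            f"taxa mismatch; only in tree: {only_tree}; "
            f"only in counts: {only_data}")
    col_of = {lab: j for j, lab in enumerate(counts.taxon_labels)}
    order = np.asarray([col_of[lab] for lab in tree.leaf_labels])
    Y = counts.values[:, order]  # columns now in tree leaf order
    tables = []
    for bs in tree.node_branches:
        cols = [Y[:, tree.branch_leaf_sets[b]].sum(axis=1) for b in bs]
        tables.append(np.stack(cols, axis=1))
    return NodeCounts(tables=tables)


def standardize(covariates: CovariateMatrix,
                indicator_cols: set[str] | frozenset[str] = frozenset()
                ) -> CovariateMatrix:
    """Z-score continuous columns (sample sd, ddof=1); leave indicators.

    Raises on constant continuous columns, which cannot be scaled.
    """
    unknown = set(indicator_cols) - set(covariates.covariate_names)
    if unknown:
        raise ValueError(f"unknown indicator columns: {sorted(unknown)}")
    V = covariates.values.copy()
    n, P = V.shape
    center = np.zeros(P)
    scale = np.ones(P)
    for j, name in enumerate(covariates.covariate_names):
        if name in indicator_cols:
            continue
        sd = V[:, j].std(ddof=1) if n > 1 else 0.0
        if sd == 0.0:
            raise ValueError(f"constant continuous column: {name!r}")
        center[j] = V[:, j].mean()
        scale[j] = sd
        V[:, j] = (V[:, j] - center[j]) / scale[j]
    return CovariateMatrix(values=V,
                           covariate_names=list(covariates.covariate_names),
                           standardized=True, center=center, scale=scale)


# ---------------------------------------------------------------------------
# Tabular I/O: TSV/CSV with header = labels, first column = subject id.

def _read_table(path_or_buf) -> pd.DataFrame:
    sep = None  # sniff , vs tab
    return pd.read_csv(path_or_buf, sep=sep, engine="python", index_col=0)


def read_counts(path_or_buf) -> CountMatrix:
    df = _read_table(path_or_buf)
    return CountMatrix(values=df.to_numpy(),
                       subject_ids=[str(i) for i in df.index],
                       taxon_labels=[str(c) for c in df.columns])


def read_covariates(path_or_buf) -> CovariateMatrix:
    df = _read_table(path_or_buf)
    return CovariateMatrix(values=df.to_numpy(dtype=float),
                           covariate_names=[str(c) for c in df.columns])


def read_graph(path_or_buf, covariate_names: list[str]) -> np.ndarray:
    """Read a symmetric 0/1 covariate adjacency matrix (TSV/CSV).

    Rows/columns are aligned to ``covariate_names``.
    """
    df = _read_table(path_or_buf)
    cols = [str(c) for c in df.columns]
    if set(cols) != set(covariate_names):
        raise ValueError("graph covariates do not match design covariates")
    df = df.loc[covariate_names, covariate_names]
    G = df.to_numpy(dtype=float)
    if not np.array_equal(G, G.T):
        raise ValueError("adjacency matrix must be symmetric")
    if np.any(np.diag(G) != 0):
        raise ValueError("adjacency matrix must have a zero diagonal")
    return G.astype(np.int64)
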