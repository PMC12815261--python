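"""Collapse a phylogeny around a protected node set W into trait-uniform cells.

A preorder traversal marks a node N as a leaf ("cell") of the collapsed
tree T_W when N is a leaf of the input tree, or when the subtree rooted at
N -- including N itself -- contains no member of W.  Marked subtrees are
not descended into; every cell therefore is a maximal W-free subtree, and
cells partition the original leaf set.  Each cell is identified by the
clade id of its ancestral node (or the leaf name for singleton leaf
cells), summarized by per-trait medians (positive fraction for binary
traits), and located in T_W at the ancestral node with the branch length
of the path down from its retained parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, InvariantError, ParameterError
from .treeio import Phylogeny, TraitMatrix

logger = logging.getLogger(__name__)

__all__ = ["Cell", "CellSet", "collapse_tree", "summarize_cells", "patristic_matrix"]


@dataclass(frozen=True)
class Cell:
    cell_id: str
    node_index: int  # index in the source tree
    leaf_names: tuple

    @property
    def size(self) -> int:
        return len(self.leaf_names)


@dataclass
class CellSet:
    """The collapsed tree and the leaf partition it induces."""

    cells: list
    tree: Phylogeny  # T_W; its leaves are named by cell ids
    source: Phylogeny

    @property
    def cell_ids(self):
        return [c.cell_id for c in self.cells]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.cells], dtype=np.int64)

    def membership(self) -> dict:
        """leaf name -> cell id."""
        out = {}
        for c in self.cells:
            for nm in c.leaf_names:
                out[nm] = c.cell_id
        return out

    def top_cells(self, n: int) -> list:
        """The n largest cells (ties broken by cell id)."""
        return sorted(self.cells, key=lambda c: (-c.size, c.cell_id))[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_ids,
            "size": self.sizes,
            "members": [";".join(c.leaf_names) for c in self.cells],
        })


def _resolve_protected(tree: Phylogeny, W) -> set:
    index = tree.id_index()
    unknown = [w for w in W if w not in index]
    if unknown:
        raise InputError(f"protected nodes absent from tree: {', '.join(sorted(map(str, unknown)))}")
    resolved = set()
    dropped = 0
    for w in W:
        v = index[w]
        if tree.is_leaf(v):
            dropped += 1
        else:
            resolved.add(v)
    if dropped:
        logger.warning("ignoring %d leaves in the protected set W", dropped)
    return resolved


def collapse_tree(tree: Phylogeny, W) -> CellSet:
    """Collapse every maximal subtree disjoint from W into a single cell.

    ``W`` is an iterable of clade ids (leaf names are ignored with a
    warning; unknown ids raise).  W = empty collapses the whole tree into
    one cell; W = all internal nodes returns every leaf as its own cell.
    """
    protected = _resolve_protected(tree, W)
    contains = np.zeros(tree.n_nodes, dtype=bool)
    for v in tree.postorder():
        contains[v] = v in protected or any(contains[c] for c in tree.children[v])

    leafsets = None
    cells = []
    cell_of = {}  # source node index -> cell
    stack = [tree.root]
    order = []
    while stack:
        v = stack.pop()
        if tree.is_leaf(v):
            cell = Cell(tree.name[v], v, (tree.name[v],))
        elif not contains[v]:
            if leafsets is None:
                leafsets = tree.subtree_leaf_sets()
            names = tuple(tree.leaf_names[i] for i in leafsets[v])
            if tree.clade_id[v] is None:
                raise InputError("internal nodes need clade ids before collapsing; "
                                 "run assign_node_ids first")
            cell = Cell(tree.clade_id[v], v, names)
        else:
            stack.extend(reversed(tree.children[v]))
            continue
        cells.append(cell)
        cell_of[v] = cell
        order.append(v)

    total = sum(c.size for c in cells)
    if total != tree.n_leaves:
        raise InvariantError(
            f"cells cover {total} leaves but the tree has {tree.n_leaves}")

    collapsed = _build_collapsed(tree, cell_of)
    return CellSet(cells=cells, tree=collapsed, source=tree)


def _build_collapsed(tree: Phylogeny, cell_of: dict) -> Phylogeny:
    """Assemble T_W: cells become leaves; unary paths are suppressed with
    branch lengths summed."""
    new_children, new_parent, new_bl, new_name, new_cid = [], [], [], [], []

    def new_node(name, cid, bl):
        new_children.append([])
        new_parent.append(-1)
        new_bl.append(bl)
        new_name.append(name)
        new_cid.append(cid)
        return len(new_name) - 1

    mapped = {}  # source index -> (new index, accumulated stem length)
    for v in tree.postorder():
        bl = float(tree.branch_length[v]) if not np.isnan(tree.branch_length[v]) else np.nan
        if v in cell_of:
            idx = new_node(cell_of[v].cell_id, tree.clade_id[v], bl)
            mapped[v] = idx
        elif tree.children[v] and any(c in mapped for c in tree.children[v]):
            kids = [mapped[c] for c in tree.children[v] if c in mapped]
            if len(kids) == 1:
                # unary passthrough: extend the child's stem by this branch
                child = kids[0]
                if not np.isnan(bl):
                    new_bl[child] = bl + (0.0 if np.isnan(new_bl[child]) else new_bl[child])
                mapped[v] = child
            else:
                idx = new_node(tree.name[v], tree.clade_id[v], bl)
                for c in kids:
                    new_children[idx].append(c)
                    new_parent[c] = idx
                mapped[v] = idx
    # children were appended in postorder-completion order, which preserves
    # the source child order because tree.children is iterated in order
    root_new = mapped[tree.root]
    new_bl[root_new] = np.nan
    new_parent[root_new] = -1
    return Phylogeny(new_children, new_parent, np.array(new_bl, dtype=float),
                     new_name, new_cid, validate=False)


def summarize_cells(cellset: CellSet, traits: TraitMatrix, scale_mode: str = "zscore",
                    ) -> pd.DataFrame:
    """Per-cell trait summaries: medians (binary traits: positive fraction),
    optionally scaled per trait across cells.

    ``scale_mode``: "zscore" (default), "minmax", or "none".
    """
    if scale_mode not in ("zscore", "minmax", "none"):
        raise ParameterError(f"scale_mode must be zscore|minmax|none, got {scale_mode!r}")
    row_of = {nm: i for i, nm in enumerate(traits.leaf_names)}
    missing = [nm for c in cellset.cells for nm in c.leaf_names if nm not in row_of]
    if missing:
        raise InputError(f"cells reference leaves absent from the trait matrix: {missing[:5]}")
    summary = np.empty((len(cellset.cells), traits.n_traits))
    for i, cell in enumerate(cellset.cells):
        if cell.size == 0:
            raise InvariantError(f"empty cell {cell.cell_id}")
        block = traits.values[[row_of[nm] for nm in cell.leaf_names]]
        for j, kind in enumerate(traits.kinds):
            summary[i, j] = block[:, j].mean() if kind == "binary" else np.median(block[:, j])
    if scale_mode == "zscore":
        mu, sd = summary.mean(axis=0), summary.std(axis=0)
        sd[sd == 0.0] = 1.0
        summary = (summary - mu) / sd
    elif scale_mode == "minmax":
        lo, hi = summary.min(axis=0), summary.max(axis=0)
        rng = np.where(hi > lo, hi - lo, 1.0)
        summary = (summary - lo) / rng
    return pd.DataFrame(summary, index=pd.Index(cellset.cell_ids, name="cell_id"),
                        columns=traits.trait_names)


def patristic_matrix(tree: Phylogeny) -> pd.DataFrame:
    """All-pairs path-length distances between the leaves of a tree.

    Missing branch lengths fall back to the treeio default (1.0) with a
    warning.  For a collapsed tree the leaves are the cells, giving the
    cell-by-cell matrix the layout stage consumes.
    """
    names = tree.leaf_names
    m = len(names)
    D = np.zeros((m, m))
    if m > 1:
        depth = tree.node_depths()
        leaf_depth = np.array([depth[v] for v in tree.leaf_indices])
        leafsets = tree.subtree_leaf_sets()
        for v in tree.postorder():
            kids = tree.children[v]
            if not kids:
                continue
            pooled = leafsets[kids[0]]
            for k in range(1, len(kids)):
                right = leafsets[kids[k]]
                block = leaf_depth[pooled][:, None] + leaf_depth[right][None, :] - 2.0 * depth[v]
                D[np.ix_(pooled, right)] = block
                D[np.ix_(right, pooled)] = block.T
                pooled = np.concatenate([pooled, right])
    return pd.DataFrame(D, index=pd.Index(names, name="cell_id"), columns=names)
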