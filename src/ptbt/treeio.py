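"""Rooted phylogenies, trait tables, and their on-disk formats.

The central container is :class:`Phylogeny`, an array-backed rooted tree
with ordered children, optional branch lengths, verbatim leaf names and
stable internal-node ("clade") identifiers.  All traversals are iterative,
so trees with tens of thousands of leaves are handled without touching the
recursion limit.

Newick parsing goes through dendropy; serialization is done in-package so
that branch lengths round-trip at 10 significant digits and output bytes
are deterministic.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import InputError, InvariantError, ParameterError

logger = logging.getLogger(__name__)

TRAIT_KINDS = ("continuous", "probability", "binary")

#: Branch length substituted when an input tree carries none.  The wavelet
#: basis itself is purely topological; lengths only enter patristic
#: distances and Brownian-motion simulation.
DEFAULT_BRANCH_LENGTH = 1.0


class Phylogeny:
    """A rooted tree with ordered children and optional branch lengths.

    Nodes are integer-indexed; ``children[v]`` lists v's children in input
    order, ``parent[v]`` is -1 for the root, ``branch_length[v]`` is NaN
    when absent, ``name[v]`` holds the leaf name (leaves) or an input
    internal label (may be None), and ``clade_id[v]`` holds the stable
    "c######" identifier once :func:`assign_node_ids` has run.
    """

    __slots__ = (
        "children",
        "parent",
        "branch_length",
        "name",
        "clade_id",
        "root",
        "_postorder",
        "_preorder",
        "_leaf_order",
    )

    def __init__(self, children, parent, branch_length, names, clade_ids=None,
                 validate=True):
        self.children = [list(c) for c in children]
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=float)
        self.name = list(names)
        n = len(self.name)
        self.clade_id = list(clade_ids) if clade_ids is not None else [None] * n
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise InputError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self._preorder = self._compute_preorder()
        self._postorder = self._compute_postorder()
        self._leaf_order = [v for v in self._preorder if not self.children[v]]
        if validate:
            self._validate()

    # -- construction helpers -------------------------------------------------

    def _compute_preorder(self):
        out = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(self.children[v]))
        return out

    def _compute_postorder(self):
        out = []
        stack = [(self.root, 0)]
        while stack:
            v, i = stack.pop()
            if i < len(self.children[v]):
                stack.append((v, i + 1))
                stack.append((self.children[v][i], 0))
            else:
                out.append(v)
        return out

    def _validate(self):
        n = self.n_nodes
        if len(self._preorder) != n:
            raise InputError("tree contains nodes unreachable from the root (cycle or forest)")
        for v in range(n):
            for c in self.children[v]:
                if self.parent[c] != v:
                    raise InvariantError(f"child/parent mismatch at node {c}")
        leaf_names = [self.name[v] for v in self._leaf_order]
        if any(nm is None or nm == "" for nm in leaf_names):
            raise InputError("every leaf must carry a non-empty name")
        seen = set()
        for nm in leaf_names:
            if nm in seen:
                raise InputError(f"duplicate leaf name: {nm!r}")
            seen.add(nm)
        with np.errstate(invalid="ignore"):
            if np.any(self.branch_length < 0):
                raise InputError("negative branch lengths are not allowed")

    # -- basic queries ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.name)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_order)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def postorder(self):
        """Node indices, children before parents, left-to-right."""
        return list(self._postorder)

    def preorder(self):
        """Node indices, parents before children, left-to-right."""
        return list(self._preorder)

    @property
    def leaf_indices(self):
        """Leaf node indices in left-to-right (input) order."""
        return list(self._leaf_order)

    @property
    def leaf_names(self):
        return [self.name[v] for v in self._leaf_order]

    @property
    def internal_indices(self):
        return [v for v in self._postorder if self.children[v]]

    def leaf_positions(self):
        """Map node index -> position in leaf order, for leaves."""
        return {v: i for i, v in enumerate(self._leaf_order)}

    def index_of(self, ident: str) -> int:
        """Resolve a leaf name or clade id to a node index."""
        for v in range(self.n_nodes):
            if self.clade_id[v] == ident or (self.is_leaf(v) and self.name[v] == ident):
                return v
        raise InputError(f"no node with id or leaf name {ident!r}")

    def id_index(self) -> dict:
        """Mapping of clade ids and leaf names to node indices."""
        out = {}
        for v in range(self.n_nodes):
            if self.clade_id[v] is not None:
                out[self.clade_id[v]] = v
            if self.is_leaf(v):
                out[self.name[v]] = v
        return out

    def subtree_leaf_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        for v in self._postorder:
            if self.is_leaf(v):
                counts[v] = 1
            else:
                counts[v] = sum(counts[c] for c in self.children[v])
        return counts

    def subtree_leaf_sets(self):
        """Per-node arrays of leaf *positions* (left-to-right leaf order)."""
        pos = self.leaf_positions()
        sets = [None] * self.n_nodes
        for v in self._postorder:
            if self.is_leaf(v):
                sets[v] = np.array([pos[v]], dtype=np.int64)
            else:
                sets[v] = np.concatenate([sets[c] for c in self.children[v]])
        return sets

    def lengths_or_default(self, warn=True) -> np.ndarray:
        """Branch lengths with NaN (absent) replaced by 1.0; root forced to 0."""
        bl = self.branch_length.copy()
        missing = np.isnan(bl)
        missing[self.root] = False
        if missing.any() and warn:
            logger.warning(
                "%d branch lengths absent; using %.1f", int(missing.sum()),
                DEFAULT_BRANCH_LENGTH)
        bl[np.isnan(bl)] = DEFAULT_BRANCH_LENGTH
        bl[self.root] = 0.0
        return bl

    def node_depths(self, warn=True) -> np.ndarray:
        """Root-to-node path lengths (root depth 0)."""
        bl = self.lengths_or_default(warn=warn)
        depth = np.zeros(self.n_nodes)
        for v in self._preorder:
            if v != self.root:
                depth[v] = depth[self.parent[v]] + bl[v]
        return depth

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            [list(c) for c in self.children],
            self.parent.copy(),
            self.branch_length.copy(),
            list(self.name),
            list(self.clade_id),
            validate=False,
        )


# -- Newick ------------------------------------------------------------------


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree into a :class:`Phylogeny`.

    Polytomies and internal labels are preserved; children keep their
    input order.  Raises :class:`InputError` on malformed input, fewer
    than 2 leaves, or duplicate leaf names.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise InputError(f"malformed Newick: {exc}") from None

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    children = [[] for _ in range(n)]
    parent = np.full(n, -1, dtype=np.int64)
    lengths = np.full(n, np.nan)
    names = [None] * n
    for i, nd in enumerate(dnodes):
        for ch in nd.child_nodes():
            j = index[id(ch)]
            children[i].append(j)
            parent[j] = i
        if nd.edge.length is not None:
            lengths[i] = float(nd.edge.length)
        if nd.is_leaf():
            names[i] = nd.taxon.label if nd.taxon is not None else nd.label
        else:
            names[i] = nd.label
    tree = Phylogeny(children, parent, lengths, names)
    if tree.n_leaves < 2:
        raise InputError(f"tree must have at least 2 leaves, found {tree.n_leaves}")
    return tree


def read_newick(path) -> Phylogeny:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except OSError as exc:
        raise InputError(f"cannot read tree file {path}: {exc}") from None
    return parse_newick(text)


def _quote_label(label: str) -> str:
    if label and not any(ch in label for ch in "(),:;[]' \t\n"):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: Phylogeny, path=None, internal_labels: str = "name") -> str:
    """Serialize to Newick; ``internal_labels`` is 'name', 'clade_id' or 'none'."""
    if internal_labels not in ("name", "clade_id", "none"):
        raise ParameterError(f"internal_labels must be name|clade_id|none, got {internal_labels!r}")
    frag = [None] * tree.n_nodes
    for v in tree.postorder():
        if tree.is_leaf(v):
            s = _quote_label(tree.name[v])
        else:
            s = "(" + ",".join(frag[c] for c in tree.children[v]) + ")"
            if internal_labels == "name" and tree.name[v]:
                s += _quote_label(tree.name[v])
            elif internal_labels == "clade_id" and tree.clade_id[v]:
                s += _quote_label(tree.clade_id[v])
        bl = tree.branch_length[v]
        if not np.isnan(bl):
            s += ":" + format(bl, ".10g")
        frag[v] = s
    text = frag[tree.root] + ";\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def assign_node_ids(tree: Phylogeny, prefix: str = "c", width: int = 6) -> Phylogeny:
    """Assign stable clade ids ("c000000", ...) to internal nodes in postorder.

    Deterministic for a given tree (ids follow the tree's own child order)
    and idempotent: re-running reproduces identical ids.  Mutates and
    returns the same tree.
    """
    k = 0
    for v in tree.postorder():
        if not tree.is_leaf(v):
            tree.clade_id[v] = f"{prefix}{k:0{width}d}"
            k += 1
    return tree


# -- trait tables ------------------------------------------------------------


@dataclass
class TraitMatrix:
    """Leaf-by-trait values with a declared kind per trait.

    ``values`` is an (n_leaves, n_traits) float array; binary traits are
    0/1, probability traits lie in [0, 1].  Row order is the associated
    tree's left-to-right leaf order after validation.
    """

    leaf_names: list
    trait_names: list
    values: np.ndarray
    kinds: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.leaf_names), len(self.trait_names)):
            raise InputError(
                f"trait values shape {self.values.shape} does not match "
                f"{len(self.leaf_names)} leaves x {len(self.trait_names)} traits")
        if len(self.kinds) != len(self.trait_names):
            raise InputError("one kind per trait required")
        for k in self.kinds:
            if k not in TRAIT_KINDS:
                raise InputError(f"unknown trait kind {k!r}; expected one of {TRAIT_KINDS}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise InputError(
                f"non-finite trait value at leaf {self.leaf_names[i]!r}, "
                f"trait {self.trait_names[j]!r}")
        self._validate_ranges()

    def _validate_ranges(self):
        for j, kind in enumerate(self.kinds):
            col = self.values[:, j]
            if kind == "binary":
                bad = ~np.isin(col, (0.0, 1.0))
            elif kind == "probability":
                bad = (col < 0.0) | (col > 1.0)
            else:
                continue
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise InputError(
                    f"trait {self.trait_names[j]!r} is {kind} but leaf "
                    f"{self.leaf_names[i]!r} has value {col[i]!r}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def kind_of(self, trait: str) -> str:
        return self.kinds[self.trait_names.index(trait)]

    def reorder(self, leaf_names) -> "TraitMatrix":
        """Return a copy with rows in the given leaf order."""
        pos = {nm: i for i, nm in enumerate(self.leaf_names)}
        missing = [nm for nm in leaf_names if nm not in pos]
        if missing:
            raise InputError(f"leaves absent from trait table: {_preview(missing)}")
        idx = [pos[nm] for nm in leaf_names]
        return TraitMatrix(list(leaf_names), list(self.trait_names),
                           self.values[idx], list(self.kinds))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.leaf_names, name="leaf"),
                            columns=self.trait_names)

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def _preview(items, limit=10):
    items = list(items)
    shown = ", ".join(map(str, items[:limit]))
    if len(items) > limit:
        shown += f", ... ({len(items)} total)"
    return shown


def infer_trait_kinds(frame: pd.DataFrame) -> dict:
    """Heuristic schema: {0,1} columns -> binary, [0,1] -> probability, else continuous."""
    kinds = {}
    for col in frame.columns:
        vals = frame[col].to_numpy(dtype=float)
        if np.isin(vals, (0.0, 1.0)).all():
            kinds[col] = "binary"
        elif ((vals >= 0.0) & (vals <= 1.0)).all():
            kinds[col] = "probability"
        else:
            kinds[col] = "continuous"
    return kinds


def read_trait_table(path, tree: Phylogeny, schema=None) -> TraitMatrix:
    """Read a TSV with header ``leaf<TAB>trait1...`` and validate against a tree.

    Rows are reordered to the tree's leaf order.  Leaves missing from the
    table raise; table rows absent from the tree are dropped with a logged
    warning.  ``schema`` maps trait name -> kind; missing entries are
    inferred from the data.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except OSError as exc:
        raise InputError(f"cannot read trait table {path}: {exc}") from None
    except pd.errors.ParserError as exc:
        raise InputError(f"malformed trait table {path}: {exc}") from None
    if frame.shape[1] < 2 or frame.columns[0] != "leaf":
        raise InputError("trait table header must start with 'leaf' followed by trait names")
    frame = frame.set_index("leaf")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            leaf = frame.index[bad][0]
            raise InputError(
                f"non-numeric value {frame.loc[leaf, col]!r} at leaf {leaf!r}, "
                f"trait {col!r}")
        if numeric.isna().any():
            leaf = frame.index[numeric.isna()][0]
            raise InputError(f"missing value at leaf {leaf!r}, trait {col!r}")
        frame[col] = numeric
    tree_leaves = tree.leaf_names
    leaf_set = set(tree_leaves)
    extra = [nm for nm in frame.index if nm not in leaf_set]
    if extra:
        logger.warning("dropping %d trait-table rows absent from the tree", len(extra))
        frame = frame.drop(index=extra)
    missing = [nm for nm in tree_leaves if nm not in frame.index]
    if missing:
        raise InputError(f"tree leaves missing from trait table: {_preview(missing)}")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise InputError(f"duplicate trait-table row for leaf {dup!r}")
    frame = frame.loc[tree_leaves]
    schema = dict(schema or {})
    inferred = infer_trait_kinds(frame)
    kinds = [schema.get(col, inferred[col]) for col in frame.columns]
    return TraitMatrix(tree_leaves, list(frame.columns), frame.to_numpy(dtype=float), kinds)
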