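"""Synthetic trees and trait matrices with planted, recoverable structure.

The generators provide the controlled study conditions every stage is
tested under: Yule (pure-birth) trees with known depth expectations,
Brownian-motion traits, mean shifts planted at chosen internal nodes to
create functionally uniform clades, and binary traits thresholded from
latent continuous ones.  A caterpillar generator covers the worst-case
(maximally unbalanced) topology.

A shift "at node v" adds the constant delta to every leaf under v's first
child, i.e. it separates the sister clades that v's own wavelet
contrasts; the wavelet at v is the one that detects it.  delta is in raw
trait units -- use :func:`bm_root_to_leaf_sd` to express effect sizes in
units of the Brownian-motion standard deviation at the root-to-leaf
scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError
from .nullsim import bm_leaf_values
from .treeio import Phylogeny, TraitMatrix, assign_node_ids

__all__ = ["ShiftSpec", "yule_tree", "caterpillar_tree", "plant_shift_traits",
           "binarize_latent", "bm_root_to_leaf_sd", "eligible_shift_nodes"]


@dataclass(frozen=True)
class ShiftSpec:
    """A planted mean jump: trait column ``trait`` gains ``delta`` on every
    leaf under the first child of internal node ``node_id``."""

    node_id: str
    trait: int
    delta: float


def yule_tree(n: int, seed: int | None = None, rate: float = 1.0) -> Phylogeny:
    """A strictly binary pure-birth tree with n leaves.

    Waiting times while k lineages exist are Exponential(rate * k); the
    tree is ultrametric with expected root-to-leaf depth
    sum_{k=2}^{n} 1/(k * rate).  Leaves are named L00001... in
    left-to-right order; internal nodes get clade ids.
    """
    if n < 2:
        raise InputError(f"a Yule tree needs at least 2 leaves, got {n}")
    if not rate > 0:
        raise ParameterError(f"rate must be positive, got {rate}")
    rng = np.random.default_rng(seed)
    n_nodes = 2 * n - 1
    children = [[] for _ in range(n_nodes)]
    parent = np.full(n_nodes, -1, dtype=np.int64)
    birth = np.zeros(n_nodes)
    lengths = np.full(n_nodes, np.nan)

    children[0] = [1, 2]
    parent[1] = parent[2] = 0
    nxt = 3
    active = [1, 2]
    t = 0.0
    k = 2
    while k < n:
        t += rng.exponential(1.0 / (rate * k))
        i = int(rng.integers(k))
        v = active[i]
        lengths[v] = t - birth[v]
        a, b = nxt, nxt + 1
        nxt += 2
        children[v] = [a, b]
        parent[a] = parent[b] = v
        birth[a] = birth[b] = t
        active[i] = a
        active.append(b)
        k += 1
    t += rng.exponential(1.0 / (rate * n))
    for v in active:
        lengths[v] = t - birth[v]

    names = [None] * n_nodes
    tree = Phylogeny(children, parent, lengths, names, validate=False)
    for i, v in enumerate(tree.leaf_indices):
        tree.name[v] = f"L{i + 1:05d}"
    tree = Phylogeny(tree.children, tree.parent, tree.branch_length, tree.name)
    return assign_node_ids(tree)


def caterpillar_tree(n: int, branch_length: float = 1.0) -> Phylogeny:
    """A fully unbalanced (comb) tree: ((((L1,L2),L3),L4)...)."""
    if n < 2:
        raise InputError(f"a caterpillar tree needs at least 2 leaves, got {n}")
    n_nodes = 2 * n - 1
    children = [[] for _ in range(n_nodes)]
    parent = np.full(n_nodes, -1, dtype=np.int64)
    lengths = np.full(n_nodes, branch_length)
    names = [None] * n_nodes
    # nodes 0..n-1 are leaves, n..2n-2 internal; node n joins leaves 0,1
    names[:n] = [f"L{i + 1:05d}" for i in range(n)]
    prev = 0
    for i in range(n - 1):
        v = n + i
        children[v] = [prev, i + 1]
        parent[prev] = v
        parent[i + 1] = v
        prev = v
    lengths[prev] = np.nan  # root
    tree = Phylogeny(children, parent, lengths, names)
    return assign_node_ids(tree)


def bm_root_to_leaf_sd(tree: Phylogeny, sigma2: float = 1.0) -> float:
    """BM standard deviation at the root-to-leaf scale:
    sqrt(sigma2 * mean root-to-leaf depth)."""
    depth = tree.node_depths(warn=False)
    mean_depth = float(np.mean([depth[v] for v in tree.leaf_indices]))
    return float(np.sqrt(sigma2 * mean_depth))


def eligible_shift_nodes(tree: Phylogeny, min_clade: int = 1) -> list:
    """Clade ids of internal nodes at which a planted shift is cleanly
    detectable: the first child and the remaining siblings each subtend
    >= min_clade leaves, and the first child is no larger than the rest.

    The size floor keeps the contrast from being a single stray leaf; the
    balance condition (shifted clade <= opposing block) guarantees the
    node's own contrast carries more of the jump than any ancestor's --
    for an ancestor opposing blocks of sizes A >= l + r and B, the squared
    deterministic contribution l^2 B / (A (A + B)) is strictly below the
    planted l r / (l + r) whenever l <= r.
    """
    counts = tree.subtree_leaf_counts()
    out = []
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            continue
        first = counts[kids[0]]
        rest = sum(counts[c] for c in kids[1:])
        if first >= min_clade and rest >= min_clade and first <= rest:
            out.append(tree.clade_id[v])
    return out


def shift_leaf_mask(tree: Phylogeny, node_id: str) -> np.ndarray:
    """Boolean mask (leaf order) of the leaves a shift at node_id moves."""
    v = tree.id_index().get(node_id)
    if v is None or tree.is_leaf(v):
        raise InputError(f"shift node {node_id!r} is not an internal node of the tree")
    first = tree.children[v][0]
    mask = np.zeros(tree.n_leaves, dtype=bool)
    mask[tree.subtree_leaf_sets()[first]] = True
    return mask


def plant_shift_traits(tree: Phylogeny, shifts, sigma2: float = 1.0,
                       n_traits: int = 6, seed: int | None = None,
                       root_value: float = 0.0) -> TraitMatrix:
    """Brownian-motion traits with mean jumps planted at chosen nodes.

    With no shifts this is exactly one :func:`ptbt.nullsim.simulate_bm`
    replicate (same seed policy, same draws).
    """
    if n_traits < 1:
        raise ParameterError(f"n_traits must be >= 1, got {n_traits}")
    rng = np.random.default_rng(seed)
    values = bm_leaf_values(tree, rng, n_traits, sigma2, root_value)
    for s in shifts:
        if not (0 <= s.trait < n_traits):
            raise ParameterError(f"shift trait index {s.trait} outside [0, {n_traits})")
        if not np.isfinite(s.delta):
            raise ParameterError(f"shift delta must be finite, got {s.delta}")
        values[shift_leaf_mask(tree, s.node_id), s.trait] += s.delta
    names = [f"trait{j + 1}" for j in range(n_traits)]
    return TraitMatrix(tree.leaf_names, names, values, ["continuous"] * n_traits)


def binarize_latent(traits: TraitMatrix, quantile: float, columns=None) -> TraitMatrix:
    """Threshold latent continuous traits into binary ones.

    Values strictly above the per-trait empirical quantile become 1.
    ``columns`` restricts which traits are binarized (names); default all.
    """
    if not (0.0 < quantile < 1.0):
        raise ParameterError(f"quantile must lie in (0, 1), got {quantile}")
    targets = set(columns) if columns is not None else set(traits.trait_names)
    unknown = targets - set(traits.trait_names)
    if unknown:
        raise InputError(f"unknown traits to binarize: {sorted(unknown)}")
    values = traits.values.copy()
    kinds = list(traits.kinds)
    for j, name in enumerate(traits.trait_names):
        if name in targets:
            thr = np.quantile(values[:, j], quantile)
            values[:, j] = (values[:, j] > thr).astype(float)
            kinds[j] = "binary"
    return TraitMatrix(list(traits.leaf_names), list(traits.trait_names), values, kinds)


def write_truth_manifest(path, tree: Phylogeny, shifts, sigma2, n_traits, seed):
    """JSON record of the planted truth, for recovery scoring."""
    payload = {
        "n_leaves": tree.n_leaves,
        "sigma2": sigma2,
        "n_traits": n_traits,
        "seed": seed,
        "root_to_leaf_sd": bm_root_to_leaf_sd(tree, sigma2),
        "shifts": [{"node_id": s.node_id, "trait": s.trait, "delta": s.delta}
                   for s in shifts],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
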