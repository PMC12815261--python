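"""Haar-like wavelet basis on rooted trees and the trait-variance transform.

Each internal node of a rooted tree contributes one wavelet per binary
split: a unit-L2-norm, zero-sum vector over the leaves that is positive
(and constant) on one child block and negative (and constant) on the
other.  For a node with c > 2 children, c - 1 sequential (Helmert-style)
contrasts are emitted: contrast k opposes the pooled leaves of children
1..k against child k+1.  Together with the constant vector the n - 1
wavelets form an orthonormal basis of leaf-value space, so squared
coefficients decompose the total sum of squared deviations of a trait
exactly (Parseval): the squared coefficient at a node is the trait
variance uniquely attributed to that node's split.

The transform is computed in a single postorder pass accumulating subtree
sums and leaf counts, O(n) per trait; the explicit basis is only
materialized on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .treeio import Phylogeny, TraitMatrix, assign_node_ids

__all__ = ["Wavelet", "WaveletResult", "haar_basis", "transform", "variance_fractions"]

#: A trait whose total sum of squares falls below this (relative to scale)
#: is flagged degenerate: all its variance fractions are reported as zero.
_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class Wavelet:
    """One two-block contrast: +left_weight on left leaves, right_weight (<0) on right."""

    wavelet_id: str
    node_index: int
    node_id: str
    left_leaves: np.ndarray  # positions in the tree's leaf order
    right_leaves: np.ndarray
    left_weight: float
    right_weight: float

    @property
    def support(self) -> np.ndarray:
        return np.concatenate([self.left_leaves, self.right_leaves])

    def dense(self, n_leaves: int) -> np.ndarray:
        w = np.zeros(n_leaves)
        w[self.left_leaves] = self.left_weight
        w[self.right_leaves] = self.right_weight
        return w


def _ensure_ids(tree: Phylogeny) -> None:
    if any(tree.clade_id[v] is None for v in tree.internal_indices):
        assign_node_ids(tree)


def _wavelet_id(tree: Phylogeny, v: int, k: int, n_children: int) -> str:
    base = tree.clade_id[v]
    return base if n_children == 2 else f"{base}.{k}"


def haar_basis(tree: Phylogeny) -> list:
    """Explicit wavelets for every internal node (including the root).

    Returns exactly n - 1 wavelets in postorder (within a multifurcating
    node, contrasts in child order).  Intended for moderate n; large trees
    should use :func:`transform` directly, which never materializes the
    basis.
    """
    if tree.n_leaves < 2:
        raise InputError("a wavelet basis requires at least 2 leaves")
    _ensure_ids(tree)
    leafsets = tree.subtree_leaf_sets()
    out = []
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            continue
        pooled = leafsets[kids[0]]
        for k in range(1, len(kids)):
            right = leafsets[kids[k]]
            ell, r = len(pooled), len(right)
            a = math.sqrt(r / (ell * (ell + r)))
            b = -math.sqrt(ell / (r * (ell + r)))
            out.append(Wavelet(
                wavelet_id=_wavelet_id(tree, v, k, len(kids)),
                node_index=v,
                node_id=tree.clade_id[v],
                left_leaves=pooled,
                right_leaves=right,
                left_weight=a,
                right_weight=b,
            ))
            pooled = np.concatenate([pooled, right])
    return out


@dataclass
class WaveletResult:
    """Coefficients and variance fractions for every wavelet of a tree.

    ``coefficients`` is (n_wavelets, n_traits); ``total_ss`` holds each
    trait's total sum of squared deviations from its mean, which the
    squared coefficients recover exactly (Parseval identity).
    """

    trait_names: list
    wavelet_ids: list
    node_ids: list
    node_indices: np.ndarray
    subtree_sizes: np.ndarray  # leaves under the wavelet's node
    coefficients: np.ndarray
    total_ss: np.ndarray
    degenerate: np.ndarray  # bool per trait

    @property
    def n_wavelets(self) -> int:
        return len(self.wavelet_ids)

    def variance_fractions(self) -> np.ndarray:
        """Squared coefficients over total SS; all-zero for degenerate traits."""
        frac = np.zeros_like(self.coefficients)
        for j in range(len(self.trait_names)):
            if not self.degenerate[j]:
                frac[:, j] = self.coefficients[:, j] ** 2 / self.total_ss[j]
        return frac

    def trait_index(self, trait: str) -> int:
        try:
            return self.trait_names.index(trait)
        except ValueError:
            raise InputError(f"unknown trait {trait!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (wavelet, trait)."""
        frac = self.variance_fractions()
        m, p = self.coefficients.shape
        return pd.DataFrame({
            "wavelet_id": np.repeat(self.wavelet_ids, p),
            "node_id": np.repeat(self.node_ids, p),
            "trait": np.tile(self.trait_names, m),
            "coefficient": self.coefficients.ravel(),
            "variance_fraction": frac.ravel(),
            "subtree_size": np.repeat(self.subtree_sizes, p),
        })


def transform(tree: Phylogeny, traits: TraitMatrix) -> WaveletResult:
    """Wavelet coefficients for every trait via one postorder pass.

    The coefficient of the contrast (pooled left block L, right block R)
    is sqrt(|L||R|/(|L|+|R|)) * (mean_L - mean_R), identical to the dense
    inner product with the explicit wavelet but O(n) per trait.  Earlier
    children weigh positive (sign convention; only magnitudes matter
    downstream).
    """
    if traits.leaf_names != tree.leaf_names:
        raise InputError("trait rows are not in the tree's leaf order; "
                         "use TraitMatrix.reorder(tree.leaf_names)")
    if tree.n_leaves < 2:
        raise InputError("transform requires at least 2 leaves")
    _ensure_ids(tree)
    X = traits.values
    n, p = X.shape
    sums = np.zeros((tree.n_nodes, p))
    counts = np.zeros(tree.n_nodes, dtype=np.int64)
    pos = tree.leaf_positions()

    wavelet_ids, node_ids, node_indices, sizes, coef_rows = [], [], [], [], []
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            sums[v] = X[pos[v]]
            counts[v] = 1
            continue
        pooled_sum = sums[kids[0]].copy()
        pooled_n = int(counts[kids[0]])
        for k in range(1, len(kids)):
            c = kids[k]
            r_n = int(counts[c])
            scale = math.sqrt(pooled_n * r_n / (pooled_n + r_n))
            coef_rows.append(scale * (pooled_sum / pooled_n - sums[c] / r_n))
            wavelet_ids.append(_wavelet_id(tree, v, k, len(kids)))
            node_ids.append(tree.clade_id[v])
            node_indices.append(v)
            pooled_sum += sums[c]
            pooled_n += r_n
        sums[v] = pooled_sum
        counts[v] = pooled_n
        sizes.extend([pooled_n] * (len(kids) - 1))

    coefficients = np.array(coef_rows)
    centered = X - X.mean(axis=0)
    total_ss = (centered ** 2).sum(axis=0)
    scale_sq = np.maximum(np.abs(X).max(axis=0), 1.0) ** 2
    degenerate = total_ss <= _DEGENERATE_RTOL * n * scale_sq
    return WaveletResult(
        trait_names=list(traits.trait_names),
        wavelet_ids=wavelet_ids,
        node_ids=node_ids,
        node_indices=np.array(node_indices, dtype=np.int64),
        subtree_sizes=np.array(sizes, dtype=np.int64),
        coefficients=coefficients,
        total_ss=total_ss,
        degenerate=degenerate,
    )


def variance_fractions(result: WaveletResult) -> np.ndarray:
    """Module-level alias for :meth:`WaveletResult.variance_fractions`."""
    return result.variance_fractions()


def reconstruct(tree: Phylogeny, result: WaveletResult, traits_mean: np.ndarray) -> np.ndarray:
    """Rebuild leaf values from the mean and all wavelet coefficients.

    Dense (uses the explicit basis); provided for verification and for
    inspecting how much signal a truncated coefficient set retains.
    """
    basis = haar_basis(tree)
    n = tree.n_leaves
    X = np.tile(np.asarray(traits_mean, dtype=float), (n, 1))
    for i, w in enumerate(basis):
        X += np.outer(w.dense(n), result.coefficients[i])
    return X
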