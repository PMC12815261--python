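"""Cumulative-variance node selection and multi-trait co-occurrence.

For each trait, wavelets are ranked by variance fraction (ties broken by
wavelet id) and the shortest prefix whose cumulative fraction reaches the
threshold tau (default 0.60) is selected.  The per-trait selections are
unioned into the node set W that the collapse stage must preserve, and
per-node trait counts quantify how often the same split carries large
variance for several traits at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .haar import WaveletResult

__all__ = [
    "SelectionParams", "SelectionResult", "variance_curve", "select_nodes",
    "union_selected", "cooccurrence_counts", "select_variance_nodes",
]

# Tolerance absorbing floating-point accumulation error in cumulative sums;
# tau = 1.0 must select every nonzero wavelet.
_CUM_TOL = 1e-9


@dataclass(frozen=True)
class SelectionParams:
    """Threshold tau in (0, 1]; ties always break by ascending wavelet id."""

    threshold: float = 0.60

    def __post_init__(self):
        if not (0.0 < self.threshold <= 1.0):
            raise ParameterError(f"threshold must lie in (0, 1], got {self.threshold}")


def variance_curve(result: WaveletResult, trait: str) -> pd.DataFrame:
    """Ranked cumulative-variance curve for one trait.

    Zero-fraction wavelets are dropped; a degenerate (constant) trait
    yields an empty curve with ``attrs['degenerate'] = True``.
    """
    j = result.trait_index(trait)
    frac = result.variance_fractions()[:, j]
    df = pd.DataFrame({
        "wavelet_id": result.wavelet_ids,
        "node_id": result.node_ids,
        "fraction": frac,
    })
    df = df[df["fraction"] > 0.0]
    df = df.sort_values(["fraction", "wavelet_id"], ascending=[False, True],
                        kind="mergesort", ignore_index=True)
    df["cumulative"] = df["fraction"].cumsum()
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["trait"] = trait
    df.attrs["degenerate"] = bool(result.degenerate[j])
    return df


def select_nodes(curve: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Shortest curve prefix whose cumulative fraction reaches the threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ParameterError(f"threshold must lie in (0, 1], got {threshold}")
    if len(curve) == 0:
        return curve
    cum = curve["cumulative"].to_numpy()
    target = min(threshold, cum[-1])  # tau = 1 -> everything nonzero
    k = int(np.searchsorted(cum, target - _CUM_TOL, side="left"))
    return curve.iloc[: k + 1].copy()


def union_selected(per_trait) -> set:
    """Union of per-trait node-id selections (the collapse-protected set W)."""
    W = set()
    for ids in dict(per_trait).values():
        W.update(ids)
    return W


def cooccurrence_counts(per_trait):
    """Per-node count of traits selecting it, plus S = #{nodes with count >= 2}."""
    counts = {}
    for ids in dict(per_trait).values():
        for nid in set(ids):
            counts[nid] = counts.get(nid, 0) + 1
    shared = sum(1 for c in counts.values() if c >= 2)
    return counts, shared


@dataclass
class SelectionResult:
    """Per-trait selections, their union W, and co-occurrence summaries."""

    threshold: float
    per_trait: dict  # trait -> selected-prefix DataFrame
    union: set = field(init=False)
    counts: dict = field(init=False)
    shared_node_count: int = field(init=False)

    def __post_init__(self):
        per_node = {t: df["node_id"].tolist() for t, df in self.per_trait.items()}
        self.union = union_selected(per_node)
        self.counts, self.shared_node_count = cooccurrence_counts(per_node)

    def selected_node_ids(self, trait: str):
        return self.per_trait[trait]["node_id"].tolist()

    def count_histogram(self) -> dict:
        """#nodes selected by exactly k traits, for k = 1..n_traits."""
        hist = {}
        for c in self.counts.values():
            hist[c] = hist.get(c, 0) + 1
        return dict(sorted(hist.items()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for trait, df in self.per_trait.items():
            d = df.copy()
            d.insert(0, "trait", trait)
            rows.append(d)
        if not rows:
            return pd.DataFrame(
                columns=["trait", "wavelet_id", "node_id", "fraction", "cumulative", "rank"])
        return pd.concat(rows, ignore_index=True)


def select_variance_nodes(result: WaveletResult, params: SelectionParams = SelectionParams(),
                          ) -> SelectionResult:
    """Run curve construction and prefix selection for every trait."""
    per_trait = {}
    for trait in result.trait_names:
        curve = variance_curve(result, trait)
        per_trait[trait] = select_nodes(curve, params.threshold)
    return SelectionResult(threshold=params.threshold, per_trait=per_trait)
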