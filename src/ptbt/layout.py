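"""Periodic-table layout: joint embedding, grid snapping, and rendering.

Phylogenetic (patristic) and trait (Euclidean on scaled cell summaries)
dissimilarities are each rescaled by their median off-diagonal entry and
blended with weight alpha; the blend is embedded in 2-D with a
stochastic-neighbor embedding (t-SNE on the precomputed dissimilarity),
cells are snapped to a near-square grid by minimum-total-squared-
displacement optimal assignment, and grid positions are grouped into k
proximity clusters with k-means.  The SVG renderer maps each trait to one
visual channel (fill, size, hatching, or a glyph) and emits
byte-deterministic output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["LayoutParams", "LayoutResult", "blend_dissimilarities", "embed",
           "snap_to_grid", "cluster_layout", "layout_cells", "render_table",
           "default_style", "grid_shape_for"]


@dataclass(frozen=True)
class LayoutParams:
    """alpha blends phylogenetic (1.0) vs trait (0.0) dissimilarity."""

    alpha: float = 0.5
    perplexity: float = 50.0
    iterations: int = 4000
    k_clusters: int = 10
    grid_shape: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not self.perplexity > 0:
            raise ParameterError(f"perplexity must be positive, got {self.perplexity}")
        if self.iterations < 250:
            raise ParameterError(f"iterations must be >= 250, got {self.iterations}")
        if self.k_clusters < 1:
            raise ParameterError(f"k_clusters must be >= 1, got {self.k_clusters}")


def _check_dissimilarity(D: np.ndarray, name: str) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InputError(f"{name} must be square, got shape {D.shape}")
    if not np.allclose(D, D.T, atol=1e-8):
        raise InputError(f"{name} must be symmetric")
    if np.any(D < 0):
        raise InputError(f"{name} must be non-negative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise InputError(f"{name} must have a zero diagonal")
    return D


def blend_dissimilarities(D_phylo, D_trait, alpha: float = 0.5) -> np.ndarray:
    """Median-rescaled convex combination alpha*phylo + (1-alpha)*trait."""
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must lie in [0, 1], got {alpha}")
    Dp = _check_dissimilarity(np.asarray(getattr(D_phylo, "values", D_phylo)), "D_phylo")
    Dt = _check_dissimilarity(np.asarray(getattr(D_trait, "values", D_trait)), "D_trait")
    if Dp.shape != Dt.shape:
        raise InputError(f"matrix shapes differ: {Dp.shape} vs {Dt.shape}")

    def rescaled(D):
        m = D.shape[0]
        off = D[~np.eye(m, dtype=bool)]
        med = np.median(off) if off.size else 1.0
        return D / med if med > 0 else D

    out = alpha * rescaled(Dp) + (1.0 - alpha) * rescaled(Dt)
    np.fill_diagonal(out, 0.0)
    return out


def embed(D: np.ndarray, params: LayoutParams = LayoutParams()) -> np.ndarray:
    """2-D stochastic-neighbor embedding of a dissimilarity matrix.

    Deterministic for a fixed seed; coordinates are centered at the
    origin.  Perplexity is clamped below (m - 1) / 3 when the instance is
    small.  With fewer than 4 points t-SNE is ill-posed and classical
    metric scaling is used instead (logged).
    """
    D = _check_dissimilarity(np.asarray(getattr(D, "values", D)), "D")
    m = D.shape[0]
    if m < 4:
        logger.warning("only %d points; falling back to classical metric scaling", m)
        coords = _classical_mds(D)
    else:
        perplexity = min(params.perplexity, (m - 1) / 3.0)
        if perplexity < params.perplexity:
            logger.info("clamping perplexity from %g to %g for m=%d",
                        params.perplexity, perplexity, m)
        tsne = TSNE(
            n_components=2,
            metric="precomputed",
            init="random",
            perplexity=perplexity,
            max_iter=params.iterations,
            random_state=params.seed,
        )
        coords = tsne.fit_transform(D)
    coords = np.asarray(coords, dtype=float)
    return coords - coords.mean(axis=0)


def _classical_mds(D: np.ndarray) -> np.ndarray:
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(m)])
    # deterministic sign: largest-magnitude entry of each axis positive
    for j in range(2):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


def grid_shape_for(m: int) -> tuple:
    """Smallest near-square grid (|rows-cols| <= 1) with rows*cols >= m."""
    cols = int(math.ceil(math.sqrt(m)))
    rows = int(math.ceil(m / cols))
    return rows, cols


def snap_to_grid(coords: np.ndarray, grid_shape: tuple | None = None):
    """Optimal assignment of points to lattice slots spanning their bounding box.

    Returns (grid_rows, grid_cols, (rows, cols)).  The assignment
    minimizes total squared displacement (Hungarian algorithm) and is a
    bijection of cells into grid slots.
    """
    coords = np.asarray(coords, dtype=float)
    m = coords.shape[0]
    rows, cols = grid_shape if grid_shape is not None else grid_shape_for(m)
    if rows * cols < m:
        raise ParameterError(f"grid {rows}x{cols} cannot hold {m} cells")
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    xs = np.linspace(xmin, xmax, cols) if cols > 1 else np.array([(xmin + xmax) / 2])
    ys = np.linspace(ymax, ymin, rows) if rows > 1 else np.array([(ymin + ymax) / 2])
    slot_rc = np.array([(r, c) for r in range(rows) for c in range(cols)])
    slot_xy = np.column_stack([xs[slot_rc[:, 1]], ys[slot_rc[:, 0]]])
    cost = ((coords[:, None, :] - slot_xy[None, :, :]) ** 2).sum(axis=2)
    ri, ci = linear_sum_assignment(cost)
    assignment = np.empty((m, 2), dtype=np.int64)
    assignment[ri] = slot_rc[ci]
    return assignment[:, 0], assignment[:, 1], (rows, cols)


def cluster_layout(grid_positions: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means on grid positions; labels 1..k numbered in reading order.

    Reading order: clusters sorted by centroid (row, then column), so
    label 1 sits nearest the top-left of the table.
    """
    pos = np.asarray(grid_positions, dtype=float)
    m = pos.shape[0]
    if k > m:
        raise ParameterError(f"k={k} clusters exceed m={m} cells")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(pos)
    order = np.lexsort((km.cluster_centers_[:, 1], km.cluster_centers_[:, 0]))
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(1, k + 1)
    return relabel[raw]


@dataclass
class LayoutResult:
    """Embedded coordinates, grid slots, and cluster labels per cell."""

    cell_ids: list
    coords: np.ndarray
    grid_rows: np.ndarray
    grid_cols: np.ndarray
    grid_shape: tuple
    clusters: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_ids,
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
            "grid_row": self.grid_rows,
            "grid_col": self.grid_cols,
            "cluster": self.clusters,
        })


def layout_cells(D_phylo: pd.DataFrame, summaries: pd.DataFrame,
                 params: LayoutParams = LayoutParams()) -> LayoutResult:
    """Full layout pipeline: blend -> embed -> snap -> cluster."""
    if list(D_phylo.index) != list(summaries.index):
        raise InputError("patristic matrix and summaries must list the same cells "
                         "in the same order")
    vals = summaries.to_numpy(dtype=float)
    diff = vals[:, None, :] - vals[None, :, :]
    D_trait = np.sqrt((diff ** 2).sum(axis=2))
    D = blend_dissimilarities(D_phylo.to_numpy(dtype=float), D_trait, params.alpha)
    coords = embed(D, params)
    grid_rows, grid_cols, shape = snap_to_grid(coords, params.grid_shape)
    k = min(params.k_clusters, len(summaries))
    clusters = cluster_layout(np.column_stack([grid_rows, grid_cols]), k, params.seed)
    return LayoutResult(
        cell_ids=list(summaries.index),
        coords=coords,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        grid_shape=shape,
        clusters=clusters,
    )


# -- rendering ---------------------------------------------------------------

_CHANNELS = ("fill", "size", "hatch", "glyph")
_CELL = 64  # px per grid slot
_PAD = 8


def default_style(trait_names, kinds=None) -> dict:
    """Assign each trait a visual channel: continuous traits get fill, then
    size, then hatch; binary traits get glyphs; leftovers cycle hatch."""
    kinds = list(kinds) if kinds is not None else ["continuous"] * len(trait_names)
    style = {}
    cont_channels = ["fill", "size", "hatch"]
    glyphs = ["circle", "triangle", "square", "diamond"]
    ci = gi = 0
    for name, kind in zip(trait_names, kinds):
        if kind == "binary" and gi < len(glyphs):
            style[name] = {"channel": "glyph", "glyph": glyphs[gi]}
            gi += 1
        elif ci < len(cont_channels):
            style[name] = {"channel": cont_channels[ci]}
            ci += 1
        else:
            style[name] = {"channel": "hatch"}
    return style


def _fill_color(t: float) -> str:
    """Blue (low) -> white -> red (high), t in [0, 1]."""
    t = min(max(t, 0.0), 1.0)
    if t < 0.5:
        f = t / 0.5
        r, g, b = int(59 + (255 - 59) * f), int(76 + (255 - 76) * f), 255
    else:
        f = (t - 0.5) / 0.5
        r, g, b = 255, int(255 - (255 - 65) * f), int(255 - (255 - 54) * f)
    return f"#{r:02x}{g:02x}{b:02x}"


def _norm_columns(summaries: pd.DataFrame) -> pd.DataFrame:
    vals = summaries.to_numpy(dtype=float)
    lo, hi = vals.min(axis=0), vals.max(axis=0)
    rng = np.where(hi > lo, hi - lo, 1.0)
    return pd.DataFrame((vals - lo) / rng, index=summaries.index,
                        columns=summaries.columns)


def _glyph_svg(shape: str, cx: float, cy: float, r: float) -> str:
    f = "%.2f"
    if shape == "circle":
        return f'<circle cx="{cx:.2f}" cy="{cy:.2f}" r="{r:.2f}" fill="#222222"/>'
    if shape == "triangle":
        pts = [(cx, cy - r), (cx - r, cy + r), (cx + r, cy + r)]
    elif shape == "square":
        pts = [(cx - r, cy - r), (cx + r, cy - r), (cx + r, cy + r), (cx - r, cy + r)]
    else:  # diamond
        pts = [(cx, cy - r), (cx + r, cy), (cx, cy + r), (cx - r, cy)]
    p = " ".join(f"{x:.2f},{y:.2f}" for x, y in pts)
    return f'<polygon points="{p}" fill="#222222"/>'


def render_table(summaries: pd.DataFrame, layout: LayoutResult,
                 style: dict | None = None) -> str:
    """Deterministic SVG periodic table: one group per cell at its grid slot.

    Every trait column of ``summaries`` must be mapped to a channel in
    ``style`` (see :func:`default_style`); an unmapped trait raises.
    """
    if list(summaries.index) != list(layout.cell_ids):
        raise InputError("summaries and layout must list the same cells in the same order")
    style = default_style(list(summaries.columns)) if style is None else style
    for trait in summaries.columns:
        spec = style.get(trait)
        if not spec or "channel" not in spec:
            raise InputError(f"trait {trait!r} has no visual channel in the style")
        if spec["channel"] not in _CHANNELS:
            raise InputError(f"trait {trait!r} maps to unknown channel {spec['channel']!r}")

    norm = _norm_columns(summaries)
    by_channel = {ch: [t for t in summaries.columns if style[t]["channel"] == ch]
                  for ch in _CHANNELS}
    rows, cols = layout.grid_shape
    legend_h = 20 * len(summaries.columns) + 28
    width = cols * _CELL + 2 * _PAD
    height = rows * _CELL + 2 * _PAD + legend_h
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        '<rect width="100%" height="100%" fill="#ffffff"/>',
    ]
    for i, cell_id in enumerate(layout.cell_ids):
        x0 = _PAD + int(layout.grid_cols[i]) * _CELL
        y0 = _PAD + int(layout.grid_rows[i]) * _CELL
        fill = "#f0f0f0"
        if by_channel["fill"]:
            fill = _fill_color(float(norm.iloc[i][by_channel["fill"][0]]))
        scale = 1.0
        if by_channel["size"]:
            scale = 0.55 + 0.45 * float(norm.iloc[i][by_channel["size"][0]])
        side = (_CELL - 6) * scale
        rx = x0 + (_CELL - side) / 2
        ry = y0 + (_CELL - side) / 2
        parts = [f'<g id="cell-{cell_id}">',
                 f'<rect x="{rx:.2f}" y="{ry:.2f}" width="{side:.2f}" height="{side:.2f}" '
                 f'fill="{fill}" stroke="#444444" stroke-width="1"/>']
        for j, trait in enumerate(by_channel["hatch"]):
            n_lines = int(round(4 * float(norm.iloc[i][trait])))
            for q in range(n_lines):
                yy = ry + side * (q + 1) / (n_lines + 1)
                parts.append(f'<line x1="{rx:.2f}" y1="{yy:.2f}" x2="{rx + side:.2f}" '
                             f'y2="{yy:.2f}" stroke="#666666" stroke-width="0.8"/>')
        for j, trait in enumerate(by_channel["glyph"]):
            if float(summaries.iloc[i][trait]) > 0.5:
                gx = x0 + 10 + 12 * j
                parts.append(_glyph_svg(style[trait].get("glyph", "circle"),
                                        gx, y0 + 10, 4.0))
        parts.append(f'<text x="{x0 + _CELL / 2:.2f}" y="{y0 + _CELL - 8:.2f}" '
                     f'font-size="8" text-anchor="middle" fill="#111111">{cell_id}</text>')
        parts.append(f'<text x="{x0 + _CELL - 10:.2f}" y="{y0 + 12:.2f}" font-size="8" '
                     f'text-anchor="middle" fill="#888888">{int(layout.clusters[i])}</text>')
        parts.append("</g>")
        out.append("".join(parts))
    # legend
    ly = rows * _CELL + 2 * _PAD + 14
    out.append(f'<text x="{_PAD}" y="{ly}" font-size="11" fill="#111111">Legend'
               " (cluster number top-right of each cell)</text>")
    for t, trait in enumerate(summaries.columns):
        ch = style[trait]["channel"]
        desc = {"fill": "cell color (blue low, red high)",
                "size": "inner square size",
                "hatch": "hatch line density",
                "glyph": f"{style[trait].get('glyph', 'circle')} glyph when positive"}[ch]
        out.append(f'<text x="{_PAD}" y="{ly + 18 * (t + 1)}" font-size="10" '
                   f'fill="#333333">{trait}: {desc}</text>')
    out.append("</svg>")
    return "\n".join(out) + "\n"
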