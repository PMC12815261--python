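"""Dissimilarity blending, embedding, grid snapping, clustering, rendering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ptbt import (InputError, LayoutParams, LayoutResult, ParameterError,
                  blend_dissimilarities, embed, layout_cells, render_table,
                  snap_to_grid)
from ptbt.layout import cluster_layout, default_style, grid_shape_for


def _random_metric(m, seed):
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((m, 2))
    D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return D


class TestBlend:
    def test_alpha_endpoints(self):
        Dp, Dt = _random_metric(6, 0), _random_metric(6, 1)
        def rescale(D):
            return D / np.median(D[~np.eye(6, dtype=bool)])
        np.testing.assert_allclose(blend_dissimilarities(Dp, Dt, 1.0), rescale(Dp))
        np.testing.assert_allclose(blend_dissimilarities(Dp, Dt, 0.0), rescale(Dt))

    def test_hand_arithmetic_three_by_three(self):
        Dp = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0.]])  # median 2
        Dt = np.array([[0, 10, 10], [10, 0, 10], [10, 10, 0.]])  # median 10
        D = blend_dissimilarities(Dp, Dt, 0.5)
        assert D[0, 1] == pytest.approx(0.5 * 2 / 2 + 0.5 * 10 / 10)

    def test_invalid_inputs_rejected(self):
        D = _random_metric(5, 2)
        with pytest.raises(InputError, match="symmetric"):
            blend_dissimilarities(D + np.triu(np.ones((5, 5)), 1), D, 0.5)
        with pytest.raises(InputError, match="non-negative"):
            blend_dissimilarities(-D, D, 0.5)

    def test_triangle_inequality_preserved(self):
        Dp, Dt = _random_metric(8, 3), _random_metric(8, 4)
        D = blend_dissimilarities(Dp, Dt, 0.3)
        assert (D[:, :, None] + D[None, :, :] >= D[:, None, :] - 1e-9).all()


class TestEmbed:
    def test_same_seed_identical(self):
        D = _random_metric(25, 5)
        p = LayoutParams(perplexity=5, iterations=300, seed=7)
        np.testing.assert_array_equal(embed(D, p), embed(D, p))

    def test_three_equidistant_points(self):
        D = np.full((3, 3), 1.0)
        np.fill_diagonal(D, 0.0)
        coords = embed(D)
        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        off = d[~np.eye(3, dtype=bool)]
        assert off.max() / off.min() == pytest.approx(1.0, rel=0.05)

    def test_blob_structure_recovered(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 0.5, (20, 2)),
                         rng.normal(10, 0.5, (20, 2))])
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        coords = embed(D, LayoutParams(perplexity=10, iterations=500, seed=1))
        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        iu = np.triu_indices(40, 1)
        assert spearmanr(D[iu], d[iu]).statistic > 0.5

    def test_coordinates_centered(self):
        coords = embed(_random_metric(20, 8),
                       LayoutParams(perplexity=5, iterations=300, seed=2))
        np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-6)


class TestSnapToGrid:
    def test_grid_shape_near_square(self):
        for m in (1, 2, 5, 7, 12, 50, 272):
            r, c = grid_shape_for(m)
            assert r * c >= m
            assert abs(r - c) <= 1

    def test_points_on_slots_identity(self):
        coords = np.array([[0.0, 1.0], [1.0, 1.0], [0.0, 0.0], [1.0, 0.0]])
        rows, cols, shape = snap_to_grid(coords, (2, 2))
        # (0,1) is top-left -> row 0, col 0
        np.testing.assert_array_equal(rows, [0, 0, 1, 1])
        np.testing.assert_array_equal(cols, [0, 1, 0, 1])

    def test_in_order_assignment_verified_by_brute_force(self):
        coords = np.array([[0.0, 0.0], [0.9, 0.0], [2.0, 0.0]])
        rows, cols, shape = snap_to_grid(coords, (1, 3))
        np.testing.assert_array_equal(cols, [0, 1, 2])
        assert _assignment_cost(coords, rows, cols, shape) == \
            pytest.approx(_brute_force_cost(coords, shape))

    @pytest.mark.parametrize("seed", range(8))
    def test_optimal_for_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 8))
        coords = rng.standard_normal((m, 2))
        shape = grid_shape_for(m)
        rows, cols, shape = snap_to_grid(coords, shape)
        assert len(set(zip(rows, cols))) == m  # bijection into slots
        assert _assignment_cost(coords, rows, cols, shape) == \
            pytest.approx(_brute_force_cost(coords, shape))

    def test_grid_too_small_rejected(self):
        with pytest.raises(ParameterError):
            snap_to_grid(np.zeros((5, 2)), (2, 2))


def _slot_xy(coords, shape):
    rows, cols = shape
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    xs = np.linspace(xmin, xmax, cols) if cols > 1 else np.array([(xmin + xmax) / 2])
    ys = np.linspace(ymax, ymin, rows) if rows > 1 else np.array([(ymin + ymax) / 2])
    rc = np.array([(r, c) for r in range(rows) for c in range(cols)])
    return rc, np.column_stack([xs[rc[:, 1]], ys[rc[:, 0]]])


def _assignment_cost(coords, rows, cols, shape):
    rc, xy = _slot_xy(coords, shape)
    lookup = {tuple(p): i for i, p in enumerate(rc)}
    idx = [lookup[(r, c)] for r, c in zip(rows, cols)]
    return ((coords - xy[idx]) ** 2).sum()


def _brute_force_cost(coords, shape):
    rc, xy = _slot_xy(coords, shape)
    m = len(coords)
    best = np.inf
    for perm in itertools.permutations(range(len(rc)), m):
        cost = ((coords - xy[list(perm)]) ** 2).sum()
        best = min(best, cost)
    return best


class TestClusterLayout:
    def test_k_equals_m_singletons(self):
        pos = np.array([[0, 0], [0, 5], [5, 0], [5, 5.]])
        labels = cluster_layout(pos, 4, seed=0)
        assert sorted(labels) == [1, 2, 3, 4]

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(3)
        pos = np.vstack([rng.normal(0, 0.3, (12, 2)),
                         rng.normal(20, 0.3, (12, 2))])
        labels = cluster_layout(pos, 2, seed=0)
        assert len(set(labels[:12])) == 1
        assert len(set(labels[12:])) == 1
        assert labels[0] != labels[12]

    def test_reading_order_numbering(self):
        pos = np.array([[10.0, 10], [10, 11], [0, 0], [0, 1]])  # (row, col)
        labels = cluster_layout(pos, 2, seed=0)
        # the cluster with the smaller centroid row comes first
        assert labels[2] == labels[3] == 1
        assert labels[0] == labels[1] == 2

    def test_determinism_and_k_validation(self):
        pos = np.random.default_rng(1).normal(size=(10, 2))
        np.testing.assert_array_equal(cluster_layout(pos, 3, seed=5),
                                      cluster_layout(pos, 3, seed=5))
        with pytest.raises(ParameterError):
            cluster_layout(pos, 11, seed=0)


class TestRenderTable:
    def _layout(self, m, seed=0):
        rng = np.random.default_rng(seed)
        summaries = pd.DataFrame(
            rng.normal(size=(m, 3)),
            index=pd.Index([f"c{i:06d}" for i in range(m)], name="cell_id"),
            columns=["gc", "size", "aerobe"])
        summaries["aerobe"] = (summaries["aerobe"] > 0).astype(float)
        D = _random_metric(m, seed)
        params = LayoutParams(perplexity=3, iterations=300, seed=seed,
                              k_clusters=min(3, m))
        return summaries, layout_cells(pd.DataFrame(D, index=summaries.index,
                                                    columns=summaries.index),
                                       summaries, params)

    def test_one_group_per_cell(self):
        summaries, lay = self._layout(9)
        svg = render_table(summaries, lay)
        assert svg.count("<g id=\"cell-") == 9

    def test_unmapped_trait_rejected(self):
        summaries, lay = self._layout(5)
        style = default_style(["gc", "size"])  # 'aerobe' missing
        with pytest.raises(InputError, match="aerobe"):
            render_table(summaries, lay, style)

    def test_byte_determinism(self):
        summaries, lay = self._layout(7)
        assert render_table(summaries, lay) == render_table(summaries, lay)


def test_layout_pipeline_end_to_end_determinism():
    rng = np.random.default_rng(9)
    m = 15
    summaries = pd.DataFrame(rng.normal(size=(m, 4)),
                             index=[f"c{i:06d}" for i in range(m)],
                             columns=list("abcd"))
    D = pd.DataFrame(_random_metric(m, 10), index=summaries.index,
                     columns=summaries.index)
    params = LayoutParams(perplexity=4, iterations=300, seed=123, k_clusters=4)
    lay1 = layout_cells(D, summaries, params)
    lay2 = layout_cells(D, summaries, params)
    pd.testing.assert_frame_equal(lay1.to_frame(), lay2.to_frame())
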