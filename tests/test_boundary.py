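import numpy as np
import pytest

from veinroi import (
    BoundaryDetectionError,
    assemble_boundary,
    classify_quality,
    detect_quadrant_edge,
    longest_horizontal_component,
    split_quadrants,
)
from veinroi.boundary import QuadrantEdge
from veinroi.threshold import binarize_at_sigma, gradient_stats


class TestSplit:
    def test_even_split_gives_four_equal_parts(self):
        views = split_quadrants(100, 200)
        assert all(v.n_rows == 50 and v.n_cols == 100 for v in views.values())

    def test_odd_split_puts_remainder_right_and_bottom(self):
        v = split_quadrants(101, 201)
        assert (v["UL"].n_rows, v["UL"].n_cols) == (50, 100)
        assert (v["UR"].n_rows, v["UR"].n_cols) == (50, 101)
        assert (v["LL"].n_rows, v["LL"].n_cols) == (51, 100)
        assert (v["LR"].n_rows, v["LR"].n_cols) == (51, 101)
        assert (v["LR"].row_offset, v["LR"].col_offset) == (50, 100)

    def test_views_tile_the_image_exactly(self):
        views = split_quadrants(37, 53)
        cover = np.zeros((37, 53), dtype=int)
        for v in views.values():
            cover[v.rows, v.cols] += 1
        assert (cover == 1).all()

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            split_quadrants(1, 50)


class TestLongestComponent:
    def test_full_width_row_spans_all_columns(self):
        B = np.zeros((10, 30), dtype=bool)
        B[4, :] = True
        comp = longest_horizontal_component(B)
        assert comp.span_cols == 30 and comp.n_pixels == 30

    def test_widest_of_two_runs_wins(self):
        B = np.zeros((10, 50), dtype=bool)
        B[2, 0:10] = True
        B[7, 20:45] = True
        comp = longest_horizontal_component(B)
        assert comp.span_cols == 25
        assert set(comp.rows) == {7}

    def test_diagonal_staircase_is_one_component(self):
        n = 12
        B = np.zeros((n, n), dtype=bool)
        B[np.arange(n), np.arange(n)] = True  # corner-to-corner steps
        comp = longest_horizontal_component(B)
        assert comp.span_cols == n and comp.n_pixels == n

    def test_empty_mask_gives_none(self):
        assert longest_horizontal_component(np.zeros((5, 5), dtype=bool)) is None


def _checkerboard_signs(shape):
    r, c = np.indices(shape)
    return np.where((r + c) % 2 == 0, 1.0, -1.0)


class TestDetectQuadrantEdge:
    def test_strong_edge_resolves_at_two_sigma(self, rng):
        G = rng.normal(0, 1, size=(40, 60))
        G[20, :] += 1000.0
        edge = detect_quadrant_edge(G, "UL", l_fraction=0.5)
        assert edge.satisfied and edge.level_used == 2.0
        assert np.array_equal(edge.trace_cols, np.arange(60))
        assert (edge.trace_rows == 20).all()

    def test_edge_between_sigma_cuts_needs_escalation(self):
        # deterministic population: ±6 checkerboard background, edge row at 10
        G = 6.0 * _checkerboard_signs((40, 60))
        G[20, :] = 10.0
        st = gradient_stats(G)
        assert st.mu + st.sigma < 10.0 < st.mu + 2 * st.sigma  # construction check
        edge = detect_quadrant_edge(G, "LL", l_fraction=0.5)
        assert edge.satisfied and edge.level_used == 1.0
        assert (edge.trace_rows == 20).all()

    def test_isolated_spikes_fail_the_whole_schedule(self):
        G = np.zeros((40, 60))
        G[1::3, 1::3] = 10.0  # isolated pixels, never 8-connected
        edge = detect_quadrant_edge(G, "UR", l_fraction=0.5)
        assert not edge.satisfied and edge.level_used is None
        assert edge.span_cols == 1

    def test_deterministic(self, rng):
        G = rng.normal(size=(30, 40))
        a = detect_quadrant_edge(G, "LR")
        b = detect_quadrant_edge(G, "LR")
        assert a.level_used == b.level_used
        assert np.array_equal(a.trace_rows, b.trace_rows)

    def test_span_is_monotone_under_escalation(self, rng):
        # nested masks imply the maximal span never shrinks as k decreases
        for _ in range(20):
            G = rng.normal(size=(20, 30)) ** 2 * rng.uniform(1, 10)
            st = gradient_stats(G)
            spans = []
            for k in (2.0, 1.0, 0.5):
                comp = longest_horizontal_component(binarize_at_sigma(G, st, k))
                spans.append(0 if comp is None else comp.span_cols)
            assert spans == sorted(spans)


def _edge(which, cols, rows, satisfied=True, level=2.0):
    cols = np.asarray(cols)
    rows = np.asarray(rows)
    return QuadrantEdge(which, level if satisfied else None, satisfied, cols, rows, len(cols), 10)


class TestAssemble:
    def test_gap_between_quadrants_interpolates_linearly(self):
        left = _edge("UL", np.arange(0, 41), np.full(41, 20))
        right = _edge("UR", np.arange(10, 50), np.full(40, 30))
        out = assemble_boundary(left, right, 100, (0, 0), (0, 50), side="upper")
        assert out[50] == 25
        assert out[0] == 20 and out[99] == 30

    def test_full_coverage_passes_through_unchanged(self):
        left = _edge("LL", np.arange(0, 50), np.arange(0, 50) % 7 + 40)
        right = _edge("LR", np.arange(0, 50), np.arange(0, 50) % 5 + 60)
        out = assemble_boundary(left, right, 100, (0, 0), (0, 50), side="lower")
        assert np.array_equal(out[:50], left.trace_rows)
        assert np.array_equal(out[50:], right.trace_rows)

    def test_one_sided_failure_extends_constant(self):
        left = _edge("UL", np.arange(0, 40), np.full(40, 20))
        right = _edge("UR", np.empty(0, int), np.empty(0, int), satisfied=False)
        out = assemble_boundary(left, right, 100, (0, 0), (0, 50), side="upper")
        assert (out == 20).all()

    def test_both_failed_raises_naming_the_side(self):
        dead = _edge("UL", np.empty(0, int), np.empty(0, int), satisfied=False)
        dead2 = _edge("UR", np.empty(0, int), np.empty(0, int), satisfied=False)
        with pytest.raises(BoundaryDetectionError, match="upper"):
            assemble_boundary(dead, dead2, 100, (0, 0), (0, 50), side="upper")


class TestQuality:
    @pytest.mark.parametrize(
        "levels, expected",
        [
            ((2.0, 2.0, 2.0, 2.0), "good"),
            ((2.0, 2.0, 1.0, 2.0), "medium"),
            ((2.0, 1.0, 0.5, 2.0), "poor"),
            ((2.0, 2.0, 2.0, None), "poor"),
            ((1.0, 1.0, 1.0, 1.0), "medium"),
        ],
    )
    def test_deepest_level_decides_the_label(self, levels, expected):
        assert classify_quality(levels) == expected

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            classify_quality([2.0, 2.0])
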