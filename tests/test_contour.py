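import numpy as np
import pytest

from guanloc import contour as cm
from guanloc import phantom
from guanloc.edges import EdgeMap
from guanloc.errors import ConnectionFailureError, NoEdgeError, OutlineError


def flood_fill_components(mask):
    """Independent BFS flood fill over 8-neighbourhoods."""
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                stack = [(r0, c0)]
                seen[r0, c0] = True
                comp = []
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < h
                                and 0 <= cc < w
                                and mask[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


def edge_map(mask):
    return EdgeMap(np.asarray(mask, dtype=bool))


class TestMaxConnectedDomain:
    def test_larger_component_wins(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2, 0:10] = True  # size 10
        mask[10, 0:3] = True  # size 3
        path = cm.max_connected_domain(edge_map(mask))
        assert len(path) == 10
        assert np.all(path.coords[:, 1] == 2)

    def test_full_width_line_spans_borders(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8] = True
        path = cm.max_connected_domain(edge_map(mask))
        assert path.spans_lateral_borders()

    def test_empty_map_raises(self):
        with pytest.raises(NoEdgeError):
            cm.max_connected_domain(edge_map(np.zeros((8, 8), dtype=bool)))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(24, 24)) < 0.25
        if not mask.any():
            return
        comps = flood_fill_components(mask)
        largest = max(len(c) for c in comps)
        got = cm.max_connected_domain(edge_map(mask))
        assert len(got) == largest
        got_set = {(r, c) for c, r in got.coords}
        assert got_set in [set(c) for c in comps]


class TestConnectBreakpoints:
    def test_spanning_component_unchanged(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8] = True
        comp = cm.max_connected_domain(edge_map(mask))
        out = cm.connect_breakpoints(edge_map(mask), comp)
        np.testing.assert_array_equal(out.coords, comp.coords)

    def test_two_segments_bridged_with_one_pixel(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[5, 0:10] = True  # ends at col 9
        mask[5, 11:16] = True  # starts at col 11, gap of 1 px at distance 2
        comp = cm.max_connected_domain(edge_map(mask))
        out = cm.connect_breakpoints(edge_map(mask), comp)
        assert out.spans_lateral_borders()
        assert len(out) == 10 + 5 + 1

    def test_three_collinear_fragments(self):
        mask = np.zeros((16, 32), dtype=bool)
        mask[7, 0:10] = True
        mask[7, 11:21] = True
        mask[7, 22:32] = True
        comp = cm.max_connected_domain(edge_map(mask))
        out = cm.connect_breakpoints(edge_map(mask), comp)
        assert out.spans_lateral_borders()
        comps = flood_fill_components(out.to_mask())
        assert len(comps) == 1

    def test_unreachable_fragment_raises_with_endpoint(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[5, 6:12] = True
        mask[12, 0:2] = True  # far away, not reachable in 2 px
        comp = cm.max_connected_domain(edge_map(mask))
        with pytest.raises(ConnectionFailureError) as err:
            cm.connect_breakpoints(edge_map(mask), comp)
        assert err.value.endpoint is not None


class TestCutBranches:
    def test_straight_line_unchanged(self):
        mask = np.zeros((10, 30), dtype=bool)
        mask[4] = True
        path = cm.PixelPath.from_mask(mask)
        out = cm.cut_branches(path)
        assert len(out) == 30

    def test_t_shape_spur_removed(self):
        mask = np.zeros((16, 24), dtype=bool)
        mask[8, 0:20] = True  # 20-px horizontal line
        mask[4:8, 10] = True  # 4-px vertical spur
        out = cm.cut_branches(cm.PixelPath.from_mask(mask), max_spur_len=8)
        assert len(out) == 20
        assert np.all(out.coords[:, 1] == 8)

    def test_plus_shape_keeps_long_arms(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[20, 0:40] = True  # long horizontal arms
        mask[16:20, 20] = True  # short spur up (4)
        mask[21:24, 20] = True  # short spur down (3)
        out = cm.cut_branches(cm.PixelPath.from_mask(mask), max_spur_len=8)
        assert len(out) == 40
        assert np.all(out.coords[:, 1] == 20)

    def test_no_junction_after_pruning(self, noiseless_phantom):
        from guanloc.edges import detect_edges

        image, _ = noiseless_phantom
        comp = cm.max_connected_domain(detect_edges(image))
        out = cm.cut_branches(comp)
        mask = out.to_mask()
        counts = cm._neighbor_counts(mask)
        # spur pruning leaves no degree-1 stub hanging off a junction
        endpoints = np.argwhere(mask & (counts == 1))
        assert len(endpoints) <= 2


class TestToOutline:
    def test_monotone_staircase_identity(self):
        coords = [(c, 10 + c // 2) for c in range(12)]
        path = cm.PixelPath(np.array(coords), shape=(32, 32))
        out = cm.to_outline(path)
        np.testing.assert_array_equal(out.rows, [10 + c // 2 for c in range(12)])

    def test_upper_takes_min_row(self):
        path = cm.PixelPath(np.array([[0, 10], [0, 30], [1, 12], [1, 20]]), shape=(40, 8))
        up = cm.to_outline(path, side="upper")
        lo = cm.to_outline(path, side="lower")
        assert list(up.rows) == [10, 12]
        assert list(lo.rows) == [30, 20]

    def test_small_gaps_interpolated(self):
        coords = [(0, 10), (1, 10), (4, 16), (5, 16)]
        path = cm.PixelPath(np.array(coords), shape=(32, 8))
        out = cm.to_outline(path)
        np.testing.assert_allclose(out.rows, [10, 10, 12, 14, 16, 16])

    def test_wide_gap_rejected(self):
        coords = [(0, 10), (6, 10)]
        path = cm.PixelPath(np.array(coords), shape=(32, 8))
        with pytest.raises(OutlineError):
            cm.to_outline(path)

    def test_phantom_outline_matches_analytic_contour(self, noiseless_spec, noiseless_phantom):
        """Extracted outline tracks the analytic phantom contour within
        1 px RMS."""
        from guanloc.edges import detect_edges

        image, _ = noiseless_phantom
        comp = cm.cut_branches(cm.max_connected_domain(detect_edges(image)))
        out = cm.to_outline(comp)
        r, _, _, _ = phantom._contour_terms(noiseless_spec, 0.0, 0.0, 1.0)
        truth_rows = r(out.columns.astype(float))
        rms = np.sqrt(np.mean((out.rows - truth_rows) ** 2))
        assert rms <= 1.0
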