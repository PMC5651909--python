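import numpy as np
import pytest

from fretion import (
    CorrectionFactors,
    PhotophysicsParams,
    annotate_fret,
    assign_ground_truth,
    build_graph,
    classify_cell_shape,
    classify_edge_rank,
    correlate_size_fret,
    match_cells_to_truth,
    preprocess,
    render_membrane_maps,
    render_stack,
    segment_cells,
)
from fretion.pipeline import FretMap, analyze_stack


def _uniform_fmap(shape, value=0.24):
    return FretMap(
        index=np.full(shape, value),
        mask=np.ones(shape, bool),
        n_valid=int(np.prod(shape)),
    )


@pytest.fixture(scope="module")
def mem100(mesh100):
    truth = assign_ground_truth(mesh100, "uniform", 0.25, 0.25)
    rho, _ = render_membrane_maps(truth)
    return rho * 1800.0


@pytest.fixture(scope="module")
def graph100(mem100):
    labels = segment_cells(mem100, min_distance=16)
    return build_graph(labels, 0.2)


class TestSegmentation:
    def test_three_cell_mesh_gives_three_labels(self):
        from fretion import generate_mesh

        mesh = generate_mesh(3, (128, 128), seed=0)
        truth = assign_ground_truth(mesh, "uniform", 0.2, 0.2)
        rho, _ = render_membrane_maps(truth)
        labels = segment_cells(rho * 1000, min_distance=20)
        assert labels.max() == 3

    def test_hundred_cell_noise_free_exact_recovery(self, mesh100, graph100):
        assert len(graph100.cells) == 100
        truth_centroids = np.array([c.centroid for c in mesh100.cells])
        match = match_cells_to_truth(graph100, truth_centroids)
        assert len(match) == 100
        for cid, j in match.items():
            err = abs(graph100.cells[cid].n_pixels / mesh100.cells[j].area_px - 1)
            assert err < 0.05

    def test_noisy_render_matches_ninety_percent(self, mesh100):
        truth = assign_ground_truth(mesh100, "uniform", 0.25, 0.25)
        stack = render_stack(truth, PhotophysicsParams(noise="poisson", seed=5))
        pre = preprocess(stack)
        labels = segment_cells(pre.yfp, min_distance=16)
        assert 95 <= labels.max() <= 105
        graph = build_graph(labels, 0.2)
        match = match_cells_to_truth(
            graph, np.array([c.centroid for c in mesh100.cells])
        )
        assert len(match) >= 90

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError):
            segment_cells(np.zeros((64, 64)))

    def test_segmentation_is_deterministic(self, mem100):
        a = segment_cells(mem100, min_distance=16)
        b = segment_cells(mem100, min_distance=16)
        np.testing.assert_array_equal(a, b)

    def test_label_partition_conserves_image_area(self, graph100):
        labels = graph100.labels
        n_background = int((labels == 0).sum())
        n_cells = sum(c.n_pixels for c in graph100.cells.values())
        assert n_background + n_cells == labels.size


class TestGraphGeometry:
    def test_single_square_cell_metrics(self):
        labels = np.zeros((30, 30), int)
        labels[10:20, 10:20] = 1
        graph = build_graph(labels, pixel_size=0.2)
        cell = graph.cells[1]
        assert cell.area_um2 == pytest.approx(4.0)  # 100 px * 0.04
        assert cell.elongation == pytest.approx(1.0, abs=0.05)

    def test_two_abutting_rectangles_share_one_edge(self):
        labels = np.zeros((40, 40), int)
        labels[5:35, 5:20] = 1
        labels[5:35, 20:35] = 2
        graph = build_graph(labels, pixel_size=1.0)
        shared = [e for e in graph.edges.values() if set(e.cells) == {1, 2}]
        assert len(shared) == 1
        # the shared side runs 30 px from row 5 to row 35
        assert shared[0].length_um == pytest.approx(30.0, rel=0.05)

    def test_interior_cells_have_about_six_edges(self, graph100):
        interior = [
            cid
            for cid, c in graph100.cells.items()
            if 50 < c.centroid[0] < 460 and 50 < c.centroid[1] < 460
        ]
        counts = [len(graph100.cell_edges(cid)) for cid in interior]
        assert 5.0 <= np.mean(counts) <= 7.0


class TestAnnotate:
    def test_uniform_index_annotates_every_cell_and_edge(self, graph100):
        annotate_fret(graph100, _uniform_fmap(graph100.labels.shape))
        for c in graph100.cells.values():
            assert c.mean_fret == pytest.approx(0.24)
        for e in graph100.edges.values():
            assert e.mean_fret == pytest.approx(0.24)

    def test_planted_bright_edge_recovered(self, mem100):
        labels = segment_cells(mem100, min_distance=16)
        graph = build_graph(labels, 0.2)
        target = next(e for e in graph.edges.values() if e.is_interior)
        idx = np.full(labels.shape, 0.20)
        b = np.rint(target.boundary_px).astype(int)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr = np.clip(b[:, 0] + dr, 0, labels.shape[0] - 1)
                cc = np.clip(b[:, 1] + dc, 0, labels.shape[1] - 1)
                idx[rr, cc] = 0.30
        fmap = FretMap(index=idx, mask=np.ones_like(idx, bool), n_valid=idx.size)
        annotate_fret(graph, fmap, edge_band=1.0)
        assert graph.edges[target.id].mean_fret == pytest.approx(0.30, abs=0.01)

    def test_fully_undefined_map_reports_undefined_means(self, graph100):
        fmap = FretMap(
            index=np.full(graph100.labels.shape, np.nan),
            mask=np.ones(graph100.labels.shape, bool),
            n_valid=0,
        )
        annotate_fret(graph100, fmap)
        assert all(np.isnan(c.mean_fret) for c in graph100.cells.values())
        assert all(e.n_fret_pixels == 0 for e in graph100.edges.values())

    def test_cell_mean_is_pixel_weighted_edge_aggregate(self, graph100):
        rng = np.random.default_rng(0)
        idx = rng.uniform(0.1, 0.4, graph100.labels.shape)
        fmap = FretMap(index=idx, mask=np.ones_like(idx, bool), n_valid=idx.size)
        annotate_fret(graph100, fmap)
        for cid, cell in graph100.cells.items():
            edges = [e for e in graph100.cell_edges(cid) if e.n_fret_pixels]
            if not edges:
                continue
            agg = sum(e.mean_fret * e.n_fret_pixels for e in edges) / sum(
                e.n_fret_pixels for e in edges
            )
            assert cell.mean_fret == pytest.approx(agg, abs=1e-6)


class TestClassifiers:
    def test_round_vs_elongated_with_tie_rule(self):
        from fretion.cellgraph import CellRecord

        mk = lambda el: CellRecord(0, 10.0, np.zeros(2), 0.0, el, 100)
        assert classify_cell_shape(mk(1.0)) == "round"
        assert classify_cell_shape(mk(3.0)) == "elongated"
        assert classify_cell_shape(mk(1.5)) == "elongated"  # >= threshold

    @staticmethod
    def _graph_with_edge_lengths(lengths):
        from fretion.cellgraph import CellGraph, CellRecord, EdgeRecord

        cell = CellRecord(1, 10.0, np.zeros(2), 0.0, 1.0, 100)
        edges = {
            i: EdgeRecord(i, (1,), np.zeros((2, 2)), L, 0.0, np.zeros((3, 2)))
            for i, L in enumerate(lengths)
        }
        return CellGraph({1: cell}, edges, np.ones((4, 4), int), 1.0)

    def test_rectangle_edges_split_two_long_two_short(self):
        graph = self._graph_with_edge_lengths([10.0, 10.0, 4.0, 4.0])
        values = sorted(classify_edge_rank(1, graph).values())
        assert values.count("long") == 2
        assert values.count("short") == 2

    def test_equal_edges_all_rank_long(self):
        # regular polygon: every side ties at the median, ties rank long
        graph = self._graph_with_edge_lengths([6.0] * 6)
        assert set(classify_edge_rank(1, graph).values()) == {"long"}

    def test_single_edge_cell_excluded(self):
        from fretion.cellgraph import CellGraph, CellRecord, EdgeRecord

        cell = CellRecord(1, 10.0, np.zeros(2), 0.0, 1.0, 100)
        edge = EdgeRecord(0, (1,), np.zeros((2, 2)), 5.0, 0.0, np.zeros((3, 2)))
        g = CellGraph({1: cell}, {0: edge}, np.ones((4, 4), int), 1.0)
        assert classify_edge_rank(1, g) == {}


class TestSizeCorrelation:
    def test_uniform_truth_shows_no_size_correlation(self, mesh100):
        truth = assign_ground_truth(mesh100, "uniform", 0.25, 0.25)
        stack = render_stack(truth, PhotophysicsParams(noise="poisson", seed=3))
        pre = preprocess(stack)
        fmap, _ = analyze_stack(pre, CorrectionFactors(0.1, 0.1))
        labels = segment_cells(pre.yfp, min_distance=16)
        graph = annotate_fret(build_graph(labels, 0.2), fmap)
        r, rows = correlate_size_fret(graph)
        n = len(rows)
        assert n >= 90
        # under the null, r ~ N(0, 1/sqrt(n)); require non-significance
        # rather than a fixed small magnitude a single seed cannot guarantee
        t = abs(r) * np.sqrt((n - 2) / (1 - r**2))
        from scipy import stats as sps

        assert 2 * sps.t.sf(t, n - 2) > 0.01

    def test_radial_truth_recovers_negative_size_correlation(self, mesh100):
        # centre cells: high FRET; periphery: low. CVT cells are equal-sized,
        # so plant the size relation by correlating against truth E instead
        truth = assign_ground_truth(mesh100, "radial", 0.05, 0.45)
        stack = render_stack(truth, PhotophysicsParams(noise="poisson", seed=4))
        pre = preprocess(stack)
        fmap, _ = analyze_stack(pre, CorrectionFactors(0.1, 0.1))
        labels = segment_cells(pre.yfp, min_distance=16)
        graph = annotate_fret(build_graph(labels, 0.2), fmap)
        match = match_cells_to_truth(
            graph, np.array([c.centroid for c in mesh100.cells])
        )
        recovered = []
        for cid, j in match.items():
            if np.isfinite(graph.cells[cid].mean_fret):
                recovered.append(
                    (truth.cell_mean_efficiency(mesh100.cells[j].id),
                     graph.cells[cid].mean_fret)
                )
        e_true, e_obs = map(np.asarray, zip(*recovered))
        assert np.corrcoef(e_true, e_obs)[0, 1] > 0.8

    def test_too_few_cells_rejected(self):
        labels = np.zeros((30, 30), int)
        labels[5:15, 5:15] = 1
        labels[16:26, 16:26] = 2
        graph = build_graph(labels, 1.0)
        annotate_fret(graph, _uniform_fmap(labels.shape))
        with pytest.raises(ValueError):
            correlate_size_fret(graph)
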