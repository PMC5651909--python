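import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretion import (
    CorrectionFactors,
    PhotophysicsParams,
    PulsingRecord,
    assign_ground_truth,
    build_graph,
    classify_edge_change,
    classify_pulsing,
    front_back_ratio,
    front_back_rois,
    paired_state_comparison,
    rasterize_labels,
    render_stack,
    simulate_pulsing_records,
)
from fretion.pipeline import FretMap, analyze_stack


class TestClassifyPulsing:
    def test_constant_areas_excluded(self):
        assert classify_pulsing(np.full(8, 100.0)) == "excluded"

    def test_steady_contraction_called(self):
        # 15% drop, SD of all 8 points ~5.6 < 15: both conditions hold
        areas = np.array([100.0, 100, 97, 94, 91, 88, 86, 85])
        assert np.std(areas, ddof=1) < 15.0
        assert classify_pulsing(areas) == "contracted"

    def test_nine_percent_change_fails_first_condition(self):
        areas = np.array([100.0, 99, 97, 96, 94, 93, 92, 91])
        assert classify_pulsing(areas) == "excluded"

    def test_large_change_small_sd_condition_interplay(self):
        # 12% change but SD of the series exceeds |delta|: excluded
        areas = np.array([100.0, 140, 60, 140, 60, 140, 60, 88])
        assert abs(areas[7] - areas[0]) > 0.1 * areas[0]
        assert abs(areas[7] - areas[0]) < np.std(areas, ddof=1)
        assert classify_pulsing(areas) == "excluded"

    def test_expansion_direction(self):
        areas = np.array([85.0, 86, 88, 91, 94, 97, 100, 100])
        assert classify_pulsing(areas) == "expanded"

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_pulsing(np.array([1.0, 2, 3]))
        with pytest.raises(ValueError):
            classify_pulsing(np.array([100.0, 100, 100, 100, -1, 100, 100, 100]))

    @settings(deadline=None, max_examples=60)
    @given(
        scale=st.floats(0.01, 100.0),
        seed=st.integers(0, 1000),
    )
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        areas = rng.uniform(50, 150, 8)
        assert classify_pulsing(areas) == classify_pulsing(areas * scale)


class TestClassifyEdgeChange:
    @pytest.mark.parametrize(
        "l0,l1,call",
        [
            (10.0, 7.5, "contracted"),  # 25% shorter
            (10.0, 11.0, "excluded"),  # 10%
            (10.0, 12.0, "excluded"),  # exactly 20%: strict inequality
            (10.0, 12.01, "expanded"),
            (10.0, 8.0, "excluded"),  # exactly -20%
            (10.0, 7.99, "contracted"),
        ],
    )
    def test_rule_and_tie_handling(self, l0, l1, call):
        assert classify_edge_change(l0, l1) == call

    @settings(deadline=None, max_examples=60)
    @given(scale=st.floats(0.01, 100.0), l0=st.floats(1.0, 50.0), l1=st.floats(1.0, 50.0))
    def test_scale_invariance(self, scale, l0, l1):
        assert classify_edge_change(l0, l1) == classify_edge_change(l0 * scale, l1 * scale)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            classify_edge_change(0.0, 5.0)


class TestPairedComparison:
    @staticmethod
    def _records(delta_e, noise, seed, n=60):
        raw = simulate_pulsing_records(
            n, delta_e=delta_e, noise_sd_fret=noise, seed=seed
        )
        return [
            PulsingRecord(
                cell_id=r["cell_id"],
                areas_um2=r["areas_um2"],
                fret_t0=r["fret_t0"],
                fret_t7=r["fret_t7"],
                call=classify_pulsing(r["areas_um2"]),
            )
            for r in raw
        ]

    def test_identical_fret_gives_p_one(self):
        recs = []
        for i, call in enumerate(["contracted", "expanded"] * 3):
            recs.append(
                PulsingRecord(i, np.full(8, 100.0), 0.24, 0.24, call=call)
            )
        res = paired_state_comparison(recs)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_planted_coupling_detected(self):
        hits = 0
        for seed in range(10):
            recs = self._records(delta_e=0.05, noise=0.004, seed=seed, n=120)
            res = paired_state_comparison(recs)
            hits += res.p < 0.05
        assert hits >= 8

    def test_null_type_i_rate_is_calibrated(self):
        pvals = []
        for seed in range(40):
            recs = self._records(delta_e=0.0, noise=0.004, seed=seed, n=120)
            pvals.append(paired_state_comparison(recs).p)
        pvals = np.asarray(pvals)
        # p should look uniform: few rejections, spread-out values
        assert (pvals < 0.05).mean() <= 0.15
        assert pvals.std() > 0.15

    def test_empty_state_reports_counts(self):
        recs = [PulsingRecord(0, np.full(8, 100.0), 0.2, 0.2, call="contracted")]
        with pytest.raises(ValueError, match="contracted=1"):
            paired_state_comparison(recs)


@pytest.fixture(scope="module")
def cluster_setup(cluster7):
    truth = assign_ground_truth(cluster7, "front_back", 0.15, 0.30)
    # border-cell clusters show a thick cortical E-Cadherin belt; render a
    # wider membrane so each cell carries well over 20 um^2 of masked signal
    phys = PhotophysicsParams(noise="poisson", seed=6, membrane_width=6.0)
    stack = render_stack(truth, phys)
    fmap, _ = analyze_stack(stack, CorrectionFactors(0.1, 0.1))
    labels = rasterize_labels(cluster7)
    graph = build_graph(labels, cluster7.pixel_size)
    return truth, fmap, graph


class TestFrontBack:
    def test_roi_areas_near_twenty_um2(self, cluster_setup):
        _, fmap, graph = cluster_setup
        rois = front_back_rois(graph, fmap.mask)
        fa, ba = rois.areas_um2(graph.pixel_size)
        assert fa == pytest.approx(20.0, rel=0.10)
        assert ba == pytest.approx(20.0, rel=0.10)

    def test_axis_reversal_swaps_front_and_back(self, cluster_setup):
        _, fmap, graph = cluster_setup
        fwd = front_back_rois(graph, fmap.mask, migration_axis=(0, 1))
        rev = front_back_rois(graph, fmap.mask, migration_axis=(0, -1))
        assert fwd.front_cell == rev.back_cell
        assert fwd.back_cell == rev.front_cell

    def test_single_cell_cluster_rejected(self):
        from fretion.cellgraph import CellGraph, CellRecord

        cell = CellRecord(1, 50.0, np.array([16.0, 16.0]), 0.0, 1.0, 1000)
        g = CellGraph({1: cell}, {}, np.ones((32, 32), int), 1.0)
        with pytest.raises(ValueError, match="at least 2"):
            front_back_rois(g, np.ones((32, 32), bool))

    def test_uniform_map_gives_unit_ratio(self, cluster_setup):
        _, fmap, graph = cluster_setup
        rois = front_back_rois(graph, np.ones_like(fmap.mask))
        uni = FretMap(
            index=np.full(fmap.index.shape, 0.30),
            mask=np.ones_like(fmap.mask),
            n_valid=fmap.index.size,
        )
        out = front_back_ratio(uni, rois)
        assert out["ratio"] == pytest.approx(1.0)

    def test_planted_ratio_recovered(self, cluster_setup):
        _, fmap, graph = cluster_setup
        rois = front_back_rois(graph, np.ones_like(fmap.mask))
        idx = np.full(fmap.index.shape, 0.300)
        idx[rois.front_mask] = 0.285
        planted = FretMap(index=idx, mask=np.ones_like(fmap.mask), n_valid=idx.size)
        out = front_back_ratio(planted, rois)
        assert out["ratio"] == pytest.approx(0.95, abs=1e-9)

    def test_front_low_efficiency_truth_gives_ratio_below_one(self, cluster_setup):
        truth, fmap, graph = cluster_setup
        rois = front_back_rois(graph, fmap.mask)
        out = front_back_ratio(fmap, rois)
        # front edges carry E=0.15, rear E=0.30: the index ratio must drop
        assert out["ratio"] < 0.9
        assert out["front_mean"] < out["back_mean"]

    def test_mirrored_input_gives_reciprocal_ratio(self, cluster_setup):
        _, fmap, graph = cluster_setup
        rois = front_back_rois(graph, np.ones_like(fmap.mask))
        idx = np.full(fmap.index.shape, 0.30)
        idx[rois.front_mask] = 0.24
        fm = FretMap(index=idx, mask=np.ones_like(fmap.mask), n_valid=idx.size)
        a = front_back_ratio(fm, rois)
        swapped = type(rois)(
            front_mask=rois.back_mask,
            back_mask=rois.front_mask,
            front_cell=rois.back_cell,
            back_cell=rois.front_cell,
            roi_area_um2=rois.roi_area_um2,
        )
        b = front_back_ratio(fm, swapped)
        assert a["ratio"] == pytest.approx(1.0 / b["ratio"], abs=1e-6)

    def test_sparse_roi_rejected(self, cluster_setup):
        _, fmap, graph = cluster_setup
        rois = front_back_rois(graph, fmap.mask)
        empty = FretMap(
            index=np.full(fmap.index.shape, np.nan),
            mask=fmap.mask,
            n_valid=0,
        )
        with pytest.raises(ValueError, match="defined pixels"):
            front_back_ratio(empty, rois)
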