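"""Segment cells, build the cell graph and test shape/edge FRET contrasts.

On a uniform-efficiency tissue a working analysis must find *no*
difference between round and elongated cells or between each cell's long
and short junctions — the comparisons a tension pattern would light up.
"""

import numpy as np

from fretion import (
    CorrectionFactors,
    PhotophysicsParams,
    SampleSet,
    analyze_stack,
    annotate_fret,
    assign_ground_truth,
    build_graph,
    classify_cell_shape,
    classify_edge_rank,
    correlate_size_fret,
    generate_mesh,
    preprocess,
    render_stack,
    segment_cells,
    welch_test,
)

mesh = generate_mesh(60, (384, 384), seed=2)
truth = assign_ground_truth(mesh, "uniform", 0.25, 0.25)
stack = render_stack(truth, PhotophysicsParams(noise="poisson", seed=2))
pre = preprocess(stack)
fret_map, _ = analyze_stack(pre, CorrectionFactors(0.1, 0.1))

labels = segment_cells(pre.yfp, min_distance=14)
graph = annotate_fret(build_graph(labels, pixel_size=0.2), fret_map)
print(f"cells segmented: {len(graph.cells)} (ground truth: 60)")

round_f, elong_f = [], []
for cell in graph.cells.values():
    if np.isfinite(cell.mean_fret):
        (elong_f if classify_cell_shape(cell) == "elongated" else round_f).append(
            cell.mean_fret
        )
res = welch_test(SampleSet("round", np.array(round_f)),
                 SampleSet("elongated", np.array(elong_f)))
print(f"round vs elongated : {res.mean_a:.4f} vs {res.mean_b:.4f}, "
      f"p={res.p:.3f} ({res.stars})")

long_f, short_f = [], []
for cid in graph.cells:
    for eid, rank in classify_edge_rank(cid, graph).items():
        v = graph.edges[eid].mean_fret
        if np.isfinite(v):
            (long_f if rank == "long" else short_f).append(v)
res = welch_test(SampleSet("long", np.array(long_f)),
                 SampleSet("short", np.array(short_f)))
print(f"long vs short edges: {res.mean_a:.4f} vs {res.mean_b:.4f}, "
      f"p={res.p:.3f} ({res.stars})")

r, _ = correlate_size_fret(graph)
print(f"cell size vs index Pearson r: {r:+.3f}")
print()
print("All contrasts are non-significant and the size correlation is ~0,")
print("as they must be when every junction carries the same efficiency.")
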