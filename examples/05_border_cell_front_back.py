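"""Front/back FRET asymmetry in a migrating cell cluster.

A 7-cell rosette migrates along +x; the leading cell's junctions carry a
lower true efficiency (higher tension).  ~20 um^2 ROIs grown inside the
leading and rear cells yield the front/back index ratio, reported together
with the absolute means — the two can tell different stories on real data.
"""

from fretion import (
    CorrectionFactors,
    PhotophysicsParams,
    analyze_stack,
    assign_ground_truth,
    build_graph,
    front_back_ratio,
    front_back_rois,
    generate_mesh,
    rasterize_labels,
    render_stack,
)

cluster = generate_mesh(7, (256, 256), seed=2, geometry="cluster")
truth = assign_ground_truth(cluster, "front_back", e_low=0.15, e_high=0.30)
phys = PhotophysicsParams(noise="poisson", seed=6, membrane_width=6.0)
stack = render_stack(truth, phys)
fret_map, _ = analyze_stack(stack, CorrectionFactors(0.1, 0.1))

graph = build_graph(rasterize_labels(cluster), pixel_size=0.2)
rois = front_back_rois(graph, fret_map.mask, migration_axis=(0, 1))
out = front_back_ratio(fret_map, rois)

fa, ba = rois.areas_um2(0.2)
print(f"front ROI {fa:.1f} um^2 in cell {rois.front_cell}, "
      f"back ROI {ba:.1f} um^2 in cell {rois.back_cell}")
print(f"front mean index {out['front_mean']:.4f}  (true E 0.15 on its edges)")
print(f"back  mean index {out['back_mean']:.4f}  (true E 0.30)")
print(f"front/back ratio {out['ratio']:.3f}")
print()
print("Ratio < 1 recovers the planted higher tension (lower FRET) at the")
print("cluster front; a ratio near 1 would mean no detectable asymmetry.")
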