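"""Time-resolved FRET analyses: pulsing states, edge dynamics, front/back ROIs.

Pulsed apical contractions (period ~4 min) are classified from eight
one-minute area snapshots: time-points 0 and 7 are in different pulsing
stages when the area difference exceeds both 10% of the initial area and
one standard deviation of all eight time-points.  Junctional edges are
called contracted/expanded when their vertex-to-vertex length changes by
more than 20% within one minute.  For migrating clusters, ~20 um^2 ROIs are
grown inside the leading and rear cells' membrane mask and the front/back
FRET ratio reported alongside the absolute means (the two can disagree).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cellgraph import CellGraph
from .pipeline import FretMap
from .stats import SampleSet, TestResult, welch_test

__all__ = [
    "PulsingRecord",
    "EdgeDynamicsRecord",
    "RoiPair",
    "classify_pulsing",
    "classify_edge_change",
    "paired_state_comparison",
    "front_back_rois",
    "front_back_ratio",
    "match_cells_over_time",
]

#: relative area change required between t0 and t7 (fraction of A0)
AREA_CHANGE_FRACTION = 0.10
#: relative length change required within one minute
EDGE_CHANGE_FRACTION = 0.20


@dataclass
class PulsingRecord:
    cell_id: int
    areas_um2: np.ndarray  # 8 values, t = 0..7 min
    fret_t0: float
    fret_t7: float
    call: str = "excluded"


@dataclass
class EdgeDynamicsRecord:
    edge_id: int
    length_t0_um: float
    length_t1_um: float
    fret_t0: float
    fret_t1: float
    call: str = "excluded"


@dataclass
class RoiPair:
    front_mask: np.ndarray
    back_mask: np.ndarray
    front_cell: int
    back_cell: int
    roi_area_um2: float

    def areas_um2(self, pixel_size: float) -> tuple[float, float]:
        px2 = pixel_size**2
        return float(self.front_mask.sum() * px2), float(self.back_mask.sum() * px2)


def classify_pulsing(areas_um2: np.ndarray) -> str:
    """Pulsing-stage call from 8 area snapshots.

    'contracted' / 'expanded' describes the transition from t0 to t7; both
    the >10%-of-A0 and the >1-SD conditions (strict inequalities, SD over
    all eight time-points, ddof=1) must hold, otherwise 'excluded'.
    """
    a = np.asarray(areas_um2, dtype=float)
    if a.shape != (8,):
        raise ValueError("need exactly 8 area values (t = 0..7 min)")
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise ValueError("areas must be finite and positive")
    delta = a[7] - a[0]
    sd = a.std(ddof=1)
    if abs(delta) > AREA_CHANGE_FRACTION * a[0] and abs(delta) > sd:
        return "contracted" if delta < 0 else "expanded"
    return "excluded"


def classify_edge_change(length_t0_um: float, length_t1_um: float) -> str:
    """Edge call from two lengths 1 min apart: >20% shorter -> 'contracted',
    >20% longer -> 'expanded', else 'excluded' (strict inequalities)."""
    if length_t0_um <= 0 or length_t1_um <= 0:
        raise ValueError("edge lengths must be positive")
    if length_t1_um < (1.0 - EDGE_CHANGE_FRACTION) * length_t0_um:
        return "contracted"
    if length_t1_um > (1.0 + EDGE_CHANGE_FRACTION) * length_t0_um:
        return "expanded"
    return "excluded"


def paired_state_comparison(records) -> TestResult:
    """Welch comparison of FRET between the contracted and expanded states.

    Pulsing records contribute the FRET value at the time-point in each
    state (t0 and t7 according to the call); edge records likewise.  Raises
    when either state has fewer than two records.
    """
    contracted, expanded = [], []
    for r in records:
        if r.call == "excluded":
            continue
        if isinstance(r, PulsingRecord):
            first, last = r.fret_t0, r.fret_t7
        else:
            first, last = r.fret_t0, r.fret_t1
        if r.call == "contracted":  # ends contracted: t0 was the expanded state
            expanded.append(first)
            contracted.append(last)
        else:
            contracted.append(first)
            expanded.append(last)
    if len(contracted) < 2 or len(expanded) < 2:
        raise ValueError(
            f"need >= 2 records per state; have contracted={len(contracted)}, "
            f"expanded={len(expanded)}"
        )
    return welch_test(
        SampleSet("contracted", np.asarray(contracted)),
        SampleSet("expanded", np.asarray(expanded)),
    )


def front_back_rois(
    graph: CellGraph,
    mask: np.ndarray,
    migration_axis: tuple[float, float] = (0.0, 1.0),
    roi_area_um2: float = 20.0,
) -> RoiPair:
    """Grow ~``roi_area_um2`` ROIs inside the leading and rear cells.

    The front (back) cell is the one whose centroid projects farthest
    (least) along ``migration_axis`` (row, col direction).  Within each
    extreme cell the ROI collects the masked pixels nearest the cell
    centroid until the target area is reached — a compact patch of
    junctional signal.
    """
    axis = np.asarray(migration_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("migration axis must be non-zero")
    axis = axis / norm
    if len(graph.cells) < 2:
        raise ValueError("cluster must contain at least 2 cells")
    proj = {cid: float(c.centroid @ axis) for cid, c in graph.cells.items()}
    front = max(proj, key=proj.get)
    back = min(proj, key=proj.get)
    px2 = graph.pixel_size**2
    target_px = int(round(roi_area_um2 / px2))

    def grow(cell_id: int) -> np.ndarray:
        cell_mask = (graph.labels == cell_id) & mask
        n_avail = int(cell_mask.sum())
        if n_avail < 0.5 * target_px:
            raise ValueError(
                f"cell {cell_id} has only {n_avail * px2:.1f} um^2 of masked "
                f"signal; cannot grow a {roi_area_um2} um^2 ROI"
            )
        n_take = min(target_px, n_avail)
        cent = graph.cells[cell_id].centroid
        rr, cc = np.nonzero(cell_mask)
        d = (rr - cent[0]) ** 2 + (cc - cent[1]) ** 2
        order = np.argsort(d, kind="stable")[:n_take]
        out = np.zeros_like(cell_mask)
        out[rr[order], cc[order]] = True
        return out

    return RoiPair(
        front_mask=grow(front),
        back_mask=grow(back),
        front_cell=front,
        back_cell=back,
        roi_area_um2=roi_area_um2,
    )


def front_back_ratio(
    fmap: FretMap, rois: RoiPair, min_pixels: int = 50
) -> dict[str, float]:
    """Front and back mean FRET index and their ratio.

    Both the absolute means and the ratio are always reported together;
    with noisy normalisation they can tell different stories.
    """
    out = {}
    for name, roi in (("front", rois.front_mask), ("back", rois.back_mask)):
        sel = roi & fmap.defined
        n = int(sel.sum())
        if n < min_pixels:
            raise ValueError(f"{name} ROI has only {n} defined pixels (< {min_pixels})")
        out[f"{name}_mean"] = float(fmap.index[sel].mean())
        out[f"{name}_n"] = n
    if out["back_mean"] == 0:
        out["ratio"] = float("nan")
        out["flag"] = "back mean is zero; ratio undefined"
    else:
        out["ratio"] = out["front_mean"] / out["back_mean"]
    return out


def match_cells_over_time(
    graph_t0: CellGraph, graph_t1: CellGraph, gate_px: float = 5.0
) -> dict[int, int]:
    """Nearest-centroid cell identity across two time-points (gated)."""
    from scipy.optimize import linear_sum_assignment

    ids0 = list(graph_t0.cells)
    ids1 = list(graph_t1.cells)
    c0 = np.asarray([graph_t0.cells[i].centroid for i in ids0])
    c1 = np.asarray([graph_t1.cells[i].centroid for i in ids1])
    cost = np.linalg.norm(c0[:, None, :] - c1[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(cost)
    return {ids0[i]: ids1[j] for i, j in zip(ri, ci) if cost[i, j] <= gate_px}
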