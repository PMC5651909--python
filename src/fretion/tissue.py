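"""Synthetic epithelial tissue meshes with known junctional FRET ground truth.

The generator produces centroidal-Voronoi-style polygonal cell sheets (or a
compact migrating cluster of 6-8 cells), assigns each cell-cell junction a
true FRET efficiency following a chosen tension pattern, and can deform the
mesh over time to emulate pulsed apical contractions.  All downstream
recovery tests measure against these ground-truth objects.

Coordinates are (row, col), origin top-left, pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import unary_union

__all__ = [
    "MeshCell",
    "MeshEdge",
    "TissueMesh",
    "GroundTruthTissue",
    "PulseSpec",
    "generate_mesh",
    "assign_ground_truth",
    "deform_mesh",
    "pulsing_mesh_series",
    "simulate_pulsing_records",
    "rasterize_labels",
]

#: minimum mean cell footprint (px^2) corresponding to an 8 px diameter
_MIN_CELL_AREA = np.pi * 4.0**2


@dataclass
class MeshCell:
    id: int
    vertices: np.ndarray  # (k, 2) polygon ring, (row, col)
    area_px: float
    centroid: np.ndarray  # (row, col)


@dataclass
class MeshEdge:
    id: int
    cells: tuple[int, ...]  # 1 (tissue border) or 2 adjacent cells
    polyline: np.ndarray  # (m, 2) vertex chain, (row, col)

    @property
    def endpoints(self) -> np.ndarray:
        return np.vstack([self.polyline[0], self.polyline[-1]])

    @property
    def length_px(self) -> float:
        """Vertex-to-vertex (endpoint) distance, the junction-length metric."""
        return float(np.linalg.norm(self.polyline[-1] - self.polyline[0]))

    @property
    def is_interior(self) -> bool:
        return len(self.cells) == 2


@dataclass
class TissueMesh:
    cells: list[MeshCell]
    edges: list[MeshEdge]
    image_shape: tuple[int, int]
    pixel_size: float = 0.2  # um per pixel
    geometry: str = "sheet"

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_edges(self, cell_id: int) -> list[MeshEdge]:
        return [e for e in self.edges if cell_id in e.cells]

    def adjacency(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e.cells)) for e in self.edges if e.is_interior}

    def front_cell(self) -> int:
        """Cell with the maximal column (x) centroid; the cluster's leader."""
        return int(max(self.cells, key=lambda c: c.centroid[1]).id)


@dataclass(frozen=True)
class PulseSpec:
    """Sinusoidal apical-area modulation of one cell."""

    period_s: float = 240.0
    amplitude: float = 0.15  # fractional area amplitude
    phase_rad: float = 0.0


@dataclass
class GroundTruthTissue:
    """Mesh plus the true junctional FRET efficiencies and cell labels."""

    mesh: TissueMesh
    edge_efficiency: dict[int, float]
    cell_pattern_label: dict[int, str]
    pulse_phase: dict[int, PulseSpec] | None = None
    pattern: str = "uniform"

    def __post_init__(self) -> None:
        for eid, e in self.edge_efficiency.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"edge {eid}: efficiency {e} outside [0, 1]")
        missing = {c.id for c in self.mesh.cells} - set(self.cell_pattern_label)
        if missing:
            raise ValueError(f"cells without pattern label: {sorted(missing)}")

    def cell_mean_efficiency(self, cell_id: int) -> float:
        es = [self.edge_efficiency[e.id] for e in self.mesh.cell_edges(cell_id)]
        return float(np.mean(es))


def _polygon_cells(points: np.ndarray, domain: Polygon) -> list[Polygon]:
    """Bounded Voronoi cells of ``points`` clipped to ``domain``.

    Seeds are mirrored across the domain bounding box so every region of an
    original seed is finite; cells are then intersected with the domain.
    """
    minr, minc, maxr, maxc = (
        domain.bounds[0],
        domain.bounds[1],
        domain.bounds[2],
        domain.bounds[3],
    )
    p = points
    mirrored = np.vstack(
        [
            p,
            np.column_stack([2 * minr - p[:, 0], p[:, 1]]),
            np.column_stack([2 * maxr - p[:, 0], p[:, 1]]),
            np.column_stack([p[:, 0], 2 * minc - p[:, 1]]),
            np.column_stack([p[:, 0], 2 * maxc - p[:, 1]]),
        ]
    )
    vor = Voronoi(mirrored)
    polys = []
    for i in range(len(p)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError("unbounded Voronoi region despite mirroring")
        poly = Polygon(vor.vertices[region]).intersection(domain)
        polys.append(poly)
    return polys


def _voronoi_edges(
    points: np.ndarray, domain: Polygon, n: int
) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Interior ridge segments between original seeds, clipped to the domain."""
    minr, minc, maxr, maxc = domain.bounds
    p = points
    mirrored = np.vstack(
        [
            p,
            np.column_stack([2 * minr - p[:, 0], p[:, 1]]),
            np.column_stack([2 * maxr - p[:, 0], p[:, 1]]),
            np.column_stack([p[:, 0], 2 * minc - p[:, 1]]),
            np.column_stack([p[:, 0], 2 * maxc - p[:, 1]]),
        ]
    )
    vor = Voronoi(mirrored)
    out = []
    for (i, j), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if i >= n and j >= n:
            continue
        if i >= n or j >= n:
            continue  # ridge with a mirror seed lies on the domain boundary
        if -1 in rv:
            continue
        seg = LineString(vor.vertices[list(rv)])
        clipped = seg.intersection(domain)
        if clipped.is_empty or clipped.length < 1e-9:
            continue
        if clipped.geom_type == "MultiLineString":
            clipped = max(clipped.geoms, key=lambda g: g.length)
        out.append(((int(min(i, j)), int(max(i, j))), np.asarray(clipped.coords)))
    return out


def _border_edges(
    cell_polys: list[Polygon], domain: Polygon
) -> list[tuple[int, np.ndarray]]:
    """Per-cell boundary polylines coincident with the domain boundary."""
    out = []
    boundary = domain.exterior
    for cid, poly in enumerate(cell_polys):
        inter = poly.exterior.intersection(boundary)
        if inter.is_empty:
            continue
        geoms = (
            list(inter.geoms) if inter.geom_type.startswith("Multi") else [inter]
        )
        lines = [g for g in geoms if g.geom_type == "LineString" and g.length > 1e-9]
        if not lines:
            continue
        merged = unary_union(lines)
        if merged.geom_type == "LineString":
            out.append((cid, np.asarray(merged.coords)))
        else:
            for g in merged.geoms:
                if g.length > 1e-9:
                    out.append((cid, np.asarray(g.coords)))
    return out


def _mesh_from_polys(
    points: np.ndarray,
    cell_polys: list[Polygon],
    domain: Polygon,
    image_shape: tuple[int, int],
    pixel_size: float,
    geometry: str,
) -> TissueMesh:
    cells = [
        MeshCell(
            id=i,
            vertices=np.asarray(poly.exterior.coords[:-1]),
            area_px=float(poly.area),
            centroid=np.asarray(poly.centroid.coords[0]),
        )
        for i, poly in enumerate(cell_polys)
    ]
    edges: list[MeshEdge] = []
    eid = 0
    if len(cell_polys) > 1:
        for (i, j), coords in _voronoi_edges(points, domain, len(cell_polys)):
            edges.append(MeshEdge(id=eid, cells=(i, j), polyline=coords))
            eid += 1
    for cid, coords in _border_edges(cell_polys, domain):
        edges.append(MeshEdge(id=eid, cells=(cid,), polyline=coords))
        eid += 1
    return TissueMesh(
        cells=cells,
        edges=edges,
        image_shape=image_shape,
        pixel_size=pixel_size,
        geometry=geometry,
    )


def generate_mesh(
    n_cells: int,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    geometry: str = "sheet",
    pixel_size: float = 0.2,
    lloyd_iterations: int = 4,
) -> TissueMesh:
    """Generate a polygonal cell tiling.

    ``geometry='sheet'`` tiles the whole field with a Lloyd-relaxed Voronoi
    mesh (centroidal, hence round-ish cells).  ``geometry='cluster'`` places
    one central cell surrounded by a ring — a compact rosette such as a
    migrating border-cell cluster — inside a disc; the ring cell at angle 0
    has the maximal column centroid and acts as the front (leading) cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    h, w = image_shape
    if geometry == "sheet":
        domain = box(0.0, 0.0, float(h), float(w))
    elif geometry == "cluster":
        if n_cells < 2:
            raise ValueError("a cluster needs >= 2 cells")
        radius = 0.38 * min(h, w)
        domain = Point(h / 2.0, w / 2.0).buffer(radius, quad_segs=24)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    if domain.area / n_cells < _MIN_CELL_AREA:
        raise ValueError(
            f"image {image_shape} too small for {n_cells} cells at >= 8 px diameter"
        )
    if n_cells == 1:
        poly = domain
        return _mesh_from_polys(
            np.asarray([[h / 2, w / 2]]), [poly], domain, image_shape, pixel_size, geometry
        )

    rng = np.random.default_rng(seed)
    if geometry == "cluster":
        ring = n_cells - 1
        r_ring = 0.55 * np.sqrt(domain.area / np.pi)
        # angle 0 points along +col so the front cell is unique
        angles = 2 * np.pi * np.arange(ring) / ring
        pts = [np.array([h / 2.0, w / 2.0])]
        pts += [
            np.array([h / 2.0 + r_ring * np.sin(a), w / 2.0 + r_ring * np.cos(a)])
            for a in angles
        ]
        points = np.asarray(pts)
        n_lloyd = 0
    else:
        minr, minc, maxr, maxc = domain.bounds
        points = np.column_stack(
            [rng.uniform(minr, maxr, n_cells), rng.uniform(minc, maxc, n_cells)]
        )
        n_lloyd = lloyd_iterations

    for _ in range(n_lloyd):
        polys = _polygon_cells(points, domain)
        points = np.asarray([p.centroid.coords[0] for p in polys])
    polys = _polygon_cells(points, domain)
    return _mesh_from_polys(points, polys, domain, image_shape, pixel_size, geometry)


def assign_ground_truth(
    mesh: TissueMesh,
    pattern: str = "uniform",
    e_low: float = 0.1,
    e_high: float = 0.3,
    seed: int = 0,
) -> GroundTruthTissue:
    """Assign a true FRET efficiency to every junction.

    Patterns mirror the tension layouts reported for the three tissues:

    - ``radial``: compressed central cells carry high FRET (low tension),
      stretched peripheral cells low FRET, with a linear radial ramp.
    - ``uniform``: every junction at ``e_low``.
    - ``front_back``: junctions of the cluster's front (leading) cell at
      ``e_low`` (high tension), all others at ``e_high``.
    """
    if not 0.0 <= e_low <= e_high <= 1.0:
        raise ValueError("need 0 <= e_low <= e_high <= 1")
    cells = mesh.cells
    labels: dict[int, str] = {}
    edge_e: dict[int, float] = {}

    if pattern == "uniform":
        labels = {c.id: "uniform" for c in cells}
        edge_e = {e.id: float(e_low) for e in mesh.edges}
    elif pattern == "radial":
        center = np.mean([c.centroid for c in cells], axis=0)
        radii = {c.id: float(np.linalg.norm(c.centroid - center)) for c in cells}
        rmax = max(radii.values()) or 1.0
        cell_e = {
            cid: e_high + (e_low - e_high) * (r / rmax) for cid, r in radii.items()
        }
        rmed = float(np.median(list(radii.values())))
        labels = {
            cid: "center-compressed" if radii[cid] <= rmed else "periphery-stretched"
            for cid in radii
        }
        for e in mesh.edges:
            edge_e[e.id] = float(np.mean([cell_e[c] for c in e.cells]))
    elif pattern == "front_back":
        front = mesh.front_cell()
        labels = {c.id: ("front" if c.id == front else "back") for c in cells}
        for e in mesh.edges:
            edge_e[e.id] = float(e_low if front in e.cells else e_high)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    return GroundTruthTissue(
        mesh=mesh,
        edge_efficiency=edge_e,
        cell_pattern_label=labels,
        pattern=pattern,
    )


def _boundary_damping(v: np.ndarray, image_shape: tuple[int, int], damp_px: float = 8.0):
    h, w = image_shape
    d = np.minimum.reduce([v[:, 0], h - v[:, 0], v[:, 1], w - v[:, 1]])
    return np.clip(d / damp_px, 0.0, 1.0)


def deform_mesh(mesh: TissueMesh, scales: dict[int, float]) -> TissueMesh:
    """Apply per-cell area scales via a smooth, tiling-preserving warp.

    Each cell pulls (or pushes) nearby vertices radially about its centroid
    with a Gaussian influence of its own radius; displacements are damped to
    zero at the field boundary so the total tiled area is conserved exactly
    for a sheet.  Because the warp is a function of position only, vertices
    shared between polygons stay shared and the tiling cannot tear.
    """
    cents = np.asarray([c.centroid for c in mesh.cells])
    sigmas = np.asarray([np.sqrt(c.area_px / np.pi) for c in mesh.cells])
    lin = np.asarray(
        [np.sqrt(max(scales.get(c.id, 1.0), 1e-6)) - 1.0 for c in mesh.cells]
    )
    # each cell is a Gaussian divergence source; the gain compensates the
    # kernel falloff between centroid and the cell's own vertices (~1.3 sigma)
    gain = float(np.exp(1.3**2 / 2.0))

    def warp(v: np.ndarray) -> np.ndarray:
        d = v[:, None, :] - cents[None, :, :]  # (m, n, 2)
        r2 = np.sum(d**2, axis=2)
        k = np.exp(-r2 / (2.0 * sigmas[None, :] ** 2))
        disp = gain * np.einsum("mn,n,mnk->mk", k, lin, d)
        disp *= _boundary_damping(v, mesh.image_shape)[:, None]
        return v + disp

    new_cells = []
    for c in mesh.cells:
        verts = warp(c.vertices)
        poly = Polygon(verts)
        new_cells.append(
            MeshCell(
                id=c.id,
                vertices=verts,
                area_px=float(poly.area),
                centroid=np.asarray(poly.centroid.coords[0]),
            )
        )
    new_edges = [
        MeshEdge(id=e.id, cells=e.cells, polyline=warp(e.polyline))
        for e in mesh.edges
    ]
    return TissueMesh(
        cells=new_cells,
        edges=new_edges,
        image_shape=mesh.image_shape,
        pixel_size=mesh.pixel_size,
        geometry=mesh.geometry,
    )


def pulsing_mesh_series(
    truth: GroundTruthTissue,
    n_timepoints: int = 8,
    interval_s: float = 60.0,
) -> list[GroundTruthTissue]:
    """Deform the mesh sinusoidally over time according to ``pulse_phase``.

    With the default 8 time-points at 60 s this reproduces a t = 0..7 min
    pulsing acquisition over a ~4 min contraction cycle.
    """
    if truth.pulse_phase is None:
        raise ValueError("truth has no pulse_phase assignments")
    out = []
    for k in range(n_timepoints):
        t = k * interval_s
        scales = {
            cid: 1.0
            + spec.amplitude * np.sin(2 * np.pi * t / spec.period_s + spec.phase_rad)
            for cid, spec in truth.pulse_phase.items()
        }
        mesh_t = deform_mesh(truth.mesh, scales)
        out.append(replace(truth, mesh=mesh_t))
    return out


def rasterize_labels(mesh: TissueMesh) -> np.ndarray:
    """Ground-truth label image: pixel value = cell id + 1 (0 = background).

    Half-open rasterization of each cell polygon; later cells win the few
    boundary pixels shared between neighbours.
    """
    from skimage.draw import polygon as draw_polygon

    h, w = mesh.image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    for c in mesh.cells:
        rr, cc = draw_polygon(c.vertices[:, 0], c.vertices[:, 1], shape=(h, w))
        labels[rr, cc] = c.id + 1
    return labels


def simulate_pulsing_records(
    n_cells: int,
    base_area_um2: float = 90.0,
    amplitude: float = 0.15,
    period_s: float = 240.0,
    interval_s: float = 60.0,
    base_fret: float = 0.235,
    delta_e: float = 0.0,
    noise_sd_area: float = 0.0,
    noise_sd_fret: float = 0.0,
    seed: int = 0,
):
    """Analytic per-cell pulsing trajectories (areas t0..t7 + FRET at t0/t7).

    Each cell's apical area follows ``A(t) = A0 (1 + a sin(2 pi t/T + phi))``
    with a random phase; ``delta_e`` couples the FRET index to the pulsing
    phase so that the index differs by ~``delta_e`` between the fully
    contracted and fully expanded states (contracted lower), providing the
    planted positive control that a working tension sensor would show.
    Returns a list of dicts consumable by :mod:`fretion.dynamics`.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(8) * interval_s
    records = []
    for cid in range(n_cells):
        phi = rng.uniform(0, 2 * np.pi)
        amp = amplitude * rng.uniform(0.6, 1.4)
        areas = base_area_um2 * (1 + amp * np.sin(2 * np.pi * t / period_s + phi))
        if noise_sd_area > 0:
            areas = areas * (1 + rng.normal(0, noise_sd_area, areas.shape))
        rel = (areas - base_area_um2) / base_area_um2
        fret = base_fret + delta_e * rel[[0, 7]] / (2.0 * amp)
        if noise_sd_fret > 0:
            fret = fret + rng.normal(0, noise_sd_fret, 2)
        records.append(
            {
                "cell_id": cid,
                "areas_um2": areas,
                "fret_t0": float(fret[0]),
                "fret_t7": float(fret[1]),
            }
        )
    return records
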