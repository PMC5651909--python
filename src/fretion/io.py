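"""Readers and writers for the package's on-disk formats.

Image stacks travel as multi-channel TIFF (channel order CFP, YFP, FRET,
ImageJ-style axes) with a JSON sidecar of generator/processing parameters;
ground truth and graph measurements as CSV tables; TCSPC decays as
two-column CSV (time_ns, counts) with a JSON header line.  CSV output is
formatted with fixed float precision so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cellgraph import CellGraph
from .decays import DecayHistogram
from .pipeline import FretMap
from .stack import ChannelStack
from .tissue import GroundTruthTissue

__all__ = [
    "write_stack",
    "read_stack",
    "write_truth_tables",
    "write_fret_map",
    "write_graph_tables",
    "write_decay_csv",
    "read_decay_csv",
]

_FLOAT_FMT = "%.6g"


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write a stack as CZYX (or CYX) TIFF plus a JSON parameter sidecar."""
    path = Path(path)
    arrs = [np.asarray(a) for a in (stack.cfp, stack.yfp, stack.fret)]
    data = np.stack(arrs)  # (3, z, h, w) or (3, h, w)
    axes = "CZYX" if data.ndim == 4 else "CYX"
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        photometric="minisblack",
        metadata={"axes": axes},
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            _jsonable(
                {
                    "bit_depth": stack.bit_depth,
                    "pixel_size": stack.pixel_size,
                    "channel_order": ["cfp", "yfp", "fret"],
                    "meta": stack.meta,
                }
            ),
            indent=2,
            sort_keys=True,
        )
    )
    return path


def read_stack(
    path: str | Path,
    channel_indices: tuple[int, int, int] = (0, 1, 2),
    bit_depth: int = 16,
    pixel_size: float = 0.2,
) -> ChannelStack:
    """Read a 3-channel TIFF; ``channel_indices`` maps (cfp, yfp, fret)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected a (C,[Z],Y,X) TIFF, got shape {data.shape}")
    sidecar = path.with_suffix(".json")
    meta = {}
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        bit_depth = info.get("bit_depth", bit_depth)
        pixel_size = info.get("pixel_size", pixel_size)
        meta = info.get("meta", {})
    ci, yi, fi = channel_indices
    return ChannelStack(
        cfp=np.asarray(data[ci], float),
        yfp=np.asarray(data[yi], float),
        fret=np.asarray(data[fi], float),
        bit_depth=bit_depth,
        pixel_size=pixel_size,
        meta=meta,
    )


def write_truth_tables(truth: GroundTruthTissue, out_dir: str | Path) -> dict:
    """cells.csv (id, centroid, area, label) and edges.csv (id, cells, length, E)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    px2 = truth.mesh.pixel_size**2
    cells = pd.DataFrame(
        {
            "cell_id": [c.id for c in truth.mesh.cells],
            "centroid_row": [c.centroid[0] for c in truth.mesh.cells],
            "centroid_col": [c.centroid[1] for c in truth.mesh.cells],
            "area_um2": [c.area_px * px2 for c in truth.mesh.cells],
            "label": [truth.cell_pattern_label[c.id] for c in truth.mesh.cells],
        }
    )
    edges = pd.DataFrame(
        {
            "edge_id": [e.id for e in truth.mesh.edges],
            "cell_a": [e.cells[0] for e in truth.mesh.edges],
            "cell_b": [e.cells[1] if e.is_interior else -1 for e in truth.mesh.edges],
            "length_um": [e.length_px * truth.mesh.pixel_size for e in truth.mesh.edges],
            "e_true": [truth.edge_efficiency[e.id] for e in truth.mesh.edges],
        }
    )
    paths = {"cells": out_dir / "cells.csv", "edges": out_dir / "edges.csv"}
    cells.to_csv(paths["cells"], index=False, float_format=_FLOAT_FMT)
    edges.to_csv(paths["edges"], index=False, float_format=_FLOAT_FMT)
    return paths


def write_fret_map(fmap: FretMap, path: str | Path) -> Path:
    """32-bit float TIFF with undefined pixels as NaN; mask as sibling TIFF."""
    path = Path(path)
    tifffile.imwrite(path, fmap.index.astype(np.float32))
    tifffile.imwrite(
        path.with_name(path.stem + "_mask.tif"),
        fmap.mask.astype(np.uint8) * 255,
    )
    return path


def write_graph_tables(graph: CellGraph, out_dir: str | Path, prefix: str = "seg") -> dict:
    """Segmented cells.csv / edges.csv mirroring the truth schema + FRET."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = pd.DataFrame(
        {
            "cell_id": [c.id for c in graph.cells.values()],
            "centroid_row": [c.centroid[0] for c in graph.cells.values()],
            "centroid_col": [c.centroid[1] for c in graph.cells.values()],
            "area_um2": [c.area_um2 for c in graph.cells.values()],
            "elongation": [c.elongation for c in graph.cells.values()],
            "orientation_rad": [c.orientation_rad for c in graph.cells.values()],
            "mean_fret": [c.mean_fret for c in graph.cells.values()],
            "n_fret_pixels": [c.n_fret_pixels for c in graph.cells.values()],
        }
    )
    edges = pd.DataFrame(
        {
            "edge_id": [e.id for e in graph.edges.values()],
            "cell_a": [e.cells[0] for e in graph.edges.values()],
            "cell_b": [e.cells[1] if e.is_interior else -1 for e in graph.edges.values()],
            "length_um": [e.length_um for e in graph.edges.values()],
            "orientation_rad": [e.orientation_rad for e in graph.edges.values()],
            "mean_fret": [e.mean_fret for e in graph.edges.values()],
            "n_fret_pixels": [e.n_fret_pixels for e in graph.edges.values()],
        }
    )
    paths = {
        "cells": out_dir / f"{prefix}_cells.csv",
        "edges": out_dir / f"{prefix}_edges.csv",
    }
    cells.to_csv(paths["cells"], index=False, float_format=_FLOAT_FMT)
    edges.to_csv(paths["edges"], index=False, float_format=_FLOAT_FMT)
    return paths


def write_decay_csv(decay: DecayHistogram, path: str | Path) -> Path:
    """Two-column CSV (time_ns, counts) preceded by a JSON header comment."""
    path = Path(path)
    header = json.dumps(
        _jsonable({"bin_width_ns": decay.bin_width_ns, **decay.meta}), sort_keys=True
    )
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("time_ns,counts\n")
        for t, c in zip(decay.times_ns, decay.counts):
            fh.write(f"{t:.6f},{c:.1f}\n")
    return path


def read_decay_csv(path: str | Path) -> DecayHistogram:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = json.loads(first[1:].strip())
    df = pd.read_csv(path, comment="#")
    bin_width = meta.get(
        "bin_width_ns", float(df["time_ns"].iloc[1] - df["time_ns"].iloc[0])
    )
    return DecayHistogram(
        times_ns=df["time_ns"].to_numpy(),
        counts=df["counts"].to_numpy(),
        bin_width_ns=bin_width,
        meta=meta,
    )
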