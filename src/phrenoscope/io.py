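"""File formats: skeleton JSON, SWC import, masks, expression tables.

Skeleton JSON schema::

    {"nodes": [{"id": 0, "x": 0.0, "y": 0.0}, ...],
     "edges": [{"parent": 0, "child": 1, "order": 1}, ...],
     "entry": 0, "side": "left", "scale_um_per_px": 1.0}

SWC-like import reads the usual 7-column format (id, type, x, y, z, radius,
parent); the type field is mapped to the branch order and z is ignored.
Masks are single-channel TIFF or PNG images, nonzero = foreground.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .lateralization import ExpressionMatrix
from .morphometry import NervePattern

__all__ = [
    "read_skeleton_json",
    "write_skeleton_json",
    "read_swc",
    "read_mask",
    "write_mask",
    "read_expression",
]

PathLike = Union[str, Path]


def read_skeleton_json(path: PathLike) -> NervePattern:
    doc = json.loads(Path(path).read_text())
    nodes = {int(n["id"]): (float(n["x"]), float(n["y"])) for n in doc["nodes"]}
    edges = [
        (int(e["parent"]), int(e["child"]), int(e["order"])) for e in doc["edges"]
    ]
    return NervePattern(nodes, edges, entry=int(doc["entry"]), side=doc["side"])


def write_skeleton_json(pattern: NervePattern, path: PathLike, scale: float = 1.0) -> None:
    doc = {
        "nodes": [
            {"id": i, "x": x, "y": y} for i, (x, y) in sorted(pattern.nodes.items())
        ],
        "edges": [
            {"parent": p, "child": c, "order": o} for p, c, o in pattern.edges
        ],
        "entry": pattern.entry,
        "side": pattern.side,
        "scale_um_per_px": scale,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_swc(path: PathLike, side: str = "left") -> NervePattern:
    """Import an SWC-like morphology file as a nerve pattern (2D, type=order)."""
    nodes: dict[int, tuple[float, float]] = {}
    edges: list[tuple[int, int, int]] = []
    entry = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        nid, ntype = int(cols[0]), int(cols[1])
        x, y = float(cols[2]), float(cols[3])
        parent = int(cols[6])
        nodes[nid] = (x, y)
        if parent == -1:
            entry = nid
        else:
            edges.append((parent, nid, max(ntype, 1)))
    if entry is None:
        raise ValueError("SWC file has no root node (parent == -1)")
    return NervePattern(nodes, edges, entry=entry, side=side)


def read_mask(path: PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0] if img.shape[-1] in (3, 4) else img.sum(axis=0)
    return np.asarray(img) > 0


def write_mask(mask: np.ndarray, path: PathLike) -> None:
    path = Path(path)
    img = (np.asarray(mask, dtype=bool) * np.uint8(255))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def read_expression(
    values_csv: PathLike, calls_csv: PathLike, meta_csv: PathLike
) -> ExpressionMatrix:
    """Assemble an expression matrix from its three companion CSV files.

    ``values_csv`` and ``calls_csv`` have probes as rows and samples as
    columns (calls are "P"/"A" or booleans); ``meta_csv`` has columns
    sample, embryo, side.
    """
    values = pd.read_csv(values_csv, index_col=0)
    calls_raw = pd.read_csv(calls_csv, index_col=0)
    calls = calls_raw.isin(["P", "True", True])
    meta = pd.read_csv(meta_csv).set_index("sample")
    return ExpressionMatrix(values, calls, meta)
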