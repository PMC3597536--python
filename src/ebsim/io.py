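"""File I/O: cell/edge tables (CSV) and raster renders of virtual sections.

CSV is the canonical tabular format.  Floats are written with ``repr`` so a
read/write round trip reproduces the arrays bit-exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .geometry import Aggregate, CellState
from .structure import SectionView

__all__ = [
    "write_cells_csv",
    "read_cells_csv",
    "write_edges_csv",
    "read_edges_csv",
    "render_section",
]

_STATE_TO_STR = {int(CellState.OCT4_POS): "POS", int(CellState.OCT4_NEG): "NEG"}
_STR_TO_STATE = {"POS": int(CellState.OCT4_POS), "NEG": int(CellState.OCT4_NEG)}

#: Section render colours: Oct4+ cyan, Oct4− dark blue.
COLOR_POS = (0, 255, 255)
COLOR_NEG = (0, 0, 139)


def write_cells_csv(agg: Aggregate, path: str | Path) -> None:
    """Write the cell table: id,x_um,y_um,z_um,radius_um,state (POS/NEG)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x_um", "y_um", "z_um", "radius_um", "state"])
        for i in range(agg.n_cells):
            x, y, z = agg.positions[i]
            w.writerow(
                [
                    int(agg.ids[i]),
                    repr(float(x)),
                    repr(float(y)),
                    repr(float(z)),
                    repr(float(agg.radii[i])),
                    _STATE_TO_STR[int(agg.states[i])],
                ]
            )


def read_cells_csv(path: str | Path, contact_slack: float | None = None) -> Aggregate:
    """Read a cell table; optionally rebuild the contact graph."""
    ids, pos, radii, states = [], [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ids.append(int(row["id"]))
            pos.append((float(row["x_um"]), float(row["y_um"]), float(row["z_um"])))
            radii.append(float(row["radius_um"]))
            states.append(_STR_TO_STATE[row["state"].strip().upper()])
    agg = Aggregate(
        np.array(pos, dtype=float),
        np.array(radii, dtype=float),
        np.array(states, dtype=np.int8),
        ids=np.array(ids, dtype=np.int64),
    )
    if contact_slack is not None:
        agg.refresh_edges(contact_slack)
    return agg


def write_edges_csv(agg: Aggregate, path: str | Path) -> None:
    """Write the edge table: id_a,id_b,length_um."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id_a", "id_b", "length_um"])
        for (i, j), length in zip(agg.edges, agg.edge_lengths):
            w.writerow([int(agg.ids[i]), int(agg.ids[j]), repr(float(length))])


def read_edges_csv(path: str | Path) -> list[tuple[int, int, float]]:
    """Read an edge table as (id_a, id_b, length_um) tuples."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append((int(row["id_a"]), int(row["id_b"]), float(row["length_um"])))
    return out


def render_section(
    section: SectionView,
    path: str | Path,
    resolution: float = 0.25,
    scale_bar_um: float = 25.0,
) -> None:
    """Render a virtual section to a raster image.

    Oct4+ cells are drawn cyan, Oct4− cells dark blue, on black, with a
    white scale bar (default 25 µm).  Pixel output is deterministic for a
    given section.
    """
    if section.n_cells == 0:
        raise ValueError("cannot render an empty section")
    xy = section.positions
    r = section.radii
    lo = (xy - r[:, None]).min(axis=0) - 2 * resolution
    hi = (xy + r[:, None]).max(axis=0) + 2 * resolution
    size = np.maximum(((hi - lo) / resolution).astype(int) + 1, 32)
    img = Image.new("RGB", (int(size[0]), int(size[1]) + 12), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    order = np.argsort(section.ids)  # deterministic draw order
    for k in order:
        cx, cy = (xy[k] - lo) / resolution
        rr = r[k] / resolution
        color = COLOR_POS if section.states[k] == int(CellState.OCT4_POS) else COLOR_NEG
        draw.ellipse([cx - rr, cy - rr, cx + rr, cy + rr], fill=color)
    bar_px = scale_bar_um / resolution
    h = img.height
    draw.line([(4, h - 6), (4 + bar_px, h - 6)], fill=(255, 255, 255), width=2)
    img.save(path, format="PNG")
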