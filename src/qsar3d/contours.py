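"""STDEV*COEFF contour fields and OpenDX export.

The quantity contoured in 3D-QSAR maps is the per-column product of the
descriptor standard deviation and the PLS regression coefficient,
``s_j · b_j``, mapped back onto the lattice of the column's field.
Positive lobes mark regions where more of the property favors activity;
the displayed iso-levels are percentiles of the nonzero value
distribution (customarily 80/20).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import FieldMatrix, GridSpec
from .pls import PLSQsar

__all__ = ["ContourMap", "stdev_coeff_field", "contour_levels", "export_dx", "read_dx", "top_loci"]


@dataclass
class ContourMap:
    """Per-grid-point STDEV*COEFF values for one field (masked columns 0)."""

    field_type: str
    values: np.ndarray  # length grid.n_points, grid C order
    grid: GridSpec
    favored_level: float | None = None
    disfavored_level: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """(x, y, z, field, stdev_coeff) records."""
        pts = self.grid.points()
        return pd.DataFrame({
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
            "field": self.field_type, "stdev_coeff": self.values,
        })


def stdev_coeff_field(model: PLSQsar, fmatrix: FieldMatrix, field_type: str,
                      descale: bool = True) -> ContourMap:
    """STDEV*COEFF values of one field mapped onto its grid points.

    For each active column j of the field, ``value = s_j · b_j`` (s_j the
    active-column standard deviation on the descriptor scale); inactive
    columns are 0.  With ``descale=True`` the block scale divisor is
    undone so values across fields share the raw field units.
    """
    fields_all = fmatrix.column_meta["field"].to_numpy()
    if field_type not in fields_all:
        raise ValueError(f"field {field_type!r} absent from the descriptor matrix")
    active_fields = fmatrix.active_fields
    sc = model.coef_ * model._x_std  # per active column
    values = np.zeros(fmatrix.grid.n_points)
    sel = active_fields == field_type
    gidx = fmatrix.column_meta["grid_index"].to_numpy()[fmatrix.active_mask][sel]
    v = sc[sel]
    if descale:
        # s_j on the descriptor scale already includes the 1/scale factor;
        # de-scaling restores the raw-field-unit stdev
        v = v * fmatrix.block_scales.get(field_type, 1.0)
    values[gidx] = v
    return ContourMap(field_type=field_type, values=values, grid=fmatrix.grid)


def contour_levels(cmap: ContourMap, favored_pct: float = 80.0,
                   disfavored_pct: float = 20.0) -> tuple[float, float]:
    """Iso-levels at percentiles of the nonzero STDEV*COEFF distribution."""
    nz = cmap.values[cmap.values != 0]
    if nz.size == 0:
        raise ValueError("contour map is identically zero; levels undefined")
    fav = float(np.percentile(nz, favored_pct))
    dis = float(np.percentile(nz, disfavored_pct))
    cmap.favored_level, cmap.disfavored_level = fav, dis
    return fav, dis


def top_loci(cmap: ContourMap, k: int = 5) -> pd.DataFrame:
    """Top-k favored and disfavored lattice points, for map summaries."""
    df = cmap.to_frame()
    fav = df.nlargest(k, "stdev_coeff").assign(kind="favored")
    dis = df.nsmallest(k, "stdev_coeff").assign(kind="disfavored")
    return pd.concat([fav, dis], ignore_index=True)


def export_dx(cmap: ContourMap, path: str | Path) -> None:
    """Write the map as an OpenDX regular scalar field.

    Data follow the grid's C order (z fastest), matching the OpenDX
    convention for gridpositions counts nx ny nz.
    """
    g = cmap.grid
    nx, ny, nz = g.dims
    ox, oy, oz = g.origin
    d = g.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {d:.6f} 0.000000 0.000000",
        f"delta 0.000000 {d:.6f} 0.000000",
        f"delta 0.000000 0.000000 {d:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {g.n_points} data follows",
    ]
    vals = cmap.values
    for i in range(0, len(vals), 3):
        lines.append(" ".join(f"{v:.6e}" for v in vals[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append(f'object "{cmap.field_type}" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> ContourMap:
    """Read an OpenDX regular scalar field written by :func:`export_dx`."""
    lines = Path(path).read_text().splitlines()
    dims = origin = None
    deltas = []
    data: list[float] = []
    in_data = False
    n_items = 0
    for line in lines:
        s = line.strip()
        if s.startswith("object 1"):
            dims = tuple(int(x) for x in s.split("counts")[1].split())
        elif s.startswith("origin"):
            origin = tuple(float(x) for x in s.split()[1:4])
        elif s.startswith("delta"):
            deltas.append([float(x) for x in s.split()[1:4]])
        elif "data follows" in s:
            n_items = int(s.split("items")[1].split()[0])
            in_data = True
        elif in_data and len(data) < n_items:
            data.extend(float(x) for x in s.split())
    if dims is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a regular OpenDX scalar field")
    spacing = float(deltas[0][0])
    grid = GridSpec(origin=origin, spacing=spacing, dims=dims)
    values = np.array(data[: grid.n_points])
    return ContourMap(field_type="dx", values=values, grid=grid)
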