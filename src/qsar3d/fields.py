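"""Lattice construction and molecular interaction fields.

Two descriptor families are computed on a rectangular lattice that
surrounds the aligned series:

* probe-interaction fields — Lennard-Jones steric and Coulomb
  electrostatic energies of an sp3-carbon-like probe (radius 1.52 Å,
  charge +1 e) at every grid point, clamped at an energy cutoff;
* Gaussian similarity-index fields — singularity-free similarity values
  ``A_F(q) = −Σ_i w_probe · w_i · exp(−α r_iq²)`` for steric (w = r_vdw³),
  electrostatic (w = partial charge), hydrophobic and H-bond donor /
  acceptor (indicator) properties.

Columns are ordered by (field, grid index), near-constant columns are
masked out, and each field block may be scaled by its pooled standard
deviation so no single field dominates the regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import DataSet, Molecule

__all__ = [
    "COULOMB_CONSTANT",
    "GridSpec",
    "FieldConfig",
    "FieldMatrix",
    "build_grid",
    "comfa_steric",
    "comfa_electrostatic",
    "comsia_field",
    "assemble_matrix",
    "FieldGenerator",
]

#: Coulomb prefactor in kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.17

COMFA_FIELDS = ("S", "E")
COMSIA_FIELDS = ("S", "E", "H", "D", "A")


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice: ``origin + spacing * (i, j, k)`` for
    ``0 ≤ i < nx`` etc.  Point (column) order is C order over (i, j, k)."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("each grid dimension must be at least 2")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """(n_points, 3) array of lattice coordinates, Å."""
        nx, ny, nz = self.dims
        idx = np.indices((nx, ny, nz)).reshape(3, -1).T  # C order: k fastest
        return np.asarray(self.origin) + self.spacing * idx


@dataclass(frozen=True)
class FieldConfig:
    """Probe and lattice settings.

    Defaults follow the customary probe: sp3-carbon radius 1.52 Å with
    +1 e charge, 30 kcal/mol energy cutoff, 2 Å spacing, 4 Å margin,
    Gaussian attenuation α = 0.3 Å⁻².  ``min_sigma`` is the column
    standard-deviation threshold below which a column is dropped (energy
    units for probe fields); ``block_scaling`` is ``'none'`` or
    ``'block_std'``.
    """

    probe_radius: float = 1.52
    probe_charge: float = 1.0
    probe_well_depth: float = 0.107
    energy_cutoff: float = 30.0
    attenuation_alpha: float = 0.3
    comsia_probe_weight: float = 1.0
    min_sigma: float = 2.0
    block_scaling: str = "block_std"
    elec_excluded: str = "column_mean"  # or "clamp": keep the clamped value

    def __post_init__(self) -> None:
        if self.energy_cutoff <= 0:
            raise ValueError("energy_cutoff must be positive")
        if self.attenuation_alpha <= 0:
            raise ValueError("attenuation_alpha must be positive")
        if self.block_scaling not in ("none", "block_std"):
            raise ValueError("block_scaling must be 'none' or 'block_std'")


def build_grid(data: DataSet | list[Molecule], spacing: float = 2.0, margin: float = 4.0) -> GridSpec:
    """Lattice enclosing the union bounding box of the aligned molecules,
    extended by ``margin`` on all sides."""
    mols = list(data)
    if not mols:
        raise ValueError("cannot build a grid from an empty data set")
    if spacing <= 0 or margin <= 0:
        raise ValueError("spacing and margin must be positive")
    coords = np.vstack([m.coords for m in mols])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(float(x) for x in lo), spacing=float(spacing), dims=dims)


def _distances(mol: Molecule, grid: GridSpec) -> np.ndarray:
    """(n_points, n_atoms) probe–atom distance matrix."""
    pts = grid.points()
    d = pts[:, None, :] - mol.coords[None, :, :]
    return np.sqrt((d * d).sum(axis=2))


def comfa_steric(mol: Molecule, grid: GridSpec, cfg: FieldConfig = FieldConfig()) -> np.ndarray:
    """Lennard-Jones probe energy at every grid point, kcal/mol.

    ``E(q) = Σ_i ε_ip [(R_ip/r)¹² − 2 (R_ip/r)⁶]`` with
    ``R_ip = r_vdw,i + probe_radius`` and ``ε_ip = sqrt(ε_i · ε_probe)``;
    the sum is clamped at ``+energy_cutoff`` and points essentially on an
    atom (r < 0.01 Å) are set to the cutoff.
    """
    r = _distances(mol, grid)
    radii = np.array([a.vdw_radius for a in mol.atoms])
    eps = np.sqrt(np.array([a.well_depth for a in mol.atoms]) * cfg.probe_well_depth)
    if not np.all(np.isfinite(radii)) or not np.all(np.isfinite(eps)):
        raise ValueError(f"molecule {mol.id!r}: atom parameters not assigned")
    on_atom = r < 0.01
    rs = np.where(on_atom, 0.01, r)
    frac = (radii[None, :] + cfg.probe_radius) / rs
    e = (eps[None, :] * (frac**12 - 2.0 * frac**6)).sum(axis=1)
    e[on_atom.any(axis=1)] = cfg.energy_cutoff
    return np.minimum(e, cfg.energy_cutoff)


def comfa_electrostatic(mol: Molecule, grid: GridSpec, cfg: FieldConfig = FieldConfig()) -> np.ndarray:
    """Coulomb probe energy with distance-dependent dielectric ε(r) = r:
    ``E(q) = Σ_i k q_i q_probe / r²``, clamped at ±energy_cutoff."""
    r = np.maximum(_distances(mol, grid), 0.01)
    q = mol.charges
    e = (COULOMB_CONSTANT * cfg.probe_charge * q[None, :] / (r * r)).sum(axis=1)
    return np.clip(e, -cfg.energy_cutoff, cfg.energy_cutoff)


_COMSIA_WEIGHT = {
    "S": lambda a: a.vdw_radius**3,
    "E": lambda a: a.partial_charge,
    "H": lambda a: a.hydrophobicity,
    "D": lambda a: 1.0 if a.is_donor else 0.0,
    "A": lambda a: 1.0 if a.is_acceptor else 0.0,
}


def comsia_field(mol: Molecule, grid: GridSpec, property: str, cfg: FieldConfig = FieldConfig()) -> np.ndarray:
    """Gaussian similarity index ``A_F(q) = −Σ_i w_p w_i exp(−α r²)``.

    Finite everywhere (no singularity at atom centers).  ``property`` is
    one of S, E, H, D, A.
    """
    try:
        wfun = _COMSIA_WEIGHT[property]
    except KeyError:
        raise ValueError(f"unknown similarity property {property!r} (use S, E, H, D or A)") from None
    w = np.array([wfun(a) for a in mol.atoms])
    if not np.all(np.isfinite(w)):
        raise ValueError(f"molecule {mol.id!r}: atom parameters not assigned")
    r2 = _distances(mol, grid) ** 2
    return -(cfg.comsia_probe_weight * w[None, :] * np.exp(-cfg.attenuation_alpha * r2)).sum(axis=1)


@dataclass
class FieldMatrix:
    """Molecules × (grid point, field) descriptor block.

    ``values`` holds the raw field values (after excluded-point
    substitution); ``column_meta`` one row per column with ``field`` and
    ``grid_index``; ``active_mask`` flags columns that survived the
    minimum-sigma filter; ``block_scales`` maps field → divisor applied to
    that block when building the regression descriptors.
    """

    values: np.ndarray
    column_meta: pd.DataFrame
    active_mask: np.ndarray
    block_scales: dict[str, float]
    grid: GridSpec
    ids: list[str] = dc_field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def fields(self) -> list[str]:
        return list(dict.fromkeys(self.column_meta["field"]))

    @property
    def active_fields(self) -> np.ndarray:
        """Field label of each active column."""
        return self.column_meta["field"].to_numpy()[self.active_mask]

    @property
    def descriptors(self) -> np.ndarray:
        """Active, block-scaled descriptor matrix for regression."""
        X = self.values[:, self.active_mask].astype(float).copy()
        fields = self.active_fields
        for f, s in self.block_scales.items():
            X[:, fields == f] /= s
        return X

    def rows(self, ids: list[str]) -> "FieldMatrix":
        """Sub-matrix for the named molecules (same columns/mask/scales)."""
        pos = [self.ids.index(i) for i in ids]
        return FieldMatrix(self.values[pos], self.column_meta, self.active_mask,
                           dict(self.block_scales), self.grid, list(ids))


def _raw_block(mol: Molecule, grid: GridSpec, cfg: FieldConfig, method: str,
               fields: tuple[str, ...]) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-field raw vectors for one molecule plus the sterically-excluded
    point mask (probe-field method only)."""
    out: dict[str, np.ndarray] = {}
    excluded = np.zeros(grid.n_points, dtype=bool)
    if method == "CoMFA":
        steric = comfa_steric(mol, grid, cfg)
        excluded = steric >= cfg.energy_cutoff
        for f in fields:
            if f == "S":
                out["S"] = steric
            elif f == "E":
                out["E"] = comfa_electrostatic(mol, grid, cfg)
            else:
                raise ValueError(f"probe-field method supports S and E only, got {f!r}")
    elif method == "CoMSIA":
        for f in fields:
            out[f] = comsia_field(mol, grid, f, cfg)
    else:
        raise ValueError(f"unknown field method {method!r} (use 'CoMFA' or 'CoMSIA')")
    return out, excluded


def assemble_matrix(data: DataSet, grid: GridSpec, cfg: FieldConfig = FieldConfig(),
                    method: str = "CoMFA", fields: tuple[str, ...] | None = None) -> FieldMatrix:
    """Build the descriptor matrix for an aligned, parameterized series.

    Electrostatic values at sterically excluded points (steric energy at
    the cutoff) are replaced by the column mean over non-excluded
    molecules; columns with standard deviation below ``cfg.min_sigma``
    (or exactly zero) are deactivated; with ``block_scaling='block_std'``
    each field block is divided by its pooled column standard deviation.
    """
    gen = FieldGenerator(method=method, fields=fields, config=cfg, grid=grid)
    gen.fit(data)
    return gen.matrix_


class FieldGenerator(BaseEstimator, TransformerMixin):
    """sklearn-style featurizer: aligned molecules → field descriptor matrix.

    Parameters
    ----------
    method : {'CoMFA', 'CoMSIA'}
        Probe-interaction (Lennard-Jones + Coulomb) or Gaussian
        similarity-index fields.
    fields : tuple of str, optional
        Field subset; defaults to ('S', 'E') for CoMFA and
        ('S', 'E', 'H', 'D', 'A') for CoMSIA.
    config : FieldConfig
        Probe, cutoff, filtering and scaling settings.
    spacing, margin : float
        Lattice geometry used when no explicit ``grid`` is supplied.
    grid : GridSpec, optional
        Freeze the lattice instead of deriving it from the fitted data.

    Attributes
    ----------
    grid_ : GridSpec
    matrix_ : FieldMatrix          (training matrix from ``fit``)
    active_mask_, block_scales_, column_meta_ : column bookkeeping reused
        verbatim by ``transform`` so new molecules map onto training columns.
    """

    def __init__(self, method: str = "CoMFA", fields: tuple[str, ...] | None = None,
                 config: FieldConfig = FieldConfig(), spacing: float = 2.0,
                 margin: float = 4.0, grid: GridSpec | None = None):
        self.method = method
        self.fields = fields
        self.config = config
        self.spacing = spacing
        self.margin = margin
        self.grid = grid

    def _field_tuple(self) -> tuple[str, ...]:
        if self.fields is not None:
            known = COMFA_FIELDS if self.method == "CoMFA" else COMSIA_FIELDS
            bad = [f for f in self.fields if f not in known]
            if bad:
                raise ValueError(f"fields {bad} not available for method {self.method}")
            return tuple(self.fields)
        return COMFA_FIELDS if self.method == "CoMFA" else COMSIA_FIELDS

    def _raw_matrix(self, data: DataSet, grid: GridSpec):
        fields = self._field_tuple()
        g = grid.n_points
        rows, excl_rows = [], []
        for mol in data:
            per_field, excluded = _raw_block(mol, grid, self.config, self.method, fields)
            rows.append(np.concatenate([per_field[f] for f in fields]))
            excl_rows.append(excluded)
        return np.vstack(rows), np.vstack(excl_rows), fields, g

    def fit(self, data: DataSet, y=None) -> "FieldGenerator":
        if len(list(data)) == 0:
            raise ValueError("empty data set")
        grid = self.grid if self.grid is not None else build_grid(data, self.spacing, self.margin)
        values, excluded, fields, g = self._raw_matrix(data, grid)
        cfg = self.config
        meta = pd.DataFrame({
            "field": np.repeat(list(fields), g),
            "grid_index": np.tile(np.arange(g), len(fields)),
        })
        # electrostatic substitution at sterically excluded lattice points
        fill = np.zeros(g)
        if self.method == "CoMFA" and "E" in fields and cfg.elec_excluded == "column_mean":
            e0 = list(fields).index("E") * g
            E = values[:, e0:e0 + g]
            ok = ~excluded
            with np.errstate(invalid="ignore"):
                fill = np.where(ok.any(axis=0), (E * ok).sum(axis=0) / np.maximum(ok.sum(axis=0), 1), 0.0)
            values[:, e0:e0 + g] = np.where(excluded, fill[None, :], E)
        std = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
        active = (std > 0) & (std >= cfg.min_sigma)
        if not active.any():
            raise ValueError("all descriptor columns were filtered out (no variance above min_sigma)")
        scales = {f: 1.0 for f in fields}
        if cfg.block_scaling == "block_std":
            farr = meta["field"].to_numpy()
            for f in fields:
                block = std[(farr == f) & active]
                if block.size:
                    s = float(np.sqrt(np.mean(block**2)))
                    scales[f] = s if s > 0 else 1.0
        self.grid_ = grid
        self.column_meta_ = meta
        self.active_mask_ = active
        self.block_scales_ = scales
        self._elec_fill = fill
        self._fields = fields
        self.matrix_ = FieldMatrix(values, meta, active, scales, grid, [m.id for m in data])
        return self

    def transform(self, data: DataSet) -> FieldMatrix:
        """Field matrix for new molecules on the training lattice, with the
        training column mask, scales and excluded-point fill values."""
        if not hasattr(self, "grid_"):
            raise RuntimeError("FieldGenerator is not fitted")
        values, excluded, fields, g = self._raw_matrix(data, self.grid_)
        if fields != self._fields:
            raise ValueError("field set changed between fit and transform")
        if self.method == "CoMFA" and "E" in fields and self.config.elec_excluded == "column_mean":
            e0 = list(fields).index("E") * g
            E = values[:, e0:e0 + g]
            values[:, e0:e0 + g] = np.where(excluded, self._elec_fill[None, :], E)
        return FieldMatrix(values, self.column_meta_, self.active_mask_,
                           dict(self.block_scales_), self.grid_, [m.id for m in data])
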