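"""Rigid common-core alignment of a congeneric series onto a template.

Every molecule shares a user-defined core substructure (SMARTS); each is
superposed onto the template by the rotation + translation that minimizes
the RMSD over the mapped core atoms (Kabsch, proper rotation only).
Symmetry-equivalent matches are resolved deterministically by taking the
lexicographically smallest atom-index tuple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import DataSet, Molecule

__all__ = ["CoreMapping", "AlignmentError", "match_core", "superpose_kabsch", "align_set", "CoreAligner"]

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Core matching or superposition failed."""


@dataclass(frozen=True)
class CoreMapping:
    """Pairing of core-pattern atoms between template and a molecule.

    ``template_atom_indices[k]`` corresponds to ``molecule_atom_indices[k]``;
    at least three non-collinear pairs are needed for a unique rigid fit.
    """

    template_atom_indices: tuple[int, ...]
    molecule_atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.template_atom_indices) != len(self.molecule_atom_indices):
            raise ValueError("mapping index tuples differ in length")
        if len(self.template_atom_indices) < 3:
            raise ValueError("a rigid superposition needs at least 3 mapped atoms")
        for idxs in (self.template_atom_indices, self.molecule_atom_indices):
            if len(set(idxs)) != len(idxs):
                raise ValueError("mapping is not one-to-one")


def _pattern_match(mol: Molecule, pattern: Chem.Mol) -> tuple[int, ...]:
    rdmol = mol.to_rdkit(sanitize=True)
    matches = rdmol.GetSubstructMatches(pattern, uniquify=False)
    if not matches:
        raise AlignmentError(f"core pattern not found in molecule {mol.id!r}")
    distinct = sorted(set(matches))
    if len(distinct) > 1:
        logger.warning(
            "molecule %r: %d symmetry-equivalent core matches; "
            "using the lexicographically smallest index tuple",
            mol.id, len(distinct),
        )
    return distinct[0]


def match_core(mol: Molecule, core: str | Chem.Mol) -> tuple[int, ...]:
    """Match the core substructure pattern (SMARTS) against ``mol``.

    Returns the atom indices of ``mol`` matched to the pattern atoms, in
    pattern-atom order; deterministic (smallest index tuple on ties).
    """
    pattern = Chem.MolFromSmarts(core) if isinstance(core, str) else core
    if pattern is None:
        raise AlignmentError(f"invalid SMARTS pattern: {core!r}")
    return _pattern_match(mol, pattern)


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of points ``P`` onto ``Q``.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det = +1) such
    that ``P @ R.T + t ≈ Q`` minimizes the RMSD.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise AlignmentError("core atoms are collinear; superposition is degenerate")
    t = qc - pc @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return R, t, rmsd


def superpose_kabsch(mobile: Molecule, mapping: CoreMapping, template: Molecule) -> tuple[Molecule, float]:
    """Rigidly transform ``mobile`` so its mapped core atoms best overlay
    the template's; returns the transformed copy and the core RMSD (Å)."""
    P = mobile.coords[list(mapping.molecule_atom_indices)]
    Q = template.coords[list(mapping.template_atom_indices)]
    for k, (ti, mi) in enumerate(zip(mapping.template_atom_indices, mapping.molecule_atom_indices)):
        te, me = template.atoms[ti].element, mobile.atoms[mi].element
        if te != me:
            raise AlignmentError(
                f"mapped atom pair {k} has mismatched elements ({te} vs {me})"
            )
    R, t, rmsd = kabsch_rotation(P, Q)
    out = mobile.copy()
    out.coords = mobile.coords @ R.T + t
    return out, rmsd


def align_set(data: DataSet, core: str, template_id: str) -> DataSet:
    """Superpose every molecule of ``data`` onto the template molecule.

    All molecules must match the core pattern; the template keeps its
    coordinates.  Per-molecule core RMSDs are logged at INFO level.
    """
    aligner = CoreAligner(core_smarts=core, template_id=template_id)
    aligner.fit(data)
    return aligner.transform(data)


class CoreAligner(BaseEstimator, TransformerMixin):
    """sklearn-style transformer for Distill-like rigid core alignment.

    Parameters
    ----------
    core_smarts : str
        Substructure pattern shared by every molecule in the series.
    template_id : str
        Id of the reference molecule; all others are superposed onto it.

    Attributes
    ----------
    template_ : Molecule
        Copy of the template molecule (coordinates frozen at fit time).
    template_core_idx_ : tuple of int
        Template atom indices matched to the core pattern atoms.
    rmsd_ : dict
        Per-molecule core RMSD (Å) from the last ``transform`` call.
    """

    def __init__(self, core_smarts: str = "", template_id: str = ""):
        self.core_smarts = core_smarts
        self.template_id = template_id

    def fit(self, data: DataSet, y=None) -> "CoreAligner":
        pattern = Chem.MolFromSmarts(self.core_smarts)
        if pattern is None:
            raise AlignmentError(f"invalid SMARTS pattern: {self.core_smarts!r}")
        try:
            template = data[self.template_id]
        except KeyError as exc:
            raise AlignmentError(f"template molecule {self.template_id!r} not in data set") from exc
        self._pattern = pattern
        self.template_ = template.copy()
        self.template_core_idx_ = _pattern_match(template, pattern)
        return self

    def transform(self, data: DataSet) -> DataSet:
        failures = []
        aligned = []
        rmsds: dict[str, float] = {}
        for mol in data:
            try:
                mol_idx = _pattern_match(mol, self._pattern)
                mapping = CoreMapping(self.template_core_idx_, mol_idx)
                moved, rmsd = superpose_kabsch(mol, mapping, self.template_)
            except AlignmentError as exc:
                failures.append((mol.id, str(exc)))
                continue
            rmsds[mol.id] = rmsd
            logger.info("aligned %s onto %s: core RMSD %.4f Å", mol.id, self.template_id, rmsd)
            aligned.append(moved)
        if failures:
            ids = ", ".join(f"{mid} ({msg})" for mid, msg in failures)
            raise AlignmentError(f"alignment failed for: {ids}")
        self.rmsd_ = rmsds
        return DataSet(aligned, dict(data.split))
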