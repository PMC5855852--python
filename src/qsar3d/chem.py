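"""Molecular data model, structure IO and per-atom parameterization.

The package works on a lightweight :class:`Molecule` container (atoms with
3D coordinates, partial charges and the physicochemical parameters the
interaction fields need) rather than carrying RDKit molecules through the
whole pipeline.  RDKit is used at the boundaries: file parsing, partial
charge assignment (Gasteiger PEOE) and substructure matching.

Units: coordinates in Å, partial charges in elementary charge units,
Lennard-Jones well depths in kcal/mol, activities as pEC50 (−log10 M).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "Atom",
    "Molecule",
    "DataSet",
    "ParseError",
    "ParameterError",
    "read_structures",
    "write_structures",
    "assign_gasteiger_charges",
    "assign_atom_parameters",
    "load_parameter_table",
]


class ParseError(ValueError):
    """A structure file could not be parsed."""


class ParameterError(KeyError):
    """An atom type has no entry in the parameter table."""


@dataclass
class Atom:
    """One atom: element, position and the per-atom field parameters.

    ``vdw_radius``/``well_depth`` parameterize the Lennard-Jones steric
    probe interaction; ``hydrophobicity`` and the donor/acceptor flags
    weight the Gaussian similarity fields.
    """

    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    vdw_radius: float = float("nan")
    well_depth: float = float("nan")
    hydrophobicity: float = float("nan")
    is_donor: bool = False
    is_acceptor: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        self.is_donor = bool(self.is_donor)
        self.is_acceptor = bool(self.is_acceptor)


@dataclass
class Molecule:
    """A small molecule: ordered atoms, bonds and an optional activity.

    Bonds are ``(i, j, order)`` triples of 0-based atom indices; ``order``
    is 1, 2, 3 or 1.5 for aromatic bonds.
    """

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    activity: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.position for a in self.atoms])

    @coords.setter
    def coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, p in zip(self.atoms, xyz):
            a.position = p.copy()

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def copy(self) -> "Molecule":
        return copy.deepcopy(self)

    def formal_charge(self) -> int:
        """Nearest integer to the partial-charge sum (total molecular charge)."""
        return int(round(float(self.charges.sum())))

    def check_charge_sum(self, tol: float = 0.01) -> None:
        s = float(self.charges.sum())
        if abs(s - round(s)) > tol:
            raise ValueError(
                f"molecule {self.id!r}: partial charges sum to {s:.4f}, "
                f"more than {tol} e from an integer formal charge"
            )

    # -- RDKit bridge -----------------------------------------------------

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        """Build an RDKit molecule (explicit H, 3D conformer, charges as
        the ``_GasteigerCharge`` look-alike property ``partial_charge``)."""
        em = Chem.RWMol()
        for a in self.atoms:
            ra = Chem.Atom(a.element)
            ra.SetNoImplicit(True)
            em.AddAtom(ra)
        order_map = {
            1.0: Chem.BondType.SINGLE,
            2.0: Chem.BondType.DOUBLE,
            3.0: Chem.BondType.TRIPLE,
            1.5: Chem.BondType.AROMATIC,
        }
        for i, j, o in self.bonds:
            em.AddBond(int(i), int(j), order_map.get(float(o), Chem.BondType.SINGLE))
        mol = em.GetMol()
        conf = Chem.Conformer(len(self.atoms))
        for idx, a in enumerate(self.atoms):
            conf.SetAtomPosition(idx, tuple(float(x) for x in a.position))
        mol.AddConformer(conf)
        for idx, a in enumerate(self.atoms):
            mol.GetAtomWithIdx(idx).SetDoubleProp("partial_charge", float(a.partial_charge))
        if sanitize:
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                # fall back to a permissive sanitization: synthetic parameter
                # bundles need not be textbook valence chemistry
                Chem.SanitizeMol(
                    mol,
                    Chem.SanitizeFlags.SANITIZE_SYMMRINGS
                    | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION
                    | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION,
                )
        mol.SetProp("_Name", self.id)
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, mol_id: str | None = None) -> "Molecule":
        if mol.GetNumConformers() == 0:
            raise ValueError("RDKit molecule carries no conformer")
        conf = mol.GetConformer()
        atoms = []
        for a in mol.GetAtoms():
            p = conf.GetAtomPosition(a.GetIdx())
            q = 0.0
            for prop in ("partial_charge", "_GasteigerCharge", "_TriposPartialCharge"):
                if a.HasProp(prop):
                    q = a.GetDoubleProp(prop)
                    break
            atoms.append(Atom(element=a.GetSymbol(), position=np.array([p.x, p.y, p.z]), partial_charge=q))
        bonds = []
        for b in mol.GetBonds():
            o = 1.5 if b.GetBondType() == Chem.BondType.AROMATIC else float(b.GetBondTypeAsDouble())
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), o))
        name = mol_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "mol")
        return cls(id=name, atoms=atoms, bonds=bonds)


@dataclass
class DataSet:
    """A collection of molecules with an optional train/test split."""

    molecules: list[Molecule]
    split: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule ids are not unique within the data set")
        for mid, label in self.split.items():
            if label not in ("train", "test"):
                raise ValueError(f"split label for {mid!r} must be 'train' or 'test'")

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self) -> Iterator[Molecule]:
        return iter(self.molecules)

    def __getitem__(self, mol_id: str) -> Molecule:
        for m in self.molecules:
            if m.id == mol_id:
                return m
        raise KeyError(mol_id)

    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    def activities(self) -> np.ndarray:
        return np.array([np.nan if m.activity is None else m.activity for m in self.molecules])

    def subset(self, label: str) -> "DataSet":
        """Molecules whose split label equals ``label`` ('train' or 'test')."""
        if not self.split:
            raise ValueError("data set carries no split labels")
        missing = [m.id for m in self.molecules if m.id not in self.split]
        if missing:
            raise ValueError(f"split labels missing for: {missing}")
        mols = [m for m in self.molecules if self.split[m.id] == label]
        return DataSet(mols, {m.id: label for m in mols})

    def copy(self) -> "DataSet":
        return DataSet([m.copy() for m in self.molecules], dict(self.split))


# ---------------------------------------------------------------------------
# structure file IO


def _read_sdf(path: Path) -> list[Molecule]:
    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    except OSError as exc:
        raise ParseError(f"{path}: not readable as SDF: {exc}") from exc
    mols = []
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ParseError(f"{path}: record {i} failed to parse as SDF")
        try:
            Chem.SanitizeMol(
                rdmol,
                Chem.SanitizeFlags.SANITIZE_ALL
                ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
                ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
            )
        except Exception as exc:  # pragma: no cover - depends on input
            raise ParseError(f"{path}: record {i} failed sanitization: {exc}") from exc
        mol = Molecule.from_rdkit(rdmol, mol_id=None)
        if not (rdmol.HasProp("_Name") and rdmol.GetProp("_Name").strip()):
            mol.id = f"mol{i}"
        if rdmol.HasProp("pEC50"):
            mol.activity = float(rdmol.GetProp("pEC50"))
        mols.append(mol)
    return mols


_MOL2_ORDER = {"1": 1.0, "2": 2.0, "3": 3.0, "ar": 1.5, "am": 1.0, "du": 1.0, "un": 1.0}
_MOL2_ORDER_INV = {1.0: "1", 2.0: "2", 3.0: "3", 1.5: "ar"}


def _read_mol2(path: Path) -> list[Molecule]:
    """Minimal TRIPOS MOL2 reader (MOLECULE/ATOM/BOND records, charges kept)."""
    text = Path(path).read_text()
    blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
    if not blocks:
        raise ParseError(f"{path}: no MOLECULE record found")
    mols = []
    for i, block in enumerate(blocks):
        try:
            mols.append(_parse_mol2_block(block, default_id=f"mol{i}"))
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"{path}: record {i} failed to parse: {exc}") from exc
    return mols


def _parse_mol2_block(block: str, default_id: str) -> Molecule:
    lines = block.splitlines()
    section = None
    name = default_id
    atoms: list[Atom] = []
    bonds: list[tuple[int, int, float]] = []
    header: list[str] = []
    for raw in lines:
        line = raw.rstrip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            header = []
            continue
        if not line.strip() or line.startswith("#"):
            continue
        if section == "MOLECULE":
            header.append(line.strip())
            if len(header) == 1 and header[0]:
                name = header[0]
        elif section == "ATOM":
            parts = line.split()
            x, y, z = map(float, parts[2:5])
            elem = parts[5].split(".")[0]
            q = float(parts[8]) if len(parts) > 8 else 0.0
            atoms.append(Atom(element=elem, position=np.array([x, y, z]), partial_charge=q))
        elif section == "BOND":
            parts = line.split()
            bonds.append((int(parts[1]) - 1, int(parts[2]) - 1, _MOL2_ORDER.get(parts[3].lower(), 1.0)))
    if not atoms:
        raise ParseError("MOL2 record contains no atoms")
    return Molecule(id=name, atoms=atoms, bonds=bonds)


def read_structures(path: str | Path, format: str | None = None) -> DataSet:
    """Read an SDF or MOL2 file into a :class:`DataSet`.

    ``format`` is ``'SDF'`` or ``'MOL2'``; when omitted it is inferred from
    the file suffix.  MOL2 partial charges are imported when present.  A
    file whose coordinates are all-zero in z (2D drawing) triggers a
    warning, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt in ("SDF", "SD", "MOL"):
        mols = _read_sdf(path)
    elif fmt == "MOL2":
        mols = _read_mol2(path)
    else:
        raise ValueError(f"unsupported structure format: {fmt}")
    if not mols:
        raise ParseError(f"{path}: file contains no molecules")
    for m in mols:
        if len(m) > 1 and np.allclose(m.coords[:, 2], 0.0):
            warnings.warn(f"molecule {m.id!r} looks 2D (all z = 0)", stacklevel=2)
    return DataSet(mols)


def write_structures(data: DataSet | Iterable[Molecule], path: str | Path, format: str | None = None) -> None:
    """Write molecules as multi-record SDF (via RDKit) or TRIPOS MOL2."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    mols = list(data.molecules if isinstance(data, DataSet) else data)
    if fmt in ("SDF", "SD"):
        writer = Chem.SDWriter(str(path))
        writer.SetKekulize(False)
        for m in mols:
            rdmol = m.to_rdkit(sanitize=True)
            if m.activity is not None:
                rdmol.SetProp("pEC50", repr(float(m.activity)))
            writer.write(rdmol)
        writer.close()
    elif fmt == "MOL2":
        with open(path, "w") as fh:
            for m in mols:
                fh.write(_mol2_block(m))
    else:
        raise ValueError(f"unsupported structure format: {fmt}")


def _mol2_block(m: Molecule) -> str:
    out = ["@<TRIPOS>MOLECULE", m.id, f"{len(m.atoms)} {len(m.bonds)} 0 0 0", "SMALL", "USER_CHARGES", "", "@<TRIPOS>ATOM"]
    for i, a in enumerate(m.atoms, start=1):
        x, y, z = a.position
        out.append(
            f"{i:>7d} {a.element}{i:<4d} {x:>12.4f} {y:>12.4f} {z:>12.4f} "
            f"{a.element:<5s} 1 LIG1 {a.partial_charge:>9.4f}"
        )
    out.append("@<TRIPOS>BOND")
    for k, (i, j, o) in enumerate(m.bonds, start=1):
        out.append(f"{k:>6d} {i + 1:>5d} {j + 1:>5d} {_MOL2_ORDER_INV.get(float(o), '1'):>4s}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# charges and parameters


def assign_gasteiger_charges(mol: Molecule, n_iter: int = 25) -> Molecule:
    """Return a copy with Gasteiger PEOE partial charges.

    Iterative partial equalization of orbital electronegativity (the σ
    component of the Gasteiger–Hückel scheme; the Hückel π refinement is
    not applied).  Charges sum to the molecular formal charge.
    """
    rdmol = mol.to_rdkit(sanitize=True)
    AllChem.ComputeGasteigerCharges(rdmol, nIter=n_iter)
    out = mol.copy()
    for idx, atom in enumerate(out.atoms):
        q = rdmol.GetAtomWithIdx(idx).GetDoubleProp("_GasteigerCharge")
        if not np.isfinite(q):
            raise ParameterError(
                f"molecule {mol.id!r}: no electronegativity parameters for atom "
                f"{idx} ({atom.element})"
            )
        atom.partial_charge = float(q)
    out.check_charge_sum()
    return out


def load_parameter_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the per-element parameter table (packaged Tripos-like defaults).

    Columns: element, vdw_radius (Å), well_depth (kcal/mol),
    hydrophobicity (dimensionless, apolar positive).
    """
    if path is None:
        with resources.files("qsar3d.data").joinpath("atom_params.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    return table.set_index("element")


def assign_atom_parameters(mol: Molecule, table: pd.DataFrame | None = None) -> Molecule:
    """Return a copy with vdW radii, well depths, hydrophobicity and
    donor/acceptor flags assigned from the element parameter table.

    Rules on top of the table: a hydrogen bonded to N or O is a donor; any
    O, and any N with fewer than four bonds, is an acceptor; a carbon
    bonded to N or O loses its apolar hydrophobicity score (set to 0).
    """
    if table is None:
        table = load_parameter_table()
    out = mol.copy()
    missing = [f"{i}:{a.element}" for i, a in enumerate(out.atoms) if a.element not in table.index]
    if missing:
        raise ParameterError(f"molecule {mol.id!r}: unparameterized atom types: {missing}")
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(out.atoms))}
    degree = {i: 0 for i in range(len(out.atoms))}
    for i, j, _ in out.bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
        degree[i] += 1
        degree[j] += 1
    for i, a in enumerate(out.atoms):
        row = table.loc[a.element]
        a.vdw_radius = float(row["vdw_radius"])
        a.well_depth = float(row["well_depth"])
        a.hydrophobicity = float(row["hydrophobicity"])
        nbr_elems = {out.atoms[j].element for j in neighbors[i]}
        if a.element == "H":
            a.is_donor = bool(nbr_elems & {"N", "O"})
            a.is_acceptor = False
        elif a.element == "O":
            a.is_donor = False
            a.is_acceptor = True
        elif a.element == "N":
            a.is_donor = False
            a.is_acceptor = degree[i] < 4
        else:
            a.is_donor = False
            a.is_acceptor = False
        if a.element == "C" and (nbr_elems & {"N", "O", "S"}):
            a.hydrophobicity = 0.0
    return out
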