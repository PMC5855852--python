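"""Synthetic congeneric series with a planted field→activity relationship.

The generator emulates the structure of an aligned congeneric QSAR study:
every pseudo-molecule shares a rigid N-benzylbenzamide-like core (embedded
once, so common-core alignment is exact by construction), differs only in
single-atom substituents drawn from a palette at a few ring decoration
sites, and carries an activity that is a linear function of substituent
properties plus Gaussian noise:

    pEC50 = baseline + Σ_sites β_(site,prop) · prop(substituent) + N(0, σ²)

Substituents are parameter bundles (vdW radius, electronegativity,
hydrophobicity, H-bond flags), not full substituent chemistry; this
isolates the field/PLS machinery from structure drawing.  Each molecule
is scattered by a random rigid motion so the alignment stage has real
work to do.  The packaged activity table of the 33-compound
N-benzylbenzamide PPARγ agonist series (actual and model-predicted pEC50,
train/test flags) is exposed for table auditing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import Atom, DataSet, Molecule, load_parameter_table

__all__ = ["SyntheticSpec", "generate_set", "ground_truth", "load_activity_table", "random_rigid_transform"]

CORE_SMILES = "O=C(NCc1ccccc1)c1ccc(O)cc1"
#: heavy-atom core pattern used for alignment of generated sets
CORE_SMARTS = "O=C(NCc1ccccc1)c1ccc(O)cc1"

# typical C–X bond lengths, Å, for placing a substituent along the C–H vector
_BOND_LENGTH = {"H": 1.09, "C": 1.52, "N": 1.47, "O": 1.43, "F": 1.35,
                "S": 1.82, "Cl": 1.77, "Br": 1.94, "I": 2.14}

# Pauling electronegativities (the 'E' substituent property)
_ELECTRONEG = {"H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98,
               "S": 2.58, "Cl": 3.16, "Br": 2.96, "I": 2.66}


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic congeneric study.

    ``beta`` maps ``(site_index, property)`` to an effect size, with
    property 'S' = vdW radius cubed (Å³), 'E' = Pauling electronegativity,
    'H' = hydrophobicity score, 'D'/'A' = donor/acceptor indicator of the
    substituent atom.  Defaults plant a purely steric signal at two sites
    with σ = 0.1 pEC50 units of noise on a 33-compound series split
    27 train / 6 test, matching the scale of a typical published series.
    """

    n_molecules: int = 33
    decoration_sites: int = 3
    substituent_palette: tuple[str, ...] = ("H", "C", "N", "O", "F", "S", "Cl", "Br")
    beta: dict = dc_field(default_factory=lambda: {(0, "S"): 0.25, (1, "S"): 0.15})
    baseline: float = 5.0
    noise_sigma: float = 0.1
    train_fraction: float = 0.82
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 8:
            raise ValueError("a synthetic series needs at least 8 molecules")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not self.substituent_palette:
            raise ValueError("substituent palette is empty")
        for site, prop in self.beta:
            if site >= self.decoration_sites:
                raise ValueError(f"beta refers to site {site} but only "
                                 f"{self.decoration_sites} decoration sites exist")
            if prop not in "SEHDA":
                raise ValueError(f"unknown substituent property {prop!r}")


def _embed_core() -> tuple[Molecule, list[int]]:
    """The shared rigid core plus the decoration-site H atom indices.

    Embedding uses a fixed conformer seed: the core geometry is part of
    the study definition, not of the per-run randomness.
    """
    rdmol = Chem.AddHs(Chem.MolFromSmiles(CORE_SMILES))
    if AllChem.EmbedMolecule(rdmol, randomSeed=20180223) != 0:  # pragma: no cover
        raise RuntimeError("core embedding failed")
    core = Molecule.from_rdkit(rdmol, mol_id="core")
    # decoration sites: hydrogens on the benzyl ring (aromatic C bearing H,
    # ring without the hydroxyl), smallest indices first
    ring_info = rdmol.GetRingInfo().AtomRings()
    hydroxyl_o = [a.GetIdx() for a in rdmol.GetAtoms()
                  if a.GetSymbol() == "O" and a.GetTotalNumHs() + sum(n.GetSymbol() == "H" for n in a.GetNeighbors()) > 0]
    benzyl_rings = [r for r in ring_info
                    if not any(nbr.GetIdx() in hydroxyl_o for idx in r for nbr in rdmol.GetAtomWithIdx(idx).GetNeighbors())]
    ring = sorted(benzyl_rings[0])
    site_h = sorted(
        nbr.GetIdx()
        for idx in ring
        for nbr in rdmol.GetAtomWithIdx(idx).GetNeighbors()
        if nbr.GetSymbol() == "H"
    )
    return core, site_h


def _substituent_property(elem: str, prop: str, params: pd.DataFrame) -> float:
    if prop == "S":
        return float(params.loc[elem, "vdw_radius"]) ** 3
    if prop == "E":
        return _ELECTRONEG[elem]
    if prop == "H":
        return float(params.loc[elem, "hydrophobicity"])
    if prop == "D":
        return 0.0  # single-atom substituents bear no polar hydrogen
    if prop == "A":
        return 1.0 if elem in ("N", "O") else 0.0
    raise ValueError(prop)


def random_rigid_transform(rng: np.random.Generator, max_shift: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a uniform translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-max_shift, max_shift, size=3)
    return R, t


def generate_set(spec: SyntheticSpec, scatter: bool = True) -> DataSet:
    """Generate the synthetic aligned-by-construction congeneric series.

    Identical spec (including seed) reproduces the data set bit for bit.
    With ``scatter=True`` each molecule is additionally moved by a random
    rigid transform, to be undone by the alignment stage.
    """
    if spec.decoration_sites > 6:
        raise ValueError("the benzyl ring offers at most 6 decoration sites")
    core, site_h = _embed_core()
    if spec.decoration_sites > len(site_h):
        raise ValueError("decoration demand exceeds available ring positions")
    sites = site_h[: spec.decoration_sites]
    params = load_parameter_table()
    missing = [e for e in spec.substituent_palette if e not in params.index]
    if missing:
        raise ValueError(f"palette elements without parameters: {missing}")
    rng = np.random.default_rng(spec.seed)
    molecules = []
    for m in range(spec.n_molecules):
        mol = core.copy()
        mol.id = f"syn{m:03d}"
        choices = [str(rng.choice(spec.substituent_palette)) for _ in sites]
        for h_idx, elem in zip(sites, choices):
            if elem == "H":
                continue
            h_atom = mol.atoms[h_idx]
            carbon = next(i if j == h_idx else j for i, j, _ in mol.bonds
                          if h_idx in (i, j))
            c_pos = mol.atoms[carbon].position
            u = h_atom.position - c_pos
            u /= np.linalg.norm(u)
            mol.atoms[h_idx] = Atom(element=elem, position=c_pos + _BOND_LENGTH[elem] * u)
        y = spec.baseline
        for (site, prop), b in spec.beta.items():
            y += b * _substituent_property(choices[site], prop, params)
        y += rng.normal(0.0, spec.noise_sigma) if spec.noise_sigma > 0 else 0.0
        mol.activity = float(y)
        # the transform is always drawn so the random stream (and hence the
        # activities) is identical with and without scattering
        R, t = random_rigid_transform(rng)
        if scatter:
            mol.coords = mol.coords @ R.T + t
        molecules.append(mol)
    split = _stratified_split([m.activity for m in molecules],
                             [m.id for m in molecules], spec.train_fraction, rng)
    return DataSet(molecules, split)


def _stratified_split(activities, ids, train_fraction: float, rng: np.random.Generator) -> dict[str, str]:
    """Seed-deterministic train/test split stratified by activity tertile,
    so both sets span the activity range."""
    n = len(ids)
    n_test = int(round(n * (1.0 - train_fraction)))
    n_test = max(1, min(n - 2, n_test))
    order = np.argsort(np.asarray(activities), kind="stable")
    tertiles = np.array_split(order, 3)
    split = {i: "train" for i in ids}
    # largest-remainder allocation of test slots across tertiles
    quota = [len(t) * n_test / n for t in tertiles]
    counts = [int(np.floor(qv)) for qv in quota]
    rem = n_test - sum(counts)
    for j in np.argsort([-(qv - np.floor(qv)) for qv in quota])[:rem]:
        counts[j] += 1
    for t, c in zip(tertiles, counts):
        pick = rng.choice(len(t), size=c, replace=False)
        for p in sorted(pick):
            split[ids[t[p]]] = "test"
    return split


def ground_truth(spec: SyntheticSpec, data: DataSet) -> dict:
    """The planted effect map of a generated set, for recovery scoring.

    Returns the β map, the dominant planted field per the |β|·property
    spread, and the template-frame coordinates of each decoration site.
    Raises if ``data`` was not generated by ``spec``.
    """
    ref = generate_set(spec, scatter=False)
    if ref.ids() != data.ids() or not np.allclose(ref.activities(), data.activities()):
        raise ValueError("data set does not match the generating spec")
    core, site_h = _embed_core()
    sites = site_h[: spec.decoration_sites]
    params = load_parameter_table()
    effects = []
    for (site, prop), b in spec.beta.items():
        spread = np.ptp([_substituent_property(e, prop, params) for e in spec.substituent_palette])
        effects.append({"site": site, "property": prop, "beta": float(b),
                        "site_position": core.atoms[sites[site]].position.tolist(),
                        "activity_spread": float(abs(b) * spread)})
    by_field: dict[str, float] = {}
    for e in effects:
        by_field[e["property"]] = by_field.get(e["property"], 0.0) + e["activity_spread"]
    dominant = max(by_field, key=by_field.get) if by_field else None
    return {"effects": effects, "dominant_field": dominant, "baseline": spec.baseline,
            "noise_sigma": spec.noise_sigma}


def load_activity_table() -> pd.DataFrame:
    """Packaged 33-compound N-benzylbenzamide PPARγ agonist activity table.

    Columns: id, r1_label, r2_label, substitution, split (train/test),
    actual_pEC50, comfa_pred, comsia_pred.  The six test compounds are
    01a, 03c, 10b, 22b, 25b and 26c.
    """
    with resources.files("qsar3d.data").joinpath("ppar_benzylbenzamide_activities.csv").open() as fh:
        table = pd.read_csv(fh, dtype={"id": str})
    if len(table) != 33:  # pragma: no cover - packaged data
        raise RuntimeError("packaged activity table is corrupted")
    return table
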