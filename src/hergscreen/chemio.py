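"""Molecule ingestion, standardization, conformers and pharmacophoric features.

Everything downstream (interaction fields, pharmacophore matching, screening)
consumes the :class:`Molecule` produced here: an RDKit mol with explicit
hydrogens, Gasteiger partial charges, per-atom van der Waals type labels and
a seeded 3D conformer.  All stochastic steps take an explicit integer seed;
there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolTransforms  # noqa: F401
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# Closed set of van der Waals type labels; the probe parameter tables in
# hergscreen.mif must cover every label emitted here.
VDW_TYPES = ("C.ar", "C.3", "C.2", "N", "O", "S", "P", "H", "F", "Cl", "Br", "I")

#: Unit tokens accepted in activity tables, as multipliers to molar.
UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6, "µM": 1e-6, "nM": 1e-9}


class ChemioError(ValueError):
    pass


class StandardizationError(ChemioError):
    pass


class ConformerError(ChemioError):
    pass


@dataclass
class ActivityRecord:
    """One assay measurement: IC50 in molar plus assay/cell-line provenance."""

    compound_id: str
    ic50: float  # molar
    assay: str = ""
    cell_line: str = ""

    @property
    def pic50(self) -> float:
        return -math.log10(self.ic50)


@dataclass
class FeatureSite:
    kind: str  # aromatic | hydrophobic | hbond_acceptor | hbond_donor
    position: np.ndarray  # (3,) Angstrom
    atom_indices: tuple[int, ...]

    KINDS = ("aromatic", "hydrophobic", "hbond_acceptor", "hbond_donor")


@dataclass
class Molecule:
    """A standardized molecule: RDKit mol + identity + provenance.

    ``mol`` carries explicit hydrogens once :func:`standardize` has run; 3D
    conformers live on the RDKit mol itself.
    """

    id: str
    mol: Chem.Mol
    provenance: dict = field(default_factory=dict)

    @property
    def mw(self) -> float:
        return Descriptors.MolWt(self.mol)

    @property
    def heavy_atom_count(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def clogp(self) -> float:
        return Crippen.MolLogP(self.mol)

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.mol))

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    def coordinates(self, conf_id: int = 0) -> np.ndarray:
        conf = self.mol.GetConformer(conf_id)
        return np.array(conf.GetPositions(), dtype=float)

    def partial_charges(self) -> np.ndarray:
        return np.array(
            [a.GetDoubleProp("_GasteigerCharge") if a.HasProp("_GasteigerCharge") else 0.0
             for a in self.mol.GetAtoms()]
        )

    def vdw_types(self) -> list[str]:
        return [atom_vdw_type(a) for a in self.mol.GetAtoms()]


def atom_vdw_type(atom: Chem.Atom) -> str:
    """Map an atom to the closed vdW label set used by the probe tables."""
    sym = atom.GetSymbol()
    if sym == "C":
        if atom.GetIsAromatic():
            return "C.ar"
        if atom.GetHybridization() == Chem.HybridizationType.SP3:
            return "C.3"
        return "C.2"
    if sym in ("N", "O", "S", "P", "H", "F", "Cl", "Br", "I"):
        return sym
    raise ChemioError(f"no vdW parameterization for element {sym!r}")


# ---------------------------------------------------------------------------
# ingestion

def parse_ic50(value, unit: str) -> float:
    """Convert an (IC50 value, unit token) pair to molar."""
    unit = unit.strip()
    if unit not in UNIT_TO_MOLAR:
        raise ChemioError(f"unknown concentration unit {unit!r}")
    v = float(value)
    if v <= 0:
        raise ChemioError(f"nonpositive IC50 {v}")
    return v * UNIT_TO_MOLAR[unit]


def read_activity_table(path, dialect: str = ","):
    """Read a delimited activity table into (Molecule, ActivityRecord) pairs.

    Mandatory columns: id, smiles, ic50, unit, assay, cell_line.  Rows whose
    SMILES fail to parse are reported, not silently dropped.

    Returns
    -------
    records : list of (Molecule, ActivityRecord)
    failures : list of (row_index, reason)
    """
    import csv

    records, failures = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect)
        required = {"id", "smiles", "ic50", "unit", "assay", "cell_line"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise ChemioError(f"activity table missing mandatory columns: {sorted(missing)}")
        for i, row in enumerate(reader):
            mol = Chem.MolFromSmiles(row["smiles"])
            if mol is None:
                failures.append((i, f"unparseable SMILES {row['smiles']!r}"))
                continue
            try:
                ic50 = parse_ic50(row["ic50"], row["unit"])
            except ChemioError as exc:
                failures.append((i, f"row {i}: {exc}"))
                continue
            records.append(
                (
                    Molecule(id=row["id"], mol=mol),
                    ActivityRecord(row["id"], ic50, row["assay"], row["cell_line"]),
                )
            )
    return records, failures


# ---------------------------------------------------------------------------
# standardization

# Minimal pH-7.4 protonation rules: dominant states of the common ionizable
# groups (pKa far from 7.4 on the relevant side).  SMARTS -> formal charge on
# the matched atom 0 plus hydrogen-count adjustment.
_PROTONATION_RULES = (
    # carboxylic acid -> carboxylate (pKa ~ 4)
    ("[CX3](=O)[OX2H1]", 2, -1, 0),  # atom index 2 (the OH oxygen): charge -1, 0 H
    # aliphatic primary/secondary/tertiary amine -> ammonium (pKa ~ 10)
    ("[NX3;H2;!$(NC=O);!$(Na);!$(N[c,n])]", 0, +1, 3),
    ("[NX3;H1;!$(NC=O);!$(Na);!$(N[c,n])]([#6])[#6]", 0, +1, 2),
    ("[NX3;H0;!$(NC=O);!$(Na);!$(N[c,n])]([#6])([#6])[#6]", 0, +1, 1),
)


def standardize(molecule: Molecule, ph: float = 7.4, minimize: bool = True) -> Molecule:
    """Assign the dominant pH-7.4 protonation state and Gasteiger charges.

    A brief MMFF relaxation hook is applied when a conformer is present and
    ``minimize`` is true; the charge scheme and relaxation method are recorded
    in provenance.  Idempotent.
    """
    mol = Chem.Mol(molecule.mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise StandardizationError(f"sanitization failed for {molecule.id}: {exc}") from exc

    rw = Chem.RWMol(Chem.RemoveHs(mol))
    for smarts, idx, charge, n_h in _PROTONATION_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetSubstructMatches(patt):
            atom = rw.GetAtomWithIdx(match[idx])
            if atom.GetFormalCharge() == 0:
                atom.SetFormalCharge(charge)
                atom.SetNumExplicitHs(n_h)
                atom.SetNoImplicit(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    mol = Chem.AddHs(mol)
    AllChem.ComputeGasteigerCharges(mol)

    out = Molecule(id=molecule.id, mol=mol, provenance=dict(molecule.provenance))
    out.provenance.update(
        {"charge_scheme": "gasteiger", "ph": ph, "relaxation": "mmff94" if minimize else "none"}
    )
    if mol.GetNumConformers() and minimize:
        try:
            AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
        except Exception:
            out.provenance["relaxation"] = "failed"
    return out


def net_charge(molecule: Molecule) -> int:
    return sum(a.GetFormalCharge() for a in molecule.mol.GetAtoms())


# ---------------------------------------------------------------------------
# conformers

def generate_conformers(
    molecule: Molecule, n: int = 1, method: str = "standard3d", seed: int = 0
) -> Molecule:
    """Embed ``n`` 3D conformers (deterministic for a fixed seed).

    method: ``standard3d`` (single ETKDG embedding + brief MMFF relax),
    ``minimized`` (ETKDG + full MMFF), ``stochastic`` (multiple random
    embeddings).  The method tag and seed are recorded in provenance.
    """
    if n < 1:
        raise ConformerError("n must be >= 1")
    mol = Chem.AddHs(Chem.Mol(molecule.mol))
    mol.RemoveAllConformers()
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.useRandomCoords = method == "stochastic"
    if method == "stochastic":
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params)
    else:
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=max(1, n), params=params)
    if len(ids) == 0:
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params)
        if len(ids) == 0:
            raise ConformerError(f"embedding failed for {molecule.id}")
    if method in ("standard3d", "minimized"):
        its = 20 if method == "standard3d" else 500
        try:
            AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=its)
        except Exception:
            pass
    AllChem.ComputeGasteigerCharges(mol)
    out = Molecule(id=molecule.id, mol=mol, provenance=dict(molecule.provenance))
    out.provenance.update({"conformer_method": method, "conformer_seed": int(seed)})
    return out


# ---------------------------------------------------------------------------
# feature perception

_HBA_SMARTS = Chem.MolFromSmarts(
    "[$([OX2;H0;+0]),$([OX2;H1;+0]),$([OX1;+0;!$([O]=[N])]),$([o;X2;+0]),"
    "$([NX3;+0;!$(N=*);!$(NC=O);!$(Na)]),$([nX2;+0]),$([NX1])]"
)
_HBD_SMARTS = Chem.MolFromSmarts("[$([O;H1]),$([N;H1,H2,H3;+0]),$([N;+1;H1,H2,H3]),$([n;H1])]")

HYDROPHOBIC_MIN_FRAGMENT = 3


def _hydrophobic_fragments(mol: Chem.Mol, min_size: int = HYDROPHOBIC_MIN_FRAGMENT):
    """Maximal connected fragments of non-polar sp3 carbons (no heteroatom
    neighbours), of at least ``min_size`` atoms."""
    eligible = set()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetIsAromatic():
            continue
        if any(n.GetSymbol() not in ("C", "H") for n in atom.GetNeighbors()):
            continue
        eligible.add(atom.GetIdx())
    seen, fragments = set(), []
    for start in sorted(eligible):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in eligible and j not in comp:
                    stack.append(j)
        seen |= comp
        if len(comp) >= min_size:
            fragments.append(tuple(sorted(comp)))
    return fragments


def perceive_features(molecule: Molecule, conf_id: int = 0) -> list[FeatureSite]:
    """Pharmacophoric feature sites on one conformer.

    aromatic: centroid of each aromatic ring; hydrophobic: centroid of each
    contiguous non-polar carbon fragment (>= 3 atoms); acceptor/donor: the
    heteroatom position.  Deterministic ordering (kind, lowest atom index).
    """
    mol = molecule.mol
    if mol.GetNumConformers() == 0:
        raise ConformerError(f"{molecule.id}: no conformer; run generate_conformers first")
    pos = molecule.coordinates(conf_id)
    sites: list[FeatureSite] = []
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            sites.append(FeatureSite("aromatic", pos[list(ring)].mean(axis=0), tuple(sorted(ring))))
    for frag in _hydrophobic_fragments(mol):
        sites.append(FeatureSite("hydrophobic", pos[list(frag)].mean(axis=0), frag))
    for (i,) in mol.GetSubstructMatches(_HBA_SMARTS):
        sites.append(FeatureSite("hbond_acceptor", pos[i].copy(), (i,)))
    for (i,) in mol.GetSubstructMatches(_HBD_SMARTS):
        sites.append(FeatureSite("hbond_donor", pos[i].copy(), (i,)))
    order = {k: r for r, k in enumerate(FeatureSite.KINDS)}
    sites.sort(key=lambda s: (order[s.kind], s.atom_indices))
    return sites


# ---------------------------------------------------------------------------
# SDF round trip

def write_sdf(molecules: list[Molecule], path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for m in molecules:
        mol = Chem.Mol(m.mol)
        mol.SetProp("_Name", m.id)
        for k, v in m.provenance.items():
            mol.SetProp(str(k), str(v))
        writer.write(mol)
    writer.close()


def read_sdf(path) -> list[Molecule]:
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=False)):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        prov = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        out.append(Molecule(id=name, mol=mol, provenance=prov))
    return out


def from_smiles(smiles: str, mol_id: str = "mol") -> Molecule:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemioError(f"unparseable SMILES {smiles!r}")
    return Molecule(id=mol_id, mol=mol)
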