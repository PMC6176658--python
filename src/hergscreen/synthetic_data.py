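"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators make every pipeline stage testable without external data:

* :func:`make_sar_dataset` — a few hundred drug-like molecules assembled
  combinatorially from aromatic/aliphatic scaffolds and substituents, with
  pIC50 generated as a known sparse linear function of feature-pair
  distance-bin descriptors plus Gaussian noise on the log scale.  The
  generating coefficients and descriptor matrix are returned, so recovery
  tests are self-contained.
* :func:`embed_pharmacophore_actives` / :func:`make_decoys` — molecules
  whose conformer geometry realizes (or deliberately does not realize) a
  given 4-feature pharmacophore distance matrix, providing ground-truth
  positives and negatives for confusion-matrix statistics.
* :func:`simulate_dose_response` — Hill-equation concentration-block traces
  with truncated Gaussian response noise.

Everything is deterministic per (spec, seed); no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement, product

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import FeatureSite, Molecule, from_smiles, generate_conformers, perceive_features
from .doseresponse import DoseResponseData, hill
from .pharmacophore import PharmacophoreModel


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SAR dataset

#: Scaffold templates with one substitution slot.  Chosen to span the
#: donor/acceptor feature-count structure of diverse hERG actives: pure
#: hydrophobic aromatics, single-donor anilines/phenols, donor+acceptor
#: amides, and polyfunctional heteroaromatics.
DEFAULT_SCAFFOLDS = (
    "c1ccc(-c2ccc({0})cc2)cc1",          # biphenyl (aromatic pair)
    "c1ccc(CCc2ccc({0})cc2)cc1",         # bibenzyl (longer aromatic pair)
    "c1ccc(Oc2ccc({0})cc2)cc1",          # diphenyl ether
    "c1ccc(C(=O)Nc2ccc({0})cc2)cc1",     # benzanilide (donor + acceptor)
    "c1ccc2[nH]c(-c3ccc({0})cc3)cc2c1",  # 2-arylindole (donor)
    "O=C(CCc1ccc({0})cc1)N1CCCCC1",      # phenylpropanoyl piperidide
    "c1ccc(CN2CCN(CC{0})CC2)cc1",        # benzylpiperazine
    "c1ccc(-c2nc({0})cs2)cc1",           # phenylthiazole (acceptor)
)

DEFAULT_SUBSTITUENTS = (
    "CCC", "CC(C)C", "CCCC", "C9CCCCC9", "OC", "N", "NC(C)=O", "C(=O)OC",
    "O", "F", "Cl", "C#N",
)

#: Descriptor bins: unordered feature-kind pairs x 2 A distance bins, 0-20 A.
KIND_PAIRS = tuple(combinations_with_replacement(FeatureSite.KINDS, 2))
BIN_WIDTH = 2.0
N_DIST_BINS = 10

#: Ground-truth coefficient defaults (pIC50 units per pair count): aromatic
#: pairs, ring-adjacent acceptors and aliphatic bulk raise potency; donor
#: pairs and spaced acceptor pairs lower it.  Bins chosen once for good
#: occupancy and mutual conditioning across the default scaffold library.
DEFAULT_BETA = {
    ("aromatic", "aromatic", 2): 0.70,            # ring pairs 4-6 A
    ("aromatic", "hydrophobic", 1): 0.80,         # aliphatic bulk near a ring
                                                  # (hydrophobicity dominates hERG block)
    ("aromatic", "hbond_acceptor", 1): 0.45,      # acceptor close to a ring
    ("aromatic", "hbond_donor", 1): -0.35,        # donors near rings
    ("hbond_acceptor", "hbond_donor", 1): -0.45,  # close donor/acceptor pair
}


def bin_labels() -> list[tuple[str, str, float, float]]:
    out = []
    for a, b in KIND_PAIRS:
        for k in range(N_DIST_BINS):
            out.append((a, b, k * BIN_WIDTH, (k + 1) * BIN_WIDTH))
    return out


def feature_pair_descriptor(molecule: Molecule, conf_id: int = 0) -> np.ndarray:
    """Counts of feature-site pairs per (kind pair, distance bin)."""
    sites = perceive_features(molecule, conf_id)
    pair_index = {p: i for i, p in enumerate(KIND_PAIRS)}
    x = np.zeros(len(KIND_PAIRS) * N_DIST_BINS)
    for i, j in _index_pairs(len(sites)):
        a, b = sorted((sites[i].kind, sites[j].kind), key=FeatureSite.KINDS.index)
        d = float(np.linalg.norm(sites[i].position - sites[j].position))
        k = int(d // BIN_WIDTH)
        if k < N_DIST_BINS:
            x[pair_index[(a, b)] * N_DIST_BINS + k] += 1.0
    return x


def _index_pairs(n):
    for i in range(n):
        for j in range(i + 1, n):
            yield i, j


@dataclass
class SarSpec:
    n_compounds: int = 200
    scaffolds: tuple = DEFAULT_SCAFFOLDS
    substituents: tuple = DEFAULT_SUBSTITUENTS
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    noise_sd: float = 0.3  # pIC50 log units
    pic50_range: tuple[float, float] = (3.0, 9.0)
    baseline: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 20:
            raise SyntheticError("n_compounds must be >= 20")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")


@dataclass
class SarDataset:
    molecules: list
    pic50: np.ndarray
    X: np.ndarray  # generating descriptor bins (n x p)
    labels: list  # bin labels aligned with X columns
    beta: np.ndarray  # generating coefficients aligned with X columns
    noise: np.ndarray
    spec: SarSpec


def make_sar_dataset(spec: SarSpec) -> SarDataset:
    """Assemble molecules combinatorially and generate activities.

    pIC50 = baseline + beta . descriptor_bins + N(0, noise_sd), clipped to
    the activity range.  Deterministic per spec.seed; the generating beta,
    bin labels and descriptor matrix are returned for oracle use.
    """
    rng = np.random.default_rng(spec.seed)
    combos = list(product(range(len(spec.scaffolds)), range(len(spec.substituents))))
    reps = -(-spec.n_compounds // len(combos))
    pool = combos * reps
    rng.shuffle(pool)

    labels = bin_labels()
    beta = np.zeros(len(labels))
    for (a, b, k), v in spec.beta.items():
        beta[KIND_PAIRS.index((a, b)) * N_DIST_BINS + k] = v

    molecules, rows = [], []
    i = 0
    for si, ti in pool:
        if len(molecules) >= spec.n_compounds:
            break
        smi = spec.scaffolds[si].format(spec.substituents[ti])
        try:
            mol = from_smiles(smi, mol_id=f"sar{i:04d}")
        except Exception:
            raise SyntheticError(f"infeasible SMILES assembly: scaffold "
                                 f"{spec.scaffolds[si]!r} + {spec.substituents[ti]!r}")
        mol = generate_conformers(mol, n=1, method="standard3d",
                                  seed=int(rng.integers(2**31 - 1)))
        molecules.append(mol)
        rows.append(feature_pair_descriptor(mol))
        i += 1

    X = np.array(rows)
    noise = rng.normal(0.0, spec.noise_sd, size=len(molecules)) if spec.noise_sd > 0 \
        else np.zeros(len(molecules))
    y = np.clip(spec.baseline + X @ beta + noise, *spec.pic50_range)
    return SarDataset(molecules=molecules, pic50=y, X=X, labels=labels,
                      beta=beta, noise=noise, spec=spec)


# ---------------------------------------------------------------------------
# pharmacophore actives and decoys

def _hexagon(center, rng, radius: float = 1.395):
    """Aromatic ring coordinates: regular hexagon at a random orientation."""
    basis = _random_rotation(rng)
    ang = np.arange(6) * np.pi / 3
    local = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])
    return center + local @ basis.T


def _random_rotation(rng) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _build_probe_molecule(anchors: np.ndarray, rng, mol_id: str) -> Molecule:
    """A molecule whose perceived features sit at the four anchor points:
    aromatic ring at anchors[0], sp3-carbon triple at anchors[1], aromatic
    ring at anchors[2], carbonyl oxygen at anchors[3].

    Graph: ringA-O-CH2-CH2-O-ringB backbone, ringA-O-CH2-propyl side chain,
    ringB-C(=O)-CH3 ketone.  Coordinates are placed geometrically (rings as
    hexagons, chain collinear) rather than embedded, so the feature geometry
    is exact by construction.
    """
    rw = Chem.RWMol()
    conf_pos = []

    def add(symbol, pos, aromatic=False):
        a = Chem.Atom(symbol)
        a.SetIsAromatic(aromatic)
        idx = rw.AddAtom(a)
        conf_pos.append(np.asarray(pos, dtype=float))
        return idx

    ring_a_pos = _hexagon(anchors[0], rng)
    ring_b_pos = _hexagon(anchors[2], rng)
    ring_a = [add("C", p, aromatic=True) for p in ring_a_pos]
    ring_b = [add("C", p, aromatic=True) for p in ring_b_pos]
    for ring in (ring_a, ring_b):
        for i in range(6):
            rw.AddBond(ring[i], ring[(i + 1) % 6], Chem.BondType.AROMATIC)

    def chain(points, symbols):
        idxs = [add(s, p) for s, p in zip(symbols, points)]
        for i in range(len(idxs) - 1):
            rw.AddBond(idxs[i], idxs[i + 1], Chem.BondType.SINGLE)
        return idxs

    # backbone ringA -> O-CH2-CH2-O -> ringB
    p0, p1 = ring_a_pos[0], ring_b_pos[0]
    backbone = chain([p0 + (p1 - p0) * t for t in (0.2, 0.4, 0.6, 0.8)],
                     ["O", "C", "C", "O"])
    rw.AddBond(ring_a[0], backbone[0], Chem.BondType.SINGLE)
    rw.AddBond(backbone[-1], ring_b[0], Chem.BondType.SINGLE)

    # hydrophobic propyl at anchors[1], reached via O-CH2 from ringA
    direction = _random_rotation(rng)[:, 0]
    prop = [anchors[1] + direction * 1.5 * k for k in (-1, 0, 1)]
    attach = ring_a_pos[3]
    side = chain([attach + (prop[0] - attach) * t for t in (0.35, 0.7)], ["O", "C"])
    rw.AddBond(ring_a[3], side[0], Chem.BondType.SINGLE)
    propyl = chain(prop, ["C", "C", "C"])
    rw.AddBond(side[-1], propyl[0], Chem.BondType.SINGLE)

    # ketone acceptor: carbonyl O exactly at anchors[3]
    towards = ring_b_pos[3] - anchors[3]
    n = np.linalg.norm(towards)
    towards = towards / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
    cc = add("C", anchors[3] + towards * 1.23)
    oo = add("O", anchors[3])
    me = add("C", anchors[3] + towards * 1.23 + _random_rotation(rng)[:, 1] * 1.5)
    rw.AddBond(ring_b[3], cc, Chem.BondType.SINGLE)
    rw.AddBond(cc, oo, Chem.BondType.DOUBLE)
    rw.AddBond(cc, me, Chem.BondType.SINGLE)

    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, p in enumerate(conf_pos):
        conf.SetAtomPosition(i, tuple(float(v) for v in p))
    mol.AddConformer(conf, assignId=True)
    AllChem.ComputeGasteigerCharges(mol)
    return Molecule(id=mol_id, mol=mol, provenance={"generator": "pharmacophore-probe"})


def embed_pharmacophore_actives(model: PharmacophoreModel, n: int, seed: int = 0,
                                jitter: float = 0.15) -> list[Molecule]:
    """Molecules whose conformer realizes the model's distance matrix.

    Anchor points come from the model's 3-space embedding, independently
    jittered by up to ``jitter`` per coordinate (pairwise distances stay
    within ~0.5 A of the matrix), then rigidly rotated per molecule.
    Only 4-feature (Aro/Hyd/Aro/HBA) models are supported.
    """
    if model.n_features != 4:
        raise SyntheticError("active generation requires a 4-feature model")
    if "embedding_deviation" in model.provenance:
        raise SyntheticError("distance matrix is not embeddable; cannot generate actives")
    base = model.embedded_coordinates()
    order = _canonical_feature_order(model)
    base = base[order]
    out = []
    for i in range(n):
        rng = np.random.default_rng((seed, i))
        rot = _random_rotation(rng)
        anchors = (base + rng.uniform(-jitter, jitter, size=base.shape)) @ rot.T
        out.append(_build_probe_molecule(anchors, rng, f"active{i:03d}"))
    return out


def _canonical_feature_order(model: PharmacophoreModel):
    """Indices reordering model features to (aromatic, hydrophobic, aromatic, HBA)."""
    arom = [i for i, k in enumerate(model.kinds) if k == "aromatic"]
    hyd = [i for i, k in enumerate(model.kinds) if k == "hydrophobic"]
    hba = [i for i, k in enumerate(model.kinds) if k == "hbond_acceptor"]
    if len(arom) != 2 or len(hyd) != 1 or len(hba) != 1:
        raise SyntheticError("expected two aromatic, one hydrophobic, one acceptor feature")
    return [arom[0], hyd[0], arom[1], hba[0]]


def make_decoys(n: int, seed: int = 0, box: float = 9.0,
                min_sep: float = 3.0) -> list[Molecule]:
    """Feature-complete molecules with random (non-pharmacophore) geometry.

    Same graph as the actives, but anchors drawn uniformly in a box with a
    minimum mutual separation — decoys carry the right feature kinds at the
    wrong distances.
    """
    out = []
    for i in range(n):
        rng = np.random.default_rng((seed + 1_000_003, i))
        while True:
            anchors = rng.uniform(-box / 2, box / 2, size=(4, 3))
            d = np.linalg.norm(anchors[:, None] - anchors[None, :], axis=2)
            if d[np.triu_indices(4, 1)].min() >= min_sep:
                break
        out.append(_build_probe_molecule(anchors, rng, f"decoy{i:03d}"))
    return out


def make_aromatic_dumbbell(separation: float = 14.0, seed: int = 0) -> Molecule:
    """A rigid template with two aromatic termini a fixed distance apart.

    Two benzene rings whose centroids sit ``separation`` Angstrom apart on
    the x axis, joined by a polyether linker (ether oxygens suppress
    hydrophobic hotspots along the chain), each ring carrying an ether cap
    below one face so that the exposed faces dominate the hydrophobic field.
    Coordinates are constructed geometrically; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    half = separation / 2.0
    rw = Chem.RWMol()
    pos = []

    def add(symbol, p, aromatic=False):
        a = Chem.Atom(symbol)
        a.SetIsAromatic(aromatic)
        i = rw.AddAtom(a)
        pos.append(np.asarray(p, dtype=float))
        return i

    def hexagon(cx):
        ang = np.arange(6) * np.pi / 3
        return np.column_stack([cx + 1.395 * np.cos(ang), 1.395 * np.sin(ang),
                                np.zeros(6)])

    ra_pos, rb_pos = hexagon(-half), hexagon(half)
    ring_a = [add("C", p, aromatic=True) for p in ra_pos]
    ring_b = [add("C", p, aromatic=True) for p in rb_pos]
    for ring in (ring_a, ring_b):
        for i in range(6):
            rw.AddBond(ring[i], ring[(i + 1) % 6], Chem.BondType.AROMATIC)

    # polyether linker between the inner para positions (C-C-O repeating)
    p_start = ra_pos[0] + np.array([0.0, 0.0, 0.0])
    p_end = rb_pos[3]
    n_link = 7
    symbols = ["C", "O", "C", "C", "O", "C", "C"][:n_link]
    link = []
    for k in range(n_link):
        t = (k + 1) / (n_link + 1)
        link.append(add(symbols[k], p_start + (p_end - p_start) * t))
    rw.AddBond(ring_a[0], link[0], Chem.BondType.SINGLE)
    for i in range(n_link - 1):
        rw.AddBond(link[i], link[i + 1], Chem.BondType.SINGLE)
    rw.AddBond(link[-1], ring_b[3], Chem.BondType.SINGLE)

    # one ether cap under each ring (-z face blocked and polarized)
    for centre, ring, ring_pos in ((-half, ring_a, ra_pos), (half, ring_b, rb_pos)):
        c = add("C", ring_pos[2] + np.array([0.0, 0.6, -1.5]))
        o = add("O", np.array([centre, 0.0, -3.3]))
        rw.AddBond(ring[2], c, Chem.BondType.SINGLE)
        rw.AddBond(c, o, Chem.BondType.SINGLE)
        me = add("C", np.array([centre, -1.2, -3.9]) + rng.uniform(-0.05, 0.05, 3))
        rw.AddBond(o, me, Chem.BondType.SINGLE)

    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, p in enumerate(pos):
        conf.SetAtomPosition(i, tuple(float(v) for v in p))
    mol.AddConformer(conf, assignId=True)
    AllChem.ComputeGasteigerCharges(mol)
    return Molecule(id="dumbbell", mol=mol,
                    provenance={"generator": "aromatic-dumbbell",
                                "separation": separation})


# ---------------------------------------------------------------------------
# dose-response simulation

@dataclass
class DoseResponseSpec:
    ic50: float  # molar
    nh: float = 1.0
    concentrations: tuple = (1e-9, 3e-9, 100e-9, 300e-9, 1000e-9)
    noise_sd: float = 0.03  # fraction of response
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise SyntheticError("concentrations must be positive, strictly increasing")
        if self.ic50 <= 0 or self.nh <= 0:
            raise SyntheticError("IC50 and nH must be positive")


def simulate_dose_response(spec: DoseResponseSpec,
                           compound_id: str = "sim") -> DoseResponseData:
    """y = Hill(conc; IC50, nH) + N(0, noise_sd), truncated to [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    conc = np.tile(np.asarray(spec.concentrations, dtype=float), spec.n_replicates)
    rep = np.repeat(np.arange(spec.n_replicates), len(spec.concentrations))
    y = hill(conc, spec.ic50, spec.nh)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
    return DoseResponseData(compound_id=compound_id, concentrations=conc,
                            response=np.clip(y, 0.0, 1.0), replicate=rep)
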