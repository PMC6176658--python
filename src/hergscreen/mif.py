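"""Grid-probe molecular interaction fields and alignment-free correlograms.

A molecule is surrounded by a regular grid; at every node the interaction
energy with a chemical probe is the sum of a 12-6 Lennard-Jones term, a
Coulomb term with distance-dependent dielectric D(r) = 4r, and a
distance- and angle-damped hydrogen-bond term:

    E(x, y, z) = sum_atoms [ E_lj + E_el + E_hb ]

Four probes are used: DRY (hydrophobic), O (sp2 carbonyl oxygen; hydrogen
bond acceptor probe mapping donor hotspots), N1 (neutral flat amide NH;
donor probe mapping acceptor hotspots) and TIP (molecular shape, computed
as a solvent-accessible-surface shell rather than an energy function).

Favourable nodes are extracted with per-probe energy cutoffs (the AMANDA
prefilter) and encoded into ten auto/cross correlograms: per probe pair and
per 0.4 Angstrom distance bin, the descriptor value is the largest absolute
product of node energies among node pairs at that distance (MACC2), or the
dataset-consistent variant (CLACC-style).

The parameterization here is deliberately simple and fully documented; the
absolute energies are not comparable to any proprietary force field, but the
geometric structure of the hotspots (ring faces, H-bond cones, molecular
extremities) — which is what the correlograms encode — is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemio import Molecule

COULOMB_CONSTANT = 332.0636  # kcal/mol * Angstrom / e^2
ENERGY_CEILING = 5.0  # kcal/mol clamp inside vdW clashes
WATER_PROBE_RADIUS = 1.4  # Angstrom, for the TIP surface shell

#: AMANDA default energy cutoffs (kcal/mol) per probe.
DEFAULT_CUTOFFS = {"DRY": -0.5, "O": -2.6, "N1": -4.2, "TIP": -0.75}

PROBE_ORDER = ("DRY", "O", "N1", "TIP")
#: 4 auto + 6 cross correlogram blocks, fixed order.
BLOCKS = (
    ("DRY", "DRY"), ("O", "O"), ("N1", "N1"), ("TIP", "TIP"),
    ("DRY", "O"), ("DRY", "N1"), ("DRY", "TIP"),
    ("O", "N1"), ("O", "TIP"), ("N1", "TIP"),
)

# Per-vdW-type 12-6 parameters: (r_min/2 contribution in Angstrom, well depth
# epsilon in kcal/mol).  Combined with the probe via r_pair = r_a + r_p,
# eps_pair = sqrt(eps_a * eps_p).
ATOM_LJ = {
    "C.ar": (1.85, 0.12), "C.3": (1.95, 0.12), "C.2": (1.90, 0.12),
    "N": (1.75, 0.16), "O": (1.65, 0.20), "S": (2.00, 0.25), "P": (2.10, 0.20),
    "H": (1.20, 0.02), "F": (1.55, 0.08), "Cl": (1.90, 0.27),
    "Br": (2.00, 0.32), "I": (2.20, 0.40),
}

#: vdW radii for the solvent-accessible surface (element-level).
SAS_RADII = {
    "C.ar": 1.70, "C.3": 1.70, "C.2": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "H": 1.10, "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}


@dataclass(frozen=True)
class ProbeParameters:
    """One probe: LJ self-parameters, charge and H-bond term.

    hb_strength is the well depth (kcal/mol) of the Gaussian radial H-bond
    term centred at hb_distance, damped by cos^hb_exponent of the deviation
    from the donor/acceptor axis.  hb_target selects which atoms the probe
    hydrogen-bonds with: 'acceptors' for a donor probe, 'donors' for an
    acceptor probe.
    """

    name: str
    radius: float  # Angstrom
    epsilon: float  # kcal/mol
    charge: float  # e
    hb_strength: float = 0.0
    hb_distance: float = 2.9
    hb_width: float = 0.5
    hb_exponent: int = 2
    hb_target: str = ""


# N1 hb_strength is calibrated so a carbonyl acceptor reaches the -4.2
# cutoff on-axis (LJ repulsion at 2.9 A and electrostatics included).
PROBES = {
    "DRY": ProbeParameters("DRY", radius=1.70, epsilon=0.25, charge=0.0),
}

#: DRY polar-proximity penalty: the hydrophobic probe is disfavoured near
#: hydrogen-bonding surface patches (kcal/mol at the Gaussian centre).
DRY_POLAR_PENALTY = 1.5
DRY_POLAR_DISTANCE = 2.8
DRY_POLAR_WIDTH = 0.6

PROBES |= {
    "O": ProbeParameters("O", radius=1.65, epsilon=0.20, charge=-0.45,
                         hb_strength=4.0, hb_target="donors"),
    "N1": ProbeParameters("N1", radius=1.75, epsilon=0.16, charge=0.20,
                          hb_strength=5.5, hb_target="acceptors"),
}


class MifError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def node_coordinates(self) -> np.ndarray:
        """All node positions, shape (n_nodes, 3), x-major (C order)."""
        ax = [np.asarray(self.origin[i]) + self.spacing * np.arange(self.shape[i])
              for i in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass
class ProbeField:
    grid: GridSpec
    probe: str
    energies: np.ndarray  # (n_nodes,), kcal/mol


@dataclass
class NodeSet:
    probe: str
    positions: np.ndarray  # (k, 3)
    energies: np.ndarray  # (k,)
    cutoff: float
    grid_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __len__(self) -> int:
        return len(self.energies)


@dataclass
class CorrelogramSet:
    """Ten distance-binned blocks of node-pair energy products for one compound."""

    compound_id: str
    bin_edges: np.ndarray  # (n_bins + 1,)
    values: dict  # (probe_a, probe_b) -> (n_bins,) array, kcal^2/mol^2
    pairs: dict  # (probe_a, probe_b) -> (n_bins, 2) int array of node indices (-1: empty)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def flatten(self) -> tuple[np.ndarray, list[tuple[str, str, float, float]]]:
        """Concatenate all blocks into one vector with (blockA, blockB, lo, hi) labels."""
        vec, labels = [], []
        for a, b in BLOCKS:
            v = self.values[(a, b)]
            vec.append(v)
            for k in range(self.n_bins):
                labels.append((a, b, float(self.bin_edges[k]), float(self.bin_edges[k + 1])))
        return np.concatenate(vec), labels


# ---------------------------------------------------------------------------
# grid construction

def build_grid(molecule: Molecule, spacing: float = 0.5, margin: float = 5.0,
               conf_id: int = 0) -> GridSpec:
    """Axis-aligned box = molecule bounding box +/- margin, snapped to spacing."""
    if spacing <= 0:
        raise MifError("spacing must be positive")
    pos = molecule.coordinates(conf_id)
    lo = np.floor((pos.min(axis=0) - margin) / spacing) * spacing
    hi = pos.max(axis=0) + margin
    shape = tuple(int(np.floor((hi[i] - lo[i]) / spacing + 1e-9)) + 1 for i in range(3))
    return GridSpec(origin=tuple(float(x) for x in lo), spacing=float(spacing), shape=shape)


# ---------------------------------------------------------------------------
# hydrogen-bond geometry helpers

def _hb_sites(molecule: Molecule, which: str):
    """Positions and axis directions of H-bond partners in the molecule.

    'acceptors': heteroatom positions, axis pointing away from the mean of
    the bonded heavy atoms (lone-pair side).  'donors': polar hydrogens, axis
    along the heavy-atom -> H bond.
    """
    from .chemio import _HBA_SMARTS

    mol = molecule.mol
    pos = molecule.coordinates()
    sites = []
    if which == "acceptors":
        for (i,) in mol.GetSubstructMatches(_HBA_SMARTS):
            heavy = [n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors()
                     if n.GetSymbol() != "H"]
            if heavy:
                axis = pos[i] - pos[heavy].mean(axis=0)
            else:
                axis = np.array([0.0, 0.0, 1.0])
            n = np.linalg.norm(axis)
            sites.append((pos[i], axis / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])))
    elif which == "donors":
        for atom in mol.GetAtoms():
            if atom.GetSymbol() != "H":
                continue
            nb = atom.GetNeighbors()
            if nb and nb[0].GetSymbol() in ("N", "O", "S"):
                i, j = atom.GetIdx(), nb[0].GetIdx()
                axis = pos[i] - pos[j]
                n = np.linalg.norm(axis)
                if n > 1e-9:
                    sites.append((pos[i], axis / n))
    return sites


# ---------------------------------------------------------------------------
# field computation

def compute_probe_field(molecule: Molecule, probe, grid: GridSpec) -> ProbeField:
    """Total probe-molecule interaction energy at every grid node (Eq. of
    module docstring), clamped above at +5 kcal/mol."""
    if isinstance(probe, str):
        if probe == "TIP":
            return surface_nodes(molecule, grid)
        probe = PROBES[probe]
    nodes = grid.node_coordinates()
    pos = molecule.coordinates()
    vdw = molecule.vdw_types()
    charges = molecule.partial_charges()
    charges = np.where(np.isfinite(charges), charges, 0.0)

    missing = [t for t in set(vdw) if t not in ATOM_LJ]
    if missing:
        raise MifError(f"atom types missing from probe parameter table: {missing}")

    e = np.zeros(len(nodes))
    # pairwise distances in atom-sized chunks to bound memory
    d = np.linalg.norm(nodes[:, None, :] - pos[None, :, :], axis=2)
    d = np.maximum(d, 0.05)

    r_pair = np.array([ATOM_LJ[t][0] for t in vdw]) + probe.radius
    eps = np.sqrt(np.array([ATOM_LJ[t][1] for t in vdw]) * probe.epsilon)
    s6 = (r_pair[None, :] / d) ** 6
    e += np.sum(eps[None, :] * (s6 * s6 - 2.0 * s6), axis=1)

    if probe.charge != 0.0:
        # distance-dependent dielectric D(r) = 4r  ->  q q' / (4 r^2)
        e += np.sum(COULOMB_CONSTANT * probe.charge * charges[None, :] / (4.0 * d * d), axis=1)

    if probe.name == "DRY":
        # hydrophobic probe disfavoured near polar (H-bonding) atoms
        for which in ("acceptors", "donors"):
            for site_pos, _axis in _hb_sites(molecule, which):
                r = np.linalg.norm(nodes - site_pos[None, :], axis=1)
                e += DRY_POLAR_PENALTY * np.exp(
                    -((r - DRY_POLAR_DISTANCE) ** 2) / (2.0 * DRY_POLAR_WIDTH**2))

    if probe.hb_strength > 0.0 and probe.hb_target:
        for site_pos, axis in _hb_sites(molecule, probe.hb_target):
            dv = nodes - site_pos[None, :]
            r = np.linalg.norm(dv, axis=1)
            r = np.maximum(r, 0.05)
            cos = np.clip(dv @ axis / r, 0.0, None)
            radial = np.exp(-((r - probe.hb_distance) ** 2) / (2.0 * probe.hb_width**2))
            e -= probe.hb_strength * radial * cos**probe.hb_exponent

    return ProbeField(grid=grid, probe=probe.name, energies=np.minimum(e, ENERGY_CEILING))


def surface_nodes(molecule: Molecule, grid: GridSpec,
                  shell_half_width: float = 0.25) -> ProbeField:
    """TIP shape probe: -1.0 kcal/mol pseudo-energy on the solvent-accessible
    surface shell (union-of-spheres boundary, probe radius 1.4 A), 0 elsewhere.

    The signed distance to the SAS is f(x) = min_i(|x - r_i| - (R_i + 1.4));
    the shell is |f| <= shell_half_width.  Buried interior regions (f strongly
    negative, e.g. the neck between fused spheres) are excluded automatically.
    """
    nodes = grid.node_coordinates()
    pos = molecule.coordinates()
    radii = np.array([SAS_RADII[t] for t in molecule.vdw_types()]) + WATER_PROBE_RADIUS
    d = np.linalg.norm(nodes[:, None, :] - pos[None, :, :], axis=2) - radii[None, :]
    f = d.min(axis=1)
    e = np.where(np.abs(f) <= shell_half_width, -1.0, 0.0)
    return ProbeField(grid=grid, probe="TIP", energies=e)


# ---------------------------------------------------------------------------
# AMANDA node extraction

def amanda_filter(fld: ProbeField, cutoff: float | None = None,
                  max_nodes: int = 100) -> NodeSet:
    """Keep nodes at or below the (negative) energy cutoff, then prune to at
    most ``max_nodes`` by energy-weighted farthest-point selection.

    Selection starts from the most favourable node and greedily adds the node
    maximizing |E| * (distance to the nearest already-selected node), subject
    to a minimum mutual separation of one grid step.  Deterministic: ties are
    broken by grid index order.
    """
    if cutoff is None:
        cutoff = DEFAULT_CUTOFFS[fld.probe]
    if cutoff >= 0:
        raise MifError("cutoff must be negative (favourable energies)")
    idx = np.nonzero(fld.energies <= cutoff)[0]
    coords = fld.grid.node_coordinates()[idx]
    energies = fld.energies[idx]
    if len(idx) > max_nodes:
        order = _farthest_point_prune(coords, energies, max_nodes, fld.grid.spacing)
        keep = np.sort(order)
        idx, coords, energies = idx[keep], coords[keep], energies[keep]
    return NodeSet(probe=fld.probe, positions=coords, energies=energies,
                   cutoff=float(cutoff), grid_indices=idx)


def _farthest_point_prune(coords, energies, k, min_sep):
    n = len(coords)
    selected = [int(np.lexsort((np.arange(n), energies))[0])]  # lowest E, first index on tie
    dmin = np.linalg.norm(coords - coords[selected[0]], axis=1)
    available = np.ones(n, dtype=bool)
    available[selected[0]] = False
    while len(selected) < k:
        cand = available & (dmin >= min_sep - 1e-9)
        if not cand.any():
            break
        score = np.where(cand, np.abs(energies) * dmin, -np.inf)
        j = int(np.argmax(score))  # argmax returns first max -> grid-index tie-break
        selected.append(j)
        available[j] = False
        dmin = np.minimum(dmin, np.linalg.norm(coords - coords[j], axis=1))
    return np.array(selected, dtype=int)


# ---------------------------------------------------------------------------
# correlogram encoding

DEFAULT_BIN_WIDTH = 0.4
DEFAULT_MAX_DIST = 40.0


def encode_correlograms(nodesets: dict, compound_id: str = "",
                        bin_width: float = DEFAULT_BIN_WIDTH,
                        max_dist: float = DEFAULT_MAX_DIST) -> CorrelogramSet:
    """MACC2 encoding: per probe pair and half-open distance bin [lo, hi),
    keep the maximum |E_i * E_j| over node pairs at that distance.

    Auto blocks use unordered pairs i < j within one node set; cross blocks
    use all ordered pairs across the two sets.  The contributing pair of node
    indices is recorded per bin (-1 when the bin is empty).
    """
    missing = [p for p in PROBE_ORDER if p not in nodesets]
    if missing:
        raise MifError(f"node sets missing for probes: {missing}")
    n_bins = int(round(max_dist / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    values, pairs = {}, {}
    for a, b in BLOCKS:
        na, nb = nodesets[a], nodesets[b]
        v = np.zeros(n_bins)
        pr = np.full((n_bins, 2), -1, dtype=int)
        if a == b:
            if len(na) >= 2:
                iu, ju = np.triu_indices(len(na), k=1)
                _bin_maximize(na, na, iu, ju, bin_width, n_bins, v, pr)
        else:
            if len(na) >= 1 and len(nb) >= 1:
                iu, ju = np.meshgrid(np.arange(len(na)), np.arange(len(nb)), indexing="ij")
                _bin_maximize(na, nb, iu.ravel(), ju.ravel(), bin_width, n_bins, v, pr)
        values[(a, b)] = v
        pairs[(a, b)] = pr
    return CorrelogramSet(compound_id=compound_id, bin_edges=edges, values=values, pairs=pairs)


def _bin_maximize(na, nb, iu, ju, bin_width, n_bins, v, pr):
    d = np.linalg.norm(na.positions[iu] - nb.positions[ju], axis=1)
    prod = np.abs(na.energies[iu] * nb.energies[ju])
    bins = np.floor(d / bin_width).astype(int)
    ok = (bins >= 0) & (bins < n_bins)
    for b_idx, p, i, j in zip(bins[ok], prod[ok], iu[ok], ju[ok]):
        if p > v[b_idx]:
            v[b_idx] = p
            pr[b_idx] = (i, j)


def encode_dataset_clacc(per_compound_nodesets: list, ids: list[str] | None = None,
                         bin_width: float = DEFAULT_BIN_WIDTH,
                         max_dist: float = DEFAULT_MAX_DIST,
                         near_max_frac: float = 0.8) -> list[CorrelogramSet]:
    """CLACC-style consistent encoding of a whole dataset.

    First every compound is MACC2-encoded; then, per bin, each compound
    re-selects among its near-maximal candidate pairs (product >=
    ``near_max_frac`` of its bin maximum) the pair whose product deviates
    least, in relative terms, from the dataset median of that bin.  This is a
    documented approximation to consistently-large auto/cross correlation;
    MACC2 is the default elsewhere.
    """
    ids = ids or [f"c{i}" for i in range(len(per_compound_nodesets))]
    base = [encode_correlograms(ns, cid, bin_width, max_dist)
            for ns, cid in zip(per_compound_nodesets, ids)]
    n_bins = base[0].n_bins
    for a, b in BLOCKS:
        stack = np.array([c.values[(a, b)] for c in base])
        med = np.median(stack, axis=0)
        for c, nodesets in zip(base, per_compound_nodesets):
            na, nb = nodesets[a], nodesets[b]
            if a == b:
                if len(na) < 2:
                    continue
                iu, ju = np.triu_indices(len(na), k=1)
            else:
                if len(na) < 1 or len(nb) < 1:
                    continue
                gi, gj = np.meshgrid(np.arange(len(na)), np.arange(len(nb)), indexing="ij")
                iu, ju = gi.ravel(), gj.ravel()
            d = np.linalg.norm(na.positions[iu] - nb.positions[ju], axis=1)
            prod = np.abs(na.energies[iu] * nb.energies[ju])
            bins = np.floor(d / bin_width).astype(int)
            for b_idx in range(n_bins):
                mask = bins == b_idx
                if not mask.any() or c.values[(a, b)][b_idx] <= 0:
                    continue
                cand = mask & (prod >= near_max_frac * c.values[(a, b)][b_idx])
                pvals = prod[cand]
                denom = med[b_idx] if med[b_idx] > 0 else 1.0
                rel = np.abs(pvals - med[b_idx]) / denom
                k = int(np.argmin(rel))
                sel = np.nonzero(cand)[0][k]
                c.values[(a, b)][b_idx] = prod[sel]
                c.pairs[(a, b)][b_idx] = (iu[sel], ju[sel])
    return base


def compound_descriptors(molecule: Molecule, spacing: float = 0.5, margin: float = 5.0,
                         cutoffs: dict | None = None, max_nodes: int = 100,
                         bin_width: float = DEFAULT_BIN_WIDTH,
                         max_dist: float = DEFAULT_MAX_DIST) -> CorrelogramSet:
    """Convenience: grid -> four probe fields -> AMANDA -> MACC2 correlograms."""
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    grid = build_grid(molecule, spacing=spacing, margin=margin)
    nodesets = {}
    for probe in PROBE_ORDER:
        fld = compute_probe_field(molecule, probe, grid)
        nodesets[probe] = amanda_filter(fld, cutoffs[probe], max_nodes)
    return encode_correlograms(nodesets, molecule.id, bin_width, max_dist)


def export_correlograms_csv(correlograms: list[CorrelogramSet], path) -> None:
    """Long-format CSV: compound, block, bin_lo, bin_hi, value, node_i, node_j."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound", "block", "bin_lo", "bin_hi", "value", "node_i", "node_j"])
        for c in correlograms:
            for a, b in BLOCKS:
                for k in range(c.n_bins):
                    v = c.values[(a, b)][k]
                    if v > 0:
                        i, j = c.pairs[(a, b)][k]
                        w.writerow([c.compound_id, f"{a}-{b}", c.bin_edges[k],
                                    c.bin_edges[k + 1], f"{v:.6g}", i, j])
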