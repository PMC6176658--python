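"""Interaction fields: grids, probe energies, AMANDA filtering, correlograms."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from conftest import rigid_transform
from hergscreen import mif
from hergscreen.chemio import Molecule, from_smiles, generate_conformers, standardize


def _point_molecule(symbol="C", positions=((0.0, 0.0, 0.0),)):
    """Bare atoms at given coordinates (no bonds) for field unit tests."""
    rw = Chem.RWMol()
    for _ in positions:
        rw.AddAtom(Chem.Atom(symbol))
    mol = rw.GetMol()
    for atom in mol.GetAtoms():
        atom.SetNoImplicit(True)
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, p in enumerate(positions):
        conf.SetAtomPosition(i, tuple(map(float, p)))
    mol.AddConformer(conf)
    AllChem.ComputeGasteigerCharges(mol)
    return Molecule(id="pts", mol=mol)


class TestGrid:
    def test_single_atom_node_count(self):
        grid = mif.build_grid(_point_molecule(), spacing=0.5, margin=5.0)
        assert grid.shape == (21, 21, 21)  # 2*5/0.5 + 1 per axis

    def test_margin_encloses_molecule(self, benzene):
        grid = mif.build_grid(benzene, spacing=0.5, margin=5.0)
        pos = benzene.coordinates()
        lo = np.array(grid.origin)
        hi = lo + grid.spacing * (np.array(grid.shape) - 1)
        assert np.all(pos.min(0) - lo >= 5.0 - grid.spacing - 1e-9)
        assert np.all(hi - pos.max(0) >= 5.0 - grid.spacing - 1e-9)

    def test_spacing_halving_doubles_nodes(self, benzene):
        g1 = mif.build_grid(benzene, spacing=0.5)
        g2 = mif.build_grid(benzene, spacing=0.25)
        for a in range(3):
            assert g2.shape[a] / g1.shape[a] == pytest.approx(2.0, rel=0.1)


class TestProbeField:
    def test_lj_profile_single_minimum(self):
        """DRY energy along an axis from a lone carbon: one negative minimum."""
        m = _point_molecule("C")
        r = np.linspace(2.0, 10.0, 200)
        grid = mif.GridSpec(origin=(2.0, 0.0, 0.0), spacing=r[1] - r[0],
                            shape=(200, 1, 1))
        e = mif.compute_probe_field(m, "DRY", grid).energies
        i = int(np.argmin(e))
        assert e[i] < 0
        assert np.all(np.diff(e[: i + 1]) <= 1e-12)  # decreasing to the minimum
        assert np.all(np.diff(e[i:]) >= -1e-12)  # increasing after it

    def test_far_field_decay(self, acetone):
        grid = mif.GridSpec(origin=(50.0, 0.0, 0.0), spacing=1.0, shape=(3, 3, 3))
        for probe in ("DRY", "O", "N1"):
            e = mif.compute_probe_field(acetone, probe, grid).energies
            assert np.abs(e).max() < 0.01

    def test_carbonyl_n1_hotspot_on_axis(self, acetone):
        grid = mif.build_grid(acetone, spacing=0.4)
        fld = mif.compute_probe_field(acetone, "N1", grid)
        nodes = grid.node_coordinates()
        i = int(np.argmin(fld.energies))
        assert fld.energies[i] <= -4.2
        mol, pos = acetone.mol, acetone.coordinates()
        o = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O")
        c = mol.GetAtomWithIdx(o).GetNeighbors()[0].GetIdx()
        axis = pos[o] - pos[c]
        axis /= np.linalg.norm(axis)
        v = nodes[i] - pos[o]
        angle = np.degrees(np.arccos(v @ axis / np.linalg.norm(v)))
        assert angle < 45.0

    def test_field_additivity_of_distant_fragments(self):
        a = _point_molecule("C", [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0)])
        b = _point_molecule("C", [(25.0, 0.0, 0.0), (26.5, 0.0, 0.0)])
        both = _point_molecule("C", [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0),
                                     (25.0, 0.0, 0.0), (26.5, 0.0, 0.0)])
        grid = mif.GridSpec(origin=(-5.0, -5.0, -5.0), spacing=1.0, shape=(37, 11, 11))
        ea = mif.compute_probe_field(a, "DRY", grid).energies
        eb = mif.compute_probe_field(b, "DRY", grid).energies
        eab = mif.compute_probe_field(both, "DRY", grid).energies
        assert np.abs(eab - np.minimum(ea + eb, mif.ENERGY_CEILING)).max() < 0.02


class TestSurface:
    def test_single_atom_shell_radius(self):
        m = _point_molecule("C")  # SAS radius 1.7 + 1.4 = 3.1
        grid = mif.GridSpec(origin=(-5.0, -5.0, -5.0), spacing=0.25, shape=(41, 41, 41))
        fld = mif.surface_nodes(m, grid)
        nodes = grid.node_coordinates()
        r = np.linalg.norm(nodes[fld.energies < 0], axis=1)
        assert len(r) > 0
        assert r.min() >= 3.1 - 0.35 and r.max() <= 3.1 + 0.35

    def test_fused_spheres_neck_is_excluded(self):
        m = _point_molecule("C", [(0.0, 0.0, 0.0), (2.0, 0.0, 0.0)])
        grid = mif.GridSpec(origin=(-5.0, -5.0, -5.0), spacing=0.25, shape=(49, 41, 41))
        fld = mif.surface_nodes(m, grid)
        nodes = grid.node_coordinates()
        shell = nodes[fld.energies < 0]
        # every shell node is on the union-of-spheres boundary, not buried
        d = np.minimum(np.linalg.norm(shell, axis=1),
                       np.linalg.norm(shell - [2.0, 0.0, 0.0], axis=1))
        assert np.all(d >= 3.1 - 0.251)

    def test_linear_molecule_tip_extent(self):
        # decane-like rod of carbons, length L = 9 * 1.5 = 13.5 A
        pts = [(1.5 * k, 0.0, 0.0) for k in range(10)]
        m = _point_molecule("C", pts)
        grid = mif.build_grid(m, spacing=0.5, margin=5.0)
        ns = mif.amanda_filter(mif.surface_nodes(m, grid), max_nodes=10**9)
        extent = np.ptp(ns.positions[:, 0])  # rod lies along x
        assert extent == pytest.approx(13.5 + 6.2, abs=1.0)


class TestAmanda:
    def _field(self, energies, spacing=1.0):
        n = len(energies)
        grid = mif.GridSpec(origin=(0.0, 0.0, 0.0), spacing=spacing, shape=(n, 1, 1))
        return mif.ProbeField(grid=grid, probe="DRY",
                              energies=np.asarray(energies, dtype=float))

    def test_all_zero_field_empty(self):
        assert len(mif.amanda_filter(self._field([0.0] * 8), cutoff=-0.5)) == 0

    def test_cutoff_keeps_favourable_nodes(self):
        ns = mif.amanda_filter(self._field([-3.0, -1.0, -0.2]), cutoff=-0.5)
        assert len(ns) == 2
        assert np.all(ns.energies <= -0.5)

    def test_prune_to_max_nodes_with_separation(self):
        rng = np.random.default_rng(0)
        e = -rng.uniform(0.5, 4.0, 500)
        grid = mif.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, shape=(500, 1, 1))
        fld = mif.ProbeField(grid=grid, probe="DRY", energies=e)
        ns = mif.amanda_filter(fld, cutoff=-0.5, max_nodes=100)
        assert len(ns) == 100
        d = np.abs(ns.positions[:, 0][:, None] - ns.positions[:, 0][None, :])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 1.0 - 1e-9

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        fld = self._field(-rng.uniform(0.0, 4.0, 60))
        tight = mif.amanda_filter(fld, cutoff=-2.0, max_nodes=10**9)
        loose = mif.amanda_filter(fld, cutoff=-0.5, max_nodes=10**9)
        assert set(tight.grid_indices) <= set(loose.grid_indices)


def _random_nodesets(rng, n_per_probe=20, scale=10.0):
    out = {}
    for p in mif.PROBE_ORDER:
        out[p] = mif.NodeSet(probe=p,
                             positions=rng.uniform(0, scale, (n_per_probe, 3)),
                             energies=-rng.uniform(0.5, 4.0, n_per_probe),
                             cutoff=-0.5)
    return out


def brute_force_correlograms(nodesets, bin_width=0.4, max_dist=40.0):
    """Independent double-loop oracle for MACC2."""
    n_bins = int(round(max_dist / bin_width))
    out = {}
    for a, b in mif.BLOCKS:
        na, nb = nodesets[a], nodesets[b]
        v = np.zeros(n_bins)
        pairs = ([(i, j) for i in range(len(na)) for j in range(i + 1, len(na))]
                 if a == b else
                 [(i, j) for i in range(len(na)) for j in range(len(nb))])
        for i, j in pairs:
            d = float(np.linalg.norm(na.positions[i] - nb.positions[j]))
            k = int(d // bin_width)
            if k < n_bins:
                v[k] = max(v[k], abs(na.energies[i] * nb.energies[j]))
        out[(a, b)] = v
    return out


class TestCorrelograms:
    def test_single_pair_value_and_bin(self):
        ns = {p: mif.NodeSet(p, np.empty((0, 3)), np.empty(0), -0.5)
              for p in mif.PROBE_ORDER}
        ns["DRY"] = mif.NodeSet("DRY", np.array([[0.0, 0, 0], [5.0, 0, 0]]),
                                np.array([-2.0, -1.0]), -0.5)
        cs = mif.encode_correlograms(ns)
        v = cs.values[("DRY", "DRY")]
        k = int(5.0 // 0.4)
        assert cs.bin_edges[k] == pytest.approx(4.8)
        assert v[k] == pytest.approx(2.0)
        assert np.count_nonzero(v) == 1
        assert tuple(cs.pairs[("DRY", "DRY")][k]) == (0, 1)

    def test_single_node_auto_blocks_zero(self):
        rng = np.random.default_rng(2)
        ns = {p: mif.NodeSet(p, rng.uniform(0, 5, (1, 3)), np.array([-1.0]), -0.5)
              for p in mif.PROBE_ORDER}
        cs = mif.encode_correlograms(ns)
        for p in mif.PROBE_ORDER:
            assert np.all(cs.values[(p, p)] == 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        ns = _random_nodesets(rng, 20)
        cs = mif.encode_correlograms(ns)
        oracle = brute_force_correlograms(ns)
        for block in mif.BLOCKS:
            assert np.allclose(cs.values[block], oracle[block])

    def test_rigid_motion_invariance(self, benzene):
        cs1 = mif.compound_descriptors(benzene, spacing=0.25)
        moved = Molecule(id=benzene.id, mol=Chem.Mol(benzene.mol))
        conf = moved.mol.GetConformer(0)
        new = rigid_transform(benzene.coordinates(), seed=9)
        for i, p in enumerate(new):
            conf.SetAtomPosition(i, tuple(float(x) for x in p))
        cs2 = mif.compound_descriptors(moved, spacing=0.25)

        def windowed_max(v, w=2):
            return np.array([v[max(0, k - w): k + w + 1].max() for k in range(len(v))])

        for block in mif.BLOCKS:
            v1, v2 = cs1.values[block], cs2.values[block]
            m1, m2 = windowed_max(v1), windowed_max(v2)
            scale = max(m1.max(), m2.max(), 1e-12)
            # values equal up to grid re-snap drift (fine grid bounds the
            # field-sampling error): compare windowed-max profiles
            assert np.abs(m1 - m2).max() / scale < 0.25

    def test_missing_probe_is_error(self):
        rng = np.random.default_rng(3)
        ns = _random_nodesets(rng, 5)
        del ns["TIP"]
        with pytest.raises(mif.MifError, match="TIP"):
            mif.encode_correlograms(ns)

    def test_clacc_selects_consistent_near_maximal_products(self):
        rng = np.random.default_rng(4)
        sets = [_random_nodesets(rng, 10) for _ in range(6)]
        base = [mif.encode_correlograms(ns) for ns in sets]
        clacc = mif.encode_dataset_clacc(sets)
        for b, c in zip(base, clacc):
            for block in mif.BLOCKS:
                sel, mx = c.values[block], b.values[block]
                nz = mx > 0
                assert np.all(sel[nz] >= 0.8 * mx[nz] - 1e-12)
                assert np.all(sel[nz] <= mx[nz] + 1e-12)


def test_dumbbell_dry_peak_near_14A():
    from hergscreen.synthetic_data import make_aromatic_dumbbell

    cs = mif.compound_descriptors(make_aromatic_dumbbell(14.0, seed=1))
    v = cs.values[("DRY", "DRY")]
    peak = int(np.argmax(v))
    assert 13.2 <= cs.bin_edges[peak] and cs.bin_edges[peak + 1] <= 15.2
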