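"""Curation rules, diverse splitting, drug-likeness and the screening funnel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hergscreen.chemio import ActivityRecord, from_smiles, generate_conformers, standardize
from hergscreen.screening import (curate, diverse_split, enrichment_factor, lipinski,
                                  virtual_screen)

GOOD = dict(assay="patch_clamp", cell_line="CHO")


def _rec(mol_id, smiles, ic50, **kw):
    args = {**GOOD, **kw}
    return (from_smiles(smiles, mol_id),
            ActivityRecord(mol_id, ic50, args["assay"], args["cell_line"]))


BIG = "c1ccc(CCCCc2ccc(OCCN3CCCCC3)cc2)cc1"  # MW > 200 parent scaffold


class TestCurate:
    def test_toy_set_rule_attribution(self):
        records = [
            _rec("a1", BIG, 1e-6),
            _rec("a2", BIG, 1e-6),                       # exact duplicate of a1
            _rec("f1", "c1ccccc1O", 1e-6),               # MW 94 fragment
            _rec("b1", BIG + "C", 1e-6, assay="binding"),
            _rec("y1", BIG + "CC", 1e-6, cell_line="yeast"),
            _rec("a3", BIG + "CCC", 2e-6),
        ]
        retained, report = curate(records)
        assert len(retained) == 2
        assert report.counts == {"input": 6, "duplicates": 1, "fragments": 1,
                                 "assay": 1, "cell_line": 1, "retained": 2}
        assert report.check_identity()

    def test_duplicate_merge_geometric_mean(self):
        records = [_rec("d1", BIG, 1e-6), _rec("d2", BIG, 4e-6)]
        retained, report = curate(records)
        assert len(retained) == 1
        assert retained[0][1].ic50 == pytest.approx(2e-6)
        assert report.discordant == []

    def test_discordant_replicates_flagged(self):
        records = [_rec("d1", BIG, 1e-7), _rec("d2", BIG, 5e-6)]  # 1.7 log apart
        _, report = curate(records)
        assert report.discordant == ["d1"]

    def test_empty_input(self):
        retained, report = curate([])
        assert retained == [] and report.n_input == 0
        assert report.check_identity()

    @given(st.lists(st.tuples(st.sampled_from([BIG, "c1ccccc1O", BIG + "C"]),
                              st.sampled_from(["patch_clamp", "binding"]),
                              st.sampled_from(["CHO", "HEK293", "yeast"])),
                    max_size=12))
    @settings(max_examples=25, deadline=None)
    def test_bookkeeping_identity(self, rows):
        records = [_rec(f"m{i}", smi, 1e-6, assay=a, cell_line=c)
                   for i, (smi, a, c) in enumerate(rows)]
        _, report = curate(records)
        assert report.check_identity()


class TestDiverseSplit:
    @pytest.fixture(scope="class")
    def library207(self):
        from hergscreen.synthetic_data import SarSpec, make_sar_dataset

        ds = make_sar_dataset(SarSpec(n_compounds=207, seed=17, noise_sd=0.3))
        return [(m, ActivityRecord(m.id, 10.0 ** (-p), "patch_clamp", "CHO"))
                for m, p in zip(ds.molecules, ds.pic50)]

    def test_80_20_of_207_gives_41_test(self, library207):
        train, test, _ = diverse_split(library207, 0.8, seed=1)
        assert len(test) == 41
        assert len(train) == 166

    def test_deterministic_per_seed(self, library207):
        t1 = diverse_split(library207, 0.8, seed=5)
        t2 = diverse_split(library207, 0.8, seed=5)
        assert [r.compound_id for _, r in t1[1]] == [r.compound_id for _, r in t2[1]]

    def test_identical_molecules_split_deterministically(self):
        records = [_rec(f"m{i}", BIG, 1e-6) for i in range(10)]
        a = diverse_split(records, 0.8, seed=3)
        b = diverse_split(records, 0.8, seed=3)
        assert len(a[1]) == 2
        assert [r.compound_id for _, r in a[1]] == [r.compound_id for _, r in b[1]]

    def test_test_set_more_diverse_than_random(self, library207):
        """Farthest-first test sets have larger mean nearest-neighbour
        fingerprint distance than random subsets of the same size."""
        from rdkit import Chem, DataStructs
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        fps = [gen.GetFingerprint(Chem.RemoveHs(m.mol)) for m, _ in library207]

        def mean_nn(idx):
            out = []
            for i in idx:
                sims = [DataStructs.TanimotoSimilarity(fps[i], fps[j])
                        for j in idx if j != i]
                out.append(1.0 - max(sims))
            return np.mean(out)

        wins = 0
        for seed in range(8):
            _, test, _ = diverse_split(library207, 0.8, seed=seed)
            ids = {r.compound_id for _, r in test}
            test_idx = [i for i, (_, r) in enumerate(library207) if r.compound_id in ids]
            rand_idx = np.random.default_rng(seed).choice(len(library207), len(test_idx),
                                                          replace=False)
            wins += mean_nn(test_idx) >= mean_nn(rand_idx)
        assert wins >= 7


class TestLipinski:
    def test_aspirin_passes_clean(self):
        ok, viol = lipinski(from_smiles("CC(=O)Oc1ccccc1C(=O)O", "aspirin"))
        assert ok and viol == []

    def test_two_violations_fail(self):
        # long greasy chain: MW > 500 and clogP > 5
        greasy = from_smiles("C" * 40, "c40")
        ok, viol = lipinski(greasy)
        assert not ok and len(viol) >= 2

    def test_single_violation_still_passes(self):
        # sorbitol: six donors, otherwise clean -> one violation, passes
        mol = from_smiles("OCC(O)C(O)C(O)C(O)CO", "sorbitol")
        ok, viol = lipinski(mol)
        assert viol == ["HBD>5"]
        assert ok


class TestFunnel:
    @pytest.fixture(scope="class")
    def trained(self):
        from hergscreen.qsar import fit_pls, pca_domain
        from hergscreen.synthetic_data import SarSpec, make_sar_dataset

        ds = make_sar_dataset(SarSpec(n_compounds=60, seed=23, noise_sd=0.3))
        model = fit_pls(ds.X, ds.pic50, 2, labels=ds.labels)
        return model, pca_domain(ds.X), ds.labels

    def _descriptor_fn(self, labels):
        from hergscreen.synthetic_data import feature_pair_descriptor

        return lambda mol: (feature_pair_descriptor(mol), labels)

    def test_enrichment_of_embedded_actives(self, trained, final_pharmacophore):
        from hergscreen.synthetic_data import embed_pharmacophore_actives, make_decoys

        model, domain, labels = trained
        actives = embed_pharmacophore_actives(final_pharmacophore, 20, seed=31)
        decoys = make_decoys(80, seed=31)
        hits, audit = virtual_screen(actives + decoys, final_pharmacophore, model,
                                     domain=domain,
                                     descriptor_fn=self._descriptor_fn(labels))
        truth = {m.id: m.id.startswith("active") for m in actives + decoys}
        assert enrichment_factor(hits, truth, 10) > 2.0
        assert len(audit) == 100

    def test_unmatchable_pharmacophore_full_attrition(self, trained):
        from hergscreen.pharmacophore import model_from_matrix
        from hergscreen.synthetic_data import make_decoys

        model, domain, labels = trained
        # giant distances: nothing in a small-molecule library can match
        impossible = model_from_matrix(
            ("Aro1", "Hyd", "Aro2", "HBA"),
            ("aromatic", "hydrophobic", "aromatic", "hbond_acceptor"),
            np.array([[0.0, 30, 30, 30], [30, 0.0, 30, 30],
                      [30, 30, 0.0, 30], [30, 30, 30, 0.0]]))
        library = make_decoys(10, seed=1)
        hits, audit = virtual_screen(library, impossible, model, domain=domain,
                                     descriptor_fn=self._descriptor_fn(labels))
        assert hits == []
        assert all(h.stage_reached == "pharmacophore" for h in audit)

    def test_filters_commute(self, trained, final_pharmacophore):
        from hergscreen.pharmacophore import match
        from hergscreen.screening import lipinski as lip
        from hergscreen.synthetic_data import embed_pharmacophore_actives, make_decoys

        model, domain, labels = trained
        library = (embed_pharmacophore_actives(final_pharmacophore, 8, seed=37)
                   + make_decoys(12, seed=37))
        hits, _ = virtual_screen(library, final_pharmacophore, model, domain=domain,
                                 descriptor_fn=self._descriptor_fn(labels))
        funnel_ids = {h.compound_id for h in hits}
        # independent order: lipinski first, then pharmacophore
        other = {m.id for m in library if lip(m)[0]
                 and match(m, final_pharmacophore).matched}
        assert funnel_ids == other

    def test_empty_library(self, trained, final_pharmacophore):
        model, domain, labels = trained
        hits, audit = virtual_screen([], final_pharmacophore, model,
                                     descriptor_fn=self._descriptor_fn(labels))
        assert hits == [] and audit == []
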