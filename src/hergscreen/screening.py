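"""Dataset curation and the end-to-end virtual-screening funnel.

Curation applies the activity-data refinement rules in a fixed order —
duplicate collapse (replicate IC50s merged by geometric mean), fragment
removal (MW < 200), assay filter (whole-cell patch clamp only), cell-line
filter (HEK293/CHO) — with per-rule bookkeeping: every input record is
attributed to exactly one fate.

The screening funnel is pharmacophore match -> Lipinski drug-likeness ->
descriptor computation -> QSAR pIC50 prediction with applicability-domain
flag -> ranking; every stage's pass/fail is persisted for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski as RDLipinski
from rdkit.Chem import rdFingerprintGenerator

from .chemio import ActivityRecord, Molecule
from .pharmacophore import MatchResult, PharmacophoreModel, match

PATCH_CLAMP_TOKENS = {"patch_clamp", "whole_cell_patch_clamp", "patch clamp"}
ALLOWED_CELL_LINES = {"HEK293", "CHO"}
FRAGMENT_MW_MIN = 200.0
DISCORDANT_LOG_RANGE = 1.0


@dataclass
class CurationReport:
    n_input: int = 0
    duplicates: list = field(default_factory=list)
    fragments: list = field(default_factory=list)
    assay_filtered: list = field(default_factory=list)
    cell_line_filtered: list = field(default_factory=list)
    discordant: list = field(default_factory=list)
    retained: list = field(default_factory=list)

    @property
    def counts(self) -> dict:
        return {"input": self.n_input, "duplicates": len(self.duplicates),
                "fragments": len(self.fragments), "assay": len(self.assay_filtered),
                "cell_line": len(self.cell_line_filtered), "retained": len(self.retained)}

    def check_identity(self) -> bool:
        removed = (len(self.duplicates) + len(self.fragments)
                   + len(self.assay_filtered) + len(self.cell_line_filtered))
        return self.n_input == len(self.retained) + removed


def curate(records) -> tuple[list, CurationReport]:
    """Apply the refinement rules in order; first failing rule attributed.

    ``records``: list of (Molecule, ActivityRecord).  Duplicates are
    collapsed on the canonical SMILES of the parent structure; replicate
    IC50s merge by geometric mean and are flagged discordant when the
    replicate range exceeds one log unit.
    """
    report = CurationReport(n_input=len(records))
    by_key: dict = {}
    order: list = []
    for mol, rec in records:
        key = Chem.MolToSmiles(Chem.RemoveHs(mol.mol))
        if key in by_key:
            by_key[key].append((mol, rec))
            report.duplicates.append(rec.compound_id)
        else:
            by_key[key] = [(mol, rec)]
            order.append(key)

    retained = []
    for key in order:
        group = by_key[key]
        mol, rec = group[0]
        if len(group) > 1:
            ic50s = np.array([r.ic50 for _, r in group])
            if np.ptp(np.log10(ic50s)) > DISCORDANT_LOG_RANGE:
                report.discordant.append(rec.compound_id)
            rec = ActivityRecord(rec.compound_id, float(np.exp(np.mean(np.log(ic50s)))),
                                 rec.assay, rec.cell_line)
        if mol.mw < FRAGMENT_MW_MIN:
            report.fragments.append(rec.compound_id)
            continue
        if rec.assay not in PATCH_CLAMP_TOKENS:
            report.assay_filtered.append(rec.compound_id)
            continue
        if rec.cell_line not in ALLOWED_CELL_LINES:
            report.cell_line_filtered.append(rec.compound_id)
            continue
        retained.append((mol, rec))
        report.retained.append(rec.compound_id)
    return retained, report


# ---------------------------------------------------------------------------
# diverse subset split

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _fingerprints(molecules):
    return [_MORGAN.GetFingerprint(Chem.RemoveHs(m.mol)) for m in molecules]


def diverse_split(records, train_frac: float = 0.8, seed: int = 0):
    """Maximum-dissimilarity 80/20 split on radius-2 circular fingerprints.

    Farthest-first traversal (seeded start) selects the test set of size
    N - round(train_frac * N); deterministic per seed.  A warning is
    attached when either split spans less than 80% of the full pIC50 range.
    """
    from rdkit import DataStructs

    n = len(records)
    if n < 5:
        raise ValueError("need at least 5 records to split")
    n_train = int(round(train_frac * n))
    n_test = n - n_train
    fps = _fingerprints([m for m, _ in records])
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    chosen = [start]
    dmin = np.array([1.0 - DataStructs.TanimotoSimilarity(fps[start], f) for f in fps])
    dmin[start] = -1.0
    while len(chosen) < n_test:
        j = int(np.argmax(dmin))
        chosen.append(j)
        dj = np.array([1.0 - DataStructs.TanimotoSimilarity(fps[j], f) for f in fps])
        dmin = np.minimum(dmin, dj)
        dmin[j] = -1.0
    test_idx = sorted(chosen)
    test_set = set(test_idx)
    train = [records[i] for i in range(n) if i not in test_set]
    test = [records[i] for i in test_idx]

    warning = None
    pic50s = np.array([r.pic50 for _, r in records])
    full = np.ptp(pic50s)
    if full > 0:
        for name, part in (("train", train), ("test", test)):
            span = np.ptp([r.pic50 for _, r in part])
            if span < 0.8 * full:
                warning = f"{name} split spans {span:.2f} of {full:.2f} pIC50 units"
    return train, test, warning


# ---------------------------------------------------------------------------
# drug-likeness

def lipinski(molecule: Molecule):
    """Rule-of-five violations; pass = at most one violation."""
    mol = Chem.RemoveHs(molecule.mol)
    checks = {
        "MW>500": Descriptors.MolWt(mol) > 500,
        "clogP>5": Descriptors.MolLogP(mol) > 5,
        "HBD>5": RDLipinski.NumHDonors(mol) > 5,
        "HBA>10": RDLipinski.NumHAcceptors(mol) > 10,
    }
    violations = [k for k, v in checks.items() if v]
    return len(violations) <= 1, violations


# ---------------------------------------------------------------------------
# virtual screening funnel

@dataclass
class ScreeningHit:
    compound_id: str
    match_result: MatchResult
    lipinski_pass: bool
    lipinski_violations: list
    predicted_pic50: float | None
    in_domain: bool | None
    rank: int | None
    stage_reached: str


def virtual_screen(library, pharm_model: PharmacophoreModel, qsar_model,
                   domain=None, descriptor_fn=None, top_k: int | None = None):
    """Funnel: pharmacophore match -> Lipinski -> descriptors -> prediction
    (+ domain flag) -> rank by predicted pIC50 (descending).

    ``descriptor_fn(molecule) -> (vector, labels)`` supplies the QSAR
    descriptors.  Returns (ranked hits, audit list covering every library
    molecule with the stage it reached).
    """
    from .qsar import predict

    audit = []
    survivors = []
    for mol in library:
        mr = match(mol, pharm_model)
        if not mr.matched:
            audit.append(ScreeningHit(mol.id, mr, False, [], None, None, None,
                                      "pharmacophore"))
            continue
        ok, viol = lipinski(mol)
        if not ok:
            audit.append(ScreeningHit(mol.id, mr, ok, viol, None, None, None,
                                      "lipinski"))
            continue
        survivors.append((mol, mr, viol))

    hits = []
    for mol, mr, viol in survivors:
        x, labels = descriptor_fn(mol)
        y_hat, flags = predict(qsar_model, x, labels_new=labels, domain=domain)
        hits.append(ScreeningHit(mol.id, mr, True, viol, float(y_hat[0]),
                                 None if flags is None else bool(flags[0]),
                                 None, "ranked"))
    hits.sort(key=lambda h: (-(h.predicted_pic50 if h.in_domain in (True, None)
                               else -np.inf), h.compound_id))
    for i, h in enumerate(hits):
        h.rank = i + 1
    audit.extend(hits)
    if top_k is not None:
        return hits[:top_k], audit
    return hits, audit


def enrichment_factor(hits, truth: dict, k: int) -> float:
    """EF@k: fraction of actives in the top k vs the base rate."""
    ranked = [h.compound_id for h in hits if h.rank is not None][:k]
    if not ranked:
        return 0.0
    base = sum(truth.values()) / len(truth)
    found = sum(truth.get(cid, False) for cid in ranked) / len(ranked)
    return found / base if base > 0 else 0.0
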