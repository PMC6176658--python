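"""Distance-matrix pharmacophore models, conformer matching and MCC scoring.

A model is an ordered set of 3 or 4 typed features (aromatic, hydrophobic,
hydrogen-bond acceptor) with a symmetric matrix of pairwise distances and a
per-pair tolerance (default 1.0 Angstrom, a hard-window stand-in for a
Gaussian feature radius; a soft Gaussian score is available as an option).
A conformer matches when some injective assignment of its perceived feature
sites to the model features, kind by kind, reproduces every pairwise
distance within tolerance.  Classification against an activity threshold
(active: IC50 <= 40 uM by default) is summarized by the Matthews
correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .chemio import Molecule, perceive_features

DEFAULT_TOLERANCE = 1.0  # Angstrom
DEFAULT_ACTIVE_IC50_MAX = 40e-6  # molar
EMBED_SLACK = 0.5  # Angstrom allowed deviation from exact 3-space embeddability


class PharmacophoreError(ValueError):
    pass


class GeometryError(PharmacophoreError):
    pass


@dataclass
class PharmacophoreModel:
    labels: tuple  # e.g. ("Aro1", "Hyd", "Aro2", "HBA")
    kinds: tuple  # feature kinds, aligned with labels
    matrix: np.ndarray  # symmetric distances, Angstrom, zero diagonal
    tolerance: float = DEFAULT_TOLERANCE
    provenance: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.labels)

    def embedded_coordinates(self) -> np.ndarray:
        """3-space coordinates realizing the distance matrix (classical MDS)."""
        return _embed_distances(self.matrix)


def _embed_distances(dm: np.ndarray) -> np.ndarray:
    """Best-effort 3-space embedding: classical MDS refined by least squares.

    Printed distance matrices carry rounding, so the MDS solution is polished
    by minimizing the pairwise distance residuals directly.
    """
    from scipy.optimize import least_squares

    n = dm.shape[0]
    d2 = dm**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:3]
    vals3 = np.clip(vals[order], 0.0, None)
    x0 = vecs[:, order] * np.sqrt(vals3)
    iu, ju = np.triu_indices(n, k=1)

    def resid(flat):
        x = flat.reshape(n, 3)
        return np.linalg.norm(x[iu] - x[ju], axis=1) - dm[iu, ju]

    sol = least_squares(resid, x0.ravel(), method="trf", max_nfev=2000)
    return sol.x.reshape(n, 3)


def model_from_matrix(labels, kinds, matrix, tolerance: float = DEFAULT_TOLERANCE,
                      provenance: dict | None = None,
                      strict: bool = True) -> PharmacophoreModel:
    """Validate and build a pharmacophore model from a printed distance matrix.

    The matrix must be symmetric with zero diagonal, the kinds drawn from the
    feature vocabulary, and the distances embeddable in 3-space: the best
    3D embedding must reproduce every entry within 0.5 Angstrom slack
    (printed matrices carry rounding and small geometric inconsistencies).
    With ``strict=False`` a non-embeddable matrix is accepted and the best
    achievable deviation recorded in provenance — needed because one
    literature matrix is printed with a gross triangle-inequality violation.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n) or len(kinds) != n:
        raise PharmacophoreError("labels/kinds/matrix dimensions disagree")
    if n not in (3, 4):
        raise PharmacophoreError("feature count must be 3 or 4")
    if not np.allclose(matrix, matrix.T, atol=1e-6) or np.any(np.diag(matrix) != 0):
        raise PharmacophoreError("matrix must be symmetric with zero diagonal")
    if np.any(matrix < 0):
        raise PharmacophoreError("distances must be nonnegative")
    bad = [k for k in kinds if k not in ("aromatic", "hydrophobic", "hbond_acceptor")]
    if bad:
        raise PharmacophoreError(f"invalid feature kinds: {bad}")
    coords = _embed_distances(matrix)
    realized = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    dev = float(np.max(np.abs(realized - matrix)))
    if dev > EMBED_SLACK and strict:
        raise GeometryError(
            f"distance matrix not embeddable in 3-space (max deviation {dev:.2f} A)")
    prov = dict(provenance or {})
    if dev > EMBED_SLACK:
        prov["embedding_deviation"] = round(dev, 3)
    return PharmacophoreModel(labels=tuple(labels), kinds=tuple(kinds),
                              matrix=matrix, tolerance=float(tolerance),
                              provenance=prov)


# ---------------------------------------------------------------------------
# matching

@dataclass
class MatchResult:
    matched: bool
    assignment: tuple | None  # site indices aligned to model features
    max_deviation: float  # Angstrom (inf when no kind-compatible assignment)
    conformer: int


def _site_distance_ok(sites, order, model, soft: bool):
    pos = np.array([sites[i].position for i in order])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    iu, ju = np.triu_indices(model.n_features, k=1)
    dev = np.abs(d[iu, ju] - model.matrix[iu, ju])
    max_dev = float(dev.max())
    if soft:
        score = float(np.prod(np.exp(-(dev**2) / (2.0 * model.tolerance**2))))
        return score >= 0.5, max_dev
    return max_dev <= model.tolerance, max_dev


def match(molecule: Molecule, model: PharmacophoreModel,
          soft: bool = False) -> MatchResult:
    """Best match of any conformer against the model.

    Exhaustive search over injective, kind-compatible assignments of
    perceived sites to model features, in deterministic order (conformer
    index, then lexicographic assignment).  Reports the assignment with the
    minimal maximum pairwise deviation over all conformers.
    """
    best = MatchResult(False, None, float("inf"), -1)
    for conf_id in range(molecule.n_conformers):
        sites = perceive_features(molecule, conf_id)
        by_kind = {}
        for i, s in enumerate(sites):
            by_kind.setdefault(s.kind, []).append(i)
        # candidate site indices per model feature
        pools = [by_kind.get(k, []) for k in model.kinds]
        if any(not p for p in pools):
            continue
        for order in _injective_assignments(pools):
            ok, dev = _site_distance_ok(sites, order, model, soft)
            if dev < best.max_deviation:
                best = MatchResult(ok, tuple(order), dev, conf_id)
    return best


def _injective_assignments(pools):
    """All injective choices of one site per feature, lexicographic order."""
    n = len(pools)

    def rec(i, used, acc):
        if i == n:
            yield tuple(acc)
            return
        for s in pools[i]:
            if s not in used:
                yield from rec(i + 1, used | {s}, acc + [s])

    yield from rec(0, frozenset(), [])


# ---------------------------------------------------------------------------
# classification statistics

@dataclass
class ConfusionStats:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def mcc(self) -> float:
        return mcc(self)


def mcc(stats: ConfusionStats) -> float:
    """Matthews correlation coefficient; defined as 0 when any marginal
    factor of the denominator is zero."""
    tp, tn, fp, fn = stats.tp, stats.tn, stats.fp, stats.fn
    if min(tp, tn, fp, fn) < 0:
        raise PharmacophoreError("confusion counts must be nonnegative")
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(den)


def classify_dataset(records, model: PharmacophoreModel,
                     active_ic50_max: float = DEFAULT_ACTIVE_IC50_MAX):
    """Confusion statistics of pharmacophore matching vs the activity label.

    ``records``: iterable of (Molecule, ActivityRecord).  Predicted-positive
    = matched; actual-positive = IC50 <= threshold (inclusive).  Records
    without an IC50 are excluded and counted.
    """
    stats = ConfusionStats()
    skipped = 0
    for molecule, rec in records:
        if rec is None or rec.ic50 is None:
            skipped += 1
            continue
        active = rec.ic50 <= active_ic50_max
        predicted = match(molecule, model).matched
        if predicted and active:
            stats.tp += 1
        elif predicted and not active:
            stats.fp += 1
        elif not predicted and active:
            stats.fn += 1
        else:
            stats.tn += 1
    return stats, skipped


# ---------------------------------------------------------------------------
# serialization

def model_to_yaml(model: PharmacophoreModel) -> str:
    import yaml

    return yaml.safe_dump({
        "features": [{"label": l, "kind": k} for l, k in zip(model.labels, model.kinds)],
        "distance_matrix": [[float(x) for x in row] for row in model.matrix],
        "tolerance": model.tolerance,
        "provenance": model.provenance,
    }, sort_keys=False)


def model_from_yaml(text: str) -> PharmacophoreModel:
    import yaml

    d = yaml.safe_load(text)
    return model_from_matrix(
        [f["label"] for f in d["features"]], [f["kind"] for f in d["features"]],
        np.array(d["distance_matrix"]), d.get("tolerance", DEFAULT_TOLERANCE),
        d.get("provenance"))
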