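"""Packaged reference pharmacophore models for hERG inhibition.

Twenty-six literature-reported distance-matrix pharmacophores, built from
thirteen efficiency-selected template drugs docked in the open and closed
conformational states of the hERG channel, each evaluated against a
207-compound inhibitor set (active threshold IC50 <= 40 uM; denominators as
printed: true/false positives out of 177 actives-style columns and 32).
Most models carry two aromatic features, one hydrophobic feature and one
hydrogen-bond acceptor; three are 3-feature models (both haloperidol models
lack the hydrophobic feature, the vesnarinone closed-state model lacks the
acceptor).

Distances are the printed values in Angstrom; confusion counts and the MCC
as printed.  The droperidol closed-state model is the consensus "final"
model used for virtual screening (MCC 0.72).
"""

from __future__ import annotations

import numpy as np

from .pharmacophore import PharmacophoreModel, model_from_matrix

FOUR_LABELS = ("Aro1", "Hyd", "Aro2", "HBA")
FOUR_KINDS = ("aromatic", "hydrophobic", "aromatic", "hbond_acceptor")

# template, state, upper-triangle distances, (TP, TN, FP, FN), printed MCC.
# 4-feature rows: (Aro1-Hyd, Aro1-Aro2, Aro1-HBA, Hyd-Aro2, Hyd-HBA, Aro2-HBA)
# 3-feature rows: explicit labels/kinds with 3 upper-triangle entries.
_ROWS_4F = [
    ("MK-499", "open", (5.8, 6.6, 6.1, 7.7, 6.3, 8.2), (102, 75, 7, 25), 0.70),
    ("MK-499", "closed", (5.3, 6.1, 5.8, 4.7, 6.3, 7.2), (108, 69, 6, 24), 0.71),
    ("E4031", "open", (7.2, 5.1, 8.1, 6.2, 5.6, 6.1), (105, 72, 9, 23), 0.69),
    ("E4031", "closed", (6.3, 5.4, 6.8, 5.7, 4.3, 5.5), (105, 72, 9, 23), 0.69),
    ("Dofetilide", "open", (6.3, 6.6, 7.3, 6.4, 5.2, 8.2), (108, 71, 8, 24), 0.69),
    ("Dofetilide", "closed", (8.2, 5.1, 6.6, 4.6, 6.8, 6.1), (110, 73, 6, 26), 0.70),
    ("Trimethoprim", "open", (4.3, 5.6, 5.3, 4.4, 5.8, 4.4), (99, 78, 9, 23), 0.69),
    ("Trimethoprim", "closed", (4.6, 5.1, 4.3, 3.8, 5.2, 5.1), (105, 72, 7, 25), 0.69),
    ("9-Hydroxy-Risperidone", "open", (4.3, 6.1, 4.4, 4.1, 5.2, 4.4), (112, 66, 12, 20), 0.69),
    ("9-Hydroxy-Risperidone", "closed", (3.6, 5.1, 4.3, 4.2, 5.2, 7.1), (123, 54, 7, 25), 0.69),
    ("Benperidol", "open", (4.6, 5.1, 7.4, 5.5, 4.8, 4.1), (120, 57, 12, 20), 0.66),
    ("Benperidol", "closed", (6.2, 5.4, 6.8, 4.7, 6.2, 4.8), (122, 55, 10, 22), 0.66),
    ("Droperidol", "open", (5.3, 4.2, 4.1, 5.7, 5.8, 6.1), (119, 68, 6, 26), 0.70),
    ("Droperidol", "closed", (4.4, 5.6, 5.8, 6.3, 4.7, 6.0), (119, 68, 6, 24), 0.72),
    ("Norastemizole", "open", (5.5, 5.2, 6.4, 5.1, 3.9, 5.8), (119, 68, 6, 26), 0.70),
    ("Norastemizole", "closed", (3.8, 5.8, 9.0, 3.5, 7.0, 7.4), (121, 56, 7, 25), 0.67),
    ("Vesnarinone", "open", (3.8, 4.5, 4.4, 5.3, 5.5, 7.2), (109, 68, 10, 22), 0.68),
    ("BMLC-1835-4", "open", (4.1, 6.5, 5.7, 5.3, 5.5, 11.5), (120, 57, 24, 8), 0.67),
    ("BMLC-1835-4", "closed", (3.4, 5.8, 3.4, 7.5, 5.7, 11.9), (123, 54, 25, 7), 0.66),
    ("Risperidone", "open", (5.1, 6.7, 8.7, 5.3, 4.5, 5.6), (117, 60, 8, 24), 0.68),
    ("Risperidone", "closed", (4.4, 6.8, 9.0, 4.3, 4.8, 4.5), (120, 57, 24, 8), 0.67),
    ("Glycerol-Nonivamide", "open", (3.4, 4.7, 3.1, 4.4, 4.5, 8.1), (120, 57, 23, 9), 0.67),
    ("Glycerol-Nonivamide", "closed", (3.7, 5.2, 3.1, 5.3, 4.1, 7.6), (122, 55, 22, 10), 0.66),
]

_ROWS_3F = [
    # vesnarinone closed: acceptor feature absent
    ("Vesnarinone", "closed", ("Aro1", "Hyd", "Aro2"),
     ("aromatic", "hydrophobic", "aromatic"), (9.4, 6.0, 4.6), (129, 48, 8, 24), 0.65),
    # haloperidol models: hydrophobic feature absent
    ("Haloperidol", "open", ("Aro1", "Aro2", "HBA"),
     ("aromatic", "aromatic", "hbond_acceptor"), (4.8, 6.7, 8.3), (130, 47, 24, 8), 0.64),
    ("Haloperidol", "closed", ("Aro1", "Aro2", "HBA"),
     ("aromatic", "aromatic", "hbond_acceptor"), (10.1, 6.1, 5.6), (132, 45, 24, 8), 0.66),
]


def _matrix(n, upper):
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = upper
    m[ju, iu] = upper
    return m


def load_reference_models(tolerance: float = 1.0) -> list[dict]:
    """All 26 reference models with their printed classification counts.

    Returns dicts: template, state, model (PharmacophoreModel),
    counts (TP, TN, FP, FN) and reported_mcc.
    """
    out = []
    for template, state, upper, counts, reported in _ROWS_4F:
        model = model_from_matrix(FOUR_LABELS, FOUR_KINDS, _matrix(4, upper),
                                  tolerance,
                                  {"template": template, "channel_state": state},
                                  strict=False)
        out.append({"template": template, "state": state, "model": model,
                    "counts": counts, "reported_mcc": reported})
    for template, state, labels, kinds, upper, counts, reported in _ROWS_3F:
        model = model_from_matrix(labels, kinds, _matrix(3, upper), tolerance,
                                  {"template": template, "channel_state": state},
                                  strict=False)
        out.append({"template": template, "state": state, "model": model,
                    "counts": counts, "reported_mcc": reported})
    return out


def final_model(tolerance: float = 1.0) -> PharmacophoreModel:
    """The selected screening model: droperidol template, closed channel state."""
    for entry in load_reference_models(tolerance):
        if entry["template"] == "Droperidol" and entry["state"] == "closed":
            return entry["model"]
    raise RuntimeError("reference model table corrupted")
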