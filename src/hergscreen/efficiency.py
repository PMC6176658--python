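"""Potency-efficiency metrics and pharmacophore template selection.

LipE = pIC50 - clogP corrects potency for lipophilic bias; LE =
1.37 * pIC50 / HA (kcal/mol per heavy atom, 1.37 = RT ln10 at 298 K) corrects
for size; FQ = LE / LE_scale(HA) removes the residual small-molecule bias of
LE using the published size-scaling curve.  Template compounds for
pharmacophore building are those passing LipE > 4.0, LE > 0.39 kcal/mol/HA
and FQ > 1, ranked by LipE then FQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

RT_LN10 = 1.37  # kcal/mol at 298 K

DEFAULT_LIPE_MIN = 4.0
DEFAULT_LE_MIN = 0.39  # kcal/mol/HA
DEFAULT_FQ_MIN = 1.0


class EfficiencyError(ValueError):
    pass


def pic50(ic50_molar: float) -> float:
    """pIC50 = -log10(IC50 in molar)."""
    if not ic50_molar > 0:
        raise EfficiencyError(f"IC50 must be positive, got {ic50_molar}")
    return -math.log10(ic50_molar)


def lipe(pic50_value: float, clogp: float) -> float:
    return pic50_value - clogp


def ligand_efficiency(pic50_value: float, heavy_atoms: int) -> float:
    if heavy_atoms < 1:
        raise EfficiencyError("heavy atom count must be >= 1")
    return RT_LN10 * pic50_value / heavy_atoms


def le_scale(heavy_atoms: int) -> float:
    """Size-dependent LE scaling curve (maximal-LE fit vs heavy atom count)."""
    ha = float(heavy_atoms)
    return 0.0715 + 7.5328 / ha + 25.7079 / ha**2 - 361.4722 / ha**3


def fit_quality(le: float, heavy_atoms: int) -> float:
    """FQ = LE / LE_scale(HA); the scaling curve is unreliable below 8 heavy
    atoms, which is a domain error."""
    if heavy_atoms < 8:
        raise EfficiencyError("fit quality undefined below 8 heavy atoms")
    return le / le_scale(heavy_atoms)


@dataclass
class EfficiencyProfile:
    compound_id: str
    pic50: float
    clogp: float
    heavy_atoms: int

    @property
    def lipe(self) -> float:
        return lipe(self.pic50, self.clogp)

    @property
    def le(self) -> float:
        return ligand_efficiency(self.pic50, self.heavy_atoms)

    @property
    def fq(self) -> float:
        return fit_quality(self.le, self.heavy_atoms)


def profile(compound_id: str, ic50_molar: float, clogp: float,
            heavy_atoms: int) -> EfficiencyProfile:
    return EfficiencyProfile(compound_id, pic50(ic50_molar), clogp, heavy_atoms)


def select_templates(profiles, lipe_min: float = DEFAULT_LIPE_MIN,
                     le_min: float = DEFAULT_LE_MIN,
                     fq_min: float = DEFAULT_FQ_MIN) -> list[EfficiencyProfile]:
    """Filter by all three thresholds (strict >) and rank by LipE descending,
    ties broken by FQ descending.  Stable under input permutation."""
    kept = [p for p in profiles
            if p.lipe > lipe_min and p.le > le_min and p.fq > fq_min]
    kept.sort(key=lambda p: (-p.lipe, -p.fq, p.compound_id))
    return kept


def profiles_table(profiles, selected=None):
    """Rows for the CSV export: id, pIC50, clogP, HA, LipE, LE, FQ, selected."""
    sel_ids = {p.compound_id for p in (selected or [])}
    return [
        {"id": p.compound_id, "pIC50": p.pic50, "clogP": p.clogp, "HA": p.heavy_atoms,
         "LipE": p.lipe, "LE": p.le, "FQ": p.fq, "selected": p.compound_id in sel_ids}
        for p in profiles
    ]
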