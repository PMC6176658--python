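"""Hill-equation analysis of concentration-block data.

The steady-state dose response of channel block is modelled as

    y = 1 / (1 + ([x] / IC50)^nH)

with y the fraction of current remaining (1 = no block), [x] the drug
concentration, IC50 the half-maximal inhibitory concentration and nH the
Hill coefficient (slope).  Fitting is nonlinear least squares in
(log IC50, log nH) space, which enforces positivity of both parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


class DoseResponseError(ValueError):
    pass


@dataclass
class DoseResponseData:
    compound_id: str
    concentrations: np.ndarray  # molar
    response: np.ndarray  # fraction of current remaining, in [0, 1]
    replicate: np.ndarray | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(self.concentrations <= 0):
            raise DoseResponseError("concentrations must be positive")
        if np.any(self.response < -0.05) or np.any(self.response > 1.05):
            self.warnings.append("responses outside [-0.05, 1.05] clipped")
        self.response = np.clip(self.response, 0.0, 1.0)


def hill(conc, ic50: float, nh: float):
    conc = np.asarray(conc, dtype=float)
    return 1.0 / (1.0 + (conc / ic50) ** nh)


@dataclass
class HillFit:
    ic50: float  # molar
    nh: float
    ic50_se: float
    nh_se: float
    residual_sd: float
    converged: bool
    warnings: list = field(default_factory=list)

    @property
    def pic50(self) -> float:
        return -math.log10(self.ic50)


def hill_fit(data: DoseResponseData, init: tuple[float, float] | None = None,
             weights: np.ndarray | None = None) -> HillFit:
    """Fit the Hill equation by least squares in log-parameter space.

    init defaults to nH = 1 and IC50 = geometric mean of the concentration
    range.  If no concentration brackets y = 0.5 an extrapolation warning is
    attached; a response that increases with concentration yields a
    convergence error (the model only describes inhibitors).
    """
    conc, y = data.concentrations, data.response
    if len(np.unique(conc)) < 3:
        raise DoseResponseError("need at least 3 distinct concentrations")
    if init is None:
        init = (math.sqrt(conc.min() * conc.max()), 1.0)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    def resid(theta):
        ic50, nh = np.exp(theta)
        return w * (hill(conc, ic50, nh) - y)

    sol = least_squares(resid, x0=[math.log(init[0]), math.log(init[1])],
                        method="lm", max_nfev=10000)
    ic50, nh = (float(v) for v in np.exp(sol.x))
    # increasing dose-response: slope of y vs log(conc) positive -> reject
    slope = np.polyfit(np.log(conc), y, 1)[0]
    if slope > 0.05 or not sol.success:
        raise DoseResponseError(
            f"{data.compound_id}: response not consistent with inhibition "
            f"(slope {slope:+.3f} vs log concentration)")

    dof = max(len(y) - 2, 1)
    rsd = float(np.sqrt(np.sum(sol.fun**2) / dof))
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * rsd**2
        se_log = np.sqrt(np.diag(cov))
        ic50_se, nh_se = float(ic50 * se_log[0]), float(nh * se_log[1])
    except np.linalg.LinAlgError:
        ic50_se = nh_se = float("nan")
    fit = HillFit(ic50=ic50, nh=nh, ic50_se=ic50_se, nh_se=nh_se,
                  residual_sd=rsd, converged=bool(sol.success),
                  warnings=list(data.warnings))
    ymin, ymax = hill(conc, ic50, nh).min(), hill(conc, ic50, nh).max()
    if not (ymin <= 0.5 <= ymax):
        fit.warnings.append("IC50 extrapolated: no concentration brackets y=0.5")
    return fit


def percent_block(conc, fit: HillFit):
    """Percentage blockade: 100 * (1 - y(conc))."""
    return 100.0 * (1.0 - hill(conc, fit.ic50, fit.nh))


def log_unit_difference(ic50_a: float, ic50_b: float) -> float:
    """|log10(a/b)| for two IC50s in the same units."""
    if not (ic50_a > 0 and ic50_b > 0):
        raise DoseResponseError("IC50 values must be positive")
    return abs(math.log10(ic50_a / ic50_b))


def prediction_report(predicted: dict, experimental: dict, threshold: float = 1.6):
    """Per-compound log-unit accounting of predicted vs experimental pIC50.

    Both dicts map compound id -> pIC50.  Returns (rows, unmatched_ids);
    each row carries the absolute difference, the raw and 1-d.p. values, and
    an outlier flag for differences beyond ``threshold``.
    """
    rows, unmatched = [], sorted(set(predicted) ^ set(experimental))
    for cid in sorted(set(predicted) & set(experimental)):
        diff = abs(predicted[cid] - experimental[cid])
        rows.append({
            "id": cid, "predicted_pic50": predicted[cid],
            "experimental_pic50": experimental[cid],
            "log_unit_difference": diff,
            "log_unit_difference_1dp": round(diff, 1),
            "outlier": diff > threshold,
        })
    return rows, unmatched
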