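"""PLS regression on correlogram descriptors with cross-validation and
fractional-factorial variable selection.

The regression is PLS1 via NIPALS on column-centred (unscaled) descriptors:
energy-product variables share units, so no autoscaling is applied by
default (a scaling option is recorded per model).  Predictive ability is
summarized by leave-one-out q2 and SDEP; q2 uses the fold-training mean in
its denominator.  Variable selection follows a two-level fractional
factorial design over variable inclusion with ~20% dummy variables: a
variable is dropped when excluding it improves the cross-validated SDEP by
more than the mean absolute dummy effect.  The applicability domain is the
min/max box of the first two principal-component scores of the training
descriptors, expanded by 10%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class QsarError(ValueError):
    pass


@dataclass
class PLSModel:
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    coef: np.ndarray  # (p,) collapsed regression vector
    r2_per_lv: np.ndarray  # (A,)
    labels: list = field(default_factory=list)
    scaled: bool = False
    x_scale: np.ndarray | None = None
    q2_per_lv: np.ndarray | None = None
    sdep_per_lv: np.ndarray | None = None

    @property
    def r2(self) -> float:
        return float(self.r2_per_lv[self.n_lv - 1])

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x_new, dtype=float)) - self.x_mean
        if self.scaled and self.x_scale is not None:
            x = x / self.x_scale
        return self.y_mean + x @ self.coef

    def to_json(self) -> str:
        d = {
            "format": "hergscreen-pls/1",
            "n_lv": self.n_lv,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "coef": self.coef.tolist(),
            "r2_per_lv": self.r2_per_lv.tolist(),
            "labels": [list(l) if isinstance(l, tuple) else l for l in self.labels],
            "scaled": self.scaled,
        }
        if self.q2_per_lv is not None:
            d["q2_per_lv"] = self.q2_per_lv.tolist()
            d["sdep_per_lv"] = self.sdep_per_lv.tolist()
        return json.dumps(d, indent=1)


def fit_pls(X, y, n_lv: int, labels=None, scale: bool = False) -> PLSModel:
    """NIPALS PLS1.  Deterministic; per-LV training r2 reported.

    At full column rank the collapsed coefficient vector reproduces ordinary
    least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise QsarError("X and y row counts differ")
    if np.ptp(y) == 0:
        raise QsarError("constant response: degenerate y")
    if n_lv > min(n - 1, p):
        raise QsarError(f"n_lv={n_lv} exceeds min(rows-1, columns)={min(n - 1, p)}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    x_scale = None
    if scale:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        Xc = Xc / x_scale
    yc = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    Xr, yr = Xc.copy(), yc.copy()
    r2 = np.zeros(n_lv)
    ss_tot = float(yc @ yc)
    for a in range(n_lv):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            # response fully deflated: pad remaining LVs with zeros
            r2[a:] = r2[a - 1] if a else 0.0
            W, P, Q, T = W[:, :a], P[:, :a], Q[:a], T[:, :a]
            n_lv = a
            r2 = r2[: max(a, 1)]
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        pvec = Xr.T @ t / tt
        q = float(yr @ t) / tt
        Xr = Xr - np.outer(t, pvec)
        yr = yr - q * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, pvec, q, t
        r2[a] = 1.0 - float(yr @ yr) / ss_tot
    if n_lv == 0:
        raise QsarError("no latent variables could be extracted")

    coef = W @ np.linalg.solve(P.T @ W, Q)
    if scale:
        coef = coef / x_scale
    return PLSModel(n_lv=n_lv, x_mean=x_mean, y_mean=y_mean, weights=W,
                    x_loadings=P, y_loadings=Q, coef=coef, r2_per_lv=r2,
                    labels=list(labels) if labels is not None else [], scaled=scale,
                    x_scale=x_scale)


def loo_stats(X, y, n_lv: int, scale: bool = False):
    """Leave-one-out q2 and SDEP per latent variable.

    q2 = 1 - PRESS / SS_tot with SS_tot taken about each fold's training
    mean (the cross-validation convention matching SDEP); SDEP =
    sqrt(PRESS / N).  Every fold refits centring (and scaling, if used).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise QsarError("need at least 3 rows for LOO")
    a_max = min(n_lv, n - 2, X.shape[1])
    press = np.zeros(a_max)
    ss = np.zeros(a_max)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_pls(X[mask], y[mask], a_max, scale=scale)
        for a in range(a_max):
            if a < model.n_lv:
                coef_a = model.weights[:, : a + 1] @ np.linalg.solve(
                    model.x_loadings[:, : a + 1].T @ model.weights[:, : a + 1],
                    model.y_loadings[: a + 1],
                )
                if model.scaled:
                    coef_a = coef_a / model.x_scale
                pred = model.y_mean + (X[i] - model.x_mean) @ coef_a
            else:
                pred = model.y_mean
            press[a] += (y[i] - pred) ** 2
            ss[a] += (y[i] - model.y_mean) ** 2
    q2 = 1.0 - press / ss
    sdep = np.sqrt(press / n)
    return q2, sdep


@dataclass
class FFDResult:
    cycles: list  # per-cycle dict: mask, q2, r2, sdep, dummy_threshold
    mask: np.ndarray  # final surviving-variable mask

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


def ffd_select(X, y, n_lv: int = 2, cycles: int = 2, dummy_frac: float = 0.2,
               seed: int = 0, scale: bool = False,
               keep_uncertain: bool = False) -> FFDResult:
    """Fractional-factorial variable selection.

    Per cycle: a balanced two-level design over variable inclusion (each row
    a random near-half subset) augmented with dummy variables; per design row
    a PLS model is LOO-validated on the included columns; each variable's
    effect is mean(SDEP | excluded) - mean(SDEP | included), so a positive
    effect means the variable helps predictivity.  By default a variable is
    kept only when its effect exceeds the mean absolute dummy effect
    (variables indistinguishable from dummies are discarded along with
    harmful ones); with ``keep_uncertain=True`` only variables whose
    exclusion *improves* SDEP beyond the dummy level are removed.  In both
    modes, variables whose univariate |correlation| with y exceeds the 95th
    percentile of seeded noise-column correlations are never removed
    (guard).  Deterministic per seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    mask = np.ones(p, dtype=bool)

    # guard: univariate correlation floor from seeded noise columns
    yc = y - y.mean()
    ysd = yc.std()
    noise = rng.standard_normal((len(y), max(20, int(np.ceil(dummy_frac * p)))))
    noise_corr = np.abs((noise - noise.mean(0)).T @ yc) / (
        noise.std(0, ddof=0) * ysd * len(y) + 1e-30)
    guard_thresh = np.quantile(noise_corr, 0.95)
    xsd = X.std(axis=0, ddof=0)
    uni_corr = np.zeros(p)
    nz = xsd > 0
    uni_corr[nz] = np.abs((X[:, nz] - X[:, nz].mean(0)).T @ yc) / (xsd[nz] * ysd * len(y))
    protected = uni_corr > guard_thresh

    cycles_out = []
    for _cycle in range(cycles):
        active = np.nonzero(mask)[0]
        v = len(active)
        if v < 2:
            break
        n_dummy = max(2, int(np.ceil(dummy_frac * v)))
        n_rows = 2 * (v + n_dummy)
        # balanced +/-1 design: each column has equal numbers of + and -
        design = np.ones((n_rows, v + n_dummy), dtype=int)
        half = n_rows // 2
        for c in range(v + n_dummy):
            col = np.array([1] * half + [-1] * (n_rows - half))
            rng.shuffle(col)
            design[:, c] = col
        sdep_rows = np.full(n_rows, np.nan)
        for r in range(n_rows):
            inc = active[design[r, :v] == 1]
            if len(inc) < max(2, n_lv):
                continue
            a = min(n_lv, len(inc), len(y) - 2)
            _, sdep = loo_stats(X[:, inc], y, a, scale=scale)
            sdep_rows[r] = sdep[a - 1]
        ok = np.isfinite(sdep_rows)
        effects = np.zeros(v + n_dummy)
        for c in range(v + n_dummy):
            exc = ok & (design[:, c] == -1)
            inc = ok & (design[:, c] == 1)
            if exc.any() and inc.any():
                effects[c] = sdep_rows[exc].mean() - sdep_rows[inc].mean()
        dummy_thresh = float(np.mean(np.abs(effects[v:])))
        if keep_uncertain:
            remove = (effects[:v] < -dummy_thresh) & ~protected[active]
        else:
            remove = (effects[:v] <= dummy_thresh) & ~protected[active]
        new_mask = mask.copy()
        new_mask[active[remove]] = False
        if not new_mask.any():
            break  # keep previous cycle's mask
        mask = new_mask
        a = min(n_lv, int(mask.sum()), len(y) - 2)
        q2, sdep = loo_stats(X[:, mask], y, a, scale=scale)
        model = fit_pls(X[:, mask], y, a, scale=scale)
        cycles_out.append({
            "mask": mask.copy(), "n_kept": int(mask.sum()),
            "q2": float(q2[a - 1]), "r2": model.r2, "sdep": float(sdep[a - 1]),
            "dummy_threshold": dummy_thresh,
        })
    return FFDResult(cycles=cycles_out, mask=mask)


# ---------------------------------------------------------------------------
# applicability domain

@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray  # (k, p)
    explained_variance_ratio: np.ndarray
    score_min: np.ndarray  # (k,) training score range
    score_max: np.ndarray
    expansion: float = 0.10

    def scores(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) @ self.components.T

    def in_domain(self, X) -> np.ndarray:
        """In-domain when the first-two-component scores fall inside the
        training min/max box expanded by ``expansion``."""
        s = self.scores(X)[:, :2]
        span = self.score_max[:2] - self.score_min[:2]
        lo = self.score_min[:2] - self.expansion * span
        hi = self.score_max[:2] + self.expansion * span
        return np.all((s >= lo) & (s <= hi), axis=1)


def pca_domain(X_train, n_components: int = 5) -> PCAModel:
    from sklearn.decomposition import PCA

    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] < 3:
        raise QsarError("need at least 3 rows for the PCA domain")
    k = min(n_components, X_train.shape[0] - 1, X_train.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X_train)
    return PCAModel(mean=pca.mean_, components=pca.components_,
                    explained_variance_ratio=pca.explained_variance_ratio_,
                    score_min=scores.min(axis=0), score_max=scores.max(axis=0))


# ---------------------------------------------------------------------------
# prediction with label alignment

def align_columns(labels_model: list, labels_new: list, X_new: np.ndarray):
    """Map descriptor columns by label; missing model variables are zero,
    extra new variables are dropped.  Returns (X_aligned, n_overlap)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    index = {tuple(l) if isinstance(l, (list, tuple)) else l: i
             for i, l in enumerate(labels_new)}
    out = np.zeros((X_new.shape[0], len(labels_model)))
    overlap = 0
    for j, lab in enumerate(labels_model):
        key = tuple(lab) if isinstance(lab, (list, tuple)) else lab
        if key in index:
            out[:, j] = X_new[:, index[key]]
            overlap += 1
    return out, overlap


def predict(model: PLSModel, X_new, labels_new=None, domain: PCAModel | None = None):
    """Predict pIC50 for new descriptor rows, with optional in-domain flags.

    When ``labels_new`` is given, columns are aligned by label (missing -> 0,
    extra -> dropped); zero overlap is an error.
    """
    if labels_new is not None:
        X_aligned, overlap = align_columns(model.labels, labels_new, X_new)
        if overlap == 0:
            raise QsarError("no overlapping descriptor variables for prediction")
    else:
        X_aligned = np.atleast_2d(np.asarray(X_new, dtype=float))
    y_hat = model.predict(X_aligned)
    flags = domain.in_domain(X_aligned) if domain is not None else None
    return y_hat, flags
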