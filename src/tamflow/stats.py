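"""Outcome classification, factor analysis, and stepwise regression.

Clinical response is classified from the percent YBOCS reduction
(>= 50% best, < 10% none — worsening included —, otherwise moderate).
The factor analysis is an unrotated principal component analysis of the
column-standardized region-activation matrix (correlation-matrix PCA;
a varimax rotation is available by flag since statistics packages
differ in their defaults), retaining components with eigenvalue above a
threshold (default 2).  Stepwise linear regression then selects factor
scores predicting the YBOCS change by forward entry / backward removal
on partial-F p-values (0.05 / 0.10 defaults), reporting standardized
coefficients and the adjusted R^2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["OutcomeRecord", "FactorModel", "StepwiseModel", "classify_response",
           "factor_analysis", "stepwise_regression", "loading_report",
           "printed_statistics_report"]

RESPONSE_BEST_MIN_PCT = 50.0
RESPONSE_NONE_MAX_PCT = 10.0


@dataclass(frozen=True)
class OutcomeRecord:
    patient_id: str
    ybocs_change_pct: float  # positive = reduction = improvement

    @property
    def response_class(self) -> str:
        return classify_response(self.ybocs_change_pct)


def classify_response(ybocs_change_pct: float) -> str:
    """'best' (>= 50% reduction), 'none' (< 10%, incl. worsening),
    otherwise 'moderate'; partitions the real line."""
    y = float(ybocs_change_pct)
    if not np.isfinite(y):
        raise ValueError("ybocs_change_pct must be finite")
    if y >= RESPONSE_BEST_MIN_PCT:
        return "best"
    if y < RESPONSE_NONE_MAX_PCT:
        return "none"
    return "moderate"


@dataclass
class FactorModel:
    eigenvalues: np.ndarray  # descending, all components
    n_retained: int
    loadings: pd.DataFrame  # variable x factor, retained only
    scores: pd.DataFrame  # patient x factor, retained only
    cumulative_variance_pct: float
    eigen_threshold: float
    rotated: bool = False


def _varimax_criterion(L: np.ndarray) -> float:
    return float(((L**2 - (L**2).mean(axis=0)) ** 2).sum())


def _varimax(loadings: np.ndarray, tol: float = 1e-12, max_iter: int = 2000):
    """Varimax rotation by the SVD fixed-point iteration.

    The identity start can sit on a saddle (notably for two factors), so
    several deterministic orthogonal starts are tried and the rotation
    with the largest varimax criterion wins.
    """
    p, k = loadings.shape
    rng = np.random.default_rng(12345)
    starts = [np.eye(k)]
    for _ in range(3):
        q, _ = np.linalg.qr(rng.normal(size=(k, k)))
        starts.append(q)
    best = loadings
    best_crit = _varimax_criterion(loadings)
    for R0 in starts:
        R = R0.copy()
        var = 0.0
        for _ in range(max_iter):
            L = loadings @ R
            u, s, vt = np.linalg.svd(
                loadings.T @ (L**3 - (L * (L**2).sum(axis=0)) / p))
            R = u @ vt
            new_var = s.sum()
            if new_var < var * (1 + tol):
                break
            var = new_var
        cand = loadings @ R
        crit = _varimax_criterion(cand)
        if crit > best_crit:
            best, best_crit = cand, crit
    return best


def factor_analysis(matrix: pd.DataFrame, eigen_threshold: float = 2.0,
                    rotate: bool = False) -> FactorModel:
    """Correlation-matrix PCA with eigenvalue-threshold retention.

    Loadings are eigenvector * sqrt(eigenvalue) (correlations between
    variables and components); scores are the standardized data
    projected on the retained eigenvectors.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    sd = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if len(constant):
        names = [matrix.columns[i] for i in constant]
        raise ValueError(f"constant column(s) not admissible: {names}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.maximum(evals, 0.0)

    k = int((evals > eigen_threshold).sum())
    max_k = n - 1
    if k > max_k:
        warnings.warn(f"retained factors truncated from {k} to {max_k} "
                      f"(only {n} observations)", stacklevel=2)
        k = max_k
    if k == 0:
        raise ValueError(f"no eigenvalue exceeds {eigen_threshold}")
    load = evecs[:, :k] * np.sqrt(evals[:k])
    # standardized factor scores F satisfy Z ~ F @ load.T
    scr = Z @ evecs[:, :k] / np.sqrt(np.maximum(evals[:k], 1e-12))
    if rotate:
        rotated = _varimax(load)
        # orthogonal rotation matrix relating the two loading sets
        R, _, _, _ = np.linalg.lstsq(load, rotated, rcond=None)
        load = rotated
        scr = scr @ R
    factor_names = [f"F{i+1}" for i in range(k)]
    loadings = pd.DataFrame(load, index=matrix.columns, columns=factor_names)
    scores = pd.DataFrame(scr, index=matrix.index, columns=factor_names)
    cum = 100.0 * evals[:k].sum() / evals.sum()
    return FactorModel(evals, k, loadings, scores, float(cum),
                       eigen_threshold, rotated=rotate)


@dataclass
class StepwiseModel:
    selected: list
    coefficients: dict  # factor -> raw coefficient
    standardized_beta: dict  # factor -> standardized coefficient
    adjusted_r2: float
    p_enter: float
    p_remove: float
    selection_path: list = field(default_factory=list)


def _fit(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(scores: pd.DataFrame, outcomes,
                        p_enter: float = 0.05, p_remove: float = 0.10) -> StepwiseModel:
    """Forward-entry / backward-removal selection on partial-F p-values.

    Candidate order cannot influence the result: at each step the
    candidate with the smallest entry p-value is taken, ties broken by
    the larger absolute correlation with the outcome (then by column
    name for full determinism).
    """
    y = np.asarray(outcomes, dtype=float)
    if len(y) != len(scores):
        raise ValueError("outcome length must match score rows")
    if np.std(y) == 0:
        raise ValueError("outcome has zero variance")
    if len(y) <= len(scores.columns):
        warnings.warn("fewer observations than candidate predictors + 1",
                      stacklevel=2)
    cols = list(scores.columns)
    corr_abs = {c: abs(np.corrcoef(scores[c], y)[0, 1]) for c in cols}
    selected: list = []
    path = []
    changed = True
    while changed:
        changed = False
        # forward step
        candidates = [c for c in cols if c not in selected]
        best = None
        for c in candidates:
            X = np.asarray(scores[selected + [c]], dtype=float)
            res = _fit(y, X)
            pval = res.pvalues[-1]
            key = (pval, -corr_abs[c], c)
            if pval < p_enter and (best is None or key < best[0]):
                best = (key, c)
        if best is not None:
            selected.append(best[1])
            path.append(("enter", best[1], float(best[0][0])))
            changed = True
        # backward step
        while len(selected) > 1:
            X = np.asarray(scores[selected], dtype=float)
            res = _fit(y, X)
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                removed = selected.pop(worst)
                path.append(("remove", removed, float(pvals[worst])))
                changed = True
            else:
                break

    if selected:
        X = np.asarray(scores[selected], dtype=float)
        res = _fit(y, X)
        coefs = {c: float(res.params[i + 1]) for i, c in enumerate(selected)}
        sd_y = np.std(y, ddof=1)
        betas = {c: coefs[c] * np.std(scores[c], ddof=1) / sd_y for c in selected}
        adj = float(res.rsquared_adj)
    else:
        coefs, betas, adj = {}, {}, 0.0
    return StepwiseModel(selected, coefs, betas, adj, p_enter, p_remove, path)


def loading_report(model: FactorModel, threshold: float = 0.9) -> dict:
    """Per retained factor, the variables with |loading| > threshold."""
    out = {}
    for f in model.loadings.columns:
        col = model.loadings[f]
        out[f] = list(col.index[np.abs(col) > threshold])
    return out


def printed_statistics_report(activation_matrix: pd.DataFrame,
                              ybocs_changes, eigen_threshold: float = 2.0,
                              p_enter: float = 0.05, p_remove: float = 0.10) -> dict:
    """Full factor-then-stepwise summary for a cohort activation table.

    Returns retained factor count, cumulative explained variance (%),
    the stepwise adjusted R^2 and the standardized Betas of the selected
    factors (sorted by |Beta| descending).
    """
    fm = factor_analysis(activation_matrix, eigen_threshold=eigen_threshold)
    sw = stepwise_regression(fm.scores, ybocs_changes,
                             p_enter=p_enter, p_remove=p_remove)
    betas = sorted(sw.standardized_beta.values(), key=abs, reverse=True)
    return {
        "n_factors": fm.n_retained,
        "cumulative_variance_pct": fm.cumulative_variance_pct,
        "adjusted_r2": sw.adjusted_r2,
        "standardized_betas": betas,
        "selected_factors": sw.selected,
        "factor_model": fm,
        "stepwise_model": sw,
    }
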