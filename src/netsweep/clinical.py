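"""Treatment-response labeling, correlation and prediction models.

Subjects are labeled responders when their HAMD-17 score falls by at
least 50% from pre- to post-treatment. Network-topology indices are
related to symptom change by partial correlation controlling for age and
sex, and screened predictors enter a forward likelihood-ratio (LR)
binary logistic regression; the fitted model's discrimination is
characterized by an ROC curve with a Youden-optimal operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "CLINICAL_COLUMNS",
    "LogisticModel",
    "PartialCorrelation",
    "RocCurve",
    "SeparationError",
    "forward_lr_logistic",
    "label_responders",
    "partial_correlation",
    "roc_analysis",
]

CLINICAL_COLUMNS = [
    "subject_id", "group", "age", "sex", "hamd17_pre", "hamd17_post",
    "hama_pre", "hama_post",
]


def label_responders(table: pd.DataFrame) -> pd.DataFrame:
    """Derive HAMD-17 reduction rates and responder labels.

    reduction_rate = (pre - post) / pre; responder iff the rate is at
    least 0.50 (the boundary counts as response). A post score above pre
    is allowed and yields a negative rate (non-responder).
    """
    if (table["hamd17_pre"] <= 0).any():
        bad = table.loc[table["hamd17_pre"] <= 0, "subject_id"].tolist()
        raise ValueError(f"non-positive pre-treatment HAMD-17: {bad}")
    out = table.copy()
    out["reduction_rate"] = (
        (out["hamd17_pre"] - out["hamd17_post"]) / out["hamd17_pre"])
    out["responder"] = out["reduction_rate"] >= 0.50
    return out


@dataclass
class PartialCorrelation:
    """Partial Pearson correlation after residualizing on covariates."""

    r_partial: float
    p: float
    df: int
    covariate_names: list[str] = field(default_factory=list)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> PartialCorrelation:
    """Correlation of x and y controlling for covariates.

    Both variables are residualized on the covariates (with intercept)
    by least squares; the partial r is the Pearson correlation of the
    residuals, with a two-tailed p from t = r * sqrt(df / (1 - r^2)),
    df = n - 2 - n_covariates. With no covariates this is the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    names: list[str] = []
    if covariates is None:
        z = np.empty((x.size, 0))
    else:
        if isinstance(covariates, pd.DataFrame):
            names = list(covariates.columns)
            z = covariates.to_numpy(dtype=float)
        else:
            z = np.atleast_2d(np.asarray(covariates, dtype=float))
            if z.shape[0] != x.size:
                z = z.T
            names = [f"cov{i}" for i in range(z.shape[1])]
    n, k = x.size, z.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > n_covariates + 3 ({n} vs {k})")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    sx, sy = rx.std(), ry.std()
    df = n - 2 - k
    if sx < 1e-12 or sy < 1e-12:
        return PartialCorrelation(0.0, 1.0, df, names)
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    if abs(r) >= 1.0:
        return PartialCorrelation(r, 0.0, df, names)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PartialCorrelation(r, float(p), df, names)


# ---------------------------------------------------------------------------
# logistic regression (maximum likelihood by IRLS) and forward-LR selection

class SeparationError(RuntimeError):
    """Raised when a feature perfectly separates the two classes."""


def _log_likelihood(design: np.ndarray, y: np.ndarray,
                    beta: np.ndarray) -> float:
    eta = design @ beta
    # numerically stable: -log(1 + exp(-eta)) piecewise
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_logistic(
    design: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    feature_names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """IRLS maximum-likelihood fit; returns (beta, cov_beta, loglik).

    Newton steps with step halving; convergence when the log-likelihood
    improves by less than ``tol``. Diverging coefficients with step
    halving exhausted are reported as perfect separation, naming the
    offending feature.
    """
    n, p = design.shape
    beta = np.zeros(p)
    ll = _log_likelihood(design, y, beta)
    for _ in range(max_iter):
        mu = expit(design @ beta)
        w = mu * (1.0 - mu)
        grad = design.T @ (y - mu)
        hess = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}")
        # step halving until the likelihood does not decrease
        scale, ll_new = 1.0, -np.inf
        for _ in range(30):
            ll_new = _log_likelihood(design, y, beta + scale * step)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        else:
            _raise_separation(beta, feature_names)
        beta = beta + scale * step
        if np.abs(beta).max() > 30.0:
            _raise_separation(beta, feature_names)
        if ll_new - ll < tol:
            ll = ll_new
            break
        ll = ll_new
    mu = expit(design @ beta)
    w = mu * (1.0 - mu)
    hess = design.T @ (design * w[:, None])
    cov = np.linalg.pinv(hess)
    return beta, cov, ll


def _raise_separation(beta: np.ndarray, names: list[str] | None):
    idx = int(np.argmax(np.abs(beta[1:]))) if beta.size > 1 else 0
    name = names[idx] if names else f"feature {idx}"
    raise SeparationError(
        f"perfect separation: coefficient of {name} diverges")


@dataclass
class LogisticModel:
    """Forward-LR-selected binary logistic regression model."""

    selected_predictors: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    odds_ratios: dict[str, tuple[float, float, float]]  # OR, lo, hi
    p_values: dict[str, float]  # Wald two-tailed
    log_likelihood: float
    selection_trace: list[dict]

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(features), self.coefficients["intercept"])
        for name in self.selected_predictors:
            eta = eta + self.coefficients[name] * \
                features[name].to_numpy(dtype=float)
        return expit(eta)


def forward_lr_logistic(
    features: pd.DataFrame,
    labels: np.ndarray,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    standardize: bool = True,
) -> LogisticModel:
    """Forward likelihood-ratio stepwise binary logistic regression.

    At each step the candidate whose likelihood-ratio chi-square
    (2 * delta log-likelihood vs the current model, df = 1) has the
    smallest p < ``entry_p`` enters; after every entry, any included
    variable whose removal LR p exceeds ``removal_p`` leaves. Selection
    stops when no candidate qualifies. Coefficients are reported on the
    original feature scale even when ``standardize`` is set (scaling is
    internal, for IRLS conditioning only).
    """
    y = np.asarray(labels).astype(float)
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(
            np.asarray(features, dtype=float),
            columns=[f"x{i}" for i in range(np.asarray(features).shape[1])])
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    x = features.to_numpy(dtype=float)
    mu_ = x.mean(axis=0)
    sd_ = x.std(axis=0)
    sd_ = np.where(sd_ > 0, sd_, 1.0)
    xs = (x - mu_) / sd_ if standardize else x
    names = list(features.columns)
    n = x.shape[0]

    def fit(cols: list[int]):
        design = np.column_stack([np.ones(n), xs[:, cols]])
        return _fit_logistic(design, y,
                             feature_names=[names[c] for c in cols])

    included: list[int] = []
    _, _, ll_current = fit(included)
    trace: list[dict] = []
    while True:
        # entry scan
        best = None
        for j in range(len(names)):
            if j in included:
                continue
            try:
                _, _, ll_j = fit(included + [j])
            except SeparationError:
                raise
            lr = max(2.0 * (ll_j - ll_current), 0.0)
            p = stats.chi2.sf(lr, df=1)
            if p < entry_p and (best is None or p < best[1]):
                best = (j, p, lr, ll_j)
        if best is None:
            break
        j, p, lr, ll_current = best[0], best[1], best[2], best[3]
        included.append(j)
        trace.append({"step": len(trace) + 1, "action": "enter",
                      "variable": names[j], "lr_chi2": lr, "p": p})
        # removal scan
        changed = True
        while changed and len(included) > 1:
            changed = False
            for j in list(included):
                rest = [c for c in included if c != j]
                _, _, ll_rest = fit(rest)
                lr = max(2.0 * (ll_current - ll_rest), 0.0)
                p = stats.chi2.sf(lr, df=1)
                if p > removal_p:
                    included.remove(j)
                    ll_current = ll_rest
                    trace.append({"step": len(trace) + 1, "action": "remove",
                                  "variable": names[j], "lr_chi2": lr,
                                  "p": p})
                    changed = True
                    break
    beta_s, cov_s, ll = fit(included)
    # map standardized coefficients back to the original scale
    sel_names = [names[c] for c in included]
    if standardize:
        slopes = beta_s[1:] / sd_[included]
        intercept = beta_s[0] - float(np.sum(beta_s[1:] * mu_[included]
                                             / sd_[included]))
        se_slopes = np.sqrt(np.diag(cov_s)[1:]) / sd_[included]
    else:
        slopes = beta_s[1:]
        intercept = beta_s[0]
        se_slopes = np.sqrt(np.diag(cov_s)[1:])
    coeffs = {"intercept": float(intercept)}
    ors: dict[str, tuple[float, float, float]] = {}
    pvals: dict[str, float] = {}
    zcrit = stats.norm.ppf(0.975)
    for name, b, se in zip(sel_names, slopes, se_slopes):
        coeffs[name] = float(b)
        ors[name] = (float(np.exp(b)), float(np.exp(b - zcrit * se)),
                     float(np.exp(b + zcrit * se)))
        z = b / se if se > 0 else np.inf
        pvals[name] = float(2.0 * stats.norm.sf(abs(z)))
    return LogisticModel(sel_names, coeffs, ors, pvals, float(ll), trace)


# ---------------------------------------------------------------------------
# ROC

@dataclass
class RocCurve:
    """ROC curve with trapezoidal AUC and Youden-optimal operating point."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    operating_point: tuple[float, float]  # (sensitivity, specificity)


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC over all distinct score thresholds (predict positive at
    score >= threshold).

    AUC by trapezoid over (1 - specificity, sensitivity). The operating
    point maximizes Youden's J = sensitivity + specificity - 1, ties
    broken toward higher specificity. Constant scores degenerate to the
    single point (1, 0) and an AUC of 0.5 by the chance-diagonal
    convention.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    cuts = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.empty(cuts.size)
    spec = np.empty(cuts.size)
    for i, t in enumerate(cuts):
        pred = scores >= t
        sens[i] = (pred & y).sum() / n_pos
        spec[i] = (~pred & ~y).sum() / n_neg
    auc = float(np.trapezoid(sens, 1.0 - spec))
    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    best = candidates[np.argmax(spec[candidates])]
    return RocCurve(cuts, sens, spec, auc,
                    (float(sens[best]), float(spec[best])))
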