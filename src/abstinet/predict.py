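"""Prediction of abstinent status: PLS1 regression and KNN with
time-series LIME importances.

The imbalanced outcome (roughly one abstinent user in seven) and the
strongly correlated predictors motivate two complementary models:

* univariate partial least squares (PLS1) on standardized predictors,
  with the component count chosen by tenfold cross-validated AUC and
  per-predictor standard errors obtained through a pseudo-inverse of the
  predictor cross-product (the design is rank-deficient in the PLS
  score space, so these are approximate by construction);
* a K-nearest-neighbour classifier on the 144-point concatenated
  monthly series (4 features x 36 months, feature-major), explained by a
  LIME-style local surrogate: mask-and-predict perturbations with an
  exponential distance kernel and a ridge surrogate, averaged over
  reference points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Ridge
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .features import FEATURES, N_MONTHS

Z95 = 1.959963984540054


# --------------------------------------------------------------------- AUC


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based area under the ROC curve with midranks for ties.

    Identical to the Mann-Whitney U statistic scaled by ``n1 * n0``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("auc needs both classes present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


# --------------------------------------------------------------------- PLS


@dataclass
class PLSModel:
    """Fitted PLS1 model: coefficients, odds ratios and diagnostics."""

    n_components: int
    feature_names: list[str]
    beta: np.ndarray           # standardized coefficients
    se: np.ndarray
    odds_ratio: np.ndarray     # exp(beta)
    ci_low: np.ndarray
    ci_high: np.ndarray
    t: np.ndarray
    p: np.ndarray
    auc: float
    r_squared: float
    dropped: list[str]

    def summary(self) -> pd.DataFrame:
        """Table mirroring the standard reporting layout."""
        return pd.DataFrame(
            {
                "variable": self.feature_names,
                "beta": self.beta,
                "OR": self.odds_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "t": self.t,
                "p": self.p,
            }
        )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Xs = np.zeros_like(X, dtype=float)
    Xs[:, keep] = (X[:, keep] - mean[keep]) / sd[keep]
    return Xs, keep


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    feature_names: Optional[Sequence[str]] = None,
    scale: bool = True,
) -> PLSModel:
    """Fit a PLS1 regression of a binary outcome on (standardized) X.

    Coefficients are reported on the standardized-predictor scale;
    adjusted odds ratios are ``exp(beta)`` with normal-theory 95%
    intervals from pseudo-inverse standard errors; the training AUC of
    the fitted scores and the coefficient of determination are attached.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
    if scale:
        Xs, keep = _standardize(X)
    else:
        Xs, keep = X.astype(float), np.std(X, axis=0) > 0
    dropped = [names[j] for j in range(p) if not keep[j]]
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}")
    Xk = Xs[:, keep]
    names_k = [names[j] for j in range(p) if keep[j]]
    n_components = min(n_components, Xk.shape[1], n - 1)
    if n_components < 1:
        raise ValueError("need at least one usable component")

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xk, y)
    beta = pls.coef_.ravel()
    fitted = pls.predict(Xk).ravel()
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0

    # pseudo-inverse standard errors: the PLS solution lives in a
    # c-dimensional score space, so X'X is treated by its pseudo-inverse
    dof = max(1, n - n_components - 1)
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.pinv(Xk.T @ Xk)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    return PLSModel(
        n_components=n_components,
        feature_names=names_k,
        beta=beta,
        se=se,
        odds_ratio=np.exp(beta),
        ci_low=np.exp(beta - Z95 * se),
        ci_high=np.exp(beta + Z95 * se),
        t=tvals,
        p=pvals,
        auc=auc(fitted, y.astype(int)),
        r_squared=r2,
        dropped=dropped,
    )


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    max_components: int = 40,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Component count maximising mean out-of-fold AUC (ties -> fewer).

    Returns the chosen count and the mean CV-AUC curve over component
    counts 1..c_max.  The fold count is reduced with a warning when the
    minority class is too small for the requested folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    Xs, keep = _standardize(X)
    Xk = Xs[:, keep]
    n = len(y)
    minority = int(min((y == 1).sum(), (y == 0).sum()))
    if minority < folds:
        warnings.warn(
            f"minority class of {minority} too small for {folds} folds; reducing"
        )
        folds = max(2, minority)
    c_max = int(min(max_components, Xk.shape[1], n - n // folds - 1))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(Xk, y))
    curve = np.zeros(c_max)
    for c in range(1, c_max + 1):
        fold_auc = []
        for train, test in splits:
            pls = PLSRegression(n_components=c, scale=False)
            pls.fit(Xk[train], y[train].astype(float))
            pred = pls.predict(Xk[test]).ravel()
            if len(np.unique(y[test])) < 2:
                continue
            fold_auc.append(auc(pred, y[test]))
        curve[c - 1] = np.mean(fold_auc) if fold_auc else np.nan
    best = int(np.nanargmax(curve)) + 1  # argmax takes the first (fewest) on ties
    return best, curve


# --------------------------------------------------------------- KNN + LIME


@dataclass
class LimeImportance:
    """Signed per-(feature, month) importances of the KNN classifier."""

    values: np.ndarray  # shape (4, 36)
    auc: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fi, feat in enumerate(FEATURES):
            for m in range(N_MONTHS):
                rows.append(
                    {"feature": feat, "month": m + 1, "importance": self.values[fi, m]}
                )
        return pd.DataFrame(rows)


def knn_lime_importance(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    n_perturb: int = 1000,
    n_refs: Optional[int] = None,
    kernel_width: Optional[float] = None,
) -> LimeImportance:
    """LIME-style importances of a KNN fit to the 144-point series.

    For each reference user, ``n_perturb`` binary masks blank random
    entries of the standardized 144-vector back to the training mean
    (zero); the KNN's predicted abstinence probability is regressed on
    the masks with a ridge surrogate, weighted by an exponential kernel
    on Euclidean mask distance.  Signed coefficients are averaged over
    reference users.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n, p = X.shape
    if p != len(FEATURES) * N_MONTHS:
        raise ValueError(f"expected {len(FEATURES) * N_MONTHS} columns, got {p}")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of users n={n}")
    Xs, keep = _standardize(X)
    if not keep.any():
        return LimeImportance(values=np.zeros((len(FEATURES), N_MONTHS)), auc=0.5)

    knn = KNeighborsClassifier(n_neighbors=k)
    knn.fit(Xs, y)
    prob = knn.predict_proba(Xs)[:, 1]
    model_auc = auc(prob, y)

    rng = np.random.default_rng(seed)
    refs = np.arange(n)
    if n_refs is not None and n_refs < n:
        refs = rng.choice(n, size=n_refs, replace=False)
    if kernel_width is None:
        kernel_width = np.sqrt(p) * 0.75

    total = np.zeros(p)
    for ref in refs:
        Z = rng.integers(0, 2, size=(n_perturb, p)).astype(float)
        Z[0] = 1.0  # include the unperturbed point
        perturbed = Xs[ref] * Z  # masked entries revert to the (zero) mean
        pr = knn.predict_proba(perturbed)[:, 1]
        d = np.sqrt(((perturbed - Xs[ref]) ** 2).sum(axis=1))
        w = np.exp(-(d**2) / kernel_width**2)
        # the surrogate is fitted on the perturbed *values*, so a positive
        # coefficient means larger feature values raise the predicted
        # abstinence probability, and signs aggregate across references
        surrogate = Ridge(alpha=1.0)
        surrogate.fit(perturbed, pr, sample_weight=w)
        total += surrogate.coef_
    values = (total / len(refs)).reshape(len(FEATURES), N_MONTHS)
    values[~keep.reshape(len(FEATURES), N_MONTHS)] = 0.0
    return LimeImportance(values=values, auc=model_auc)
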