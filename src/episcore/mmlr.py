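"""Pseudoinverse multivariate multiple linear regression (MMLR) epi scores.

The model writes the methylation matrix as the product of a trait design and
a coefficient matrix, M = T C (samples x sites = samples x traits times
traits x sites).  Fitting solves C = pinv(T) M with the Moore-Penrose
pseudoinverse — the minimum-norm least-squares solution per site column.
Trait prediction for a (possibly external) methylation profile inverts the
coefficients the same way: T_hat = M_new pinv(C).  The continuous predicted
value of a trait for a sample is its "epi score" (epi-ATG, epi-infection,
EpiAge, ...); leave-one-out cross-validation produces a panel of epi scores
in which no sample contributes to its own training fold.

No intercept is added implicitly; pass ``add_intercept=True`` to append an
explicit column of ones (recorded so predictions decode consistently).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.metrics import roc_curve
from sklearn.model_selection import LeaveOneGroupOut, LeaveOneOut, StratifiedKFold

from .io import ValidationError

__all__ = [
    "encode_traits",
    "EpiScoreRegressor",
    "fit_mmlr",
    "predict_traits",
    "loocv_episcores",
    "EpiScorePanel",
    "roc_auc",
    "actual_vs_predicted_correlation",
    "group_score_test",
    "RidgeLogisticRegression",
    "cross_validated_logistic",
]

BINARY_ENCODING = {
    # trait -> (metadata column, value mapped to 1)
    "sex": ("sex", "M"),
    "cmv": ("cmv", "positive"),
    "atg": ("atg", "yes"),
    "transplant": ("transplant", "post"),
    "infection_risk": ("infection_risk", "yes"),
}

DEFAULT_TRAITS = ("age", "sex", "cmv", "atg", "transplant", "infection_risk")


def encode_traits(metadata: pd.DataFrame, cell_pcs: pd.DataFrame | None = None,
                  traits: tuple = DEFAULT_TRAITS, include_ancestry_pcs: bool = True,
                  add_intercept: bool = False) -> pd.DataFrame:
    """Build the sample x trait design matrix under the documented encoding.

    Binary traits map to 0/1 (ATG yes=1, infection yes=1, transplant post=1,
    CMV positive=1, sex M=1); age is in years; cell-type and ancestry PCs
    enter as continuous columns.  Column order is deterministic: intercept
    (opt-in), then ``traits`` in the given order, then cell PCs, then
    ancestry PCs.  A constant column triggers a rank-hazard warning.
    """
    meta = metadata.set_index("sample_id", drop=False)
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["intercept"] = np.ones(len(meta))
    for trait in traits:
        if trait == "age":
            cols["age"] = meta["age"].to_numpy(dtype=float)
        elif trait in BINARY_ENCODING:
            col, one = BINARY_ENCODING[trait]
            if meta[col].isna().any():
                bad = meta.loc[meta[col].isna(), "sample_id"].iloc[0]
                raise ValidationError(f"missing {col!r} for sample {bad!r}")
            cols[trait] = meta[col].eq(one).to_numpy(dtype=float)
        else:
            raise ValidationError(f"unknown trait {trait!r}")
    if cell_pcs is not None:
        pcs = cell_pcs.loc[meta.index]
        for c in pcs.columns:
            cols[c] = pcs[c].to_numpy(dtype=float)
    if include_ancestry_pcs:
        for c in [c for c in meta.columns if c.startswith("ancestry_pc")]:
            cols[c] = meta[c].to_numpy(dtype=float)
    T = pd.DataFrame(cols, index=meta.index)
    if T.isna().any().any():
        col = T.columns[T.isna().any()][0]
        bad = T.index[T[col].isna()][0]
        raise ValidationError(f"missing value for trait {col!r}, sample {bad!r}")
    for c in T.columns:
        if c != "intercept" and T[c].nunique() == 1:
            warnings.warn(f"trait column {c!r} is constant (rank hazard)", stacklevel=2)
    return T


def _pinv(A: np.ndarray) -> np.ndarray:
    # SVD pseudoinverse; singular values below max(dim) * eps * s_max are zero
    return np.linalg.pinv(A)


class EpiScoreRegressor(BaseEstimator, RegressorMixin):
    """MMLR trait predictor fit by Moore-Penrose pseudoinverse.

    ``fit(X, Y)`` takes X = samples x sites methylation and Y = samples x
    traits, and stores ``coef_`` = pinv(Y) X (traits x sites).
    ``predict(X)`` returns X pinv(coef_), the epi scores.  Prediction is
    stateless in the samples scored: an external profile gets the same score
    whether scored alone or with others.

    Parameters
    ----------
    standardize : z-score continuous columns of Y before fitting (recorded in
        ``scale_`` so predictions are decoded back to the original units).
    """

    def __init__(self, standardize: bool = False):
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(pd.DataFrame(X), dtype=float)
        Y = pd.DataFrame(y)
        T = Y.to_numpy(dtype=float)
        if X.shape[0] != T.shape[0]:
            raise ValidationError(
                f"dimension mismatch: {X.shape[0]} methylation rows vs {T.shape[0]} trait rows"
            )
        if not np.isfinite(X).all() or not np.isfinite(T).all():
            raise ValidationError("non-finite values in inputs")
        self.trait_names_ = list(Y.columns)
        if self.standardize:
            mu, sd = T.mean(axis=0), T.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            self.scale_ = (mu, sd)
            T = (T - mu) / sd
        else:
            self.scale_ = None
        self.coef_ = _pinv(T) @ X  # traits x sites
        self.coef_pinv_ = _pinv(self.coef_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise ValidationError("EpiScoreRegressor is not fitted")
        Xdf = pd.DataFrame(X)
        if Xdf.shape[1] != self.coef_.shape[1]:
            raise ValidationError(
                f"site misalignment: model has {self.coef_.shape[1]} sites, "
                f"input has {Xdf.shape[1]}"
            )
        T_hat = np.asarray(Xdf, dtype=float) @ self.coef_pinv_
        if self.scale_ is not None:
            mu, sd = self.scale_
            T_hat = T_hat * sd + mu
        return pd.DataFrame(T_hat, index=Xdf.index, columns=self.trait_names_)


def fit_mmlr(T, M) -> pd.DataFrame:
    """Estimate the trait x site coefficient matrix C = pinv(T) M.

    ``T`` is samples x traits, ``M`` sites x samples (matrix orientation of
    the file format); returns C as traits x sites.
    """
    Tdf, Mdf = pd.DataFrame(T), pd.DataFrame(M)
    model = EpiScoreRegressor().fit(Mdf.T, Tdf)
    return pd.DataFrame(model.coef_, index=Tdf.columns, columns=Mdf.index)


def predict_traits(M_new, C) -> pd.DataFrame:
    """Predict traits for new profiles: T_hat = M_new pinv(C).

    ``M_new`` is sites x samples, aligned to C's site columns.
    """
    Cdf, Mdf = pd.DataFrame(C), pd.DataFrame(M_new)
    if list(Cdf.columns) != list(Mdf.index):
        raise ValidationError("site misalignment between coefficient matrix and input")
    T_hat = Mdf.T.to_numpy(dtype=float) @ _pinv(Cdf.to_numpy(dtype=float))
    return pd.DataFrame(T_hat, index=Mdf.columns, columns=Cdf.index)


@dataclass
class EpiScorePanel:
    """LOOCV-predicted trait values ("epi scores") with evaluation slots."""

    scores: pd.DataFrame                       # samples x traits
    auc: dict = field(default_factory=dict)    # binary trait -> AUC
    correlation: dict = field(default_factory=dict)  # continuous trait -> Spearman rho


def loocv_episcores(T: pd.DataFrame, M: pd.DataFrame,
                    groups: pd.Series | None = None,
                    standardize: bool = False) -> EpiScorePanel:
    """Leave-one-out epi scores: each sample scored by a model trained
    without it.

    ``T``: samples x traits; ``M``: sites x samples.  With ``groups`` (e.g.
    subject ids for paired pre/post samples) whole groups are left out
    together so a subject's other sample never leaks into its fold.
    """
    Tdf, Mdf = pd.DataFrame(T), pd.DataFrame(M)
    X = Mdf.T  # samples x sites
    if list(Tdf.index) != list(X.index):
        raise ValidationError("trait rows must align with matrix sample columns")
    n = len(Tdf)
    if n < 3:
        raise ValidationError("LOOCV needs at least 3 samples")

    Xa, Ta = X.to_numpy(dtype=float), Tdf.to_numpy(dtype=float)
    binary_cols = [j for j in range(Ta.shape[1])
                   if set(np.unique(Ta[:, j])) == {0.0, 1.0}]
    if groups is not None:
        splitter = LeaveOneGroupOut()
        splits = splitter.split(Xa, groups=np.asarray(groups))
    else:
        splits = LeaveOneOut().split(Xa)

    preds = np.empty_like(Ta)
    warned = False
    for train, test in splits:
        for j in binary_cols:
            if not warned and len(np.unique(Ta[train, j])) == 1:
                warnings.warn(
                    f"binary trait {Tdf.columns[j]!r} constant in a training fold",
                    stacklevel=2,
                )
                warned = True
        model = EpiScoreRegressor(standardize=standardize).fit(Xa[train], Ta[train])
        preds[test] = model.predict(Xa[test]).to_numpy()

    panel = EpiScorePanel(scores=pd.DataFrame(preds, index=Tdf.index, columns=Tdf.columns))
    for j, name in enumerate(Tdf.columns):
        col = Ta[:, j]
        if j in binary_cols:
            panel.auc[name] = roc_auc(preds[:, j], col)[0]
        elif np.ptp(col) > 0:  # constant columns (e.g. intercept) have no rho
            rho = stats.spearmanr(col, preds[:, j]).statistic
            panel.correlation[name] = float(rho)
    return panel


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def roc_auc(scores, labels):
    """Tie-aware AUC (normalized Mann-Whitney U; ties count 0.5) + ROC points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError("ROC requires both classes present")
    pos = scores[labels == classes.max()]
    neg = scores[labels == classes.min()]
    ranks = stats.rankdata(scores)
    u = ranks[labels == classes.max()].sum() - len(pos) * (len(pos) + 1) / 2
    auc = float(u / (len(pos) * len(neg)))
    fpr, tpr, thresholds = roc_curve(labels == classes.max(), scores)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


def actual_vs_predicted_correlation(T: pd.DataFrame, panel: EpiScorePanel):
    """Spearman rho (and p) for every (actual trait, predicted trait) pair."""
    Tdf = pd.DataFrame(T)
    P = panel.scores
    if list(Tdf.index) != list(P.index):
        raise ValidationError("sample misalignment between traits and panel")
    rho = pd.DataFrame(index=Tdf.columns, columns=P.columns, dtype=float)
    pval = rho.copy()
    for a in Tdf.columns:
        for b in P.columns:
            x, y = Tdf[a].to_numpy(float), P[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"constant vector for ({a}, {b}); rho undefined",
                              stacklevel=2)
                continue
            res = stats.spearmanr(x, y)
            rho.loc[a, b], pval.loc[a, b] = res.statistic, res.pvalue
    return rho, pval


def group_score_test(scores, labels) -> float:
    """Two-sided Mann-Whitney U p-value for score separation between groups."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError("group test requires both classes present")
    a = scores[labels == classes[0]]
    b = scores[labels == classes[1]]
    return float(mannwhitney_p(a, b))


def mannwhitney_p(a, b) -> float:
    # exact U null distribution for small tie-free samples, tie-corrected
    # normal approximation otherwise
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (no_ties and len(a) + len(b) <= 30) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


# --------------------------------------------------------------------------
# penalized-logistic baseline
# --------------------------------------------------------------------------

class RidgeLogisticRegression(BaseEstimator, ClassifierMixin):
    """L2-penalized logistic regression fit by IRLS (Newton) iterations.

    Minimizes sum of log-losses + (penalty / 2) * ||w||^2 (intercept
    unpenalized) to a gradient infinity-norm below ``tol``.  Serves as the
    site-level baseline classifier against which epi scores are compared.
    """

    def __init__(self, penalty: float = 1.0, tol: float = 1e-6,
                 max_iter: int = 100, fit_intercept: bool = True):
        self.penalty = penalty
        self.tol = tol
        self.max_iter = max_iter
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValidationError("labels must be 0/1")
        n, p = X.shape
        if self.fit_intercept:
            X = np.hstack([np.ones((n, 1)), X])
        w = np.zeros(X.shape[1])
        pen = np.full(X.shape[1], float(self.penalty))
        if self.fit_intercept:
            pen[0] = 0.0
        for it in range(self.max_iter):
            eta = X @ w
            mu = 1.0 / (1.0 + np.exp(-eta))
            grad = X.T @ (mu - y) + pen * w
            if np.max(np.abs(grad)) < self.tol:
                break
            W = np.clip(mu * (1 - mu), 1e-10, None)
            H = (X * W[:, None]).T @ X + np.diag(pen)
            w = w - np.linalg.solve(H, grad)
        else:
            raise ValidationError(
                f"IRLS did not converge in {self.max_iter} iterations "
                f"(|grad|_inf = {np.max(np.abs(grad)):.3g})"
            )
        if self.fit_intercept:
            self.intercept_, self.coef_ = w[0], w[1:]
        else:
            self.intercept_, self.coef_ = 0.0, w
        self.n_iter_ = it + 1
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


def cross_validated_logistic(M, y, penalty: float = 1.0, folds: int = 5,
                             penalty_grid=None, seed: int = 0):
    """Out-of-fold ridge-logistic scores and AUC on a sites x samples matrix.

    With ``penalty_grid``, the penalty is chosen per training fold on an
    inner stratified split by AUC.  Returns (scores Series, AUC).
    """
    Mdf = pd.DataFrame(M)
    X = Mdf.T.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < folds or folds < 2:
        raise ValidationError("need n >= folds >= 2")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for train, test in cv.split(X, y):
        pen = penalty
        if penalty_grid is not None:
            inner = StratifiedKFold(n_splits=min(3, folds), shuffle=True, random_state=seed)
            best, best_auc = penalty, -np.inf
            for cand in penalty_grid:
                aucs = []
                for itr, ite in inner.split(X[train], y[train]):
                    clf = RidgeLogisticRegression(penalty=cand).fit(X[train][itr], y[train][itr])
                    s = clf.decision_function(X[train][ite])
                    if len(np.unique(y[train][ite])) == 2:
                        aucs.append(roc_auc(s, y[train][ite])[0])
                if aucs and np.mean(aucs) > best_auc:
                    best, best_auc = cand, float(np.mean(aucs))
            pen = best
        clf = RidgeLogisticRegression(penalty=pen).fit(X[train], y[train])
        scores[test] = clf.decision_function(X[test])
    auc = roc_auc(scores, y)[0]
    return pd.Series(scores, index=Mdf.columns), auc
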