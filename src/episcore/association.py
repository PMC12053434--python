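"""Per-CpG covariate-adjusted association (EWAS-style).

For each site, methylation (fraction scale by default; logit opt-in) is
regressed on the full covariate design — intercept, age, sex, CMV
serostatus, ATG induction, infection risk, transplant status, cell-type PCs,
ancestry PCs — by ordinary least squares, with a two-sided t-test per
coefficient.  P-values are Benjamini-Hochberg adjusted per explanatory
variable across all tested sites; trait-associated sites are those with
adjusted p below alpha and the requested coefficient sign.

The per-site fits are vectorized: one QR/pseudoinverse of the shared design
solves every site at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

__all__ = [
    "build_design",
    "fit_sitewise_models",
    "AssociationResult",
    "bh_adjust",
    "select_trait_associated_sites",
    "methylation_expression_correlation",
]


def build_design(trait_matrix: pd.DataFrame, add_intercept: bool = True) -> pd.DataFrame:
    """Covariate design for site-wise models; prunes constant columns and
    errors on remaining collinearity (listing the offending columns)."""
    X = pd.DataFrame(trait_matrix).astype(float)
    dropped = [c for c in X.columns if X[c].nunique() == 1 and c != "intercept"]
    if dropped:
        warnings.warn(f"dropping constant covariate column(s): {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    if add_intercept and "intercept" not in X.columns:
        X.insert(0, "intercept", 1.0)
    A = X.to_numpy()
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify collinear columns by greedy QR: a column whose removal
        # restores full rank among those kept so far
        keep: list[int] = []
        collinear = []
        for j in range(A.shape[1]):
            test = A[:, keep + [j]]
            if np.linalg.matrix_rank(test) == len(keep) + 1:
                keep.append(j)
            else:
                collinear.append(X.columns[j])
        raise ValidationError(f"design is rank deficient; collinear column(s): {collinear}")
    return X


@dataclass
class AssociationResult:
    """Per-(site, covariate) OLS statistics.

    Each attribute is a sites x covariates DataFrame; ``sigma2`` is the
    per-site residual variance.
    """

    beta: pd.DataFrame
    se: pd.DataFrame
    tstat: pd.DataFrame
    pvalue: pd.DataFrame
    p_adjusted: pd.DataFrame
    sigma2: pd.Series
    df_resid: int

    def to_long(self) -> pd.DataFrame:
        frames = []
        for name, df in (("beta", self.beta), ("se", self.se), ("t", self.tstat),
                         ("p", self.pvalue), ("p_adj", self.p_adjusted)):
            s = df.stack()
            s.name = name
            frames.append(s)
        out = pd.concat(frames, axis=1).reset_index()
        out.columns = ["site", "trait", "beta", "se", "t", "p", "p_adj"]
        return out


def fit_sitewise_models(M: pd.DataFrame, design: pd.DataFrame,
                        logit: bool = False, eps: float = 1e-3) -> AssociationResult:
    """OLS of each site's methylation on the covariate design.

    ``M`` is sites x samples; ``design`` is samples x covariates (build with
    :func:`build_design`).  With ``logit``, methylation is transformed to
    log(m/(1-m)) after clamping to [eps, 1-eps].
    """
    Mdf, X = pd.DataFrame(M), pd.DataFrame(design)
    if list(Mdf.columns) != list(X.index):
        raise ValidationError("design rows must align with matrix sample columns")
    n, p = X.shape
    if n <= p + 1:
        raise ValidationError(f"need n_samples > n_covariates + 1 ({n} <= {p + 1})")
    A = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < p:
        raise ValidationError("design is rank deficient; prune with build_design first")

    Y = Mdf.to_numpy(dtype=float).T  # samples x sites
    if logit:
        Yc = np.clip(Y, eps, 1 - eps)
        Y = np.log(Yc / (1 - Yc))

    XtX_inv = np.linalg.inv(A.T @ A)
    B = XtX_inv @ A.T @ Y                    # covariates x sites
    resid = Y - A @ B
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof  # per site
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(t), dof)

    sites, covs = Mdf.index, X.columns
    beta = pd.DataFrame(B.T, index=sites, columns=covs)
    se_df = pd.DataFrame(se.T, index=sites, columns=covs)
    t_df = pd.DataFrame(t.T, index=sites, columns=covs)
    p_df = pd.DataFrame(pvals.T, index=sites, columns=covs)
    # BH family: all tested sites, per explanatory variable
    p_adj = pd.DataFrame({c: bh_adjust(p_df[c].to_numpy()) for c in covs}, index=sites)
    return AssociationResult(
        beta=beta, se=se_df, tstat=t_df, pvalue=p_df, p_adjusted=p_adj,
        sigma2=pd.Series(sigma2, index=sites), df_resid=dof,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-stable)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_trait_associated_sites(result: AssociationResult, trait: str,
                                  alpha: float = 0.05,
                                  direction: str = "both") -> list[str]:
    """Sites with adjusted p < alpha for ``trait`` and the requested sign."""
    if trait not in result.p_adjusted.columns:
        raise ValidationError(
            f"unknown trait {trait!r}; have {list(result.p_adjusted.columns)}"
        )
    if direction not in ("positive", "negative", "both"):
        raise ValidationError("direction must be positive/negative/both")
    mask = result.p_adjusted[trait] < alpha
    if direction == "positive":
        mask &= result.beta[trait] > 0
    elif direction == "negative":
        mask &= result.beta[trait] < 0
    return list(result.p_adjusted.index[mask])


def methylation_expression_correlation(M: pd.DataFrame, expression: pd.DataFrame,
                                       mapping: dict, r_threshold: float = 0.3,
                                       p_threshold: float = 0.05) -> pd.DataFrame:
    """Pearson correlation filter between site methylation and gene expression.

    Computes R and p per mapped (site, gene) pair over shared samples; keeps
    pairs with |R| > r_threshold and p < p_threshold.  The ``direction``
    column annotates the regulatory reading: negative R at a
    hypermethylated site suggests down-regulation, positive R up-regulation.
    """
    if not mapping:
        raise ValidationError("empty site->gene mapping")
    shared = [s for s in M.columns if s in expression.columns]
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared samples, have {len(shared)}")
    rows = []
    for site, gene in mapping.items():
        if site not in M.index or gene not in expression.index:
            continue
        r, p = stats.pearsonr(M.loc[site, shared].to_numpy(dtype=float),
                              expression.loc[gene, shared].to_numpy(dtype=float))
        rows.append((site, gene, float(r), float(p)))
    table = pd.DataFrame(rows, columns=["site", "gene", "r", "p"])
    table["passes"] = (table["r"].abs() > r_threshold) & (table["p"] < p_threshold)
    table["direction"] = np.where(table["r"] < 0, "down-regulation", "up-regulation")
    return table


def plot_manhattan(result: AssociationResult, trait: str, alpha: float = 0.05, ax=None):
    """Basic Manhattan plot of -log10 p along site order for one trait."""
    if trait not in result.pvalue.columns:
        raise ValidationError(f"unknown trait {trait!r}")
    if ax is None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        _, ax = plt.subplots(figsize=(8, 3))
    p = result.pvalue[trait].to_numpy()
    sig = result.p_adjusted[trait].to_numpy() < alpha
    x = np.arange(len(p))
    ax.scatter(x[~sig], -np.log10(p[~sig]), s=4, c="grey")
    ax.scatter(x[sig], -np.log10(p[sig]), s=6, c="crimson")
    ax.set_xlabel("site index")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(trait)
    return ax
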