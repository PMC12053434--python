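"""Reference-based cell-type deconvolution.

Marker discovery is one-vs-all: per cell type, the per-site delta is the
type's replicate mean minus the pooled mean of all other replicates.
Candidate regions are maximal runs of consecutive sites with delta at or
below the threshold (inter-site gap bounded); a region is kept when its
genomic span reaches the minimum length and a rank-sum test of the type's
replicates against the rest on region-mean methylation survives
Benjamini-Hochberg correction across all candidates of all types.  Only
hypomethylated (negative-delta) markers are used.

Fractions are then estimated per sample by nonnegative least squares on the
marker-site reference means and, by default, renormalized to sum to one so
the coefficients read as cell-type fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .io import ValidationError, parse_site_key
from .simulate import ReferencePanel

__all__ = [
    "MarkerSiteSet",
    "call_celltype_dmrs",
    "estimate_cell_fractions",
    "compute_cell_pcs",
    "MethylDeconvolver",
]


@dataclass
class MarkerSiteSet:
    """Cell-type-specific marker regions and their member sites.

    ``regions``: one row per kept region (celltype, chrom, start, end in BED
    convention, n_sites, delta = mean over member sites, p, p_adj).
    ``sites``: celltype -> list of member site keys.
    """

    regions: pd.DataFrame
    sites: dict

    def all_sites(self) -> list[str]:
        out: list[str] = []
        seen = set()
        for ct in self.sites:
            for s in self.sites[ct]:
                if s not in seen:
                    seen.add(s)
                    out.append(s)
        return out


def _candidate_runs(pos: np.ndarray, mask: np.ndarray, gap_bp: int):
    """Maximal runs of True sites with inter-site spacing <= gap_bp."""
    runs, start = [], None
    for i in range(len(mask)):
        if mask[i]:
            if start is None:
                start = i
            elif pos[i] - pos[i - 1] > gap_bp:
                runs.append((start, i - 1))
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def call_celltype_dmrs(panel: ReferencePanel, min_length_bp: int = 500,
                       delta_threshold: float = -0.30, fdr: float = 0.05,
                       gap_bp: int = 300) -> MarkerSiteSet:
    """Call cell-type-specific hypomethylated marker regions one-vs-all.

    A region is kept when (1) its span (last - first position) is at least
    ``min_length_bp``, (2) its member-site deltas are all at or below
    ``delta_threshold``, and (3) its BH-adjusted rank-sum p-value is below
    ``fdr``.
    """
    celltypes = panel.celltypes
    if len(celltypes) < 2:
        raise ValidationError("DMR calling needs at least 2 cell types")
    if panel.n_replicates < 2:
        raise ValidationError("DMR calling needs >= 2 replicates per cell type")

    parsed = [parse_site_key(s) for s in panel.site_ids]
    chroms = np.array([c for c, _ in parsed])
    pos = np.array([p for _, p in parsed])
    order = np.lexsort((pos, chroms))

    prof = panel.profiles
    candidates = []  # (celltype, site indices, p)
    for ct in celltypes:
        own = prof[ct].to_numpy()                       # sites x reps
        other = prof.drop(columns=ct, level=0).to_numpy()
        delta = own.mean(axis=1) - other.mean(axis=1)
        for chrom in np.unique(chroms):
            sel = order[chroms[order] == chrom]
            mask = delta[sel] <= delta_threshold
            for a, b in _candidate_runs(pos[sel], mask, gap_bp):
                idx = sel[a:b + 1]
                span = pos[idx[-1]] - pos[idx[0]]
                if span < min_length_bp:
                    continue
                own_means = own[idx].mean(axis=0)
                other_means = other[idx].mean(axis=0)
                p = mannwhitneyu(own_means, other_means,
                                 alternative="two-sided").pvalue
                candidates.append((ct, chrom, idx, float(delta[idx].mean()), p))

    if not candidates:
        return MarkerSiteSet(
            regions=pd.DataFrame(columns=["celltype", "chrom", "start", "end",
                                          "n_sites", "delta", "p", "p_adj"]),
            sites={ct: [] for ct in celltypes},
        )

    pvals = np.array([c[4] for c in candidates])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    rows, sites = [], {ct: [] for ct in celltypes}
    site_keys = list(panel.site_ids)
    for (ct, chrom, idx, delta_mean, p), pa in zip(candidates, p_adj):
        if pa >= fdr:
            continue
        rows.append((ct, chrom, int(pos[idx[0]]) - 1, int(pos[idx[-1]]),
                     len(idx), delta_mean, p, pa))
        sites[ct].extend(site_keys[i] for i in idx)
    regions = pd.DataFrame(rows, columns=["celltype", "chrom", "start", "end",
                                          "n_sites", "delta", "p", "p_adj"])
    return MarkerSiteSet(regions=regions, sites=sites)


def _nnls_fractions(reference: np.ndarray, m: np.ndarray, normalize: bool) -> np.ndarray:
    f, _ = nnls(reference, m)
    if normalize:
        s = f.sum()
        if s == 0:
            raise ValidationError("degenerate fit: all-zero NNLS solution")
        f = f / s
    return f


def estimate_cell_fractions(sample: pd.Series, panel: ReferencePanel,
                            markers: MarkerSiteSet, normalize: bool = True) -> pd.Series:
    """NNLS cell fractions for one sample over the union of marker sites."""
    ref_means = panel.mean_profiles()
    marker_sites = markers.all_sites()
    if not marker_sites:
        raise ValidationError("empty marker set")
    present = [s for s in marker_sites if s in sample.index]
    if not present:
        raise ValidationError("no marker sites present in sample")
    if len(present) < 0.5 * len(marker_sites):
        warnings.warn(
            f"only {len(present)}/{len(marker_sites)} marker sites present in sample",
            stacklevel=2,
        )
    R = ref_means.loc[present].to_numpy()
    if np.linalg.matrix_rank(R) < R.shape[1]:
        warnings.warn("reference profiles are collinear at marker sites; "
                      "fraction split among collinear types is arbitrary", stacklevel=2)
    f = _nnls_fractions(R, sample.loc[present].to_numpy(), normalize)
    return pd.Series(f, index=ref_means.columns, name=sample.name)


class MethylDeconvolver(BaseEstimator, TransformerMixin):
    """Estimate cell-type fractions from methylation profiles.

    ``fit`` takes the reference replicate profiles (replicates x sites, with
    per-replicate cell-type labels), calls one-vs-all marker regions, and
    freezes the marker-site reference means.  ``transform`` maps samples x
    sites methylation onto samples x celltype fractions by NNLS.

    Parameters
    ----------
    min_length_bp, delta_threshold, fdr, gap_bp : marker-calling criteria.
    normalize : divide each NNLS solution by its sum (raw sums are kept in
        ``raw_sums_`` after transform).
    """

    def __init__(self, min_length_bp: int = 500, delta_threshold: float = -0.30,
                 fdr: float = 0.05, gap_bp: int = 300, normalize: bool = True):
        self.min_length_bp = min_length_bp
        self.delta_threshold = delta_threshold
        self.fdr = fdr
        self.gap_bp = gap_bp
        self.normalize = normalize

    def fit(self, X, y=None):
        """Fit from a ReferencePanel, or (replicates x sites, labels)."""
        if isinstance(X, ReferencePanel):
            panel = X
        else:
            X = pd.DataFrame(X)
            if y is None:
                raise ValidationError("per-replicate cell-type labels required")
            labels = np.asarray(y)
            cols = pd.MultiIndex.from_arrays(
                [labels, [f"rep{i}" for i in range(len(labels))]],
                names=["celltype", "replicate"],
            )
            prof = pd.DataFrame(X.to_numpy().T, index=X.columns, columns=cols)
            prof = prof.sort_index(axis=1, level=0, sort_remaining=False)
            panel = ReferencePanel(profiles=prof,
                                   base_profiles=prof.T.groupby(level=0).mean().T)
        self.markers_ = call_celltype_dmrs(
            panel, self.min_length_bp, self.delta_threshold, self.fdr, self.gap_bp
        )
        self.celltypes_ = panel.celltypes
        marker_sites = self.markers_.all_sites()
        if not marker_sites:
            raise ValidationError("no marker regions survive the criteria")
        self.reference_means_ = panel.mean_profiles().loc[marker_sites]
        return self

    def transform(self, X) -> pd.DataFrame:
        """Samples x sites -> samples x celltype fractions."""
        if not hasattr(self, "reference_means_"):
            raise ValidationError("MethylDeconvolver is not fitted")
        X = pd.DataFrame(X)
        marker_sites = [s for s in self.reference_means_.index if s in X.columns]
        if not marker_sites:
            raise ValidationError("empty marker intersection with input sites")
        if len(marker_sites) < 0.5 * len(self.reference_means_):
            warnings.warn(
                f"only {len(marker_sites)}/{len(self.reference_means_)} marker "
                "sites present in input", stacklevel=2,
            )
        R = self.reference_means_.loc[marker_sites].to_numpy()
        if np.linalg.matrix_rank(R) < R.shape[1]:
            warnings.warn("reference profiles are collinear at marker sites; "
                          "fraction split among collinear types is arbitrary",
                          stacklevel=2)
        M = X[marker_sites].to_numpy(dtype=float)
        raw = np.stack([nnls(R, m)[0] for m in M])
        self.raw_sums_ = pd.Series(raw.sum(axis=1), index=X.index)
        if self.normalize:
            sums = raw.sum(axis=1)
            if (sums == 0).any():
                bad = X.index[np.argmax(sums == 0)]
                raise ValidationError(f"degenerate fit: all-zero NNLS solution for {bad!r}")
            raw = raw / sums[:, None]
        return pd.DataFrame(raw, index=X.index, columns=self.celltypes_)


def compute_cell_pcs(fractions: pd.DataFrame, n_pcs: int) -> pd.DataFrame:
    """Principal-component scores of the cell-fraction matrix.

    Columns are centered; the sign of each component is fixed so its
    largest-magnitude loading is positive.  Requires n_pcs < n_celltypes and
    at least n_pcs + 1 samples (a fraction matrix has rank < n_celltypes).
    """
    fractions = pd.DataFrame(fractions)
    n, k = fractions.shape
    if n_pcs >= k:
        raise ValidationError(f"n_pcs={n_pcs} must be < n_celltypes={k}")
    if n < n_pcs + 1:
        raise ValidationError(f"need at least {n_pcs + 1} samples for {n_pcs} PCs")
    X = fractions.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(n_pcs):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    scores = U[:, :n_pcs] * S[:n_pcs]
    return pd.DataFrame(scores, index=fractions.index,
                        columns=[f"cell_pc{i + 1}" for i in range(n_pcs)])
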