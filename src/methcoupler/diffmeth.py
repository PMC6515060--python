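"""Per-CpG two-group differential methylation and cohort-level structure.

The primary test is a two-sided Welch (unequal-variance) t-test on beta
values per probe, case vs control, with Benjamini-Hochberg FDR across all
tested probes.  Significance (p < alpha) and biological relevance
(|delta beta| >= delta_min, default 5 percentage points of methylation) are
kept as separate flags.  A pooled-variance t-test and a covariate-adjusted
linear model (group coefficient t-test) are available as alternatives.

Also provided: a covariate correlation screen over the sample sheet, PCA of
an omics matrix, and Ward/Euclidean hierarchical clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .ioformats import OmicsMatrix, SampleSheet

log = logging.getLogger(__name__)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def drop_snp_probes(manifest: pd.DataFrame) -> pd.DataFrame:
    """Remove probes whose interrogated CpG overlaps a known SNP."""
    flagged = int(manifest["snp_flag"].sum())
    out = manifest[~manifest["snp_flag"]]
    log.info("drop_snp_probes: removed %d of %d probes", flagged, len(manifest))
    if out.empty:
        warnings.warn("all probes were SNP-flagged; manifest is empty")
    return out


def _welch_pvalues(a: np.ndarray, b: np.ndarray,
                   equal_var: bool = False) -> np.ndarray:
    """Row-wise two-sided t-test p-values with degenerate rows made definite:
    zero variance in both groups gives p=1 for equal means, p=0 otherwise."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def _lm_group_pvalues(y: np.ndarray, group: np.ndarray,
                      covs: np.ndarray) -> np.ndarray:
    """Per-row OLS of y on [1, group, covariates]; two-sided t-test p-value
    of the group coefficient.  y is features x samples."""
    n = y.shape[1]
    X = np.column_stack([np.ones(n), group, covs])
    k = X.shape[1]
    if n <= k:
        raise ValueError("not enough samples for covariate adjustment")
    pinv = np.linalg.pinv(X)                      # k x n
    coef = y @ pinv.T                             # features x k
    resid = y - coef @ X.T
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=1) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2[:, None] * np.diag(xtx_inv)[None, :], 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef[:, 1] / se[:, 1]
    p = 2 * stats.t.sf(np.abs(t), dof)
    p[np.isnan(p)] = 1.0
    return p


def test_dmc(beta: OmicsMatrix, samples: SampleSheet,
             alpha: float = 0.05, delta_min: float = 0.05,
             covariates: list[str] | None = None,
             method: str = "welch") -> pd.DataFrame:
    """Per-probe two-group differential methylation on beta values.

    Returns a DataFrame indexed by probe_id with columns delta_beta
    (mean case - mean control), p_value, fdr, significant (p < alpha) and
    biologically_relevant (|delta_beta| >= delta_min).

    ``method`` is 'welch' (default), 'pooled', or 'lm'; giving ``covariates``
    implies the linear-model route with the group-coefficient t-test.
    """
    if beta.kind != "beta":
        raise ValueError("test_dmc expects a beta-kind matrix")
    case, control = samples.case_ids, samples.control_ids
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = beta.data[case].to_numpy(float)
    b = beta.data[control].to_numpy(float)
    delta = a.mean(axis=1) - b.mean(axis=1)

    if covariates or method == "lm":
        order = case + control
        y = beta.data[order].to_numpy(float)
        group = np.array([1.0] * len(case) + [0.0] * len(control))
        cov_df = samples.table.loc[order, covariates or []]
        covs = cov_df.to_numpy(float) if covariates else np.empty((len(order), 0))
        if np.isnan(covs).any():
            raise ValueError("missing covariate values; impute or drop first")
        p = _lm_group_pvalues(y, group, covs)
    else:
        p = _welch_pvalues(a, b, equal_var=(method == "pooled"))

    out = pd.DataFrame({
        "delta_beta": delta,
        "p_value": p,
        "fdr": bh_fdr(p),
    }, index=beta.data.index)
    out.index.name = "probe_id"
    out["significant"] = out["p_value"] < alpha
    out["biologically_relevant"] = out["delta_beta"].abs() >= delta_min
    return out


@dataclass
class CovariateScreen:
    """Pairwise Pearson screen over sample covariates (plus the group code)."""

    r: pd.DataFrame
    p: pd.DataFrame
    masked: pd.DataFrame  # r with entries at p > alpha (or undefined) as NaN


def covariate_screen(samples: SampleSheet, alpha: float = 0.05,
                     include_group: bool = True) -> CovariateScreen:
    """Pairwise-complete Pearson correlations between covariates; entries
    whose two-sided P exceeds ``alpha`` are masked (NaN).  Diagonal is 1.
    Constant variables get their row/column masked with a warning."""
    df = samples.covariates.copy()
    if include_group:
        df.insert(0, "group", (samples.table["group"] == "case").astype(float))
    if len(df) < 3:
        raise ValueError("covariate screen needs at least 3 samples")
    cols = list(df.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x, y = df[cols[i]], df[cols[j]]
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if i == j:
                if x[ok].nunique() > 1:
                    r[i, i], p[i, i] = 1.0, 0.0
                continue
            if n < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                continue
            rr, pp = stats.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    for i in range(k):
        if df[cols[i]].dropna().nunique() < 2:
            warnings.warn(f"covariate {cols[i]!r} is constant; "
                          "correlation undefined, masked")
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    masked = rdf.where((pdf <= alpha))
    return CovariateScreen(rdf, pdf, masked)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # features x components
    variance_ratio: np.ndarray    # fractions, sum to 1 over all components
    mean: np.ndarray              # per-feature centring vector


def pca(matrix: OmicsMatrix) -> PCAResult:
    """PCA of samples in feature space.  Features are centred (not scaled).

    The sign of each component is fixed by forcing its largest-magnitude
    loading positive, so results are deterministic across runs/backends.
    """
    X = matrix.data.to_numpy(float).T            # samples x features
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 features")
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for c in range(Vt.shape[0]):
        jmax = np.abs(Vt[c]).argmax()
        if Vt[c, jmax] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    var = S ** 2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    comps = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=matrix.data.columns, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=matrix.data.index, columns=comps)
    return PCAResult(scores, loadings, ratio, mean)


@dataclass
class HClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]


def hcluster(matrix: OmicsMatrix, axis: str = "samples") -> HClusterResult:
    """Ward minimum-variance linkage on Euclidean distances.

    ``axis`` = 'samples' clusters columns, 'features' clusters rows.  The
    leaf order is emitted for heatmap export.
    """
    if axis == "samples":
        X = matrix.data.to_numpy(float).T
        labels = list(matrix.data.columns)
    elif axis == "features":
        X = matrix.data.to_numpy(float)
        labels = list(matrix.data.index)
    else:
        raise ValueError("axis must be 'samples' or 'features'")
    if len(labels) < 2:
        raise ValueError("clustering needs at least 2 items")
    Z = linkage(X, method="ward", metric="euclidean")
    order = [labels[i] for i in leaves_list(Z)]
    return HClusterResult(Z, labels, order)
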