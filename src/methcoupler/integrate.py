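"""Methylation x expression integration.

The core operation pairs significant promoter-island DMCs with inversely
changed, filter-passing DEGs on the same gene (a gene may carry several
probes, so pairing is many-to-one), then computes one pooled Pearson
correlation per sample group over the (beta, log2 expression) points of all
pairs x group samples.  In a cohort where promoter methylation suppresses
expression in cases only, the case group shows a significant negative
correlation and the control group does not.

Also here: ranking of all genes by expression covariation with a seed
regulator gene, and cross-study co-directionality of two DEG tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import LOG_OFFSET
from .ioformats import OmicsMatrix, SampleSheet

log = logging.getLogger(__name__)


def pair_inverse(dmcs: pd.DataFrame, degs: pd.DataFrame,
                 annotation: pd.DataFrame, require_delta: bool = False,
                 deg_mode: str = "filter",
                 deg_p_max: float = 0.05) -> pd.DataFrame:
    """One row per (promoter-island DMC probe, inversely changed DEG).

    A pair qualifies when the probe is significant (optionally also
    |delta beta| >= the biological-relevance threshold via
    ``require_delta``), is annotated promoter+island to the gene, the gene's
    DEG record qualifies (``deg_mode='filter'`` uses passes_filter,
    ``'pvalue'`` uses p < deg_p_max only), and the methylation and expression
    changes have opposite signs.
    """
    if deg_mode not in ("filter", "pvalue"):
        raise ValueError("deg_mode must be 'filter' or 'pvalue'")
    sig = dmcs[dmcs["significant"]]
    if require_delta:
        sig = sig[sig["biologically_relevant"]]
    ann = annotation.loc[annotation.index.intersection(sig.index)]
    ann = ann[(ann["region"] == "promoter") & (ann["context"] == "island")
              & ann["gene_id"].notna()]
    if deg_mode == "filter":
        deg_ok = degs[degs["passes_filter"]]
    else:
        deg_ok = degs[degs["p_value"] < deg_p_max]

    rows = []
    for probe_id, arow in ann.sort_index().iterrows():
        gene = arow["gene_id"]
        if gene not in deg_ok.index:
            continue
        db = float(sig.loc[probe_id, "delta_beta"])
        lfc = float(deg_ok.loc[gene, "log2fc"])
        if db == 0 or lfc == 0 or np.sign(db) == np.sign(lfc):
            continue
        rows.append((probe_id, gene, db, lfc))
    out = pd.DataFrame(rows, columns=["probe_id", "gene_id", "delta_beta",
                                      "log2fc"])
    out["inverse"] = True
    if out.empty:
        warnings.warn("no inverse promoter-island DMC/DEG pairs found")
    log.info("pair_inverse: %d pairs, %d unique probes, %d unique genes",
             len(out), out["probe_id"].nunique(), out["gene_id"].nunique())
    return out


@dataclass
class GroupCorrelation:
    group: str
    n_points: int
    pearson_r: float | None
    p_value: float | None


def groupwise_correlation(pairs: pd.DataFrame, beta: OmicsMatrix,
                          expr: OmicsMatrix, samples: SampleSheet,
                          offset: float = LOG_OFFSET,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled Pearson correlation per group over all pairs x group samples.

    For each group, every (pair, sample) contributes one point:
    x = beta of the probe in that sample, y = log2(FPKM + offset) of the
    gene.  Returns (summary table, scatter-point table).  Groups with zero
    variance in x or y are reported with r and P absent.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for the pooled correlation")
    summaries, points = [], []
    for group, ids in (("case", samples.case_ids),
                       ("control", samples.control_ids)):
        if len(ids) < 3:
            raise ValueError(f"group {group!r} needs at least 3 samples")
        x = beta.data.loc[pairs["probe_id"], ids].to_numpy(float).ravel()
        y = np.log2(expr.data.loc[pairs["gene_id"], ids].to_numpy(float)
                    + offset).ravel()
        for (pid, gid), xs, ys in zip(
                pairs[["probe_id", "gene_id"]].itertuples(index=False),
                x.reshape(len(pairs), -1), y.reshape(len(pairs), -1)):
            for s, xv, yv in zip(ids, xs, ys):
                points.append((group, pid, gid, s, xv, yv))
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"group {group!r}: zero variance; r undefined")
            summaries.append(GroupCorrelation(group, len(x), None, None))
            continue
        r, p = stats.pearsonr(x, y)
        summaries.append(GroupCorrelation(group, len(x), float(r), float(p)))
    summary = pd.DataFrame(
        [(s.group, s.n_points, s.pearson_r, s.p_value) for s in summaries],
        columns=["group", "n_points", "pearson_r", "p_value"],
    ).set_index("group")
    scatter = pd.DataFrame(points, columns=["group", "probe_id", "gene_id",
                                            "sample_id", "beta", "log2_expr"])
    return summary, scatter


def per_pair_correlation(pairs: pd.DataFrame) -> tuple[float, float]:
    """Alternative statistic: Pearson of (delta_beta, log2fc) across pairs."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    r, p = stats.pearsonr(pairs["delta_beta"], pairs["log2fc"])
    return float(r), float(p)


def covariation_with_seed(expr: OmicsMatrix, seed_gene: str,
                          samples: SampleSheet | None = None,
                          alpha: float = 0.05,
                          offset: float = LOG_OFFSET) -> pd.DataFrame:
    """Pearson correlation of every gene's expression with a seed regulator.

    Expression is taken on the log2(FPKM + offset) scale across all samples
    (or the samples in ``samples`` when given).  The seed is excluded from
    its own output.  Genes with P < alpha are classed 'positive' or
    'negative' by the sign of r; others 'ns'.
    """
    if seed_gene not in expr.data.index:
        raise KeyError(f"seed gene {seed_gene!r} not in expression matrix")
    cols = samples.sample_ids if samples is not None else expr.sample_ids
    X = np.log2(expr.data[cols].to_numpy(float) + offset)
    seed = X[expr.data.index.get_loc(seed_gene)]
    if np.ptp(seed) == 0:
        raise ValueError(f"seed gene {seed_gene!r} has constant expression")
    n = len(cols)
    Xc = X - X.mean(axis=1, keepdims=True)
    sc = seed - seed.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=1) * (sc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ sc) / denom
    r = np.clip(r, -1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.isnan(r)] = np.nan
    out = pd.DataFrame({"pearson_r": r, "p_value": p}, index=expr.data.index)
    out = out.drop(index=seed_gene)
    out["sign_class"] = np.where(
        out["p_value"] < alpha,
        np.where(out["pearson_r"] > 0, "positive", "negative"), "ns")
    out.loc[out["p_value"].isna(), "sign_class"] = "ns"
    out.index.name = "gene_id"
    return out.sort_values("p_value")


@dataclass
class Concordance:
    n_overlap: int
    n_codirectional: int
    percent: float | None  # co-directional / overlap * 100; None if no overlap


def cross_study_concordance(deg_a: pd.DataFrame, deg_b: pd.DataFrame,
                            p_max: float = 0.05,
                            fpkm_min: float | None = 2.0) -> Concordance:
    """Overlap and co-directionality of two DEG tables.

    Overlap = genes significant (p < p_max, and mean FPKM > fpkm_min where
    FPKM columns exist) in both studies; co-directional = agreement of
    log2fc sign; the fraction is reported as a percentage of the overlap.
    """
    def sig(df: pd.DataFrame) -> pd.DataFrame:
        keep = df["p_value"] < p_max
        if fpkm_min is not None and \
                {"mean_fpkm_case", "mean_fpkm_control"}.issubset(df.columns):
            keep &= df[["mean_fpkm_case",
                        "mean_fpkm_control"]].max(axis=1) > fpkm_min
        return df[keep]

    a, b = sig(deg_a), sig(deg_b)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        warnings.warn("no overlapping significant genes; fraction undefined")
        return Concordance(0, 0, None)
    same = np.sign(a.loc[common, "log2fc"]) == np.sign(b.loc[common, "log2fc"])
    n_co = int(same.sum())
    return Concordance(len(common), n_co, 100.0 * n_co / len(common))
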