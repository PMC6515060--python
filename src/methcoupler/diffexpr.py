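"""Two-group differential expression on FPKM-scale matrices.

The built-in test is a simple surrogate suited to the synthetic cohorts:
a Welch t-test on log2(FPKM + 1) per gene with BH FDR.  Externally computed
differential-expression tables can be imported instead.  The expression
filter is the three-part rule p < 0.05, |fold-change| > 1.5, FPKM > 2
(strict inequalities); fold-change is defined on (mean FPKM + 1) ratios so
the threshold is well-defined at zero expression, and the FPKM clause is
interpreted as max of the two group means by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diffmeth import _welch_pvalues, bh_fdr
from .ioformats import FormatError, OmicsMatrix, SampleSheet

log = logging.getLogger(__name__)

LOG_OFFSET = 1.0  # the +1 in log2(FPKM + 1); configurable at call sites


def _apply_filter(df: pd.DataFrame, p_max: float, fc_min: float,
                  fpkm_min: float, fpkm_rule: str = "max") -> pd.Series:
    fc = 2.0 ** df["log2fc"].abs()
    if {"mean_fpkm_case", "mean_fpkm_control"}.issubset(df.columns):
        pair = df[["mean_fpkm_case", "mean_fpkm_control"]]
        if fpkm_rule == "max":
            fpkm_ok = pair.max(axis=1) > fpkm_min
        elif fpkm_rule == "either":
            fpkm_ok = (pair > fpkm_min).any(axis=1)
        elif fpkm_rule == "mean":
            fpkm_ok = pair.mean(axis=1) > fpkm_min
        else:
            raise ValueError(f"unknown fpkm_rule {fpkm_rule!r}")
    else:
        log.info("no FPKM columns present; expression-level filter waived")
        fpkm_ok = pd.Series(True, index=df.index)
    return (df["p_value"] < p_max) & (fc > fc_min) & fpkm_ok


def test_deg(expr: OmicsMatrix, samples: SampleSheet,
             p_max: float = 0.05, fc_min: float = 1.5,
             fpkm_min: float = 2.0, offset: float = LOG_OFFSET,
             fpkm_rule: str = "max") -> pd.DataFrame:
    """Welch t-test on log2(FPKM + offset) per gene, case vs control.

    Returns a DataFrame indexed by gene_id with log2fc (difference of
    log2(group-mean FPKM + offset)), p_value, fdr, group mean FPKMs and the
    passes_filter flag.
    """
    if expr.kind != "fpkm":
        raise ValueError("test_deg expects an fpkm-kind matrix")
    case, control = samples.case_ids, samples.control_ids
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = np.log2(expr.data[case].to_numpy(float) + offset)
    b = np.log2(expr.data[control].to_numpy(float) + offset)
    p = _welch_pvalues(a, b)
    mean_case = expr.data[case].mean(axis=1)
    mean_control = expr.data[control].mean(axis=1)
    out = pd.DataFrame({
        "log2fc": np.log2(mean_case + offset) - np.log2(mean_control + offset),
        "p_value": p,
        "fdr": bh_fdr(p),
        "mean_fpkm_case": mean_case,
        "mean_fpkm_control": mean_control,
    }, index=expr.data.index)
    out.index.name = "gene_id"
    out["passes_filter"] = _apply_filter(out, p_max, fc_min, fpkm_min,
                                         fpkm_rule)
    return out


def import_deg_table(path: str, p_max: float = 0.05, fc_min: float = 1.5,
                     fpkm_min: float = 2.0) -> pd.DataFrame:
    """Import an external differential-expression TSV.

    Requires a gene column (first), a p column (``p_value``/``p``), and
    either ``log2fc`` or a linear ``fold_change`` column.  A missing ``fdr``
    (or ``q``) column is recomputed by BH; when present it is preserved.
    ``passes_filter`` is always recomputed under this package's rule.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "gene_id"
    cols = {c.lower(): c for c in df.columns}
    pcol = cols.get("p_value") or cols.get("p")
    if pcol is None:
        raise FormatError(f"{path}: no p-value column")
    out = pd.DataFrame(index=df.index)
    if "log2fc" in cols:
        out["log2fc"] = df[cols["log2fc"]].astype(float)
    elif "fold_change" in cols:
        fc = df[cols["fold_change"]].astype(float)
        if (fc <= 0).any():
            raise FormatError(f"{path}: fold_change must be positive")
        out["log2fc"] = np.log2(fc)
    else:
        raise FormatError(f"{path}: neither log2fc nor fold_change present")
    out["p_value"] = df[pcol].astype(float)
    qcol = cols.get("fdr") or cols.get("q")
    out["fdr"] = (df[qcol].astype(float) if qcol is not None
                  else bh_fdr(out["p_value"].to_numpy()))
    for extra in ("mean_fpkm_case", "mean_fpkm_control"):
        if extra in cols:
            out[extra] = df[cols[extra]].astype(float)
    out["passes_filter"] = _apply_filter(out, p_max, fc_min, fpkm_min)
    return out


def filter_degs(degs: pd.DataFrame, p_max: float = 0.05, fc_min: float = 1.5,
                fpkm_min: float = 2.0, fpkm_rule: str = "max") -> pd.DataFrame:
    """Keep genes passing p < p_max, |fold-change| > fc_min, FPKM > fpkm_min
    (all strict, exactly as the thresholds are stated)."""
    keep = _apply_filter(degs, p_max, fc_min, fpkm_min, fpkm_rule)
    out = degs[keep]
    log.info("filter_degs: %d of %d genes retained", len(out), len(degs))
    return out


def export_deg_table(degs: pd.DataFrame, path: str) -> None:
    from .ioformats import _comment_header
    with open(path, "w") as fh:
        fh.write(_comment_header({"format": "deg"}) + "\n")
        degs.to_csv(fh, sep="\t", float_format="%.17g")
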