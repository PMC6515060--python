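"""Over-representation analysis and ChIP-target overlap summaries.

ORA is the one-sided Fisher exact (hypergeometric upper-tail) test of a
query gene list against each set of a GMT collection, restricted to a stated
gene universe, with BH FDR across the collection.  The enrichment ratio is
the fraction of a set hit by the query.  ChIP-target hypermethylation flags
each target gene that carries at least one significant hypermethylated
promoter-island probe.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_fdr
from .ioformats import GeneSetCollection

log = logging.getLogger(__name__)


def ora(query: Iterable[str], universe: Iterable[str],
        collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided over-representation of ``query`` in each collection set.

    Query and sets are deduplicated and intersected with the universe before
    testing.  P is the hypergeometric upper tail P(X >= hits); FDR is BH
    across the collection; results are ranked by P.
    """
    uni = set(universe)
    q = set(query) & uni
    if set(query) - uni:
        log.info("ora: %d query genes outside the universe ignored",
                 len(set(query) - uni))
    N = len(uni)
    rows = []
    for name, genes in collection.sets.items():
        s = set(genes) & uni
        k = len(q & s)
        # P(X >= k) for X ~ Hypergeom(N, |s|, |q|)
        p = float(stats.hypergeom.sf(k - 1, N, len(s), len(q))) if s else 1.0
        ratio = k / len(s) if s else 0.0
        rows.append((name, k, len(s), N, ratio, p))
    out = pd.DataFrame(rows, columns=["set_name", "n_query_hits", "set_size",
                                      "universe_size", "enrichment_ratio",
                                      "p_value"]).set_index("set_name")
    out["fdr"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values(["p_value", "set_name"])


def chip_target_hypermethylation(chip_targets: Sequence[str],
                                 dmcs: pd.DataFrame,
                                 annotation: pd.DataFrame,
                                 require_all: bool = False,
                                 ) -> tuple[pd.DataFrame, float]:
    """Flag ChIP target genes with promoter-island hypermethylation.

    A target is flagged when >= 1 (or, with ``require_all``, every one of
    its) significant promoter-island probe(s) has delta_beta > 0.  Targets
    absent from the annotated gene universe stay in the denominator, flagged
    False, with a warning.  Returns (per-gene table, flagged fraction).
    """
    targets = list(dict.fromkeys(chip_targets))
    known = set(annotation["gene_id"].dropna())
    missing = [g for g in targets if g not in known]
    if missing:
        warnings.warn(f"{len(missing)} ChIP targets absent from gene "
                      "annotation; counted unflagged")
    sig = dmcs[dmcs["significant"]]
    pi = annotation[(annotation["region"] == "promoter")
                    & (annotation["context"] == "island")]
    pi = pi.loc[pi.index.intersection(sig.index)]
    rows = []
    for gene in targets:
        probes = pi[pi["gene_id"] == gene].index
        hyper = sig.loc[probes, "delta_beta"] > 0
        if len(probes) == 0:
            flagged = False
        elif require_all:
            flagged = bool(hyper.all())
        else:
            flagged = bool(hyper.any())
        rows.append((gene, len(probes), int(hyper.sum()), flagged))
    table = pd.DataFrame(rows, columns=["gene_id", "n_sig_promoter_island",
                                        "n_hyper", "flagged"]
                         ).set_index("gene_id")
    fraction = float(table["flagged"].mean()) if len(table) else 0.0
    log.info("chip_target_hypermethylation: %d/%d targets flagged (%.1f%%)",
             int(table["flagged"].sum()), len(table), 100 * fraction)
    return table, fraction


def gene_cpg_profile(gene_id: str, dmcs: pd.DataFrame,
                     manifest: pd.DataFrame,
                     annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG differential-methylation profile of one gene.

    All probes annotated to the gene (any region), ordered by genomic
    position, with delta_beta and a bubble-size column -log10(p).
    """
    probes = annotation[annotation["gene_id"] == gene_id].index
    probes = probes.intersection(dmcs.index).intersection(manifest.index)
    if len(probes) == 0:
        warnings.warn(f"gene {gene_id!r} has no annotated probes")
        return pd.DataFrame(columns=["chrom", "pos", "region", "delta_beta",
                                     "p_value", "neg_log10_p"])
    out = manifest.loc[probes, ["chrom", "pos"]].copy()
    out["region"] = annotation.loc[probes, "region"]
    out["delta_beta"] = dmcs.loc[probes, "delta_beta"]
    out["p_value"] = dmcs.loc[probes, "p_value"]
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    out.index.name = "probe_id"
    return out.sort_values("pos")
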