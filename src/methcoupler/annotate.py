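"""Dual CpG annotation: gene region x CpG-island context.

Each probe receives exactly one gene-region label (promoter, utr5, body,
utr3, other) and one CGI-context label (island, shore, shelf, open_sea).

* The annotation promoter is the span strictly upstream of the TSS
  (default 1500 bp), strand-aware.  Gene models are BED-like and carry no
  transcript structure, so 5'/3' UTRs are approximated as fixed-length spans
  at the strand-aware gene ends (optional ``utr5_len``/``utr3_len`` columns,
  default 200 bp); the remainder of the gene span is body.
* Context comes from the distance to the nearest CGI edge: 0 -> island,
  <= shore_span -> shore, <= shore_span + shelf_span -> shelf, else open sea
  (the standard 450K-style 2 kb shore / 2 kb shelf convention).
* When a probe hits features of several genes, region priority is
  promoter > utr5 > utr3 > body > other, ties broken by smallest TSS
  distance; one gene per probe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

log = logging.getLogger(__name__)

REGIONS = ["promoter", "utr5", "body", "utr3", "other"]
CONTEXTS = ["island", "shore", "shelf", "open_sea"]
_REGION_PRIORITY = {"promoter": 0, "utr5": 1, "utr3": 2, "body": 3}

DEFAULT_UTR_LEN = 200


def _gene_feature_intervals(gene: pd.Series, gene_id: str,
                            promoter_span: int) -> list[tuple[int, int, str]]:
    """1-based inclusive (start, end, region) features for one gene."""
    start, end, strand, tss = (int(gene["start"]), int(gene["end"]),
                               gene["strand"], int(gene["tss"]))
    u5 = int(gene.get("utr5_len", DEFAULT_UTR_LEN) or DEFAULT_UTR_LEN)
    u3 = int(gene.get("utr3_len", DEFAULT_UTR_LEN) or DEFAULT_UTR_LEN)
    length = end - start + 1
    u5 = min(u5, length)
    u3 = min(u3, max(length - u5, 0))
    feats = []
    if strand == "+":
        feats.append((max(tss - promoter_span, 1), tss - 1, "promoter"))
        feats.append((start, start + u5 - 1, "utr5"))
        feats.append((end - u3 + 1, end, "utr3"))
        body_s, body_e = start + u5, end - u3
    else:
        feats.append((tss + 1, tss + promoter_span, "promoter"))
        feats.append((end - u5 + 1, end, "utr5"))
        feats.append((start, start + u3 - 1, "utr3"))
        body_s, body_e = start + u3, end - u5
    if body_s <= body_e:
        feats.append((body_s, body_e, "body"))
    return [(s, e, r) for s, e, r in feats if s <= e]


def annotate_cpgs(manifest: pd.DataFrame, gene_models: pd.DataFrame,
                  cgis: pd.DataFrame, promoter_span: int = 1500,
                  shore_span: int = 2000,
                  shelf_span: int = 2000) -> pd.DataFrame:
    """Assign every probe one (gene_id, region, context).

    Returns a DataFrame indexed by probe_id with columns gene_id (None when
    no gene feature matched), region and context.  Annotation is total:
    probes on chromosomes without gene models get region='other'; context is
    computed from CGIs on the probe's chromosome, else 'open_sea'.
    """
    trees: dict[str, IntervalTree] = {}
    for gene_id, gene in gene_models.iterrows():
        tree = trees.setdefault(str(gene["chrom"]), IntervalTree())
        for s, e, region in _gene_feature_intervals(gene, gene_id,
                                                    promoter_span):
            # intervaltree is half-open; +1 on the end converts inclusive ends
            tree.addi(s, e + 1, (region, gene_id, int(gene["tss"])))

    cgi_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in cgis.groupby("chrom"):
        starts = grp["start"].to_numpy(int)
        ends = grp["end"].to_numpy(int)
        order = np.argsort(starts)
        cgi_by_chrom[str(chrom)] = (starts[order], ends[order])

    multi_mapped = 0
    records = []
    for probe_id, probe in manifest.iterrows():
        chrom, pos = str(probe["chrom"]), int(probe["pos"])
        region, gene_id = "other", None
        hits = trees[chrom][pos] if chrom in trees else ()
        if hits:
            if len({h.data[1] for h in hits}) > 1:
                multi_mapped += 1
            best = min(hits, key=lambda h: (_REGION_PRIORITY[h.data[0]],
                                            abs(pos - h.data[2]), h.data[1]))
            region, gene_id = best.data[0], best.data[1]
        context = "open_sea"
        if chrom in cgi_by_chrom:
            starts, ends = cgi_by_chrom[chrom]
            inside = (starts <= pos) & (pos <= ends)
            if inside.any():
                dist = 0
            else:
                d_left = np.where(pos > ends, pos - ends, np.inf)
                d_right = np.where(pos < starts, starts - pos, np.inf)
                dist = int(min(d_left.min(), d_right.min()))
            if dist == 0:
                context = "island"
            elif dist <= shore_span:
                context = "shore"
            elif dist <= shore_span + shelf_span:
                context = "shelf"
        records.append((probe_id, gene_id, region, context))
    if multi_mapped:
        log.info("annotate_cpgs: %d probes hit features of multiple genes; "
                 "kept highest-priority assignment", multi_mapped)
    out = pd.DataFrame(records,
                       columns=["probe_id", "gene_id", "region", "context"])
    return out.set_index("probe_id")


def region_context_grid(dmcs: pd.DataFrame,
                        annotation: pd.DataFrame) -> pd.DataFrame:
    """5x4 count grid of DMC probes by (gene region, CGI context).

    ``dmcs`` should already be restricted to the significant probes of
    interest; probes missing from the annotation are counted in
    (other, open_sea) with a warning.  The grand total equals len(dmcs).
    """
    grid = pd.DataFrame(0, index=REGIONS, columns=CONTEXTS, dtype=int)
    missing = dmcs.index.difference(annotation.index)
    if len(missing):
        warnings.warn(f"{len(missing)} DMC probes lack annotation; "
                      "counted as (other, open_sea)")
        grid.loc["other", "open_sea"] += len(missing)
    ann = annotation.loc[dmcs.index.intersection(annotation.index)]
    counts = ann.groupby(["region", "context"], observed=True).size()
    for (region, context), n in counts.items():
        grid.loc[region, context] += int(n)
    return grid


@dataclass
class EnrichmentTest:
    """2x2 chi-squared result for promoter-island DMC enrichment."""

    chi2: float
    df: int
    p_value: float
    observed: np.ndarray   # [[dmc & promoter-island, dmc & other],
                           #  [rest & promoter-island, rest & other]]
    expected: np.ndarray
    fisher_p: float | None = None  # reported when any expected cell < 1


def promoter_cgi_enrichment(dmcs: pd.DataFrame, annotation: pd.DataFrame,
                            background: pd.DataFrame) -> EnrichmentTest:
    """Chi-squared test (no continuity correction) of promoter-associated
    CGI membership among DMCs versus the non-DMC array background.

    ``background`` is the annotation of all tested probes and must be a
    superset of the DMC probes.
    """
    if not dmcs.index.isin(background.index).all():
        raise ValueError("background must cover all DMC probes")
    is_pi = (background["region"] == "promoter") & \
            (background["context"] == "island")
    dmc_mask = background.index.isin(dmcs.index)
    a = int((is_pi & dmc_mask).sum())
    b = int((~is_pi & dmc_mask).sum())
    c = int((is_pi & ~dmc_mask).sum())
    d = int((~is_pi & ~dmc_mask).sum())
    observed = np.array([[a, b], [c, d]], dtype=float)
    chi2, p, df, expected = stats.chi2_contingency(observed, correction=False)
    fisher_p = None
    if (expected < 1).any():
        warnings.warn("expected cell < 1; Fisher exact result also reported")
        fisher_p = float(stats.fisher_exact(observed)[1])
    _ = annotation  # the DMC annotation is implied by the background rows
    return EnrichmentTest(float(chi2), int(df), float(p), observed.astype(int),
                          expected, fisher_p)


def context_magnitude(dmcs: pd.DataFrame,
                      annotation: pd.DataFrame) -> pd.DataFrame:
    """Mean |delta beta| (and SEM) of DMCs within each CGI context.

    Contexts with no DMCs are omitted.  SEM is sd/sqrt(n) (ddof=1), reported
    as 0 for singleton contexts.
    """
    joined = dmcs.join(annotation[["context"]], how="inner")
    rows = []
    for context in CONTEXTS:
        vals = joined.loc[joined["context"] == context, "delta_beta"].abs()
        n = len(vals)
        if n == 0:
            continue
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append((context, n, float(vals.mean()), sem))
    return pd.DataFrame(rows, columns=["context", "n", "mean_abs_delta",
                                       "sem"]).set_index("context")
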