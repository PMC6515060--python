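"""Sequence windows around DMCs, PWM scanning and motif enrichment.

Windows of +/- ``flank`` bases (default 10) are cut around each DMC's
cytosine on the forward genomic strand.  PWMs score windows by log2 odds
against a uniform base background; a window is a hit when the best placement
on either strand reaches a fraction (default 0.8) of the PWM's maximum
attainable score.  Enrichment of a motif in a target window set versus a
CpG-content-matched background is tested with the one-sided hypergeometric
tail and summarised by the log10 odds detection ratio (ODT, Haldane 0.5
correction).  De novo discovery is an exhaustive k-mer enrichment over
window presence counts — reproducible and directly testable against
enumeration, unlike seed-refinement heuristics.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_fdr
from .ioformats import MotifModel, revcomp

log = logging.getLogger(__name__)


@dataclass
class WindowSet:
    """Uniform-length sequence windows centred on DMC cytosines.

    ``table`` is indexed by probe_id with columns seq, cpg_count (CG
    dinucleotides in the window) and gc_frac.  The centre base (index
    ``flank``) is the interrogated cytosine.
    """

    table: pd.DataFrame
    flank: int = 10

    def __post_init__(self) -> None:
        lens = self.table["seq"].str.len().unique() if len(self.table) else []
        want = 2 * self.flank + 1
        if len(lens) > 1 or (len(lens) == 1 and lens[0] != want):
            raise ValueError(f"window length must be uniform = {want}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sequences(self) -> list[str]:
        return list(self.table["seq"])


def _window_stats(seq: str) -> tuple[int, float]:
    cpg = sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "CG")
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    return cpg, gc


def extract_windows(probe_ids, manifest: pd.DataFrame,
                    genome: dict[str, str], flank: int = 10) -> WindowSet:
    """Cut forward-strand windows of 2*flank+1 bases centred on each probe's
    cytosine.  Probes whose window would run past a chromosome end (or whose
    chromosome is absent) are dropped with a warning."""
    rows, dropped = [], 0
    for probe_id in probe_ids:
        if probe_id not in manifest.index:
            dropped += 1
            continue
        chrom = str(manifest.loc[probe_id, "chrom"])
        pos = int(manifest.loc[probe_id, "pos"])
        seq = genome.get(chrom)
        if seq is None or pos - 1 - flank < 0 or pos + flank > len(seq):
            dropped += 1
            continue
        window = seq[pos - 1 - flank: pos + flank].upper()
        cpg, gc = _window_stats(window)
        rows.append((probe_id, window, cpg, gc))
    if dropped:
        warnings.warn(f"extract_windows: {dropped} probes dropped "
                      "(missing chromosome or window past chromosome end)")
    table = pd.DataFrame(rows, columns=["probe_id", "seq", "cpg_count",
                                        "gc_frac"]).set_index("probe_id")
    return WindowSet(table, flank)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _best_placement(seq: str, lom: np.ndarray) -> tuple[float, int] | None:
    """Best (score, start) of the motif on one strand of ``seq``; placements
    covering an ambiguous base are skipped.  None when nothing scoreable."""
    L = lom.shape[1]
    best = None
    for s in range(len(seq) - L + 1):
        sub = seq[s:s + L]
        score = 0.0
        ok = True
        for j, base in enumerate(sub):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                ok = False
                break
            score += lom[idx, j]
        if ok and (best is None or score > best[0]):
            best = (score, s)
    return best


def scan_pwm(windows: WindowSet, motif: MotifModel,
             score_frac: float = 0.8) -> pd.DataFrame:
    """Scan every window with the PWM on both strands.

    A window is a hit when its best log-odds placement reaches
    ``score_frac`` x the maximum attainable score.  ``center_offset`` is the
    offset of the motif centre from the window's central CpG cytosine in
    forward-strand coordinates.
    """
    L = motif.length
    W = 2 * windows.flank + 1
    if L > W:
        raise ValueError("motif longer than window")
    lom = motif.log_odds()
    thresh = score_frac * motif.max_score()
    rows = []
    for probe_id, seq in windows.table["seq"].items():
        best_score, best_start, best_strand = -np.inf, None, None
        fwd = _best_placement(seq, lom)
        if fwd is not None:
            best_score, best_start, best_strand = fwd[0], fwd[1], "+"
        rev = _best_placement(revcomp(seq), lom)
        if rev is not None and rev[0] > best_score:
            # map the reverse-strand start back to forward coordinates
            best_score, best_start, best_strand = (
                rev[0], W - rev[1] - L, "-")
        hit = best_start is not None and best_score >= thresh
        center = (best_start + (L - 1) / 2 - windows.flank
                  if best_start is not None else np.nan)
        rows.append((probe_id, hit, best_score, best_start, best_strand,
                     center))
    return pd.DataFrame(rows, columns=["probe_id", "hit", "best_score",
                                       "best_start", "strand",
                                       "center_offset"]).set_index("probe_id")


def match_background(target: WindowSet, pool: WindowSet,
                     seed: int) -> WindowSet:
    """Sample a background window set matching the target's joint
    (CpG count, GC fraction) histogram.

    GC is binned to 0.05; sampling is without replacement and deterministic
    given ``seed``.  When a bin of the pool is short the match is
    best-effort with a warning.
    """
    if len(pool) == 0:
        raise ValueError("empty background pool")
    overlap = target.table.index.intersection(pool.table.index)
    if len(overlap):
        raise ValueError("background pool overlaps the target set")
    rng = np.random.default_rng(seed)

    def binkey(row) -> tuple[int, int]:
        return int(row["cpg_count"]), int(round(row["gc_frac"] * 20))

    pool_bins: dict[tuple[int, int], list[str]] = {}
    for pid, row in pool.table.iterrows():
        pool_bins.setdefault(binkey(row), []).append(pid)
    want = Counter(binkey(row) for _, row in target.table.iterrows())
    chosen: list[str] = []
    short = 0
    for key, k in sorted(want.items()):
        avail = pool_bins.get(key, [])
        take = min(k, len(avail))
        short += k - take
        if take:
            picks = rng.choice(len(avail), size=take, replace=False)
            chosen.extend(avail[i] for i in sorted(picks))
    if short:
        warnings.warn(f"match_background: pool short by {short} windows in "
                      "occupied bins; best-effort match")
    return WindowSet(pool.table.loc[chosen], pool.flank)


@dataclass
class MotifEnrichment:
    motif_name: str
    target_hits: int
    target_n: int
    background_hits: int
    background_n: int
    log10_odt: float
    p_value: float
    pct_targets_with_motif: float
    offsets: list[float] = field(default_factory=list)


def _hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _log10_odt(th: int, tn: int, bh: int, bn: int) -> float:
    odds_t = (th + 0.5) / (tn - th + 0.5)
    odds_b = (bh + 0.5) / (bn - bh + 0.5)
    return float(np.log10(odds_t / odds_b))


def motif_enrichment(target: WindowSet, background: WindowSet,
                     motif: MotifModel,
                     score_frac: float = 0.8) -> MotifEnrichment:
    """Hypergeometric enrichment of PWM hits in target vs background windows,
    with log10 ODT ranking statistic and positional offsets of target hits
    relative to the central CpG."""
    if len(target) == 0:
        raise ValueError("empty target window set")
    t_scan = scan_pwm(target, motif, score_frac)
    b_scan = scan_pwm(background, motif, score_frac)
    th, tn = int(t_scan["hit"].sum()), len(t_scan)
    bh, bn = int(b_scan["hit"].sum()), len(b_scan)
    p = _hypergeom_tail(th, tn + bn, th + bh, tn)
    offsets = t_scan.loc[t_scan["hit"], "center_offset"].tolist()
    return MotifEnrichment(motif.name, th, tn, bh, bn,
                           _log10_odt(th, tn, bh, bn), p,
                           100.0 * th / tn, offsets)


def rank_motifs(target: WindowSet, background: WindowSet,
                motifs: list[MotifModel],
                score_frac: float = 0.8) -> pd.DataFrame:
    """Run motif_enrichment for a panel of PWMs; rank by (P, -log10 ODT)."""
    rows = []
    for m in motifs:
        e = motif_enrichment(target, background, m, score_frac)
        rows.append((e.motif_name, e.target_hits, e.target_n,
                     e.background_hits, e.background_n, e.log10_odt,
                     e.p_value, e.pct_targets_with_motif))
    out = pd.DataFrame(rows, columns=["motif", "target_hits", "target_n",
                                      "background_hits", "background_n",
                                      "log10_odt", "p_value", "pct_targets"])
    out = out.sort_values(["p_value", "log10_odt", "motif"],
                          ascending=[True, False, True])
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("motif")


def _window_kmers(seq: str, k: int) -> set[str]:
    """k-mers present in a window on either strand (a window counts once per
    k-mer; palindromes are not double-counted because this is a set)."""
    rc = revcomp(seq)
    kmers = {seq[i:i + k] for i in range(len(seq) - k + 1)}
    kmers |= {rc[i:i + k] for i in range(len(rc) - k + 1)}
    return {m for m in kmers if "N" not in m}


def kmer_enrichment(target: WindowSet, background: WindowSet,
                    k: int = 7) -> pd.DataFrame:
    """Exhaustive k-mer window-presence enrichment (both strands).

    For every k-mer seen in either set: presence counts, one-sided
    hypergeometric P, log10 ODT and BH FDR, ranked by (P, -ODT, k-mer).
    """
    if k > 2 * target.flank + 1:
        raise ValueError("k exceeds window length")
    t_counts: Counter = Counter()
    for seq in target.sequences:
        t_counts.update(_window_kmers(seq, k))
    b_counts: Counter = Counter()
    for seq in background.sequences:
        b_counts.update(_window_kmers(seq, k))
    tn, bn = len(target), len(background)
    rows = []
    for kmer in sorted(set(t_counts) | set(b_counts)):
        th, bh = t_counts.get(kmer, 0), b_counts.get(kmer, 0)
        p = _hypergeom_tail(th, tn + bn, th + bh, tn)
        rows.append((kmer, th, bh, _log10_odt(th, tn, bh, bn), p))
    out = pd.DataFrame(rows, columns=["kmer", "target_hits",
                                      "background_hits", "log10_odt",
                                      "p_value"])
    out["fdr"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    out = out.sort_values(["p_value", "log10_odt", "kmer"],
                          ascending=[True, False, True])
    return out.set_index("kmer")


def extract_promoter_sequences(gene_models: pd.DataFrame,
                               genome: dict[str, str],
                               upstream: int = 1500,
                               downstream: int = 500) -> dict[str, str]:
    """Strand-aware proximal promoter sequences around each TSS.

    For a + strand gene the window is [tss-upstream, tss+downstream]
    (1-based inclusive); for a - strand gene it is
    [tss-downstream, tss+upstream] reverse-complemented.  Windows running
    past a chromosome edge are truncated with a warning.
    """
    seqs = {}
    truncated = 0
    for gene_id, gene in gene_models.iterrows():
        chrom = str(gene["chrom"])
        if chrom not in genome:
            continue
        tss, strand = int(gene["tss"]), gene["strand"]
        chrom_seq = genome[chrom]
        if strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream, tss + upstream
        if lo < 1 or hi > len(chrom_seq):
            truncated += 1
            lo, hi = max(lo, 1), min(hi, len(chrom_seq))
        seq = chrom_seq[lo - 1:hi].upper()
        seqs[gene_id] = seq if strand == "+" else revcomp(seq)
    if truncated:
        warnings.warn(f"{truncated} promoters truncated at chromosome edges")
    return seqs


def _promoter_hit(seq: str, motif: MotifModel, thresh: float) -> bool:
    lom = motif.log_odds()
    for s in (seq, revcomp(seq)):
        best = _best_placement(s, lom)
        if best is not None and best[0] >= thresh:
            return True
    return False


def promoter_motif_scan(degs: pd.DataFrame, gene_models: pd.DataFrame,
                        genome: dict[str, str], motifs: list[MotifModel],
                        upstream: int = 1500, downstream: int = 500,
                        score_frac: float = 0.8,
                        p_max: float = 0.05) -> pd.DataFrame:
    """Per-motif enrichment in DEG promoters vs non-DEG promoters.

    DEG = p_value < p_max.  Promoters are the strand-aware
    (-upstream, +downstream) windows around each TSS; hit rates are compared
    with the one-sided Fisher exact test, BH-corrected across motifs.
    """
    seqs = extract_promoter_sequences(gene_models, genome, upstream,
                                      downstream)
    deg_genes = [g for g in degs.index[degs["p_value"] < p_max] if g in seqs]
    bg_genes = [g for g in seqs if g not in set(deg_genes)]
    if not deg_genes or not bg_genes:
        raise ValueError("need both DEG and non-DEG promoters to compare")
    rows = []
    for m in motifs:
        thresh = score_frac * m.max_score()
        dh = sum(_promoter_hit(seqs[g], m, thresh) for g in deg_genes)
        bh = sum(_promoter_hit(seqs[g], m, thresh) for g in bg_genes)
        table = [[dh, len(deg_genes) - dh], [bh, len(bg_genes) - bh]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append((m.name, dh, len(deg_genes), bh, len(bg_genes),
                     _log10_odt(dh, len(deg_genes), bh, len(bg_genes)), p))
    out = pd.DataFrame(rows, columns=["motif", "deg_hits", "deg_n",
                                      "background_hits", "background_n",
                                      "log10_odt", "p_value"])
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "motif"]).set_index("motif")
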