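import numpy as np
import pandas as pd
import pytest

from methcoupler import motif
from methcoupler.ioformats import MotifModel, revcomp
from _oracles import hypergeom_upper_tail, naive_pwm_hits


def _manifest(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions,
                         "snp_flag": False},
                        index=[f"cg{i}" for i in range(len(positions))])


def _windows(seqs, flank=10):
    rows = []
    for i, s in enumerate(seqs):
        cpg = sum(1 for j in range(len(s) - 1) if s[j:j + 2] == "CG")
        gc = (s.count("G") + s.count("C")) / len(s)
        rows.append((f"w{i}", s, cpg, gc))
    return motif.WindowSet(pd.DataFrame(
        rows, columns=["probe_id", "seq", "cpg_count", "gc_frac"]
    ).set_index("probe_id"), flank)


def test_extract_windows_centering_and_boundaries():
    genome = {"chr1": "AAAAAAAAAAAACGAAAAAAAAAAAA"}  # C at 1-based pos 13
    man = _manifest([13, 5, 20])
    with pytest.warns(UserWarning, match="dropped"):
        ws = motif.extract_windows(man.index, man, genome, flank=10)
    assert list(ws.table.index) == ["cg0"]        # 5 and 20 cannot centre
    seq = ws.table.loc["cg0", "seq"]
    assert len(seq) == 21
    assert seq[10] == "C" and seq[11] == "G"
    assert ws.table.loc["cg0", "cpg_count"] == 1


def test_scan_consensus_hit_and_strand_symmetry():
    pwm = MotifModel.from_consensus("CCCGCCC")
    win = "AAACCCGCCCAAAAAAAAAAA"
    ws = _windows([win])
    res = motif.scan_pwm(ws, pwm)
    assert res.loc["w0", "hit"] and res.loc["w0", "strand"] == "+"
    assert res.loc["w0", "best_start"] == 3
    ws_rc = _windows([revcomp(win)])
    res_rc = motif.scan_pwm(ws_rc, pwm)
    assert res_rc.loc["w0", "hit"] and res_rc.loc["w0", "strand"] == "-"
    assert res_rc.loc["w0", "best_score"] == pytest.approx(
        res.loc["w0", "best_score"], abs=1e-12)


def test_scan_center_offset_of_cpg_aligned_motif():
    """A consensus planted with its CG on the central CpG reports a centre
    offset of 0."""
    # CCCGCCC with its CG at window positions 10-11 -> starts at index 8
    win = "AAAAAAAA" + "CCCGCCC" + "AAAAAA"
    ws = _windows([win])
    res = motif.scan_pwm(ws, MotifModel.from_consensus("CCCGCCC"))
    assert res.loc["w0", "hit"]
    assert res.loc["w0", "center_offset"] == pytest.approx(1.0)
    # the motif centre (position index 11) sits one base 3' of the C


def test_scan_matches_naive_rescoring_oracle():
    rng = np.random.default_rng(23)
    pwm = MotifModel.from_consensus("CCCGCCC")
    seqs = ["".join(rng.choice(list("ACGT"), 21)) for _ in range(8)]
    seqs += ["AAAA" + "CCCGCCC" + "AAAAAAAAAA",
             "AAAA" + "GGGCGGG" + "AAAAAAAAAA"]
    ws = _windows(seqs)
    res = motif.scan_pwm(ws, pwm, score_frac=0.8)
    expected = naive_pwm_hits(seqs, pwm.counts, pwm.pseudocount, 0.8)
    assert list(res["hit"]) == expected
    assert res["hit"].iloc[-2] and res["hit"].iloc[-1]


def test_scan_skips_ambiguous_bases():
    ws = _windows(["N" * 21])
    res = motif.scan_pwm(ws, MotifModel.from_consensus("CCCGCCC"))
    assert not res["hit"].any()


def test_strand_symmetry_property():
    """Reverse-complementing every window leaves hit counts unchanged."""
    rng = np.random.default_rng(31)
    pwm = MotifModel.from_consensus("CCGCGGA")
    seqs = ["".join(rng.choice(list("ACGT"), 21)) for _ in range(30)]
    seqs[3] = seqs[3][:5] + "CCGCGGA" + seqs[3][12:]
    n1 = motif.scan_pwm(_windows(seqs), pwm)["hit"].sum()
    n2 = motif.scan_pwm(_windows([revcomp(s) for s in seqs]), pwm)["hit"].sum()
    assert n1 == n2 and n1 >= 1


# ---------------------------------------------------------------------- #
# background matching
# ---------------------------------------------------------------------- #

def _bins(ws):
    return sorted((int(r["cpg_count"]), int(round(r["gc_frac"] * 20)))
                  for _, r in ws.table.iterrows())


def test_match_background_histogram_and_determinism():
    rng = np.random.default_rng(41)
    target_seqs = ["".join(rng.choice(list("ACGT"), 21)) for _ in range(20)]
    pool_seqs = target_seqs * 3 + \
        ["".join(rng.choice(list("ACGT"), 21)) for _ in range(60)]
    target = _windows(target_seqs)
    pool = motif.WindowSet(_windows(pool_seqs).table.set_axis(
        [f"p{i}" for i in range(len(pool_seqs))]), 10)
    b1 = motif.match_background(target, pool, seed=5)
    b2 = motif.match_background(target, pool, seed=5)
    assert list(b1.table.index) == list(b2.table.index)   # deterministic
    assert _bins(b1) == _bins(target)                     # exact histogram
    assert abs(b1.table["cpg_count"].mean()
               - target.table["cpg_count"].mean()) <= 0.1


def test_match_background_rejects_empty_and_overlapping_pool():
    ws = _windows(["A" * 21])
    empty = motif.WindowSet(ws.table.iloc[0:0], 10)
    with pytest.raises(ValueError, match="empty"):
        motif.match_background(ws, empty, 1)
    with pytest.raises(ValueError, match="overlap"):
        motif.match_background(ws, ws, 1)


# ---------------------------------------------------------------------- #
# enrichment
# ---------------------------------------------------------------------- #

def test_motif_enrichment_null_and_oracle():
    rng = np.random.default_rng(51)
    base = ["".join(rng.choice(list("ACGT"), 21)) for _ in range(40)]
    planted = ["AAAA" + "CCCGCCC" + s[11:] for s in base[:10]]
    pwm = MotifModel.from_consensus("CCCGCCC")
    # null: same composition in target and background
    t_null = _windows(base[:20])
    b_null = motif.WindowSet(_windows(base[20:]).table.set_axis(
        [f"b{i}" for i in range(20)]), 10)
    e = motif.motif_enrichment(t_null, b_null, pwm)
    assert e.p_value > 0.05
    assert abs(e.log10_odt) < 0.5
    # enriched: hypergeometric tail equals exhaustive enumeration
    t_enr = _windows(planted + base[:10])
    b_enr = motif.WindowSet(_windows(base[10:40]).table.set_axis(
        [f"b{i}" for i in range(30)]), 10)
    e2 = motif.motif_enrichment(t_enr, b_enr, pwm)
    expected = hypergeom_upper_tail(
        e2.target_hits, e2.target_n + e2.background_n,
        e2.target_hits + e2.background_hits, e2.target_n)
    assert e2.p_value == pytest.approx(expected, abs=1e-12)
    assert e2.target_hits >= 10
    assert e2.log10_odt > 0


def test_kmer_palindrome_counted_once():
    # ACGCGCGT's reverse complement is itself at k=8; use a 6-mer palindrome
    win = "AAAAAAA" + "ACGCGT" + "AAAAAAAA"
    target = _windows([win])
    background = motif.WindowSet(_windows(["A" * 21]).table.set_axis(["b0"]),
                                 10)
    res = motif.kmer_enrichment(target, background, k=6)
    assert res.loc["ACGCGT", "target_hits"] == 1


def test_kmer_enrichment_recovers_planted_consensus(cohort, cohort_products):
    dmcs, ann = cohort_products["dmcs"], cohort_products["annotation"]
    man = cohort_products["manifest"]
    sig = dmcs[dmcs["significant"]]
    pi = ann[(ann["region"] == "promoter") & (ann["context"] == "island")]
    tids = sig.index.intersection(pi.index)
    target = motif.extract_windows(tids, man, cohort.genome, 10)
    pool = motif.extract_windows(man.index.difference(tids), man,
                                 cohort.genome, 10)
    with pytest.warns(UserWarning):
        background = motif.match_background(target, pool, seed=102)
    res = motif.kmer_enrichment(target, background, k=7)
    assert res.index[0] in ("CCCGCCC", "GGGCGGG")


# ---------------------------------------------------------------------- #
# promoter scan
# ---------------------------------------------------------------------- #

def test_promoter_sequence_strand_arithmetic():
    rng = np.random.default_rng(61)
    chrom = "".join(rng.choice(list("ACGT"), 30_000))
    genome = {"chr1": chrom}
    genes = pd.DataFrame(
        [("gP", "chr1", 10_000, 14_000, "+", 10_000),
         ("gM", "chr1", 16_000, 20_000, "-", 20_000)],
        columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    ).set_index("gene_id")
    seqs = motif.extract_promoter_sequences(genes, genome)
    # + strand TSS 10,000 -> genomic 8,500..10,500 inclusive
    assert seqs["gP"] == chrom[8_499:10_500]
    assert len(seqs["gP"]) == 2001
    # - strand TSS 20,000 -> genomic 19,500..21,500 reverse-complemented
    assert seqs["gM"] == revcomp(chrom[19_499:21_500])


def test_promoter_motif_scan_planted_enrichment():
    rng = np.random.default_rng(71)
    chrom = list("".join(rng.choice(list("ACGT"), 305_000)))
    rows, pvals = [], {}
    for i in range(30):
        tss = 5_000 + i * 10_000
        rows.append((f"g{i}", "chr1", tss, tss + 3_000, "+", tss))
        if i < 10:          # DEGs, motif planted in the proximal promoter
            s = tss - 300
            chrom[s:s + 7] = list("CCCGCCC")
            pvals[f"g{i}"] = 0.001
        else:
            pvals[f"g{i}"] = 0.8
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand", "tss"]).set_index("gene_id")
    degs = pd.DataFrame({"p_value": pd.Series(pvals),
                         "log2fc": -1.0})
    res = motif.promoter_motif_scan(degs, genes, {"chr1": "".join(chrom)},
                                    [MotifModel.from_consensus("CCCGCCC")])
    assert res.iloc[0]["deg_hits"] == 10
    assert res.iloc[0]["p_value"] < 0.01
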