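"""Synthetic two-group methylation + expression cohorts with a truth table.

The generator emulates the statistical structure the integration analysis
assumes, on a single synthetic chromosome with genes tiled at a fixed
spacing:

* planted "oxidative" genes get promoter-CGI CpGs hypermethylated in cases
  and their expression suppressed; planted "glycolytic" genes the reverse
  (hypomethylated, induced);
* beta values are drawn on the logit scale (normal noise whose sd is
  calibrated to give ``beta_noise_sd`` on the beta scale near 0.5) and
  mapped back through the inverse logit, so values stay strictly in (0, 1);
* case-group expression is mechanistically coupled to each planted gene's
  realized promoter methylation, log2(FPKM+1) = baseline +
  coupling_slope x (promoter mean beta - planted control mean) + noise;
  control expression is independent of methylation;
* one null gene acts as a seed regulator whose expression shares a latent
  factor with a set of target genes (signed, half positive half negative);
* the genome sequence carries a planted consensus motif, centred on the CpG,
  inside the promoter-island windows of planted genes at
  ``motif_target_rate`` and elsewhere at ``motif_background_rate``.

Everything is reproducible from ``SimConfig.seed``; a truth table records
planted directions per gene, planted deltas per CpG and motif planting per
window for recovery scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ioformats import (
    GeneSetCollection,
    MotifModel,
    OmicsMatrix,
    SampleSheet,
    ValidationError,
)

log = logging.getLogger(__name__)

# CpG placement template per gene: (direction, offset from TSS, note).
# 'up' is strand-aware upstream (promoter side), 'down' is into/past the gene.
_CPG_TEMPLATE = [
    ("up", 50),     # promoter CGI
    ("up", 150),    # promoter CGI
    ("up", 250),    # promoter CGI
    ("up", 1000),   # promoter, CGI shore
    ("down", 2500), # gene body, CGI shelf
    ("down", 4800), # intergenic, open sea
    ("up", 1400),   # promoter edge
    ("down", 3300), # gene body
]
_N_ISLAND = 3          # first template entries inside the promoter CGI
_CGI_HALF = 300        # promoter CGI spans tss +/- 300
_GENE_LEN = 3500
_UTR_LEN = 300


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_case: int = 6
    n_control: int = 6
    drop_case_outlier: bool = True   # 6v6 generated, one case dropped -> 5v6
    n_genes: int = 120
    cpgs_per_gene: int = 6
    gene_spacing: int = 10_000
    promoter_span: int = 1500
    frac_hyper_genes: float = 0.2
    frac_hypo_genes: float = 0.2
    delta_beta: float = 0.15
    beta_noise_sd: float = 0.03
    coupling_slope: float = -6.0     # on log2(FPKM+1) per unit beta
    expr_noise_sd: float = 0.25
    regulator_targets: int = 10
    motif_consensus: str = "CCCGCCC"
    motif_target_rate: float = 0.40
    motif_background_rate: float = 0.05
    snp_frac: float = 0.02
    frac_null_promoter_cgi: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_hyper_genes", "frac_hypo_genes",
                     "motif_target_rate", "motif_background_rate",
                     "snp_frac", "frac_null_promoter_cgi"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.delta_beta < 1:
            raise ValidationError("delta_beta must lie in [0, 1)")
        if self.n_case < 3 or self.n_control < 3:
            raise ValidationError("need at least 3 samples per group")
        if self.drop_case_outlier and self.n_case < 4:
            raise ValidationError("outlier drop needs n_case >= 4")
        if not 4 <= self.cpgs_per_gene <= len(_CPG_TEMPLATE):
            raise ValidationError(
                f"cpgs_per_gene must be in [4, {len(_CPG_TEMPLATE)}]")
        if self.frac_hyper_genes + self.frac_hypo_genes > 0.8:
            raise ValidationError("planted fractions leave too few null genes")
        n_null = self.n_genes - int(self.frac_hyper_genes * self.n_genes) \
            - int(self.frac_hypo_genes * self.n_genes)
        if n_null < self.regulator_targets + 1:
            raise ValidationError("not enough null genes for the regulator "
                                  "and its targets")
        if self.beta_noise_sd <= 0 or self.expr_noise_sd <= 0:
            raise ValidationError("noise SDs must be positive")
        if self.gene_spacing < 2 * (max(o for _, o in _CPG_TEMPLATE) + 200):
            raise ValidationError("gene_spacing too small for CpG template")


@dataclass
class TruthTable:
    """Planted effects: per-gene direction/regulator roles, per-CpG deltas,
    per-window motif planting."""

    genes: pd.DataFrame     # planted_direction, is_regulator_target,
                            # regulator_sign, is_regulator
    cpgs: pd.DataFrame      # planted_delta, motif_planted
    regulator: str


@dataclass
class SyntheticCohort:
    config: SimConfig
    samples: SampleSheet
    manifest: pd.DataFrame
    beta: OmicsMatrix
    fpkm: OmicsMatrix
    genes: pd.DataFrame
    cgis: pd.DataFrame
    genome: dict[str, str]
    gene_sets: GeneSetCollection
    chip_targets: list[str]
    pwm: MotifModel
    truth: TruthTable


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full cohort (all pipeline inputs plus the truth table)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    n_genes = config.n_genes

    # --- gene layout ---------------------------------------------------
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    centers = config.gene_spacing // 2 + np.arange(n_genes) * config.gene_spacing
    strands = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    starts = np.where(strands == "+", centers, centers - _GENE_LEN + 1)
    ends = np.where(strands == "+", centers + _GENE_LEN - 1, centers)
    genes = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": ends, "strand": strands,
        "tss": centers, "utr5_len": _UTR_LEN, "utr3_len": _UTR_LEN,
    }, index=pd.Index(gene_ids, name="gene_id"))

    # --- planted classes ------------------------------------------------
    n_hyper = int(round(config.frac_hyper_genes * n_genes))
    n_hypo = int(round(config.frac_hypo_genes * n_genes))
    order = rng.permutation(n_genes)
    hyper_idx = set(order[:n_hyper])
    hypo_idx = set(order[n_hyper:n_hyper + n_hypo])
    null_idx = [i for i in order[n_hyper + n_hypo:]]
    regulator_i = null_idx[0]
    target_is = null_idx[1:1 + config.regulator_targets]
    target_signs = {gi: (1 if k % 2 == 0 else -1)
                    for k, gi in enumerate(target_is)}

    direction = np.array(["null"] * n_genes, dtype=object)
    for i in hyper_idx:
        direction[i] = "hyper_down"
    for i in hypo_idx:
        direction[i] = "hypo_up"

    # --- CGIs: promoter islands for planted genes + a fraction of nulls --
    has_cgi = np.zeros(n_genes, dtype=bool)
    for i in range(n_genes):
        if i in hyper_idx or i in hypo_idx:
            has_cgi[i] = True
        elif rng.random() < config.frac_null_promoter_cgi:
            has_cgi[i] = True
    cgis = pd.DataFrame({
        "chrom": chrom,
        "start": centers[has_cgi] - _CGI_HALF,
        "end": centers[has_cgi] + _CGI_HALF,
        "name": [f"cgi_{g}" for g, h in zip(gene_ids, has_cgi) if h],
    }).reset_index(drop=True)

    # --- CpG manifest ----------------------------------------------------
    probe_rows, planted_delta, planted_island = [], [], []
    island_probe_of_gene = {}
    probe_n = 0
    for i, gid in enumerate(gene_ids):
        c = centers[i]
        upstream_sign = -1 if strands[i] == "+" else 1
        islands = []
        for side, off in _CPG_TEMPLATE[:config.cpgs_per_gene]:
            pos = c + upstream_sign * off if side == "up" else \
                c - upstream_sign * off
            probe_n += 1
            pid = f"cg{probe_n:07d}"
            probe_rows.append((pid, chrom, int(pos),
                               bool(rng.random() < config.snp_frac), gid))
            is_island_probe = has_cgi[i] and abs(pos - c) <= _CGI_HALF
            if is_island_probe:
                islands.append(pid)
            planted_here = is_island_probe and direction[i] != "null"
            planted_island.append(planted_here)
            if planted_here and direction[i] == "hyper_down":
                planted_delta.append(config.delta_beta)
            elif planted_here:
                planted_delta.append(-config.delta_beta)
            else:
                planted_delta.append(0.0)
        island_probe_of_gene[gid] = islands
    manifest = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos", "snp_flag",
                             "source_gene"]).set_index("probe_id")
    planted_delta = np.array(planted_delta)
    planted_island = np.array(planted_island)
    n_probes = len(manifest)

    # --- samples ---------------------------------------------------------
    case_ids = [f"ICM{j + 1:02d}" for j in range(config.n_case)]
    control_ids = [f"NICM{j + 1:02d}" for j in range(config.n_control)]
    all_ids = case_ids + control_ids
    n_samples = len(all_ids)
    sheet = pd.DataFrame(index=pd.Index(all_ids, name="sample_id"))
    sheet["group"] = ["case"] * len(case_ids) + ["control"] * len(control_ids)
    sheet["age"] = np.round(rng.normal(60, 6, n_samples))
    sheet["ejection_fraction"] = np.round(rng.normal(20, 5, n_samples), 1)
    sheet["diabetes"] = (rng.random(n_samples) < 0.4).astype(float)
    sheet["smoking_pack_years"] = np.round(rng.exponential(10, n_samples), 1)
    samples = SampleSheet(sheet, ("ICM", "NICM"))

    # --- beta matrix (logit-normal around planted means) -----------------
    base_mean = np.empty(n_probes)
    base_mean[:] = rng.uniform(0.2, 0.8, n_probes)
    # planted promoter-island CpGs share a narrow intermediate baseline
    # (CGI promoters sit near half-methylation in tissue arrays); keeping
    # the between-probe mean dispersion small also keeps the pooled
    # correlation statistic calibrated under the null (see methods note)
    base_mean[planted_island] = rng.uniform(0.48, 0.52, planted_island.sum())
    case_mean = np.clip(base_mean + planted_delta, 0.02, 0.98)
    sd_logit = 4.0 * config.beta_noise_sd  # d(sigmoid)/dx = 1/4 at beta = 0.5
    noise = rng.normal(0.0, sd_logit, size=(n_probes, n_samples))
    mean_grid = np.column_stack([
        np.repeat(case_mean[:, None], len(case_ids), axis=1),
        np.repeat(base_mean[:, None], len(control_ids), axis=1),
    ])
    beta_vals = _sigmoid(_logit(mean_grid) + noise)
    beta = OmicsMatrix(pd.DataFrame(beta_vals, index=manifest.index,
                                    columns=all_ids), "beta")

    # --- expression ------------------------------------------------------
    baseline = rng.normal(3.0, 1.5, n_genes)
    planted_any = (direction != "null")
    # planted modules share one well-expressed baseline: keeps them clear of
    # the FPKM filter and makes the control group exactly exchangeable, so
    # the pooled control correlation is null by construction
    baseline[planted_any] = 4.5
    factor = rng.normal(0.0, 1.0, n_samples)      # regulator latent factor
    y = baseline[:, None] + rng.normal(0.0, config.expr_noise_sd,
                                       (n_genes, n_samples))
    y[regulator_i] = baseline[regulator_i] + factor + \
        rng.normal(0.0, 0.3, n_samples)
    for gi in target_is:
        y[gi] = baseline[gi] + target_signs[gi] * factor + \
            rng.normal(0.0, 0.3, n_samples)
    # mechanistic case-only coupling to realized promoter methylation
    for i, gid in enumerate(gene_ids):
        if direction[i] == "null":
            continue
        probes = island_probe_of_gene[gid]
        if not probes:
            continue
        prom_beta = beta.data.loc[probes, case_ids].mean(axis=0).to_numpy()
        control_target = float(np.mean(base_mean[manifest.index.isin(probes)]))
        y[i, :len(case_ids)] += config.coupling_slope * \
            (prom_beta - control_target)
    fpkm_vals = np.clip(2.0 ** y - 1.0, 0.0, None)
    fpkm = OmicsMatrix(pd.DataFrame(fpkm_vals, index=genes.index,
                                    columns=all_ids), "fpkm")

    # --- genome sequence with planted motif -------------------------------
    genome_len = n_genes * config.gene_spacing + config.gene_spacing
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytearray(base_codes[rng.integers(0, 4, genome_len)].tobytes())
    positions = manifest["pos"].to_numpy(int)
    for pos in positions:
        seq[pos - 1:pos + 1] = b"CG"
    consensus = config.motif_consensus.upper().encode()
    cg_off = consensus.find(b"CG")
    motif_planted = np.zeros(n_probes, dtype=bool)
    target_window = planted_island
    for k, pos in enumerate(positions):
        rate = (config.motif_target_rate if target_window[k]
                else config.motif_background_rate)
        if rng.random() >= rate:
            continue
        start = (pos - 1 - cg_off) if cg_off >= 0 else pos + 1
        if start < 0 or start + len(consensus) > genome_len:
            continue
        seq[start:start + len(consensus)] = consensus
        motif_planted[k] = True
    genome = {chrom: seq.decode("ascii")}

    # --- gene sets, ChIP targets, PWM -------------------------------------
    hyper_genes = [gene_ids[i] for i in sorted(hyper_idx)]
    hypo_genes = [gene_ids[i] for i in sorted(hypo_idx)]
    sets = {"oxidative": hyper_genes, "glycolytic": hypo_genes}
    for d in range(5):
        members = rng.choice(gene_ids, size=min(20, n_genes), replace=False)
        sets[f"decoy_{d + 1}"] = sorted(members)
    gene_sets = GeneSetCollection(sets)
    n_chip = max(3, int(round(0.8 * len(hyper_genes))))
    chip_targets = sorted(rng.choice(hyper_genes, size=min(n_chip,
                          len(hyper_genes)), replace=False))
    pwm = MotifModel.from_consensus(config.motif_consensus,
                                    name=f"planted_{config.motif_consensus}")

    # --- truth table -------------------------------------------------------
    truth_genes = pd.DataFrame({
        "planted_direction": direction,
        "is_regulator_target": [i in set(target_is) for i in range(n_genes)],
        "regulator_sign": [target_signs.get(i, 0) for i in range(n_genes)],
        "is_regulator": [i == regulator_i for i in range(n_genes)],
    }, index=genes.index)
    truth_cpgs = pd.DataFrame({
        "planted_delta": planted_delta,
        "motif_planted": motif_planted,
    }, index=manifest.index)
    truth = TruthTable(truth_genes, truth_cpgs, gene_ids[regulator_i])

    # --- optional outlier drop (6v6 -> 5v6) --------------------------------
    if config.drop_case_outlier:
        dropped = case_ids[-1]
        samples = samples.drop_samples([dropped])
        beta = beta.subset_samples(samples.sample_ids)
        fpkm = fpkm.subset_samples(samples.sample_ids)
        log.info("dropped case sample %s (outlier-exclusion path)", dropped)

    return SyntheticCohort(config, samples, manifest.drop(columns="source_gene"),
                           beta, fpkm, genes, cgis, genome, gene_sets,
                           chip_targets, pwm, truth)


@dataclass
class RecoveryReport:
    per_class: pd.DataFrame       # n_planted, n_recovered, sensitivity
    sensitivity: float            # over all planted inverse genes
    false_discovery_fraction: float | None
    regulator_sign_recovery: float | None = None


def truth_recovery_report(truth: TruthTable, pairs: pd.DataFrame,
                          covariation: pd.DataFrame | None = None,
                          ) -> RecoveryReport:
    """Score pipeline outputs against the planted truth.

    ``pairs`` is the pair_inverse output; recovery of a planted gene
    additionally requires the pair's sign pattern to match its class
    (hyper_down: delta_beta > 0, log2fc < 0; hypo_up: the reverse).
    ``covariation`` (optional) is covariation_with_seed output, scored for
    planted-sign-class assignment of regulator targets.
    """
    universe = set(truth.genes.index)
    predicted_all = set(pairs["gene_id"])
    if predicted_all - universe:
        raise ValueError("pairs reference genes outside the truth universe")

    rows = []
    recovered_total, planted_total = 0, 0
    correct_genes: set[str] = set()
    for cls, sign in (("hyper_down", 1), ("hypo_up", -1)):
        planted = set(truth.genes.index[
            truth.genes["planted_direction"] == cls])
        ok = pairs[(np.sign(pairs["delta_beta"]) == sign)
                   & (np.sign(pairs["log2fc"]) == -sign)]
        hit = planted & set(ok["gene_id"])
        correct_genes |= hit
        rows.append((cls, len(planted), len(hit),
                     len(hit) / len(planted) if planted else np.nan))
        recovered_total += len(hit)
        planted_total += len(planted)
    per_class = pd.DataFrame(rows, columns=["class", "n_planted",
                                            "n_recovered", "sensitivity"]
                             ).set_index("class")
    sensitivity = recovered_total / planted_total if planted_total else np.nan
    fdf = (len(predicted_all - correct_genes) / len(predicted_all)
           if predicted_all else None)

    reg_recovery = None
    if covariation is not None:
        targets = truth.genes[truth.genes["is_regulator_target"]]
        if not set(targets.index) <= set(covariation.index) | {truth.regulator}:
            raise ValueError("covariation table misses regulator targets")
        good = 0
        for gid, row in targets.iterrows():
            want = "positive" if row["regulator_sign"] > 0 else "negative"
            if gid in covariation.index and \
                    covariation.loc[gid, "sign_class"] == want:
                good += 1
        reg_recovery = good / len(targets) if len(targets) else np.nan
    return RecoveryReport(per_class, float(sensitivity), fdf, reg_recovery)


def write_cohort(cohort: SyntheticCohort, outdir: str) -> dict[str, str]:
    """Write every pipeline input file plus the truth tables to ``outdir``.

    Returns a mapping of logical names to the paths written.
    """
    import os

    from . import ioformats as io

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "samples": os.path.join(outdir, "samples.tsv"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
        "beta": os.path.join(outdir, "beta.tsv"),
        "fpkm": os.path.join(outdir, "fpkm.tsv"),
        "genes": os.path.join(outdir, "genes.tsv"),
        "cgis": os.path.join(outdir, "cgis.bed"),
        "genome": os.path.join(outdir, "genome.fa"),
        "gene_sets": os.path.join(outdir, "genesets.gmt"),
        "chip_targets": os.path.join(outdir, "chip_targets.txt"),
        "pwm": os.path.join(outdir, "motif.pwm"),
        "truth_genes": os.path.join(outdir, "truth_genes.tsv"),
        "truth_cpgs": os.path.join(outdir, "truth_cpgs.tsv"),
    }
    io.write_sample_sheet(cohort.samples, paths["samples"])
    io.write_manifest(cohort.manifest, paths["manifest"])
    io.write_matrix(cohort.beta, paths["beta"])
    io.write_matrix(cohort.fpkm, paths["fpkm"])
    io.write_gene_models(cohort.genes, paths["genes"])
    io.write_regions(cohort.cgis, paths["cgis"])
    io.write_fasta(cohort.genome, paths["genome"])
    io.write_gmt(cohort.gene_sets, paths["gene_sets"])
    io.write_gene_list(cohort.chip_targets, paths["chip_targets"])
    io.write_pwm(cohort.pwm, paths["pwm"])
    cohort.truth.genes.to_csv(paths["truth_genes"], sep="\t")
    tc = cohort.truth.cpgs.copy()
    tc["motif_planted"] = tc["motif_planted"].astype(int)
    tc.to_csv(paths["truth_cpgs"], sep="\t")
    return paths


def null_config(seed: int = 0, n_genes: int = 420,
                cpgs_per_gene: int = 8) -> SimConfig:
    """A no-effect configuration for type-I calibration runs: zero planted
    methylation delta and zero methylation-expression coupling."""
    return SimConfig(n_genes=n_genes, cpgs_per_gene=cpgs_per_gene,
                     delta_beta=0.0, coupling_slope=0.0, seed=seed)
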