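"""Domain types and readers/writers for the external formats the pipeline touches.

Conventions
-----------
* All genomic coordinates are **1-based inclusive** internally.  BED input
  (0-based half-open) is converted at the boundary:
  ``start_internal = start_bed + 1``, ``end_internal = end_bed``.
* Matrices, sample sheets, manifests and gene models travel as TSV with a
  header row; lines starting with ``#`` are comments (writers emit a comment
  line recording tool version and parameters).
* Beta matrices hold per-CpG methylation fractions in [0, 1]; FPKM matrices
  hold non-negative expression values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__

log = logging.getLogger(__name__)

_TRUE_WORDS = {"yes", "true", "t", "y", "1"}
_FALSE_WORDS = {"no", "false", "f", "n", "0"}


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


class ValidationError(ValueError):
    """A file parsed but violates a domain invariant."""


def _comment_header(params: Mapping[str, object] | None = None) -> str:
    items = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    return f"# methcoupler v{__version__}" + (f" {items}" if items else "")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Sample IDs, case/control group labels and numeric covariates.

    ``table`` is indexed by sample ID and carries a ``group`` column with
    values ``case``/``control`` plus numeric covariate columns (booleans
    coded 1/0, missing values as NaN).  ``group_labels`` records the original
    (case, control) labels from the file, e.g. ``("ICM", "NICM")``.
    """

    table: pd.DataFrame
    group_labels: tuple[str, str] = ("case", "control")

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r}")
        if "group" not in self.table.columns:
            raise FormatError("sample sheet lacks a 'group' column")
        groups = set(self.table["group"])
        if groups != {"case", "control"}:
            raise FormatError(
                f"both groups must be represented; found {sorted(groups)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def case_ids(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "case"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "control"])

    @property
    def covariates(self) -> pd.DataFrame:
        return self.table.drop(columns="group")

    def drop_samples(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.table.drop(index=list(sample_ids)),
                           self.group_labels)


def _coerce_covariate(col: pd.Series) -> pd.Series:
    """Map Yes/No & TRUE/FALSE words to 1/0; everything else numeric or NaN."""
    def one(v: object) -> float:
        if isinstance(v, (int, float, np.integer, np.floating)):
            return float(v)
        s = str(v).strip().lower()
        if s in _TRUE_WORDS:
            return 1.0
        if s in _FALSE_WORDS:
            return 0.0
        try:
            return float(s)
        except ValueError:
            return np.nan  # unparseable becomes missing, never silently 0

    return col.map(one).astype(float)


def read_sample_sheet(path: str, case_label: str | None = None) -> SampleSheet:
    """Read a TSV sample sheet (first column sample ID, a ``group`` column,
    remaining columns covariates).

    ``case_label`` names which of the two group labels is the case group; by
    default the lexicographically smaller label is the case (so ICM/NICM maps
    ICM -> case).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if "group" not in df.columns:
        raise FormatError(f"{path}: missing 'group' column")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    labels = sorted(df["group"].unique())
    if len(labels) != 2:
        raise FormatError(
            f"{path}: expected exactly two group labels, found {labels}"
        )
    if case_label is None:
        case_label = labels[0]
    elif case_label not in labels:
        raise FormatError(f"{path}: case label {case_label!r} not in {labels}")
    control_label = next(l for l in labels if l != case_label)
    out = pd.DataFrame(index=df.index)
    out["group"] = np.where(df["group"] == case_label, "case", "control")
    for col in df.columns:
        if col != "group":
            out[col] = _coerce_covariate(df[col])
    return SampleSheet(out, (case_label, control_label))


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    case_l, control_l = sheet.group_labels
    df = sheet.table.copy()
    df["group"] = np.where(df["group"] == "case", case_l, control_l)
    with open(path, "w") as fh:
        fh.write(_comment_header({"format": "sample_sheet"}) + "\n")
        df.to_csv(fh, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# CpG manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str) -> pd.DataFrame:
    """Read a CpG probe manifest TSV: probe_id, chrom, pos (1-based cytosine
    position), snp_flag.  Returns a DataFrame indexed by probe_id."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     dtype={"chrom": str})
    for col in ("chrom", "pos", "snp_flag"):
        if col not in df.columns:
            raise FormatError(f"{path}: manifest missing column {col!r}")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate probe IDs")
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        raise ValidationError(f"{path}: probe positions must be >= 1")
    df["snp_flag"] = df["snp_flag"].map(
        lambda v: str(v).strip().lower() in _TRUE_WORDS)
    return df[["chrom", "pos", "snp_flag"]]


def write_manifest(manifest: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header({"format": "manifest"}) + "\n")
        out = manifest.copy()
        out["snp_flag"] = out["snp_flag"].astype(int)
        out.to_csv(fh, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str) -> pd.DataFrame:
    """Read gene models: gene_id, chrom, start, end (1-based inclusive),
    strand (+/-), tss; optional utr5_len / utr3_len columns."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     dtype={"chrom": str, "strand": str})
    for col in ("chrom", "start", "end", "strand", "tss"):
        if col not in df.columns:
            raise FormatError(f"{path}: gene models missing column {col!r}")
    for col in ("start", "end", "tss"):
        df[col] = df[col].astype(int)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene IDs")
    bad = df[df["start"] > df["end"]]
    if len(bad):
        raise ValidationError(f"{path}: start > end for {bad.index[0]!r}")
    bad = df[(df["tss"] < df["start"]) | (df["tss"] > df["end"])]
    if len(bad):
        raise ValidationError(f"{path}: tss outside span for {bad.index[0]!r}")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    return df


def write_gene_models(genes: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header({"format": "gene_models"}) + "\n")
        genes.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Omics matrix
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix; ``kind`` is 'beta' or 'fpkm'.

    beta values must lie in [0, 1]; fpkm values must be >= 0.
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "fpkm"):
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicated feature ID {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        if self.kind == "beta":
            bad = np.argwhere((vals < 0) | (vals > 1))
        else:
            bad = np.argwhere(vals < 0)
        if len(bad):
            i, j = bad[0]
            raise ValidationError(
                f"{self.kind} value {vals[i, j]!r} out of range for feature "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.data[list(sample_ids)], self.kind)


def read_matrix(path: str, kind: str) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix cell ({exc})") from exc
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or missing matrix cells")
    return OmicsMatrix(df, kind)


def write_matrix(matrix: OmicsMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header({"format": "matrix", "kind": matrix.kind})
                 + "\n")
        matrix.data.to_csv(fh, sep="\t", index_label="feature_id",
                           float_format="%.17g")


# ---------------------------------------------------------------------------
# BED regions (CGIs, ChIP peaks)
# ---------------------------------------------------------------------------

def read_regions(path: str) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals,
    sorted within each chromosome.  Columns: chrom, start, end, name."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED line with <3 fields")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            if s >= e:
                raise FormatError(
                    f"{path}:{ln}: empty or inverted interval ({s} >= {e})")
            name = parts[3] if len(parts) > 3 else f"region{ln}"
            rows.append((chrom, s + 1, e, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start", "end"],
                          kind="mergesort").reset_index(drop=True)


def write_regions(regions: pd.DataFrame, path: str) -> None:
    """Write 1-based inclusive intervals back out as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.name}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets; member lists are deduplicated, order-preserving."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = list(dict.fromkeys(genes))

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str,
              description: str = "methcoupler") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description] + genes) + "\n")


# ---------------------------------------------------------------------------
# Genome FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA into {chrom: uppercase sequence}.  N is allowed."""
    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(path, "fasta")}
    if not genome:
        raise FormatError(f"{path}: no FASTA records")
    return genome


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A 4 x L base-count matrix over A,C,G,T with a pseudocount.

    Scoring uses log2 odds against a uniform 0.25 background; the CpG bias of
    methylation-centred windows is handled downstream by background *selection*
    rather than by the scoring background.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValidationError(f"PWM {self.name!r}: counts must be 4 x L")
        if self.counts.shape[1] < 4:
            raise ValidationError(f"PWM {self.name!r}: length must be >= 4")
        if (self.counts < 0).any():
            raise ValidationError(f"PWM {self.name!r}: negative counts")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValidationError(
                f"PWM {self.name!r}: a column sums to zero")
        if self.pseudocount <= 0:
            raise ValidationError(f"PWM {self.name!r}: pseudocount must be > 0")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def probs(self) -> np.ndarray:
        c = self.counts + self.pseudocount
        return c / c.sum(axis=0, keepdims=True)

    def log_odds(self) -> np.ndarray:
        """4 x L log2(p_base / 0.25) scoring matrix."""
        return np.log2(self.probs() / 0.25)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(self.name, self.counts[::-1, ::-1],
                          self.pseudocount)

    @classmethod
    def from_consensus(cls, consensus: str, name: str | None = None,
                       weight: float = 10.0,
                       pseudocount: float = 0.5) -> "MotifModel":
        counts = np.zeros((4, len(consensus)))
        for j, base in enumerate(consensus.upper()):
            counts[ALPHABET.index(base), j] = weight
        return cls(name or consensus, counts, pseudocount)


def read_pwm(path: str) -> MotifModel:
    """Read a plain-text PWM: optional ``>name`` line, then 4 rows of counts
    in A, C, G, T order (each row may be prefixed with its base letter)."""
    name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                name = line[1:].strip()
                continue
            parts = line.replace(":", " ").split()
            if parts[0].upper() in ("A", "C", "G", "T"):
                parts = parts[1:]
            rows.append([float(x) for x in parts])
    if len(rows) != 4:
        raise FormatError(f"{path}: expected 4 count rows, found {len(rows)}")
    if len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path}: ragged PWM rows")
    return MotifModel(name or "pwm", np.array(rows))


def write_pwm(motif: MotifModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{motif.name}\n")
        for i, base in enumerate(ALPHABET):
            fh.write(base + "\t" +
                     "\t".join(f"{v:g}" for v in motif.counts[i]) + "\n")


# ---------------------------------------------------------------------------
# Plain gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        genes = [ln.strip() for ln in fh if ln.strip()
                 and not ln.startswith("#")]
    return list(dict.fromkeys(genes))


def write_gene_list(genes: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
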