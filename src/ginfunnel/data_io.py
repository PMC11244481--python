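"""Readers/writers for the standard formats the funnel touches.

All genomic coordinates are 1-based and inclusive (the VCF/GFF3 convention);
no half-open intervals are used anywhere in the package.  Genotypes are coded
as alt-allele dosage 0/1/2 with ``-1`` marking a missing call; phase is
ignored because every downstream stage uses additive coding only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

MISSING = -1


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class EmptyInputError(ValueError):
    """Raised when an input contains no usable records."""


@dataclass
class SnpRecord:
    id: str
    chrom: str
    pos: int  # 1-based bp
    ref: str
    alt: str

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class GenotypeMatrix:
    """Samples x biallelic SNPs, coded as alt-allele dosage.

    ``calls`` is an int8 array of shape (n_samples, n_snps) with values in
    {0, 1, 2, -1}; -1 is a missing call.
    """

    samples: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def dosage(self, impute: bool = False) -> np.ndarray:
        """Float dosage matrix with missing as NaN or per-SNP mean."""
        x = self.calls.astype(float)
        x[self.calls == MISSING] = np.nan
        if impute:
            col_mean = np.nanmean(x, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(x))
            x[idx] = col_mean[idx[1]]
        return x

    def allele_freq(self) -> np.ndarray:
        """Per-SNP alt-allele frequency, missing calls excluded."""
        x = self.dosage()
        return np.nanmean(x, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in idx],
            calls=self.calls[:, idx],
        )


@dataclass
class ExpressionMatrix:
    """Genes/transcripts x samples, non-negative normalized expression."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match gene/sample lists")
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = [g for g in gene_ids if g in set(self.genes)]
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = [pos[g] for g in wanted]
        return ExpressionMatrix(wanted, list(self.samples), self.values[idx])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.genes), list(sample_ids), self.values[:, idx])


@dataclass
class TraitTable:
    """Replicated trait measurements: (sample id, replicate id, content mg/g)."""

    records: pd.DataFrame  # columns: sample, rep, value

    def __post_init__(self) -> None:
        required = {"sample", "rep", "value"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"trait table needs columns {sorted(required)}")
        if (self.records["value"] < 0).any():
            raise ValueError("trait content must be >= 0")
        if self.records.empty:
            raise EmptyInputError("trait table is empty")

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.records["sample"]))

    def sample_means(self) -> pd.Series:
        return self.records.groupby("sample", sort=False)["value"].mean()


@dataclass
class GeneModel:
    id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    mrna: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.id}: strand must be + or -")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic records of a VCF into a dosage matrix.

    Multiallelic rows are skipped with a logged warning; positions are taken
    verbatim (1-based).  Raises FormatError when no GT field is present and
    EmptyInputError when no biallelic record survives.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    saw_record = False
    for v in vcf:
        saw_record = True
        if "GT" not in (v.FORMAT or []):
            raise FormatError(f"record {v.CHROM}:{v.POS} has no GT field")
        if len(v.ALT) != 1:
            log.warning("skipping multiallelic record %s:%d (ALT=%s)", v.CHROM, v.POS, ",".join(v.ALT))
            continue
        g = v.gt_types.astype(np.int8)  # gts012: 0,1,2; 3 = unknown
        g[g == 3] = MISSING
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        snps.append(SnpRecord(vid, v.CHROM, v.POS, v.REF, v.ALT[0]))
        cols.append(g)
    if not saw_record or not snps:
        raise EmptyInputError(f"no biallelic SNP records in {path}")
    calls = np.column_stack(cols)
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 that read_vcf round-trips losslessly."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in gm.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for j, s in enumerate(gm.snps):
            gts = "\t".join(_GT_STR[int(c)] for c in gm.calls[:, j])
            fh.write(f"{s.chrom}\t{s.pos}\t{s.id}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Expression / traits (TSV)

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-by-samples TSV (first column gene id, header sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty expression file {path}") from exc
    if df.empty or df.shape[1] == 0:
        raise EmptyInputError(f"no expression values in {path}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in {path}: {dups[:5]}")
    if df.isna().any().any():
        raise FormatError(f"ragged rows or missing values in {path}")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise FormatError(f"negative expression values in {path}")
    return ExpressionMatrix(genes=[str(g) for g in df.index], samples=[str(s) for s in df.columns], values=values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_traits(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "rep": str})
    return TraitTable(records=df)


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 / FASTA

def read_gff_genes(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneModel]:
    """Read gene features of a GFF3 file (coordinates kept 1-based inclusive)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr_map.get("ID") or attr_map.get("Name")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: gene feature lacks an ID attribute")
            genes.append(GeneModel(id=gid, chrom=chrom, start=start_i, end=end_i, strand=strand))
    return genes


def write_gff_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tginfunnel\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA id (to first whitespace) -> upper-case sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Generic tables

def write_table(records: pd.DataFrame, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a TSV with a fixed, documented column order."""
    df = records if columns is None else records.loc[:, list(columns)]
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
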