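"""Domain types and file I/O for the allelic imprinting pipeline.

All genomic coordinates are 0-based half-open (BED convention) in every
module; a gene's TSS is the 0-based position of its first transcribed base.
Chromosome names are taken verbatim from inputs — no "chr"-prefix
normalisation is attempted.

File formats handled here are deliberately simple and text-based:
BED3/BED6 for intervals, headered TSV for SNP tables, count matrices,
sample sheets and methylation calls, and a RepeatMasker-out-like TSV for
repeat annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("imprintseq")

VALID_STRANDS = ("+", "-", ".")
NUCLEOTIDES = ("A", "C", "G", "T")

#: chromosomes excluded from size-factor estimation (sex + mitochondrial)
NON_AUTOSOMES = frozenset(
    {"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"}
)


class ParseError(ValueError):
    """Malformed input file content (carries file and line context)."""


class SchemaError(ValueError):
    """A table is missing required columns or violates declared types."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def expanded(self, flank: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, max(0, self.start - flank), self.end + flank, self.strand
        )


@dataclass(frozen=True)
class Peak:
    id: str
    interval: GenomicInterval
    mark: str = "H3K4me3"
    tissue: str = "ExE"


@dataclass(frozen=True)
class Gene:
    """Gene model with TSS and exon structure.

    The TSS equals ``interval.start`` on the + strand and
    ``interval.end - 1`` on the - strand.
    """

    id: str
    name: str
    interval: GenomicInterval
    strand: str
    tss: int
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        expected_tss = (
            self.interval.start if self.strand == "+" else self.interval.end - 1
        )
        if self.tss != expected_tss:
            raise ValueError(
                f"gene {self.id}: tss {self.tss} inconsistent with strand "
                f"{self.strand} and interval {self.interval}"
            )
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.id}: exon outside gene body")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.id}: exons overlap or unsorted")
            prev_end = ex.end

    def exons_in_transcription_order(self) -> tuple[GenomicInterval, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


@dataclass(frozen=True)
class SNPRecord:
    """A strain-discriminating SNP: genome1 vs genome2 base at ``pos``."""

    chrom: str
    pos: int
    base_genome1: str
    base_genome2: str

    def __post_init__(self) -> None:
        if self.base_genome1 not in NUCLEOTIDES or self.base_genome2 not in NUCLEOTIDES:
            raise ValueError("SNP bases must be A/C/G/T")
        if self.base_genome1 == self.base_genome2:
            raise ValueError("SNP bases must differ between genomes")


@dataclass(frozen=True)
class ReadRecord:
    """Simplified aligned read carrying SNP-base observations and junctions.

    ``snp_obs`` is a tuple of (position, observed base); ``junctions`` a
    tuple of (donor, acceptor) splice coordinates with donor < acceptor
    in genomic order.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    snp_obs: tuple[tuple[int, str], ...] = ()
    junctions: tuple[tuple[int, int], ...] = ()
    sample_id: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        for pos, _base in self.snp_obs:
            if not (self.start <= pos < self.end):
                raise ValueError(
                    f"read {self.read_id}: SNP obs at {pos} outside "
                    f"[{self.start},{self.end})"
                )
        for donor, acceptor in self.junctions:
            if donor >= acceptor:
                raise ValueError(f"read {self.read_id}: junction donor >= acceptor")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class CrossDesign:
    """One sequencing sample of a hybrid cross.

    ``maternal_methylation_intact`` is False for matDKO samples, whose
    maternal genome is the admixed B6_129 strain.
    """

    sample_id: str
    maternal_strain: str
    paternal_strain: str
    maternal_methylation_intact: bool = True
    tissue: str = "ExE"
    assay: str = "H3K4me3"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.maternal_strain == self.paternal_strain:
            raise ValueError("maternal and paternal strains must differ")
        if not self.maternal_methylation_intact and self.maternal_strain != "B6_129":
            raise ValueError("matDKO samples must have maternal_strain B6_129")

    @property
    def cross_name(self) -> str:
        if self.maternal_strain == "B6_129":
            return "matDKO/CAST"
        return f"{self.maternal_strain}/{self.paternal_strain}"


@dataclass(frozen=True)
class MethylSite:
    """Per-CpG allele-resolved methylation call."""

    chrom: str
    pos: int
    allele: str  # maternal / paternal / unassigned
    meth_count: int
    unmeth_count: int
    sample_id: str
    stage: str

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError("methylation counts must be non-negative")
        if self.allele not in ("maternal", "paternal", "unassigned"):
            raise ValueError(f"invalid allele {self.allele!r}")

    @property
    def level(self) -> float | None:
        total = self.meth_count + self.unmeth_count
        return self.meth_count / total if total > 0 else None


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    repeat_family: str
    is_solo: bool = True

    def __post_init__(self) -> None:
        if not self.repeat_class or not self.repeat_family:
            raise ValueError("repeat class/family must be non-empty")

    @property
    def strand(self) -> str:
        return self.interval.strand


# ---------------------------------------------------------------------------
# Interval file I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 as 0-based half-open intervals; strand "." if absent."""
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def read_peaks_bed(path: str | Path, mark: str = "H3K4me3", tissue: str = "ExE") -> list[Peak]:
    """Read peaks from BED; column 4 is the peak id (generated if absent)."""
    peaks = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            pid = fields[3] if len(fields) >= 4 and fields[3] else f"peak_{lineno}"
            if pid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate peak id {pid!r}")
            seen.add(pid)
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                interval = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(Peak(pid, interval, mark=mark, tissue=tissue))
    return peaks


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as handle:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv_{i}"
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_repeats(path: str | Path) -> list[RepeatElement]:
    """Read a RepeatMasker-out-like TSV with a header row.

    Required columns: chrom, start, end, strand, repeat_name, repeat_class,
    repeat_family. Optional: is_solo (default True).
    """
    df = read_table(path, schema={
        "chrom": str, "start": int, "end": int, "strand": str,
        "repeat_name": str, "repeat_class": str, "repeat_family": str,
    }, optional={"is_solo": (bool, True)})
    out = []
    for row in df.itertuples(index=False):
        out.append(RepeatElement(
            GenomicInterval(row.chrom, row.start, row.end, row.strand),
            row.repeat_name, row.repeat_class, row.repeat_family,
            bool(row.is_solo),
        ))
    return out


def write_repeats(repeats: Iterable[RepeatElement], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.interval.chrom, "start": r.interval.start,
            "end": r.interval.end, "strand": r.interval.strand,
            "repeat_name": r.repeat_name, "repeat_class": r.repeat_class,
            "repeat_family": r.repeat_family, "is_solo": r.is_solo,
        }
        for r in repeats
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> list[Gene]:
    """Read the minimal gene-model TSV.

    Columns: gene_id, name, chrom, start, end, strand, tss, exons where
    exons is a comma-separated list of start-end pairs ("100-200,300-400").
    """
    df = read_table(path, schema={
        "gene_id": str, "name": str, "chrom": str, "start": int,
        "end": int, "strand": str, "tss": int, "exons": str,
    })
    genes = []
    for row in df.itertuples(index=False):
        exons = []
        if row.exons:
            for part in row.exons.split(","):
                s, _, e = part.partition("-")
                exons.append(GenomicInterval(row.chrom, int(s), int(e), row.strand))
        genes.append(Gene(
            row.gene_id, row.name,
            GenomicInterval(row.chrom, row.start, row.end, row.strand),
            row.strand, row.tss, tuple(exons),
        ))
    return genes


def write_genes(genes: Iterable[Gene], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.id, "name": g.name, "chrom": g.interval.chrom,
            "start": g.interval.start, "end": g.interval.end,
            "strand": g.strand, "tss": g.tss,
            "exons": ",".join(f"{e.start}-{e.end}" for e in g.exons),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic headered-TSV reader with schema enforcement
# ---------------------------------------------------------------------------

def read_table(path: str | Path, schema: dict[str, type],
               optional: dict[str, tuple[type, object]] | None = None) -> pd.DataFrame:
    """Read a headered TSV enforcing required columns and cell types.

    ``schema`` maps required column names to types; ``optional`` maps
    optional column names to (type, default).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, header row required") from exc
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    optional = optional or {}
    for col, (typ, default) in optional.items():
        if col not in df.columns:
            df[col] = str(default)
    for col, typ in list(schema.items()) + [(c, t) for c, (t, _d) in optional.items()]:
        if typ is str:
            continue
        try:
            if typ is bool:
                df[col] = df[col].map(_parse_bool)
            else:
                df[col] = df[col].map(typ)
        except (ValueError, KeyError) as exc:
            bad = _first_bad_row(df[col], typ)
            raise SchemaError(
                f"{path}: column {col!r} row {bad}: cannot parse as {typ.__name__}"
            ) from exc
    return df


def _parse_bool(value: str) -> bool:
    low = str(value).strip().lower()
    if low in ("true", "1", "yes", "t"):
        return True
    if low in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def _first_bad_row(series: pd.Series, typ: type) -> int:
    for idx, val in series.items():
        try:
            _parse_bool(val) if typ is bool else typ(val)
        except (ValueError, KeyError):
            return int(idx)
    return -1


# ---------------------------------------------------------------------------
# Specific tables
# ---------------------------------------------------------------------------

def read_snp_table(path: str | Path) -> list[SNPRecord]:
    df = read_table(path, schema={
        "chrom": str, "pos": int, "base_genome1": str, "base_genome2": str,
    })
    return [
        SNPRecord(r.chrom, r.pos, r.base_genome1, r.base_genome2)
        for r in df.itertuples(index=False)
    ]


def write_snp_table(snps: Iterable[SNPRecord], path: str | Path) -> None:
    rows = [
        {"chrom": s.chrom, "pos": s.pos,
         "base_genome1": s.base_genome1, "base_genome2": s.base_genome2}
        for s in snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[CrossDesign]:
    df = read_table(path, schema={
        "sample_id": str, "maternal_strain": str, "paternal_strain": str,
        "maternal_methylation_intact": bool, "tissue": str, "assay": str,
        "replicate": int,
    })
    return [
        CrossDesign(r.sample_id, r.maternal_strain, r.paternal_strain,
                    r.maternal_methylation_intact, r.tissue, r.assay, r.replicate)
        for r in df.itertuples(index=False)
    ]


def write_sample_sheet(samples: Iterable[CrossDesign], path: str | Path) -> None:
    rows = [
        {"sample_id": s.sample_id, "maternal_strain": s.maternal_strain,
         "paternal_strain": s.paternal_strain,
         "maternal_methylation_intact": s.maternal_methylation_intact,
         "tissue": s.tissue, "assay": s.assay, "replicate": s.replicate}
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read an allelic count table (region x sample x replicate)."""
    df = read_table(path, schema={
        "region_id": str, "sample_id": str, "replicate": int,
        "mat": int, "pat": int, "unassigned": int,
    }, optional={"region_kind": (str, "peak")})
    for col in ("mat", "pat", "unassigned"):
        if (df[col] < 0).any():
            bad = int(df.index[df[col] < 0][0])
            raise SchemaError(f"{path}: negative count in column {col!r} row {bad}")
    dup = df.duplicated(subset=["region_id", "sample_id", "replicate"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (region_id, sample_id, replicate) rows")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_methyl_sites(path: str | Path) -> list[MethylSite]:
    df = read_table(path, schema={
        "chrom": str, "pos": int, "allele": str, "meth": int,
        "unmeth": int, "sample_id": str, "stage": str,
    })
    return [
        MethylSite(r.chrom, r.pos, r.allele, r.meth, r.unmeth, r.sample_id, r.stage)
        for r in df.itertuples(index=False)
    ]


def write_methyl_sites(sites: Iterable[MethylSite], path: str | Path) -> None:
    rows = [
        {"chrom": s.chrom, "pos": s.pos, "allele": s.allele, "meth": s.meth_count,
         "unmeth": s.unmeth_count, "sample_id": s.sample_id, "stage": s.stage}
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reads(path: str | Path) -> list[ReadRecord]:
    """Read the SAM-lite TSV of simplified aligned reads.

    ``snp_obs`` cells look like "1234:A;1300:G" and ``junctions`` like
    "1500-2500;2600-3000"; empty strings mean none.
    """
    df = read_table(path, schema={
        "read_id": str, "chrom": str, "start": int, "end": int, "strand": str,
        "snp_obs": str, "junctions": str, "sample_id": str, "replicate": int,
    })
    reads = []
    for r in df.itertuples(index=False):
        snp_obs = tuple(
            (int(p.split(":")[0]), p.split(":")[1])
            for p in r.snp_obs.split(";") if p
        )
        junctions = tuple(
            (int(p.split("-")[0]), int(p.split("-")[1]))
            for p in r.junctions.split(";") if p
        )
        reads.append(ReadRecord(r.read_id, r.chrom, r.start, r.end, r.strand,
                                snp_obs, junctions, r.sample_id, r.replicate))
    return reads


def write_reads(reads: Iterable[ReadRecord], path: str | Path) -> None:
    rows = []
    for r in reads:
        rows.append({
            "read_id": r.read_id, "chrom": r.chrom, "start": r.start,
            "end": r.end, "strand": r.strand,
            "snp_obs": ";".join(f"{p}:{b}" for p, b in r.snp_obs),
            "junctions": ";".join(f"{d}-{a}" for d, a in r.junctions),
            "sample_id": r.sample_id, "replicate": r.replicate,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bedgraph(windows: Sequence[GenomicInterval], values: Sequence[float],
                   path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv, val in zip(windows, values):
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{val:.6g}\n")


def is_autosome(chrom: str) -> bool:
    return chrom not in NON_AUTOSOMES
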