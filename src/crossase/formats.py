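"""Readers and writers for the text formats the pipeline touches.

Conventions
-----------
* VCF and allele-count tables use 1-based positions; BED is 0-based
  half-open.  Everything in memory is 1-based; the conversion happens once,
  when the BED file is loaded.
* Only biallelic SNPs are modelled.  Multi-allelic records and indels are
  dropped (and counted) on VCF read, not decomposed: the informative-SNP
  rule and the paternal read ratio are defined for exactly two alleles.
* All files are UTF-8, tab-separated, LF-terminated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")

COUNT_COLUMNS = ("chrom", "pos", "pool_id", "count_ref", "count_alt")


class FormatError(ValueError):
    """A file violates the dialect this package documents."""


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's called genotype at a site, with its read depth."""

    sample: str
    gt: Genotype
    dp: int

    def __post_init__(self) -> None:
        if self.dp < 0:
            raise ValueError(f"negative depth {self.dp} for sample {self.sample}")
        if self.dp == 0 and self.gt is not Genotype.MISSING:
            raise ValueError(
                f"sample {self.sample}: dp=0 requires a missing genotype, got {self.gt.value}"
            )


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP with quality annotations and per-sample calls.

    ``fs`` is the phred-scaled Fisher-strand bias and ``qd`` the
    quality-by-depth annotation; both are non-negative and default to 0.0
    (i.e. unfiltered) when the source file does not annotate them.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    fs: float
    qd: float
    calls: tuple[GenotypeCall, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError(
                f"{self.chrom}:{self.pos}: alleles must be single bases, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt ({self.ref_allele})")
        if self.fs < 0 or self.qd < 0:
            raise ValueError(f"{self.chrom}:{self.pos}: FS and QD must be >= 0")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(c.sample for c in self.calls)

    def call(self, sample: str) -> GenotypeCall:
        for c in self.calls:
            if c.sample == sample:
                return c
        raise KeyError(f"no call for sample {sample!r} at {self.chrom}:{self.pos}")


@dataclass
class VcfData:
    """Result of :func:`read_vcf`: the retained sites plus bookkeeping.

    ``n_dropped + len(sites)`` equals the number of data lines in the file.
    """

    sites: list[VariantSite]
    samples: tuple[str, ...]
    n_dropped: int
    n_data_lines: int


_GT_MAP = {
    ("0", "0"): Genotype.HOM_REF,
    ("0", "1"): Genotype.HET,
    ("1", "0"): Genotype.HET,
    ("1", "1"): Genotype.HOM_ALT,
}


def _parse_gt(token: str, lineno: int, sample: str) -> Genotype | None:
    """Return the genotype, or None for a missing call ('./.' or '.')."""
    if token in (".", "./."):
        return None
    parts = tuple(token.split("/"))
    gt = _GT_MAP.get(parts)
    if gt is None:
        raise FormatError(
            f"line {lineno}: malformed GT {token!r} for sample {sample!r} "
            "(expected 0/0, 0/1, 1/0, 1/1 or ./.)"
        )
    return gt


def read_vcf(path: str | Path, required_samples: Sequence[str]) -> VcfData:
    """Read a minimal VCF 4.2 file, keeping biallelic SNP records only.

    Multi-allelic and indel records are dropped and counted.  Sample order
    in every returned site follows ``required_samples``.  Missing FS or QD
    annotations parse as 0.0 with a logged warning.

    Raises
    ------
    FormatError
        If a required sample column is absent (the error names the sample)
        or a GT string is malformed (the error carries the line number).
    """
    path = Path(path)
    sites: list[VariantSite] = []
    sample_index: dict[str, int] = {}
    n_dropped = 0
    n_data_lines = 0
    n_missing_fs = 0
    n_missing_qd = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                file_samples = cols[9:]
                for s in required_samples:
                    if s not in file_samples:
                        raise FormatError(
                            f"{path.name}: required sample {s!r} not in VCF header "
                            f"(found: {', '.join(file_samples) or 'none'})"
                        )
                sample_index = {s: 9 + file_samples.index(s) for s in required_samples}
                continue
            if line.startswith("#"):
                continue
            if not sample_index:
                raise FormatError(f"{path.name}: data line {lineno} before #CHROM header")
            n_data_lines += 1
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(f"line {lineno}: expected >= 10 columns, got {len(fields)}")
            chrom, pos_s, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if not (len(ref) == 1 and ref in BASES and len(alt) == 1 and alt in BASES and ref != alt):
                n_dropped += 1
                continue
            info = dict(
                kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
            )
            if "FS" in info:
                fs = float(info["FS"])
            else:
                fs, n_missing_fs = 0.0, n_missing_fs + 1
            if "QD" in info:
                qd = float(info["QD"])
            else:
                qd, n_missing_qd = 0.0, n_missing_qd + 1
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise FormatError(f"line {lineno}: FORMAT lacks GT") from None
            dp_idx = fmt.index("DP") if "DP" in fmt else None
            calls = []
            for sample in required_samples:
                tokens = fields[sample_index[sample]].split(":")
                gt = _parse_gt(tokens[gt_idx], lineno, sample)
                dp = 0
                if dp_idx is not None and dp_idx < len(tokens) and tokens[dp_idx] != ".":
                    try:
                        dp = int(tokens[dp_idx])
                    except ValueError:
                        raise FormatError(
                            f"line {lineno}: malformed DP {tokens[dp_idx]!r} for sample {sample!r}"
                        ) from None
                if gt is None or dp == 0:
                    calls.append(GenotypeCall(sample, Genotype.MISSING, 0))
                else:
                    calls.append(GenotypeCall(sample, gt, dp))
            sites.append(
                VariantSite(chrom, int(pos_s), ref, alt, fs, qd, tuple(calls))
            )
    if n_missing_fs or n_missing_qd:
        logger.warning(
            "%s: %d records missing FS and %d missing QD; parsed as 0.0 (not filtered)",
            path.name, n_missing_fs, n_missing_qd,
        )
    if n_dropped:
        logger.info("%s: dropped %d non-biallelic-SNP records", path.name, n_dropped)
    return VcfData(sites, tuple(required_samples), n_dropped, n_data_lines)


_GT_STR = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled Fisher strand bias">
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(path: str | Path, sites: Iterable[VariantSite], samples: Sequence[str]) -> None:
    """Write sites in the minimal VCF 4.2 dialect :func:`read_vcf` parses."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for site in sites:
            cols = [c.sample for c in site.calls]
            if tuple(cols) != tuple(samples):
                raise ValueError(f"{site.chrom}:{site.pos}: sample order {cols} != {list(samples)}")
            sample_fields = "\t".join(f"{_GT_STR[c.gt]}:{c.dp}" for c in site.calls)
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t{site.alt_allele}\t.\t.\t"
                f"FS={site.fs:.2f};QD={site.qd:.2f}\tGT:DP\t{sample_fields}\n"
            )


def _union_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for start, end in ivs[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(x) for x in merged]


class GeneAnnotation:
    """Gene-indexed exon intervals with point queries.

    Exon intervals are unioned per gene on construction; ``query`` answers
    "which genes' exons contain this 1-based position" via an interval tree.
    """

    def __init__(self, exons: Mapping[str, Mapping[str, list[tuple[int, int]]]]):
        # exons: gene_id -> chrom -> list of (start, end), 0-based half-open
        self.genes: dict[str, dict[str, list[tuple[int, int]]]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for gene_id, by_chrom in exons.items():
            self.genes[gene_id] = {}
            for chrom, ivs in by_chrom.items():
                merged = _union_intervals(list(ivs))
                self.genes[gene_id][chrom] = merged
                tree = self._trees.setdefault(chrom, IntervalTree())
                for start, end in merged:
                    tree.addi(start, end, gene_id)

    def query(self, chrom: str, pos: int) -> frozenset[str]:
        """Genes whose unioned exons contain 1-based position ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return frozenset()
        return frozenset(iv.data for iv in tree[pos - 1])

    def __len__(self) -> int:
        return len(self.genes)


def read_bed(path: str | Path) -> GeneAnnotation:
    """Read a BED4+ exon annotation (0-based half-open) into a GeneAnnotation."""
    path = Path(path)
    exons: dict[str, dict[str, list[tuple[int, int]]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"line {lineno}: BED needs >= 4 columns, got {len(fields)}")
            chrom, start_s, end_s, gene_id = fields[0], fields[1], fields[2], fields[3]
            start, end = int(start_s), int(end_s)
            if start < 0 or start >= end:
                raise FormatError(f"line {lineno}: invalid interval [{start}, {end})")
            exons.setdefault(gene_id, {}).setdefault(chrom, []).append((start, end))
    return GeneAnnotation(exons)


def write_bed(path: str | Path, records: Iterable[tuple[str, int, int, str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for chrom, start, end, gene_id in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene_id}\n")


@dataclass(frozen=True)
class AlleleCountRecord:
    """RNA read counts for one SNP in one offspring pool, keyed by base."""

    chrom: str
    pos: int
    pool_id: str
    count_ref: int
    count_alt: int

    def __post_init__(self) -> None:
        if self.count_ref < 0 or self.count_alt < 0:
            raise ValueError(
                f"{self.chrom}:{self.pos} pool {self.pool_id}: negative counts"
            )


def read_counts(path: str | Path) -> list[AlleleCountRecord]:
    """Read an allele-count TSV (columns chrom, pos, pool_id, count_ref, count_alt)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != list(COUNT_COLUMNS):
        raise FormatError(
            f"{path.name}: expected columns {list(COUNT_COLUMNS)}, got {list(df.columns)}"
        )
    records: list[AlleleCountRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for row in df.itertuples(index=False):
        try:
            pos = int(row.pos)
            count_ref = int(row.count_ref)
            count_alt = int(row.count_alt)
        except ValueError as exc:
            raise FormatError(f"{path.name}: non-integer field: {exc}") from None
        if count_ref < 0 or count_alt < 0:
            raise FormatError(f"{path.name}: negative count at {row.chrom}:{pos}")
        key = (row.chrom, pos, row.pool_id)
        if key in seen:
            raise FormatError(f"{path.name}: duplicate record for {key}")
        seen.add(key)
        records.append(AlleleCountRecord(row.chrom, pos, row.pool_id, count_ref, count_alt))
    return records


def write_counts(path: str | Path, records: Iterable[AlleleCountRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(COUNT_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pool_id}\t{r.count_ref}\t{r.count_alt}\n")
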