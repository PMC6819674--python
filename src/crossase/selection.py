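"""Site filtering and informative-SNP selection.

A SNP is *informative* when each parent (strategy I) or each same-breed
joint sample (strategy II) is homozygous and the two breeds carry different
alleles, so that every F1 offspring is heterozygous with a known parental
origin for each allele.

Filters applied before selection, in a fixed attribution order:

1. strand bias: remove FS > 30 (phred-scaled Fisher strand);
2. weak support: remove QD < 2 (quality by depth);
3. SNP clusters: remove any SNP that lies, together with >= 2 other
   quality-passing SNPs, inside a 35 bp window (inclusive span,
   i.e. last - first <= 34);
4. low depth: remove sites where any relevant sample has DP < 3
   (strategy I, individual parents) or DP < 6 (strategy II, joint samples).

Boundary semantics follow the inequalities strictly: FS = 30, QD = 2 and
DP = 3 (or 6) all pass.  A site failing several rules is counted once,
under the first failing rule in the order above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .design import BREEDS, KNP, LANDRACE, CrossDesign
from .formats import GeneAnnotation, Genotype, VariantSite

logger = logging.getLogger(__name__)

FILTER_RULES = ("fs", "qd", "cluster", "dp")


class Strategy(str, Enum):
    """Mapping strategy: individual parents (I) or same-breed joint (II)."""

    I = "I"
    II = "II"


@dataclass(frozen=True)
class FilterConfig:
    fs_max: float = 30.0
    qd_min: float = 2.0
    cluster_size: int = 3
    cluster_window_bp: int = 35
    dp_min_individual: int = 3
    dp_min_joint: int = 6

    def __post_init__(self) -> None:
        for name in ("fs_max", "qd_min", "cluster_size", "cluster_window_bp",
                     "dp_min_individual", "dp_min_joint"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def dp_min(self, strategy: Strategy) -> int:
        return self.dp_min_individual if strategy is Strategy.I else self.dp_min_joint


@dataclass
class FilterResult:
    kept: list[VariantSite]
    removed: dict[str, int]

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def _check_sorted(sites: Sequence[VariantSite]) -> None:
    """Require chrom-contiguous blocks with strictly increasing positions."""
    seen: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = 0
    for s in sites:
        if s.chrom != prev_chrom:
            if s.chrom in seen:
                raise ValueError(
                    f"sites not sorted: chromosome {s.chrom} appears in two blocks"
                )
            seen.add(s.chrom)
            prev_chrom, prev_pos = s.chrom, 0
        if s.pos <= prev_pos:
            raise ValueError(
                f"sites not sorted at {s.chrom}:{s.pos} (previous position {prev_pos})"
            )
        prev_pos = s.pos


def clustered_indices(positions: Sequence[int], size: int, window_bp: int) -> set[int]:
    """Indices of positions lying in any run of >= ``size`` positions whose
    inclusive span fits a ``window_bp``-base window (last - first <= window_bp - 1).

    ``positions`` must be sorted ascending (one chromosome at a time).
    """
    out: set[int] = set()
    n = len(positions)
    j = 0
    for i in range(n):
        if j < i:
            j = i
        while j + 1 < n and positions[j + 1] - positions[i] <= window_bp - 1:
            j += 1
        if j - i + 1 >= size:
            out.update(range(i, j + 1))
    return out


def filter_sites(
    sites: Sequence[VariantSite],
    config: FilterConfig | None = None,
    strategy: Strategy = Strategy.I,
) -> FilterResult:
    """Apply the quality, cluster and depth filters; see the module docstring.

    The cluster rule is evaluated per chromosome on the set of sites that
    pass the FS and QD filters.  Filtering is idempotent.
    """
    config = config or FilterConfig()
    _check_sorted(sites)
    removed = {rule: 0 for rule in FILTER_RULES}

    quality_pass: list[VariantSite] = []
    for s in sites:
        if s.fs > config.fs_max:
            removed["fs"] += 1
        elif s.qd < config.qd_min:
            removed["qd"] += 1
        else:
            quality_pass.append(s)

    clustered: set[int] = set()
    start = 0
    for i in range(1, len(quality_pass) + 1):
        if i == len(quality_pass) or quality_pass[i].chrom != quality_pass[start].chrom:
            block = [s.pos for s in quality_pass[start:i]]
            for k in clustered_indices(block, config.cluster_size, config.cluster_window_bp):
                clustered.add(start + k)
            start = i
    removed["cluster"] = len(clustered)

    dp_min = config.dp_min(strategy)
    kept: list[VariantSite] = []
    for i, s in enumerate(quality_pass):
        if i in clustered:
            continue
        if any(c.dp < dp_min for c in s.calls):
            removed["dp"] += 1
        else:
            kept.append(s)
    return FilterResult(kept, removed)


@dataclass(frozen=True)
class ExonicSite:
    """A filtered site annotated with the genes whose exons contain it."""

    site: VariantSite
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("ExonicSite requires at least one gene id")


def assign_exonic(
    sites: Sequence[VariantSite], annotation: GeneAnnotation
) -> tuple[list[ExonicSite], int]:
    """Keep sites inside (unioned) exons, attaching gene ids; returns
    the kept sites and the number dropped as non-exonic.

    A SNP inside the exons of two overlapping genes is kept with both gene
    ids and later contributes to both genes' ASE evaluation.
    """
    kept: list[ExonicSite] = []
    n_dropped = 0
    n_multi = 0
    for s in sites:
        genes = annotation.query(s.chrom, s.pos)
        if genes:
            if len(genes) > 1:
                n_multi += 1
            kept.append(ExonicSite(s, genes))
        else:
            n_dropped += 1
    if n_multi:
        logger.info("%d exonic SNPs fall in more than one gene", n_multi)
    return kept, n_dropped


@dataclass(frozen=True)
class InformativeSNP:
    """A breed-diagnostic exonic SNP with its breed-to-allele map.

    ``ref_allele`` is retained so that base-keyed count tables can be
    oriented to parental origin downstream.
    """

    chrom: str
    pos: int
    gene_ids: frozenset[str]
    ref_allele: str
    knp_allele: str
    landrace_allele: str
    strategy: Strategy

    def __post_init__(self) -> None:
        if self.knp_allele == self.landrace_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: breed alleles must differ")
        if self.ref_allele not in (self.knp_allele, self.landrace_allele):
            raise ValueError(f"{self.chrom}:{self.pos}: ref allele is neither breed allele")

    @property
    def alt_allele(self) -> str:
        return self.knp_allele if self.landrace_allele == self.ref_allele else self.landrace_allele

    def allele_of(self, breed: str) -> str:
        if breed == KNP:
            return self.knp_allele
        if breed == LANDRACE:
            return self.landrace_allele
        raise KeyError(f"unknown breed {breed!r}")


def _hom_allele(site: VariantSite, sample: str) -> str | None:
    """The sample's homozygous base, or None for het/missing calls."""
    gt = site.call(sample).gt
    if gt is Genotype.HOM_REF:
        return site.ref_allele
    if gt is Genotype.HOM_ALT:
        return site.alt_allele
    return None


def select_informative(
    exonic_sites: Sequence[ExonicSite],
    strategy: Strategy,
    breed_of_sample: Mapping[str, str],
    require_breed_agreement: bool = True,
    design: CrossDesign | None = None,
) -> list[InformativeSNP]:
    """Select SNPs homozygous within each breed but different between breeds.

    Strategy I inspects the four individual parents, strategy II the two
    joint same-breed samples.  Heterozygous or missing genotypes disqualify
    a site.  With ``require_breed_agreement=False`` (strategy I only, needs
    ``design``), the condition is relaxed to "dam and sire differ within
    each cross"; sites whose two same-breed parents are homozygous for
    different alleles then satisfy it but admit no single breed-to-allele
    map, so they are excluded and counted (for a biallelic SNP the two
    readings otherwise select the same set).
    """
    out: list[InformativeSNP] = []
    n_crossed = 0
    for ex in exonic_sites:
        site = ex.site
        for c in site.calls:
            if c.sample not in breed_of_sample:
                raise ValueError(
                    f"sample-to-breed map incomplete: no breed for sample {c.sample!r}"
                )
        by_breed: dict[str, list[str | None]] = {b: [] for b in BREEDS}
        for c in site.calls:
            by_breed[breed_of_sample[c.sample]].append(_hom_allele(site, c.sample))
        expected = 2 if strategy is Strategy.I else 1
        for b in BREEDS:
            if len(by_breed[b]) != expected:
                raise ValueError(
                    f"strategy {strategy.value} expects {expected} sample(s) per breed, "
                    f"got {len(by_breed[b])} for {b} at {site.chrom}:{site.pos}"
                )
        if any(a is None for alleles in by_breed.values() for a in alleles):
            continue
        knp_alleles = set(by_breed[KNP])
        lr_alleles = set(by_breed[LANDRACE])
        if len(knp_alleles) == 1 and len(lr_alleles) == 1:
            knp, lr = knp_alleles.pop(), lr_alleles.pop()
            if knp != lr:
                out.append(
                    InformativeSNP(site.chrom, site.pos, ex.gene_ids,
                                   site.ref_allele, knp, lr, strategy)
                )
        elif not require_breed_agreement and strategy is Strategy.I:
            if design is None:
                raise ValueError("require_breed_agreement=False needs a CrossDesign")
            per_cross_diff = all(
                _hom_allele(site, c.dam) != _hom_allele(site, c.sire)
                for c in design.crosses
            )
            if per_cross_diff:
                n_crossed += 1
    if n_crossed:
        logger.warning(
            "%d sites differ within each cross but have no consistent "
            "breed-to-allele map; excluded", n_crossed,
        )
    return out


@dataclass(frozen=True)
class OverlapSummary:
    count_i: int
    count_ii: int
    shared: int
    unique_i: int
    unique_ii: int


def compare_strategies(
    set_i: Iterable[InformativeSNP], set_ii: Iterable[InformativeSNP]
) -> OverlapSummary:
    """Overlap of the two strategies' informative SNPs, keyed by (chrom, pos)."""
    keys_i = {(s.chrom, s.pos) for s in set_i}
    keys_ii = {(s.chrom, s.pos) for s in set_ii}
    shared = len(keys_i & keys_ii)
    return OverlapSummary(
        count_i=len(keys_i),
        count_ii=len(keys_ii),
        shared=shared,
        unique_i=len(keys_i) - shared,
        unique_ii=len(keys_ii) - shared,
    )


INFORMATIVE_COLUMNS = (
    "chrom", "pos", "gene_ids", "ref_allele", "knp_allele", "landrace_allele", "strategy"
)


def write_informative(path: str | Path, snps: Iterable[InformativeSNP]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(INFORMATIVE_COLUMNS) + "\n")
        for s in snps:
            genes = ",".join(sorted(s.gene_ids))
            fh.write(
                f"{s.chrom}\t{s.pos}\t{genes}\t{s.ref_allele}\t{s.knp_allele}\t"
                f"{s.landrace_allele}\t{s.strategy.value}\n"
            )


def read_informative(path: str | Path) -> list[InformativeSNP]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != list(INFORMATIVE_COLUMNS):
        raise ValueError(f"unexpected informative-SNP columns: {list(df.columns)}")
    return [
        InformativeSNP(
            row.chrom, int(row.pos), frozenset(row.gene_ids.split(",")),
            row.ref_allele, row.knp_allele, row.landrace_allele, Strategy(row.strategy),
        )
        for row in df.itertuples(index=False)
    ]


def write_filter_report(path: str | Path, result: FilterResult, n_input: int) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("stage\tcount\n")
        fh.write(f"input\t{n_input}\n")
        for rule in FILTER_RULES:
            fh.write(f"removed_{rule}\t{result.removed[rule]}\n")
        fh.write(f"kept\t{len(result.kept)}\n")
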