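"""Paternal read ratios, the G-test of allelic balance, and per-gene
cross-pattern classification.

For every informative SNP the RNA reads of an offspring pool are oriented
by parental origin: the sire breed's allele is paternal.  The paternal
read ratio of a pool is

    ratio = paternal reads / (paternal + maternal reads),

0.5 under balanced biallelic expression.  A gene is a candidate for
allele-biased expression when any pool's ratio is <= 0.3 or >= 0.7
(boundaries inclusive).  Deviation from 1:1 is tested with the likelihood
ratio (G) goodness-of-fit statistic

    G = 2 * sum_i O_i ln(O_i / E_i),   E_i = n/2,

referred to a chi-square upper tail.  Per-pool G statistics add, so the
gene-level default sums G over pools with reads and uses df = number of
such pools; this detects a deviation in any direction in any pool, which
is what distinguishes allele-dominant genes (opposite deviations in the
two crosses) from a pooled test where those deviations would cancel.

Pattern calls use per-cross mean ratios (the male and female pools of a
cross are replicates): both >= 0.7 -> paternal_biased; both <= 0.3 ->
maternal_biased; opposite sides -> allele_dominant (the "same allele
regardless of parent" pattern); both strictly inside (0.3, 0.7) ->
biallelic; anything else -> inconsistent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import chi2

from .design import CrossDesign
from .formats import AlleleCountRecord
from .selection import InformativeSNP

logger = logging.getLogger(__name__)

PATERNAL_BIASED = "paternal_biased"
MATERNAL_BIASED = "maternal_biased"
ALLELE_DOMINANT = "allele_dominant"
BIALLELIC = "biallelic"
INCONSISTENT = "inconsistent"
INSUFFICIENT_DATA = "insufficient_data"

PATTERNS = (
    PATERNAL_BIASED, MATERNAL_BIASED, ALLELE_DOMINANT,
    BIALLELIC, INCONSISTENT, INSUFFICIENT_DATA,
)


class InsufficientDataError(ValueError):
    """Raised when a statistic is requested for zero observed reads."""


@dataclass(frozen=True)
class OrientedCount:
    """Parent-of-origin read counts for one SNP, pool and gene."""

    chrom: str
    pos: int
    gene_id: str
    pool_id: str
    paternal_count: int
    maternal_count: int

    def __post_init__(self) -> None:
        if self.paternal_count < 0 or self.maternal_count < 0:
            raise ValueError("oriented counts must be >= 0")


def orient_counts(
    counts: Sequence[AlleleCountRecord],
    informative: Iterable[InformativeSNP],
    design: CrossDesign,
) -> tuple[list[OrientedCount], int]:
    """Assign base-keyed counts to paternal/maternal origin.

    The sire breed's allele at the SNP is the paternal allele of the pool's
    cross.  Counts at SNPs absent from the informative list are dropped and
    counted.  A SNP assigned to several genes yields one oriented record
    per gene.
    """
    by_pos: dict[tuple[str, int], InformativeSNP] = {
        (s.chrom, s.pos): s for s in informative
    }
    oriented: list[OrientedCount] = []
    n_dropped = 0
    for rec in counts:
        snp = by_pos.get((rec.chrom, rec.pos))
        if snp is None:
            n_dropped += 1
            continue
        sire_breed = design.sire_breed(rec.pool_id)  # KeyError -> caller bug; raises
        paternal_base = snp.allele_of(sire_breed)
        if paternal_base == snp.ref_allele:
            pat, mat = rec.count_ref, rec.count_alt
        else:
            pat, mat = rec.count_alt, rec.count_ref
        for gene_id in sorted(snp.gene_ids):
            oriented.append(
                OrientedCount(rec.chrom, rec.pos, gene_id, rec.pool_id, pat, mat)
            )
    if n_dropped:
        logger.info("dropped %d count records at non-informative SNPs", n_dropped)
    return oriented, n_dropped


def paternal_read_ratio(paternal_count: int, maternal_count: int) -> float | None:
    """paternal / (paternal + maternal); None when both counts are zero.

    The maternal read ratio is 1 minus this value by construction.
    """
    if paternal_count < 0 or maternal_count < 0:
        raise ValueError("counts must be >= 0")
    total = paternal_count + maternal_count
    if total == 0:
        return None
    return paternal_count / total


def flag_candidate(
    ratios: Iterable[float | None], lo: float = 0.3, hi: float = 0.7
) -> bool | None:
    """True iff any defined ratio is <= lo or >= hi; None if none is defined.

    The boundaries are inclusive: a pool sitting exactly on 0.3 or 0.7
    still flags the gene.
    """
    defined = [r for r in ratios if r is not None]
    if not defined:
        return None
    return any(r <= lo or r >= hi for r in defined)


def g_test(
    paternal_count: int, maternal_count: int, williams: bool = False
) -> tuple[float, float]:
    """G goodness-of-fit statistic against a 1:1 expectation, with its
    chi-square (df=1) upper-tail p-value.

    Zero-count cells contribute 0 to the sum.  With ``williams=True`` the
    statistic is divided by the Williams correction q = 1 + 1/(2n) before
    the tail computation.
    """
    total = paternal_count + maternal_count
    if total < 1:
        raise InsufficientDataError("G-test needs at least one read")
    expected = total / 2.0
    g = 2.0 * sum(
        o * math.log(o / expected) for o in (paternal_count, maternal_count) if o > 0
    )
    g = max(g, 0.0)
    if williams:
        g /= 1.0 + 1.0 / (2.0 * total)
    return g, float(chi2.sf(g, df=1))


@dataclass
class GeneASEResult:
    gene_id: str
    n_snps: int
    pool_counts: dict[str, tuple[int, int]]  # pool_id -> (paternal, maternal)
    ratios: dict[str, float | None]
    g_statistic: float
    df: int
    p_value: float
    candidate: bool | None
    pattern: str
    significant: bool
    q_value: float | None = None


def _cross_mean_ratio(ratios: Sequence[float | None]) -> float | None:
    defined = [r for r in ratios if r is not None]
    if not defined:
        return None
    return sum(defined) / len(defined)


def _classify(r1: float | None, r2: float | None, lo: float, hi: float) -> str:
    if r1 is None or r2 is None:
        return INCONSISTENT
    if r1 >= hi and r2 >= hi:
        return PATERNAL_BIASED
    if r1 <= lo and r2 <= lo:
        return MATERNAL_BIASED
    if (r1 >= hi and r2 <= lo) or (r1 <= lo and r2 >= hi):
        return ALLELE_DOMINANT
    if lo < r1 < hi and lo < r2 < hi:
        return BIALLELIC
    return INCONSISTENT


def evaluate_gene(
    gene_id: str,
    oriented: Sequence[OrientedCount],
    design: CrossDesign,
    alpha: float = 0.05,
    lo: float = 0.3,
    hi: float = 0.7,
    per_snp: bool = False,
    williams: bool = False,
) -> GeneASEResult:
    """Summarise one gene's oriented counts into ratios, G, p and a pattern.

    Counts are summed per pool over the gene's SNPs.  With ``per_snp=True``
    the G statistic is instead summed over (pool, SNP) cells with reads,
    with matching degrees of freedom.
    """
    if not oriented:
        raise ValueError(f"gene {gene_id}: no oriented counts")
    pool_ids = design.pool_ids
    sums: dict[str, list[int]] = {p: [0, 0] for p in pool_ids}
    snps: set[tuple[str, int]] = set()
    for rec in oriented:
        if rec.pool_id not in sums:
            raise KeyError(f"pool {rec.pool_id!r} not in design")
        sums[rec.pool_id][0] += rec.paternal_count
        sums[rec.pool_id][1] += rec.maternal_count
        snps.add((rec.chrom, rec.pos))
    pool_counts = {p: (s[0], s[1]) for p, s in sums.items()}
    ratios = {p: paternal_read_ratio(*pool_counts[p]) for p in pool_ids}
    total_reads = sum(pat + mat for pat, mat in pool_counts.values())

    if total_reads == 0:
        return GeneASEResult(gene_id, len(snps), pool_counts, ratios,
                             0.0, 0, 1.0, None, INSUFFICIENT_DATA, False)

    if per_snp:
        cells = [
            (rec.paternal_count, rec.maternal_count)
            for rec in oriented
            if rec.paternal_count + rec.maternal_count > 0
        ]
    else:
        cells = [c for c in pool_counts.values() if c[0] + c[1] > 0]
    g = sum(g_test(pat, mat, williams=williams)[0] for pat, mat in cells)
    df = len(cells)
    p_value = float(chi2.sf(g, df=df)) if df > 0 else 1.0

    candidate = flag_candidate(ratios.values(), lo=lo, hi=hi)
    c1, c2 = design.crosses
    r1 = _cross_mean_ratio([ratios[p] for p in c1.pool_ids])
    r2 = _cross_mean_ratio([ratios[p] for p in c2.pool_ids])
    pattern = _classify(r1, r2, lo, hi)
    return GeneASEResult(
        gene_id, len(snps), pool_counts, ratios, g, df, p_value,
        candidate, pattern, bool(p_value < alpha),
    )


@dataclass
class AseRunResult:
    results: list[GeneASEResult]
    summary: dict
    n_noninformative_dropped: int


def run_ase(
    informative: Sequence[InformativeSNP],
    counts: Sequence[AlleleCountRecord],
    design: CrossDesign,
    alpha: float = 0.05,
    lo: float = 0.3,
    hi: float = 0.7,
    per_snp: bool = False,
    williams: bool = False,
    bh_correction: bool = False,
) -> AseRunResult:
    """Orient counts, evaluate every gene with an informative SNP in the
    count tables, and tabulate pattern/significance summaries.

    With ``bh_correction=True``, Benjamini-Hochberg q-values are attached
    and ``significant`` is re-defined as q < alpha.
    """
    oriented, n_dropped = orient_counts(counts, informative, design)
    by_gene: dict[str, list[OrientedCount]] = {}
    for rec in oriented:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    results = [
        evaluate_gene(gene_id, recs, design, alpha=alpha, lo=lo, hi=hi,
                      per_snp=per_snp, williams=williams)
        for gene_id, recs in sorted(by_gene.items())
    ]
    if bh_correction and results:
        from statsmodels.stats.multitest import multipletests

        reject, qvals, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="fdr_bh"
        )
        for r, q, rej in zip(results, qvals, reject):
            r.q_value = float(q)
            r.significant = bool(rej)
    summary = {
        "n_genes": len(results),
        "n_candidate": sum(1 for r in results if r.candidate),
        "n_significant": sum(1 for r in results if r.significant),
        "patterns": {
            pat: sum(1 for r in results if r.pattern == pat) for pat in PATTERNS
        },
        "n_noninformative_count_records": n_dropped,
    }
    return AseRunResult(results, summary, n_dropped)


def results_frame(results: Sequence[GeneASEResult], design: CrossDesign) -> pd.DataFrame:
    """Tabulate results, one row per gene, ratio columns suffixed by pool id."""
    pool_ids = design.pool_ids
    rows = []
    for r in results:
        row: dict = {
            "gene_id": r.gene_id,
            "n_snps": r.n_snps,
            "n_pools": sum(1 for p in pool_ids if sum(r.pool_counts[p]) > 0),
        }
        for p in pool_ids:
            row[f"ratio_{p}"] = r.ratios[p]
        row.update(
            G=r.g_statistic, df=r.df, p=r.p_value,
            candidate=r.candidate, pattern=r.pattern, significant=r.significant,
        )
        if r.q_value is not None:
            row["q"] = r.q_value
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(path: str | Path, results: Sequence[GeneASEResult], design: CrossDesign) -> None:
    """Write the per-gene result table; ratios are printed at 3 decimals
    (internal computation is full precision)."""
    df = results_frame(results, design)
    for col in df.columns:
        if col.startswith("ratio_"):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    df["G"] = df["G"].map(lambda v: f"{v:.4f}")
    df["p"] = df["p"].map(lambda v: f"{v:.4g}")
    if "q" in df.columns:
        df["q"] = df["q"].map(lambda v: f"{v:.4g}")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
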