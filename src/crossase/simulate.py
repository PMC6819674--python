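"""Synthetic reciprocal-cross datasets with the statistical structure the
analysis assumes.

The generator emulates the study design end to end at desk scale:

* two diverged breeds — a fraction of segregating sites is fixed for
  different alleles between breeds (the informative sites), the rest carry
  within-breed heterozygosity;
* shallow parental genome sequencing — per-parent depth is Poisson around
  ~4x, each read samples one of the parent's two alleles, and the genotype
  is called naively (homozygous iff all reads agree, missing at zero
  depth).  This reproduces the phenomenon that matters downstream: at
  depth d a true heterozygote is mis-called homozygous with probability
  2^(1-d), and low-depth sites fall below the DP cutoffs.  Joint same-breed
  samples pool the two parents' reads, doubling effective depth;
* Mendelian transmission to F1 pools of three same-sex piglets, and pooled
  RNA allele counts per SNP at Poisson depth (~15x) whose allelic
  composition follows each gene's true ASE mode.

A small fraction of sites (default 2%) is given failing FS or QD
annotations so the quality filters have work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .design import BREEDS, KNP, LANDRACE, PARENT_SAMPLES, CrossDesign, default_design
from .formats import (
    AlleleCountRecord,
    Genotype,
    GenotypeCall,
    VariantSite,
    write_bed,
    write_counts,
    write_vcf,
)
from .selection import InformativeSNP, Strategy

MODE_BIALLELIC = "biallelic"
MODE_PATERNAL = "paternal_imprinted"
MODE_MATERNAL = "maternal_imprinted"
MODE_DOMINANT = "allele_dominant"
MODES = (MODE_BIALLELIC, MODE_PATERNAL, MODE_MATERNAL, MODE_DOMINANT)

_BASE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]


def _default_fractions() -> dict[str, float]:
    return {
        MODE_BIALLELIC: 0.85,
        MODE_PATERNAL: 0.05,
        MODE_MATERNAL: 0.05,
        MODE_DOMINANT: 0.05,
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Depth defaults mirror the sequencing regime being emulated: ~4x
    per-parent genomes (so ~8x joint) and ~15 RNA reads per SNP per pool
    of three littermates.  ``dominant_share`` defaults to 0.85 rather than
    1.0 so allele-dominant genes exercise the 0.7 ratio threshold region.
    """

    n_genes: int = 200
    snps_per_gene: int = 3
    breed_divergence: float = 0.3
    within_breed_het: float = 0.2
    dna_depth_individual: float = 4.0
    rna_depth: float = 15.0
    pool_size: int = 3
    ase_mode_fractions: Mapping[str, float] = field(default_factory=_default_fractions)
    dominant_share: float = 0.85
    imprint_leakage: float = 0.0
    qc_fail_fraction: float = 0.02
    overdispersion: float = 0.0
    snp_spacing: int = 300
    n_chromosomes: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.snps_per_gene < 1 or self.pool_size < 1:
            raise ValueError("n_genes, snps_per_gene and pool_size must be >= 1")
        if self.dna_depth_individual <= 0 or self.rna_depth <= 0:
            raise ValueError("depths must be > 0")
        for name in ("breed_divergence", "within_breed_het", "dominant_share",
                     "imprint_leakage", "qc_fail_fraction", "overdispersion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if set(self.ase_mode_fractions) - set(MODES):
            raise ValueError(f"unknown ASE modes: {set(self.ase_mode_fractions) - set(MODES)}")
        if abs(sum(self.ase_mode_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("ase_mode_fractions must sum to 1")
        if self.n_chromosomes < 1 or self.snp_spacing < 1:
            raise ValueError("n_chromosomes and snp_spacing must be >= 1")


@dataclass(frozen=True)
class SiteInfo:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene_id: str


@dataclass
class SimTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    true_mode: str
    true_paternal_fraction: float
    favored_breed: str | None
    snp_positions: list[tuple[str, int]]


@dataclass
class SimulatedGenotypes:
    """True parental genotypes: alt-allele dosage (0/1/2) per site per parent."""

    sites: list[SiteInfo]
    parents: tuple[str, ...]
    dosage: np.ndarray  # shape (n_sites, n_parents), values 0/1/2
    truth: list[SimTruth]
    gene_sites: dict[str, list[int]]  # gene_id -> site indices


def simulate_true_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimulatedGenotypes:
    """Draw true parental genotypes and per-gene ASE modes.

    With probability ``breed_divergence`` a site is fixed hom-ref in one
    breed and hom-alt in the other (truly informative); otherwise each
    parent is independently heterozygous with probability
    ``within_breed_het`` and homozygous for a random allele otherwise.
    Genes are laid out along ``n_chromosomes`` chromosomes with SNPs spaced
    ``snp_spacing`` bp apart inside a single exon per gene.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_genes, k = config.n_genes, config.snps_per_gene
    genes_per_chrom = -(-n_genes // config.n_chromosomes)
    gene_span = k * config.snp_spacing + 400

    sites: list[SiteInfo] = []
    truth: list[SimTruth] = []
    gene_sites: dict[str, list[int]] = {}
    modes = rng.choice(
        MODES,
        size=n_genes,
        p=[config.ase_mode_fractions.get(m, 0.0) for m in MODES],
    )
    dosage = np.zeros((n_genes * k, len(PARENT_SAMPLES)), dtype=np.int8)
    idx = 0
    for g in range(n_genes):
        gene_id = f"G{g + 1:06d}"
        chrom = str(g // genes_per_chrom + 1)
        start0 = (g % genes_per_chrom) * gene_span
        mode = str(modes[g])
        favored = None
        if mode == MODE_PATERNAL:
            frac = 1.0 - config.imprint_leakage
        elif mode == MODE_MATERNAL:
            frac = config.imprint_leakage
        elif mode == MODE_DOMINANT:
            favored = str(rng.choice(BREEDS))
            frac = config.dominant_share
        else:
            frac = 0.5
        positions: list[tuple[str, int]] = []
        site_idx: list[int] = []
        for s in range(k):
            pos = start0 + 100 + s * config.snp_spacing + 1  # 1-based
            ref, alt = _BASE_PAIRS[rng.integers(len(_BASE_PAIRS))]
            sites.append(SiteInfo(chrom, pos, ref, alt, gene_id))
            positions.append((chrom, pos))
            site_idx.append(idx)
            if rng.random() < config.breed_divergence:
                knp_dose = 0 if rng.random() < 0.5 else 2
                dosage[idx, 0] = dosage[idx, 1] = knp_dose
                dosage[idx, 2] = dosage[idx, 3] = 2 - knp_dose
            else:
                for p in range(len(PARENT_SAMPLES)):
                    if rng.random() < config.within_breed_het:
                        dosage[idx, p] = 1
                    else:
                        dosage[idx, p] = 0 if rng.random() < 0.5 else 2
            idx += 1
        truth.append(SimTruth(gene_id, mode, frac, favored, positions))
        gene_sites[gene_id] = site_idx
    return SimulatedGenotypes(sites, PARENT_SAMPLES, dosage, truth, gene_sites)


def call_genotype(n_ref: int, n_alt: int) -> Genotype:
    """Naive all-reads-agree caller: hom iff every read shows one allele."""
    if n_ref + n_alt == 0:
        return Genotype.MISSING
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_ref == 0:
        return Genotype.HOM_ALT
    return Genotype.HET


def observe_reads(
    dosage: np.ndarray, depth: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-site read tallies: each read picks one of the two true
    alleles uniformly, so alt reads ~ Binomial(depth, dosage/2)."""
    n_alt = rng.binomial(depth, np.asarray(dosage, dtype=float) / 2.0)
    return depth - n_alt, n_alt


def draw_site_annotations(
    n_sites: int, rng: np.random.Generator, fail_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """FS and QD annotations; a ``fail_fraction`` of sites violates the
    FS > 30 or QD < 2 filter (half each)."""
    fs = rng.exponential(3.0, size=n_sites)
    qd = rng.uniform(5.0, 35.0, size=n_sites)
    u = rng.random(n_sites)
    fs_fail = u < fail_fraction / 2.0
    qd_fail = (u >= fail_fraction / 2.0) & (u < fail_fraction)
    fs[fs_fail] = rng.uniform(30.01, 60.0, size=int(fs_fail.sum()))
    qd[qd_fail] = rng.uniform(0.0, 1.99, size=int(qd_fail.sum()))
    return np.round(fs, 2), np.round(qd, 2)


@dataclass
class ObservedGenotypes:
    sites: list[VariantSite]
    samples: tuple[str, ...]
    tallies: np.ndarray  # (n_sites, n_samples, 2) ref/alt read counts


def _sites_from_tallies(
    sim_sites: Sequence[SiteInfo],
    samples: Sequence[str],
    tallies: np.ndarray,
    fs: np.ndarray,
    qd: np.ndarray,
) -> list[VariantSite]:
    out: list[VariantSite] = []
    for i, si in enumerate(sim_sites):
        calls = []
        for j, sample in enumerate(samples):
            n_ref, n_alt = int(tallies[i, j, 0]), int(tallies[i, j, 1])
            calls.append(GenotypeCall(sample, call_genotype(n_ref, n_alt), n_ref + n_alt))
        out.append(
            VariantSite(si.chrom, si.pos, si.ref_allele, si.alt_allele,
                        float(fs[i]), float(qd[i]), tuple(calls))
        )
    return out


def simulate_genotype_observation(
    sim: SimulatedGenotypes,
    mean_depth: float,
    rng: np.random.Generator,
    qc_fail_fraction: float = 0.02,
    depth_override: np.ndarray | None = None,
    fs: np.ndarray | None = None,
    qd: np.ndarray | None = None,
) -> ObservedGenotypes:
    """Observe the true genotypes through shallow sequencing.

    Depth is Poisson(``mean_depth``) per site per parent unless an exact
    ``depth_override`` array (n_sites, n_parents) is given.  FS/QD arrays
    may be supplied (e.g. to share annotations between the individual and
    joint renderings of the same sites); otherwise they are drawn here.
    """
    n_sites, n_parents = sim.dosage.shape
    if depth_override is not None:
        depth = np.asarray(depth_override, dtype=np.int64)
    else:
        depth = rng.poisson(mean_depth, size=(n_sites, n_parents))
    n_ref, n_alt = observe_reads(sim.dosage, depth, rng)
    tallies = np.stack([n_ref, n_alt], axis=-1)
    if fs is None or qd is None:
        fs, qd = draw_site_annotations(n_sites, rng, qc_fail_fraction)
    sites = _sites_from_tallies(sim.sites, sim.parents, tallies, fs, qd)
    return ObservedGenotypes(sites, sim.parents, tallies)


def joint_observation(
    sim: SimulatedGenotypes,
    obs: ObservedGenotypes,
    fs: np.ndarray,
    qd: np.ndarray,
) -> ObservedGenotypes:
    """Merge the two same-breed parents' reads into one joint sample per
    breed (depth adds; the genotype is re-called from the pooled reads)."""
    breed_cols = {KNP: [0, 1], LANDRACE: [2, 3]}
    samples = tuple(breed_cols)
    tallies = np.stack(
        [obs.tallies[:, cols, :].sum(axis=1) for cols in breed_cols.values()], axis=1
    )
    sites = _sites_from_tallies(sim.sites, samples, tallies, fs, qd)
    return ObservedGenotypes(sites, samples, tallies)


def simulate_offspring(
    sim: SimulatedGenotypes,
    design: CrossDesign,
    pool_size: int,
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mendelian transmission: per pool, per offspring, per site, one
    uniformly chosen allele from the sire (paternal) and dam (maternal).

    Returns pool_id -> (paternal, maternal) alt-indicator arrays of shape
    (n_sites, pool_size).
    """
    n_sites = sim.dosage.shape[0]
    col = {s: i for i, s in enumerate(sim.parents)}
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cross in design.crosses:
        for parent in (cross.dam, cross.sire):
            if parent not in col:
                raise ValueError(f"cross design references unknown parent {parent!r}")
        p_sire = sim.dosage[:, col[cross.sire]].astype(float) / 2.0
        p_dam = sim.dosage[:, col[cross.dam]].astype(float) / 2.0
        for pool_id in cross.pool_ids:
            pat = rng.binomial(1, p_sire[:, None], size=(n_sites, pool_size))
            mat = rng.binomial(1, p_dam[:, None], size=(n_sites, pool_size))
            out[pool_id] = (pat.astype(np.int8), mat.astype(np.int8))
    return out


def simulate_offspring_counts(
    sim: SimulatedGenotypes,
    haplotypes: Mapping[str, tuple[np.ndarray, np.ndarray]],
    design: CrossDesign,
    config: SimConfig,
    rng: np.random.Generator,
    with_totals: bool = False,
):
    """Pooled RNA allele counts per SNP per pool.

    Reads per (pool, SNP) are Poisson(``rna_depth``), split uniformly over
    pool members.  A member's reads come from its paternal haplotype with
    probability given by the gene's mode; for allele-dominant genes the
    probability attaches to the haplotype inherited from the favored breed
    (the sire's side in one cross, the dam's in the reciprocal), not to a
    parent.  Each read reports the base its haplotype carries.  With
    ``overdispersion`` rho > 0 the per-(pool, SNP) success probability is
    drawn from a Beta with mean at the mode's value and nu = (1-rho)/rho.
    """
    records: list[AlleleCountRecord] = []
    totals: dict[tuple[str, int, str], int] = {}
    k = config.pool_size
    uniform = np.full(k, 1.0 / k)
    rho = config.overdispersion
    for pool_id in design.pool_ids:
        pat, mat = haplotypes[pool_id]
        sire_breed = design.sire_breed(pool_id)
        for tr in sim.truth:
            if tr.true_mode == MODE_DOMINANT:
                p_pat = tr.true_paternal_fraction if sire_breed == tr.favored_breed \
                    else 1.0 - tr.true_paternal_fraction
            else:
                p_pat = tr.true_paternal_fraction
            for site_idx in sim.gene_sites[tr.gene_id]:
                si = sim.sites[site_idx]
                n = int(rng.poisson(config.rna_depth))
                p_eff = p_pat
                if rho > 0.0 and 0.0 < p_pat < 1.0:
                    nu = (1.0 - rho) / rho
                    p_eff = float(rng.beta(p_pat * nu, (1.0 - p_pat) * nu))
                n_alt = 0
                if n:
                    member_n = rng.multinomial(n, uniform)
                    for m, nm in enumerate(member_n):
                        if nm == 0:
                            continue
                        n_from_pat = int(rng.binomial(nm, p_eff))
                        n_alt += n_from_pat * int(pat[site_idx, m]) \
                            + (nm - n_from_pat) * int(mat[site_idx, m])
                records.append(
                    AlleleCountRecord(si.chrom, si.pos, pool_id, n - n_alt, n_alt)
                )
                totals[(si.chrom, si.pos, pool_id)] = n
    if with_totals:
        return records, totals
    return records


def true_informative_snps(
    sim: SimulatedGenotypes, strategy: Strategy = Strategy.I
) -> list[InformativeSNP]:
    """Informative SNPs read off the *true* genotypes (no observation
    noise): both KNP parents hom for one allele, both Landrace parents hom
    for the other.  Useful as a noiseless benchmark for the RNA stage."""
    out: list[InformativeSNP] = []
    for i, si in enumerate(sim.sites):
        d = sim.dosage[i]
        if d[0] == d[1] and d[2] == d[3] and {int(d[0]), int(d[2])} == {0, 2}:
            knp = si.ref_allele if d[0] == 0 else si.alt_allele
            lr = si.alt_allele if d[0] == 0 else si.ref_allele
            out.append(
                InformativeSNP(si.chrom, si.pos, frozenset([si.gene_id]),
                               si.ref_allele, knp, lr, strategy)
            )
    return out


TRUTH_COLUMNS = ("gene_id", "true_mode", "true_paternal_fraction", "favored_breed")


def write_truth(path: str | Path, truth: Sequence[SimTruth]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                f"{t.gene_id}\t{t.true_mode}\t{t.true_paternal_fraction:.4f}\t"
                f"{t.favored_breed or ''}\n"
            )


def generate_dataset(
    config: SimConfig,
    outdir: str | Path,
    design: CrossDesign | None = None,
) -> dict[str, Path]:
    """Write a complete synthetic dataset (parents.vcf, joint.vcf,
    exons.bed, four counts_<pool>.tsv, truth.tsv) into ``outdir``.

    All files parse with :mod:`crossase.formats`; the same seed yields
    byte-identical output.
    """
    design = design or default_design()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    r_geno, r_obs, r_off, r_rna = (np.random.default_rng(s) for s in ss.spawn(4))

    sim = simulate_true_genotypes(config, r_geno)
    fs, qd = draw_site_annotations(len(sim.sites), r_obs, config.qc_fail_fraction)
    obs = simulate_genotype_observation(
        sim, config.dna_depth_individual, r_obs,
        qc_fail_fraction=config.qc_fail_fraction, fs=fs, qd=qd,
    )
    joint = joint_observation(sim, obs, fs, qd)
    haplos = simulate_offspring(sim, design, config.pool_size, r_off)
    counts = simulate_offspring_counts(sim, haplos, design, config, r_rna)

    paths: dict[str, Path] = {}
    paths["parents_vcf"] = outdir / "parents.vcf"
    write_vcf(paths["parents_vcf"], obs.sites, obs.samples)
    paths["joint_vcf"] = outdir / "joint.vcf"
    write_vcf(paths["joint_vcf"], joint.sites, joint.samples)

    paths["exons_bed"] = outdir / "exons.bed"
    bed_records = []
    for gene_id, idxs in sim.gene_sites.items():
        chrom = sim.sites[idxs[0]].chrom
        first = sim.sites[idxs[0]].pos - 1
        last = sim.sites[idxs[-1]].pos
        bed_records.append((chrom, max(first - 100, 0), last + 100, gene_id))
    write_bed(paths["exons_bed"], bed_records)

    for pool_id in design.pool_ids:
        p = outdir / f"counts_{pool_id}.tsv"
        write_counts(p, [r for r in counts if r.pool_id == pool_id])
        paths[f"counts_{pool_id}"] = p

    paths["truth"] = outdir / "truth.tsv"
    write_truth(paths["truth"], sim.truth)
    return paths
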