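# Methods

`crossase` detects allele-biased expression — and separates parent-of-origin
effects (imprinting-like patterns) from allele-dominant, parent-independent
expression — from a reciprocal cross between two outbred pig breeds, Korean
native pig (KNP) and Landrace, using the parents' whole-genome genotypes and
pooled RNA-seq of F1 offspring. This note records the model, the defaults,
and the design choices that were genuinely open.

## The experimental design being modelled

Two crosses, KNP♀×Landrace♂ and Landrace♀×KNP♂, each yield one male and one
female RNA pool of three same-sex littermates: four pools in total. Because
the animals are outbred, parental origin of an expressed allele can only be
traced at *informative* SNPs: sites homozygous within each parent (or
within each breed) and different between the breeds, so every F1 is
heterozygous with known phase. Cross labels use the dam-first convention
("KxL" = KNP dam); `default_design(sire_first=True)` flips the reading, and
all classifications are invariant under the swap (the orientation
antisymmetry property in the test suite).

## Site filtering

Variant sites are filtered in a fixed attribution order, with strict
inequalities matching the stated thresholds:

1. **FS > 30** — phred-scaled Fisher-strand bias (strand artefacts);
2. **QD < 2** — quality by depth (weak support);
3. **SNP clusters** — three or more SNPs within a 35 bp window. The window
   arithmetic is taken as inclusive span: a SNP is removed iff some set of
   ≥ 3 quality-passing SNPs containing it spans ≤ 34 bp (last − first).
   The rule is evaluated per chromosome on the post-quality-filter set and
   is verified against a brute-force all-windows oracle. Other window
   conventions (e.g. open span) exist; this one is documented and frozen.
4. **DP** — any relevant sample below depth 3 (strategy I: the four
   individual parents) or 6 (strategy II: the two same-breed joint
   samples) removes the site.

A site failing several rules is counted once under the first failing rule,
so removal reports are reproducible. Filtering is idempotent.

## Informative-SNP selection, strategies I and II

Strategy I calls genotypes per parent; strategy II pools the two same-breed
parents' reads into one joint sample per breed, doubling effective depth.
Selection requires every inspected sample homozygous, the two breeds
carrying different alleles and — under strategy I — the two same-breed
parents agreeing. The agreement requirement is relaxable
(`require_breed_agreement=False`): the alternative reading only demands
dam ≠ sire within each cross. For a biallelic SNP the two readings select
the same set whenever a consistent breed→allele map exists; the only extra
configuration ("crossed" same-breed disagreement) admits no such map,
cannot be oriented downstream, and is counted and excluded.

The emitted record keeps the reference base alongside the KNP and Landrace
alleles, because count tables are keyed by ref/alt base and must be
re-keyed to parental origin later.

## Orientation, ratio, and the G-test

For a pool, the sire breed's allele is paternal. The paternal read ratio is
paternal/(paternal+maternal) reads, undefined at zero coverage; the
maternal ratio is its complement. A gene is a *candidate* when any pool's
ratio is ≤ 0.3 or ≥ 0.7. The boundaries are inclusive: the worked example
table lists a gene whose only extreme-side cell sits exactly on 0.3, which
a strict inequality would read inconsistently.

Deviation from 1:1 uses the likelihood-ratio goodness-of-fit statistic
G = 2·Σ O·ln(O/E) with E = n/2 and zero cells contributing nothing,
referred to the χ² upper tail. An optional Williams correction
(G / (1 + 1/(2n))) is off by default. The *unit* of testing was genuinely
open (per SNP, per pool, or pooled over the gene). Pooling
paternal-vs-maternal across pools would cancel exactly for allele-dominant
genes (pattern 1,1,0,0), which are nonetheless reported as significant in
the motivating analysis; the default therefore sums per-pool G over the
gene's SNP-summed pools with df = number of pools with reads, detecting a
deviation in any direction in any pool. A per-(pool, SNP) mode is available
(`per_snp=True`). No multiple-testing correction is applied by default
(raw p < 0.05); Benjamini–Hochberg is available behind a flag.

Pattern calls use per-cross mean ratios r₁, r₂ (male and female pools are
replicates of a cross; sex-specific imprinting is out of scope):
both ≥ 0.7 → `paternal_biased`; both ≤ 0.3 → `maternal_biased`; opposite
sides → `allele_dominant`; both strictly inside (0.3, 0.7) → `biallelic`;
anything else (including a cross with no defined ratio) → `inconsistent`;
zero reads overall → `insufficient_data`. Output tables print ratios at
three decimals; computation is full precision.

## The synthetic-data generator

The generator emulates the cross at desk scale; its defaults are the study
conditions, not tuning knobs.

| parameter | default | meaning / rationale |
|---|---|---|
| `dna_depth_individual` | 4.0 | mean per-parent genome depth (the ~4.05–4.25× regime); joint samples sum two parents (~8×) |
| `rna_depth` | 15.0 | mean RNA reads per SNP per pool (~12–19× exonic) |
| `pool_size` | 3 | three same-sex littermates per pool |
| `snps_per_gene` | 3 | a few informative exonic SNPs per testable gene |
| `breed_divergence` | 0.3 | P(site fixed-different between breeds); chosen once as plausible for two diverged breeds, so most sites are non-informative as in real data |
| `within_breed_het` | 0.2 | per-site heterozygosity at non-divergent sites |
| `ase_mode_fractions` | 0.85/0.05/0.05/0.05 | biallelic / paternal- / maternal-imprinted / allele-dominant; ASE is the minority |
| `dominant_share` | 0.85 | favored-allele share < 1 so dominant genes exercise the 0.7 threshold region |
| `imprint_leakage` | 0.0 | leakage from the silenced allele |
| `qc_fail_fraction` | 0.02 | fraction of sites given failing FS or QD annotations |
| `overdispersion` | 0.0 | beta-binomial ρ for pooled RNA; off by default (the replication structure of pools is not characterised) |

Genotype observation uses a naive all-reads-agree caller: depth is Poisson,
each read samples one of the parent's two alleles uniformly, and a site is
called homozygous iff every read agrees (missing at depth 0). This is
deliberately not a likelihood caller — it reproduces, in closed form, the
phenomenon that matters downstream: a true het at depth d is mis-called
homozygous with probability 2^(1−d), which both depletes informative SNPs
and fabricates false ones at ~4× coverage, and it makes the strategy II
depth advantage measurable. RNA counts are Poisson per (pool, SNP), split
uniformly over pool members; each read comes from a member's paternal
haplotype with the gene's mode probability — except allele-dominant genes,
where the probability attaches to the haplotype inherited from the favored
*breed* (the sire's side in one cross, the dam's in the reciprocal), which
is what makes the dominant pattern flip between crosses at informative
sites and stay well-defined at non-informative ones.

What the generator does **not** model: read-level errors and alignment /
reference bias, sequencing-error genotype miscalls (only sampling
miscalls), sex chromosomes, linkage beyond a single gene, library-size
differences between pools, and RNA-seq variant-calling artefacts. Passing
recovery tests therefore demonstrates correctness of the inference given
the sampling model, not robustness to mapping bias or overdispersed pools
(the ρ knob exists for sensitivity analyses).

## Numerical and degenerate-input choices

* Zero-count cells contribute 0 to G; G is clamped at 0 against rounding.
* p-values come from `scipy.stats.chi2.sf`; df = pools (or cells) with ≥ 1
  read; a gene with zero reads reports G = 0, df = 0, p = 1,
  `insufficient_data`.
* Undefined ratios (0/0 pools) are excluded from candidate flagging and
  from per-cross means; all-undefined yields `insufficient_data`, one
  undefined cross yields `inconsistent`.
* VCF reading treats DP = 0 or GT `./.` as missing (missing disqualifies a
  site from informativeness); absent FS/QD parse as 0.0 (not filtered on
  that criterion) with a warning.
* A SNP inside two genes' exons contributes to both genes; this is logged
  so users can exclude overlaps.
* Seeds: every stochastic stage takes a `numpy` Generator; dataset
  generation spawns independent child streams from one `SeedSequence`, so
  identical seeds give byte-identical files.

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale by design: the
worked nine-gene ratio table as an end-to-end fixture; Monte-Carlo checks
of the mis-call law at 1.5×10⁵ draws per depth; strategy comparison over
20 simulated replicates of 120 sites; calibration of the type-I error on
2,000 all-biallelic genes (observed rate must lie in 0.05 ± 0.02) and
pattern recovery on 1,200 genes split over the three ASE modes (≥ 99%
correct for fully imprinted genes, ≥ 95% for allele-dominant at share
0.85). These sizes give Monte-Carlo standard errors well inside the stated
bands while keeping the whole suite in a few seconds.

## Known limitations

* The genome-scale yields of a real cross (millions of raw SNPs, hundreds
  of candidate genes) depend on real sequencing data and are covered only
  qualitatively (strategy II ≥ strategy I at low depth), not numerically.
* The G-test is asymptotic; at very low per-pool totals its type-I error
  is conservative/discrete. The Williams correction helps mildly; an exact
  binomial test is not provided.
* No phasing, no reference-bias correction, no eQTL mapping, no
  sex-specific imprinting; these are explicit non-goals.
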