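"""Filter rules, cluster-window semantics and informative-SNP selection."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossase.design import PARENT_BREEDS, PARENT_SAMPLES
from crossase.formats import GeneAnnotation, Genotype, GenotypeCall, VariantSite
from crossase.selection import (
    ExonicSite,
    FilterConfig,
    InformativeSNP,
    Strategy,
    assign_exonic,
    clustered_indices,
    compare_strategies,
    filter_sites,
    select_informative,
)
from crossase.simulate import (
    SimConfig,
    simulate_genotype_observation,
    simulate_true_genotypes,
    true_informative_snps,
)


def site(pos=100, chrom="1", fs=1.0, qd=10.0, gts=("0/0", "0/0", "1/1", "1/1"),
         dps=(5, 5, 5, 5), ref="A", alt="G"):
    gt_map = {"0/0": Genotype.HOM_REF, "0/1": Genotype.HET,
              "1/1": Genotype.HOM_ALT, "./.": Genotype.MISSING}
    calls = tuple(
        GenotypeCall(s, gt_map[g] if d > 0 else Genotype.MISSING, d)
        for s, g, d in zip(PARENT_SAMPLES, gts, dps)
    )
    return VariantSite(chrom, pos, ref, alt, fs, qd, calls)


class TestFilterSites:
    def test_fs_boundary_is_strict(self):
        kept = filter_sites([site(pos=10, fs=30.0), site(pos=50, fs=30.01)]).kept
        assert [s.pos for s in kept] == [10]

    def test_qd_boundary_is_strict(self):
        res = filter_sites([site(pos=10, qd=2.0), site(pos=50, qd=1.99)])
        assert [s.pos for s in res.kept] == [10]
        assert res.removed["qd"] == 1

    def test_cluster_window_span(self):
        # span 34 bp (<= 35 bp window) -> all three removed; span 36 -> kept
        tight = [site(pos=p) for p in (100, 110, 134)]
        loose = [site(pos=p) for p in (100, 110, 136)]
        assert filter_sites(tight).removed["cluster"] == 3
        assert filter_sites(tight).kept == []
        res = filter_sites(loose)
        assert res.removed["cluster"] == 0 and len(res.kept) == 3

    def test_cluster_evaluated_per_chromosome(self):
        sites = [site(pos=100, chrom="1"), site(pos=110, chrom="1"),
                 site(pos=120, chrom="2")]
        assert filter_sites(sites).removed["cluster"] == 0

    def test_dp_threshold_depends_on_strategy(self):
        s_ind = site(dps=(2, 5, 5, 5))
        assert filter_sites([s_ind], strategy=Strategy.I).removed["dp"] == 1
        joint = VariantSite("1", 100, "A", "G", 1.0, 10.0, (
            GenotypeCall("KNP", Genotype.HOM_REF, 6),
            GenotypeCall("Landrace", Genotype.HOM_ALT, 6),
        ))
        assert filter_sites([joint], strategy=Strategy.II).kept == [joint]
        assert filter_sites([site(dps=(3, 3, 3, 3))], strategy=Strategy.I).removed["dp"] == 0

    def test_attribution_order_counts_each_site_once(self):
        sites = [site(pos=10, fs=50.0, qd=1.0, dps=(0, 0, 0, 0)),
                 site(pos=60, qd=1.0, dps=(1, 1, 1, 1)),
                 site(pos=120, dps=(1, 5, 5, 5))]
        res = filter_sites(sites)
        assert res.removed == {"fs": 1, "qd": 1, "cluster": 0, "dp": 1}
        assert res.n_removed + len(res.kept) == len(sites)

    def test_idempotent(self):
        rnd = random.Random(0)
        sites = [site(pos=p, fs=rnd.uniform(0, 40), qd=rnd.uniform(0, 10),
                      dps=tuple(rnd.randint(0, 8) for _ in range(4)))
                 for p in sorted(rnd.sample(range(1, 5000), 300))]
        once = filter_sites(sites)
        twice = filter_sites(once.kept)
        assert twice.kept == once.kept
        assert twice.n_removed == 0

    def test_unsorted_input_is_an_error(self):
        with pytest.raises(ValueError, match="sorted"):
            filter_sites([site(pos=200), site(pos=100)])
        with pytest.raises(ValueError, match="sorted"):
            filter_sites([site(pos=100, chrom="1"), site(pos=100, chrom="2"),
                          site(pos=200, chrom="1")])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 120))
    def test_cluster_rule_matches_bruteforce_windows(self, seed, n):
        rnd = random.Random(seed)
        positions = sorted(rnd.sample(range(1, 2000), n))
        got = clustered_indices(positions, size=3, window_bp=35)
        # oracle: every 35-bp window (inclusive span <= 34) with >= 3 SNPs
        expected = set()
        for i in range(len(positions)):
            for j in range(i, len(positions)):
                if positions[j] - positions[i] <= 34 and j - i + 1 >= 3:
                    expected.update(range(i, j + 1))
        assert got == expected


class TestAssignExonic:
    def test_boundary_and_multi_gene_semantics(self):
        ann = GeneAnnotation({"G1": {"1": [(100, 250)]}, "G2": {"1": [(200, 400)]}})
        sites = [site(pos=250), site(pos=251), site(pos=401), site(pos=240)]
        kept, dropped = assign_exonic(sites, ann)
        assert dropped == 1  # 401 is 1 bp past G2's exon end
        by_pos = {e.site.pos: e.gene_ids for e in kept}
        assert by_pos[250] == {"G1", "G2"}  # last base of G1's exon
        assert by_pos[251] == {"G2"}
        assert by_pos[240] == {"G1", "G2"}


class TestSelectInformative:
    def exonic(self, s):
        return [ExonicSite(s, frozenset(["G1"]))]

    def test_all_hom_breed_diagnostic_site(self):
        snps = select_informative(self.exonic(site()), Strategy.I, PARENT_BREEDS)
        assert len(snps) == 1
        snp = snps[0]
        assert snp.knp_allele == "A" and snp.landrace_allele == "G"
        assert snp.allele_of("KNP") == snp.ref_allele

    @pytest.mark.parametrize("gts", [
        ("0/0", "0/1", "1/1", "1/1"),  # one het parent
        ("0/0", "./.", "1/1", "1/1"),  # missing call
        ("0/0", "0/0", "0/0", "0/0"),  # no breed difference
        ("0/0", "1/1", "1/1", "1/1"),  # same-breed disagreement
    ])
    def test_disqualifying_genotypes(self, gts):
        dps = tuple(0 if g == "./." else 5 for g in gts)
        got = select_informative(self.exonic(site(gts=gts, dps=dps)),
                                 Strategy.I, PARENT_BREEDS)
        assert got == []

    def test_strategy_ii_uses_joint_samples(self):
        s = VariantSite("1", 100, "A", "G", 1.0, 10.0, (
            GenotypeCall("KNP", Genotype.HOM_ALT, 8),
            GenotypeCall("Landrace", Genotype.HOM_REF, 8),
        ))
        snps = select_informative([ExonicSite(s, frozenset(["G1"]))],
                                  Strategy.II, PARENT_BREEDS)
        assert len(snps) == 1 and snps[0].knp_allele == "G"

    def test_incomplete_breed_map_is_an_error(self):
        with pytest.raises(ValueError, match="KNP_F"):
            select_informative(self.exonic(site()), Strategy.I, {"KNP_M": "KNP"})

    def test_lowdepth_miscalled_het_creates_false_informative_snp(self):
        """A true het observed at dp=1 is forcibly called hom, which can
        fabricate an informative site."""
        cfg = SimConfig(n_genes=1, snps_per_gene=1, breed_divergence=0.0,
                        within_breed_het=1.0, seed=0)
        rng = np.random.default_rng(0)
        sim = simulate_true_genotypes(cfg, rng)
        assert (sim.dosage == 1).all()  # every parent a true het
        # force depth 1 everywhere: each parent shows exactly one allele
        depth = np.ones_like(sim.dosage, dtype=np.int64)
        found = False
        for trial in range(200):
            obs = simulate_genotype_observation(sim, 1.0, rng, depth_override=depth)
            s = obs.sites[0]
            assert all(c.gt in (Genotype.HOM_REF, Genotype.HOM_ALT) for c in s.calls)
            got = select_informative([ExonicSite(s, frozenset(["G1"]))],
                                     Strategy.I, PARENT_BREEDS)
            if got:
                found = True
                break
        assert found  # P(informative per trial) = 2/16, so ~1e-12 to miss 200x


class TestCompareStrategies:
    def make(self, positions, strategy=Strategy.I):
        return [InformativeSNP("1", p, frozenset(["G"]), "A", "A", "G", strategy)
                for p in positions]

    def test_identical_and_disjoint_sets(self):
        a = self.make(range(10))
        assert compare_strategies(a, a) == compare_strategies(a, self.make(range(10), Strategy.II))
        r = compare_strategies(a, a)
        assert (r.count_i, r.count_ii, r.shared, r.unique_i, r.unique_ii) == (10, 10, 10, 0, 0)
        r = compare_strategies(self.make([1, 2, 3]), self.make([10, 11, 12, 13]))
        assert (r.count_i, r.count_ii, r.shared, r.unique_i, r.unique_ii) == (3, 4, 0, 3, 4)

    def test_additivity_identity_on_random_sets(self):
        rnd = random.Random(1)
        a = self.make(rnd.sample(range(1000), 50))
        b = self.make(rnd.sample(range(1000), 80), Strategy.II)
        r = compare_strategies(a, b)
        assert r.shared + r.unique_i == r.count_i
        assert r.shared + r.unique_ii == r.count_ii


def _informative_counts(seed, mean_depth=4.0):
    """Informative SNP counts under strategies I and II for one simulated
    genotype observation at the given parental depth."""
    from crossase.simulate import draw_site_annotations, joint_observation

    cfg = SimConfig(n_genes=60, snps_per_gene=2, breed_divergence=0.4,
                    within_breed_het=0.3, seed=seed)
    rng = np.random.default_rng(seed)
    sim = simulate_true_genotypes(cfg, rng)
    fs, qd = draw_site_annotations(len(sim.sites), rng, 0.0)
    obs = simulate_genotype_observation(sim, mean_depth, rng, fs=fs, qd=qd)
    joint = joint_observation(sim, obs, fs, qd)
    res_i = filter_sites(obs.sites, FilterConfig(), Strategy.I)
    res_ii = filter_sites(joint.sites, FilterConfig(), Strategy.II)
    ex_i = [ExonicSite(s, frozenset(["G"])) for s in res_i.kept]
    ex_ii = [ExonicSite(s, frozenset(["G"])) for s in res_ii.kept]
    n_i = len(select_informative(ex_i, Strategy.I, PARENT_BREEDS))
    n_ii = len(select_informative(ex_ii, Strategy.II, PARENT_BREEDS))
    return n_i, n_ii


def test_joint_mapping_recovers_more_informative_snps():
    """At ~4x parental depth, pooling same-breed reads (strategy II) passes
    the DP cutoff more often and detects hets better, so it should yield at
    least as many informative SNPs in nearly every replicate."""
    wins = sum(1 for seed in range(20) if
               (lambda c: c[1] >= c[0])(_informative_counts(seed)))
    assert wins >= 17


def test_perfect_genotypes_make_strategies_agree():
    """With saturating depth there are no mis-calls or DP failures, so the
    two strategies select identical informative sets."""
    cfg = SimConfig(n_genes=40, snps_per_gene=2, breed_divergence=0.5,
                    within_breed_het=0.3, seed=5)
    rng = np.random.default_rng(5)
    sim = simulate_true_genotypes(cfg, rng)
    from crossase.simulate import draw_site_annotations, joint_observation

    fs, qd = draw_site_annotations(len(sim.sites), rng, 0.0)
    obs = simulate_genotype_observation(sim, 500.0, rng, fs=fs, qd=qd)
    joint = joint_observation(sim, obs, fs, qd)
    ex_i = [ExonicSite(s, frozenset(["G"])) for s in obs.sites]
    ex_ii = [ExonicSite(s, frozenset(["G"])) for s in joint.sites]
    set_i = {(s.chrom, s.pos) for s in select_informative(ex_i, Strategy.I, PARENT_BREEDS)}
    set_ii = {(s.chrom, s.pos) for s in select_informative(ex_ii, Strategy.II, PARENT_BREEDS)}
    assert set_i == set_ii
    truth = {(s.chrom, s.pos) for s in true_informative_snps(sim)}
    assert set_i == truth
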