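"""SNP filtering, GRM, association scan, thresholds, clumping, loci,
candidate windows and haplotype contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hyperphen import SimulationConfig, simulate_population
from hyperphen.genetics import (
    GenotypeMatrix,
    association_scan,
    candidate_window,
    clump_leads,
    compute_grm,
    define_loci,
    filter_snps,
    haplotype_compare,
    ld_r2,
    read_vcf,
    thresholds_from_N,
)
from hyperphen.synthetic_data import write_gff3, write_vcf

from conftest import clump_oracle, grm_oracle, loci_oracle


def tiny_panel(dosage, chrom=None, pos=None):
    dosage = np.asarray(dosage, dtype=float)
    m = dosage.shape[1]
    return GenotypeMatrix(
        np.array([f"s{j}" for j in range(m)], dtype=object),
        np.array(chrom or ["chr01"] * m, dtype=object),
        np.array(pos or np.arange(1, m + 1) * 1000),
        dosage,
    )


class TestFilterSnps:
    def test_low_maf_removed(self):
        # freq 0.04 in 50 accessions (4 het carriers)
        col = np.zeros(50)
        col[:4] = 1.0
        with pytest.warns(UserWarning, match="all SNPs removed"):
            g = filter_snps(tiny_panel(col[:, None]), mac_min=1)
        assert g.n_snps == 0

    def test_few_carriers_removed(self):
        col = np.zeros(50)
        col[:5] = 2.0  # MAF 0.1 but only 5 carriers
        with pytest.warns(UserWarning, match="all SNPs removed"):
            g = filter_snps(tiny_panel(col[:, None]))
        assert g.n_snps == 0

    def test_matches_per_snp_count_oracle(self, rng):
        dosage = rng.binomial(2, rng.uniform(0.01, 0.5, 60), size=(40, 60))
        g = filter_snps(tiny_panel(dosage))
        kept = set(g.snp_ids)
        for j in range(60):
            col = dosage[:, j].astype(float)
            f = col.mean() / 2
            maf = min(f, 1 - f)
            minor = col if f <= 0.5 else 2 - col
            carriers = (minor > 0).sum()
            assert ((maf >= 0.05) and (carriers >= 6)) == (f"s{j}" in kept)

    def test_orientation_caps_maf(self, rng):
        dosage = rng.binomial(2, 0.9, size=(80, 5)).astype(float)
        g = filter_snps(tiny_panel(dosage))
        assert (g.maf <= 0.5 + 1e-12).all()


class TestGRM:
    def test_matches_double_loop_oracle(self, rng):
        dosage = rng.binomial(2, rng.uniform(0.1, 0.5, 12), size=(9, 12))
        K = compute_grm(tiny_panel(dosage))
        np.testing.assert_allclose(K, grm_oracle(dosage), atol=1e-12)

    def test_symmetric_psd_unit_diagonal(self, rng):
        dosage = rng.binomial(2, rng.uniform(0.1, 0.5, 300), size=(50, 300))
        K = compute_grm(tiny_panel(dosage))
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        assert K.diagonal().mean() == pytest.approx(1.0, abs=0.05)

    def test_identical_rows_maximally_related(self, rng):
        dosage = rng.binomial(2, rng.uniform(0.2, 0.5, 400),
                              size=(20, 400)).astype(float)
        dosage[1] = dosage[0]
        K = compute_grm(tiny_panel(dosage))
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-10)


class TestAssociationScan:
    def test_null_p_values_uniform(self):
        cfg = SimulationConfig(seed=5, n_accessions=200, n_snps=5000,
                               h2=(0.0, 0.0), r_g=0.0)
        pop = simulate_population(cfg)
        out = association_scan(pop.geno, pop.traits["y1"])
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01

    def test_planted_qtl_is_top_hit(self):
        """A QTL explaining 20% of phenotypic variance at n=500 is the
        study-wide minimum P in at least 18 of 20 replicates."""
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_accessions=500, n_snps=1000,
                                   h2=(0.2, 0.2), r_g=0.0, n_qtl=1,
                                   qtl_share=1.0)
            pop = simulate_population(cfg)
            out = association_scan(pop.geno, pop.traits["y1"])
            top = out.loc[out["p"].idxmin(), "snp"]
            hits += top == pop.qtl["snp"].iloc[0]
        assert hits >= 18

    def test_zero_variance_phenotype_raises(self):
        pop = simulate_population(SimulationConfig(seed=0, n_accessions=30,
                                                   n_snps=50))
        with pytest.raises(ValueError, match="zero-variance"):
            association_scan(pop.geno, np.ones(30))


class TestThresholds:
    def test_basic(self):
        assert thresholds_from_N(1e6) == (1e-6, pytest.approx(5e-8))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n=st.floats(1, 1e8))
    def test_significant_is_5_percent_of_suggestive(self, n):
        suggestive, significant = thresholds_from_N(n)
        assert significant == pytest.approx(0.05 * suggestive, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            thresholds_from_N(0)


def ld_panel(seed, n_snps=200, n_acc=300):
    cfg = SimulationConfig(seed=seed, n_accessions=n_acc, n_snps=n_snps,
                           h2=(0.5, 0.5), r_g=0.5, n_qtl=3, qtl_share=0.7,
                           ld_block_size=8, ld_resample=0.2)
    return simulate_population(cfg)


class TestClumpLeads:
    def test_correlated_pair_keeps_lower_p(self, rng):
        base = rng.binomial(2, 0.4, 200).astype(float)
        near = base.copy()
        flip = rng.random(200) < 0.05
        near[flip] = rng.binomial(2, 0.4, flip.sum())
        geno = tiny_panel(np.column_stack([base, near]))
        assert ld_r2(geno, "s0", "s1") > 0.25
        assoc = pd.DataFrame({
            "snp": ["s0", "s1"], "chrom": ["chr01"] * 2,
            "pos": [1000, 2000], "p": [1e-9, 1e-7],
        })
        leads = clump_leads(assoc, geno, suggestive=1e-5, min_support=0)
        assert leads["snp"].tolist() == ["s0"]

    def test_unsupported_lead_dropped(self, rng):
        pop = ld_panel(3)
        assoc = association_scan(pop.geno, pop.traits["y1"])
        with_support = clump_leads(assoc, pop.geno, suggestive=1e-5,
                                   support_p=1e-3, min_support=3)
        demanding = clump_leads(assoc, pop.geno, suggestive=1e-5,
                                support_p=1e-3, min_support=100)
        assert len(demanding) == 0
        assert set(demanding["snp"]).issubset(set(with_support["snp"]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        pop = ld_panel(seed)
        assoc = association_scan(pop.geno, pop.traits["y1"])
        leads = clump_leads(assoc, pop.geno, suggestive=1e-4,
                            support_p=1e-3, min_support=3)
        expected = clump_oracle(assoc, pop.geno.dosage, pop.geno.snp_ids,
                                suggestive=1e-4, support_p=1e-3, min_support=3)
        assert leads["snp"].tolist() == expected

    def test_row_order_invariance(self, rng):
        pop = ld_panel(5)
        assoc = association_scan(pop.geno, pop.traits["y1"])
        shuffled = assoc.sample(frac=1.0, random_state=9)
        a = clump_leads(assoc, pop.geno, suggestive=1e-4, min_support=0)
        b = clump_leads(shuffled, pop.geno, suggestive=1e-4, min_support=0)
        assert a["snp"].tolist() == b["snp"].tolist()


class TestDefineLoci:
    def test_printed_example(self):
        df = pd.DataFrame({
            "snp": ["a", "b", "c"], "chrom": ["chr01"] * 3,
            "pos": [1_000_000, 1_200_000, 1_900_000],
        })
        loci = define_loci(df).loci
        assert len(loci) == 2
        assert loci.iloc[0][["start", "end"]].tolist() == [1_000_000, 1_200_000]
        assert loci.iloc[1][["start", "end"]].tolist() == [1_900_000, 1_900_000]

    def test_single_snp_singleton_locus(self):
        df = pd.DataFrame({"snp": ["x"], "chrom": ["chr05"], "pos": [123]})
        ls = define_loci(df)
        assert len(ls.loci) == 1
        assert ls.loci.iloc[0]["lead_snp"] == "x"

    def test_lead_is_lowest_p(self):
        df = pd.DataFrame({
            "snp": ["a", "b"], "chrom": ["chr01"] * 2,
            "pos": [100, 200], "p": [1e-5, 1e-9],
        })
        assert define_loci(df).loci.iloc[0]["lead_snp"] == "b"

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_union_find(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        chrom = rng.choice(["chr01", "chr02", "chr03"], n)
        pos = rng.integers(1, 5_000_000, n)
        df = pd.DataFrame({
            "snp": [f"s{i}" for i in range(n)], "chrom": chrom, "pos": pos,
        }).drop_duplicates(["chrom", "pos"])
        ls = define_loci(df)
        ls.validate()
        got = sorted(
            (r.chrom, r.start, r.end, r.n_snps)
            for r in ls.loci.itertuples(index=False)
        )
        assert got == loci_oracle(df["chrom"].to_numpy(), df["pos"].to_numpy(),
                                  300_000)
        assert ls.assignment.size == len(df)  # every SNP assigned once


class TestCandidateWindow:
    @pytest.fixture()
    def annotation(self, tmp_path):
        genes = pd.DataFrame({
            "gene_id": ["near", "far", "inside"],
            "chrom": ["chr09"] * 3,
            "start": [1_107_000, 1_250_000, 1_050_000],
            "end": [1_109_000, 1_260_000, 1_060_000],
        })
        return write_gff3(genes, tmp_path / "genes.gff3")

    def test_flank_membership(self, annotation):
        # lead at 1.1 Mb: 'near' is 7 kb away, 'inside' within the window,
        # 'far' starts 150 kb away
        hits = candidate_window("chr09", 1_100_000, annotation)
        assert hits == ["inside", "near"]

    def test_random_intervals_match_overlap_oracle(self, tmp_path, rng):
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(40)],
            "chrom": rng.choice(["chr01", "chr02"], 40),
            "start": rng.integers(1, 2_000_000, 40),
        })
        genes["end"] = genes["start"] + rng.integers(500, 20_000, 40)
        path = write_gff3(genes, tmp_path / "r.gff3")
        from hyperphen.genetics import load_annotation

        db = load_annotation(path)
        for _ in range(10):
            chrom = rng.choice(["chr01", "chr02"])
            pos = int(rng.integers(1, 2_000_000))
            hits = set(candidate_window(chrom, pos, db))
            lo, hi = pos - 100_000, pos + 100_000
            expected = {
                r.gene_id for r in genes.itertuples(index=False)
                if r.chrom == chrom and r.end >= lo and r.start <= hi
            }
            assert hits == expected

    def test_absent_chromosome_warns_empty(self, annotation):
        with pytest.warns(UserWarning, match="absent"):
            assert candidate_window("chr12", 500, annotation) == []


class TestHaplotypeCompare:
    def test_shifted_groups_detected(self):
        detections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            dosage = np.r_[np.zeros((200, 2)), np.full((200, 2), 2.0)]
            y = np.r_[rng.normal(0, 1, 200), rng.normal(1, 1, 200)]
            res = haplotype_compare(dosage, y)
            detections += res.p_value < 0.01
        assert detections >= 19

    def test_null_p_uniform_over_seeds(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            dosage = np.r_[np.zeros((80, 2)), np.full((80, 2), 2.0)]
            ps.append(haplotype_compare(dosage, rng.normal(size=160)).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_group_excluded(self):
        dosage = np.r_[np.zeros((40, 1)), np.ones((40, 1)), np.full((5, 1), 2.0)]
        y = np.arange(85, dtype=float)
        res = haplotype_compare(dosage, y)
        assert set(res.groups["haplotype"]) == {"0", "1"}

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="haplotype groups"):
            haplotype_compare(np.zeros((50, 2)), np.arange(50.0))


class TestVcfRoundTrip:
    def test_dosages_survive(self, tmp_path):
        pop = simulate_population(
            SimulationConfig(seed=2, n_accessions=25, n_snps=40)
        )
        path = write_vcf(pop.geno, tmp_path / "panel.vcf")
        back = read_vcf(path)
        np.testing.assert_array_equal(back.dosage, pop.geno.dosage)
        assert list(back.snp_ids) == list(pop.geno.snp_ids)
        assert back.accessions == pop.geno.accessions
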