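import numpy as np
import pytest

from crypticex import junctions
from crypticex.junctions import count_alignments, parse_spliced_alignment
from crypticex.simulate import (
    CohortDesign,
    GenoDesign,
    GroupDesign,
    SampleParams,
    simulate_abundance,
    simulate_amplicon_reads,
    simulate_cohort,
    simulate_genotype_cohort,
    simulate_rnaseq_sample,
)


class TestSampleParams:
    def test_rates_validated(self):
        with pytest.raises(ValueError):
            SampleParams(psi_true=1.2)
        with pytest.raises(ValueError):
            SampleParams(depth=0)

    def test_read_too_short_for_overhangs(self):
        with pytest.raises(ValueError):
            SampleParams(read_length=11)


class TestRnaseqSample:
    def test_psi_zero_gives_no_ce_junction_reads(self, locus):
        _, truth = simulate_rnaseq_sample(
            locus, SampleParams(psi_true=0.0, depth=300, seed=1)
        )
        assert truth.junction_counts["e20-CE128"] == 0
        assert truth.junction_counts["e20-CE178"] == 0
        assert truth.junction_counts["CE-e21"] == 0

    def test_psi_one_gives_no_exclusion_reads(self, locus):
        _, truth = simulate_rnaseq_sample(
            locus, SampleParams(psi_true=1.0, depth=200, seed=2)
        )
        assert truth.junction_counts["e20-e21"] == 0
        assert truth.junction_counts["CE-e21"] > 0

    def test_byte_identical_given_seed(self, locus, tmp_path):
        p = SampleParams(psi_true=0.3, depth=300, duplicate_rate=0.1, seed=17)
        a, b = str(tmp_path / "a.sam"), str(tmp_path / "b.sam")
        simulate_rnaseq_sample(locus, p, out_sam=a)
        simulate_rnaseq_sample(locus, p, out_sam=b)
        assert open(a, "rb").read() == open(b, "rb").read()

    def test_truth_conserves_junction_reads(self, locus):
        _, truth = simulate_rnaseq_sample(
            locus, SampleParams(psi_true=0.4, depth=500, seed=4)
        )
        # each junction-spanning read spans exactly one named junction at
        # the default read length, so counts sum to the read tally
        assert sum(truth.junction_counts.values()) == truth.n_junction_reads

    def test_depth_controls_junction_reads(self, locus):
        _, truth = simulate_rnaseq_sample(
            locus, SampleParams(psi_true=0.2, depth=2_000, seed=5)
        )
        assert truth.n_junction_reads == pytest.approx(2_000, rel=0.1)

    def test_deep_sample_recovers_psi(self, locus):
        from crypticex.cecall import psi_ce

        recs, truth = simulate_rnaseq_sample(
            locus, SampleParams(psi_true=0.3, depth=10_000, seed=42)
        )
        t = count_alignments(
            [parse_spliced_alignment(r) for r in recs], locus
        )
        assert psi_ce(t) == pytest.approx(0.3, abs=0.02)

    def test_unspliced_reads_show_up_as_intron_body(self, locus):
        _, truth = simulate_rnaseq_sample(
            locus,
            SampleParams(psi_true=0.0, depth=300, unspliced_rate=0.5, seed=6),
        )
        assert truth.n_intron_body_reads > 0


class TestCohort:
    def test_null_group_has_zero_ce_reads(self, locus):
        design = CohortDesign(
            groups=(GroupDesign("control", 5, ("point", 0.0), 0.0),),
            defaults=SampleParams(depth=200),
            seed=0,
        )
        _, truth = simulate_cohort(locus, design)
        assert (truth["psi_true"] == 0).all()
        assert (truth[["e20-CE128", "e20-CE178", "CE-e21"]] == 0).all().all()

    def test_prevalence_controls_positive_fraction(self, locus):
        design = CohortDesign(
            groups=(GroupDesign("ftld", 40, ("beta", 2, 8), 0.5),),
            defaults=SampleParams(depth=200),
            seed=1,
        )
        _, truth = simulate_cohort(locus, design)
        frac = (truth["psi_true"] > 0).mean()
        # binomial 95% band around 0.5 at n=40
        assert 0.5 - 1.96 * np.sqrt(0.25 / 40) <= frac <= 0.5 + 1.96 * np.sqrt(0.25 / 40)

    def test_truth_table_deterministic(self, locus):
        design = CohortDesign(
            groups=(GroupDesign("g", 4, ("beta", 2, 8), 0.5),),
            defaults=SampleParams(depth=100),
            seed=9,
        )
        _, t1 = simulate_cohort(locus, design)
        _, t2 = simulate_cohort(locus, design)
        assert t1.equals(t2)

    def test_empty_group_list_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(groups=())


class TestAmplicon:
    def test_homozygote_rejected(self, locus):
        with pytest.raises(ValueError):
            simulate_amplicon_reads(locus, ("C", "C"), 1.0, 100)

    def test_zero_reads(self, locus):
        recs, truth = simulate_amplicon_reads(locus, ("C", "G"), 1.0, 0)
        assert recs == []
        assert all(v == 0 for v in truth.values())

    def test_odds_ratio_sets_risk_share(self, locus):
        _, truth = simulate_amplicon_reads(locus, ("C", "G"), 3.0, 3_000, seed=1)
        share = truth["ce_risk"] / (truth["ce_risk"] + truth["ce_ref"])
        assert share == pytest.approx(0.75, abs=0.03)

    def test_symmetric_null(self, locus):
        _, truth = simulate_amplicon_reads(locus, ("C", "G"), 1.0, 4_000, seed=2)
        share = truth["ce_risk"] / (truth["ce_risk"] + truth["ce_ref"])
        assert share == pytest.approx(0.5, abs=0.03)


class TestGenotypes:
    def test_perfect_ld_gives_identical_doses(self, locus):
        design = GenoDesign(n_individuals=100, r2_link=1.0, seed=0)
        _, truth = simulate_genotype_cohort(locus, design)
        assert (truth["snp_ce_dose"] == truth["snp_intron_dose"]).all()
        assert (truth["snp_ce_dose"] == truth["haplotype_dose"]).all()

    def test_risk_homozygotes_carry_3_to_5_extra_units(self, locus):
        design = GenoDesign(n_individuals=300, r2_link=1.0, seed=1)
        geno, truth = simulate_genotype_cohort(locus, design)
        hom = truth["haplotype_dose"] == 2
        extras = geno.loc[hom, "repeat_extra"]
        assert len(extras) > 0
        for e1, e2 in extras:
            assert 3 <= e1 <= 5 and 3 <= e2 <= 5
        ref_hom = truth["haplotype_dose"] == 0
        for e1, e2 in geno.loc[ref_hom, "repeat_extra"]:
            assert 0 <= e1 <= 2 and 0 <= e2 <= 2

    def test_vcf_round_trip_matches_memory_table(self, locus, tmp_path):
        from crypticex.haplotypes import read_genotypes_vcf

        path = str(tmp_path / "g.vcf")
        design = GenoDesign(n_individuals=50, r2_link=0.8, seed=2)
        geno, _ = simulate_genotype_cohort(locus, design, out_vcf=path)
        table = read_genotypes_vcf(path)
        assert table.individuals == list(geno["individual"])
        for i, gt in enumerate(geno["snp_ce"]):
            assert sorted(table.genotypes["snp_ce"][i]) == sorted(gt)

    def test_vcf_deterministic(self, locus, tmp_path):
        a, b = str(tmp_path / "a.vcf"), str(tmp_path / "b.vcf")
        design = GenoDesign(n_individuals=30, seed=5)
        simulate_genotype_cohort(locus, design, out_vcf=a)
        simulate_genotype_cohort(locus, design, out_vcf=b)
        assert open(a, "rb").read() == open(b, "rb").read()

    def test_r2_bounds_validated(self):
        with pytest.raises(ValueError):
            GenoDesign(r2_link=1.5)


class TestAbundance:
    def test_noiseless_line(self):
        df = simulate_abundance([2], beta0=1.0, beta1=0.175, sigma=0.0)
        assert df["abundance"].iloc[0] == pytest.approx(1.35)

    def test_dose_domain_checked(self):
        with pytest.raises(ValueError):
            simulate_abundance([0, 3], 0.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            simulate_abundance([0, 1], 0.0, 0.1, -0.1)
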