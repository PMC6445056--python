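import numpy as np
import pytest
from scipy import stats as sps

from tailsweep import (
    CohortSimConfig,
    fit_association,
    parse_repeatmasker_out,
    plant_retrocopy,
    random_gene,
    simulate_cohort,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_repeat_annotation,
)
from tailsweep.repeats import union_length


class TestCohortConfig:
    def test_sweep_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="sweep_interval"):
            CohortSimConfig(chrom_length=1000, n_sites=10, sweep_interval=(500, 2000))

    def test_too_many_sites_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            CohortSimConfig(chrom_length=1000, n_sites=2000)


class TestSimulateCohort:
    def test_same_seed_byte_identical(self, tmp_path):
        config = CohortSimConfig(
            n_per_pop=5, chrom_length=100_000, n_sites=300, seed=9
        )
        a = simulate_cohort(config, tmp_path / "a")
        b = simulate_cohort(config, tmp_path / "b")
        assert a.vcf_path.read_bytes() == b.vcf_path.read_bytes()
        assert a.manifest_path.read_bytes() == b.manifest_path.read_bytes()

    def test_mean_fst_matches_balding_nichols_expectation(self, tmp_path):
        """Per-site Wright FST averaged over true frequencies should match
        the analytic expectation F/(2−F) for two populations drifting
        independently with parameter F (each has frequency variance pqF)."""
        config = CohortSimConfig(
            n_per_pop=4, chrom_length=2_000_000, n_sites=10_000, drift_F=0.01, seed=2
        )
        cohort = simulate_cohort(config, tmp_path)
        f = {p: np.array(v) for p, v in cohort.truth.alt_freq.items()}
        fa, fb = f["selected"], f["sister"]
        pbar = (fa + fb) / 2
        ht = 2 * pbar * (1 - pbar)
        hs = fa * (1 - fa) + fb * (1 - fb)
        per_site = (ht - hs)[ht > 0] / ht[ht > 0]
        expected = 0.01 / (2 - 0.01)
        assert per_site.mean() == pytest.approx(expected, abs=1e-3)

    def test_fixed_difference_gives_fst_one(self):
        from tailsweep import window_fst

        assert window_fst([1.0], [0.0]) == 1.0

    def test_genotypes_consistent_with_truth_frequencies(self, tmp_path):
        """Aggregated chi-square goodness of fit of per-site ALT allele
        counts against Binomial(2n, f_true) is not rejected at α = 0.001."""
        config = CohortSimConfig(
            n_per_pop=30, chrom_length=1_000_000, n_sites=2_000, seed=4
        )
        cohort = simulate_cohort(config, tmp_path)
        from tailsweep import read_manifest, read_vcf

        table = read_vcf(str(cohort.vcf_path), cohort.manifest)
        for pop in table.pops:
            f_true = np.array(cohort.truth.alt_freq[pop])
            n = table.n_alleles[pop].astype(float)
            obs = table.f_alt[pop] * n
            exp = n * f_true
            var = n * f_true * (1 - f_true)
            ok = var >= 5  # normal approximation support
            chi2 = np.sum((obs[ok] - exp[ok]) ** 2 / var[ok])
            p = sps.chi2.sf(chi2, df=int(ok.sum()))
            assert p > 0.001

    def test_truth_frequencies_in_bounds(self, tmp_path):
        config = CohortSimConfig(n_per_pop=3, chrom_length=50_000, n_sites=200, seed=5)
        cohort = simulate_cohort(config, tmp_path)
        for freqs in cohort.truth.alt_freq.values():
            arr = np.array(freqs)
            assert ((arr >= 0) & (arr <= 1)).all()


class TestSimulatePhenotypes:
    def test_noiseless_recovery_to_machine_precision(self):
        geno = simulate_genotypes(60, {"m1": 0.4}, seed=1)
        table, _ = simulate_phenotypes(
            geno, {"m1": -3.3}, beta_age=0.5, beta_sex=1.0, noise_sd=0.0, seed=1
        )
        res = fit_association(table, "m1", "tail_length_cm", "additive", adjust=True)
        assert res.beta == pytest.approx(-3.3, abs=1e-10)

    def test_mean_estimate_within_three_se(self):
        """Over 20 seeds the mean OLS estimate should sit within 3 standard
        errors (closed form) of the planted effect."""
        betas, ses = [], []
        for seed in range(20):
            geno = simulate_genotypes(116, {"m1": 0.5}, seed=seed)
            table, _ = simulate_phenotypes(
                geno, {"m1": -3.3}, beta_age=0.5, beta_sex=1.0, noise_sd=1.0, seed=seed
            )
            res = fit_association(table, "m1", "tail_length_cm", adjust=True)
            betas.append(res.beta)
            ses.append(res.se)
        se_mean = np.mean(ses) / np.sqrt(len(betas))
        assert np.mean(betas) == pytest.approx(-3.3, abs=3 * se_mean)

    def test_constant_genotypes_inestimable(self):
        import pandas as pd

        geno = pd.DataFrame({"sample": [f"s{i}" for i in range(30)], "m1": [2] * 30})
        table, _ = simulate_phenotypes(
            geno, {"m1": 1.0}, beta_age=0.0, beta_sex=0.0, noise_sd=1.0, seed=0
        )
        res = fit_association(table, "m1", "tail_length_cm")
        assert not res.estimable
        assert np.isnan(res.beta)

    def test_bad_genotype_codes_rejected(self):
        import pandas as pd

        geno = pd.DataFrame({"sample": ["a", "b", "c"], "m1": [0, 3, 1]})
        with pytest.raises(ValueError, match="genotype codes"):
            simulate_phenotypes(
                geno, {"m1": 1.0}, beta_age=0.0, beta_sex=0.0, noise_sd=1.0, seed=0
            )


class TestPlantRetrocopy:
    def test_identity_one_inserts_exact_mrna(self):
        rng = np.random.default_rng(0)
        gene = random_gene("g", rng, n_exons=3)
        host = "A" * 500
        new_host, truth = plant_retrocopy(gene, host, 250, 1.0, False, seed=1)
        assert new_host[250 : 250 + len(gene.mrna())] == gene.mrna()
        assert truth.start == 250 and not truth.intron_retained

    def test_retain_introns_inserts_full_sequence(self):
        rng = np.random.default_rng(0)
        gene = random_gene("g", rng, n_exons=4)
        new_host, truth = plant_retrocopy(gene, "C" * 100, 50, 1.0, True, seed=1)
        assert new_host[50 : 50 + len(gene.sequence)] == gene.sequence

    def test_substitution_count_matches_identity(self):
        rng = np.random.default_rng(1)
        gene = random_gene("g", rng, n_exons=5)
        mrna = gene.mrna()
        new_host, _ = plant_retrocopy(gene, "", 0, 0.85, False, seed=2)
        diffs = sum(a != b for a, b in zip(new_host, mrna))
        assert diffs == round(0.15 * len(mrna))

    def test_insert_outside_host_rejected(self):
        rng = np.random.default_rng(0)
        gene = random_gene("g", rng, n_exons=2)
        with pytest.raises(ValueError, match="insert_at"):
            plant_retrocopy(gene, "ACGT", 10, 0.9, False, seed=0)


class TestSimulateRepeatAnnotation:
    def test_single_class_hits_coverage_target(self, tmp_path):
        text = simulate_repeat_annotation(
            1_000_000, {"LINE/RTE-BovB": 0.2132}, seed=3
        )
        path = tmp_path / "rm.out"
        path.write_text(text)
        anns = parse_repeatmasker_out(path)
        covered = union_length([(a.start, a.end) for a in anns])
        assert covered == pytest.approx(213_200, abs=10_000)
        assert all(a.class_family == "LINE/RTE-BovB" for a in anns)

    def test_realized_coverage_within_one_percent_of_targets(self, tmp_path):
        targets = {"LINE/RTE-BovB": 0.10, "LINE/L1": 0.14, "SINE/MIR": 0.05}
        path = tmp_path / "rm.out"
        path.write_text(simulate_repeat_annotation(500_000, targets, seed=6))
        anns = parse_repeatmasker_out(path)
        for cls, frac in targets.items():
            got = union_length(
                [(a.start, a.end) for a in anns if a.class_family == cls]
            ) / 500_000
            assert got == pytest.approx(frac, abs=0.01)

    def test_elements_do_not_overlap(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(
            simulate_repeat_annotation(200_000, {"LINE/L1": 0.3, "SINE/MIR": 0.2}, seed=7)
        )
        anns = sorted(parse_repeatmasker_out(path), key=lambda a: a.start)
        for a, b in zip(anns, anns[1:]):
            assert a.end <= b.start

    def test_empty_targets_header_only(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(simulate_repeat_annotation(10_000, {}, seed=0))
        assert parse_repeatmasker_out(path) == []

    def test_same_seed_identical(self):
        a = simulate_repeat_annotation(50_000, {"LINE/L1": 0.1}, seed=11)
        b = simulate_repeat_annotation(50_000, {"LINE/L1": 0.1}, seed=11)
        assert a == b

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="more than 1"):
            simulate_repeat_annotation(1000, {"LINE/L1": 0.8, "SINE/MIR": 0.4}, seed=0)
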